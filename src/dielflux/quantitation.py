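"""Absolute transcript quantitation and fold-change analysis.

Gene read counts are converted to mRNA molecules per bacterial cell via two
internal spike-in standards of known copy number added before extraction::

    tpc(g, s) = reads(g, s) / Σ_std reads(std, s)
                × Σ_std copies_added(std) / cells_extracted(s)

which cancels sequencing depth and library-size effects.  Per-cell
(absolute) and proportion-of-transcriptome (relative) noon:night fold
changes are then compared gene by gene: genes can be significantly up in
absolute terms yet significantly down as a share of the transcriptome
("masked" regulation) when the total mRNA per cell itself cycles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FeatureMatrix

__all__ = [
    "SpikeInfo",
    "TpcResult",
    "transcripts_per_cell",
    "spike_info_from_table",
    "znormalize",
    "fold_change_analysis",
    "noon_night_groups",
]


def noon_night_groups(columns, clock_offset: float = 0.0) -> tuple[list, list]:
    """Noon and night sample groups from ``t{HH}_rep{j}`` column labels.

    Noon: all samples at clock 12:00 (two timepoints over two cycles).
    Night: the midnight closing each cycle (the last two midnight
    timepoints), pairing each noon with the following midnight.  The very
    first midnight precedes full bacterial drawdown of accumulated
    metabolites and carries systematically elevated inventories, so it is
    not a steady-state night reference.  Missing replicates simply shrink a
    group (available-case means).
    """
    from .design import parse_sample_label

    times = np.array([parse_sample_label(c)[0] for c in columns])
    clocks = np.mod(times + clock_offset, 24.0)
    noon = [c for c, k in zip(columns, clocks) if k == 12.0]
    mid_times = sorted({t for t, k in zip(times, clocks) if k == 0.0})[-2:]
    night = [c for c, t, k in zip(columns, times, clocks)
             if k == 0.0 and t in mid_times]
    return noon, night


@dataclass
class SpikeInfo:
    """Spike-in standards: per-sample read counts and copies added."""

    spike_reads: pd.DataFrame   # standards x samples
    copies_added: np.ndarray    # molecules per standard
    cells_extracted: pd.Series  # per sample

    def __post_init__(self) -> None:
        self.copies_added = np.asarray(self.copies_added, dtype=float)
        if len(self.copies_added) != len(self.spike_reads):
            raise ValueError("copies_added must have one entry per standard")
        if (self.copies_added <= 0).any():
            raise ValueError("spike copies added must be > 0")


SPIKE_ROWS = ["spike_1", "spike_2"]
RRNA_ROW = "rrna"


def spike_info_from_table(matrix: FeatureMatrix, copies_added) -> tuple[pd.DataFrame, SpikeInfo]:
    """Split a read table with reserved spike/rRNA rows into genes + SpikeInfo."""
    missing = [r for r in SPIKE_ROWS if r not in matrix.values.index]
    if missing:
        raise ValueError(f"read table lacks spike rows {missing}")
    spikes = SpikeInfo(spike_reads=matrix.values.loc[SPIKE_ROWS],
                       copies_added=copies_added,
                       cells_extracted=matrix.cell_counts)
    drop = SPIKE_ROWS + ([RRNA_ROW] if RRNA_ROW in matrix.values.index else [])
    genes = matrix.values.drop(index=drop)
    return genes, spikes


@dataclass
class TpcResult:
    """Transcripts-per-cell matrix plus per-sample diagnostics."""

    tpc: pd.DataFrame
    excluded_samples: list = field(default_factory=list)
    diagnostics: pd.DataFrame | None = None


def transcripts_per_cell(reads: pd.DataFrame, spikes: SpikeInfo) -> TpcResult:
    """Scale gene reads to absolute per-cell transcript numbers.

    Samples with zero total spike reads cannot be calibrated; they are
    excluded and reported, never imputed.  The diagnostics table compares
    the observed ratio of the two standards' reads to the ratio of copies
    added (they should agree when recovery is unbiased).
    """
    if list(reads.columns) != list(spikes.spike_reads.columns):
        raise ValueError("reads and spike table must share sample columns")
    spike_tot = spikes.spike_reads.sum(axis=0)
    excluded = list(spike_tot.index[spike_tot <= 0])
    if excluded:
        warnings.warn(
            f"samples excluded for zero spike-in reads: {excluded}", stacklevel=2
        )
    keep = [c for c in reads.columns if c not in excluded]
    copies_total = spikes.copies_added.sum()
    tpc = (reads[keep] / spike_tot[keep]) * copies_total / spikes.cells_extracted[keep]

    diag = None
    if len(spikes.spike_reads) == 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            read_ratio = (spikes.spike_reads.iloc[0] / spikes.spike_reads.iloc[1])
        diag = pd.DataFrame({
            "spike_read_ratio": read_ratio,
            "copies_ratio": spikes.copies_added[0] / spikes.copies_added[1],
        })
    return TpcResult(tpc=tpc, excluded_samples=excluded, diagnostics=diag)


def znormalize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Per-feature auto-scaling to mean 0, SD 1 (ddof = 1).

    Zero-variance features are emitted as all-zero rows and returned in the
    flag list with a warning.
    """
    values = matrix.astype(float)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    flagged = list(values.index[sd == 0])
    if flagged:
        warnings.warn(f"zero-variance features emitted as zeros: {flagged[:5]}"
                      f"{'...' if len(flagged) > 5 else ''}", stacklevel=2)
    safe_sd = sd.replace(0.0, 1.0)
    z = values.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[flagged] = 0.0
    return z, flagged


_QUADRANTS = ("concordant-up", "concordant-down", "masked-up", "masked-down", "null")


def fold_change_analysis(tpc: pd.DataFrame, noon_samples, night_samples,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Absolute vs relative noon:night comparison, per gene.

    Absolute fold change uses transcripts per cell; relative fold change
    uses each gene's per-sample proportion of the summed transcriptome.
    Two-sided Welch tests on log2 values, Benjamini-Hochberg adjusted
    separately per axis.  Quadrants: concordant-up/-down (both axes
    significant, same direction), masked-up (absolute up, relative down),
    masked-down (the converse), else null.  Genes with a zero group mean get
    an undefined fold change and are flagged.
    """
    noon_samples = list(noon_samples)
    night_samples = list(night_samples)
    if len(noon_samples) < 2 or len(night_samples) < 2:
        raise ValueError("need at least 2 samples per group")
    prop = tpc.div(tpc.sum(axis=0), axis=1)

    out = pd.DataFrame(index=tpc.index)
    for name, mat in (("abs", tpc), ("rel", prop)):
        g1 = mat[noon_samples].to_numpy(dtype=float)
        g0 = mat[night_samples].to_numpy(dtype=float)
        m1, m0 = g1.mean(axis=1), g0.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = m1 / m0
        fc[(m0 == 0) | (m1 == 0)] = np.nan
        valid = np.isfinite(fc) & (g1 > 0).all(axis=1) & (g0 > 0).all(axis=1)
        p = np.full(len(mat), np.nan)
        if valid.any():
            with np.errstate(divide="ignore", invalid="ignore"):
                res = stats.ttest_ind(np.log2(g1[valid]), np.log2(g0[valid]),
                                      axis=1, equal_var=False)
            p[valid] = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        q = np.full(len(mat), np.nan)
        if valid.any():
            q[valid] = multipletests(p[valid], method="fdr_bh")[1]
        out[f"{name}_fc"] = fc
        out[f"{name}_p"] = p
        out[f"{name}_q"] = q

    up_abs = (out.abs_q < alpha) & (out.abs_fc > 1)
    dn_abs = (out.abs_q < alpha) & (out.abs_fc < 1)
    up_rel = (out.rel_q < alpha) & (out.rel_fc > 1)
    dn_rel = (out.rel_q < alpha) & (out.rel_fc < 1)
    quadrant = np.where(
        out.abs_fc.isna() | out.rel_fc.isna(), "undefined",
        np.where(up_abs & up_rel, "concordant-up",
        np.where(dn_abs & dn_rel, "concordant-down",
        np.where(up_abs & dn_rel, "masked-up",
        np.where(dn_abs & up_rel, "masked-down", "null")))))
    out["quadrant"] = quadrant
    return out
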