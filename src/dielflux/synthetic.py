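"""Synthetic experiment generator with known ground truth.

Emulates the shape of the diel co-culture data so that every downstream
stage (normalisation, clustering, rhythm detection, fold-change analysis,
model fitting) can be exercised and validated without the deposited raw
data: 9 timepoints at 6-h spacing over 48 h, 3 replicates, 281 metabolite
NMR peaks over four temporal archetypes, 4,278 bacterial genes over three
archetypes, diel modulation of the total mRNA per cell, two internal
spike-in standards near 2.2% of mRNA reads, and ~17.5% residual rRNA.

Temporal archetypes (all on a dimensionless Z-like scale):

* ``M-1`` / ``M-2`` — monotone increase / decrease with a small diel ripple;
* ``M-3`` / ``M-4`` — truncated 24-h cosine peaking at mid-afternoon (18:00)
  / noon (12:00);
* ``G-1`` — truncated 24-h cosine peaking at noon;
* ``G-2`` — G-1 plus a decaying component elevated at the first samples;
* ``G-3`` — the decaying component only (non-diel declining).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .design import ExperimentDesign
from .io import FeatureMatrix
from .light import IrradianceProfile
from .model import (
    ModelParameters,
    SimConfig,
    canonical_variant,
    comparison_sample_times,
    simulate_batch,
)

__all__ = [
    "ArchetypeSpec",
    "GroundTruth",
    "default_metabolite_archetypes",
    "default_gene_archetypes",
    "archetype_profile",
    "largest_remainder",
    "generate_cell_counts",
    "generate_metabolite_table",
    "generate_transcript_reads",
    "generate_from_model",
    "archetype_pair_series",
    "expected_spike_share",
    "solve_spike_copies",
    "DEFAULT_PHASE_MEANS",
]

#: Mean total mRNA molecules per bacterial cell by clock phase (night,
#: mid-morning, noon, mid-afternoon).
DEFAULT_PHASE_MEANS = {0.0: 58.0, 6.0: 95.0, 12.0: 114.0, 18.0: 42.0}

#: Residual rRNA fraction of total reads and spike-in share of mRNA reads.
DEFAULT_RRNA_FRACTION = 0.175
DEFAULT_SPIKE_FRACTION = 0.022

DEFAULT_DEPTH = 19_200_000        # reads per library
DEFAULT_CELLS_EXTRACTED = 1e9     # bacterial cells per sample

#: Default within-replicate noise on the Z scale (free parameter of the
#: generator; the source data do not constrain it).
DEFAULT_NOISE_SD = 0.3


@dataclass(frozen=True)
class ArchetypeSpec:
    """One temporal archetype: shape parameters and its share of features."""

    id: str
    proportion: float
    amplitude: float = 1.0     # diel (truncated-cosine) amplitude, Z units
    phase: float = 12.0        # clock hour of the diel peak
    slope: float = 0.0         # linear trend, Z units per hour
    baseline: float = 0.0      # additive offset, Z units
    decay: float = 0.0         # amplitude of a decaying early component
    decay_tau: float = 9.0     # e-folding time of that component, hours

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if not 0 <= self.proportion <= 1:
            raise ValueError(f"proportion must be in [0, 1], got {self.proportion}")


def default_metabolite_archetypes() -> list[ArchetypeSpec]:
    """M-1..M-4 with cluster shares 102/73/59/47 of 281 peaks."""
    return [
        ArchetypeSpec("M-1", 102 / 281, amplitude=0.2, phase=12.0,
                      slope=3.0 / 48.0, baseline=-1.5),
        ArchetypeSpec("M-2", 73 / 281, amplitude=0.2, phase=12.0,
                      slope=-3.0 / 48.0, baseline=1.5),
        ArchetypeSpec("M-3", 59 / 281, amplitude=1.0, phase=18.0),
        ArchetypeSpec("M-4", 47 / 281, amplitude=1.0, phase=12.0),
    ]


def default_gene_archetypes() -> list[ArchetypeSpec]:
    """G-1..G-3 with shares proportional to 3294/756/271.

    The reported cluster sizes sum to 4,321 while the genome carries 4,278
    protein-coding genes; shares are therefore normalised proportions and
    the default gene table allocates 3261/749/268 by largest remainder.
    """
    total = 3294 + 756 + 271
    base = 0.3
    return [
        ArchetypeSpec("G-1", 3294 / total, amplitude=1.0, phase=12.0, baseline=base),
        ArchetypeSpec("G-2", 756 / total, amplitude=1.0, phase=12.0, baseline=base,
                      decay=1.2, decay_tau=9.0),
        ArchetypeSpec("G-3", 271 / total, amplitude=0.0, baseline=base,
                      decay=1.2, decay_tau=9.0),
    ]


def archetype_profile(spec: ArchetypeSpec, times, clock_offset: float = 0.0) -> np.ndarray:
    """Noise-free Z-scale profile of an archetype at elapsed ``times`` (h)."""
    t = np.asarray(times, dtype=float)
    clock = np.mod(t + clock_offset, 24.0)
    diel = np.maximum(np.cos(2.0 * np.pi * (clock - spec.phase) / 24.0), 0.0)
    out = spec.baseline + spec.slope * t + spec.amplitude * diel
    if spec.decay:
        out = out + spec.decay * np.exp(-t / spec.decay_tau)
    return out


def largest_remainder(total: int, proportions) -> np.ndarray:
    """Deterministic integer allocation of ``total`` over ``proportions``.

    Floors the exact shares, then hands out remaining units by descending
    fractional part (ties broken by list position).  Rejects proportions not
    summing to 1 within 1e-9.
    """
    p = np.asarray(proportions, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {p.sum()!r}, expected 1")
    exact = total * p
    counts = np.floor(exact).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_cell_counts(design: ExperimentDesign = ExperimentDesign(),
                         start_density: float = 0.87e5,
                         end_density: float = 1.9e5,
                         cv: float = 0.0,
                         seed=0) -> pd.Series:
    """Per-sample diatom densities (cells/mL).

    Expected densities interpolate exponentially from ``start_density`` to
    ``end_density`` across the sampling window (the reference culture grew
    ~2-fold, 0.87 to 1.9 × 10⁵ cells/mL over 48 h); replicate scatter is
    lognormal with the given coefficient of variation and unit mean.
    """
    for name, v in (("start_density", start_density), ("end_density", end_density)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    if cv < 0:
        raise ValueError(f"cv must be >= 0, got {cv}")
    rng = _rng(seed)
    frac = design.times / design.window
    expected = start_density * (end_density / start_density) ** frac
    labels = design.sample_labels()
    values = np.repeat(expected, design.n_replicates)
    if cv > 0:
        sigma2 = np.log1p(cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2),
                              size=values.shape)
        values = values * noise
    return pd.Series(values, index=labels, name="cells_per_ml")


@dataclass
class GroundTruth:
    """Generating truth emitted alongside every synthetic table."""

    archetype: pd.Series                  # feature id -> archetype id
    profiles: pd.DataFrame                # noise-free Z profiles, feature x timepoint
    cell_counts: pd.Series
    tpc_true: pd.DataFrame | None = None  # transcripts per cell, gene x timepoint
    spike_copies: np.ndarray | None = None
    rrna_fraction: float | None = None
    extras: dict = field(default_factory=dict)

    def to_files(self, stem) -> None:
        """Sidecar export: JSON summary plus TSV truth matrices."""
        import json
        from pathlib import Path

        stem = Path(stem)
        self.profiles.to_csv(stem.with_suffix(".truth_profiles.tsv"), sep="\t")
        if self.tpc_true is not None:
            self.tpc_true.to_csv(stem.with_suffix(".truth_tpc.tsv"), sep="\t")
        meta = {
            "archetype": self.archetype.to_dict(),
            "cell_counts": self.cell_counts.to_dict(),
            "spike_copies": None if self.spike_copies is None
            else list(map(float, self.spike_copies)),
            "rrna_fraction": self.rrna_fraction,
            **self.extras,
        }
        stem.with_suffix(".truth.json").write_text(json.dumps(meta, indent=1))


def _assign_archetypes(n_features: int, archetypes) -> tuple[np.ndarray, np.ndarray]:
    if n_features < len(archetypes):
        raise ValueError("need at least one feature per archetype")
    counts = largest_remainder(n_features, [a.proportion for a in archetypes])
    labels = np.repeat([a.id for a in archetypes], counts)
    return counts, labels


def generate_metabolite_table(design: ExperimentDesign = ExperimentDesign(),
                              n_peaks: int = 281,
                              archetypes=None,
                              noise_sd: float = DEFAULT_NOISE_SD,
                              seed=0,
                              cell_counts: pd.Series | None = None
                              ) -> tuple[FeatureMatrix, GroundTruth]:
    """Raw metabolite peak intensities with archetype ground truth.

    Each peak follows its archetype's Z profile; the emitted table holds raw
    intensities (per-cell abundance × cells sampled) so cell-count
    normalisation is exercised downstream.  Gaussian noise of ``noise_sd``
    (Z units) is added independently per replicate.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    archetypes = archetypes or default_metabolite_archetypes()
    rng = _rng(seed)
    if cell_counts is None:
        cell_counts = generate_cell_counts(design, seed=rng.integers(2**31))
    counts, labels = _assign_archetypes(n_peaks, archetypes)
    by_id = {a.id: a for a in archetypes}

    t = design.times
    profiles = np.vstack([
        archetype_profile(by_id[a], t, design.clock_offset) for a in labels
    ])  # (n_peaks, n_timepoints)
    feature_ids = [f"peak_{i + 1:04d}" for i in range(n_peaks)]

    base = 10.0 ** rng.uniform(3.0, 6.0, size=n_peaks)  # per-cell intensity scale
    noise = rng.normal(0.0, noise_sd, size=(n_peaks, design.n_samples)) if noise_sd else 0.0
    z_rep = np.repeat(profiles, design.n_replicates, axis=1) + noise
    per_cell = base[:, None] * np.maximum(1.0 + 0.25 * z_rep, 1e-3)
    intensity = per_cell * cell_counts.values[None, :]

    values = pd.DataFrame(intensity, index=feature_ids,
                          columns=design.sample_labels())
    matrix = FeatureMatrix(values=values, cell_counts=cell_counts.copy())
    truth = GroundTruth(
        archetype=pd.Series(labels, index=feature_ids, name="archetype"),
        profiles=pd.DataFrame(profiles, index=feature_ids,
                              columns=[f"t{int(x):02d}" for x in t]),
        cell_counts=cell_counts.copy(),
        extras={"counts_per_archetype": {a.id: int(c)
                                         for a, c in zip(archetypes, counts)}},
    )
    return matrix, truth


def _phase_mean_vector(design: ExperimentDesign, phase_means: dict) -> np.ndarray:
    clocks = design.clocks
    missing = sorted({float(c) for c in clocks} - {float(k) for k in phase_means})
    if missing:
        raise ValueError(
            f"total_mrna_per_cell lacks phase means for clock hours {missing}"
        )
    return np.array([phase_means[float(c)] for c in clocks])


def _gene_mrna_mass(design, phase_means, cells) -> np.ndarray:
    """Total gene mRNA molecules per sample (timepoint-major replicate order)."""
    totals = np.repeat(_phase_mean_vector(design, phase_means),
                       design.n_replicates)
    return totals * np.asarray(cells, dtype=float)


def solve_spike_copies(design: ExperimentDesign = ExperimentDesign(),
                       total_mrna_per_cell: dict | None = None,
                       spike_fraction_target: float = DEFAULT_SPIKE_FRACTION,
                       cells_extracted: float = DEFAULT_CELLS_EXTRACTED
                       ) -> np.ndarray:
    """Copies added per standard so the mean expected spike share of mRNA
    reads equals the target.

    The gene mRNA mass varies with the diel phase means, so the total spike
    mass ``S`` is found by root-finding on ``mean_s S/(S + G_s) = target``
    and split equally between the two standards.
    """
    if not 0 <= spike_fraction_target < 1:
        raise ValueError("spike_fraction_target must be in [0, 1)")
    phase_means = total_mrna_per_cell or DEFAULT_PHASE_MEANS
    cells = np.full(design.n_samples, cells_extracted)
    G = _gene_mrna_mass(design, phase_means, cells)
    if spike_fraction_target == 0:
        return np.zeros(2)

    def gap(S):
        return np.mean(S / (S + G)) - spike_fraction_target

    lo, hi = G.min() * 1e-9, G.max() * 1e3
    S = optimize.brentq(gap, lo, hi, xtol=1e-12 * G.mean(), rtol=1e-14)
    return np.array([S / 2.0, S / 2.0])


def expected_spike_share(design: ExperimentDesign = ExperimentDesign(),
                         total_mrna_per_cell: dict | None = None,
                         spike_copies: np.ndarray | None = None,
                         spike_fraction_target: float = DEFAULT_SPIKE_FRACTION,
                         cells_extracted: float = DEFAULT_CELLS_EXTRACTED
                         ) -> float:
    """Analytic expected spike-in share of mRNA (non-rRNA) reads, percent.

    Computed from the multinomial sampling probabilities, averaged over
    samples — not from a stochastic draw.
    """
    phase_means = total_mrna_per_cell or DEFAULT_PHASE_MEANS
    if spike_copies is None:
        spike_copies = solve_spike_copies(design, phase_means,
                                          spike_fraction_target, cells_extracted)
    S = float(np.sum(spike_copies))
    cells = np.full(design.n_samples, cells_extracted)
    G = _gene_mrna_mass(design, phase_means, cells)
    return float(np.mean(S / (S + G)) * 100.0)


def generate_transcript_reads(design: ExperimentDesign = ExperimentDesign(),
                              n_genes: int = 4278,
                              archetypes=None,
                              total_mrna_per_cell: dict | None = None,
                              spike_copies: np.ndarray | None = None,
                              spike_fraction_target: float = DEFAULT_SPIKE_FRACTION,
                              rrna_fraction: float = DEFAULT_RRNA_FRACTION,
                              depth: int = DEFAULT_DEPTH,
                              cells_extracted: float = DEFAULT_CELLS_EXTRACTED,
                              amplitude_sigma: float = 0.6,
                              seed=0) -> tuple[FeatureMatrix, GroundTruth]:
    """Gene read counts with spike-in standards, rRNA and ground truth.

    True transcripts-per-cell follow the gene archetype profiles with
    lognormal per-gene diel amplitudes (``amplitude_sigma`` on the log
    scale, so genes span weak to strong diel regulation), scaled per
    timepoint so the cell total matches the diel phase means.  Reads are
    drawn multinomially over {rRNA, spike-1, spike-2, genes} with
    probabilities proportional to the respective molecule masses.  The
    emitted table carries reserved rows ``spike_1``, ``spike_2`` and
    ``rrna``; cell counts are the bacterial cells extracted per sample.
    """
    if depth <= 0:
        raise ValueError(f"depth must be > 0, got {depth}")
    if not 0 <= rrna_fraction < 1:
        raise ValueError(f"rrna_fraction must be in [0, 1), got {rrna_fraction}")
    archetypes = archetypes or default_gene_archetypes()
    phase_means = total_mrna_per_cell or DEFAULT_PHASE_MEANS
    rng = _rng(seed)

    counts, labels = _assign_archetypes(n_genes, archetypes)
    by_id = {a.id: a for a in archetypes}
    t = design.times
    amp_jitter = rng.lognormal(mean=0.0, sigma=amplitude_sigma, size=n_genes)
    raw = np.vstack([
        archetype_profile(replace(by_id[a], amplitude=by_id[a].amplitude * j),
                          t, design.clock_offset)
        for a, j in zip(labels, amp_jitter)
    ])
    if (raw < 0).any():
        raise ValueError("gene archetype profiles must be non-negative")
    abundance = rng.lognormal(mean=0.0, sigma=1.2, size=n_genes)
    raw = raw * abundance[:, None]
    # scale each timepoint so the summed transcripts per cell hit the phase mean
    totals = _phase_mean_vector(design, phase_means)
    tpc = raw * (totals / raw.sum(axis=0))[None, :]

    gene_ids = [f"gene_{i + 1:04d}" for i in range(n_genes)]
    cells = pd.Series(np.full(design.n_samples, float(cells_extracted)),
                      index=design.sample_labels(), name="cells_extracted")
    if spike_copies is None:
        spike_copies = solve_spike_copies(design, phase_means,
                                          spike_fraction_target, cells_extracted)
    spike_copies = np.asarray(spike_copies, dtype=float)

    n_samples = design.n_samples
    reads = np.zeros((n_genes + 3, n_samples), dtype=int)  # rrna, s1, s2, genes
    tp_index = np.repeat(np.arange(design.n_timepoints), design.n_replicates)
    for s in range(n_samples):
        gene_mass = tpc[:, tp_index[s]] * cells.iloc[s]
        mrna_mass = spike_copies.sum() + gene_mass.sum()
        rrna_mass = rrna_fraction / (1.0 - rrna_fraction) * mrna_mass
        masses = np.concatenate(([rrna_mass], spike_copies, gene_mass))
        reads[:, s] = rng.multinomial(depth, masses / masses.sum())

    index = ["rrna", "spike_1", "spike_2"] + gene_ids
    values = pd.DataFrame(reads, index=index, columns=design.sample_labels())
    matrix = FeatureMatrix(values=values.astype(float), cell_counts=cells)
    truth = GroundTruth(
        archetype=pd.Series(labels, index=gene_ids, name="archetype"),
        profiles=pd.DataFrame(raw, index=gene_ids,
                              columns=[f"t{int(x):02d}" for x in t]),
        cell_counts=cells,
        tpc_true=pd.DataFrame(tpc, index=gene_ids,
                              columns=[f"t{int(x):02d}" for x in t]),
        spike_copies=spike_copies,
        rrna_fraction=rrna_fraction,
        extras={"counts_per_archetype": {a.id: int(c)
                                         for a, c in zip(archetypes, counts)},
                "depth": int(depth)},
    )
    return matrix, truth


def generate_from_model(params: ModelParameters, variant: str = "base",
                        design: ExperimentDesign = ExperimentDesign(),
                        noise_sd: float = DEFAULT_NOISE_SD,
                        seed=0,
                        config: SimConfig = SimConfig(),
                        profile: IrradianceProfile | None = None) -> dict:
    """Paired metabolite/transcript-proxy series drawn from the model itself.

    Samples P and U at the design timepoints and adds Gaussian replicate
    noise with standard deviation ``noise_sd`` × the sample standard
    deviation of each noise-free series.  The returned dict carries the
    noisy replicate series, the noise-free truth and the generating
    parameters (a fixture for parameter-recovery tests).
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    profile = profile or design.light
    variant = canonical_variant(variant)
    rng = _rng(seed)
    arrays = {f: np.array([getattr(params, f)]) for f in (
        *ModelParameters.BASE_FIELDS, "o_decay", "h_coef", "b_factor")}
    times = comparison_sample_times(design, config)
    P_s, U_s, _ = simulate_batch(arrays, variant, times, config, profile)
    met_true, gene_true = P_s[0], U_s[0]

    def noisy(series):
        reps = np.tile(series[:, None], (1, design.n_replicates))
        if noise_sd > 0:
            scale = noise_sd * np.std(series, ddof=1)
            reps = reps + rng.normal(0.0, scale, size=reps.shape)
        return reps

    return {
        "met_series": noisy(met_true),
        "gene_series": noisy(gene_true),
        "met_true": met_true,
        "gene_true": gene_true,
        "params": params,
        "variant": variant,
    }


#: Transcript archetype paired with each metabolite archetype, mirroring
#: the experimentally matched transporter/catabolic systems: the compounds
#: with increasing (M-1) and diel (M-3/M-4) endometabolite patterns pair
#: with strongly noon-peaking uptake genes, while the declining compound's
#: (M-2) partner genes showed no significant diel expression (flat,
#: declining inventories).
PAIRED_GENE_ARCHETYPE = {"M-1": "G-1", "M-2": "G-3", "M-3": "G-1", "M-4": "G-1"}


def archetype_pair_series(met_archetype: str,
                          design: ExperimentDesign = ExperimentDesign(),
                          noise_sd: float = DEFAULT_NOISE_SD,
                          seed=0,
                          gene_archetype: str | None = None) -> dict:
    """Experiment-shaped metabolite/gene series for one metabolite archetype.

    The metabolite series follows the requested archetype (M-1..M-4); the
    paired transcript series follows the matched transcript archetype from
    :data:`PAIRED_GENE_ARCHETYPE` unless overridden.  Gaussian noise is
    added per replicate on the Z scale.
    """
    mets = {a.id: a for a in default_metabolite_archetypes()}
    if met_archetype not in mets:
        raise ValueError(f"unknown metabolite archetype {met_archetype!r}")
    genes = {a.id: a for a in default_gene_archetypes()}
    gene_archetype = gene_archetype or PAIRED_GENE_ARCHETYPE[met_archetype]
    rng = _rng(seed)
    t = design.times
    met_true = archetype_profile(mets[met_archetype], t, design.clock_offset)
    gene_true = archetype_profile(genes[gene_archetype], t, design.clock_offset)

    def noisy(series):
        reps = np.tile(series[:, None], (1, design.n_replicates))
        if noise_sd > 0:
            reps = reps + rng.normal(0.0, noise_sd, size=reps.shape)
        return reps

    return {"met_series": noisy(met_true), "gene_series": noisy(gene_true),
            "met_true": met_true, "gene_true": gene_true}
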