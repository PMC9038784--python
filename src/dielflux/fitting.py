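"""Grid-search fitting of the release-mechanism variants.

For every mechanism variant (base plus any subset of {o, h, b}) an
exhaustive Cartesian sweep over per-parameter value lists is run.  Each
parameter set is simulated, its modelled endometabolite pool P is correlated
(Pearson) against the experimental metabolite series and its modelled
uptake U against the experimental transcript series, both at the nine
design timepoints.  Sets significant for BOTH series (two-sided p < 0.05,
n = 9) are saved.  Variants are then compared on the mean of the two r
values, penalised for the number of active terms via an adjusted
correlation, and a winner is declared (ties broken toward fewer terms).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import ExperimentDesign
from .light import IrradianceProfile
from .model import (
    ModelParameters,
    SimConfig,
    canonical_variant,
    comparison_sample_times,
    simulate_batch,
)

__all__ = [
    "ParamGrid",
    "FitRecord",
    "VariantResult",
    "ComparisonReport",
    "pearson",
    "adjusted_r",
    "evaluate_params",
    "grid_search",
    "select_variant",
    "default_grid",
]


class ZeroVarianceError(ValueError):
    """A correlation input had no variance; the record is unfittable."""


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with the t-transform p-value.

    p is two-sided from ``t = r sqrt((n-2)/(1-r^2))`` on ``n-2`` degrees of
    freedom.  Raises :class:`ZeroVarianceError` when either series is
    constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise ZeroVarianceError("zero variance in correlation input")
    r = float(xc @ yc) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return r, min(p, 1.0)


def _pearson_batch(X: np.ndarray, y: np.ndarray):
    """Row-wise correlation of X (m, n) against y (n,). Returns (r, p, ok)."""
    n = X.shape[1]
    yc = y - y.mean()
    sy = math.sqrt(float(yc @ yc))
    Xc = X - X.mean(axis=1, keepdims=True)
    sx = np.sqrt(np.einsum("ij,ij->i", Xc, Xc))
    ok = (sx > 0) & (sy > 0)
    r = np.zeros(len(X))
    with np.errstate(divide="ignore", invalid="ignore"):
        r[ok] = (Xc[ok] @ yc) / (sx[ok] * sy)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    p = np.ones(len(X))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r[ok] * np.sqrt(df / np.maximum(1.0 - r[ok] ** 2, 0.0))
    p_ok = 2.0 * stats.t.sf(np.abs(t), df)
    p_ok = np.where(np.isfinite(t), p_ok, 0.0)  # |r| == 1 -> p = 0
    p[ok] = np.minimum(p_ok, 1.0)
    return r, p, ok


def adjusted_r(r: float, n: int, k: int, mode: str = "standard") -> float:
    """Correlation penalised for the number of active terms k.

    ``standard`` implements the conventional adjustment
    ``1 - (1 - r)(n - 1)/(n - k - 1)`` (identity at k = 0, fixed point at
    r = 1).  ``printed`` implements the alternative
    ``1 - (1/r)(n - 1)/(n - k - 1)``, which is undefined at r = 0; both are
    exposed so reports can state which convention produced a ranking.
    """
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")
    if mode == "standard":
        return 1.0 - (1.0 - r) * (n - 1) / (n - k - 1)
    if mode == "printed":
        if r == 0.0:
            raise ValueError("printed-mode adjustment is undefined at r = 0")
        return 1.0 - (1.0 / r) * (n - 1) / (n - k - 1)
    raise ValueError(f"unknown adjustment mode {mode!r}")


@dataclass(frozen=True)
class ParamGrid:
    """Per-parameter value lists for one mechanism variant.

    ``values`` must cover the six base parameters and exactly the active
    terms of ``variant``.  Grid contents are pure configuration.
    """

    variant: str
    values: dict

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", canonical_variant(self.variant))
        needed = set(ModelParameters.BASE_FIELDS) | {
            ModelParameters.ACTIVE_FIELDS[t] for t in self.active_terms
        }
        got = set(self.values)
        if got != needed:
            raise ValueError(
                f"grid for variant {self.variant!r} must define {sorted(needed)}, "
                f"got {sorted(got)}"
            )
        for name, vals in self.values.items():
            if len(vals) == 0:
                raise ValueError(f"empty value list for {name}")

    @property
    def active_terms(self) -> frozenset:
        return frozenset() if self.variant == "base" else frozenset(self.variant)

    @property
    def n_combinations(self) -> int:
        out = 1
        for vals in self.values.values():
            out *= len(vals)
        return out

    def param_names(self) -> list[str]:
        """Deterministic parameter order: base fields then o, h, b."""
        names = list(ModelParameters.BASE_FIELDS)
        for term in "ohb":
            if term in self.active_terms:
                names.append(ModelParameters.ACTIVE_FIELDS[term])
        return names

    def expand(self) -> dict:
        """Cartesian product as a dict of arrays, one entry per field
        (inactive terms filled with their neutral values)."""
        names = self.param_names()
        combos = np.array(
            list(itertools.product(*[self.values[n] for n in names])), dtype=float
        ).reshape(-1, len(names))
        arrays = {n: combos[:, i] for i, n in enumerate(names)}
        m = len(combos)
        defaults = {"o_decay": 0.0, "h_coef": 0.0, "b_factor": 1.0}
        for term, fname in ModelParameters.ACTIVE_FIELDS.items():
            if fname not in arrays:
                arrays[fname] = np.full(m, defaults[fname])
        return arrays


# Documented default ranges: allocation/release rates span slow (multi-day
# relaxation, so inoculation transients persist through the comparison
# window) to fast (sub-hour, so pools track irradiance with little lag);
# uptake parameters span linear to saturated Michaelis-Menten regimes at
# the default production scale.  Active-term lists deliberately exclude the
# neutral values so each variant is a genuinely distinct mechanism.
DEFAULT_BASE_VALUES = {
    "n_scale": [0.02],
    "t_frac": [0.01, 0.05, 0.25, 1.0],
    "r_diff": [0.01, 0.05, 0.25, 1.0, 2.0],
    "u_vmax": [0.3, 2.0, 5.0, 12.0],
    "u_km": [0.1, 1.0, 10.0],
    "c_frac": [0.1],
}
DEFAULT_ACTIVE_VALUES = {
    "o_decay": [0.1, 0.25, 0.6],
    "h_coef": [0.3, 1.0, 3.0],
    "b_factor": [2.0, 4.0, 8.0],
}


def default_grid(variant: str) -> ParamGrid:
    """Small log-spaced default grid for one variant (sweep runs in seconds).

    Active-term lists deliberately exclude the neutral values (o_decay = 0,
    h_coef = 0, b_factor = 1) so each variant tests a genuinely distinct
    mechanism rather than nesting the base model.
    """
    variant = canonical_variant(variant)
    values = {k: list(v) for k, v in DEFAULT_BASE_VALUES.items()}
    for term in ([] if variant == "base" else list(variant)):
        fname = ModelParameters.ACTIVE_FIELDS[term]
        values[fname] = list(DEFAULT_ACTIVE_VALUES[fname])
    return ParamGrid(variant=variant, values=values)


@dataclass(frozen=True)
class FitRecord:
    """One saved parameter set with its dual correlations."""

    params: ModelParameters
    variant: str
    r_met: float
    p_met: float
    r_gene: float
    p_gene: float

    @property
    def mean_r(self) -> float:
        return 0.5 * (self.r_met + self.r_gene)


@dataclass
class VariantResult:
    """Outcome of a grid sweep for one variant."""

    variant: str
    n_combinations: int
    records: list = field(default_factory=list)  # saved FitRecords
    n_unfittable: int = 0  # zero-variance model output
    n_clamped: int = 0     # combos with clamping events (still evaluated)

    @property
    def n_saved(self) -> int:
        return len(self.records)

    @property
    def best(self) -> FitRecord | None:
        if not self.records:
            return None
        return max(self.records, key=lambda rec: rec.mean_r)


def _prepare_series(series, design: ExperimentDesign) -> np.ndarray:
    """Average replicate-level data to one value per timepoint."""
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 2:
        arr = arr.mean(axis=1)
    if len(arr) != design.n_timepoints:
        raise ValueError(
            f"series has {len(arr)} timepoints, design expects {design.n_timepoints}"
        )
    return arr


def evaluate_params(params: ModelParameters, variant: str,
                    design: ExperimentDesign, met_series, gene_series,
                    config: SimConfig = SimConfig(),
                    profile: IrradianceProfile | None = None,
                    alpha: float = 0.05) -> FitRecord | None:
    """Simulate one parameter set and screen it against both series.

    Returns a :class:`FitRecord` if both correlations are significant at
    ``alpha``; ``None`` otherwise (including unfittable zero-variance
    cases).
    """
    profile = profile or design.light
    variant = canonical_variant(variant)
    met = _prepare_series(met_series, design)
    gene = _prepare_series(gene_series, design)
    arrays = {f: np.array([getattr(params, f)]) for f in (
        *ModelParameters.BASE_FIELDS, "o_decay", "h_coef", "b_factor")}
    times = comparison_sample_times(design, config)
    P_s, U_s, _ = simulate_batch(arrays, variant, times, config, profile)
    try:
        r_met, p_met = pearson(P_s[0], met)
        r_gene, p_gene = pearson(U_s[0], gene)
    except ZeroVarianceError:
        return None
    if p_met < alpha and p_gene < alpha:
        return FitRecord(params=params, variant=variant, r_met=r_met,
                         p_met=p_met, r_gene=r_gene, p_gene=p_gene)
    return None


def grid_search(grid: ParamGrid, design: ExperimentDesign, met_series,
                gene_series, config: SimConfig = SimConfig(),
                profile: IrradianceProfile | None = None,
                alpha: float = 0.05) -> VariantResult:
    """Exhaustive sweep of one variant's grid with dual-correlation screening.

    Deterministic and order-independent: the saved set depends only on the
    set of parameter combinations, not on list ordering.
    """
    profile = profile or design.light
    met = _prepare_series(met_series, design)
    gene = _prepare_series(gene_series, design)
    if np.ptp(met) == 0 or np.ptp(gene) == 0:
        raise ZeroVarianceError("experimental series is constant")
    arrays = grid.expand()
    times = comparison_sample_times(design, config)
    P_s, U_s, clamp_counts = simulate_batch(arrays, grid.variant, times, config, profile)
    r_m, p_m, ok_m = _pearson_batch(P_s, met)
    r_g, p_g, ok_g = _pearson_batch(U_s, gene)
    ok = ok_m & ok_g
    keep = ok & (p_m < alpha) & (p_g < alpha)
    records = []
    for i in np.flatnonzero(keep):
        params = ModelParameters(**{k: float(v[i]) for k, v in arrays.items()})
        records.append(FitRecord(params=params, variant=grid.variant,
                                 r_met=float(r_m[i]), p_met=float(p_m[i]),
                                 r_gene=float(r_g[i]), p_gene=float(p_g[i])))
    records.sort(key=lambda rec: -rec.mean_r)
    return VariantResult(variant=grid.variant,
                         n_combinations=grid.n_combinations,
                         records=records,
                         n_unfittable=int((~ok).sum()),
                         n_clamped=int((clamp_counts > 0).sum()))


@dataclass
class ComparisonReport:
    """Cross-variant ranking by adjusted mean correlation."""

    n: int
    adjust_mode: str
    rows: list = field(default_factory=list)  # dicts per variant
    winner: str | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows)


def select_variant(results: dict, n: int, mode: str = "standard") -> ComparisonReport:
    """Rank variants by adjusted mean r of their best saved record.

    ``results`` maps variant id -> :class:`VariantResult`.  Variants with no
    significant record are reported as "no fit".  Ties on adjusted r go to
    the variant with fewer active terms, then lexicographic id.

    In printed mode the adjustment rewards r values closer to zero on the
    negative side (1/r grows without bound), so only variants whose best
    mean r is positive are eligible; others are reported as "no positive
    fit".
    """
    if not results:
        raise ValueError("no variant results to compare")
    rows = []
    candidates = []
    for variant in sorted(results, key=lambda v: (len(_terms(v)), v)):
        res = results[variant]
        k = len(_terms(variant))
        best = res.best
        if best is None:
            rows.append({"variant": variant, "k": k,
                         "n_combinations": res.n_combinations,
                         "n_saved": res.n_saved, "mean_r": None,
                         "adjusted_r": None, "status": "no fit"})
            continue
        if mode == "printed" and best.mean_r <= 0:
            rows.append({"variant": variant, "k": k,
                         "n_combinations": res.n_combinations,
                         "n_saved": res.n_saved, "mean_r": best.mean_r,
                         "adjusted_r": None, "status": "no positive fit"})
            continue
        adj = adjusted_r(best.mean_r, n, k, mode)
        rows.append({"variant": variant, "k": k,
                     "n_combinations": res.n_combinations,
                     "n_saved": res.n_saved, "mean_r": best.mean_r,
                     "adjusted_r": adj, "status": "ok"})
        candidates.append((adj, -k, variant))
    winner = None
    if candidates:
        # max adjusted r; ties -> fewer terms (larger -k) -> reverse-lex id,
        # i.e. smallest id wins after negation below
        winner = max(candidates, key=lambda c: (c[0], c[1], _neg_lex(c[2])))[2]
    return ComparisonReport(n=n, adjust_mode=mode, rows=rows, winner=winner)


def _terms(variant: str) -> frozenset:
    return frozenset() if variant == "base" else frozenset(variant)


def _neg_lex(s: str):
    return tuple(-ord(c) for c in s)
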