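"""Diel rhythmicity detection by cosinor fit with a permutation test.

For each feature, a least-squares cosinor ``mean + A·cos(2πt/period) +
B·sin(2πt/period)`` is fitted to the replicate-level values; the statistic
is the variance explained (R²).  Significance comes from permuting the
timepoint labels independently within each replicate: ``p = (1 + #{perm ≥
obs}) / (1 + n_perm)``.  The peak phase is ``atan2(B, A)`` mapped to clock
hours.

This is a deliberate, simple stand-in for umbrella-alternative rhythm
detectors (e.g. RAIN): it tests a sinusoidal alternative only, which is
adequate for the smooth truncated-cosine diel shapes generated here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ExperimentDesign
from .io import FeatureMatrix

__all__ = ["rhythm_test", "RhythmResult", "phase_class"]


@dataclass
class RhythmResult:
    """Per-feature rhythmicity table and the test settings."""

    table: pd.DataFrame  # amplitude, phase, r2, p, periodic
    period: float
    n_perm: int
    alpha: float


def _design_matrix(t: np.ndarray, period: float) -> np.ndarray:
    w = 2.0 * np.pi * t / period
    return np.column_stack([np.ones_like(t), np.cos(w), np.sin(w)])


def rhythm_test(values, times=None, replicates=None, period: float = 24.0,
                n_perm: int = 199, alpha: float = 0.05, seed=0,
                clock_offset: float = 0.0) -> RhythmResult:
    """Test features for periodicity at the given period.

    ``values`` may be a :class:`FeatureMatrix` (times/replicates inferred)
    or an array/frame of shape (features, samples) with explicit ``times``
    (elapsed hours per sample) and ``replicates`` (replicate index per
    sample).  A single 1-D series is treated as one feature.

    Zero-variance features get p = 1.  Coverage below two full cycles
    degrades the test and triggers a warning.
    """
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")
    if isinstance(values, FeatureMatrix):
        times = values.sample_times
        replicates = values.replicates
        mat = values.values
    else:
        mat = values
        if times is None or replicates is None:
            raise ValueError("times and replicates are required for raw arrays")
    if isinstance(mat, pd.DataFrame):
        index = mat.index
        X = mat.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(mat, dtype=float))
        index = pd.RangeIndex(len(X))
    t = np.asarray(times, dtype=float)
    reps = np.asarray(replicates)
    if np.ptp(t) < 2 * period - 1e-9:
        warnings.warn(
            f"window covers {np.ptp(t):.1f} h < two full {period}-h cycles; "
            "the permutation test degenerates", stacklevel=2)

    D = _design_matrix(t, period)
    Q, _ = np.linalg.qr(D)           # orthonormal basis of [1, cos, sin]
    Qp = Q[:, 1:]                    # periodic subspace (mean removed)
    coef_basis = np.linalg.pinv(D)   # for amplitude/phase

    rng = np.random.default_rng(seed)
    rep_groups = [np.flatnonzero(reps == r) for r in np.unique(reps)]

    n_feat = len(X)
    amp = np.zeros(n_feat)
    phase = np.zeros(n_feat)
    r2 = np.zeros(n_feat)
    pvals = np.ones(n_feat)

    for i in range(n_feat):
        y = X[i]
        yc = y - y.mean()
        sst = float(yc @ yc)
        beta = coef_basis @ y
        A, B = beta[1], beta[2]
        amp[i] = float(np.hypot(A, B))
        ph = (np.arctan2(B, A) * period / (2.0 * np.pi))
        # cos(w t - atan2(B,A)) peaks at t = atan2/w; map to clock hours
        phase[i] = float(np.mod(ph + clock_offset, period))
        if sst == 0.0:
            pvals[i] = 1.0
            continue
        proj = Qp.T @ y
        obs = float(proj @ proj) / sst
        r2[i] = obs
        # permute timepoint labels within each replicate, vectorised over perms
        perm_idx = np.tile(np.arange(len(y)), (n_perm, 1))
        for grp in rep_groups:
            order = np.argsort(rng.random((n_perm, len(grp))), axis=1)
            perm_idx[:, grp] = grp[order]
        Yp = y[perm_idx]                      # (n_perm, n_samples)
        stat = np.einsum("ij,ij->i", Yp @ Qp, Yp @ Qp) / sst
        pvals[i] = (1.0 + np.sum(stat >= obs - 1e-12)) / (1.0 + n_perm)

    table = pd.DataFrame({
        "amplitude": amp,
        "phase": phase,
        "r2": r2,
        "p": pvals,
        "periodic": pvals < alpha,
    }, index=index)
    return RhythmResult(table=table, period=period, n_perm=n_perm, alpha=alpha)


def phase_class(phase_hours: float) -> str:
    """Bin an estimated peak phase into the sampling clock classes."""
    ph = phase_hours % 24.0
    if 9.0 <= ph < 15.0:
        return "noon"
    if 15.0 <= ph < 21.0:
        return "mid-afternoon"
    if 3.0 <= ph < 9.0:
        return "mid-morning"
    return "night"
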