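"""LRR artifact removal before HMM segmentation.

Two passes, in order: (1) principal components of the cohort's LRR over a
set of "stable" probes (uniquely mapping, not commonly copy-variable)
capture DNA quantity/quality and batch effects; these sample scores are
regressed out of every probe.  (2) a per-sample GC-wave adjustment regresses
each sample's LRR on local GC content using only copy-neutral-behaving
markers, so real CNV signal is not absorbed.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.decomposition import PCA

from .core import MarkerMap


def select_stable_probes(
    marker_map: MarkerMap,
    lrr_matrix: np.ndarray,
    variance_quantile: float = 0.90,
    min_probes: int = 100,
) -> np.ndarray:
    """Indices of probes usable for intensity PCA: flagged ``is_stable`` in
    the map and with cross-sample LRR variance below the given quantile
    (drops probes sitting in common CNVs)."""
    stable = marker_map.table["is_stable"].to_numpy()
    idx = np.flatnonzero(stable)
    if len(idx) == 0:
        raise ValueError("no probes flagged is_stable")
    var = np.var(lrr_matrix[:, idx], axis=0)
    cut = np.quantile(var, variance_quantile)
    out = idx[var <= cut]
    if len(out) < min_probes:
        raise ValueError(
            f"only {len(out)} stable probes selected; >= {min_probes} required for a stable PCA"
        )
    return out


def pca_correct_lrr(
    lrr_matrix: np.ndarray,
    stable_idx: np.ndarray,
    n_pcs: int = 10,
    clip_at: float = 0.3,
) -> np.ndarray:
    """Regress the top ``n_pcs`` intensity principal components out of every
    probe's LRR.

    The PCA and the per-probe regressions are fitted on a robustified copy
    of the matrix in which any value deviating from its probe's
    cross-sample median by more than ``clip_at`` is replaced by that
    median: cohort-level artifacts (quantity/quality, batch, waves) live
    well inside that range, while a rare CNV's extreme values would
    otherwise let sample-specific noise components absorb the very signal
    the HMM needs.  The fitted artifact is then subtracted from the raw
    values.  ``n_pcs=0`` is the identity.
    """
    lrr = np.asarray(lrr_matrix, dtype=float)
    n_samples = lrr.shape[0]
    if n_pcs == 0:
        return lrr.copy()
    if n_pcs >= n_samples:
        raise ValueError(f"n_pcs={n_pcs} must be < n_samples={n_samples}")
    probe_median = np.median(lrr, axis=0)
    dev = lrr - probe_median
    fit = np.where(np.abs(dev) > clip_at, probe_median, lrr)
    sub = fit[:, stable_idx]
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(sub - sub.mean(axis=0))  # samples x n_pcs, orthogonal
    # closed-form per-probe OLS: scores are orthogonal with zero column mean
    centred_fit = fit - fit.mean(axis=0)
    norms = (scores**2).sum(axis=0)
    beta = (scores.T @ centred_fit) / norms[:, None]  # n_pcs x n_probes
    return lrr - scores @ beta


def gc_adjust(
    lrr: np.ndarray,
    gc_frac: np.ndarray,
    neutral_lrr_window: float = 0.5,
    degree: int = 1,
) -> np.ndarray:
    """Per-sample GC-wave adjustment: fit LRR ~ poly(GC) on markers whose
    |LRR| < ``neutral_lrr_window`` (copy-neutral-behaving, so CNV signal is
    not regressed away), subtract the fitted wave everywhere and restore the
    neutral-marker mean.  Constant GC is a warned no-op."""
    lrr = np.asarray(lrr, dtype=float)
    gc = np.asarray(gc_frac, dtype=float)
    if len(lrr) != len(gc):
        raise ValueError("lrr and gc_frac length mismatch")
    if np.ptp(gc) == 0:
        warnings.warn("gc_frac is constant; GC adjustment is a no-op")
        return lrr.copy()
    neutral = np.abs(lrr) < neutral_lrr_window
    if neutral.sum() < degree + 2:
        warnings.warn("too few copy-neutral markers; GC adjustment skipped")
        return lrr.copy()
    coef = np.polynomial.polynomial.polyfit(gc[neutral], lrr[neutral], degree)
    fitted = np.polynomial.polynomial.polyval(gc, coef)
    return lrr - fitted + float(lrr[neutral].mean() - np.polynomial.polynomial.polyval(gc[neutral], coef).mean())


def correct_cohort(
    marker_map: MarkerMap,
    lrr_matrix: np.ndarray,
    n_pcs: int = 10,
    variance_quantile: float = 0.90,
    gc_degree: int = 1,
) -> np.ndarray:
    """Full correction: stable-probe PCA regression, per-sample GC
    adjustment, then per-sample median re-centring (the genome-wide median
    is copy-neutral, so residual whole-sample offsets are removed without
    touching CNV signal).  Returns a corrected samples x probes matrix."""
    stable_idx = select_stable_probes(marker_map, lrr_matrix, variance_quantile)
    n_pcs_eff = min(n_pcs, lrr_matrix.shape[0] - 2)
    if n_pcs_eff < n_pcs:
        warnings.warn(f"reducing n_pcs to {n_pcs_eff} for cohort of {lrr_matrix.shape[0]}")
    corrected = pca_correct_lrr(lrr_matrix, stable_idx, n_pcs=max(n_pcs_eff, 0))
    gc = marker_map.gc_frac
    for i in range(corrected.shape[0]):
        corrected[i] = gc_adjust(corrected[i], gc, degree=gc_degree)
        corrected[i] -= np.median(corrected[i])
    return corrected
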