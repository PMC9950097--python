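"""Sample- and marker-level quality control.

Implements the standard intensity-QC battery for SNP-array CNV studies:
Peiffer-style LRR/BAF derivation from raw allele intensities, outlier-sample
exclusion on noise metrics (cohort mean + 3 SD on LRR SD within [-2, 2] and
on heterozygous-band BAF SD within [0.15, 0.85], call rate > 95%), marker
filters (call rate, Hardy-Weinberg exact test, sex-differential missingness
and allele frequency), LD pruning, method-of-moments relatedness (PI_HAT)
and ancestry PCA, plus a sex-chromosome aneuploidy screen.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .core import IntensitySample, MarkerMap

LRR_WINDOW = (-2.0, 2.0)       # metric restricted to exclude real CNV signal
HET_BAF_WINDOW = (0.15, 0.85)  # putative heterozygotes


# ------------------------------------------------------------ LRR/BAF from X/Y

@dataclass
class ClusterMedians:
    """Canonical genotype cluster positions for one marker in polar
    intensity coordinates: theta = (2/pi) atan2(Y, X), R = X + Y."""

    theta_aa: float
    theta_ab: float
    theta_bb: float
    r_aa: float
    r_ab: float
    r_bb: float


def compute_lrr_baf(x_intensity, y_intensity, clusters: ClusterMedians):
    """Derive (LRR, BAF) from raw two-channel allele intensities by linear
    interpolation between genotype cluster medians.

    BAF is piecewise linear in theta (0 at/below the AA cluster, 0.5 at AB,
    1 at/above BB); the expected intensity R_expected is interpolated between
    the flanking clusters and LRR = log2(R_observed / R_expected).
    """
    x = np.asarray(x_intensity, dtype=float)
    y = np.asarray(y_intensity, dtype=float)
    theta = (2.0 / np.pi) * np.arctan2(y, x)
    r = x + y

    t_aa, t_ab, t_bb = clusters.theta_aa, clusters.theta_ab, clusters.theta_bb
    r_aa, r_ab, r_bb = clusters.r_aa, clusters.r_ab, clusters.r_bb
    if not (t_aa < t_ab < t_bb):
        raise ValueError("cluster thetas must satisfy AA < AB < BB")

    baf = np.empty_like(theta)
    r_exp = np.empty_like(theta)

    lo = theta <= t_aa
    hi = theta >= t_bb
    left = (~lo) & (theta < t_ab)
    right = (~hi) & (theta >= t_ab)

    baf[lo] = 0.0
    r_exp[lo] = r_aa
    baf[hi] = 1.0
    r_exp[hi] = r_bb
    frac_l = (theta[left] - t_aa) / (t_ab - t_aa)
    baf[left] = 0.5 * frac_l
    r_exp[left] = r_aa + frac_l * (r_ab - r_aa)
    frac_r = (theta[right] - t_ab) / (t_bb - t_ab)
    baf[right] = 0.5 + 0.5 * frac_r
    r_exp[right] = r_ab + frac_r * (r_bb - r_ab)

    with np.errstate(divide="ignore", invalid="ignore"):
        lrr = np.log2(r / r_exp)
    return lrr, baf


# -------------------------------------------------------------- sample metrics

@dataclass
class SampleQcMetrics:
    sample_id: str
    lrr_mean: float
    lrr_sd: float
    het_baf_sd: float
    call_rate: float
    passed: bool = True
    reasons: list[str] = field(default_factory=list)


def sample_metrics(sample: IntensitySample) -> SampleQcMetrics:
    """Noise metrics over restricted windows: LRR stats only for values in
    [-2, +2] (excludes real copy-number signal), BAF SD only over the
    heterozygous band [0.15, 0.85]."""
    in_win = (sample.lrr >= LRR_WINDOW[0]) & (sample.lrr <= LRR_WINDOW[1])
    lrr_w = sample.lrr[in_win & np.isfinite(sample.lrr)]
    het = (sample.baf >= HET_BAF_WINDOW[0]) & (sample.baf <= HET_BAF_WINDOW[1])
    baf_h = sample.baf[het]
    return SampleQcMetrics(
        sample_id=sample.sample_id,
        lrr_mean=float(lrr_w.mean()) if len(lrr_w) else float("nan"),
        lrr_sd=float(lrr_w.std(ddof=1)) if len(lrr_w) > 1 else float("nan"),
        het_baf_sd=float(baf_h.std(ddof=1)) if len(baf_h) > 1 else float("nan"),
        call_rate=sample.call_rate,
    )


def sample_pass_filter(
    metrics: list[SampleQcMetrics],
    n_sd: float = 3.0,
    min_call_rate: float = 0.95,
) -> pd.DataFrame:
    """Exclude samples whose LRR SD or het-band BAF SD exceeds the cohort
    mean + ``n_sd`` cohort SDs of that metric, or whose call rate is not
    above ``min_call_rate``.  Mutates ``passed``/``reasons`` in place and
    returns a per-sample report table."""
    if len(metrics) < 2:
        raise ValueError("sample filter needs >= 2 samples (cohort mean/SD undefined)")
    for name in ("lrr_sd", "het_baf_sd"):
        vals = np.array([getattr(m, name) for m in metrics])
        mu, sd = np.nanmean(vals), np.nanstd(vals)
        cut = mu + n_sd * sd
        for m, v in zip(metrics, vals):
            if np.isfinite(v) and v > cut and sd > 0:
                m.passed = False
                m.reasons.append(f"{name}>{cut:.4g}")
    for m in metrics:
        if m.call_rate <= min_call_rate:
            m.passed = False
            m.reasons.append("call_rate")
    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metrics],
            "lrr_mean": [m.lrr_mean for m in metrics],
            "lrr_sd": [m.lrr_sd for m in metrics],
            "het_baf_sd": [m.het_baf_sd for m in metrics],
            "call_rate": [m.call_rate for m in metrics],
            "pass": [m.passed for m in metrics],
            "reasons": [";".join(m.reasons) for m in metrics],
        }
    )


# ------------------------------------------------------------------- HWE exact

def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test p-value (two-sided, no mid-p correction):
    sum of probabilities of all heterozygote counts no more likely than the
    observed one, conditional on the allele counts.

    Uses the stable ratio recurrence over possible het counts.  A
    monomorphic marker has p = 1 by convention.
    """
    n = n_aa + n_ab + n_bb
    rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    if n == 0 or rare == 0:
        return 1.0
    # het counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    probs = np.empty(len(hets), dtype=float)
    mid = len(hets) // 2
    probs[mid] = 1.0
    # P(h+2)/P(h) = 4 * n_aa(h) * n_bb(h) / ((h+2)(h+1)) with genotype counts
    # implied by h given fixed allele counts
    for i in range(mid, len(hets) - 1):
        h = hets[i]
        n_rare_hom = (rare - h) // 2
        n_common_hom = n - n_rare_hom - h
        probs[i + 1] = probs[i] * 4.0 * n_rare_hom * n_common_hom / ((h + 2.0) * (h + 1.0))
    for i in range(mid, 0, -1):
        h = hets[i]
        n_rare_hom = (rare - h) // 2
        n_common_hom = n - n_rare_hom - h
        probs[i - 1] = probs[i] * h * (h - 1.0) / (4.0 * (n_rare_hom + 1.0) * (n_common_hom + 1.0))
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_ab)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# -------------------------------------------------------------- marker filters

def marker_pass_filter(
    genotypes: np.ndarray,
    sexes: np.ndarray | None = None,
    min_call_rate: float = 0.95,
    hwe_p_min: float = 1e-5,
    sex_p_min: float = 1e-4,
) -> pd.DataFrame:
    """Per-marker QC over a samples x markers dosage matrix (-1 missing).

    Filters: call rate > ``min_call_rate``; HWE exact p > ``hwe_p_min``;
    with ``sexes`` given, Fisher-exact sex-differential missingness and
    allele-count sex-differential frequency (chi-square, Fisher fallback at
    expected counts < 5), both at p > ``sex_p_min``.
    """
    g = np.asarray(genotypes)
    n_samples, n_markers = g.shape
    called = g >= 0
    call_rate = called.mean(axis=0)

    hwe = np.ones(n_markers)
    for j in range(n_markers):
        col = g[called[:, j], j]
        hwe[j] = hwe_exact_p(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))

    miss_p = np.ones(n_markers)
    freq_p = np.ones(n_markers)
    if sexes is not None:
        sexes = np.asarray(sexes)
        male = sexes == "male"
        female = sexes == "female"
        for j in range(n_markers):
            mm = int((~called[male, j]).sum())
            mf = int((~called[female, j]).sum())
            cm = int(called[male, j].sum())
            cf = int(called[female, j].sum())
            if mm + mf > 0:
                miss_p[j] = stats.fisher_exact([[mm, cm], [mf, cf]])[1]
            bm = int(g[male & called[:, j], j].sum())
            bf = int(g[female & called[:, j], j].sum())
            am = 2 * cm - bm
            af = 2 * cf - bf
            table = np.array([[bm, am], [bf, af]])
            if table.sum() and table.sum(axis=0).min() > 0 and table.sum(axis=1).min() > 0:
                expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
                if expected.min() < 5:
                    freq_p[j] = stats.fisher_exact(table)[1]
                else:
                    freq_p[j] = stats.chi2_contingency(table, correction=False)[1]

    ok = (call_rate > min_call_rate) & (hwe > hwe_p_min) & (miss_p > sex_p_min) & (freq_p > sex_p_min)
    return pd.DataFrame(
        {
            "call_rate": call_rate,
            "hwe_p": hwe,
            "sex_miss_p": miss_p,
            "sex_freq_p": freq_p,
            "pass": ok,
        }
    )


# ------------------------------------------------------------------ LD pruning

def ld_prune(
    genotypes: np.ndarray,
    window_snps: int = 50,
    step: int = 5,
    r2_threshold: float = 0.2,
) -> np.ndarray:
    """Sliding-window greedy LD pruning (PLINK --indep-pairwise semantics):
    within each window of ``window_snps`` markers, advanced by ``step``, the
    later marker of any retained pair with genotypic r^2 > threshold is
    removed.  Returns the boolean retained mask over markers.

    The 0.2 preset prepares markers for ancestry PCA; 0.3 prepares the ROH
    marker set.
    """
    if not (0.0 < r2_threshold < 1.0):
        raise ValueError("r2_threshold must be in (0, 1)")
    g = np.asarray(genotypes, dtype=float)
    g = np.where(g < 0, np.nan, g)
    n_samples, n_markers = g.shape
    col_mean = np.nanmean(g, axis=0)
    g_f = np.where(np.isnan(g), col_mean, g)  # mean-impute missing for r^2
    keep = np.ones(n_markers, dtype=bool)
    start = 0
    while True:
        stop = min(start + window_snps, n_markers)
        idx = np.flatnonzero(keep[start:stop]) + start
        if len(idx) > 1:
            sub = g_f[:, idx]
            sd = sub.std(axis=0)
            ok = sd > 0
            if ok.sum() > 1:
                sub_ok = (sub[:, ok] - sub[:, ok].mean(axis=0)) / sd[ok]
                corr = sub_ok.T @ sub_ok / n_samples
                r2 = corr**2
                live = idx[ok]
                removed = np.zeros(len(live), dtype=bool)
                for a in range(len(live)):
                    if removed[a]:
                        continue
                    for b in range(a + 1, len(live)):
                        if removed[b]:
                            continue
                        if r2[a, b] > r2_threshold:
                            removed[b] = True
                keep[live[removed]] = False
        if stop >= n_markers:
            break
        start += step
    return keep


# ------------------------------------------------------------------ relatedness

@dataclass
class RelatednessEstimate:
    sample_pair: tuple[str, str]
    pi_hat: float
    ibs0: int
    ibs1: int
    ibs2: int


def estimate_pi_hat(
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    allele_freqs: np.ndarray,
    pair: tuple[str, str] = ("a", "b"),
) -> RelatednessEstimate:
    """Method-of-moments proportion-IBD estimate from IBS counts, the
    algebra behind PLINK's --genome PI_HAT.

    P(IBD=0) is estimated from the observed IBS0 count against its
    null expectation, P(IBD=1) from the residual IBS1, P(IBD=2) from the
    residual IBS2; negative estimates are truncated to zero and the triple
    renormalised.  pi_hat = P(IBD=2) + P(IBD=1)/2.
    """
    ga = np.asarray(geno_a)
    gb = np.asarray(geno_b)
    p = np.asarray(allele_freqs, dtype=float)
    ok = (ga >= 0) & (gb >= 0) & (p > 0) & (p < 1)
    ga, gb, p = ga[ok], gb[ok], p[ok]
    n = len(ga)
    if n == 0:
        raise ValueError("no overlapping non-missing markers")
    if n < 1000:
        warnings.warn(f"only {n} overlapping markers; PI_HAT estimate unstable")
    diff = np.abs(ga.astype(int) - gb.astype(int))
    ibs2 = int((diff == 0).sum())
    ibs1 = int((diff == 1).sum())
    ibs0 = int((diff == 2).sum())

    q = 1.0 - p
    e0_ibd0 = float((2 * p**2 * q**2).sum())
    e1_ibd0 = float((4 * p**3 * q + 4 * p * q**3).sum())
    e2_ibd0 = float((p**4 + q**4 + 4 * p**2 * q**2).sum())
    e1_ibd1 = float((2 * p * q).sum())
    e2_ibd1 = float((1 - 2 * p * q).sum())

    p0 = ibs0 / e0_ibd0 if e0_ibd0 > 0 else 0.0
    p1 = (ibs1 - p0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
    p2 = (ibs2 - p0 * e2_ibd0 - p1 * e2_ibd1) / n
    probs = np.clip([p0, p1, p2], 0.0, 1.0)
    total = probs.sum()
    if total > 0:
        probs = probs / total
    pi_hat = float(np.clip(probs[2] + 0.5 * probs[1], 0.0, 1.0))
    return RelatednessEstimate(pair, pi_hat, ibs0, ibs1, ibs2)


# ---------------------------------------------------------------- ancestry PCA

def ancestry_pca(genotypes: np.ndarray, n_components: int = 10):
    """PCA of the frequency-standardised genotype matrix (samples x pruned
    markers).  Missing dosages are mean-imputed; each marker is centred at
    2p and scaled by sqrt(2p(1-p)).  Returns (scores, variance_explained)."""
    g = np.asarray(genotypes, dtype=float)
    g = np.where(g < 0, np.nan, g)
    n_samples, n_markers = g.shape
    k = min(n_components, n_samples - 1, n_markers)
    if k < n_components:
        warnings.warn(f"reducing components from {n_components} to {k}")
    p = np.nanmean(g, axis=0) / 2.0
    g = np.where(np.isnan(g), 2.0 * p, g)
    denom = np.sqrt(np.clip(2.0 * p * (1.0 - p), 1e-12, None))
    z = (g - 2.0 * p) / denom
    pca = PCA(n_components=max(k, 1), svd_solver="full")
    scores = pca.fit_transform(z)
    return scores, pca.explained_variance_ratio_


# --------------------------------------------------------- sex/aneuploidy scan

def sex_aneuploidy_screen(
    samples: list[IntensitySample],
    marker_map: MarkerMap,
    reported_sex: dict[str, str] | None = None,
    y_loss_lrr: float = -0.5,
    x_het_male_max: float = 0.05,
    x_het_female_min: float = 0.05,
    mosaic_x_baf_sd: float = 0.11,
) -> pd.DataFrame:
    """Validate reported sex and screen for sex-chromosome aneuploidy from
    X/Y intensity and the X heterozygosity pattern.

    Flags per sample: ``sex_discordant`` (X het rate inconsistent with the
    label), ``partial_y_loss`` (male median Y LRR below ``y_loss_lrr``,
    the mosaic loss-of-Y signature) and ``mosaic_x`` (split X het-band BAF).
    """
    x_idx = marker_map.chrom_index("X")
    y_idx = marker_map.chrom_index("Y")
    if len(x_idx) == 0 and len(y_idx) == 0:
        warnings.warn("no sex-chromosome markers in map; screen skipped")
        return pd.DataFrame(columns=["sample_id", "median_lrr_x", "median_lrr_y",
                                     "x_het_rate", "x_het_baf_sd", "flags"])
    rows = []
    for s in samples:
        med_x = float(np.median(s.lrr[x_idx])) if len(x_idx) else float("nan")
        med_y = float(np.median(s.lrr[y_idx])) if len(y_idx) else float("nan")
        gx = s.genotype[x_idx]
        called = gx >= 0
        het_rate = float((gx[called] == 1).mean()) if called.any() else float("nan")
        bafx = s.baf[x_idx]
        band = (bafx >= HET_BAF_WINDOW[0]) & (bafx <= HET_BAF_WINDOW[1])
        het_baf_sd = float(bafx[band].std(ddof=1)) if band.sum() > 10 else float("nan")
        flags = []
        label = (reported_sex or {}).get(s.sample_id)
        looks_male = np.isfinite(het_rate) and het_rate < x_het_male_max
        if label == "male" and np.isfinite(het_rate) and het_rate > x_het_female_min:
            flags.append("sex_discordant")
        if label == "female" and looks_male:
            flags.append("sex_discordant")
        is_male = label == "male" if label else looks_male
        if is_male and np.isfinite(med_y) and med_y < y_loss_lrr:
            flags.append("partial_y_loss")
        if np.isfinite(het_baf_sd) and het_baf_sd > mosaic_x_baf_sd and not looks_male:
            flags.append("mosaic_x")
        rows.append(
            {
                "sample_id": s.sample_id,
                "median_lrr_x": med_x,
                "median_lrr_y": med_y,
                "x_het_rate": het_rate,
                "x_het_baf_sd": het_baf_sd,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)
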