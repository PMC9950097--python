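"""Arm-scale mosaicism detection from split heterozygous BAF bands.

A chromosomal alteration present in only a fraction f of cells moves the
heterozygous BAF band from 0.5 to 0.5 +/- d, where d depends on f and on
whether the event is a loss, a gain or copy-neutral LOH.  The screen works
in three steps: (1) per-arm SD and IQR of het-band BAF (values in
(0.15, 0.85)) place every arm of every sample on a scatter where mosaic
arms are outliers; (2) a robust median + k*MAD rule flags outlier arms,
excluding arms that are near-total runs of homozygosity (few hets, a
separate cloud); (3) a two-state distance-aware HMM over |BAF - 0.5| maps
the event's breakpoints and profiles the band deviation d, from which the
cell fraction is estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import norm

from .core import IntensitySample, MarkerMap

HET_BAND = (0.15, 0.85)


def arm_table(marker_map: MarkerMap, centromeres: pd.DataFrame) -> pd.DataFrame:
    """Chromosome arms implied by the centromere table: for each chromosome
    present in the map, the p arm covers markers before the centromere and
    the q arm markers after it."""
    cen = {str(r["chromosome"]): (int(r["start_bp"]), int(r["end_bp"]))
           for _, r in centromeres.iterrows()}
    rows = []
    for chrom in marker_map.chromosomes:
        idx = marker_map.chrom_index(chrom)
        pos = marker_map.positions[idx]
        if chrom in cen:
            cs, ce = cen[chrom]
            p_mask = pos < cs
            q_mask = pos > ce
            if p_mask.any():
                rows.append({"chrom_arm": f"{chrom}p", "chromosome": chrom,
                             "start_bp": int(pos[p_mask][0]), "end_bp": int(pos[p_mask][-1])})
            if q_mask.any():
                rows.append({"chrom_arm": f"{chrom}q", "chromosome": chrom,
                             "start_bp": int(pos[q_mask][0]), "end_bp": int(pos[q_mask][-1])})
        else:
            rows.append({"chrom_arm": f"{chrom}", "chromosome": chrom,
                         "start_bp": int(pos[0]), "end_bp": int(pos[-1])})
    return pd.DataFrame(rows)


def arm_baf_stats(
    sample: IntensitySample,
    marker_map: MarkerMap,
    arms: pd.DataFrame,
    min_het_markers: int = 50,
) -> pd.DataFrame:
    """Per-arm SD and IQR of heterozygous-band BAF for one sample.

    Arms with fewer than ``min_het_markers`` het-band values get
    ``has_min_het = False``: they are typically whole-arm runs of
    homozygosity and are excluded from mosaic outlier flagging.
    """
    rows = []
    for _, arm in arms.iterrows():
        idx = marker_map.region_index(arm["chromosome"], arm["start_bp"], arm["end_bp"])
        baf = sample.baf[idx]
        band = baf[(baf > HET_BAND[0]) & (baf < HET_BAND[1])]
        n = len(band)
        rows.append(
            {
                "sample_id": sample.sample_id,
                "chrom_arm": arm["chrom_arm"],
                "n_het_markers": n,
                "baf_sd": float(np.std(band, ddof=1)) if n > 1 else float("nan"),
                "baf_iqr": float(np.subtract(*np.percentile(band, [75, 25]))) if n > 1 else float("nan"),
                "has_min_het": n >= min_het_markers,
            }
        )
    return pd.DataFrame(rows)


def flag_mosaic_outliers(arm_stats: pd.DataFrame, k: float = 5.0) -> pd.DataFrame:
    """Robust bivariate outlier rule over the cohort's arm cloud: an arm is
    flagged when its het-band BAF SD or IQR exceeds the cohort median +
    k * MAD (normal-consistent MAD).  Arms without the het-marker minimum
    are never flagged (they are the ROH cloud, not mosaicism)."""
    eligible = arm_stats[arm_stats["has_min_het"]].copy()
    if len(eligible) < 20:
        raise ValueError("need >= 20 eligible arms to form a reference cloud")
    out = arm_stats.copy()
    out["outlier"] = False
    for col in ("baf_sd", "baf_iqr"):
        vals = eligible[col].to_numpy()
        med = float(np.median(vals))
        mad = float(sps.median_abs_deviation(vals, scale="normal"))
        cut = med + k * max(mad, 1e-12)
        out.loc[out["has_min_het"] & (out[col] > cut), "outlier"] = True
    return out


# ------------------------------------------------------------------ BAF HMM

@dataclass
class MosaicHmmParams:
    """Two-state HMM over |BAF - 0.5| of het-band markers: state N (normal)
    emits half-normal(0, sigma), state M (mosaic) emits a folded normal
    centred at the profiled deviation d."""

    d_grid: np.ndarray = field(default_factory=lambda: np.arange(0.02, 0.301, 0.01))
    sigma: float | None = None  # estimated from the data when None
    outlier_weight: float = 0.02  # genotyping failures hit both states alike
    prior_m: float = 0.01
    distance_scale_bp: float = 2_000_000.0
    rho_max: float = 0.9
    min_event_markers: int = 25
    lrr_dead_zone: float = 0.02  # |mean LRR| below this: direction unknown


@dataclass
class MosaicEvent:
    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    band_deviation: float
    direction: str  # gain | loss | unknown
    cell_fraction_estimate: float | None
    n_het_markers: int


def estimate_mosaic_fraction(d: float, direction: str):
    """Cell fraction from the het-band deviation d = |BAF - 0.5|.

    loss:    f = 4d / (1 + 2d)
    gain:    f = 4d / (1 - 2d)
    neutral: f = 2d            (copy-neutral LOH)
    unknown: both loss and gain estimates, capped at 1, returned as a dict.

    d = 1/6 under a gain gives f = 1: constitutional trisomy with BAF bands
    at 1/3 and 2/3.
    """
    d = float(d)
    if not (0.0 <= d < 0.5):
        raise ValueError("band deviation d must lie in [0, 0.5)")
    loss = 4.0 * d / (1.0 + 2.0 * d)
    gain = min(1.0, 4.0 * d / (1.0 - 2.0 * d))
    if direction == "loss":
        return loss
    if direction == "gain":
        return gain
    if direction == "neutral":
        return min(1.0, 2.0 * d)
    if direction == "unknown":
        return {"loss": loss, "gain": gain}
    raise ValueError(f"unknown direction {direction!r}")


def _state_logdens(y, d, sigma, params: MosaicHmmParams):
    """Per-marker log-densities of |BAF - 0.5| under the normal (half-normal
    at 0) and mosaic (folded normal at d) states, each mixed with a uniform
    outlier component so genotyping failures cannot dominate either state."""
    w = params.outlier_weight
    dens_n = 2.0 * norm.pdf(y, 0.0, sigma)
    dens_m = norm.pdf(y, d, sigma) + norm.pdf(y, -d, sigma)
    return (np.log((1 - w) * dens_n + w * 2.0),
            np.log((1 - w) * dens_m + w * 2.0))  # uniform on [0, 0.5]


def _two_state_viterbi(y, positions, d, sigma, params: MosaicHmmParams):
    """Viterbi over the two-state folded-normal model; returns (path, score)."""
    n = len(y)
    emis = np.empty((n, 2))
    emis[:, 0], emis[:, 1] = _state_logdens(y, d, sigma, params)
    pri = np.array([1.0 - params.prior_m, params.prior_m])
    dist = np.diff(positions).astype(float)
    rho = params.rho_max * (1.0 - np.exp(-dist / params.distance_scale_bp))
    # off-diagonal i->j = prior_j * rho(d); diagonal takes the remainder
    logT = np.empty((n - 1, 2, 2))
    with np.errstate(divide="ignore"):
        logT[:, 0, 1] = np.log(rho * pri[1])
        logT[:, 1, 0] = np.log(rho * pri[0])
        logT[:, 0, 0] = np.log(1.0 - rho * pri[1])
        logT[:, 1, 1] = np.log(1.0 - rho * pri[0])
    delta = np.log(pri) + emis[0]
    psi = np.empty((n, 2), dtype=np.int8)
    for t in range(1, n):
        scores = delta[:, None] + logT[t - 1]
        psi[t] = np.argmax(scores, axis=0)
        delta = scores[psi[t], np.arange(2)] + emis[t]
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(delta))
    score = float(np.max(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path, score


def mosaic_baf_hmm(
    sample: IntensitySample,
    marker_map: MarkerMap,
    chromosome: str,
    params: MosaicHmmParams | None = None,
    start_bp: int | None = None,
    end_bp: int | None = None,
) -> list[MosaicEvent]:
    """Segment one chromosome (or sub-interval) of a sample into mosaic
    events.  The band deviation d is profiled over a grid and the best
    Viterbi likelihood wins; runs of the mosaic state shorter than
    ``min_event_markers`` het markers are discarded.  Event direction comes
    from the sign of mean LRR over the event, with a dead zone mapping to
    ``unknown`` (copy-neutral events shift BAF but not LRR)."""
    params = params or MosaicHmmParams()
    idx = marker_map.chrom_index(chromosome)
    if start_bp is not None or end_bp is not None:
        pos_all = marker_map.positions[idx]
        lo = start_bp if start_bp is not None else pos_all[0]
        hi = end_bp if end_bp is not None else pos_all[-1]
        idx = idx[(pos_all >= lo) & (pos_all <= hi)]
    baf = sample.baf[idx]
    band = (baf > HET_BAND[0]) & (baf < HET_BAND[1])
    het_idx = idx[band]
    if len(het_idx) < 2:
        return []
    y = np.abs(sample.baf[het_idx] - 0.5)
    positions = marker_map.positions[het_idx]
    sigma = params.sigma
    if sigma is None:
        # half-normal-consistent robust scale from the whole het band
        sigma = max(float(np.median(y)) / 0.6745, 1e-3)

    best = None
    for d in params.d_grid:
        path, score = _two_state_viterbi(y, positions, float(d), sigma, params)
        if best is None or score > best[1]:
            best = (path, score, float(d))
    path, _, d_best = best

    # emission-only changepoint refinement: the Viterbi transition cost
    # systematically trims a few markers off each boundary
    emis_n, emis_m = _state_logdens(y, d_best, sigma, params)
    diff = emis_m - emis_n  # positive where the mosaic state fits better

    events = []
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(path)]])
    w = 80
    for a, b in zip(starts, ends):
        if path[a] != 1 or (b - a) < params.min_event_markers:
            continue
        # refine each boundary within a window: the changepoint maximises
        # sum(diff) over the event side, i.e. cumulative-sum argmax
        lo = a if a == 0 else max(0, a - w)
        if a > 0:
            cums = np.cumsum(diff[lo : min(a + w, b)][::-1])[::-1]
            a = lo + int(np.argmax(cums))
        hi = b if b == len(path) else min(len(path), b + w)
        if b < len(path):
            cums = np.cumsum(diff[max(a, b - w) : hi])
            b = max(a, b - w) + int(np.argmax(cums)) + 1
        ev_het = het_idx[a:b]
        d_hat = float(np.mean(np.abs(sample.baf[ev_het] - 0.5)))
        mean_lrr = float(np.mean(sample.lrr[ev_het]))
        if mean_lrr > params.lrr_dead_zone:
            direction = "gain"
        elif mean_lrr < -params.lrr_dead_zone:
            direction = "loss"
        else:
            direction = "unknown"
        cf = estimate_mosaic_fraction(d_hat, direction) if direction in ("gain", "loss") else None
        events.append(
            MosaicEvent(
                sample_id=sample.sample_id,
                chromosome=str(chromosome),
                start_bp=int(positions[a]),
                end_bp=int(positions[b - 1]),
                band_deviation=d_hat,
                direction=direction,
                cell_fraction_estimate=cf,
                n_het_markers=int(b - a),
            )
        )
    return events


def screen_cohort(
    samples: list[IntensitySample],
    marker_map: MarkerMap,
    centromeres: pd.DataFrame,
    min_het_markers: int = 50,
    k: float = 5.0,
    hmm_params: MosaicHmmParams | None = None,
) -> tuple[pd.DataFrame, list[MosaicEvent]]:
    """Cohort screen: per-arm stats for every sample, robust outlier
    flagging, then breakpoint mapping on each flagged arm.  Returns the
    flagged arm-stats table and the list of mapped events."""
    arms = arm_table(marker_map, centromeres)
    stats_all = pd.concat(
        [arm_baf_stats(s, marker_map, arms, min_het_markers) for s in samples],
        ignore_index=True,
    )
    flagged = flag_mosaic_outliers(stats_all, k=k)
    by_id = {s.sample_id: s for s in samples}
    arm_bounds = {r["chrom_arm"]: r for _, r in arms.iterrows()}
    params = hmm_params or MosaicHmmParams()
    if params.sigma is None:
        # noise scale from the copy-neutral cloud, not the flagged arms;
        # IQR-based so BAF outliers inside the het band do not inflate it
        clean = flagged[flagged["has_min_het"] & ~flagged["outlier"]]
        if len(clean):
            sigma = float(clean["baf_iqr"].median()) / 1.349
            params = MosaicHmmParams(**{**vars(params), "sigma": sigma})
    events: list[MosaicEvent] = []
    for _, row in flagged[flagged["outlier"]].iterrows():
        arm = arm_bounds[row["chrom_arm"]]
        events.extend(
            mosaic_baf_hmm(
                by_id[row["sample_id"]], marker_map, arm["chromosome"],
                params, start_bp=int(arm["start_bp"]), end_bp=int(arm["end_bp"]),
            )
        )
    return flagged, events
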