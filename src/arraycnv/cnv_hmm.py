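"""Six-state copy-number HMM over corrected LRR + BAF, with the downstream
confidence, probe-count, merge and centromere rules.

The model follows the classic SNP-array CNV topology: hidden states CN0,
CN1, CN2 (diploid reference), CN2-LOH (copy-neutral loss of heterozygosity),
CN3 and CN4.  Emissions combine a Gaussian on LRR (state-specific mean/SD)
with a BAF mixture whose cluster weights come from Hardy-Weinberg
proportions at the marker's population B-allele frequency, adapted to the
state's allele count, plus a uniform outlier component.  Transitions decay
with inter-marker distance, so physically close markers resist state
switching.  Calls are scored by an emission-only log10 Bayes factor against
the diploid state, filtered on probe-count minima (3 for homozygous
deletions, 15 otherwise) and confidence >= 10, merged when same-copy-number
neighbours are separated by < 20% of the smaller call, and split at
centromeres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import AUTOSOMES, CnvCall, IntensitySample, MarkerMap

STATE_NAMES = ("CN0", "CN1", "CN2", "CN2_LOH", "CN3", "CN4")
STATE_COPY_NUMBER = {"CN0": 0, "CN1": 1, "CN2": 2, "CN2_LOH": 2, "CN3": 3, "CN4": 4}
CN2_INDEX = 2


@dataclass
class HmmParams:
    """HMM parameters; all configurable, defaults on the conventional
    Illumina/PennCNV intensity scale."""

    lrr_means: dict = field(
        default_factory=lambda: {"CN0": -3.0, "CN1": -0.66, "CN2": 0.0,
                                 "CN2_LOH": 0.0, "CN3": 0.40, "CN4": 0.68}
    )
    lrr_sds: dict = field(
        default_factory=lambda: {"CN0": 1.0, "CN1": 0.22, "CN2": 0.20,
                                 "CN2_LOH": 0.20, "CN3": 0.22, "CN4": 0.24}
    )
    baf_sd: float = 0.04
    outlier_weight: float = 0.01
    priors: dict = field(
        default_factory=lambda: {"CN0": 0.001, "CN1": 0.004, "CN2": 0.990,
                                 "CN2_LOH": 0.0005, "CN3": 0.004, "CN4": 0.0005}
    )
    distance_scale_bp: float = 100_000.0  # transition decay length D
    rho_max: float = 0.9
    min_confidence: float = 10.0
    min_probes_homozygous_del: int = 3
    min_probes_other: int = 15
    merge_gap_fraction: float = 0.20

    def __post_init__(self) -> None:
        total = sum(self.priors[s] for s in STATE_NAMES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state priors sum to {total}, not 1")
        if any(self.lrr_sds[s] <= 0 for s in STATE_NAMES):
            raise ValueError("lrr_sd must be positive for every state")

    @property
    def prior_vector(self) -> np.ndarray:
        return np.array([self.priors[s] for s in STATE_NAMES])


def _baf_clusters(state: str, pfb: np.ndarray):
    """(cluster means, n_markers x n_clusters weights) for a state.  CN0 has
    no allelic signal and is handled as uniform by the caller."""
    p = pfb
    q = 1.0 - p
    if state == "CN1" or state == "CN2_LOH":
        means = np.array([0.0, 1.0])
        weights = np.stack([q, p], axis=-1)
    elif state == "CN2":
        means = np.array([0.0, 0.5, 1.0])
        weights = np.stack([q**2, 2 * p * q, p**2], axis=-1)
    elif state == "CN3":
        means = np.array([0.0, 1 / 3, 2 / 3, 1.0])
        weights = np.stack([q**3, 3 * p * q**2, 3 * p**2 * q, p**3], axis=-1)
    elif state == "CN4":
        means = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        weights = np.stack([q**4, 4 * p * q**3, 6 * p**2 * q**2, 4 * p**3 * q, p**4], axis=-1)
    else:
        raise ValueError(f"no BAF cluster model for state {state!r}")
    return means, weights


def _cluster_density(baf: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Truncated-Gaussian cluster density on [0, 1] with the truncated tail
    mass assigned to the boundary points (BAF clips at 0 and 1)."""
    dens = norm.pdf(baf, mean, sd)
    at0 = baf <= 0.0
    at1 = baf >= 1.0
    if at0.any():
        dens = np.where(at0, norm.cdf(0.0, mean, sd), dens)
    if at1.any():
        dens = np.where(at1, norm.sf(1.0, mean, sd), dens)
    return dens


def baf_likelihood(state: str, baf: np.ndarray, pfb: np.ndarray, params: HmmParams) -> np.ndarray:
    """Per-marker BAF likelihood under a state's cluster mixture plus the
    uniform outlier component."""
    baf = np.asarray(baf, dtype=float)
    pfb = np.clip(np.asarray(pfb, dtype=float), 0.01, 0.99)
    if state == "CN0":
        mix = np.ones_like(baf)  # deleted: BAF is pure noise, uniform
    else:
        means, weights = _baf_clusters(state, pfb)
        mix = np.zeros_like(baf)
        for c, mu in enumerate(means):
            mix += weights[..., c] * _cluster_density(baf, float(mu), params.baf_sd)
    w = params.outlier_weight
    return (1.0 - w) * mix + w * 1.0


def emission_loglik(state: str, lrr, baf, pfb, params: HmmParams | None = None) -> np.ndarray:
    """Joint per-marker emission log-likelihood: Gaussian LRR density plus
    the state's BAF mixture log-density."""
    params = params or HmmParams()
    lrr = np.asarray(lrr, dtype=float)
    ll_lrr = norm.logpdf(lrr, params.lrr_means[state], params.lrr_sds[state])
    ll_baf = np.log(baf_likelihood(state, np.asarray(baf, dtype=float), pfb, params))
    return ll_lrr + ll_baf


def emission_matrix(lrr, baf, pfb, params: HmmParams) -> np.ndarray:
    """n_markers x 6 emission log-likelihoods in state order."""
    return np.stack(
        [emission_loglik(s, lrr, baf, pfb, params) for s in STATE_NAMES], axis=1
    )


def transition_matrix(distance_bp: float, params: HmmParams | None = None) -> np.ndarray:
    """Distance-dependent transition matrix: off-diagonal i->j equals
    prior_j * rho(d) with rho(d) = rho_max * (1 - exp(-d / D)); the diagonal
    takes the remainder.  rho(0) = 0, so coincident markers cannot switch
    state; as d -> infinity rows approach the (renormalised) priors."""
    params = params or HmmParams()
    if distance_bp < 0:
        raise ValueError("distance_bp must be >= 0")
    pri = params.prior_vector
    rho = params.rho_max * (1.0 - np.exp(-distance_bp / params.distance_scale_bp))
    mat = np.tile(pri * rho, (len(pri), 1))
    np.fill_diagonal(mat, 0.0)
    np.fill_diagonal(mat, 1.0 - mat.sum(axis=1))
    return mat


def _log_transition_stack(distances: np.ndarray, params: HmmParams) -> np.ndarray:
    """(n-1) x 6 x 6 log transition matrices for consecutive marker gaps."""
    pri = params.prior_vector
    rho = params.rho_max * (1.0 - np.exp(-distances / params.distance_scale_bp))
    k = len(pri)
    mats = np.tile(pri[None, None, :], (len(distances), k, 1)) * rho[:, None, None]
    eye = np.eye(k, dtype=bool)
    mats[:, eye] = 0.0
    diag = 1.0 - mats.sum(axis=2)
    mats[:, eye] = diag
    with np.errstate(divide="ignore"):
        return np.log(mats)


@dataclass
class Segment:
    """A raw Viterbi segment in any non-diploid state (CN2-LOH included;
    it is excluded from the CNV list at the filter stage)."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    state: str
    n_probes: int
    confidence: float

    @property
    def copy_number(self) -> int:
        return STATE_COPY_NUMBER[self.state]

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def viterbi_path(emissions: np.ndarray, positions: np.ndarray, params: HmmParams) -> np.ndarray:
    """Most probable state sequence for one chromosome (log-space Viterbi
    with distance-dependent transitions)."""
    n = emissions.shape[0]
    with np.errstate(divide="ignore"):
        log_prior = np.log(params.prior_vector)
    if n == 0:
        return np.empty(0, dtype=int)
    logT = _log_transition_stack(np.diff(positions).astype(float), params)
    delta = log_prior + emissions[0]
    psi = np.empty((n, len(STATE_NAMES)), dtype=np.int8)
    for t in range(1, n):
        scores = delta[:, None] + logT[t - 1]
        psi[t] = np.argmax(scores, axis=0)
        delta = scores[psi[t], np.arange(len(STATE_NAMES))] + emissions[t]
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path


def bayes_factor(emissions: np.ndarray, idx: np.ndarray, state: str) -> float:
    """Emission-only log10 likelihood ratio of ``state`` versus diploid CN2
    summed over a segment's probes — the call-confidence score."""
    s = STATE_NAMES.index(state)
    return float((emissions[idx, s] - emissions[idx, CN2_INDEX]).sum() / np.log(10.0))


def viterbi_segments(
    sample: IntensitySample,
    marker_map: MarkerMap,
    params: HmmParams | None = None,
    lrr: np.ndarray | None = None,
    autosomes_only: bool = True,
) -> list[Segment]:
    """Run the HMM per chromosome and emit maximal non-diploid runs as raw
    segments with Bayes-factor confidences.  ``lrr`` overrides the sample's
    stored LRR (used to pass corrected values)."""
    params = params or HmmParams()
    lrr_all = sample.lrr if lrr is None else np.asarray(lrr, dtype=float)
    segments: list[Segment] = []
    chroms = marker_map.chromosomes
    if autosomes_only:
        chroms = [c for c in chroms if c in AUTOSOMES]
    for chrom in chroms:
        idx = marker_map.chrom_index(chrom)
        if len(idx) < 2:
            warnings.warn(f"chromosome {chrom}: fewer than 2 markers, skipped")
            continue
        pos = marker_map.positions[idx]
        em = emission_matrix(lrr_all[idx], sample.baf[idx], marker_map.pfb[idx], params)
        path = viterbi_path(em, pos, params)
        # maximal runs of a single non-CN2 state
        change = np.flatnonzero(np.diff(path)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(path)]])
        for a, b in zip(starts, ends):
            s = path[a]
            if s == CN2_INDEX:
                continue
            seg_idx = np.arange(a, b)
            segments.append(
                Segment(
                    sample_id=sample.sample_id,
                    chromosome=chrom,
                    start_bp=int(pos[a]),
                    end_bp=int(pos[b - 1]),
                    state=STATE_NAMES[s],
                    n_probes=int(b - a),
                    confidence=bayes_factor(em, seg_idx, STATE_NAMES[s]),
                )
            )
    return segments


def _segment_confidence(
    sample: IntensitySample,
    marker_map: MarkerMap,
    params: HmmParams,
    seg: Segment,
    lrr: np.ndarray | None,
) -> tuple[int, float]:
    """Recount probes and recompute the Bayes factor of a (possibly merged
    or split) segment from the map."""
    idx = marker_map.region_index(seg.chromosome, seg.start_bp, seg.end_bp)
    if len(idx) == 0:
        return 0, float("-inf")
    lrr_all = sample.lrr if lrr is None else lrr
    em_state = emission_loglik(seg.state, lrr_all[idx], sample.baf[idx], marker_map.pfb[idx], params)
    em_cn2 = emission_loglik("CN2", lrr_all[idx], sample.baf[idx], marker_map.pfb[idx], params)
    return len(idx), float((em_state - em_cn2).sum() / np.log(10.0))


def filter_calls(segments: list[Segment], params: HmmParams | None = None) -> list[Segment]:
    """Quality filters: homozygous deletions (CN0) need >= 3 probes, all
    other CNVs >= 15; confidence must reach the Bayes-factor threshold;
    copy-neutral LOH segments are routed out of the CNV list."""
    params = params or HmmParams()
    out = []
    for seg in segments:
        if seg.state == "CN2_LOH":
            continue
        min_probes = params.min_probes_homozygous_del if seg.state == "CN0" else params.min_probes_other
        if seg.n_probes < min_probes:
            continue
        if seg.confidence < params.min_confidence:
            continue
        out.append(seg)
    return out


def merge_adjacent(
    segments: list[Segment],
    sample: IntensitySample,
    marker_map: MarkerMap,
    params: HmmParams | None = None,
    lrr: np.ndarray | None = None,
) -> list[Segment]:
    """Merge same-copy-number neighbours whose gap is strictly less than
    20% of the smaller call's length; probe counts and confidences are
    recomputed over the merged span (gap probes included); iterates to a
    fixed point."""
    params = params or HmmParams()
    by_key: dict[tuple[str, str], list[Segment]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample_id, seg.chromosome), []).append(seg)
    out: list[Segment] = []
    for key, segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start_bp)
        for a, b in zip(segs, segs[1:]):
            if b.start_bp <= a.end_bp:
                raise ValueError(f"overlapping input calls at {key}")
        changed = True
        while changed:
            changed = False
            merged: list[Segment] = []
            i = 0
            while i < len(segs):
                cur = segs[i]
                if i + 1 < len(segs):
                    nxt = segs[i + 1]
                    gap = nxt.start_bp - cur.end_bp - 1
                    smaller = min(cur.length_bp, nxt.length_bp)
                    if cur.copy_number == nxt.copy_number and gap < params.merge_gap_fraction * smaller:
                        new = replace(cur, end_bp=nxt.end_bp)
                        n_probes, conf = _segment_confidence(sample, marker_map, params, new, lrr)
                        new = replace(new, n_probes=n_probes, confidence=conf)
                        segs[i + 1] = new
                        i += 1
                        changed = True
                        continue
                merged.append(cur)
                i += 1
            segs = merged
        out.extend(segs)
    return sorted(out, key=lambda s: (s.sample_id, s.chromosome, s.start_bp))


def split_at_centromere(
    segments: list[Segment],
    centromeres: pd.DataFrame,
    sample: IntensitySample,
    marker_map: MarkerMap,
    params: HmmParams | None = None,
    lrr: np.ndarray | None = None,
) -> list[Segment]:
    """Split any call spanning a centromere into a p-arm call ending at the
    last probe before the gap and a q-arm call starting at the first probe
    after; counts and confidences are recomputed, and a probe-free side is
    dropped with a warning."""
    params = params or HmmParams()
    cen = {
        str(r["chromosome"]): (int(r["start_bp"]), int(r["end_bp"]))
        for _, r in centromeres.iterrows()
    }
    out: list[Segment] = []
    for seg in segments:
        if seg.chromosome not in cen:
            out.append(seg)
            continue
        cs, ce = cen[seg.chromosome]
        if seg.end_bp < cs or seg.start_bp > ce:
            out.append(seg)
            continue
        halves = []
        idx = marker_map.chrom_index(seg.chromosome)
        pos = marker_map.positions[idx]
        p_side = pos[(pos >= seg.start_bp) & (pos < cs)]
        q_side = pos[(pos > ce) & (pos <= seg.end_bp)]
        if len(p_side):
            halves.append(replace(seg, start_bp=int(p_side[0]), end_bp=int(p_side[-1])))
        if len(q_side):
            halves.append(replace(seg, start_bp=int(q_side[0]), end_bp=int(q_side[-1])))
        if not halves:
            warnings.warn(
                f"call {seg.chromosome}:{seg.start_bp}-{seg.end_bp} lies entirely in the "
                "centromere gap with no probes; dropped"
            )
        for half in halves:
            n_probes, conf = _segment_confidence(sample, marker_map, params, half, lrr)
            if n_probes == 0:
                continue
            out.append(replace(half, n_probes=n_probes, confidence=conf))
    return sorted(out, key=lambda s: (s.sample_id, s.chromosome, s.start_bp))


def segments_to_calls(segments: list[Segment]) -> list[CnvCall]:
    return [
        CnvCall(s.sample_id, s.chromosome, s.start_bp, s.end_bp, s.copy_number,
                s.n_probes, s.confidence)
        for s in segments
        if s.state != "CN2_LOH"
    ]


def call_cnvs(
    sample: IntensitySample,
    marker_map: MarkerMap,
    params: HmmParams | None = None,
    centromeres: pd.DataFrame | None = None,
    lrr: np.ndarray | None = None,
) -> list[CnvCall]:
    """Full per-sample pipeline: Viterbi segmentation, adjacency merging,
    centromere splitting, then probe-count/confidence filtering."""
    params = params or HmmParams()
    segs = viterbi_segments(sample, marker_map, params, lrr=lrr)
    segs = merge_adjacent(segs, sample, marker_map, params, lrr=lrr)
    if centromeres is not None and len(centromeres):
        segs = split_at_centromere(segs, centromeres, sample, marker_map, params, lrr=lrr)
    segs = filter_calls(segs, params)
    return segments_to_calls(segs)
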