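"""Runs of homozygosity: calling, burden comparison and the case/control
region scan.

A run must satisfy five criteria simultaneously: span >= 1 Mb, >= 100 SNPs,
density of at least one SNP per 50 kb, no more than one heterozygous call
per Mb of span (floor of one), and no inter-marker gap above 1 Mb.  Calling
is performed on a MAF- and LD-pruned marker set; missing genotypes are
neutral (they neither break a run nor count as heterozygous).

The region scan mirrors the published procedure: seed regions where >= 10
cases carry an overlapping ROH are extended outward while >= 7 cases still
overlap and no new control carrier appears; separately, regions with >= 7
case carriers and zero control carriers are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import IntensitySample, MarkerMap, RohSegment
from .association import permute_label_test


@dataclass
class RohParams:
    min_length_kb: float = 1000.0
    min_snps: int = 100
    max_kb_per_snp: float = 50.0   # density: at least one SNP per 50 kb
    max_het_per_mb: float = 1.0    # floor of one het allowed regardless of span
    max_gap_kb: float = 1000.0

    def het_budget(self, span_bp: int) -> int:
        return max(1, int(np.floor(self.max_het_per_mb * span_bp / 1_000_000)))


def _validate_run(pos, het_mask, params: RohParams) -> bool:
    span = int(pos[-1] - pos[0] + 1)
    n = len(pos)
    if span < params.min_length_kb * 1000:
        return False
    if n < params.min_snps:
        return False
    if span / n > params.max_kb_per_snp * 1000:
        return False
    if int(het_mask.sum()) > params.het_budget(span):
        return False
    if n > 1 and np.max(np.diff(pos)) > params.max_gap_kb * 1000:
        return False
    return True


def call_roh_sample(
    genotype: np.ndarray,
    marker_map: MarkerMap,
    sample_id: str,
    params: RohParams | None = None,
    marker_subset: np.ndarray | None = None,
) -> list[RohSegment]:
    """Greedy maximal-run ROH calling for one sample over (optionally
    subset) map markers.

    Runs grow marker by marker; a heterozygote is admitted only while the
    running one-per-Mb budget holds, a gap > 1 Mb closes the run, and a
    closed run is emitted when all five criteria hold.  After a violation
    the scan restarts just past the first heterozygote of the closed run so
    later windows are not missed.
    """
    params = params or RohParams()
    g = np.asarray(genotype)
    segments: list[RohSegment] = []
    for chrom in marker_map.chromosomes:
        cidx = marker_map.chrom_index(chrom)
        if marker_subset is not None:
            cidx = cidx[np.isin(cidx, marker_subset)]
        if len(cidx) == 0:
            continue
        pos = marker_map.positions[cidx]
        gt = g[cidx]
        n = len(cidx)
        start = 0
        while start < n:
            i = start
            j = start  # run is [i..j]
            het_positions: list[int] = [i] if gt[i] == 1 else []
            broke_at = None
            while j + 1 < n:
                nxt = j + 1
                if (pos[nxt] - pos[j]) > params.max_gap_kb * 1000:
                    broke_at = nxt
                    break
                if gt[nxt] == 1:
                    span = int(pos[nxt] - pos[i] + 1)
                    if len(het_positions) + 1 > params.het_budget(span):
                        broke_at = nxt
                        break
                    het_positions.append(nxt)
                j = nxt
            run_pos = pos[i : j + 1]
            run_het = gt[i : j + 1] == 1
            valid = _validate_run(run_pos, run_het, params)
            if valid:
                segments.append(
                    RohSegment(
                        sample_id=sample_id,
                        chromosome=chrom,
                        start_bp=int(run_pos[0]),
                        end_bp=int(run_pos[-1]),
                        n_snps=int(len(run_pos)),
                        n_het=int(run_het.sum()),
                    )
                )
            if broke_at is None:
                break
            if valid:
                # an emitted run is maximal; continue past its break point
                start = broke_at
            else:
                # retry just past the run's first het so a cleaner window
                # starting inside the failed run is not missed
                start = (het_positions[0] + 1) if het_positions else broke_at
                if start <= i:
                    start = broke_at
    return segments


def call_roh(
    samples: list[IntensitySample],
    marker_map: MarkerMap,
    params: RohParams | None = None,
    marker_subset: np.ndarray | None = None,
    pruned: bool = True,
) -> list[RohSegment]:
    """Cohort ROH calling.  ``marker_subset`` should be the MAF >= 1% and
    r^2 <= 0.30 pruned marker index; calling on unpruned markers is allowed
    but warned (LD segments masquerade as autozygosity)."""
    if not pruned:
        warnings.warn("calling ROH on unpruned markers; results not comparable")
    out: list[RohSegment] = []
    for s in samples:
        out.extend(call_roh_sample(s.genotype, marker_map, s.sample_id, params, marker_subset))
    return out


def validate_roh_segments(
    segments: list[RohSegment],
    samples: dict[str, np.ndarray],
    marker_map: MarkerMap,
    params: RohParams | None = None,
    marker_subset: np.ndarray | None = None,
) -> pd.DataFrame:
    """Independent post-hoc checker: recompute every constraint for every
    emitted segment directly from the genotypes.  Returns a table with one
    row per segment and boolean columns per criterion."""
    params = params or RohParams()
    rows = []
    for seg in segments:
        idx = marker_map.region_index(seg.chromosome, seg.start_bp, seg.end_bp)
        if marker_subset is not None:
            idx = idx[np.isin(idx, marker_subset)]
        pos = marker_map.positions[idx]
        gt = samples[seg.sample_id][idx]
        span = seg.end_bp - seg.start_bp + 1
        n = len(idx)
        rows.append(
            {
                "sample_id": seg.sample_id,
                "chromosome": seg.chromosome,
                "start_bp": seg.start_bp,
                "end_bp": seg.end_bp,
                "length_ok": span >= params.min_length_kb * 1000,
                "snps_ok": n >= params.min_snps,
                "density_ok": n > 0 and span / n <= params.max_kb_per_snp * 1000,
                "het_ok": int((gt == 1).sum()) <= params.het_budget(span),
                "gap_ok": n < 2 or float(np.max(np.diff(pos))) <= params.max_gap_kb * 1000,
            }
        )
    tab = pd.DataFrame(rows)
    if len(tab):
        tab["all_ok"] = tab[["length_ok", "snps_ok", "density_ok", "het_ok", "gap_ok"]].all(axis=1)
    return tab


# ------------------------------------------------------------------- burden

def roh_burden_summary(
    segments: list[RohSegment],
    phenotypes: pd.DataFrame,
    n_perms: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-group ROH burden (count, rate per sample, proportion of samples
    with >= 1 run, mean per-sample total span, mean run size) with one-sided
    empirical p-values from case/control label permutation."""
    ids = phenotypes["sample_id"].tolist()
    labels = (phenotypes["status"] == "case").to_numpy()
    if labels.all() or not labels.any():
        raise ValueError("both a case and a control group are required")
    pos = {s: i for i, s in enumerate(ids)}
    counts = np.zeros(len(ids))
    total_kb = np.zeros(len(ids))
    for seg in segments:
        if seg.sample_id not in pos:
            raise ValueError(f"segment for unknown sample {seg.sample_id!r}")
        counts[pos[seg.sample_id]] += 1
        total_kb[pos[seg.sample_id]] += seg.length_kb

    def group_stats(mask):
        n = int(mask.sum())
        n_events = int(counts[mask].sum())
        return {
            "n_samples": n,
            "n_events": n_events,
            "rate": n_events / n,
            "prop_with_event": float((counts[mask] > 0).mean()),
            "mean_total_kb_per_sample": float(total_kb[mask].mean()),
            "mean_event_kb": float(total_kb[mask].sum() / n_events) if n_events else 0.0,
        }

    rows = {
        "case": group_stats(labels),
        "control": group_stats(~labels),
    }
    if segments:
        tests = {
            "rate": permute_label_test(counts, labels, n_perms=n_perms, seed=seed),
            "prop_with_event": permute_label_test((counts > 0).astype(float), labels,
                                                  n_perms=n_perms, seed=seed + 1),
            "mean_total_kb_per_sample": permute_label_test(total_kb, labels,
                                                           n_perms=n_perms, seed=seed + 2),
            "mean_event_kb": permute_label_test(total_kb, labels, denominators=counts,
                                                n_perms=n_perms, seed=seed + 3),
        }
        pvals = {k: t.emp1 for k, t in tests.items()}
    else:
        pvals = {k: 1.0 for k in ("rate", "prop_with_event",
                                  "mean_total_kb_per_sample", "mean_event_kb")}
    tab = pd.DataFrame(rows).T
    tab["group"] = tab.index
    pcol = pd.Series(pvals, name="perm_p")
    out = tab.reset_index(drop=True)
    out = out[["group", "n_samples", "n_events", "rate", "prop_with_event",
               "mean_total_kb_per_sample", "mean_event_kb"]]
    out.attrs["perm_p"] = pvals
    return out, pcol


# ---------------------------------------------------------------- region scan

def _carrier_counts(segments, phenotypes, marker_map):
    ids = phenotypes["sample_id"].tolist()
    is_case = dict(zip(ids, phenotypes["status"] == "case"))
    case_c = np.zeros(len(marker_map), dtype=int)
    ctrl_c = np.zeros(len(marker_map), dtype=int)
    by_sample: dict[str, list[RohSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    for sid, segs in by_sample.items():
        cover = np.zeros(len(marker_map), dtype=bool)
        for seg in segs:
            cover[marker_map.region_index(seg.chromosome, seg.start_bp, seg.end_bp)] = True
        if is_case.get(sid, False):
            case_c += cover
        else:
            ctrl_c += cover
    return case_c, ctrl_c


def _maximal_runs(mask: np.ndarray):
    change = np.flatnonzero(np.diff(mask.astype(int)))
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [len(mask)]])
    return [(a, b) for a, b in zip(starts, ends) if mask[a]]


def roh_region_scan(
    segments: list[RohSegment],
    phenotypes: pd.DataFrame,
    marker_map: MarkerMap,
    core_cases: int = 10,
    flank_min_cases: int = 7,
    alt_min_cases: int = 7,
) -> pd.DataFrame:
    """Case-enriched ROH regions.

    (a) Seed regions are maximal marker runs with >= ``core_cases`` case
    carriers; each is extended marker-by-marker in both directions while
    case carriers stay >= ``flank_min_cases`` and the control-carrier count
    does not exceed its maximum over the seed.  (b) Maximal runs with
    >= ``alt_min_cases`` case carriers and zero control carriers are
    reported separately (skipping any already inside an (a) region).
    Output columns mirror the published region table: minAFF/maxAFF are the
    min/max case-carrier counts across the final region, numUNAFF the
    maximum control-carrier count.
    """
    case_c, ctrl_c = _carrier_counts(segments, phenotypes, marker_map)
    pos = marker_map.positions
    chrom_arr = marker_map.table["chromosome"].to_numpy()
    regions = []
    for chrom in marker_map.chromosomes:
        cidx = marker_map.chrom_index(chrom)
        cc = case_c[cidx]
        uc = ctrl_c[cidx]
        cpos = pos[cidx]
        n = len(cidx)
        taken = np.zeros(n, dtype=bool)
        for a, b in _maximal_runs(cc >= core_cases):
            seed_ctrl = int(uc[a:b].max()) if b > a else 0
            lo, hi = a, b - 1
            while lo - 1 >= 0 and cc[lo - 1] >= flank_min_cases and uc[lo - 1] <= seed_ctrl:
                lo -= 1
            while hi + 1 < n and cc[hi + 1] >= flank_min_cases and uc[hi + 1] <= seed_ctrl:
                hi += 1
            taken[lo : hi + 1] = True
            regions.append(
                {
                    "chromosome": chrom,
                    "start_bp": int(cpos[lo]),
                    "end_bp": int(cpos[hi]),
                    "min_aff": int(cc[lo : hi + 1].min()),
                    "max_aff": int(cc[lo : hi + 1].max()),
                    "num_unaff": int(uc[lo : hi + 1].max()),
                    "rule": "core10_extend",
                }
            )
        for a, b in _maximal_runs((cc >= alt_min_cases) & (uc == 0)):
            if taken[a:b].all():
                continue
            regions.append(
                {
                    "chromosome": chrom,
                    "start_bp": int(cpos[a]),
                    "end_bp": int(cpos[b - 1]),
                    "min_aff": int(cc[a:b].min()),
                    "max_aff": int(cc[a:b].max()),
                    "num_unaff": 0,
                    "rule": "cases7_zero_controls",
                }
            )
    cols = ["chromosome", "start_bp", "end_bp", "min_aff", "max_aff", "num_unaff", "rule"]
    out = pd.DataFrame(regions, columns=cols)
    return out.sort_values(["chromosome", "start_bp"]).reset_index(drop=True)
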