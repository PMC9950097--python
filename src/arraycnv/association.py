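"""Case-control burden statistics, label-permutation inference, the
segmental (per-locus) scan and known-locus annotation.

Inference is purely empirical: the case/control labels are permuted while
group sizes are preserved, and p-values use the (r + 1) / (n + 1) estimator
so they are never zero.  The segmental scan reports both a pointwise
empirical p (EMP1) and a family-wise max-statistic p (EMP2): the fraction
of permutations whose genome-wide maximum statistic reaches the locus's
observed value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CnvCall, MarkerMap


def interval_length(start_bp: int, end_bp: int) -> dict:
    """Length of a 1-based inclusive interval: bp = end - start + 1, kb
    rounded to the nearest integer, Mb to one decimal."""
    if start_bp > end_bp:
        raise ValueError("interval start > end")
    bp = int(end_bp) - int(start_bp) + 1
    return {"bp": bp, "kb": int(round(bp / 1000.0)), "mb": round(bp / 1e6, 1)}


# ------------------------------------------------------------------- burden

def cnv_burden_summary(
    calls: list[CnvCall],
    phenotypes: pd.DataFrame,
    min_kb: float = 100.0,
) -> pd.DataFrame:
    """Per-group CNV burden over calls strictly larger than ``min_kb``:
    event count, rate per sample, proportion of samples with >= 1 event,
    mean per-sample total kb and mean event size kb."""
    ids = phenotypes["sample_id"].tolist()
    pos = {s: i for i, s in enumerate(ids)}
    labels = (phenotypes["status"] == "case").to_numpy()
    counts = np.zeros(len(ids))
    total_kb = np.zeros(len(ids))
    for c in calls:
        if c.length_kb <= min_kb:
            continue
        if c.sample_id not in pos:
            raise ValueError(f"call for sample {c.sample_id!r} absent from phenotype table")
        counts[pos[c.sample_id]] += 1
        total_kb[pos[c.sample_id]] += c.length_kb

    rows = []
    for group, mask in (("case", labels), ("control", ~labels)):
        n = int(mask.sum())
        n_events = int(counts[mask].sum())
        rows.append(
            {
                "group": group,
                "n_samples": n,
                "n_events": n_events,
                "rate": n_events / n if n else float("nan"),
                "prop_with_event": float((counts[mask] > 0).mean()) if n else float("nan"),
                "mean_total_kb_per_sample": float(total_kb[mask].mean()) if n else float("nan"),
                "mean_event_kb": float(total_kb[mask].sum() / n_events) if n_events else 0.0,
            }
        )
    return pd.DataFrame(rows)


def per_sample_burden_vectors(calls, phenotypes, min_kb: float = 100.0):
    """(counts, total_kb, case_labels) aligned to the phenotype table, over
    calls strictly larger than ``min_kb`` — inputs for the permutation
    tests."""
    ids = phenotypes["sample_id"].tolist()
    pos = {s: i for i, s in enumerate(ids)}
    labels = (phenotypes["status"] == "case").to_numpy()
    counts = np.zeros(len(ids))
    total_kb = np.zeros(len(ids))
    for c in calls:
        if c.length_kb > min_kb and c.sample_id in pos:
            counts[pos[c.sample_id]] += 1
            total_kb[pos[c.sample_id]] += c.length_kb
    return counts, total_kb, labels


# -------------------------------------------------------------- permutation

@dataclass
class PermResult:
    statistic_name: str
    observed: float
    n_perms: int
    emp1: float
    emp2: float
    seed: int


def permute_label_test(
    values: np.ndarray,
    case_labels: np.ndarray,
    n_perms: int = 10_000,
    seed: int = 0,
    sided: str = "one",
    denominators: np.ndarray | None = None,
    statistic_name: str = "mean_difference",
) -> PermResult:
    """Label-permutation test for a difference of group summaries.

    Without ``denominators`` the statistic is mean(case values) -
    mean(control values).  With ``denominators`` it is the ratio-of-sums
    difference sum(values)/sum(denominators) per group (e.g. mean event
    size from per-sample totals and counts); a group whose denominator sum
    is zero contributes 0.  ``sided='one'`` tests case > control;
    ``sided='two'`` compares absolute values.  emp1 = (1 + #{perm >= obs})
    / (1 + n_perms); emp2 equals emp1 for a single statistic.
    """
    if n_perms < 100:
        raise ValueError("n_perms must be >= 100")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(case_labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both groups must be non-empty")
    n = len(values)
    n_case = int(labels.sum())

    def stat(mask_matrix: np.ndarray) -> np.ndarray:
        # mask_matrix: n_perm x n boolean
        if denominators is None:
            case_mean = mask_matrix @ values / n_case
            ctrl_mean = (~mask_matrix) @ values / (n - n_case)
            return case_mean - ctrl_mean
        den = np.asarray(denominators, dtype=float)
        num_c = mask_matrix @ values
        den_c = mask_matrix @ den
        num_u = values.sum() - num_c
        den_u = den.sum() - den_c
        with np.errstate(divide="ignore", invalid="ignore"):
            mc = np.where(den_c > 0, num_c / np.where(den_c > 0, den_c, 1), 0.0)
            mu = np.where(den_u > 0, num_u / np.where(den_u > 0, den_u, 1), 0.0)
        return mc - mu

    observed = float(stat(labels[None, :])[0])
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perms)
    chunk = 2000
    base = np.zeros(n, dtype=bool)
    base[:n_case] = True
    done = 0
    while done < n_perms:
        k = min(chunk, n_perms - done)
        masks = rng.permuted(np.tile(base, (k, 1)), axis=1)
        perm_stats[done : done + k] = stat(masks)
        done += k
    if sided == "two":
        exceed = np.abs(perm_stats) >= np.abs(observed) - 1e-12
    else:
        exceed = perm_stats >= observed - 1e-12
    emp1 = (1.0 + int(exceed.sum())) / (1.0 + n_perms)
    return PermResult(statistic_name, observed, n_perms, emp1, emp1, seed)


# ----------------------------------------------------------- segmental scan

def carrier_matrix(calls: list[CnvCall], sample_ids: list[str], marker_map: MarkerMap) -> np.ndarray:
    """Boolean samples x markers matrix: does a sample's CNV cover the
    marker."""
    pos = {s: i for i, s in enumerate(sample_ids)}
    mat = np.zeros((len(sample_ids), len(marker_map)), dtype=bool)
    for c in calls:
        if c.sample_id in pos:
            mat[pos[c.sample_id], marker_map.region_index(c.chromosome, c.start_bp, c.end_bp)] = True
    return mat


def segmental_scan(
    calls: list[CnvCall],
    phenotypes: pd.DataFrame,
    marker_map: MarkerMap,
    n_perms: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-marker case-enrichment scan with label permutation.

    The statistic at each marker is the case carrier count minus the
    control carrier count scaled by n_case/n_control (one-sided,
    case-enriched).  EMP1 is pointwise; EMP2 is the max-statistic
    family-wise p: the fraction of permutations whose genome-wide maximum
    statistic reaches the marker's observed value.
    """
    ids = phenotypes["sample_id"].tolist()
    labels = (phenotypes["status"] == "case").to_numpy()
    n_case = int(labels.sum())
    n_ctrl = len(ids) - n_case
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("both groups must be non-empty")
    cols = ["chromosome", "position_bp", "case_carriers", "control_carriers",
            "statistic", "emp1", "emp2"]
    if not calls:
        return pd.DataFrame(columns=cols)
    mat = carrier_matrix(calls, ids, marker_map).astype(np.float32)
    scale = n_case / n_ctrl

    def stats_for(mask_matrix: np.ndarray) -> np.ndarray:
        case_counts = mask_matrix.astype(np.float32) @ mat
        ctrl_counts = (~mask_matrix).astype(np.float32) @ mat
        return case_counts - scale * ctrl_counts

    obs = stats_for(labels[None, :])[0]
    rng = np.random.default_rng(seed)
    exceed1 = np.zeros(len(obs), dtype=np.int64)
    exceed_max = np.zeros(len(obs), dtype=np.int64)
    base = np.zeros(len(ids), dtype=bool)
    base[:n_case] = True
    done = 0
    chunk = 512
    while done < n_perms:
        k = min(chunk, n_perms - done)
        masks = rng.permuted(np.tile(base, (k, 1)), axis=1)
        ps = stats_for(masks)
        exceed1 += (ps >= obs[None, :] - 1e-6).sum(axis=0)
        gmax = ps.max(axis=1)
        exceed_max += (gmax[:, None] >= obs[None, :] - 1e-6).sum(axis=0)
        done += k
    emp1 = (1.0 + exceed1) / (1.0 + n_perms)
    emp2 = (1.0 + exceed_max) / (1.0 + n_perms)
    case_carriers = mat[labels].sum(axis=0).astype(int)
    ctrl_carriers = mat[~labels].sum(axis=0).astype(int)
    return pd.DataFrame(
        {
            "chromosome": marker_map.table["chromosome"],
            "position_bp": marker_map.table["position_bp"],
            "case_carriers": case_carriers,
            "control_carriers": ctrl_carriers,
            "statistic": obs,
            "emp1": emp1,
            "emp2": np.maximum(emp1, emp2),
        }
    )


# -------------------------------------------------------------- known loci

def _overlap_bp(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def annotate_known_loci(
    calls: list[CnvCall],
    known: pd.DataFrame,
    reciprocal_overlap: float = 0.0,
    gene_bed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Annotate each call with the known loci it overlaps, requiring the
    call's direction (loss for CN < 2, gain for CN > 2) to match the locus
    ``cnv_type`` (loss/gain/both).  ``reciprocal_overlap`` > 0 additionally
    requires that fraction of both intervals to overlap.  With a gene table
    (1-based columns chromosome/start_bp/end_bp/name) the number of genes
    each call spans is reported."""
    rows = []
    for c in calls:
        direction = "loss" if c.copy_number < 2 else "gain"
        hits = []
        for _, loc in known.iterrows():
            if str(loc["chromosome"]) != c.chromosome:
                continue
            if loc["cnv_type"] not in (direction, "both"):
                continue
            ov = _overlap_bp(c.start_bp, c.end_bp, int(loc["start_bp"]), int(loc["end_bp"]))
            if ov <= 0:
                continue
            if reciprocal_overlap > 0:
                len_call = c.end_bp - c.start_bp + 1
                len_loc = int(loc["end_bp"]) - int(loc["start_bp"]) + 1
                if ov / len_call < reciprocal_overlap or ov / len_loc < reciprocal_overlap:
                    continue
            hits.append(str(loc["name"]))
        n_genes = None
        if gene_bed is not None:
            sub = gene_bed[gene_bed["chromosome"] == c.chromosome]
            n_genes = int(
                ((sub["start_bp"] <= c.end_bp) & (sub["end_bp"] >= c.start_bp)).sum()
            )
        rows.append(
            {
                "sample_id": c.sample_id,
                "chromosome": c.chromosome,
                "start_bp": c.start_bp,
                "end_bp": c.end_bp,
                "copy_number": c.copy_number,
                "length_kb": interval_length(c.start_bp, c.end_bp)["kb"],
                "known_loci": ";".join(hits),
                "n_genes": n_genes,
            }
        )
    return pd.DataFrame(rows)
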