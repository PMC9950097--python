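"""Self-contained recovery benchmarks on simulated cohorts.

These drive the whole pipeline — simulation with planted truth, intensity
correction, HMM calling or mosaic screening — and score the results against
the planted events.  They back both the test suite's end-to-end checks and
the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import cnv_hmm, intensity_correction, mosaic_screen, synthetic_data
from .core import MarkerMap, NoiseModel, TruthEvent, centromere_table


def simulate_cnv_cohort(
    n_samples: int = 60,
    n_markers: int = 3000,
    seed: int = 0,
    events_per_sample: tuple[int, int] = (1, 3),
    probe_range: tuple[int, int] = (16, 80),
    noise: NoiseModel | None = None,
):
    """Cohort on one 60 Mb chromosome (centromere at 24-26 Mb) with planted
    deletions and duplications of >= 15 probes, GC waves and two intensity
    batches."""
    cen = centromere_table({"1": (24_000_000, 26_000_000)})
    m = synthetic_data.generate_marker_map(
        n_markers, {"1": 60_000_000}, centromeres=cen, seed=seed)
    rng = np.random.default_rng(seed + 1)
    pos = m.positions
    events: list[TruthEvent] = []
    for i in range(n_samples):
        sid = f"case_{i + 1:04d}"
        for _ in range(int(rng.integers(*events_per_sample))):
            n_probes = int(rng.integers(*probe_range))
            j = int(rng.integers(0, len(m) - n_probes))
            start, end = int(pos[j]), int(pos[j + n_probes - 1])
            # keep a sample's events well separated so merging is unambiguous,
            # and off the centromere so the split rule does not apply
            if start <= 26_000_000 and end >= 24_000_000:
                continue
            if any(e.sample_id == sid
                   and not (end < e.start_bp - 3_000_000 or start > e.end_bp + 3_000_000)
                   for e in events):
                continue
            cn = int(rng.choice([0, 1, 3, 4]))
            events.append(TruthEvent(sid, "cnv", "1", start, end, cn))
    noise = noise or NoiseModel(gc_wave_amplitude=0.3, batch_shift_sd=0.1)
    cohort = synthetic_data.simulate_cohort(
        m, n_samples, 0, events, noise=noise, seed=seed + 2, n_batches=2)
    return m, cen, cohort


def run_cnv_recovery(
    n_samples: int = 60,
    n_markers: int = 3000,
    seed: int = 0,
    probe_tol: int = 3,
    correct: bool = True,
    params: cnv_hmm.HmmParams | None = None,
):
    """End-to-end CNV recovery: returns (precision, recall, calls, truth)."""
    m, cen, cohort = simulate_cnv_cohort(n_samples, n_markers, seed)
    lrr = np.stack([s.lrr for s in cohort.samples])
    if correct:
        n_pcs = min(10, len(cohort.samples) - 2)
        lrr = intensity_correction.correct_cohort(m, lrr, n_pcs=n_pcs)
    calls = []
    for s, row in zip(cohort.samples, lrr):
        calls.extend(cnv_hmm.call_cnvs(s, m, params, centromeres=cen, lrr=row))
    precision, recall = match_calls_to_truth(calls, cohort.truth, m, probe_tol)
    return precision, recall, calls, cohort.truth


def match_calls_to_truth(calls, truth, marker_map: MarkerMap, probe_tol: int = 3):
    """Breakpoint-tolerant scoring: a call matches a planted event when the
    sample agrees, the direction (deletion/duplication) agrees, and both
    boundary probe indices are within ``probe_tol`` probes of the truth."""
    def probe_span(chrom, s, e):
        idx = marker_map.region_index(chrom, s, e)
        return (int(idx[0]), int(idx[-1])) if len(idx) else (0, -1)

    matched_calls: set[int] = set()
    matched_truth: set[int] = set()
    for ti, t in enumerate(truth):
        t0, t1 = probe_span(t.chromosome, t.start_bp, t.end_bp)
        for ci, c in enumerate(calls):
            if ci in matched_calls or c.sample_id != t.sample_id:
                continue
            if (c.copy_number < 2) != (t.copy_number < 2):
                continue
            c0, c1 = probe_span(c.chromosome, c.start_bp, c.end_bp)
            if abs(c0 - t0) <= probe_tol and abs(c1 - t1) <= probe_tol:
                matched_calls.add(ci)
                matched_truth.add(ti)
                break
    precision = len(matched_calls) / len(calls) if calls else 1.0
    recall = len(matched_truth) / len(truth) if truth else 1.0
    return precision, recall


def run_mosaic_recovery(seed: int = 0, d: float = 0.05, n_samples: int = 30):
    """Plant a low-grade mosaic loss over 85% of a q arm (band deviation
    ``d``), screen the cohort, and report span and cell-fraction errors.

    Returns a dict with keys span_error_pct (relative to arm length),
    cell_fraction_error, n_events and the truth fraction.
    """
    cen = centromere_table({"15": (39_000_000, 41_000_000)})
    m = synthetic_data.generate_marker_map(
        4000, {"15": 102_000_000}, centromeres=cen, seed=seed)
    q_lo, q_hi = 41_000_001, 102_000_000
    arm_len = q_hi - q_lo
    span = int(0.85 * arm_len)
    start = q_lo + (arm_len - span) // 2
    end = start + span - 1
    f_true = 4 * d / (1 + 2 * d)  # mosaic loss at this band deviation
    events = [TruthEvent("case_0001", "mosaic", "15", start, end, -1,
                         cell_fraction=f_true)]
    cohort = synthetic_data.simulate_cohort(m, 2, n_samples - 2, events, seed=seed + 1)
    _, found = mosaic_screen.screen_cohort(cohort.samples, m, cen)
    found = [e for e in found if e.sample_id == "case_0001"]
    if not found:
        return {"n_events": 0, "span_error_pct": 100.0,
                "cell_fraction_error": 1.0, "true_fraction": f_true}
    ev = max(found, key=lambda e: e.end_bp - e.start_bp)
    span_err = max(abs(ev.start_bp - start), abs(ev.end_bp - end)) / arm_len
    cf = ev.cell_fraction_estimate
    cf_err = abs(cf - f_true) if cf is not None else 1.0
    return {
        "n_events": len(found),
        "span_error_pct": 100.0 * span_err,
        "cell_fraction_error": cf_err,
        "true_fraction": f_true,
        "direction": ev.direction,
    }
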