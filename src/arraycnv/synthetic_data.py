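"""Simulated SNP-array cohorts with planted, machine-readable ground truth.

The generator emulates the statistical structure the calling pipeline
assumes: genotypes in Hardy-Weinberg proportions at each marker's population
B-allele frequency (PFB), LRR centred on per-copy-number state means, BAF
concentrated on genotype cluster means, plus GC waves, batch intensity
offsets, uniform BAF outliers and Gaussian noise.  Planted events (deletions
CN0/CN1, duplications CN3/CN4, copy-neutral and unbalanced arm-scale
mosaicism, autozygous runs) are returned as a truth table so every
downstream stage can be scored against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import IntensitySample, MarkerMap, NoiseModel, TruthEvent

# Conventional Illumina/PennCNV-scale LRR state means; configurable because
# array chemistry shifts them.
DEFAULT_LRR_STATE_MEANS = {0: -3.0, 1: -0.66, 2: 0.0, 3: 0.40, 4: 0.68}


def _smooth_field(rng: np.random.Generator, n: int, window: int = 75) -> np.ndarray:
    """Smooth standard-normal field, mapped into [0.3, 0.7]."""
    z = rng.normal(size=n + window)
    kernel = np.exp(-0.5 * ((np.arange(window) - window / 2) / (window / 6.0)) ** 2)
    kernel /= kernel.sum()
    sm = np.convolve(z, kernel, mode="same")[:n]
    sd = sm.std() or 1.0
    return 0.5 + 0.2 * np.tanh(sm / (2.0 * sd))


def generate_marker_map(
    n_markers: int,
    chrom_lengths: Mapping[str, int],
    centromeres: pd.DataFrame | None = None,
    seed: int = 0,
    stable_fraction: float = 0.95,
) -> MarkerMap:
    """Scatter ``n_markers`` uniformly over the genome (proportionally to
    chromosome length), avoiding centromere gaps, and attach PFB and a
    smooth GC field.

    PFB ~ Beta(0.5, 0.5) truncated to [0.01, 0.99]; GC is a smooth random
    field in [0.3, 0.7].  Deterministic given ``seed``.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if not chrom_lengths:
        raise ValueError("chrom_lengths must be nonempty")
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has zero or negative length")

    rng = np.random.default_rng(seed)
    chroms = [str(c) for c in chrom_lengths]
    lengths = np.array([chrom_lengths[c] for c in chrom_lengths], dtype=float)
    counts = np.maximum(1, np.round(n_markers * lengths / lengths.sum()).astype(int))
    # fix rounding so totals match exactly
    while counts.sum() > n_markers:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n_markers:
        counts[np.argmin(counts)] += 1

    cen = {}
    if centromeres is not None:
        for _, row in centromeres.iterrows():
            cen[str(row["chromosome"])] = (int(row["start_bp"]), int(row["end_bp"]))

    frames = []
    for chrom, length, k in zip(chroms, lengths, counts):
        pos = np.sort(rng.integers(1, int(length) + 1, size=int(k)))
        if chrom in cen:
            s, e = cen[chrom]
            inside = (pos >= s) & (pos <= e)
            # re-scatter centromeric draws onto the arms
            n_in = int(inside.sum())
            if n_in and (s > 1 or e < length):
                arm_sizes = np.array([max(s - 1, 0), max(int(length) - e, 0)], dtype=float)
                pick_q = rng.random(n_in) < arm_sizes[1] / arm_sizes.sum()
                repl = np.where(
                    pick_q,
                    rng.integers(e + 1, int(length) + 1, size=n_in),
                    rng.integers(1, max(s, 2), size=n_in),
                )
                pos[inside] = repl
                pos = np.sort(pos)
        # enforce strictly increasing positions
        for i in range(1, len(pos)):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        pfb = np.clip(rng.beta(0.5, 0.5, size=len(pos)), 0.01, 0.99)
        frames.append(
            pd.DataFrame(
                {
                    "marker_id": [f"m_{chrom}_{p}" for p in pos],
                    "chromosome": chrom,
                    "position_bp": pos,
                    "pfb": pfb,
                    "gc_frac": _smooth_field(rng, len(pos)),
                    "is_stable": rng.random(len(pos)) < stable_fraction,
                }
            )
        )
    return MarkerMap(pd.concat(frames, ignore_index=True))


def mosaic_baf_deviation(cell_fraction: float, change: int) -> float:
    """Deviation d of the split heterozygous BAF bands (0.5 +/- d) produced
    by a mosaic event at cell fraction f.

    loss (change -1):  d = f / (4 - 2f)      (one allele lost in f of cells)
    gain (change +1):  d = f / (4 + 2f)      (one allele gained)
    copy-neutral LOH (change 0): d = f / 2
    """
    f = float(cell_fraction)
    if not (0.0 < f <= 1.0):
        raise ValueError("cell_fraction must be in (0, 1]")
    if change < 0:
        return f / (4.0 - 2.0 * f)
    if change > 0:
        return f / (4.0 + 2.0 * f)
    return f / 2.0


def mosaic_lrr_shift(cell_fraction: float, change: int) -> float:
    """Mean LRR shift of a mosaic single-copy change at cell fraction f:
    log2 of the average copy number over cells divided by 2."""
    f = float(cell_fraction)
    if change == 0:
        return 0.0
    return float(np.log2((2.0 + change * f) / 2.0))


@dataclass
class SimulatedCohort:
    """Bundle returned by :func:`simulate_cohort`; iterable as
    ``samples, truth = simulate_cohort(...)``."""

    samples: list[IntensitySample]
    truth: list[TruthEvent]
    phenotypes: pd.DataFrame

    def __iter__(self):
        return iter((self.samples, self.truth))


def simulate_cohort(
    marker_map: MarkerMap,
    n_cases: int,
    n_controls: int,
    events: Sequence[TruthEvent] = (),
    noise: NoiseModel | None = None,
    seed: int = 0,
    lrr_state_means: Mapping[int, float] | None = None,
    missing_rate: float = 0.005,
    n_batches: int = 1,
    male_fraction: float = 0.5,
) -> SimulatedCohort:
    """Simulate ``n_cases + n_controls`` intensity samples on ``marker_map``
    with the given planted events.

    Sample ids are ``case_0001..`` and ``ctrl_0001..``; every event's
    ``sample_id`` must name one of them and lie inside map coordinates.
    Deterministic given ``seed``.
    """
    noise = noise or NoiseModel()
    means = dict(DEFAULT_LRR_STATE_MEANS)
    if lrr_state_means:
        means.update(lrr_state_means)

    sample_ids = [f"case_{i + 1:04d}" for i in range(n_cases)] + [
        f"ctrl_{i + 1:04d}" for i in range(n_controls)
    ]
    id_set = set(sample_ids)
    chrom_bounds = {
        c: (
            int(marker_map.table.loc[marker_map.chrom_index(c), "position_bp"].min()),
            int(marker_map.table.loc[marker_map.chrom_index(c), "position_bp"].max()),
        )
        for c in marker_map.chromosomes
    }
    for ev in events:
        if ev.sample_id not in id_set:
            raise ValueError(f"event names unknown sample {ev.sample_id!r}")
        if ev.chromosome not in chrom_bounds:
            raise ValueError(f"event on chromosome {ev.chromosome!r} absent from map")
        lo, hi = chrom_bounds[ev.chromosome]
        if ev.end_bp < lo or ev.start_bp > hi:
            raise ValueError(
                f"event {ev.chromosome}:{ev.start_bp}-{ev.end_bp} outside map coordinates"
            )

    rng = np.random.default_rng(seed)
    n_markers = len(marker_map)
    pfb = marker_map.pfb
    gc = marker_map.gc_frac
    gc_centered = gc - gc.mean()
    chrom_arr = marker_map.table["chromosome"].to_numpy()
    on_x = chrom_arr == "X"
    on_y = chrom_arr == "Y"

    batch_of = np.arange(len(sample_ids)) % max(1, n_batches)
    batch_shift = (
        rng.normal(0.0, noise.batch_shift_sd, size=max(1, n_batches))
        if noise.batch_shift_sd > 0
        else np.zeros(max(1, n_batches))
    )
    sexes = np.where(rng.random(len(sample_ids)) < male_fraction, "male", "female")

    by_sample: dict[str, list[TruthEvent]] = {}
    for ev in events:
        by_sample.setdefault(ev.sample_id, []).append(ev)

    samples = []
    for si, sid in enumerate(sample_ids):
        g = rng.binomial(2, pfb).astype(np.int8)
        lrr = rng.normal(0.0, noise.lrr_sd, size=n_markers)
        male = sexes[si] == "male"
        if male:
            # hemizygous X: no heterozygotes, CN1-scale intensity
            g[on_x] = np.where(rng.random(on_x.sum()) < pfb[on_x], 2, 0)
            lrr[on_x] += means[1]
            g[on_y] = np.where(rng.random(on_y.sum()) < pfb[on_y], 2, 0)
        else:
            g[on_y] = -1
            lrr[on_y] += means[0]  # no Y material
        baf = g / 2.0 + rng.normal(0.0, noise.baf_sd, size=n_markers)

        for ev in by_sample.get(sid, ()):
            idx = marker_map.region_index(ev.chromosome, ev.start_bp, ev.end_bp)
            if len(idx) == 0:
                continue
            if ev.kind == "cnv":
                cn = ev.copy_number
                lrr[idx] = rng.normal(means[cn], noise.lrr_sd, size=len(idx))
                if cn == 0:
                    g[idx] = -1
                    baf[idx] = rng.random(len(idx))  # no signal: uniform
                elif cn == 1:
                    b = (rng.random(len(idx)) < pfb[idx]).astype(np.int8)
                    g[idx] = 2 * b
                    baf[idx] = b + rng.normal(0.0, noise.baf_sd, size=len(idx))
                else:  # CN3 / CN4
                    nb = rng.binomial(cn, pfb[idx])
                    g[idx] = np.where(nb == 0, 0, np.where(nb == cn, 2, 1)).astype(np.int8)
                    baf[idx] = nb / cn + rng.normal(0.0, noise.baf_sd, size=len(idx))
            elif ev.kind == "roh":
                b = (rng.random(len(idx)) < pfb[idx]).astype(np.int8)
                g[idx] = 2 * b
                baf[idx] = b + rng.normal(0.0, noise.baf_sd, size=len(idx))
            else:  # mosaic
                d = mosaic_baf_deviation(ev.cell_fraction, ev.copy_number)
                lrr[idx] += mosaic_lrr_shift(ev.cell_fraction, ev.copy_number)
                het = idx[g[idx] == 1]
                sign = np.where(rng.random(len(het)) < 0.5, 1.0, -1.0)
                baf[het] = 0.5 + sign * d + rng.normal(0.0, noise.baf_sd, size=len(het))

        lrr += noise.gc_wave_amplitude * gc_centered
        lrr += batch_shift[batch_of[si]]
        out = rng.random(n_markers) < noise.outlier_rate
        baf[out] = rng.random(int(out.sum()))
        baf = np.clip(baf, 0.0, 1.0)
        miss = rng.random(n_markers) < missing_rate
        g[miss] = -1
        samples.append(IntensitySample(sid, lrr, baf, g))

    phenotypes = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "status": ["case"] * n_cases + ["control"] * n_controls,
            "sex": sexes,
            "cohort_label": ["sim_case"] * n_cases + ["sim_control"] * n_controls,
        }
    )
    return SimulatedCohort(samples, list(events), phenotypes)
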