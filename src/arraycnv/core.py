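"""Core domain containers shared by every pipeline stage.

Coordinates are 1-based inclusive (UCSC hg19 browser convention) everywhere
inside the package; BED export converts to 0-based half-open at the boundary.

Genotypes are stored as ``int8`` B-allele dosage codes: 0 = AA, 1 = AB,
2 = BB, -1 = missing (``NC`` on disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GENOTYPE_LABELS = {0: "AA", 1: "AB", 2: "BB", -1: "NC"}
GENOTYPE_CODES = {v: k for k, v in GENOTYPE_LABELS.items()}

AUTOSOMES = tuple(str(c) for c in range(1, 23))


class MarkerMap:
    """Array marker manifest: genome coordinates, population B-allele
    frequency (PFB) and local GC fraction per marker.

    Wraps a DataFrame with columns ``marker_id, chromosome, position_bp,
    pfb, gc_frac, is_stable``; rows are sorted by (chromosome, position)
    and positions are strictly increasing within a chromosome.
    """

    COLUMNS = ("marker_id", "chromosome", "position_bp", "pfb", "gc_frac", "is_stable")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"marker map missing columns: {missing}")
        tab = table.loc[:, list(self.COLUMNS)].copy()
        tab["chromosome"] = tab["chromosome"].astype(str)
        tab["position_bp"] = tab["position_bp"].astype(np.int64)
        tab["pfb"] = tab["pfb"].astype(float)
        tab["gc_frac"] = tab["gc_frac"].astype(float)
        tab["is_stable"] = tab["is_stable"].astype(bool)
        if tab["marker_id"].duplicated().any():
            dup = tab.loc[tab["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicate marker_id: {dup!r}")
        if ((tab["pfb"] < 0) | (tab["pfb"] > 1)).any():
            raise ValueError("pfb outside [0, 1]")
        if ((tab["gc_frac"] < 0) | (tab["gc_frac"] > 1)).any():
            raise ValueError("gc_frac outside [0, 1]")
        # stable sort keeps input order of chromosomes, positions sorted within
        tab = tab.sort_values(["chromosome", "position_bp"], kind="stable").reset_index(drop=True)
        for chrom, grp in tab.groupby("chromosome", sort=False):
            pos = grp["position_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")
        self.table = tab

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chromosome"]))

    @property
    def positions(self) -> np.ndarray:
        return self.table["position_bp"].to_numpy()

    @property
    def pfb(self) -> np.ndarray:
        return self.table["pfb"].to_numpy()

    @property
    def gc_frac(self) -> np.ndarray:
        return self.table["gc_frac"].to_numpy()

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    def chrom_index(self, chromosome: str) -> np.ndarray:
        """Row indices of all markers on ``chromosome`` (map order)."""
        return np.flatnonzero((self.table["chromosome"] == str(chromosome)).to_numpy())

    def region_index(self, chromosome: str, start_bp: int, end_bp: int) -> np.ndarray:
        """Row indices of markers inside a 1-based inclusive interval."""
        idx = self.chrom_index(chromosome)
        pos = self.table["position_bp"].to_numpy()[idx]
        return idx[(pos >= start_bp) & (pos <= end_bp)]

    def autosomal_index(self) -> np.ndarray:
        return np.flatnonzero(self.table["chromosome"].isin(AUTOSOMES).to_numpy())


@dataclass
class IntensitySample:
    """Per-marker LRR/BAF/genotype signal for one individual, aligned to a
    :class:`MarkerMap`."""

    sample_id: str
    lrr: np.ndarray
    baf: np.ndarray
    genotype: np.ndarray  # int8 B-dosage codes, -1 missing

    def __post_init__(self) -> None:
        self.lrr = np.asarray(self.lrr, dtype=float)
        self.baf = np.asarray(self.baf, dtype=float)
        self.genotype = np.asarray(self.genotype, dtype=np.int8)
        n = len(self.lrr)
        if len(self.baf) != n or len(self.genotype) != n:
            raise ValueError("lrr/baf/genotype length mismatch")

    @property
    def call_rate(self) -> float:
        return float(np.mean(self.genotype >= 0))

    def __len__(self) -> int:
        return len(self.lrr)


@dataclass(frozen=True)
class TruthEvent:
    """A planted ground-truth event used to verify recovery.

    ``kind`` is one of ``cnv`` (copy_number 0,1,3,4), ``mosaic``
    (copy_number is the signed arm-level change -1/0/+1 and ``cell_fraction``
    the affected fraction of cells) or ``roh`` (forced autozygosity).
    """

    sample_id: str
    kind: str
    chromosome: str
    start_bp: int
    end_bp: int
    copy_number: int
    cell_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("cnv", "mosaic", "roh"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.start_bp > self.end_bp:
            raise ValueError("event start_bp > end_bp")
        if self.kind == "mosaic":
            if self.cell_fraction is None or not (0.0 < self.cell_fraction <= 1.0):
                raise ValueError("mosaic events need cell_fraction in (0, 1]")
        if self.kind == "cnv" and self.copy_number not in (0, 1, 3, 4):
            raise ValueError("cnv copy_number must be 0, 1, 3 or 4")


@dataclass
class NoiseModel:
    """Noise structure of the simulated array.

    lrr_sd:            per-marker Gaussian SD of LRR in the diploid state
    baf_sd:            Gaussian SD of each BAF genotype cluster
    outlier_rate:      probability a BAF value is replaced by Uniform(0,1)
    gc_wave_amplitude: slope of the GC wave added as amp*(gc - mean gc)
    batch_shift_sd:    SD of per-batch constant LRR offsets
    """

    lrr_sd: float = 0.18
    baf_sd: float = 0.03
    outlier_rate: float = 0.005
    gc_wave_amplitude: float = 0.0
    batch_shift_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.lrr_sd <= 0 or self.baf_sd <= 0:
            raise ValueError("noise SDs must be positive")
        if not (0.0 <= self.outlier_rate < 0.1):
            raise ValueError("outlier_rate must lie in [0, 0.1)")


@dataclass
class CnvCall:
    """One called copy-number variant; confidence is a log10 Bayes factor
    against the diploid state."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    copy_number: int
    n_probes: int
    confidence: float

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("call start_bp > end_bp")
        if self.n_probes < 1:
            raise ValueError("call must span at least one probe")
        if self.copy_number == 2:
            raise ValueError("copy-neutral segments are not CNV calls")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


@dataclass
class RohSegment:
    """A run of homozygosity."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


def centromere_table(intervals: Mapping[str, tuple[int, int]]) -> pd.DataFrame:
    """Normalise a chromosome -> (start, end) mapping into the centromere
    interval table used by the splitting and arm logic."""
    rows = [
        {"chromosome": str(c), "start_bp": int(s), "end_bp": int(e)}
        for c, (s, e) in intervals.items()
    ]
    tab = pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp"])
    if ((tab["end_bp"] - tab["start_bp"]) < 0).any():
        raise ValueError("centromere interval with start > end")
    return tab


def genotypes_to_labels(codes: np.ndarray) -> np.ndarray:
    out = np.empty(len(codes), dtype=object)
    for code, label in GENOTYPE_LABELS.items():
        out[codes == code] = label
    return out


def labels_to_genotypes(labels: Iterable[str]) -> np.ndarray:
    try:
        return np.array([GENOTYPE_CODES[str(l)] for l in labels], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"unknown genotype label {exc.args[0]!r}") from exc
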