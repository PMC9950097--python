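"""Readers and writers for the pipeline's on-disk formats.

All formats are plain tab-delimited text.  Internal coordinates are 1-based
inclusive; the BED exporters convert to 0-based half-open.  Floats are
written with ``repr`` so write-then-read round-trips are exact.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    CnvCall,
    IntensitySample,
    MarkerMap,
    RohSegment,
    TruthEvent,
    genotypes_to_labels,
    labels_to_genotypes,
)

_LRR_SUFFIX = ".Log R Ratio"
_BAF_SUFFIX = ".B Allele Freq"
_GT_SUFFIX = ".GType"


def _fmt(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------- signal files

def write_signal_matrix(samples: Sequence[IntensitySample], marker_map: MarkerMap, path) -> None:
    """Write a PennCNV-style signal file: ``Name  Chr  Position`` followed by
    ``<sample>.Log R Ratio``, ``<sample>.B Allele Freq``, ``<sample>.GType``
    column triplets."""
    header = ["Name", "Chr", "Position"]
    for s in samples:
        header += [s.sample_id + _LRR_SUFFIX, s.sample_id + _BAF_SUFFIX, s.sample_id + _GT_SUFFIX]
    labels = [genotypes_to_labels(s.genotype) for s in samples]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        tab = marker_map.table
        ids = tab["marker_id"].to_numpy()
        chroms = tab["chromosome"].to_numpy()
        pos = tab["position_bp"].to_numpy()
        for i in range(len(marker_map)):
            row = [str(ids[i]), str(chroms[i]), str(pos[i])]
            for s, lab in zip(samples, labels):
                row += [_fmt(s.lrr[i]), _fmt(s.baf[i]), str(lab[i])]
            fh.write("\t".join(row) + "\n")


def read_signal_matrix(path, expected_map: MarkerMap | None = None) -> list[IntensitySample]:
    """Read a signal file back into per-sample arrays.

    With ``expected_map`` the rows are re-aligned to map order; a marker in
    the file but absent from the map is an error naming the marker.
    Non-numeric LRR/BAF and truncated lines raise errors citing the 1-based
    line number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["Name", "Chr", "Position"]:
            raise ValueError(f"{path}: not a signal file (bad header)")
        sample_ids = []
        for col in header[3::3]:
            if not col.endswith(_LRR_SUFFIX):
                raise ValueError(f"{path}: unexpected column {col!r}")
            sample_ids.append(col[: -len(_LRR_SUFFIX)])
        ncol = len(header)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol:
                raise ValueError(
                    f"{path}: line {lineno}: expected {ncol} fields, found {len(parts)}"
                )
            rows.append((lineno, parts))

    marker_ids = [p[0] for _, p in rows]
    n = len(rows)
    lrr = np.empty((len(sample_ids), n))
    baf = np.empty((len(sample_ids), n))
    gts = [[None] * n for _ in sample_ids]
    for j, (lineno, parts) in enumerate(rows):
        for k in range(len(sample_ids)):
            base = 3 + 3 * k
            try:
                lrr[k, j] = float(parts[base])
                baf[k, j] = float(parts[base + 1])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric LRR/BAF value"
                ) from None
            gts[k][j] = parts[base + 2]

    order = np.arange(n)
    if expected_map is not None:
        pos_of = {m: i for i, m in enumerate(marker_ids)}
        unknown = set(marker_ids) - set(expected_map.marker_ids)
        if unknown:
            raise ValueError(f"{path}: marker {sorted(unknown)[0]!r} absent from marker map")
        order = np.array([pos_of[m] for m in expected_map.marker_ids if m in pos_of])

    out = []
    for k, sid in enumerate(sample_ids):
        gt = labels_to_genotypes([gts[k][j] for j in order])
        out.append(IntensitySample(sid, lrr[k, order], baf[k, order], gt))
    return out


def write_pfb(marker_map: MarkerMap, path) -> None:
    """Population-frequency-of-B file: Name, Chr, Position, PFB."""
    tab = marker_map.table
    with open(path, "w") as fh:
        fh.write("Name\tChr\tPosition\tPFB\n")
        for _, r in tab.iterrows():
            fh.write(f"{r.marker_id}\t{r.chromosome}\t{r.position_bp}\t{_fmt(r.pfb)}\n")


def write_marker_map(marker_map: MarkerMap, path) -> None:
    marker_map.table.to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> MarkerMap:
    return MarkerMap(pd.read_csv(path, sep="\t", dtype={"chromosome": str}, float_precision="round_trip"))


# ------------------------------------------------------------------ phenotypes

def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "status"}
    if not required.issubset(tab.columns):
        raise ValueError(f"phenotype table needs columns {sorted(required)}")
    if tab["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in phenotype table")
    bad = set(tab["status"]) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown status values: {sorted(bad)}")
    return tab


# ----------------------------------------------------------------- truth table

def write_truth(events: Sequence[TruthEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tkind\tchromosome\tstart_bp\tend_bp\tcopy_number\tcell_fraction\n")
        for e in events:
            cf = "" if e.cell_fraction is None else _fmt(e.cell_fraction)
            fh.write(
                f"{e.sample_id}\t{e.kind}\t{e.chromosome}\t{e.start_bp}\t{e.end_bp}"
                f"\t{e.copy_number}\t{cf}\n"
            )


def read_truth(path) -> list[TruthEvent]:
    tab = pd.read_csv(path, sep="\t", dtype={"chromosome": str}, float_precision="round_trip")
    out = []
    for _, r in tab.iterrows():
        cf = None if pd.isna(r.get("cell_fraction")) else float(r["cell_fraction"])
        out.append(
            TruthEvent(
                str(r["sample_id"]), str(r["kind"]), str(r["chromosome"]),
                int(r["start_bp"]), int(r["end_bp"]), int(r["copy_number"]), cf,
            )
        )
    return out


# ------------------------------------------------------------------- CNV calls

CNV_COLUMNS = ("sample_id", "chromosome", "start_bp", "end_bp", "copy_number", "n_probes", "confidence")


def write_cnv_calls(calls: Sequence[CnvCall], path) -> None:
    """PennCNV/PLINK-style .cnv text table; an empty call list produces a
    header-only file."""
    with open(path, "w") as fh:
        fh.write("\t".join(CNV_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.sample_id}\t{c.chromosome}\t{c.start_bp}\t{c.end_bp}"
                f"\t{c.copy_number}\t{c.n_probes}\t{_fmt(c.confidence)}\n"
            )


def read_cnv_calls(path) -> list[CnvCall]:
    tab = pd.read_csv(path, sep="\t", dtype={"chromosome": str}, float_precision="round_trip")
    return [
        CnvCall(
            str(r["sample_id"]), str(r["chromosome"]), int(r["start_bp"]), int(r["end_bp"]),
            int(r["copy_number"]), int(r["n_probes"]), float(r["confidence"]),
        )
        for _, r in tab.iterrows()
    ]


def write_cnv_bed(calls: Sequence[CnvCall], path) -> None:
    """BED export: 1-based inclusive internal coordinates become 0-based
    half-open (start-1, end)."""
    with open(path, "w") as fh:
        for c in calls:
            name = f"{c.sample_id}:CN{c.copy_number}"
            fh.write(
                f"chr{c.chromosome}\t{c.start_bp - 1}\t{c.end_bp}\t{name}\t{_fmt(c.confidence)}\n"
            )


# ---------------------------------------------------------------- ROH segments

ROH_COLUMNS = ("sample_id", "chromosome", "start_bp", "end_bp", "n_snps", "n_het", "length_kb")


def write_roh(segments: Sequence[RohSegment], path) -> None:
    """Per-segment table mirroring PLINK's .hom layout."""
    with open(path, "w") as fh:
        fh.write("\t".join(ROH_COLUMNS) + "\n")
        for s in segments:
            fh.write(
                f"{s.sample_id}\t{s.chromosome}\t{s.start_bp}\t{s.end_bp}"
                f"\t{s.n_snps}\t{s.n_het}\t{_fmt(s.length_kb)}\n"
            )


def read_roh(path) -> list[RohSegment]:
    tab = pd.read_csv(path, sep="\t", dtype={"chromosome": str}, float_precision="round_trip")
    return [
        RohSegment(
            str(r["sample_id"]), str(r["chromosome"]), int(r["start_bp"]), int(r["end_bp"]),
            int(r["n_snps"]), int(r["n_het"]),
        )
        for _, r in tab.iterrows()
    ]


def write_roh_bed(segments: Sequence[RohSegment], path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"chr{s.chromosome}\t{s.start_bp - 1}\t{s.end_bp}\t{s.sample_id}\n")


# ----------------------------------------------------------------- known loci

def read_known_loci(path=None) -> pd.DataFrame:
    """Load a known-CNV-locus table (name, chromosome, start_bp, end_bp,
    cnv_type in {loss, gain, both}, direction in {risk, protective}).

    Without ``path`` the packaged table of recurrent schizophrenia-associated
    loci (hg19) is returned.
    """
    if path is None:
        src = resources.files("arraycnv").joinpath("data/known_loci_hg19.tsv")
        with resources.as_file(src) as p:
            tab = pd.read_csv(p, sep="\t", dtype={"chromosome": str})
    else:
        tab = pd.read_csv(path, sep="\t", dtype={"chromosome": str}, float_precision="round_trip")
    for i, r in tab.iterrows():
        if r["cnv_type"] not in ("loss", "gain", "both"):
            raise ValueError(f"known-locus row {i}: bad cnv_type {r['cnv_type']!r}")
        if not (int(r["start_bp"]) <= int(r["end_bp"])):
            raise ValueError(f"known-locus row {i}: start > end")
    return tab


def read_centromeres(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype={"chromosome": str}, float_precision="round_trip")
    need = {"chromosome", "start_bp", "end_bp"}
    if not need.issubset(tab.columns):
        raise ValueError(f"centromere table needs columns {sorted(need)}")
    return tab


def read_gene_bed(path) -> pd.DataFrame:
    """Minimal BED reader for gene annotation: chrom, start, end, name.
    Converts to internal 1-based inclusive coordinates."""
    tab = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2, 3], names=["chromosome", "bed_start", "bed_end", "name"],
                      dtype={"chromosome": str})
    tab["chromosome"] = tab["chromosome"].str.removeprefix("chr")
    tab["start_bp"] = tab["bed_start"].astype(int) + 1
    tab["end_bp"] = tab["bed_end"].astype(int)
    return tab[["chromosome", "start_bp", "end_bp", "name"]]
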