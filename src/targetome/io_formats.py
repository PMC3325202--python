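"""Readers and writers for the genomic formats the pipeline touches.

All coordinates are 0-based half-open internally (BED native; GTF converted
on read and write).  Readers reject malformed records rather than silently
repairing them, and error messages name the offending file and line.

Domain types shared across the package live here: :class:`GenomicInterval`,
:class:`GeneModel`, :class:`Peak` (the BED record for a called peak) and
:class:`PWM`.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "Peak",
    "PWM",
    "read_bed",
    "write_bed",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "read_pwm_library",
    "write_pwm_library",
    "read_expression",
    "write_expression",
    "read_coverage",
    "write_coverage",
    "read_loci",
    "write_loci",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("GenomicInterval chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"GenomicInterval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"GenomicInterval end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint (floor) of the interval."""
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A TSS-anchored gene annotation with exon structure.

    The TSS is the strand-dependent 5' end: ``interval.start`` on the plus
    strand, ``interval.end - 1`` on the minus strand.  Unstranded genes are
    treated as plus-strand for TSS purposes.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        object.__setattr__(self, "exons", tuple(sorted(self.exons, key=lambda e: e.start)))
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.interval.chrom:
                raise ValueError(f"exon chrom differs from gene {self.gene_id}")
            if exon.strand != self.interval.strand:
                raise ValueError(f"exon strand differs from gene {self.gene_id}")
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValueError(f"exon outside gene body for {self.gene_id}")
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")
            prev_end = exon.end
        if not self.interval.contains(self.tss):
            raise ValueError(f"TSS outside gene interval for {self.gene_id}")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start


@dataclass(frozen=True)
class Peak:
    """A called enriched interval with its summit and height.

    ``height`` is the treatment coverage (tag count) at the summit, carried in
    the BED score column; whether heights should additionally be
    depth-normalized is left to the caller — raw summit counts are stored.
    """

    interval: GenomicInterval
    summit: int
    height: float = 0.0
    pvalue: float = 1.0
    caller: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside peak interval "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.height < 0:
            raise ValueError("peak height must be >= 0")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"peak pvalue must be in (0, 1], got {self.pvalue}")

    @property
    def center(self) -> int:
        return self.interval.center


class PWM:
    """Position weight matrix over {A, C, G, T} with pseudocount smoothing.

    Rows of ``matrix`` are positions; columns are base frequencies in A, C,
    G, T order.  Construction from counts adds a pseudocount to every cell
    before per-position normalization, so all frequencies are strictly
    positive and each row sums to one.
    """

    def __init__(self, motif_id: str, matrix: np.ndarray, family: str | None = None):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (L, 4)")
        if matrix.shape[0] < 4:
            raise ValueError("PWM must have length >= 4")
        if np.any(matrix <= 0):
            raise ValueError("PWM frequencies must be > 0 after pseudocount smoothing")
        if np.any(np.abs(matrix.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("PWM rows must each sum to 1 within 1e-9")
        self.motif_id = motif_id
        self.matrix = matrix
        self.family = family

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        family: str | None = None,
        pseudocount: float = 0.01,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise ValueError(f"negative entries in counts for motif {motif_id}")
        smoothed = counts + pseudocount
        matrix = smoothed / smoothed.sum(axis=1, keepdims=True)
        return cls(motif_id, matrix, family=family)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def information_content(self) -> np.ndarray:
        """Per-position information content in bits: 2 + sum_b f log2 f."""
        f = self.matrix
        return 2.0 + np.sum(f * np.log2(f), axis=1)

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.matrix[::-1, ::-1].copy(), family=self.family)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PWM({self.motif_id!r}, L={len(self)}, family={self.family!r})"


# ---------------------------------------------------------------------------
# BED (peaks): BED6+1, column 7 = summit offset from interval start
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Peak]:
    """Read peaks from a BED6+1 file (0-based half-open, native BED).

    Optional columns 4-7 are name, score (peak height), strand and summit
    offset from the interval start.  A missing height becomes 0; a missing
    summit defaults to the interval midpoint (floor).
    """
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            name = fields[3] if len(fields) > 3 else ""
            try:
                height = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            if len(fields) > 6 and fields[6] != ".":
                try:
                    summit = start + int(fields[6])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer summit offset") from exc
            else:
                summit = (start + end) // 2
            try:
                interval = GenomicInterval(chrom, start, end, strand)
                peaks.append(Peak(interval, summit=summit, height=height, name=name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def _fmt_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as BED6+1 (summit offset in column 7)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                "\t".join(
                    [
                        p.interval.chrom,
                        str(p.interval.start),
                        str(p.interval.end),
                        p.name or f"peak_{i + 1}",
                        _fmt_number(p.height),
                        p.interval.strand,
                        str(p.summit - p.interval.start),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GTF gene models
# ---------------------------------------------------------------------------

def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GTF2.2 file.

    Requires ``gene`` and ``exon`` features carrying a ``gene_id`` attribute;
    1-based inclusive GTF coordinates are converted to 0-based half-open.
    An exon whose gene_id has no gene feature is an error, as is a strand
    character outside ``{+, -, .}``.
    """
    import gffutils

    path = Path(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, dict] = {}
    order: list[str] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if feat.strand not in ("+", "-", "."):
            raise ValueError(f"{path}: unknown strand {feat.strand!r} for gene feature")
        gene_id = feat.attributes["gene_id"][0]
        genes[gene_id] = {
            "chrom": feat.seqid,
            "start": feat.start - 1,
            "end": feat.end,
            "strand": feat.strand,
            "exons": [],
        }
        order.append(gene_id)
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        if feat.strand not in ("+", "-", "."):
            raise ValueError(f"{path}: unknown strand {feat.strand!r} for exon feature")
        gene_id = feat.attributes["gene_id"][0]
        if gene_id not in genes:
            raise ValueError(f"{path}: exon with gene_id {gene_id!r} has no parent gene")
        genes[gene_id]["exons"].append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        )
    models = []
    for gene_id in order:
        g = genes[gene_id]
        models.append(
            GeneModel(
                gene_id=gene_id,
                interval=GenomicInterval(g["chrom"], g["start"], g["end"], g["strand"]),
                exons=tuple(g["exons"]),
            )
        )
    return models


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "targetome") -> None:
    """Write gene models as GTF2.2 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        for gene in genes:
            attrs = f'gene_id "{gene.gene_id}";'
            iv = gene.interval
            fh.write(
                "\t".join(
                    [iv.chrom, source, "gene", str(iv.start + 1), str(iv.end), ".",
                     iv.strand, ".", attrs]
                )
                + "\n"
            )
            for exon in gene.exons:
                fh.write(
                    "\t".join(
                        [exon.chrom, source, "exon", str(exon.start + 1), str(exon.end),
                         ".", exon.strand, ".", attrs]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# JASPAR-style PWM libraries
# ---------------------------------------------------------------------------

def read_pwm_library(path: str | Path, pseudocount: float = 0.01) -> list[PWM]:
    """Read a JASPAR-style PWM library.

    Each record is a ``>id [family]`` header followed by four rows labelled
    A, C, G and T holding counts (or frequencies), optionally wrapped in
    square brackets.  Counts are pseudocount-smoothed and normalized per
    position on read.
    """
    path = Path(path)
    pwms: list[PWM] = []
    header: tuple[str, str | None] | None = None
    rows: dict[str, list[float]] = {}

    def flush(lineno: int) -> None:
        nonlocal header, rows
        if header is None:
            return
        missing = [b for b in _BASES if b not in rows]
        if missing:
            raise ValueError(f"{path}:{lineno}: motif {header[0]} missing rows {missing}")
        lengths = {len(rows[b]) for b in _BASES}
        if len(lengths) != 1:
            raise ValueError(f"{path}:{lineno}: rows of unequal length in {header[0]}")
        counts = np.array([rows[b] for b in _BASES]).T  # (L, 4)
        pwms.append(PWM.from_counts(header[0], counts, family=header[1], pseudocount=pseudocount))
        header, rows = None, {}

    with open(path) as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                parts = line[1:].split(None, 1)
                if not parts:
                    raise ValueError(f"{path}:{lineno}: empty motif header")
                header = (parts[0], parts[1].strip() if len(parts) > 1 else None)
                continue
            if header is None:
                raise ValueError(f"{path}:{lineno}: matrix row before any header")
            base = line[0].upper()
            if base not in _BASE_INDEX:
                raise ValueError(f"{path}:{lineno}: unexpected row label {line[0]!r}")
            body = line[1:].replace("[", " ").replace("]", " ")
            try:
                values = [float(tok) for tok in body.split()]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric matrix entry") from exc
            if any(v < 0 for v in values):
                raise ValueError(f"{path}:{lineno}: negative entries")
            rows[base] = values
        flush(lineno)
    return pwms


def write_pwm_library(pwms: Iterable[PWM], path: str | Path, scale: float = 100.0) -> None:
    """Write PWMs in JASPAR bracket style (frequencies scaled to pseudo-counts)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            family = f" {pwm.family}" if pwm.family else ""
            fh.write(f">{pwm.motif_id}{family}\n")
            for bi, base in enumerate(_BASES):
                vals = " ".join(f"{v * scale:.4f}" for v in pwm.matrix[:, bi])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Expression matrices, coverage tracks, disease loci
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene-level expression table.

    TSV with a ``gene_id`` column followed by one column per replicate named
    ``WT_*`` or ``KO_*``; linear-scale, non-negative values.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing gene_id column")
    df = df.set_index("gene_id")
    bad = [c for c in df.columns if not (c.startswith("WT_") or c.startswith("KO_"))]
    if bad:
        raise ValueError(f"{path}: replicate columns must be named WT_* or KO_*, got {bad}")
    if not any(c.startswith("WT_") for c in df.columns):
        raise ValueError(f"{path}: no WT_* columns")
    if not any(c.startswith("KO_") for c in df.columns):
        raise ValueError(f"{path}: no KO_* columns")
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")


def write_coverage(tracks: dict[str, np.ndarray], path: str | Path) -> None:
    """Write per-bp integer coverage as fixedStep wiggle text."""
    with open(path, "w") as fh:
        for chrom, values in tracks.items():
            fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
            fh.write("\n".join(str(int(v)) for v in values))
            fh.write("\n")


def read_coverage(path: str | Path) -> dict[str, np.ndarray]:
    path = Path(path)
    tracks: dict[str, list[int]] = {}
    current: list[int] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("fixedStep"):
                attrs = dict(tok.split("=", 1) for tok in line.split()[1:])
                if "chrom" not in attrs:
                    raise ValueError(f"{path}:{lineno}: fixedStep without chrom")
                current = tracks.setdefault(attrs["chrom"], [])
                continue
            if current is None:
                raise ValueError(f"{path}:{lineno}: data before fixedStep header")
            try:
                current.append(int(line))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coverage value") from exc
    return {chrom: np.asarray(vals, dtype=np.int64) for chrom, vals in tracks.items()}


def read_loci(path: str | Path) -> pd.DataFrame:
    """Read a disease-locus table: locus_id, chrom, start, end[, n_genes]."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"locus_id", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: locus table needs columns {sorted(required)}")
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: locus with end <= start")
    return df


def write_loci(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
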