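"""Genomic data containers and readers/writers for the standard text formats.

All coordinates are 0-based, half-open throughout the package; GTF I/O
(1-based, inclusive) converts at the boundary.  The containers here —
:class:`GenomicInterval`, :class:`TranscriptModel`, :class:`ExpressionMatrix`,
:class:`CoverageTrack` and :class:`PWMMotif` — are the shared currency of
every analysis stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "GenomicInterval",
    "TranscriptModel",
    "ExpressionMatrix",
    "CoverageTrack",
    "PWMMotif",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "read_bedgraph",
    "write_bedgraph",
    "read_meme",
    "write_meme",
    "read_tsv",
    "write_tsv",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "reverse_complement",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FormatError(ValueError):
    """Raised for malformed input files (message carries the line number)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge gap in bp; 0 if overlapping or abutting.

        Raises if the intervals are on different chromosomes.
        """
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start - other.end, other.start - self.end, 0)


@dataclass
class TranscriptModel:
    """An assembled transcript with exon structure and a Cuffcompare class code."""

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    class_code: str = "="
    source: str = "."

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.interval.chrom or exon.strand != self.interval.strand:
                raise ValueError(
                    f"{self.transcript_id}: exon chrom/strand differs from transcript"
                )
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValueError(f"{self.transcript_id}: exon outside transcript span")
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = exon.end

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        """Concatenated exon sequence, reverse-complemented for ``-`` strand."""
        chrom_seq = genome[self.interval.chrom]
        seq = "".join(chrom_seq[e.start : e.end] for e in self.exons)
        if self.interval.strand == "-":
            seq = reverse_complement(seq)
        return seq.upper()


class ExpressionMatrix:
    """Transcript x sample FPKM matrix with (genotype, condition, replicate) metadata.

    Sample names follow the pattern ``{genotype}_{condition}_r{replicate}``
    (e.g. ``tolerant_salt_r1``) so a single TSV round-trips the metadata.
    """

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame | None = None):
        if values.index.has_duplicates:
            raise ValueError("duplicate transcript ids")
        if (values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        self.values = values.astype(float)
        if samples is None:
            samples = self._metadata_from_names(values.columns)
        missing = set(values.columns) - set(samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        self.samples = samples.loc[values.columns]

    @staticmethod
    def _metadata_from_names(names: Iterable[str]) -> pd.DataFrame:
        rows = {}
        for name in names:
            m = re.fullmatch(r"(\w+?)_(\w+?)_r(\d+)", name)
            if not m:
                raise ValueError(
                    f"sample name {name!r} does not follow genotype_condition_rN"
                )
            rows[name] = {
                "genotype": m.group(1),
                "condition": m.group(2),
                "replicate": int(m.group(3)),
            }
        return pd.DataFrame.from_dict(rows, orient="index")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    def sample_names(
        self, genotype: str | None = None, condition: str | None = None
    ) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if genotype is not None:
            mask &= self.samples["genotype"] == genotype
        if condition is not None:
            mask &= self.samples["condition"] == condition
        return list(self.samples.index[mask])

    def get(self, transcript_id: str, samples: Sequence[str] | None = None) -> np.ndarray:
        if transcript_id not in self.values.index:
            raise KeyError(f"transcript {transcript_id!r} not in expression matrix")
        row = self.values.loc[transcript_id]
        if samples is not None:
            row = row[list(samples)]
        return row.to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "transcript_id"
        out.to_csv(path, sep="\t", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="transcript_id")
        df.index.name = None
        return cls(df)

    def __eq__(self, other: object) -> bool:
        # values compare at text round-trip precision
        return (
            isinstance(other, ExpressionMatrix)
            and self.values.shape == other.values.shape
            and list(self.values.index) == list(other.values.index)
            and list(self.values.columns) == list(other.values.columns)
            and np.allclose(self.values, other.values, rtol=1e-9, atol=1e-12)
            and self.samples.equals(other.samples)
        )


class CoverageTrack:
    """Dense per-base signal per chromosome (e.g. normalized ATAC-seq coverage)."""

    def __init__(self, sizes: Mapping[str, int], data: Mapping[str, np.ndarray] | None = None):
        self.sizes = dict(sizes)
        self.data: dict[str, np.ndarray] = {}
        for chrom, size in self.sizes.items():
            if data is not None and chrom in data:
                arr = np.asarray(data[chrom], dtype=float)
                if arr.shape != (size,):
                    raise ValueError(
                        f"{chrom}: track length {arr.shape[0]} != size {size}"
                    )
                if (arr < 0).any():
                    raise ValueError(f"{chrom}: negative coverage values")
                self.data[chrom] = arr
            else:
                self.data[chrom] = np.zeros(size, dtype=float)

    def values(self, interval: GenomicInterval) -> np.ndarray:
        if interval.chrom not in self.data:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > self.sizes[interval.chrom]:
            raise FormatError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds chromosome size {self.sizes[interval.chrom]}"
            )
        return self.data[interval.chrom][interval.start : interval.end]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CoverageTrack)
            and self.sizes == other.sizes
            and all(np.array_equal(self.data[c], other.data[c]) for c in self.sizes)
        )


@dataclass
class PWMMotif:
    """Position weight matrix over ACGT with a background distribution."""

    motif_id: str
    matrix: np.ndarray  # shape (length, 4), rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )  # shape (4,)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must have shape (length, 4)")
        if (self.matrix < 0).any() or (self.background < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each matrix row must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWMMotif":
        return PWMMotif(
            self.motif_id,
            self.matrix[::-1, ::-1].copy(),
            self.background[::-1].copy(),
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PWMMotif)
            and self.motif_id == other.motif_id
            and np.allclose(self.matrix, other.matrix, atol=1e-9)
            and np.allclose(self.background, other.background, atol=1e-9)
        )


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a GTF file.

    GTF coordinates (1-based inclusive) are converted to the internal 0-based
    half-open convention.  Transcripts are grouped with their exons; a missing
    ``class_code`` attribute is stored as ``"="``.  Malformed lines raise
    :class:`FormatError` naming the line number; an exon whose transcript_id
    has no ``transcript`` feature raises :class:`FormatError` as well.
    """
    spans: dict[str, dict] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            try:
                start_1 = int(start_s)
                end_1 = int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start_1 < 1 or end_1 < start_1:
                raise FormatError(
                    f"{path}:{lineno}: invalid GTF coordinates {start_1}-{end_1}"
                )
            attrs = _parse_attributes(attrs_s)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise FormatError(f"{path}:{lineno}: missing transcript_id attribute")
            # 1-based inclusive -> 0-based half-open
            iv = GenomicInterval(chrom, start_1 - 1, end_1, strand)
            if feature == "transcript":
                spans[tid] = {
                    "interval": iv,
                    "gene_id": attrs.get("gene_id", tid),
                    "class_code": attrs.get("class_code", "="),
                    "source": source,
                }
                order.append(tid)
            elif feature == "exon":
                exons.setdefault(tid, []).append(iv)

    orphans = set(exons) - set(spans)
    if orphans:
        raise FormatError(
            f"{path}: exon(s) without a parent transcript feature: {sorted(orphans)}"
        )
    out = []
    for tid in order:
        info = spans[tid]
        ex = exons.get(tid) or [info["interval"]]
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=info["gene_id"],
                interval=info["interval"],
                exons=ex,
                class_code=info["class_code"],
                source=info["source"],
            )
        )
    return out


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GTF (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'class_code "{t.class_code}";'
            )
            iv = t.interval
            fh.write(
                f"{iv.chrom}\t{t.source}\ttranscript\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            for e in t.exons:
                fh.write(
                    f"{e.chrom}\t{t.source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# bedGraph / BED / chrom.sizes


def read_bedgraph(path: str | Path, sizes: Mapping[str, int]) -> CoverageTrack:
    """Read a 4-column bedGraph (0-based half-open) into a dense track.

    Bases not covered by any row are 0.  An interval exceeding its chromosome
    size raises :class:`FormatError`.
    """
    track = CoverageTrack(sizes)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            chrom, start_s, end_s, value_s = fields
            if chrom not in sizes:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            start, end, value = int(start_s), int(end_s), float(value_s)
            if start < 0 or end > sizes[chrom] or end < start:
                raise FormatError(
                    f"{path}:{lineno}: interval {start}-{end} out of bounds for "
                    f"{chrom} (size {sizes[chrom]})"
                )
            track.data[chrom][start:end] = value
    return track


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as bedGraph, run-length encoded; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in track.sizes:
            arr = track.data[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            strand = fields[5] if len(fields) >= 6 else "."
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format


def read_meme(path: str | Path) -> list[PWMMotif]:
    """Read motifs from MEME minimal format via Biopython."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        matrix = np.array(
            [[m.pwm[b][i] for b in ALPHABET] for i in range(m.length)], dtype=float
        )
        bg = np.array([m.background[b] for b in ALPHABET], dtype=float)
        out.append(PWMMotif(m.name, matrix, bg))
    return out


def write_meme(motifs: Iterable[PWMMotif], path: str | Path) -> None:
    motifs = list(motifs)
    if not motifs:
        raise ValueError("cannot write an empty motif set")
    bg = motifs[0].background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {p:.6f}" for b, p in zip(ALPHABET, bg)) + "\n\n"
        )
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            # large nsites keeps probability->count->probability round trips
            # exact to the printed precision
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.length} "
                f"nsites= 1000000 E= 0\n"
            )
            for row in m.matrix:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# TSV


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False, lineterminator="\n")
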