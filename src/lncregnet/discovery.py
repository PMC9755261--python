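"""The lncRNA discovery cascade.

Assembled transcripts are filtered down to potential long non-coding RNAs by
five successive per-transcript filters — Cuffcompare class code, expression
support, small-RNA overlap, spliced length, and coding potential — and the
survivors are classified into the four positional lncRNA categories
(sense / antisense / intronic / lincRNA) from their class code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .annotation_io import ExpressionMatrix, GenomicInterval, TranscriptModel

__all__ = [
    "CodingEvidence",
    "LncRNAAnnotation",
    "LNCRNA_CLASS_CODES",
    "CATEGORY_BY_CLASS_CODE",
    "filter_class_codes",
    "filter_expression",
    "remove_small_rna_overlaps",
    "filter_length",
    "filter_coding_potential",
    "orf_heuristic_evidence",
    "classify_lncrna",
    "run_discovery_cascade",
]

#: Cuffcompare class codes retained as lncRNA candidates: intronic (i),
#: antisense (x), intergenic (u) and generic exonic overlap (o).
LNCRNA_CLASS_CODES = frozenset("ixuo")

CATEGORY_BY_CLASS_CODE = {
    "u": "lincRNA",
    "i": "intronic",
    "x": "antisense",
    "o": "sense",
}


@dataclass(frozen=True)
class CodingEvidence:
    """Per-transcript coding-potential verdicts (CPC / Pfam / SwissProt style).

    ``heuristic`` marks evidence produced by the built-in ORF-length stand-in
    rather than the external engines.
    """

    transcript_id: str
    cpc_coding: bool
    pfam_hit: bool = False
    swissprot_hit: bool = False
    heuristic: bool = False

    @property
    def noncoding(self) -> bool:
        return not (self.cpc_coding or self.pfam_hit or self.swissprot_hit)


@dataclass(frozen=True)
class LncRNAAnnotation:
    transcript: TranscriptModel
    category: str  # sense | antisense | intronic | lincRNA


def filter_class_codes(transcripts: Sequence[TranscriptModel]) -> list[TranscriptModel]:
    """Keep transcripts whose class code is one of i, x, u, o (order preserved)."""
    return [t for t in transcripts if t.class_code in LNCRNA_CLASS_CODES]


def expression_threshold(n_exons: int) -> float:
    """FPKM threshold: 0.5 for multi-exon transcripts, 2.0 for single-exon."""
    return 0.5 if n_exons >= 2 else 2.0


def filter_expression(
    matrix: ExpressionMatrix,
    transcripts: Sequence[TranscriptModel],
    min_samples: int = 2,
) -> list[TranscriptModel]:
    """Keep transcripts expressed in at least ``min_samples`` samples.

    A sample counts as expressing the transcript when its FPKM meets the
    exon-dependent threshold (>= 0.5 multi-exon, >= 2.0 single-exon),
    boundaries inclusive.
    """
    kept = []
    for t in transcripts:
        fpkm = matrix.get(t.transcript_id)
        thr = expression_threshold(t.n_exons)
        if int((fpkm >= thr).sum()) >= min_samples:
            kept.append(t)
    return kept


def remove_small_rna_overlaps(
    transcripts: Sequence[TranscriptModel],
    small_rnas: Sequence[GenomicInterval],
    stranded: bool = False,
) -> list[TranscriptModel]:
    """Drop transcripts with >= 1 bp exonic overlap with any small-RNA interval.

    Strand-agnostic by default; with ``stranded=True`` only same-strand
    overlaps count.
    """
    kept = []
    for t in transcripts:
        hit = any(
            e.overlaps(s) and (not stranded or s.strand == "." or s.strand == e.strand)
            for e in t.exons
            for s in small_rnas
        )
        if not hit:
            kept.append(t)
    return kept


def filter_length(
    transcripts: Sequence[TranscriptModel], min_exclusive: int = 200
) -> list[TranscriptModel]:
    """Keep transcripts with spliced length strictly greater than 200 bp."""
    return [t for t in transcripts if t.spliced_length > min_exclusive]


def filter_coding_potential(
    transcripts: Sequence[TranscriptModel],
    evidence: Iterable[CodingEvidence],
) -> list[TranscriptModel]:
    """Keep the intersection of the CPC-, Pfam- and SwissProt-negative sets."""
    by_id = {e.transcript_id: e for e in evidence}
    kept = []
    for t in transcripts:
        if t.transcript_id not in by_id:
            raise KeyError(f"no coding evidence for transcript {t.transcript_id!r}")
        if by_id[t.transcript_id].noncoding:
            kept.append(t)
    return kept


_STOPS = {"TAA", "TAG", "TGA"}


def longest_orf_codons(seq: str) -> int:
    """Longest complete ORF (ATG..stop, codons counted excluding the stop).

    Scans the three forward frames of the given sequence only.
    """
    seq = seq.upper()
    best = 0
    n = len(seq)
    for frame in range(3):
        i = frame
        while i + 3 <= n:
            if seq[i : i + 3] == "ATG":
                j = i + 3
                while j + 3 <= n and seq[j : j + 3] not in _STOPS:
                    j += 3
                if j + 3 <= n:  # found a stop codon
                    best = max(best, (j - i) // 3)
                i = j + 3
            else:
                i += 3
    return best


def orf_heuristic_evidence(
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    min_codons: int = 100,
) -> list[CodingEvidence]:
    """ORF-length stand-in for the external coding-potential engines.

    A transcript is flagged coding when its spliced sequence (transcript
    forward strand) contains a complete ORF of >= ``min_codons`` codons.
    Pfam/SwissProt verdicts are emitted as False; ``heuristic=True`` marks
    the provenance.
    """
    out = []
    for t in transcripts:
        coding = longest_orf_codons(t.spliced_sequence(genome)) >= min_codons
        out.append(CodingEvidence(t.transcript_id, coding, False, False, heuristic=True))
    return out


def classify_lncrna(transcript: TranscriptModel) -> LncRNAAnnotation:
    """Map the class code to its lncRNA category (u->lincRNA, i->intronic,
    x->antisense, o->sense)."""
    try:
        category = CATEGORY_BY_CLASS_CODE[transcript.class_code]
    except KeyError:
        raise ValueError(
            f"transcript {transcript.transcript_id!r} has non-lncRNA class code "
            f"{transcript.class_code!r}"
        ) from None
    return LncRNAAnnotation(transcript, category)


def run_discovery_cascade(
    transcripts: Sequence[TranscriptModel],
    matrix: ExpressionMatrix,
    small_rnas: Sequence[GenomicInterval],
    evidence: Iterable[CodingEvidence],
    min_length_exclusive: int = 200,
    min_samples: int = 2,
) -> tuple[list[LncRNAAnnotation], dict[str, int]]:
    """Run the full filtering cascade and classify the survivors.

    Returns the classified lncRNAs and an ordered per-stage count report
    (counts are monotone non-increasing through the cascade).
    """
    counts: dict[str, int] = {"input": len(transcripts)}
    stage = filter_class_codes(transcripts)
    counts["class_code"] = len(stage)
    stage = filter_expression(matrix, stage, min_samples=min_samples)
    counts["expressed"] = len(stage)
    stage = remove_small_rna_overlaps(stage, small_rnas)
    counts["small_rna_removed"] = len(stage)
    stage = filter_length(stage, min_exclusive=min_length_exclusive)
    counts["length"] = len(stage)
    stage = filter_coding_potential(stage, evidence)
    counts["noncoding"] = len(stage)
    annotations = [classify_lncrna(t) for t in stage]
    counts["classified"] = len(annotations)
    return annotations, counts
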