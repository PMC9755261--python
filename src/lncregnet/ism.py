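"""In-silico mutagenesis of regulatory sequence against a pluggable predictor.

A predictor maps a fixed-length sequence window to a scalar accessibility
score at the window's central position (its TSS).  The region-level scan
slides a window (default 1000 nt) across the sequence, replaces its contents
with random nucleotides, and records ISMS = |f(modified) - f(reference)|;
profile z-scores >= 3 are merged into significant peaks.  The base-level
scan substitutes every base with the three alternatives and records the
extreme increase (gain) and decrease (loss) of the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence, runtime_checkable
import warnings

import numpy as np

from .annotation_io import GenomicInterval, reverse_complement

__all__ = [
    "Predictor",
    "ISMSProfile",
    "BaseMutagenesisProfile",
    "WindowFeature",
    "extract_tss_window",
    "isms_scan",
    "call_isms_peaks",
    "single_base_mutagenesis",
    "annotate_window",
]

ALPHABET = "ACGT"
DEFAULT_WINDOW = 1000
DEFAULT_Z_THRESHOLD = 3.0
#: Sequence length extracted around a TSS for full-scale accessibility models.
FULL_SCALE_TSS_WINDOW = 196_698


@runtime_checkable
class Predictor(Protocol):
    """Contract for sequence -> accessibility-score models.

    ``predict`` must be deterministic, defined over {A,C,G,T,N} and return a
    bounded scalar; ``window_length`` is the exact input length it accepts.
    """

    window_length: int

    def predict(self, sequence: str) -> float: ...


@dataclass
class ISMSProfile:
    tss: int | None
    window_size: int
    stride: int
    positions: np.ndarray  # window start offsets
    scores: np.ndarray  # ISMS = |f(modified) - f(reference)| >= 0
    reference_score: float
    z: np.ndarray
    peaks: list[tuple[int, int]]
    seed: int


@dataclass
class BaseMutagenesisProfile:
    positions: np.ndarray
    gain: np.ndarray  # max over the 3 substitutions of f(mut) - f(ref)
    loss: np.ndarray  # min over the 3 substitutions of f(mut) - f(ref)


@dataclass(frozen=True)
class WindowFeature:
    feature_id: str
    role: str  # gene | tf | lncrna
    interval: GenomicInterval
    clipped: bool


def extract_tss_window(
    genome: Mapping[str, str],
    chrom: str,
    tss: int,
    strand: str = "+",
    length: int = FULL_SCALE_TSS_WINDOW,
) -> str:
    """Extract ``length`` bases centered on a TSS (tss at index length // 2).

    Positions beyond the chromosome ends are filled with ``N``; minus-strand
    windows are the reverse complement of the plus-strand extraction.
    """
    if chrom not in genome:
        raise KeyError(f"unknown chromosome {chrom!r}")
    seq = genome[chrom]
    start = tss - length // 2
    end = start + length
    left_pad = max(0, -start)
    right_pad = max(0, end - len(seq))
    window = "N" * left_pad + seq[max(0, start) : min(len(seq), end)] + "N" * right_pad
    if strand == "-":
        window = reverse_complement(window)
    return window.upper()


def _offset_rng(seed: int, offset: int) -> np.random.Generator:
    # Per-offset stream: stride changes subsample, not reshuffle, the draws.
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(offset,)))


def isms_scan(
    sequence: str,
    predictor: Predictor,
    window: int = DEFAULT_WINDOW,
    stride: int = 1,
    seed: int = 0,
    replicates: int = 1,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> ISMSProfile:
    """Sliding-window random-swap mutagenesis profile.

    At each window offset the window contents are replaced by seeded uniform
    random nucleotides and ISMS = |f(modified) - f(reference)| recorded
    (averaged over ``replicates`` independent draws when > 1).  The profile's
    z-scores and peak calls use its own mean/SD.
    """
    if len(sequence) != predictor.window_length:
        raise ValueError(
            f"sequence length {len(sequence)} != predictor window "
            f"{predictor.window_length}"
        )
    if window > len(sequence):
        raise ValueError("mutagenesis window exceeds sequence length")
    sequence = sequence.upper()
    reference_score = predictor.predict(sequence)
    offsets = np.arange(0, len(sequence) - window + 1, stride)
    scores = np.empty(offsets.size)
    bases = np.frombuffer(ALPHABET.encode(), dtype="S1").astype("U1")
    for i, off in enumerate(offsets):
        rng = _offset_rng(seed, int(off))
        acc = 0.0
        for _ in range(replicates):
            random_fill = "".join(bases[rng.integers(0, 4, size=window)])
            modified = sequence[:off] + random_fill + sequence[off + window :]
            acc += abs(predictor.predict(modified) - reference_score)
        scores[i] = acc / replicates
    profile = ISMSProfile(
        tss=len(sequence) // 2,
        window_size=window,
        stride=stride,
        positions=offsets,
        scores=scores,
        reference_score=reference_score,
        z=np.full(offsets.size, np.nan),
        peaks=[],
        seed=seed,
    )
    _standardize(profile)
    profile.peaks = call_isms_peaks(profile, z_threshold)
    return profile


def _standardize(profile: ISMSProfile) -> None:
    sd = profile.scores.std()
    if sd > 0:
        profile.z = (profile.scores - profile.scores.mean()) / sd
    else:
        profile.z = np.zeros_like(profile.scores)


def call_isms_peaks(
    profile: ISMSProfile, z_threshold: float = DEFAULT_Z_THRESHOLD
) -> list[tuple[int, int]]:
    """Merge maximal runs of offsets with z >= threshold into peak intervals.

    Intervals are half-open in window-offset coordinates (a run of one offset
    at position p with stride s is (p, p + s)).  A flat profile (zero SD)
    yields no peaks.
    """
    if profile.scores.std() == 0:
        warnings.warn("flat ISMS profile: no peaks called")
        return []
    sig = profile.z >= z_threshold
    peaks: list[tuple[int, int]] = []
    run_start = None
    prev = None
    for pos, s in zip(profile.positions, sig):
        if s and run_start is None:
            run_start = pos
        elif not s and run_start is not None:
            peaks.append((int(run_start), int(prev + profile.stride)))
            run_start = None
        prev = pos
    if run_start is not None:
        peaks.append((int(run_start), int(profile.positions[-1] + profile.stride)))
    return peaks


def single_base_mutagenesis(
    sequence: str,
    predictor: Predictor,
    region: tuple[int, int] | None = None,
) -> BaseMutagenesisProfile:
    """Exhaustive single-base substitution scan over ``region`` (offsets).

    For each position, each of the 3 alternative bases is substituted and
    f(mut) - f(ref) computed; the per-position max is the gain score and the
    min the loss score (both signed; gain >= loss always).
    """
    sequence = sequence.upper()
    if len(sequence) != predictor.window_length:
        raise ValueError("sequence length does not match predictor window")
    start, end = region if region is not None else (0, len(sequence))
    if start < 0 or end > len(sequence) or end < start:
        raise ValueError(f"region ({start}, {end}) outside sequence")
    f_ref = predictor.predict(sequence)
    positions = np.arange(start, end)
    gain = np.zeros(positions.size)
    loss = np.zeros(positions.size)
    for i, pos in enumerate(positions):
        ref_base = sequence[pos]
        deltas = []
        for alt in ALPHABET:
            if alt == ref_base:
                continue
            mutant = sequence[:pos] + alt + sequence[pos + 1 :]
            deltas.append(predictor.predict(mutant) - f_ref)
        gain[i] = max(deltas)
        loss[i] = min(deltas)
    return BaseMutagenesisProfile(positions=positions, gain=gain, loss=loss)


def annotate_window(
    features: Mapping[str, tuple[str, GenomicInterval]],
    window: GenomicInterval,
) -> list[WindowFeature]:
    """Features intersecting a genomic window, clipped to it and role-labelled.

    ``features`` maps feature id -> (role, interval); roles are free-form
    labels such as gene / tf / lncrna.
    """
    out = []
    for fid, (role, iv) in features.items():
        if not iv.overlaps(window):
            continue
        clipped = iv.start < window.start or iv.end > window.end
        out.append(
            WindowFeature(
                feature_id=fid,
                role=role,
                interval=GenomicInterval(
                    iv.chrom,
                    max(iv.start, window.start),
                    min(iv.end, window.end),
                    iv.strand,
                ),
                clipped=clipped,
            )
        )
    return sorted(out, key=lambda f: (f.interval.start, f.feature_id))
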