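"""Seeded synthetic dataset with planted ground truth.

Generates a complete toy study — genome, transcript annotation with mixed
Cuffcompare class codes, FPKM matrix over 2 genotypes x 2 conditions x
replicates, coding-potential evidence, small-RNA annotation, an
accessibility coverage track, PWM motifs with planted genomic instances and
mature miRNAs with planted complementary sites — together with a
TruthManifest so every downstream stage can be tested without external data.

Default conditions mirror the rice salt-stress study design at desk scale:
two genotypes (tolerant / sensitive), control vs salt, three biological
replicates, planted differential lncRNAs carrying the published log2 fold
changes (2 up + 2 down in the tolerant genotype, 6 up + 3 down in the
sensitive one), one planted co-expression module (default target pairwise
r = 0.96) driven by the tolerant up-regulated lncRNA, accessible chromatin
over the differential lncRNA loci, and motif instances that drive the toy
accessibility predictor.

The noise model is log-normal multiplicative on FPKM (sigma default 0.2);
the module is induced by a single shared latent factor with loading
sqrt(r), which makes the target pairwise correlation analytically exact in
expectation.  All randomness flows from one seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation_io import (
    ALPHABET,
    CoverageTrack,
    ExpressionMatrix,
    GenomicInterval,
    PWMMotif,
    TranscriptModel,
    write_bed,
    write_bedgraph,
    write_chrom_sizes,
    write_fasta,
    write_gtf,
    write_meme,
    write_tsv,
    reverse_complement,
)
from .discovery import CodingEvidence

__all__ = [
    "SimulationConfig",
    "TranscriptTruth",
    "TruthManifest",
    "SimulatedDataset",
    "simulate_dataset",
    "toy_predictor",
    "ToyAccessibilityPredictor",
]

# Published log2 fold changes of the salt-responsive DE-lncRNAs; these are
# the default planted effect sizes (tolerant: 2 up / 2 down, sensitive:
# 6 up / 3 down).
TOLERANT_DE_LOG2FC = (-1.84777, 1.33505, -1.84449, 1.3109)
SENSITIVE_DE_LOG2FC = (
    -2.84421,
    2.43485,
    1.77214,
    1.20362,
    -19.3908,
    -1.70111,
    2.11511,
    1.21378,
    1.81551,
)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 100_000
    # transcript counts by role
    n_lincRNA: int = 12
    n_antisense: int = 6
    n_intronic: int = 4
    n_sense: int = 8
    n_coding: int = 110  # class '='
    n_other: int = 20  # class 'j'
    n_decoy_short: int = 10  # candidate class codes, spliced length <= 200
    n_decoy_coding: int = 10  # candidate class codes, CPC-coding
    n_decoy_lowexpr: int = 10  # candidate class codes, below FPKM support
    n_decoy_smallrna: int = 10  # candidate class codes, small-RNA overlap
    # design
    genotypes: tuple[str, str] = ("tolerant", "sensitive")
    conditions: tuple[str, str] = ("control", "salt")
    n_replicates: int = 3
    # expression model
    noise_sigma: float = 0.2  # sd of ln-scale multiplicative noise
    de_log2fc_tolerant: tuple[float, ...] = TOLERANT_DE_LOG2FC
    de_log2fc_sensitive: tuple[float, ...] = SENSITIVE_DE_LOG2FC
    # planted co-expression module
    module_size: int = 50
    module_r: float = 0.96  # target pairwise Pearson r among members (log scale)
    module_amplitude: float = 3.0  # log2-scale dynamic range of the latent factor
    # continuous per-sample component of the latent factor, shared by the
    # driver (log2 sd); models shared regulation beyond the condition contrast
    # and keeps the latent profile free of exact ties
    module_driver_jitter: float = 0.005
    # accessibility
    accessible_amplitude: float = 10.0  # added over ~1.0 background coverage
    # sequence plants
    n_motifs: int = 2
    motif_length: int = 18  # long enough for confident PWM hits at p <= 1e-10
    n_mirnas: int = 3
    mirna_length: int = 21

    def __post_init__(self) -> None:
        counts = (
            self.n_lincRNA, self.n_antisense, self.n_intronic, self.n_sense,
            self.n_coding, self.n_other, self.n_decoy_short, self.n_decoy_coding,
            self.n_decoy_lowexpr, self.n_decoy_smallrna, self.module_size,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not -1.0 <= self.module_r <= 1.0:
            raise ValueError("module_r must be in [-1, 1]")
        if self.accessible_amplitude < 0:
            raise ValueError("accessible_amplitude must be >= 0")

    @property
    def n_lncrna(self) -> int:
        return self.n_lincRNA + self.n_antisense + self.n_intronic + self.n_sense


@dataclass
class TranscriptTruth:
    transcript_id: str
    is_lncrna: bool
    category: str | None  # sense | antisense | intronic | lincRNA
    reason: str  # lncrna | coding_gene | other_code | short | coding | lowexpr | smallrna
    de_genotype: str | None = None
    log2fc: float | None = None
    direction: str | None = None  # up | down
    in_module: bool = False


@dataclass
class TruthManifest:
    transcripts: dict[str, TranscriptTruth]
    module_members: list[str]
    module_driver: str | None
    module_r: float
    accessible_regions: list[GenomicInterval]
    motif_instances: list[tuple[str, str, int, str]]  # motif_id, chrom, pos, strand
    mirna_sites: list[tuple[str, str, int]]  # mirna_id, lncrna_id, offset in transcript

    def lncrna_ids(self) -> set[str]:
        return {t for t, tr in self.transcripts.items() if tr.is_lncrna}

    def de_ids(self, genotype: str) -> set[str]:
        return {
            t
            for t, tr in self.transcripts.items()
            if tr.de_genotype == genotype
        }


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, str]
    sizes: dict[str, int]
    transcripts: list[TranscriptModel]
    matrix: ExpressionMatrix
    evidence: list[CodingEvidence]
    small_rnas: list[GenomicInterval]
    track: CoverageTrack
    motifs: list[PWMMotif]
    mirnas: dict[str, str]
    de_stats: pd.DataFrame  # transcript_id, genotype, qvalue (upstream-style)
    manifest: TruthManifest

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Serialize all components as plain-text standard formats."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "sizes": outdir / "chrom.sizes",
            "annotation": outdir / "annotation.gtf",
            "expression": outdir / "expression.tsv",
            "evidence": outdir / "coding_evidence.tsv",
            "small_rnas": outdir / "small_rnas.bed",
            "coverage": outdir / "coverage.bedGraph",
            "motifs": outdir / "motifs.meme",
            "mirnas": outdir / "mirnas.fasta",
            "de_stats": outdir / "de_stats.tsv",
            "truth": outdir / "truth_transcripts.tsv",
            "truth_accessible": outdir / "truth_accessible.bed",
            "truth_motifs": outdir / "truth_motif_instances.tsv",
            "truth_mirna_sites": outdir / "truth_mirna_sites.tsv",
        }
        write_fasta(self.genome, paths["genome"])
        write_chrom_sizes(self.sizes, paths["sizes"])
        write_gtf(self.transcripts, paths["annotation"])
        self.matrix.to_tsv(paths["expression"])
        write_tsv(
            pd.DataFrame(
                [
                    {
                        "transcript_id": e.transcript_id,
                        "cpc_coding": e.cpc_coding,
                        "pfam_hit": e.pfam_hit,
                        "swissprot_hit": e.swissprot_hit,
                    }
                    for e in self.evidence
                ]
            ),
            paths["evidence"],
        )
        write_bed(self.small_rnas, paths["small_rnas"])
        write_bedgraph(self.track, paths["coverage"])
        write_meme(self.motifs, paths["motifs"])
        write_fasta(self.mirnas, paths["mirnas"])
        write_tsv(self.de_stats, paths["de_stats"])
        write_tsv(
            pd.DataFrame(
                [
                    {
                        "transcript_id": t.transcript_id,
                        "is_lncrna": t.is_lncrna,
                        "category": t.category or "",
                        "reason": t.reason,
                        "de_genotype": t.de_genotype or "",
                        "log2fc": t.log2fc if t.log2fc is not None else "",
                        "direction": t.direction or "",
                        "in_module": t.in_module,
                    }
                    for t in self.manifest.transcripts.values()
                ]
            ),
            paths["truth"],
        )
        write_bed(self.manifest.accessible_regions, paths["truth_accessible"])
        write_tsv(
            pd.DataFrame(
                self.manifest.motif_instances,
                columns=["motif_id", "chrom", "pos", "strand"],
            ),
            paths["truth_motifs"],
        )
        write_tsv(
            pd.DataFrame(
                self.manifest.mirna_sites,
                columns=["mirna_id", "lncrna_id", "offset"],
            ),
            paths["truth_mirna_sites"],
        )
        return paths


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    return [ALPHABET[i] for i in rng.integers(0, 4, size=length)]


def _consensus_pwm(rng: np.random.Generator, motif_id: str, length: int) -> PWMMotif:
    """Information-rich PWM: one dominant base (0.97) per position."""
    consensus = rng.integers(0, 4, size=length)
    matrix = np.full((length, 4), 0.01)
    matrix[np.arange(length), consensus] = 0.97
    return PWMMotif(motif_id, matrix)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full toy dataset; deterministic for a fixed seed."""
    root = np.random.SeedSequence(config.seed)
    (
        ss_genome,
        ss_layout,
        ss_expr,
        ss_module,
        ss_track,
        ss_motif,
        ss_mirna,
    ) = root.spawn(7)
    rng_genome = np.random.default_rng(ss_genome)
    rng_layout = np.random.default_rng(ss_layout)
    rng_expr = np.random.default_rng(ss_expr)
    rng_module = np.random.default_rng(ss_module)
    rng_track = np.random.default_rng(ss_track)
    rng_motif = np.random.default_rng(ss_motif)
    rng_mirna = np.random.default_rng(ss_mirna)

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    sizes = {c: config.chromosome_length for c in chroms}
    genome_chars = {c: _random_sequence(rng_genome, sizes[c]) for c in chroms}

    # ----- transcript roles ------------------------------------------------
    roles: list[tuple[str, str, str | None]] = []  # (reason, class_code, category)
    lnc_specs = (
        [("lncrna", "u", "lincRNA")] * config.n_lincRNA
        + [("lncrna", "x", "antisense")] * config.n_antisense
        + [("lncrna", "i", "intronic")] * config.n_intronic
        + [("lncrna", "o", "sense")] * config.n_sense
    )
    roles += lnc_specs
    roles += [("coding_gene", "=", None)] * config.n_coding
    roles += [("other_code", "j", None)] * config.n_other
    decoy_codes = ["u", "o", "x", "i"]
    for kind, n in (
        ("short", config.n_decoy_short),
        ("coding", config.n_decoy_coding),
        ("lowexpr", config.n_decoy_lowexpr),
        ("smallrna", config.n_decoy_smallrna),
    ):
        roles += [(kind, decoy_codes[k % 4], None) for k in range(n)]

    # ----- genomic layout --------------------------------------------------
    transcripts: list[TranscriptModel] = []
    truth: dict[str, TranscriptTruth] = {}
    small_rnas: list[GenomicInterval] = []
    cursors = {c: 500 for c in chroms}
    order = rng_layout.permutation(len(roles))
    for idx, role_idx in enumerate(order):
        reason, class_code, category = roles[role_idx]
        tid = f"TX{idx + 1:04d}"
        chrom = chroms[idx % len(chroms)]
        if reason == "short":
            span = int(rng_layout.integers(100, 201))  # spliced length <= 200
        elif reason == "coding":
            span = int(rng_layout.integers(400, 701))  # room for a planted ORF
        else:
            span = int(rng_layout.integers(300, 701))
        gap = int(rng_layout.integers(100, 301))
        start = cursors[chrom]
        end = start + span
        if end + gap > sizes[chrom] - 500:
            raise ValueError(
                "planted features exceed chromosome bounds; increase "
                "chromosome_length or reduce transcript counts"
            )
        cursors[chrom] = end + gap
        strand = "+" if rng_layout.random() < 0.5 else "-"
        iv = GenomicInterval(chrom, start, end, strand)
        # lowexpr decoys stay single-exon so the stricter 2.0 FPKM support
        # threshold applies to them
        multi_exon = reason not in ("short", "coding", "lowexpr") and span >= 500 and (
            rng_layout.random() < 0.3
        )
        if multi_exon:
            e1 = span // 3
            intron = span // 6
            exons = [
                GenomicInterval(chrom, start, start + e1, strand),
                GenomicInterval(chrom, start + e1 + intron, end, strand),
            ]
        else:
            exons = [iv]
        transcripts.append(
            TranscriptModel(tid, f"G{idx + 1:04d}", iv, exons, class_code, "sim")
        )
        truth[tid] = TranscriptTruth(
            transcript_id=tid,
            is_lncrna=(reason == "lncrna"),
            category=category,
            reason=reason,
        )
        if reason == "smallrna":
            # small RNA overlapping the first exon by 40 bp
            e = exons[0]
            small_rnas.append(
                GenomicInterval(chrom, e.start + 10, e.start + 50, strand)
            )
        if reason == "coding":
            # plant an uninterrupted ORF: ATG + 100 codons + TAA (306 nt)
            e = exons[0]
            orf = "ATG" + "".join(
                ["GCT"] * 100  # alanine codons, stop-free
            ) + "TAA"
            pos = e.start + 5 if strand == "+" else e.end - 5 - len(orf)
            seq_chars = genome_chars[chrom]
            insert = orf if strand == "+" else reverse_complement(orf)
            seq_chars[pos : pos + len(orf)] = list(insert)

    by_id = {t.transcript_id: t for t in transcripts}
    lnc_ids = [t.transcript_id for t in transcripts if truth[t.transcript_id].is_lncrna]
    coding_ids = [
        t.transcript_id for t in transcripts if truth[t.transcript_id].reason == "coding_gene"
    ]

    # ----- planted differential expression ---------------------------------
    tol, sen = config.genotypes
    n_tol = len(config.de_log2fc_tolerant)
    n_sen = len(config.de_log2fc_sensitive)
    if n_tol + n_sen > len(lnc_ids):
        raise ValueError("not enough lncRNAs to host the planted DE effects")
    de_tol = lnc_ids[:n_tol]
    de_sen = lnc_ids[n_tol : n_tol + n_sen]
    for tid, lfc in zip(de_tol, config.de_log2fc_tolerant):
        truth[tid].de_genotype = tol
        truth[tid].log2fc = lfc
        truth[tid].direction = "up" if lfc > 0 else "down"
    for tid, lfc in zip(de_sen, config.de_log2fc_sensitive):
        truth[tid].de_genotype = sen
        truth[tid].log2fc = lfc
        truth[tid].direction = "up" if lfc > 0 else "down"

    # module driver: the tolerant up-regulated lncRNA with the largest planted
    # fold change (the lncRNA.2-FL analog), when one exists.
    driver = None
    if de_tol:
        ups = [t for t in de_tol if truth[t].log2fc and truth[t].log2fc > 0]
        driver = max(ups, key=lambda t: truth[t].log2fc) if ups else de_tol[0]

    module_members = coding_ids[: config.module_size]
    for tid in module_members:
        truth[tid].in_module = True
    if driver is not None:
        truth[driver].in_module = True

    # ----- expression matrix ------------------------------------------------
    sample_names = [
        f"{g}_{c}_r{r + 1}"
        for g in config.genotypes
        for c in config.conditions
        for r in range(config.n_replicates)
    ]
    geno = np.array([s.split("_")[0] for s in sample_names])
    cond = np.array([s.split("_")[1] for s in sample_names])
    n_samples = len(sample_names)

    base = {}
    for t in transcripts:
        tid = t.transcript_id
        if truth[tid].reason == "lowexpr":
            base[tid] = 0.8  # below even the multi-exon support threshold x2
        else:
            base[tid] = float(2.0 ** rng_expr.uniform(np.log2(5), np.log2(60)))

    log2x = np.zeros((len(transcripts), n_samples))
    for i, t in enumerate(transcripts):
        tid = t.transcript_id
        log2x[i, :] = np.log2(base[tid])
        tr = truth[tid]
        if tr.de_genotype is not None:
            mask = (geno == tr.de_genotype) & (cond == "salt")
            log2x[i, mask] += tr.log2fc

    # latent module factor = z-scored profile of the planted driver (so the
    # driver correlates maximally with the module summary at zero noise).
    if module_members and driver is not None:
        d = np.zeros(n_samples)
        d[(geno == truth[driver].de_genotype) & (cond == "salt")] = truth[driver].log2fc
        jitter = config.module_driver_jitter * rng_module.standard_normal(n_samples)
        d = d + jitter
        i_driver = next(
            i for i, t in enumerate(transcripts) if t.transcript_id == driver
        )
        log2x[i_driver, :] += jitter
        latent = (d - d.mean()) / d.std()
        a = math.sqrt(max(config.module_r, 0.0))
        b = math.sqrt(max(1.0 - config.module_r, 0.0))
        row_index = {t.transcript_id: i for i, t in enumerate(transcripts)}
        for tid in module_members:
            i = row_index[tid]
            eps = rng_module.standard_normal(n_samples)
            log2x[i, :] += config.module_amplitude * (a * latent + b * eps)

    values = 2.0 ** log2x
    if config.noise_sigma > 0:
        values = values * np.exp(
            config.noise_sigma * rng_expr.standard_normal(values.shape)
        )
    matrix = ExpressionMatrix(
        pd.DataFrame(
            values, index=[t.transcript_id for t in transcripts], columns=sample_names
        )
    )

    # upstream-style significance for the planted truth (stands in for the
    # external DE caller's q-values; see de.welch_bh_stats for the data-driven
    # alternative)
    de_rows = []
    for g in config.genotypes:
        for t in transcripts:
            tid = t.transcript_id
            q = 1e-6 if truth[tid].de_genotype == g else 1.0
            de_rows.append({"transcript_id": tid, "genotype": g, "qvalue": q})
    de_stats = pd.DataFrame(de_rows)

    # ----- coding evidence --------------------------------------------------
    evidence = []
    for t in transcripts:
        reason = truth[t.transcript_id].reason
        coding = reason in ("coding_gene", "other_code", "coding")
        evidence.append(CodingEvidence(t.transcript_id, coding, False, False))

    # ----- coverage track with planted accessible regions -------------------
    data = {
        c: rng_track.gamma(shape=2.0, scale=0.5, size=sizes[c]) for c in chroms
    }
    accessible = []
    for tid in de_tol + de_sen:
        iv = by_id[tid].interval
        data[iv.chrom][iv.start : iv.end] += config.accessible_amplitude
        accessible.append(iv)
    track = CoverageTrack(sizes, data)

    # ----- motifs with planted genomic instances ----------------------------
    motifs = [
        _consensus_pwm(rng_motif, f"MOTIF{m + 1}", config.motif_length)
        for m in range(config.n_motifs)
    ]
    motif_instances = []
    for k, tid in enumerate(de_tol + de_sen):
        iv = by_id[tid].interval
        pwm = motifs[k % len(motifs)]
        pos = iv.start + 20
        genome_chars[iv.chrom][pos : pos + pwm.length] = list(pwm.consensus())
        motif_instances.append((pwm.motif_id, iv.chrom, pos, "+"))

    # ----- miRNAs with planted complementary sites --------------------------
    mirnas = {
        f"mir{m + 1}": "".join(_random_sequence(rng_mirna, config.mirna_length))
        for m in range(config.n_mirnas)
    }
    mirna_sites = []
    hosts = de_tol[: config.n_mirnas] if de_tol else lnc_ids[: config.n_mirnas]
    for (mirna_id, mseq), tid in zip(sorted(mirnas.items()), hosts):
        t = by_id[tid]
        e = t.exons[0]
        offset_in_exon = 100
        if e.length < offset_in_exon + len(mseq) + 10:
            offset_in_exon = max(40, e.length - len(mseq) - 10)
        site = reverse_complement(mseq)  # perfect antiparallel complement
        pos = e.start + offset_in_exon
        genome_chars[e.chrom][pos : pos + len(site)] = list(
            site if t.interval.strand == "+" else reverse_complement(site)
        )
        # offset within the spliced transcript (first exon, forward strand)
        if t.interval.strand == "+":
            toffset = offset_in_exon
        else:
            toffset = t.spliced_length - offset_in_exon - len(site)
        mirna_sites.append((mirna_id, tid, toffset))

    genome = {c: "".join(genome_chars[c]) for c in chroms}
    manifest = TruthManifest(
        transcripts=truth,
        module_members=module_members,
        module_driver=driver,
        module_r=config.module_r,
        accessible_regions=accessible,
        motif_instances=motif_instances,
        mirna_sites=mirna_sites,
    )
    dataset = SimulatedDataset(
        config=config,
        genome=genome,
        sizes=sizes,
        transcripts=transcripts,
        matrix=matrix,
        evidence=evidence,
        small_rnas=small_rnas,
        track=track,
        motifs=motifs,
        mirnas=mirnas,
        de_stats=de_stats,
        manifest=manifest,
    )
    validate_manifest(dataset)
    return dataset


def validate_manifest(dataset: SimulatedDataset) -> None:
    """Check that every planted entity resolves in the generated data."""
    ids = {t.transcript_id for t in dataset.transcripts}
    m = dataset.manifest
    if set(m.transcripts) != ids:
        raise AssertionError("manifest transcript ids do not match annotation")
    if not set(m.module_members) <= ids:
        raise AssertionError("module member missing from annotation")
    for iv in m.accessible_regions:
        if iv.chrom not in dataset.sizes or iv.end > dataset.sizes[iv.chrom]:
            raise AssertionError("accessible region out of bounds")
    motif_by_id = {p.motif_id: p for p in dataset.motifs}
    for motif_id, chrom, pos, _strand in m.motif_instances:
        pwm = motif_by_id[motif_id]
        word = dataset.genome[chrom][pos : pos + pwm.length]
        if word != pwm.consensus():
            raise AssertionError(f"planted motif instance not found at {chrom}:{pos}")
    by_id = {t.transcript_id: t for t in dataset.transcripts}
    for mirna_id, tid, offset in m.mirna_sites:
        seq = by_id[tid].spliced_sequence(dataset.genome)
        site = seq[offset : offset + len(dataset.mirnas[mirna_id])]
        if site != reverse_complement(
            dataset.mirnas[mirna_id].replace("U", "T")
        ):
            raise AssertionError(f"planted miRNA site not found in {tid}")


# ---------------------------------------------------------------------------
# Toy accessibility predictor


class ToyAccessibilityPredictor:
    """Motif-content accessibility model satisfying the Predictor contract.

    f(window) = squash of the summed log2-odds scores of motif matches within
    ``receptive_field`` bp of the window center (forward strand), where a
    match is a word scoring at least ``match_threshold`` times the motif's
    maximum achievable score and squash(x) = 1 / (1 + exp(-x / scale)) maps
    to (0, 1).  A window with no motif match scores the baseline
    squash(0) = 0.5.  Deterministic; destroying a planted consensus instance
    strictly decreases the score.
    """

    def __init__(
        self,
        motifs: list[PWMMotif],
        window_length: int,
        receptive_field: int = 500,
        scale: float = 10.0,
        match_threshold: float = 0.9,
    ):
        if not motifs:
            raise ValueError("need at least one motif")
        if window_length < receptive_field:
            raise ValueError(
                f"window_length {window_length} shorter than receptive_field "
                f"{receptive_field}"
            )
        self.motifs = list(motifs)
        self.window_length = window_length
        self.receptive_field = receptive_field
        self.scale = scale
        self.match_threshold = match_threshold
        # uniform-background log2 odds with the standard probability floor
        self._lom = [
            np.log2(np.maximum(p.matrix, 1e-4) / 0.25) for p in self.motifs
        ]
        self._cutoff = [
            match_threshold * lom.max(axis=1).sum() for lom in self._lom
        ]

    def predict(self, sequence: str) -> float:
        if len(sequence) != self.window_length:
            raise ValueError(
                f"sequence length {len(sequence)} != window_length {self.window_length}"
            )
        c = self.window_length // 2
        lo = max(0, c - self.receptive_field)
        hi = min(self.window_length, c + self.receptive_field)
        region = sequence[lo:hi].upper()
        arr = np.frombuffer(region.encode(), dtype=np.uint8)
        enc = np.full(arr.size, 4, dtype=np.int64)
        for i, bse in enumerate(ALPHABET):
            enc[arr == ord(bse)] = i
        total = 0.0
        for lom, cutoff in zip(self._lom, self._cutoff):
            L = lom.shape[0]
            if enc.size < L:
                continue
            ext = np.concatenate([lom, np.zeros((L, 1))], axis=1)  # N scores 0
            n_pos = enc.size - L + 1
            scores = np.zeros(n_pos)
            for i in range(L):
                scores += ext[i, enc[i : i + n_pos]]
            total += float(scores[scores >= cutoff].sum())
        return 1.0 / (1.0 + math.exp(-total / self.scale))


def toy_predictor(
    motifs: list[PWMMotif],
    window_length: int,
    receptive_field: int = 500,
    scale: float = 10.0,
) -> ToyAccessibilityPredictor:
    """Build the toy accessibility predictor over a motif set."""
    return ToyAccessibilityPredictor(motifs, window_length, receptive_field, scale)
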