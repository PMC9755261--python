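"""End-to-end orchestration over a dataset directory.

A :class:`PipelineConfig` names the input files (defaulting to the layout
written by :func:`lncregnet.synthetic.SimulatedDataset.write`) and carries
every stage threshold with the study defaults: FPKM support 0.5 / 2.0 in
>= 2 samples, spliced length > 200 bp, q <= 0.05 and |log2FC| >= 1, 100 kb
cis window, 50 random null regions, 1000-nt mutagenesis window with z >= 3
peaks, PWM p <= 1e-10, mimicry expectation <= 5 with < 4 mismatches.

``run_pipeline`` executes the stages in dependency order, writes one TSV per
stage plus a JSON run manifest (parameters, seed, per-stage row counts), and
is byte-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import accessibility as acc
from . import de as de_mod
from . import discovery, mimicry, motifs as motifs_mod, targets
from .annotation_io import (
    ExpressionMatrix,
    GenomicInterval,
    read_bed,
    read_chrom_sizes,
    read_bedgraph,
    read_fasta,
    read_gtf,
    read_meme,
    read_tsv,
    write_tsv,
)
from .discovery import CodingEvidence
from .ism import call_isms_peaks, extract_tss_window, isms_scan
from .synthetic import toy_predictor

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    data_dir: Path
    out_dir: Path
    seed: int = 0
    # discovery
    min_length_exclusive: int = 200
    min_expressed_samples: int = 2
    # differential expression
    max_q: float = 0.05
    min_abs_log2fc: float = 1.0
    genotypes: tuple[str, str] = ("tolerant", "sensitive")
    # targets
    cis_window: int = 100_000
    min_abs_r: float = 0.8
    module_beta: float = 6.0
    module_min_size: int = 10
    module_cut_height: float = 0.8
    # accessibility
    n_null: int = 50
    # in-silico mutagenesis (desk-scale defaults)
    ism_window: int = 500
    ism_stride: int = 25
    ism_sequence_length: int = 10_001
    ism_receptive_field: int = 4000
    ism_z_threshold: float = 3.0
    # motif scanning
    motif_p_threshold: float = 1e-10
    # mimicry
    max_expectation: float = 5.0
    max_mismatches: int = 3
    stages: tuple[str, ...] = (
        "discover",
        "de",
        "targets",
        "accessibility",
        "ism",
        "scan_motifs",
        "mimicry",
    )

    def __post_init__(self) -> None:
        self.data_dir = Path(self.data_dir)
        self.out_dir = Path(self.out_dir)

    def input_path(self, name: str) -> Path:
        names = {
            "genome": "genome.fasta",
            "sizes": "chrom.sizes",
            "annotation": "annotation.gtf",
            "expression": "expression.tsv",
            "evidence": "coding_evidence.tsv",
            "small_rnas": "small_rnas.bed",
            "coverage": "coverage.bedGraph",
            "motifs": "motifs.meme",
            "mirnas": "mirnas.fasta",
            "de_stats": "de_stats.tsv",
        }
        return self.data_dir / names[name]

    def validate(self) -> None:
        required = [
            "genome", "sizes", "annotation", "expression", "evidence",
            "small_rnas", "coverage", "motifs", "mirnas",
        ]
        missing = [n for n in required if not self.input_path(n).exists()]
        if missing:
            raise FileNotFoundError(
                f"missing input files in {self.data_dir}: "
                + ", ".join(str(self.input_path(n)) for n in missing)
            )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; returns the run manifest."""
    config.validate()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
    }

    genome = read_fasta(config.input_path("genome"))
    sizes = read_chrom_sizes(config.input_path("sizes"))
    transcripts = read_gtf(config.input_path("annotation"))
    matrix = ExpressionMatrix.from_tsv(config.input_path("expression"))
    ev_df = read_tsv(config.input_path("evidence"))
    evidence = [
        CodingEvidence(
            r.transcript_id, bool(r.cpc_coding), bool(r.pfam_hit), bool(r.swissprot_hit)
        )
        for r in ev_df.itertuples()
    ]
    small_rnas = read_bed(config.input_path("small_rnas"))

    # ---- discovery --------------------------------------------------------
    lncrnas = []
    if "discover" in config.stages:
        try:
            lncrnas, counts = discovery.run_discovery_cascade(
                transcripts,
                matrix,
                small_rnas,
                evidence,
                min_length_exclusive=config.min_length_exclusive,
                min_samples=config.min_expressed_samples,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("discover", str(exc)) from exc
        write_tsv(
            pd.DataFrame(
                [
                    {
                        "transcript_id": a.transcript.transcript_id,
                        "chrom": a.transcript.interval.chrom,
                        "start": a.transcript.interval.start,
                        "end": a.transcript.interval.end,
                        "strand": a.transcript.interval.strand,
                        "class_code": a.transcript.class_code,
                        "category": a.category,
                    }
                    for a in lncrnas
                ]
            ),
            out / "lncrnas.tsv",
        )
        write_tsv(
            pd.DataFrame([{"stage": k, "count": v} for k, v in counts.items()]),
            out / "discovery_counts.tsv",
        )
        manifest["stages"]["discover"] = {"n_lncrnas": len(lncrnas), "counts": counts}

    by_id = {t.transcript_id: t for t in transcripts}
    lnc_ids = [a.transcript.transcript_id for a in lncrnas]

    # ---- differential expression -----------------------------------------
    de_results: dict[str, list[de_mod.DEResult]] = {}
    if "de" in config.stages:
        stats_path = config.input_path("de_stats")
        upstream = read_tsv(stats_path) if stats_path.exists() else None
        for genotype in config.genotypes:
            if upstream is not None:
                sub = upstream[upstream["genotype"] == genotype]
                qvals = dict(zip(sub["transcript_id"], sub["qvalue"]))
            else:
                stand_in = de_mod.welch_bh_stats(matrix, genotype, lnc_ids)
                qvals = dict(zip(stand_in["transcript_id"], stand_in["qvalue"]))
            rows = []
            for tid in lnc_ids:
                lfc = de_mod.compute_log2fc(matrix, tid, genotype)
                q = float(qvals.get(tid, 1.0))
                rows.append(
                    de_mod.DEResult(tid, lfc, q, de_mod.call_de(
                        lfc, q, config.min_abs_log2fc, config.max_q
                    ))
                )
            de_results[genotype] = rows
            write_tsv(
                pd.DataFrame([dataclasses.asdict(r) for r in rows]),
                out / f"de_{genotype}.tsv",
            )
            n_up, n_down = de_mod.count_directions(rows)
            manifest["stages"][f"de_{genotype}"] = {"n_up": n_up, "n_down": n_down}

    de_lnc_ids = sorted(
        {
            r.transcript_id
            for rows in de_results.values()
            for r in rows
            if r.direction != "none"
        }
    )

    # ---- targets ----------------------------------------------------------
    if "targets" in config.stages and de_lnc_ids:
        genes = {
            t.transcript_id: t.interval for t in transcripts if t.class_code == "="
        }
        cis_rows = []
        for tid in de_lnc_ids:
            pairs = targets.find_cis_neighbors(
                by_id[tid].interval, tid, genes, window=config.cis_window
            )
            pairs = targets.attach_correlations(pairs, matrix, on_undefined="drop")
            for p in targets.call_cis_targets(pairs, config.min_abs_r):
                cis_rows.append(dataclasses.asdict(p))
        write_tsv(pd.DataFrame(cis_rows), out / "cis_targets.tsv")
        expressed = discovery.filter_expression(
            matrix, [t for t in transcripts if t.class_code == "="]
        )
        et_matrix = ExpressionMatrix(
            matrix.values.loc[[t.transcript_id for t in expressed]], matrix.samples
        )
        modules = targets.detect_modules(
            et_matrix,
            beta=config.module_beta,
            min_module_size=config.module_min_size,
            cut_height=config.module_cut_height,
        )
        module_rows = []
        for module in modules:
            for tid in de_lnc_ids:
                assoc = targets.lncrna_module_association(
                    matrix.get(tid), et_matrix, module, seed=config.seed
                )
                module_rows.append(
                    {
                        "module_id": module.module_id,
                        "n_members": len(module.members),
                        "lncrna_id": tid,
                        "r": assoc.correlation,
                        "r_squared": assoc.r_squared,
                        "pvalue": assoc.pvalue,
                    }
                )
        write_tsv(pd.DataFrame(module_rows), out / "module_associations.tsv")
        manifest["stages"]["targets"] = {
            "n_cis_pairs": len(cis_rows),
            "n_modules": len(modules),
        }

    # ---- accessibility ----------------------------------------------------
    if "accessibility" in config.stages and de_lnc_ids:
        track = read_bedgraph(config.input_path("coverage"), sizes)
        rows = []
        for i, tid in enumerate(de_lnc_ids):
            test = acc.accessibility_significance(
                track, by_id[tid].interval, n_null=config.n_null,
                seed=config.seed + i,
            )
            rows.append(
                {
                    "transcript_id": tid,
                    "observed_mean": test.observed_mean,
                    "null_mean": float(test.null_means.mean()),
                    "z": test.z,
                    "empirical_p": test.empirical_p,
                    "t_p": test.t_p,
                    "stars": test.stars,
                }
            )
        write_tsv(pd.DataFrame(rows), out / "accessibility.tsv")
        manifest["stages"]["accessibility"] = {
            "n_tested": len(rows),
            "n_significant": sum(1 for r in rows if r["empirical_p"] < 0.05),
        }

    # ---- in-silico mutagenesis --------------------------------------------
    peaks_by_lncrna: dict[str, list[tuple[int, int]]] = {}
    if "ism" in config.stages and de_lnc_ids:
        pwms = read_meme(config.input_path("motifs"))
        predictor = toy_predictor(
            pwms, config.ism_sequence_length, config.ism_receptive_field
        )
        rows = []
        for tid in de_lnc_ids:
            t = by_id[tid]
            tss = t.interval.start if t.interval.strand != "-" else t.interval.end - 1
            seq = extract_tss_window(
                genome, t.interval.chrom, tss, "+", config.ism_sequence_length
            )
            profile = isms_scan(
                seq,
                predictor,
                window=config.ism_window,
                stride=config.ism_stride,
                seed=config.seed,
                z_threshold=config.ism_z_threshold,
            )
            peaks_by_lncrna[tid] = profile.peaks
            for off, score, z in zip(profile.positions, profile.scores, profile.z):
                rows.append(
                    {
                        "transcript_id": tid,
                        "offset": int(off),
                        "isms": score,
                        "z": z,
                        "in_peak": any(s <= off < e for s, e in profile.peaks),
                    }
                )
        write_tsv(pd.DataFrame(rows), out / "isms_profiles.tsv")
        manifest["stages"]["ism"] = {
            "n_profiles": len(peaks_by_lncrna),
            "n_peaks": sum(len(p) for p in peaks_by_lncrna.values()),
        }

    # ---- motif scanning ----------------------------------------------------
    if "scan_motifs" in config.stages and de_lnc_ids:
        pwms = read_meme(config.input_path("motifs"))
        rows = []
        for tid in de_lnc_ids:
            t = by_id[tid]
            seq = genome[t.interval.chrom][t.interval.start : t.interval.end]
            for pwm in pwms:
                for hit in motifs_mod.scan_sequence(
                    seq, pwm, p_threshold=config.motif_p_threshold,
                    chrom=t.interval.chrom,
                ):
                    rows.append(
                        {
                            "lncrna_id": tid,
                            "motif_id": hit.motif_id,
                            "start": hit.interval.start + t.interval.start,
                            "end": hit.interval.end + t.interval.start,
                            "strand": hit.interval.strand,
                            "score": hit.score,
                            "pvalue": hit.pvalue,
                        }
                    )
        write_tsv(pd.DataFrame(rows), out / "motif_hits.tsv")
        manifest["stages"]["scan_motifs"] = {"n_hits": len(rows)}

    # ---- miRNA mimicry -----------------------------------------------------
    if "mimicry" in config.stages and de_lnc_ids:
        mirnas = read_fasta(config.input_path("mirnas"))
        lnc_seqs = {
            tid: by_id[tid].spliced_sequence(genome) for tid in de_lnc_ids
        }
        duplexes = mimicry.screen(
            mirnas,
            lnc_seqs,
            max_expectation=config.max_expectation,
            max_mismatches=config.max_mismatches,
        )
        write_tsv(
            pd.DataFrame(
                [
                    {
                        "mirna_id": d.mirna_id,
                        "lncrna_id": d.lncrna_id,
                        "offset": d.offset,
                        "site": d.site,
                        "alignment": d.alignment,
                        "expectation": d.expectation,
                        "n_mismatches": d.n_mismatches,
                        "upe": "NA",  # not evaluated (structure term out of scope)
                    }
                    for d in duplexes
                ]
            ),
            out / "mimicry.tsv",
        )
        manifest["stages"]["mimicry"] = {"n_duplexes": len(duplexes)}

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
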