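"""The lncRNA filtering cascade: each filter's rule, order invariance, and
exact truth recovery on planted data."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lncregnet.annotation_io import ExpressionMatrix, GenomicInterval, TranscriptModel
from lncregnet.discovery import (
    CodingEvidence,
    classify_lncrna,
    filter_class_codes,
    filter_coding_potential,
    filter_expression,
    filter_length,
    longest_orf_codons,
    orf_heuristic_evidence,
    remove_small_rna_overlaps,
    run_discovery_cascade,
)


def make_tx(tid, start=0, end=500, code="u", chrom="c1", n_exons=1, strand="+"):
    iv = GenomicInterval(chrom, start, end, strand)
    if n_exons == 1:
        exons = [iv]
    else:
        third = (end - start) // 3
        exons = [
            GenomicInterval(chrom, start, start + third, strand),
            GenomicInterval(chrom, end - third, end, strand),
        ]
    return TranscriptModel(tid, f"g_{tid}", iv, exons, code)


def make_matrix(rows):
    samples = [
        f"{g}_{c}_r{r}" for g in ("tolerant", "sensitive")
        for c in ("control", "salt") for r in (1, 2, 3)
    ]
    return ExpressionMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=samples))


class TestClassCodeFilter:
    def test_keeps_exactly_the_four_candidate_codes(self):
        txs = [make_tx(c, code=c) for c in ["u", "o", "i", "x", "=", "j", "c"]]
        kept = filter_class_codes(txs)
        assert [t.transcript_id for t in kept] == ["u", "o", "i", "x"]

    def test_reference_matches_are_all_removed(self):
        assert filter_class_codes([make_tx(f"t{i}", code="=") for i in range(5)]) == []

    def test_published_de_lncrna_codes_all_pass(self):
        # the 13 reported DE-lncRNAs carry 11 "o" and 2 "u" class codes
        txs = [make_tx(f"o{i}", code="o") for i in range(11)]
        txs += [make_tx(f"u{i}", code="u") for i in range(2)]
        assert len(filter_class_codes(txs)) == 13


class TestExpressionFilter:
    def test_multiexon_boundary_two_samples_at_half_fpkm(self):
        t = make_tx("t", n_exons=2)
        m = make_matrix({"t": [0.5, 0.5, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]})
        assert filter_expression(m, [t]) == [t]

    def test_single_exon_below_two_fpkm_everywhere_dropped(self):
        t = make_tx("t", n_exons=1)
        m = make_matrix({"t": [1.9] * 12})
        assert filter_expression(m, [t]) == []

    def test_one_expressing_sample_is_not_enough(self):
        t = make_tx("t", n_exons=2)
        m = make_matrix({"t": [100.0] + [0.0] * 11})
        assert filter_expression(m, [t]) == []

    def test_missing_transcript_raises_with_id(self):
        t = make_tx("absent")
        m = make_matrix({"present": [1.0] * 12})
        with pytest.raises(KeyError, match="absent"):
            filter_expression(m, [t])


class TestSmallRnaFilter:
    def test_single_bp_overlap_removes(self):
        t = make_tx("t", 100, 200)
        assert remove_small_rna_overlaps([t], [GenomicInterval("c1", 199, 250)]) == []

    def test_halfopen_adjacency_keeps(self):
        t = make_tx("t", 100, 200)
        assert remove_small_rna_overlaps([t], [GenomicInterval("c1", 200, 250)]) == [t]

    def test_empty_annotation_is_identity(self):
        txs = [make_tx("a"), make_tx("b", 600, 900)]
        assert remove_small_rna_overlaps(txs, []) == txs

    def test_intronic_overlap_does_not_remove(self):
        # overlap must be exonic: a small RNA inside the intron is ignored
        t = make_tx("t", 0, 600, n_exons=2)  # exons [0,200) and [400,600)
        assert remove_small_rna_overlaps([t], [GenomicInterval("c1", 250, 350)]) == [t]


class TestLengthFilter:
    def test_strict_boundary_at_200(self):
        t200 = make_tx("a", 0, 200)
        t201 = make_tx("b", 300, 501)
        assert filter_length([t200, t201]) == [t201]

    def test_published_828bp_lncrna_passes(self):
        t = make_tx("lnc2fl", 21_764_438, 21_765_266, code="o", chrom="6")
        assert t.spliced_length == 828
        assert filter_length([t]) == [t]

    def test_spliced_not_genomic_length_is_used(self):
        # genomic span 600 but spliced 400: still kept; spliced 150 dropped
        t = make_tx("t", 0, 600, n_exons=2)
        assert t.spliced_length == 400
        assert filter_length([t]) == [t]


class TestCodingPotentialFilter:
    def test_intersection_rule(self):
        txs = [make_tx("a"), make_tx("b", 600, 900)]
        ev = [
            CodingEvidence("a", False, False, False),
            CodingEvidence("b", False, True, False),
        ]
        assert [t.transcript_id for t in filter_coding_potential(txs, ev)] == ["a"]

    def test_all_coding_gives_empty(self):
        txs = [make_tx(f"t{i}", i * 1000, i * 1000 + 500) for i in range(4)]
        ev = [CodingEvidence(t.transcript_id, True) for t in txs]
        assert filter_coding_potential(txs, ev) == []

    def test_matches_bruteforce_set_intersection(self):
        rng = np.random.default_rng(0)
        txs = [make_tx(f"t{i}", i * 1000, i * 1000 + 500) for i in range(10)]
        ev = [
            CodingEvidence(t.transcript_id, *map(bool, rng.integers(0, 2, 3)))
            for t in txs
        ]
        # independent oracle: intersect the three per-engine pass lists
        pass_cpc = {e.transcript_id for e in ev if not e.cpc_coding}
        pass_pfam = {e.transcript_id for e in ev if not e.pfam_hit}
        pass_sp = {e.transcript_id for e in ev if not e.swissprot_hit}
        expected = [
            t for t in txs
            if t.transcript_id in (pass_cpc & pass_pfam & pass_sp)
        ]
        assert filter_coding_potential(txs, ev) == expected

    def test_missing_evidence_raises(self):
        with pytest.raises(KeyError):
            filter_coding_potential([make_tx("t")], [])


def _orf_oracle(seq):
    """Brute-force: longest ATG..stop codon run over all start offsets."""
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        codons = 0
        for j in range(i, len(seq) - 2, 3):
            if seq[j : j + 3] in stops:
                best = max(best, codons)
                break
            codons += 1
    return best


class TestOrfHeuristic:
    def test_no_atg_means_noncoding(self):
        genome = {"c1": "CCGG" * 100}
        t = make_tx("t", 0, 400)
        (e,) = orf_heuristic_evidence([t], genome)
        assert e.cpc_coding is False and e.heuristic is True

    def test_303bp_orf_flags_coding(self):
        orf = "ATG" + "GCA" * 99 + "TAA"  # 100 codons + stop = 303 nt
        genome = {"c1": "C" * 20 + orf + "C" * 77}
        t = make_tx("t", 0, 400)
        (e,) = orf_heuristic_evidence([t], genome)
        assert e.cpc_coding is True

    def test_empty_input(self):
        assert orf_heuristic_evidence([], {}) == []

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=300))
            assert longest_orf_codons(seq) == _orf_oracle(seq)


class TestClassification:
    @pytest.mark.parametrize(
        "code,category",
        [("u", "lincRNA"), ("i", "intronic"), ("x", "antisense"), ("o", "sense")],
    )
    def test_class_code_category_mapping(self, code, category):
        assert classify_lncrna(make_tx("t", code=code)).category == category

    def test_non_candidate_code_rejected(self):
        with pytest.raises(ValueError):
            classify_lncrna(make_tx("t", code="="))


class TestCascade:
    def test_recovers_planted_truth_exactly(self, zero_noise_dataset):
        ds = zero_noise_dataset
        ann, counts = run_discovery_cascade(
            ds.transcripts, ds.matrix, ds.small_rnas, ds.evidence
        )
        found = {a.transcript.transcript_id for a in ann}
        assert found == ds.manifest.lncrna_ids()
        for a in ann:
            assert a.category == ds.manifest.transcripts[a.transcript.transcript_id].category

    def test_stage_counts_monotone_nonincreasing(self, dataset):
        _, counts = run_discovery_cascade(
            dataset.transcripts, dataset.matrix, dataset.small_rnas, dataset.evidence
        )
        values = list(counts.values())
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_empty_input(self, dataset):
        ann, counts = run_discovery_cascade([], dataset.matrix, [], [])
        assert ann == [] and all(v == 0 for v in counts.values())

    def test_per_transcript_filters_commute(self, dataset):
        """Survivors are identical under any order of the independent filters."""
        ds = dataset
        ev = ds.evidence
        filters = {
            "class": filter_class_codes,
            "length": filter_length,
            "coding": lambda ts: filter_coding_potential(ts, ev),
        }
        results = []
        for order in itertools.permutations(filters):
            stage = list(ds.transcripts)
            for name in order:
                stage = filters[name](stage)
            results.append({t.transcript_id for t in stage})
        assert all(r == results[0] for r in results)

    @pytest.mark.parametrize("name", ["class", "length"])
    def test_filters_idempotent(self, dataset, name):
        f = {"class": filter_class_codes, "length": filter_length}[name]
        once = f(dataset.transcripts)
        assert f(once) == once
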