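"""Cis windowing, correlation thresholds, module detection and enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lncregnet.annotation_io import ExpressionMatrix, GenomicInterval
from lncregnet.discovery import filter_expression
from lncregnet.synthetic import SimulationConfig, simulate_dataset
from lncregnet.targets import (
    CisPair,
    ModuleAssignment,
    call_cis_targets,
    detect_modules,
    fisher_enrichment,
    find_cis_neighbors,
    lncrna_module_association,
    module_summary_profile,
    pearson,
)


def _et_matrix(ds):
    expressed = filter_expression(
        ds.matrix, [t for t in ds.transcripts if t.class_code == "="]
    )
    return ExpressionMatrix(
        ds.matrix.values.loc[[t.transcript_id for t in expressed]], ds.matrix.samples
    )


class TestCisNeighbors:
    LNC = GenomicInterval("1", 1_000_000, 1_001_000, "+")

    def _genes(self, **kw):
        return {k: v for k, v in kw.items()}

    def test_boundary_inclusive_at_window(self):
        genes = {
            "at": GenomicInterval("1", 1_101_000, 1_102_000),  # gap exactly 100000
            "beyond": GenomicInterval("1", 1_101_001, 1_102_000),  # 100001
        }
        pairs = find_cis_neighbors(self.LNC, "lnc", genes)
        assert [p.gene_id for p in pairs] == ["at"]
        assert pairs[0].distance == 100_000

    def test_overlap_has_distance_zero(self):
        genes = {"g": GenomicInterval("1", 1_000_500, 1_002_000)}
        (p,) = find_cis_neighbors(self.LNC, "lnc", genes)
        assert p.distance == 0 and p.orientation == "overlapping"

    def test_published_distance_93kb_downstream_included(self):
        # a zinc-finger gene 93,163 bp downstream of its lncRNA is a neighbor
        genes = {"g": GenomicInterval("1", self.LNC.end + 93_163, self.LNC.end + 95_000)}
        (p,) = find_cis_neighbors(self.LNC, "lnc", genes)
        assert p.distance == 93_163 and p.orientation == "downstream"

    def test_other_chromosome_excluded(self):
        genes = {"g": GenomicInterval("2", 1_000_000, 1_001_000)}
        assert find_cis_neighbors(self.LNC, "lnc", genes) == []

    def test_window_symmetry(self):
        """g neighbors lnc iff lnc neighbors g (same window both ways)."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = int(rng.integers(0, 500_000))
            b = int(rng.integers(0, 500_000))
            iv_a = GenomicInterval("1", a, a + 500)
            iv_b = GenomicInterval("1", b, b + 800)
            ab = bool(find_cis_neighbors(iv_a, "a", {"b": iv_b}, window=50_000))
            ba = bool(find_cis_neighbors(iv_b, "b", {"a": iv_a}, window=50_000))
            assert ab == ba


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(6.0)
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        x = np.array([1.0, 4.0, 2.0, 7.0, 5.0, 3.0])
        y = np.array([2.0, 3.0, 1.0, 9.0, 4.0, 4.0])
        # brute-force covariance / sigma computation
        expected = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        assert pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCisTargets:
    def _pair(self, r):
        return CisPair("lnc", "g", 10, "upstream", correlation=r)

    def test_threshold_default_and_override(self):
        strong = self._pair(-0.97)
        weak = self._pair(0.56)
        assert call_cis_targets([strong, weak]) == [strong]
        assert call_cis_targets([strong, weak], min_abs_r=0.5) == [strong, weak]

    def test_empty(self):
        assert call_cis_targets([]) == []

    def test_unset_correlation_rejected(self):
        with pytest.raises(ValueError):
            call_cis_targets([CisPair("l", "g", 0, "upstream")])


class TestModules:
    def test_two_perfect_blocks_recovered(self):
        rng = np.random.default_rng(0)
        p1, p2 = rng.normal(size=12), rng.normal(size=12)
        rows = {}
        for i in range(12):
            rows[f"a{i}"] = 100 + 10 * p1 + 0.01 * i
        for i in range(12):
            rows[f"b{i}"] = 100 + 10 * p2 + 0.01 * i
        samples = [
            f"{g}_{c}_r{r}" for g in ("tolerant", "sensitive")
            for c in ("control", "salt") for r in (1, 2, 3)
        ]
        m = ExpressionMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=samples))
        mods = detect_modules(m, min_module_size=5, log_transform=False)
        member_sets = sorted(frozenset(mod.members) for mod in mods)
        assert len(mods) == 2
        assert {frozenset(f"a{i}" for i in range(12)), frozenset(f"b{i}" for i in range(12))} == set(member_sets)

    def test_small_cluster_unassigned(self, dataset):
        et = _et_matrix(dataset)
        mods = detect_modules(et, min_module_size=10)
        assert all(len(m.members) >= 10 for m in mods)

    def test_planted_module_coassigned_over_seeds(self):
        """>= 90% of planted members land in one module at target r = 0.9."""
        fracs = []
        for seed in range(20):
            ds = simulate_dataset(SimulationConfig(seed=100 + seed, module_r=0.9))
            et = _et_matrix(ds)
            mods = detect_modules(et)
            members = set(ds.manifest.module_members)
            best = max((len(members & set(m.members)) for m in mods), default=0)
            fracs.append(best / len(members))
        assert np.mean(fracs) >= 0.9

    def test_row_permutation_invariance(self, dataset):
        et = _et_matrix(dataset)
        mods = detect_modules(et)
        rng = np.random.default_rng(7)
        perm = rng.permutation(len(et.values))
        shuffled = ExpressionMatrix(et.values.iloc[perm], et.samples)
        mods_p = detect_modules(shuffled)
        assert sorted(frozenset(m.members) for m in mods) == sorted(
            frozenset(m.members) for m in mods_p
        )


class TestModuleAssociation:
    def test_driver_association_near_perfect_at_zero_noise(self, zero_noise_dataset):
        ds = zero_noise_dataset
        et = _et_matrix(ds)
        mods = detect_modules(et)
        members = set(ds.manifest.module_members)
        module = max(mods, key=lambda m: len(members & set(m.members)))
        assoc = lncrna_module_association(
            ds.matrix.get(ds.manifest.module_driver), et, module, seed=0
        )
        assert assoc.r_squared >= 0.98
        # permutation resolution is bounded by block-preserving permutations
        # of the 2x2x3 design (~1/220 of all orders), not by 1/(n_perm + 1)
        assert assoc.pvalue <= 0.005

    def test_driver_association_significant_with_noise(self, dataset):
        ds = dataset
        et = _et_matrix(ds)
        mods = detect_modules(et)
        members = set(ds.manifest.module_members)
        module = max(mods, key=lambda m: len(members & set(m.members)))
        assoc = lncrna_module_association(
            ds.matrix.get(ds.manifest.module_driver), et, module, seed=0
        )
        assert assoc.r_squared >= 0.7
        assert assoc.pvalue <= 0.01

    def test_tightly_coupled_lncrna_reaches_permutation_floor(self, dataset):
        """A lncRNA tracking the module summary yields r^2 ~ 1 and a p-value
        at the resolution the blocked design permits."""
        et = _et_matrix(dataset)
        (module, *_rest) = detect_modules(et)
        profile = module_summary_profile(et, module)
        rng = np.random.default_rng(3)
        lnc = 2.0 ** (5 + 3 * profile + 0.05 * rng.standard_normal(profile.size))
        assoc = lncrna_module_association(lnc, et, module, seed=2)
        assert assoc.r_squared >= 0.99
        assert assoc.pvalue <= 0.005

    def test_vector_equal_to_profile_gives_r2_one(self, dataset):
        et = _et_matrix(dataset)
        (module, *_rest) = detect_modules(et)
        profile = module_summary_profile(et, module)
        # feed the summary profile itself (in linear FPKM space)
        assoc = lncrna_module_association(
            2.0 ** profile, et, module, n_permutations=500, seed=1
        )
        # the log pseudocount leaves a ~1e-8 dent in an otherwise exact r^2
        assert assoc.r_squared == pytest.approx(1.0, abs=1e-6)

    def test_permutation_p_uniform_under_null(self):
        """Independent lncRNA vectors give uniform permutation p-values."""
        rng = np.random.default_rng(0)
        samples = [
            f"{g}_{c}_r{r}" for g in ("tolerant", "sensitive")
            for c in ("control", "salt") for r in (1, 2, 3)
        ]
        rows = {f"m{i}": 50 * 2.0 ** rng.normal(size=12) for i in range(10)}
        m = ExpressionMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=samples))
        module = ModuleAssignment(1, list(rows))
        pvals = [
            lncrna_module_association(
                50 * 2.0 ** rng.normal(size=12), m, module,
                n_permutations=500, seed=1000 + i,
            ).pvalue
            for i in range(200)
        ]
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


def _hypergeom_tail(N, K, n, k):
    """Direct summation oracle for the upper-tail hypergeometric p."""
    from math import comb

    total = 0.0
    for i in range(k, min(K, n) + 1):
        total += comb(K, i) * comb(N - K, n - i) / comb(N, n)
    return total


class TestFisherEnrichment:
    def test_extreme_table_minimal_p(self):
        universe = [f"g{i}" for i in range(20)]
        members = universe[:10]
        res = fisher_enrichment(members, {"T": members}, universe)
        assert res[0].pvalue == pytest.approx(_hypergeom_tail(20, 10, 10, 10))

    def test_matches_direct_summation(self):
        universe = [f"g{i}" for i in range(100)]
        term = universe[:10]
        members = universe[:5] + universe[50:55]
        (res,) = fisher_enrichment(members, {"T": term}, universe)
        assert res.k == 5
        assert res.pvalue == pytest.approx(_hypergeom_tail(100, 10, 10, 5), rel=1e-12)

    def test_disjoint_term_gives_p_one(self):
        universe = [f"g{i}" for i in range(30)]
        (res,) = fisher_enrichment(universe[:5], {"T": universe[20:25]}, universe)
        assert res.pvalue == pytest.approx(1.0)

    def test_exhaustive_small_universes(self):
        """DP-free check across many table shapes on universes <= 200."""
        rng = np.random.default_rng(5)
        for _ in range(30):
            N = int(rng.integers(10, 201))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            universe = [f"g{i}" for i in range(N)]
            term = list(rng.choice(universe, size=K, replace=False))
            members = list(rng.choice(universe, size=n, replace=False))
            k = len(set(term) & set(members))
            (res,) = fisher_enrichment(members, {"T": term}, universe)
            assert res.pvalue == pytest.approx(_hypergeom_tail(N, K, n, k), rel=1e-9)

    def test_member_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(["x"], {"T": ["a"]}, ["a", "b"])

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment([], {}, [])
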