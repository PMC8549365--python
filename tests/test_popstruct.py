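import numpy as np
import pandas as pd
import pytest

from oracles import (
    brute_force_mst_weight,
    exhaustive_mantel,
    random_distance_matrix,
    two_level_components,
)

from crisprtyper.errors import (
    DegenerateDesign,
    Disconnected,
    PositionOutOfRange,
    TooFewEntries,
    UndefinedCorrelation,
)
from crisprtyper.oisl import DistanceMatrix
from crisprtyper.popstruct import (
    FstMatrix,
    SampleHierarchy,
    amova,
    count_gene_haplotypes,
    lingoes_correct,
    mantel,
    min_spanning_network,
    pairwise_fst,
)


def hierarchy_from_counts(pop_counts, levels=("host",)):
    """pop_counts: {pop: {hap: n}} -> one-level SampleHierarchy."""
    rows = []
    for pop, counts in pop_counts.items():
        for hap, n in counts.items():
            rows += [{"host": pop, "haplotype_id": hap}] * n
    return SampleHierarchy(pd.DataFrame(rows), levels=levels)


def gower_min_eig(values):
    n = values.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return float(np.linalg.eigvalsh(J @ (-0.5 * values**2) @ J)[0])


class TestLingoes:
    def test_points_on_a_line_unchanged(self):
        d = DistanceMatrix(list("abc"), [[0, 1, 3], [1, 0, 2], [3, 2, 0]])
        assert lingoes_correct(d) is d

    def test_non_euclidean_matrix_corrected(self):
        # severe triangle-violating matrix
        m = np.array(
            [[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 3.0], [1, 1, 3.0, 0]]
        )
        # symmetric and non-negative but not Euclidean-embeddable
        d = DistanceMatrix(list("abcd"), np.sqrt(m))  # sqrt keeps it non-Euclid?
        d = DistanceMatrix(list("abcd"), m / m.max())
        assert gower_min_eig(d.values) < -1e-9
        out = lingoes_correct(d)
        assert gower_min_eig(out.values) >= -1e-9
        # off-diagonal squared distances shifted by one constant
        delta = out.values**2 - d.values**2
        off = delta[np.triu_indices(4, k=1)]
        assert np.allclose(off, off[0])

    def test_ultrametric_unchanged(self):
        m = np.array(
            [
                [0.0, 0.2, 0.8, 0.8],
                [0.2, 0.0, 0.8, 0.8],
                [0.8, 0.8, 0.0, 0.4],
                [0.8, 0.8, 0.4, 0.0],
            ]
        )
        d = DistanceMatrix(list("abcd"), m)
        assert lingoes_correct(d) is d

    def test_random_matrices_pass_euclidean_check_after_correction(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 10))
            d = DistanceMatrix(
                [f"p{i}" for i in range(n)], random_distance_matrix(rng, n)
            )
            assert gower_min_eig(lingoes_correct(d).values) >= -1e-9


class TestAmova:
    def test_two_clonal_populations_maximal_structure(self):
        h = hierarchy_from_counts({"p1": {"h1": 5}, "p2": {"h2": 5}})
        d = DistanceMatrix(["h1", "h2"], [[0, 1], [1, 0]])
        res = amova(h, d, n_perm=0)
        assert res.table.loc["host", "percent"] == pytest.approx(100.0)
        assert res.phi_total == pytest.approx(1.0)

    def test_balanced_toy_matches_hand_solved_components(self):
        # 2 groups x 2 individuals; d(within) = 2 (d2 = 4), d(between) = 4
        # (d2 = 16). Hand algebra: SS_W = 4, MS_W = sigma_w = 2;
        # SS_T = 72/4 = 18, SS_A = 14, n_c = 2, sigma_a = (14 - 2)/2 = 6.
        rows = [
            {"host": "g1", "haplotype_id": "a"},
            {"host": "g1", "haplotype_id": "b"},
            {"host": "g2", "haplotype_id": "c"},
            {"host": "g2", "haplotype_id": "d"},
        ]
        h = SampleHierarchy(pd.DataFrame(rows), levels=("host",))
        m = np.full((4, 4), 4.0)
        m[0, 1] = m[1, 0] = m[2, 3] = m[3, 2] = 2.0
        np.fill_diagonal(m, 0.0)
        d = DistanceMatrix(list("abcd"), m)
        res = amova(h, d, n_perm=0)
        assert res.table.loc["host", "SS"] == pytest.approx(14.0)
        assert res.table.loc["Within", "SS"] == pytest.approx(4.0)
        assert res.table.loc["host", "sigma"] == pytest.approx(6.0)
        assert res.table.loc["Within", "sigma"] == pytest.approx(2.0)
        assert res.table.loc["host", "percent"] == pytest.approx(75.0)
        assert res.phi["host"] == pytest.approx(0.75)

    def test_matches_independent_two_level_oracle_unbalanced(self, rng):
        # unbalanced groups, arbitrary distances
        sizes = [3, 5, 2]
        groups = np.repeat(np.arange(3), sizes)
        n = groups.size
        haps = [f"i{k}" for k in range(n)]
        m = random_distance_matrix(rng, n)
        d = DistanceMatrix(haps, m)
        rows = [{"host": f"g{g}", "haplotype_id": haps[k]}
                for k, g in enumerate(groups)]
        h = SampleHierarchy(pd.DataFrame(rows), levels=("host",))
        res = amova(h, d, n_perm=0)
        sigma_a, sigma_w = two_level_components(m**2, groups)
        assert res.table.loc["host", "sigma"] == pytest.approx(sigma_a)
        assert res.table.loc["Within", "sigma"] == pytest.approx(sigma_w)

    def test_percentages_sum_to_100_and_df_to_n_minus_1(self, rng):
        from crisprtyper.simulate import SimConfig, simulate_hierarchy

        cfg = SimConfig(seed=3, n_regions=2, n_habitats=2, n_sites=1,
                        n_hosts=2, depth=30)
        haps = [f"H{i}" for i in range(1, 9)]
        h = simulate_hierarchy(haps, cfg)
        d = DistanceMatrix(haps, random_distance_matrix(rng, 8))
        res = amova(h, lingoes_correct(d), levels=["region", "habitat", "host"],
                    n_perm=0)
        body = res.table.drop(index="Total")
        assert body["percent"].sum() == pytest.approx(100.0, abs=0.01)
        assert body["df"].sum() == len(h) - 1
        assert res.table.loc["Total", "SS"] == pytest.approx(
            body["SS"].sum()
        )

    def test_single_group_level_raises(self):
        h = hierarchy_from_counts({"p1": {"h1": 3, "h2": 2}})
        d = DistanceMatrix(["h1", "h2"], [[0, 1], [1, 0]])
        with pytest.raises(DegenerateDesign):
            amova(h, d, n_perm=0)

    def test_one_level_phi_equals_pairwise_fst(self):
        h = hierarchy_from_counts(
            {"p1": {"h1": 8, "h2": 2}, "p2": {"h1": 2, "h2": 8}}
        )
        res = amova(h, None, levels=["host"], n_perm=0)
        fm = pairwise_fst(h, "host", mode="haplotype-frequency", n_perm=0)
        assert fm.values[0, 1] == pytest.approx(res.phi["host"])


class TestPairwiseFst:
    def test_fixed_alternative_haplotypes(self):
        h = hierarchy_from_counts({"p1": {"h1": 6}, "p2": {"h2": 6}})
        fm = pairwise_fst(h, "host", n_perm=99, seed=1)
        assert fm.values[0, 1] == pytest.approx(1.0)
        assert fm.pvalues[0, 1] <= 0.05

    def test_identical_frequencies_no_differentiation(self):
        h = hierarchy_from_counts(
            {"p1": {"h1": 25, "h2": 25}, "p2": {"h1": 25, "h2": 25}}
        )
        fm = pairwise_fst(h, "host", n_perm=99, seed=1)
        assert fm.values[0, 1] <= 1e-9
        assert fm.pvalues[0, 1] > 0.05

    def test_toy_counts_match_excoffier_oracle(self):
        h = hierarchy_from_counts(
            {"p1": {"h1": 8, "h2": 2}, "p2": {"h1": 2, "h2": 8}}
        )
        fm = pairwise_fst(h, "host", n_perm=0)
        haps = np.array(["h1"] * 8 + ["h2"] * 2 + ["h1"] * 2 + ["h2"] * 8)
        d2 = (haps[:, None] != haps[None, :]).astype(float)
        sigma_a, sigma_w = two_level_components(
            d2, np.repeat([0, 1], 10)
        )
        assert fm.values[0, 1] == pytest.approx(sigma_a / (sigma_a + sigma_w))

    def test_small_population_rejected(self):
        h = hierarchy_from_counts({"p1": {"h1": 1}, "p2": {"h2": 5}})
        with pytest.raises(DegenerateDesign):
            pairwise_fst(h, "host", n_perm=0)


class TestMantel:
    def _fst(self, values, pvalues=None):
        n = values.shape[0]
        if pvalues is None:
            pvalues = np.zeros((n, n))
        return FstMatrix(
            labels=tuple(f"p{i}" for i in range(n)),
            values=values, pvalues=pvalues,
        )

    def test_identity_gives_r1_and_minimal_exact_p(self, rng):
        m = random_distance_matrix(rng, 5)
        r, p = mantel(self._fst(m), self._fst(m.copy()), n_perm=0)
        assert r == pytest.approx(1.0)
        # identity is the unique maximum for a generic matrix: p = 1/5!
        assert p == pytest.approx(1 / 120, abs=1e-12)

    def test_constant_matrix_undefined(self, rng):
        m1 = random_distance_matrix(rng, 4)
        m2 = np.ones((4, 4)) * 0.3
        np.fill_diagonal(m2, 0.0)
        with pytest.raises(UndefinedCorrelation):
            mantel(self._fst(m1), self._fst(m2), n_perm=0)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(5):
            m1 = random_distance_matrix(rng, 4)
            m2 = m1.copy()
            # swap one pair of rows/cols to decorrelate
            perm = np.array([1, 0, 2, 3])
            m2 = m2[np.ix_(perm, perm)]
            r_ref, p_ref = exhaustive_mantel(m1, m2)
            r, p = mantel(self._fst(m1), self._fst(m2), n_perm=0)
            assert r == pytest.approx(r_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_zero_nonsignificant_handling(self, rng):
        m1 = random_distance_matrix(rng, 5)
        m2 = m1 * 0.9
        pv = np.zeros((5, 5))
        pv[0, 1] = pv[1, 0] = 0.4  # one non-significant pair
        r_zeroed, _ = mantel(self._fst(m1), self._fst(m2, pv), n_perm=0)
        v2 = m2.copy()
        v2[0, 1] = v2[1, 0] = 0.0
        r_manual, _ = mantel(self._fst(m1), self._fst(v2), n_perm=0)
        assert r_zeroed == pytest.approx(r_manual, abs=1e-12)

    def test_exclusion_leaves_too_few_pairs(self, rng):
        m1 = random_distance_matrix(rng, 4)
        pv = np.full((4, 4), 0.9)
        with pytest.raises(TooFewEntries):
            mantel(self._fst(m1), self._fst(m1.copy(), pv),
                   handling="exclude_nonsignificant", n_perm=0)


class TestMinSpanningNetwork:
    def test_chain(self):
        d = DistanceMatrix(
            list("ABC"), [[0, 1, 2], [1, 0, 1], [2, 1, 0]]
        )
        g = min_spanning_network(d)
        assert set(map(frozenset, g.edges)) == {
            frozenset("AB"), frozenset("BC")
        }

    def test_weight_matches_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 8))
            m = random_distance_matrix(rng, n)
            d = DistanceMatrix([f"h{i}" for i in range(n)], m)
            g = min_spanning_network(d)
            weight = sum(data["weight"] for _, _, data in g.edges(data=True))
            assert weight == pytest.approx(brute_force_mst_weight(m), abs=1e-9)

    def test_equal_weight_tie_is_lexicographic(self):
        m = np.ones((3, 3))
        np.fill_diagonal(m, 0.0)
        g = min_spanning_network(DistanceMatrix(list("ABC"), m))
        assert sorted(map(tuple, map(sorted, g.edges))) == [
            ("A", "B"), ("A", "C")
        ]

    def test_capped_distances_disconnect(self):
        m = np.array([[0, 1, 20], [1, 0, 20], [20, 20, 0.0]])
        with pytest.raises(Disconnected):
            min_spanning_network(DistanceMatrix(list("ABC"), m), cap=20.0)

    def test_node_attributes(self):
        d = DistanceMatrix(["A", "B"], [[0, 1], [1, 0]])
        g = min_spanning_network(d, node_attrs={"A": {"p1": 3, "p2": 1}})
        assert g.nodes["A"]["total"] == 4
        assert g.nodes["B"]["total"] == 0


class TestGeneHaplotypes:
    def test_counts_two_locus_haplotypes(self):
        reads = [("AxxG", [40, 40, 40, 40])] * 10 + [("CxxT", [40] * 4)] * 5
        counts = count_gene_haplotypes(reads, (0, 3))
        assert counts == {"AG": 10, "CT": 5}

    def test_low_quality_base_drops_read(self):
        reads = [("AxxG", [40, 40, 40, 27]), ("AxxG", [40, 40, 40, 28])]
        counts = count_gene_haplotypes(reads, (0, 3), min_qual=28)
        assert counts == {"AG": 1}

    def test_position_out_of_range(self):
        with pytest.raises(PositionOutOfRange):
            count_gene_haplotypes([("ACGT", [40] * 4)], (0, 9))

    def test_sampling_fluctuation_within_binomial_bound(self, rng):
        # two haplotypes at 0.7/0.3, depth 300
        n, f = 300, 0.7
        draws = rng.random(n) < f
        reads = [("AxG" if x else "CxT", [40, 40, 40]) for x in draws]
        counts = count_gene_haplotypes(reads, (0, 2))
        sd = np.sqrt(n * f * (1 - f))
        assert abs(counts.get("AG", 0) - n * f) < 3 * sd


class TestPermutationCalibration:
    def test_null_pvalues_roughly_uniform(self, rng):
        # 40 null datasets (quick version of the 200-dataset acceptance run)
        pvals = []
        haps = [f"h{i}" for i in range(6)]
        d = DistanceMatrix(haps, random_distance_matrix(rng, 6))
        for i in range(40):
            rows = [{"host": f"g{k % 4}", "haplotype_id": haps[rng.integers(6)]}
                    for k in range(40)]
            h = SampleHierarchy(pd.DataFrame(rows), levels=("host",))
            res = amova(h, d, n_perm=49, seed=int(rng.integers(2**31)))
            pvals.append(res.table.loc["host", "p_value"])
        pvals = np.array(pvals)
        # no mass concentration at the significant end under the null
        assert (pvals <= 0.1).mean() < 0.3
        assert pvals.mean() == pytest.approx(0.5, abs=0.2)
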