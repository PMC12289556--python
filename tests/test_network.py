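"""Spearman association testing, BH adjustment, network assembly and layout."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from comorbnet.cooccurrence import DiagnosisSetTable
from comorbnet.network import (
    EdgeTest,
    adjust_bh,
    build_network,
    compute_layout,
    export_network,
    import_network,
    node_centrality,
    pairwise_associations,
    spearman_association,
)
from comorbnet.synthetic import AssociationSpec, SyntheticCohortConfig, sample_disease_indicators


def rank_then_pearson(x, y):
    """Brute-force oracle: mid-ranks computed by hand, then the Pearson formula."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        out = np.empty(len(v))
        order = np.argsort(v, kind="mergesort")
        sv = v[order]
        i = 0
        while i < len(sv):
            j = i
            while j + 1 < len(sv) and sv[j + 1] == sv[i]:
                j += 1
            out[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return out

    rx, ry = midranks(x), midranks(y)
    mx, my = rx.mean(), ry.mean()
    num = ((rx - mx) * (ry - my)).sum()
    den = np.sqrt(((rx - mx) ** 2).sum() * ((ry - my) ** 2).sum())
    return num / den


def phi_coefficient(x, y):
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    n11 = ((x == 1) & (y == 1)).sum()
    n10 = ((x == 1) & (y == 0)).sum()
    n01 = ((x == 0) & (y == 1)).sum()
    n00 = ((x == 0) & (y == 0)).sum()
    num = n11 * n00 - n10 * n01
    den = np.sqrt(float((n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)))
    return num / den


class TestSpearmanAssociation:
    def test_identical_rankings(self):
        res = spearman_association([0, 0, 1, 1], [0, 0, 1, 1])
        assert res.rho == pytest.approx(1.0)

    def test_balanced_2x2_gives_zero(self):
        res = spearman_association([0, 1, 0, 1], [0, 1, 1, 0])
        assert res.rho == pytest.approx(0.0, abs=1e-15)

    def test_constant_vector_flagged_degenerate(self):
        res = spearman_association([1, 1, 1, 1], [0, 1, 0, 1])
        assert res.degenerate and res.rho is None and res.p_value is None

    def test_length_mismatch_fails(self):
        with pytest.raises(ValueError):
            spearman_association([0, 1, 0], [0, 1])

    def test_too_short_fails(self):
        with pytest.raises(ValueError):
            spearman_association([0, 1], [1, 0])

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(101)
        for _ in range(200):
            n = 200
            if rng.random() < 0.5:
                x = (rng.random(n) < 0.4).astype(float)
                y = (rng.random(n) < 0.4).astype(float)
            else:
                x = rng.integers(0, 5, n).astype(float)
                y = rng.integers(0, 5, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = spearman_association(x, y)
            assert abs(res.rho - rank_then_pearson(x, y)) < 1e-12

    def test_binary_rho_equals_phi(self):
        rng = np.random.default_rng(103)
        for _ in range(100):
            x = (rng.random(150) < 0.3).astype(float)
            y = (rng.random(150) < 0.5).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = spearman_association(x, y)
            assert abs(res.rho - phi_coefficient(x, y)) < 1e-12

    def test_large_n_p_matches_t_approximation(self):
        rng = np.random.default_rng(107)
        x = rng.normal(size=100)
        y = x + rng.normal(size=100)
        res = spearman_association(x, y)
        rho_ref, p_ref = stats.spearmanr(x, y)
        assert res.rho == pytest.approx(rho_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, rel=1e-9)

    def test_small_n_exact_permutation_matches_full_enumeration(self):
        # n = 7 distinct values: 5040 orderings, enumerated exactly; the
        # oracle here walks itertools.permutations directly.
        rng = np.random.default_rng(109)
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        res = spearman_association(x, y)

        obs = abs(rank_then_pearson(x, y))
        hits = total = 0
        for perm in itertools.permutations(y):
            total += 1
            if abs(rank_then_pearson(x, perm)) >= obs - 1e-12:
                hits += 1
        assert res.p_value == pytest.approx(hits / total, abs=1e-12)

    def test_small_n_permutation_with_ties_is_valid_probability(self):
        res = spearman_association([0, 0, 1, 1, 0, 1, 1, 0], [0, 1, 1, 1, 0, 0, 1, 0])
        assert 0 <= res.p_value <= 1


class TestAdjustBH:
    def test_hand_computed_step_up(self):
        assert adjust_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_value_identity(self):
        assert adjust_bh([0.5]) == [0.5]

    def test_matches_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(211)
        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            ours = np.array(adjust_bh(p))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, ref, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(223)
        p = rng.random(50)
        assert (np.array(adjust_bh(p)) >= p - 1e-15).all()


def _sets_from_matrix(mat, codes, year=2024):
    entries = {}
    for i, row in enumerate(mat):
        present = frozenset(c for c, v in zip(codes, row) if v)
        if present:
            entries[(f"P{i}", year)] = present
    return DiagnosisSetTable(entries), len(mat)


class TestPairwiseAssociations:
    def test_pair_count_is_k_choose_2(self):
        rng = np.random.default_rng(301)
        codes = [f"A{i:02d}" for i in range(6)]
        mat = (rng.random((50, 6)) < 0.5).astype(int)
        sets, n = _sets_from_matrix(mat, codes)
        tests = pairwise_associations(sets, codes, n_universe=n)
        assert len(tests) == 15

    def test_perfect_copresence(self):
        entries = {}
        for i in range(10):
            entries[(f"P{i}", 2024)] = frozenset({"A01", "B02"})
        for i in range(10, 20):
            entries[(f"P{i}", 2024)] = frozenset({"C03"})
        tests = pairwise_associations(
            DiagnosisSetTable(entries), ["A01", "B02", "C03"], n_universe=20
        )
        ab = next(t for t in tests if t.pair == ("A01", "B02"))
        assert ab.rho == pytest.approx(1.0)
        assert ab.significant

    def test_degenerate_code_excluded_not_fatal(self):
        entries = {(f"P{i}", 2024): frozenset({"A01"} | ({"B02"} if i % 2 else set()))
                   for i in range(40)}
        tests = pairwise_associations(DiagnosisSetTable(entries), ["A01", "B02", "C03"])
        # A01 present everywhere (constant), C03 absent everywhere (constant)
        degenerate = {t.pair for t in tests if t.degenerate}
        assert ("A01", "B02") in degenerate  # A01 constant among utilizers
        assert ("B02", "C03") in degenerate
        assert all(not t.significant for t in tests if t.degenerate)

    def test_edge_set_invariant_to_test_order(self):
        rng = np.random.default_rng(307)
        codes = [f"A{i:02d}" for i in range(5)]
        mat = (rng.random((200, 5)) < 0.4).astype(int)
        sets, n = _sets_from_matrix(mat, codes)
        tests = pairwise_associations(sets, codes, n_universe=n)
        shuffled = list(tests)
        rng.shuffle(shuffled)
        g1 = build_network(tests)
        g2 = build_network(shuffled)
        assert set(map(frozenset, g1.edges)) == set(map(frozenset, g2.edges))

    def test_too_few_observations_fail(self):
        sets = DiagnosisSetTable({("P1", 2024): frozenset({"A01"})})
        with pytest.raises(ValueError):
            pairwise_associations(sets, ["A01", "B02"])

    def test_bh_null_rarely_discovers(self):
        rng = np.random.default_rng(311)
        zero_free = 0
        reps = 20
        for _ in range(reps):
            mat = (rng.random((300, 15)) < 0.3).astype(int)
            codes = [f"A{i:02d}" for i in range(15)]
            sets, n = _sets_from_matrix(mat, codes)
            tests = pairwise_associations(sets, codes, use_adjusted=True, n_universe=n)
            if not any(t.significant for t in tests):
                zero_free += 1
        assert zero_free >= 0.9 * reps


class TestBuildNetworkAndCentrality:
    def _tests(self, ps, rho=0.5):
        return [
            EdgeTest(f"A{i:02d}", f"B{i:02d}", rho, p, 100,
                     significant=p < 0.05)
            for i, p in enumerate(ps)
        ]

    def test_alpha_threshold_strict(self):
        G = build_network(self._tests([0.01, 0.04, 0.06]), alpha=0.05)
        assert G.number_of_edges() == 2

    def test_empty_network_is_valid(self):
        G = build_network(self._tests([0.5, 0.9]), alpha=0.05)
        assert G.number_of_edges() == 0

    def test_degenerate_tests_never_edges(self):
        tests = [EdgeTest("A01", "B02", None, None, 10, degenerate=True)]
        G = build_network(tests)
        assert G.number_of_edges() == 0

    def test_triangle_centrality(self):
        tests = [
            EdgeTest("A01", "B02", 0.5, 0.01, 100),
            EdgeTest("B02", "C03", -0.5, 0.01, 100),
            EdgeTest("A01", "C03", 0.5, 0.01, 100),
        ]
        cent = node_centrality(build_network(tests))
        assert (cent["degree"] == 2).all()
        assert cent["strength"].tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_star_centrality_and_tiebreak(self):
        tests = [EdgeTest("H00", f"L{i:02d}", 0.4, 0.01, 100) for i in range(4)]
        cent = node_centrality(build_network(tests))
        assert cent.iloc[0]["code"] == "H00"
        assert cent.iloc[0]["degree"] == 4
        leaves = cent.iloc[1:]
        assert (leaves["degree"] == 1).all()
        assert leaves["code"].tolist() == sorted(leaves["code"])


class TestLayoutAndExport:
    def _graph(self):
        tests = [
            EdgeTest("A01", "B02", 0.5, 0.01, 100),
            EdgeTest("B02", "C03", 0.3, 0.02, 100),
        ]
        return build_network(tests)

    def test_layout_deterministic(self):
        G1, G2 = self._graph(), self._graph()
        pos1 = compute_layout(G1, seed=42)
        pos2 = compute_layout(G2, seed=42)
        assert pos1 == pos2

    def test_disconnected_components_no_collisions(self):
        tests = [
            EdgeTest("A01", "B02", 0.5, 0.01, 100),
            EdgeTest("C03", "D04", 0.5, 0.01, 100),
        ]
        G = build_network(tests)
        pos = compute_layout(G, seed=1)
        coords = np.array(list(pos.values()))
        dists = [
            np.linalg.norm(coords[i] - coords[j])
            for i, j in itertools.combinations(range(len(coords)), 2)
        ]
        assert min(dists) > 0

    def test_planted_clusters_separate_in_layout(self):
        codes_a = ["A01", "A02", "A03"]
        codes_b = ["B01", "B02", "B03"]
        prev = {c: 0.3 for c in codes_a + codes_b}
        assocs = tuple(
            AssociationSpec(x, y, 6.0)
            for grp in (codes_a, codes_b)
            for x, y in itertools.combinations(grp, 2)
        )
        cfg = SyntheticCohortConfig(
            n_patients=5000, years=(2024,), prevalence=prev, associations=assocs, seed=9
        )
        ind = sample_disease_indicators(cfg)
        entries = {
            (f"P{i}", 2024): frozenset(ind.columns[ind.iloc[i].astype(bool)])
            for i in range(len(ind))
            if ind.iloc[i].sum()
        }
        tests = pairwise_associations(
            DiagnosisSetTable(entries), codes_a + codes_b, n_universe=5000
        )
        G = build_network(tests)
        pos = compute_layout(G, seed=3)

        def mean_dist(pairs):
            return np.mean(
                [np.linalg.norm(np.subtract(pos[a], pos[b])) for a, b in pairs
                 if a in pos and b in pos]
            )

        intra = mean_dist(
            list(itertools.combinations(codes_a, 2))
            + list(itertools.combinations(codes_b, 2))
        )
        inter = mean_dist(list(itertools.product(codes_a, codes_b)))
        assert intra < inter

    def test_graphml_round_trip(self, tmp_path):
        G = self._graph()
        compute_layout(G, seed=0)
        path = str(tmp_path / "net.graphml")
        export_network(G, path, fmt="graphml")
        back = import_network(path, fmt="graphml")
        assert set(back.nodes) == set(G.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, G.edges))
        for a, b in G.edges:
            assert back[a][b]["weight"] == G[a][b]["weight"]

    def test_edge_list_round_trip_and_line_count(self, tmp_path):
        G = self._graph()
        path = tmp_path / "edges.csv"
        export_network(G, str(path), fmt="edge-list")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == G.number_of_edges() + 1
        back = import_network(str(path), fmt="edge-list")
        assert set(map(frozenset, back.edges)) == set(map(frozenset, G.edges))

    def test_empty_network_exports(self, tmp_path):
        G = build_network([])
        path = str(tmp_path / "empty.csv")
        export_network(G, path, fmt="edge-list")
        back = import_network(path, fmt="edge-list")
        assert back.number_of_edges() == 0

    def test_unknown_format_fails(self, tmp_path):
        with pytest.raises(ValueError):
            export_network(self._graph(), str(tmp_path / "x"), fmt="dot")
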