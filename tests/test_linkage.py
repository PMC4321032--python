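import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cavemap import linkage as lk
from oracles import grid_search_rf


class TestKosambi:
    def test_closed_forms(self):
        assert lk.kosambi_cM(0.0) == 0.0
        assert lk.kosambi_cM(0.25) == pytest.approx(25 * np.log(3), abs=1e-12)
        assert lk.kosambi_inverse(0.0) == 0.0
        assert lk.kosambi_inverse(25 * np.log(3)) == pytest.approx(0.25, abs=1e-12)

    def test_inverse_monotone_bounded(self):
        d = np.linspace(0, 300, 500)
        r = lk.kosambi_inverse(d)
        assert (np.diff(r) > 0).all()
        assert r.max() < 0.5
        assert lk.kosambi_inverse(1e9) <= 0.5

    @given(st.floats(0.01, 0.49))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, r):
        assert lk.kosambi_inverse(lk.kosambi_cM(r)) == pytest.approx(r, abs=1e-12)

    def test_r_at_half_raises_unless_capped(self):
        with pytest.raises(ValueError):
            lk.kosambi_cM(0.5)
        assert lk.kosambi_cM(0.5, cap=100.0) == 100.0


class TestTwoPointEM:
    def test_identical_vectors_give_zero_rf(self):
        codes = np.array([0, 1, 2] * 20)
        pl = lk.estimate_rf_em(codes, codes)
        assert pl.rf_hat == pytest.approx(0.0, abs=1e-6)
        assert pl.linkage_lod > 10

    def test_unlinked_markers_near_half(self):
        rng = np.random.default_rng(0)
        n = 10_000
        a = rng.choice(3, size=n, p=[0.25, 0.5, 0.25])
        b = rng.choice(3, size=n, p=[0.25, 0.5, 0.25])
        pl = lk.estimate_rf_em(a, b)
        se = np.sqrt(0.25 / n)  # crude binomial scale
        assert abs(pl.rf_hat - 0.5) < 5 * se + 0.01
        assert pl.independence_lod < 2.0

    def test_missing_dropped_and_few_pairs_error(self):
        a = np.array([0, 1, -1, -1])
        b = np.array([-1, 1, 2, -1])
        with pytest.raises(ValueError):
            lk.estimate_rf_em(a, b)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            table = rng.integers(0, 30, size=(3, 3)).astype(float)
            if table.sum() < 2:
                continue
            r_em = float(lk.em_rf(table))
            r_grid = grid_search_rf(table)
            assert abs(r_em - r_grid) <= 1e-3

    def test_em_loglik_nondecreasing(self):
        rng = np.random.default_rng(3)
        table = rng.integers(0, 40, size=(3, 3)).astype(float)
        r = 0.25
        lls = []
        for _ in range(30):
            lls.append(lk.loglik_rf(r, table))
            n0 = table[0, 0] + table[2, 2]
            n2 = table[0, 2] + table[2, 0]
            n1 = table[0, 1] + table[1, 0] + table[1, 2] + table[2, 1]
            nh = table[1, 1]
            w = r**2 / (r**2 + (1 - r) ** 2)
            r = (n1 + 2 * n2 + 2 * nh * w) / (2 * table.sum())
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_pairwise_matrix_matches_single_pairs(self):
        rng = np.random.default_rng(1)
        codes = rng.choice([0, 1, 2, -1], size=(6, 80), p=[0.24, 0.5, 0.24, 0.02])
        rf, lod, ind, _ = lk.pairwise_linkage_matrix(codes)
        for i, j in itertools.combinations(range(6), 2):
            pl = lk.estimate_rf_em(codes[i], codes[j])
            assert rf[i, j] == pytest.approx(pl.rf_hat, abs=1e-9)
            assert lod[i, j] == pytest.approx(pl.linkage_lod, abs=1e-6)
            assert ind[i, j] == pytest.approx(pl.independence_lod, abs=1e-6)
            assert rf[i, j] == rf[j, i]


class TestGrouping:
    def test_threshold_above_everything_gives_singletons(self):
        rng = np.random.default_rng(2)
        codes = rng.choice(3, size=(5, 50))
        _, _, ind, _ = lk.pairwise_linkage_matrix(codes)
        groups = lk.group_markers(ind, threshold=ind.max() + 1)
        assert len(groups) == 5

    def test_duplicate_markers_one_group(self):
        codes = np.tile(np.array([0, 1, 2] * 20), (4, 1))
        _, _, ind, _ = lk.pairwise_linkage_matrix(codes)
        groups = lk.group_markers(ind, threshold=5)
        assert len(groups) == 1

    def test_threshold_monotonicity(self, small_map):
        _, _, _, codes = small_map
        _, _, ind, _ = lk.pairwise_linkage_matrix(codes)
        previous = None
        for t in range(1, 30, 3):
            groups = lk.group_markers(ind, t)
            sizes = sorted(len(g) for g in groups)
            if previous is not None:
                assert len(groups) >= previous  # raising never merges
            previous = len(groups)

    def test_partition(self, small_map):
        _, _, ids, codes = small_map
        _, _, ind, _ = lk.pairwise_linkage_matrix(codes)
        groups = lk.group_markers(ind, 8)
        flat = [m for g in groups for m in g]
        assert sorted(flat) == list(range(len(ids)))


class TestOrdering:
    def test_two_markers_length_is_kosambi(self):
        rng = np.random.default_rng(5)
        # simulate a linked pair directly from the two-locus distribution
        r = 0.2
        q = 1 - r
        probs = np.array([q*q/4, r*q/2, r*r/4, r*q/2, (r*r+q*q)/2, r*q/2,
                          r*r/4, r*q/2, q*q/4])
        cells = rng.choice(9, size=400, p=probs)
        codes = np.stack([cells // 3, cells % 3])
        rf, lod, ind, _ = lk.pairwise_linkage_matrix(codes)
        group = lk.order_group(["m1", "m2"], [0, 1], rf, lod)
        assert group.length_cM == pytest.approx(float(lk.kosambi_cM(rf[0, 1])))

    def test_three_marker_order_matches_exhaustive_search(self):
        # pairwise rf (0.10, 0.10, 0.18): the marker sharing both 0.10
        # fractions belongs in the middle
        rf = np.array([[0.0, 0.10, 0.18],
                       [0.10, 0.0, 0.10],
                       [0.18, 0.10, 0.0]])
        lod = np.where(np.eye(3, dtype=bool), 0.0, 20.0)
        group = lk.order_group(["mA", "mB", "mC"], [0, 1, 2], rf, lod)
        assert group.markers[1] == "mB"
        # exhaustive check over the 3 distinct orders
        scores = {}
        for perm in [(0, 1, 2), (0, 2, 1), (1, 0, 2)]:
            scores[perm] = lk._order_criterion(list(perm), rf, lod)
        assert min(scores, key=scores.get) == (0, 1, 2)

    def test_reversal_invariance_and_canonical_orientation(self):
        rf = np.array([[0.0, 0.05, 0.15],
                       [0.05, 0.0, 0.08],
                       [0.15, 0.08, 0.0]])
        lod = np.where(np.eye(3, dtype=bool), 0.0, 15.0)
        fwd = lk._order_criterion([0, 1, 2], rf, lod)
        rev = lk._order_criterion([2, 1, 0], rf, lod)
        assert fwd == pytest.approx(rev)
        group = lk.order_group(["mZ", "mM", "mA"], [0, 1, 2], rf, lod)
        assert group.markers[0] < group.markers[-1]

    def test_simulated_chromosome_order_recovery(self):
        from cavemap.marker_qc import codes_matrix, retained, screen_and_code
        from cavemap.simcross import SimConfig, simulate_cross
        from scipy.stats import kendalltau

        config = SimConfig(n_chromosomes=1, markers_per_chromosome=20,
                           chrom_length_cM=60.0, n_f2=170, error_rate=0.005,
                           missing_rate=0.02, seed=13)
        truemap, panelset, _ = simulate_cross(config)
        coded, _ = screen_and_code(panelset)
        ids, codes = codes_matrix(retained(coded))
        rf, lod, ind, _ = lk.pairwise_linkage_matrix(codes)
        group = lk.order_group(ids, list(range(len(ids))), rf, lod)
        true_pos = [truemap.markers.at[m, "pos_cM"] for m in group.markers]
        tau, _ = kendalltau(true_pos, group.positions)
        assert abs(tau) >= 0.9
        true_len = truemap.markers.pos_cM.max()
        assert group.length_cM == pytest.approx(true_len, rel=0.25)


class TestSplitTrim:
    def test_split_recovers_planted_fusion(self):
        from cavemap.marker_qc import codes_matrix, retained, screen_and_code
        from cavemap.simcross import SimConfig, simulate_cross

        config = SimConfig(n_chromosomes=2, markers_per_chromosome=15,
                           chrom_length_cM=50.0, n_f2=170, seed=21)
        truemap, panelset, _ = simulate_cross(config)
        coded, _ = screen_and_code(panelset)
        ids, codes = codes_matrix(retained(coded))
        _, _, ind, _ = lk.pairwise_linkage_matrix(codes)
        # plant a spurious bridge between the two chromosomes
        bridge = ind.copy()
        bridge[0, 29] = bridge[29, 0] = 12.0
        fused = lk.group_markers(bridge, 8)[0]
        assert len(fused) == 30
        parts, t, did = lk.split_group(list(fused), bridge, min_markers=10)
        assert did
        chroms = [{truemap.chromosome_of(ids[i]) for i in p} for p in parts]
        assert chroms[0] != chroms[1]
        assert all(len(c) == 1 for c in chroms)

    def test_split_nested_min_markers(self):
        rng = np.random.default_rng(0)
        # any split valid at min 20 is also valid at min 10
        ind = rng.uniform(0, 5, size=(50, 50))
        ind = (ind + ind.T) / 2
        for i in range(49):
            ind[i, i + 1] = ind[i + 1, i] = 30.0
        members = list(range(50))
        _, _, did20 = lk.split_group(members, ind, 20)
        _, _, did10 = lk.split_group(members, ind, 10)
        if did20:
            assert did10

    def test_uniform_group_unchanged_with_flag(self):
        codes = np.tile([0, 1, 2], (12, 30))
        _, _, ind, _ = lk.pairwise_linkage_matrix(codes)
        parts, t, did = lk.split_group(list(range(12)), ind, min_markers=5)
        assert not did
        assert len(parts) == 1

    def test_trim_uniform_unchanged(self):
        g = lk.LinkageGroup("g", [f"m{i}" for i in range(10)],
                            np.arange(10, dtype=float))
        trimmed, removed = lk.trim_distal(g)
        assert removed == []
        assert trimmed.markers == g.markers

    def test_trim_removes_distal_outlier(self):
        pos = np.concatenate([np.arange(10, dtype=float), [49.0]])
        g = lk.LinkageGroup("g", [f"m{i}" for i in range(11)], pos)
        trimmed, removed = lk.trim_distal(g)
        assert removed == ["m10"]
        assert trimmed.length_cM == pytest.approx(9.0)

    def test_trim_idempotent(self):
        rng = np.random.default_rng(6)
        pos = np.sort(rng.uniform(0, 80, size=25))
        pos[0] = 0.0
        g = lk.LinkageGroup("g", [f"m{i}" for i in range(25)], pos - pos[0])
        once, _ = lk.trim_distal(g)
        twice, removed = lk.trim_distal(once)
        assert removed == []
        assert once.markers == twice.markers


class TestBuildMapAndSummary:
    def test_groups_match_truth(self, small_cross, small_map):
        _, truemap, _, _ = small_cross
        gmap, audit, ids, _ = small_map
        assert len(gmap.groups) == 3
        for g in gmap.groups:
            chroms = {truemap.chromosome_of(m) for m in g.markers}
            assert len(chroms) == 1

    def test_audit_conservation(self, small_map):
        gmap, audit, ids, _ = small_map
        final = audit[-1]
        assert final["placed"] + final["eliminated"] == len(ids)

    def test_summary_values(self):
        g1 = lk.LinkageGroup("LG1", [f"m{i}" for i in range(2)],
                             np.array([0.0, 10.0]))
        assert g1.mean_intermarker_cM == pytest.approx(10.0)
        assert lk.mean_intermarker(52, 67.061) == pytest.approx(1.315, abs=5e-4)
        assert lk.marker_density(2235, 2110.7) == pytest.approx(1.06)
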