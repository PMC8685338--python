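import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surfreho.mesh import CortexMask, icosphere, vertex_areas
from surfreho.reho import SurfaceScalarMap
from surfreho.stats import (bh_fdr, chi_square_2x2, correlate_clusters,
                            demographics_table, extract_clusters,
                            global_group_test, partial_spearman, two_sample_t,
                            vertexwise_group_test)
from surfreho.synthetic import SubjectRecord


def brute_force_bh(p, q):
    """Exhaustive-threshold oracle: try every candidate rejection count."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p, kind="stable")
    best_k = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            best_k = k
    flags = np.zeros(m, dtype=bool)
    flags[order[:best_k]] = True
    return flags


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p, _ = two_sample_t([1.0, 2, 3], [1.0, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed(self):
        # s_p = 1, se = sqrt(2/3), t = -3 / 0.8165 = -3.674, df = 4
        t, p, df = two_sample_t([1.0, 2, 3], [4.0, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == 4

    def test_antisymmetry(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(12) + 1
        t1, p1, _ = two_sample_t(a, b)
        t2, p2, _ = two_sample_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_welch(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(40) * 5
        t, p, df = two_sample_t(a, b, variance="welch")
        assert df != 48

    def test_degenerate(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


class TestBhFdr:
    def test_all_ones(self):
        assert not bh_fdr([1.0, 1.0, 1.0], 0.05).any()

    def test_single_small_p(self):
        assert bh_fdr([0.04], 0.05).all()

    def test_step_up_rule(self):
        flags = bh_fdr([0.01, 0.02, 0.03, 0.04], 0.05)
        assert flags.all()

    def test_empty(self):
        assert bh_fdr([], 0.05).size == 0

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5], 0.05)

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            m = rng.integers(1, 51)
            p = rng.uniform(0, 1, m)
            if rng.random() < 0.3:  # inject some signal and ties
                p[: m // 2] = rng.uniform(0, 0.05, m // 2)
                p = np.round(p, 2)
            q = rng.choice([0.01, 0.05, 0.1, 0.2])
            np.testing.assert_array_equal(bh_fdr(p, q), brute_force_bh(p, q))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
           st.sampled_from([0.01, 0.05, 0.2, 0.99]))
    @settings(max_examples=100, deadline=None)
    def test_property_matches_oracle(self, pvals, q):
        np.testing.assert_array_equal(
            bh_fdr(pvals, q), brute_force_bh(pvals, q)
        )

    def test_fdp_controlled_on_null(self):
        """Empirical FDR on independent null p-values stays below q."""
        rng = np.random.default_rng(11)
        q = 0.1
        fdps = []
        for _ in range(500):
            p = rng.uniform(0, 1, 100)
            rej = bh_fdr(p, q)
            fdps.append(rej.sum() > 0)
        # under the global null FDR = P(any rejection) <= q
        assert np.mean(fdps) <= q + 3 * np.sqrt(q * (1 - q) / 500)


def _maps_from_array(arr, mesh, keep=None):
    mask = CortexMask(keep if keep is not None
                      else np.ones(mesh.n_vertices, dtype=bool))
    return [SurfaceScalarMap(row, mesh, mask) for row in arr]


class TestVertexwiseGroupTest:
    def test_rejects_planted_shift(self, ico1, rng):
        v = ico1.n_vertices
        a = rng.standard_normal((10, v))
        b = rng.standard_normal((10, v))
        a[:, :5] += 4.0
        res = vertexwise_group_test(_maps_from_array(a, ico1),
                                    _maps_from_array(b, ico1), q=0.05)
        assert res.significant[:5].all()
        assert res.df == 18
        assert np.nanmin(res.p_map.values) >= 0
        assert np.nanmax(res.p_map.values) <= 1

    def test_extreme_q(self, ico1, rng):
        v = ico1.n_vertices
        a = rng.standard_normal((5, v))
        b = rng.standard_normal((5, v))
        res_hi = vertexwise_group_test(_maps_from_array(a, ico1),
                                       _maps_from_array(b, ico1), q=1.0)
        assert res_hi.significant.sum() == v  # q=1 rejects everything with p <= 1
        res_lo = vertexwise_group_test(_maps_from_array(a, ico1),
                                       _maps_from_array(b, ico1), q=1e-12)
        assert not res_lo.significant.any()

    def test_mask_mismatch(self, ico1, rng):
        v = ico1.n_vertices
        keep1 = np.ones(v, dtype=bool)
        keep2 = keep1.copy()
        keep2[0] = False
        a = _maps_from_array(rng.standard_normal((2, v)), ico1, keep1)
        b = _maps_from_array(rng.standard_normal((2, v)), ico1, keep2)
        with pytest.raises(ValueError):
            vertexwise_group_test(a, b)

    def test_needs_two_per_group(self, ico1, rng):
        maps = _maps_from_array(rng.standard_normal((3, ico1.n_vertices)), ico1)
        with pytest.raises(ValueError):
            vertexwise_group_test(maps[:1], maps[1:])


class TestExtractClusters:
    def _result(self, mesh, t_values, significant):
        mask = CortexMask.full(mesh.n_vertices)
        from surfreho.stats import GroupComparisonResult

        return GroupComparisonResult(
            t_map=SurfaceScalarMap(t_values, mesh, mask),
            p_map=SurfaceScalarMap(np.full(mesh.n_vertices, 0.5), mesh, mask),
            q=0.05, significant=significant, df=10.0,
        )

    def test_empty_mask(self, ico1):
        res = self._result(ico1, np.zeros(ico1.n_vertices),
                           np.zeros(ico1.n_vertices, dtype=bool))
        assert len(extract_clusters(res, ico1)) == 0

    def test_two_opposite_patches(self, ico2):
        from surfreho.mesh import kring_neighbors

        t = np.zeros(ico2.n_vertices)
        pos = np.array(sorted({0} | kring_neighbors(ico2, 0, 1)))
        neg_seed = 100
        neg = np.array(sorted({neg_seed} | kring_neighbors(ico2, neg_seed, 1)))
        t[pos] = np.linspace(3, 5, len(pos))
        t[neg] = -np.linspace(3, 6, len(neg))
        sig = t != 0
        table = extract_clusters(self._result(ico2, t, sig), ico2)
        assert len(table) == 2
        signs = {r["sign"] for r in table.rows}
        assert signs == {"+", "-"}
        for r in table.rows:
            members = np.array(r["members"])
            assert abs(r["peak_t"]) == np.max(np.abs(t[members]))

    def test_area_conservation(self, ico2, rng):
        t = rng.standard_normal(ico2.n_vertices)
        sig = np.abs(t) > 1.0
        areas = vertex_areas(ico2)
        table = extract_clusters(self._result(ico2, t, sig), ico2, areas)
        total = sum(r["area_mm2"] for r in table.rows)
        assert total == pytest.approx(areas[sig].sum())
        assert sum(r["n_vertices"] for r in table.rows) == sig.sum()

    def test_relabeling_invariance(self, ico1, rng):
        """Same partition and peaks under a vertex permutation."""
        t = rng.standard_normal(ico1.n_vertices)
        sig = np.abs(t) > 0.8
        if not sig.any():
            pytest.skip("no significant vertices in draw")
        table = extract_clusters(self._result(ico1, t, sig), ico1)

        perm = rng.permutation(ico1.n_vertices)
        inv = np.argsort(perm)
        from surfreho.mesh import TriangleMesh

        mesh_p = TriangleMesh(ico1.vertices[perm], inv[ico1.triangles])
        table_p = extract_clusters(
            self._result(mesh_p, t[perm], sig[perm]), mesh_p
        )
        orig = sorted(frozenset(r["members"]) for r in table.rows)
        relab = sorted(frozenset(int(perm[v]) for v in r["members"])
                       for r in table_p.rows)
        assert orig == relab

    def test_frame_index_base(self, ico1, rng):
        t = rng.standard_normal(ico1.n_vertices)
        sig = np.abs(t) > 1.0
        table = extract_clusters(self._result(ico1, t, sig), ico1)
        f0 = table.to_frame(index_base=0)
        f1 = table.to_frame(index_base=1)
        if len(f0):
            assert (f1["peak_vertex"] - f0["peak_vertex"] == 1).all()


class TestGlobalGroupTest:
    def test_identical(self):
        t, p = global_group_test([1.0, 2, 3], [1.0, 2, 3])
        assert t == pytest.approx(0.0)

    def test_equals_two_sample_t(self, rng):
        a = rng.standard_normal(20)
        b = rng.standard_normal(25)
        t1, p1 = global_group_test(a, b)
        t2, p2, _ = two_sample_t(a, b)
        assert (t1, p1) == (t2, p2)


class TestPartialSpearman:
    def test_monotone_no_covariates(self):
        x = np.arange(10.0)
        y = np.exp(x)
        r, p = partial_spearman(x, y)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-6)

    def test_covariate_driven_y(self, rng):
        """y a linear function of the covariate, x independent: r near 0."""
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            g = np.random.default_rng(seed)
            c = g.standard_normal(100)
            y = 2.0 * c + 1.0
            x = g.standard_normal(100)
            r, _ = partial_spearman(x, y + 1e-9 * g.standard_normal(100), c)
            hits += abs(r) < 0.2
        assert hits >= 0.9 * n_seeds  # nominal rate is ~95% of seeds

    def test_constant_residual_flagged(self):
        x = np.ones(10)
        y = np.arange(10.0)
        r, p = partial_spearman(x, y)
        assert np.isnan(r) and np.isnan(p)

    def test_n_too_small(self):
        with pytest.raises(ValueError):
            partial_spearman([1.0, 2, 3], [1.0, 2, 3], np.ones((3, 2)))


def _patients(n, rng, durations=None):
    recs = []
    for i in range(n):
        recs.append(SubjectRecord(
            f"p{i}", "SZ", age=float(rng.uniform(20, 60)),
            sex="F" if rng.random() < 0.3 else "M",
            illness_duration=float(durations[i] if durations is not None
                                   else rng.uniform(0, 30)),
            panss_positive=float(rng.uniform(7, 30)),
            panss_negative=float(rng.uniform(7, 30)),
            panss_general=float(rng.uniform(16, 50)),
            panss_total=float(rng.uniform(110, 120)),
        ))
    return recs


class TestCorrelateClusters:
    def test_constant_variable_not_significant(self, rng):
        recs = _patients(20, rng, durations=np.full(20, 5.0))
        means = pd.DataFrame({"r0": rng.standard_normal(20)})
        res = correlate_clusters(means, recs, ["illness_duration"])
        assert len(res) == 1
        assert not res[0].valid or res[0].p > 0.05

    def test_family_size(self, rng):
        recs = _patients(30, rng)
        means = pd.DataFrame({f"r{i}": rng.standard_normal(30) for i in range(4)})
        res = correlate_clusters(
            means, recs, ["illness_duration", "panss_positive"])
        assert len(res) == 4 * 2
        assert all(r.q is not None for r in res if r.valid)

    def test_planted_coupling_is_top_result(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            g = np.random.default_rng(seed)
            dur = g.uniform(0, 30, 40)
            recs = _patients(40, g, durations=dur)
            means = {f"r{i}": g.standard_normal(40) for i in range(8)}
            means["r3"] = dur + g.standard_normal(40) * 12.0  # planted link
            res = correlate_clusters(pd.DataFrame(means), recs,
                                     ["illness_duration", "panss_positive",
                                      "panss_negative"])
            top = max((r for r in res if r.valid), key=lambda r: abs(r.r))
            hits += (top.region_id == "r3" and top.variable == "illness_duration")
        assert hits >= 8

    def test_row_mismatch(self, rng):
        recs = _patients(5, rng)
        means = pd.DataFrame({"r0": rng.standard_normal(4)})
        with pytest.raises(ValueError):
            correlate_clusters(means, recs, ["illness_duration"])


class TestDemographics:
    def test_cohort_gender_chi_square(self):
        """Post-exclusion sex counts (65/28 vs 84/41) give chi-square p = 0.67."""
        chi2, p = chi_square_2x2(np.array([[65, 28], [84, 41]]))
        assert p == pytest.approx(0.67, abs=0.005)

    def test_chi_square_matches_hand_formula(self, rng):
        for _ in range(20):
            table = rng.integers(5, 100, size=(2, 2)).astype(float)
            chi2, _ = chi_square_2x2(table)
            row = table.sum(axis=1, keepdims=True)
            col = table.sum(axis=0, keepdims=True)
            expected = row @ col / table.sum()
            hand = np.sum((table - expected) ** 2 / expected)
            assert chi2 == pytest.approx(hand)

    def test_identical_groups_p_one(self, rng):
        recs = []
        for grp in ("SZ", "HC"):
            for i in range(10):
                recs.append(SubjectRecord(f"{grp}{i}", grp, age=30.0 + i,
                                          sex="M" if i % 2 else "F"))
        df = demographics_table(recs)
        age_row = df[df["variable"] == "age"].iloc[0]
        assert age_row["p"] == pytest.approx(1.0)
        sex_row = df[df["variable"] == "sex (M/F)"].iloc[0]
        assert sex_row["p"] == pytest.approx(1.0)

    def test_requires_two_groups(self, rng):
        recs = _patients(5, rng)
        with pytest.raises(ValueError):
            demographics_table(recs)
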