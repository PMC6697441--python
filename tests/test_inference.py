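"""Hypothesis-test battery: LRTs, PERMANOVA, Mantel, precision, CV tests."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microrepeat.counts import CountTable, StudyDesign
from microrepeat.inference import (bh_fdr, centroid_distances,
                                   feltz_miller_cv_test, levene_median,
                                   lmm_lrt_alpha, mantel, nested_permanova,
                                   permanova, pln_taxon_tests)
from microrepeat.simulate import SimulationConfig, simulate_dataset


def euclid(points):
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.shape[0] == 1:
        pts = pts.T
    return np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))


# --------------------------------------------------------------------------
# mixed-model LRTs
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def design():
    cfg = SimulationConfig(n_taxa=5, library_depth=100, seed=0)
    return simulate_dataset(cfg).design


class TestLmmLrt:

    def test_df_conventions(self, design):
        """protocol tests on 2 df, population on 1, interaction on 2."""
        rng = np.random.default_rng(1)
        vals = rng.normal(size=108)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert lmm_lrt_alpha(vals, design, "protocol").df == 2
            assert lmm_lrt_alpha(vals, design, "population").df == 1
            assert lmm_lrt_alpha(vals, design, "interaction").df == 2

    def test_zero_effect_column_gives_null_statistic(self, design):
        """Response built without any interaction effect: the interaction
        LRT statistic is ~0 for data that the reduced model fits exactly."""
        rng = np.random.default_rng(2)
        tab = design.table
        # pure fish-level signal, no fixed effects at all
        fish_eff = dict(zip(tab.fish_id.unique(),
                            rng.normal(0, 1, tab.fish_id.nunique())))
        vals = tab.fish_id.map(fish_eff).to_numpy() + rng.normal(0, .2, 108)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tr = lmm_lrt_alpha(vals, design, "interaction")
        assert tr.statistic < stats.chi2.ppf(0.999, 2)
        assert tr.p_value > 0.001

    def test_detects_strong_protocol_effect(self, design):
        rng = np.random.default_rng(3)
        tab = design.table
        vals = rng.normal(0, 0.5, 108) + np.where(tab.protocol == "DEP", 3.0, 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tr = lmm_lrt_alpha(vals, design, "protocol")
        assert tr.p_value < 1e-6

    def test_invalid_effect(self, design):
        with pytest.raises(ValueError):
            lmm_lrt_alpha(np.zeros(108), design, "tank")


# --------------------------------------------------------------------------
# BH-FDR
# --------------------------------------------------------------------------

class TestBhFdr:
    def test_single_p_unchanged(self):
        adj, rej = bh_fdr([0.03], q=0.1)
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_step_up_hand_trace(self):
        adj, rej = bh_fdr([0.01, 0.02, 0.04, 0.8], q=0.1)
        assert list(rej) == [True, True, True, False]

    def test_all_ones_rejected_nothing(self):
        adj, rej = bh_fdr([1.0, 1.0, 1.0], q=0.1)
        assert not rej.any()

    def test_matches_brute_force_threshold_search(self):
        """BH rejection set equals max-k threshold search on random vectors."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            m = rng.integers(1, 13)
            p = np.round(rng.uniform(0, 1, m), 3)
            q = 0.1
            _, rej = bh_fdr(p, q)
            order = np.argsort(p)
            ks = [k for k in range(1, m + 1) if p[order[k - 1]] <= q * k / m]
            kmax = max(ks) if ks else 0
            brute = np.zeros(m, bool)
            brute[order[:kmax]] = True
            assert (rej == brute).all()

    def test_adjusted_monotone(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=20)
        adj, _ = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


# --------------------------------------------------------------------------
# PERMANOVA
# --------------------------------------------------------------------------

class TestPermanova:
    def test_equals_classical_anova_on_scalar_euclidean(self):
        """One factor, Euclidean distances of scalar data: pseudo-F equals
        the classical one-way ANOVA F to 1e-10."""
        rng = np.random.default_rng(4)
        for _ in range(10):
            k = rng.integers(2, 5)
            ns = rng.integers(3, 6, k)
            g = np.repeat([f"g{i}" for i in range(k)], ns)
            v = rng.normal(size=len(g))
            D = euclid(v)
            design = pd.DataFrame({"grp": g})
            res = permanova(D, design, ["grp"], n_perm=19, seed=0)
            F_classic = stats.f_oneway(*(v[g == l] for l in np.unique(g)))[0]
            assert res[0].statistic == pytest.approx(F_classic, abs=1e-10)

    def test_identical_points_degenerate(self):
        D = np.zeros((8, 8))
        design = pd.DataFrame({"grp": list("aabbccdd")})
        res = permanova(D, design, ["grp"], n_perm=49, seed=1)
        assert res[0].p_value == 1.0

    def test_permutation_p_lower_bound(self):
        rng = np.random.default_rng(5)
        v = np.array([10.0, 11, 12, 0, 1, 2])  # huge group separation
        D = euclid(v)
        design = pd.DataFrame({"grp": list("aaabbb")})
        for n_perm in (9, 99):
            res = permanova(D, design, ["grp"], n_perm=n_perm, seed=2)
            assert res[0].p_value >= 1.0 / (n_perm + 1) - 1e-12

    def test_stratified_permutation_respects_blocks(self, small_sim):
        """With strata = fish, protocol labels only move within fish."""
        table, design, _ = small_sim
        rng = np.random.default_rng(6)
        n = table.n_libraries
        v = rng.normal(size=n)
        D = euclid(v)
        res = permanova(D, design.table, ["protocol"], strata="fish_id",
                        n_perm=49, seed=3)
        assert res[0].n_permutations == 49
        assert 0 < res[0].p_value <= 1

    def test_factorial_with_interaction_terms(self, small_sim):
        table, design, _ = small_sim
        rng = np.random.default_rng(7)
        v = rng.normal(size=table.n_libraries)
        D = euclid(v)
        res = permanova(D, design.table, ["protocol", "family_id"],
                        interactions=[("protocol", "family_id")],
                        n_perm=19, seed=4)
        names = [t.method for t in res]
        assert names == ["permanova[protocol]", "permanova[family_id]",
                         "permanova[protocol:family_id]"]
        ss_terms = sum(t.auxiliary["ss"] for t in res) + res[0].auxiliary["ss_res"]
        # sequential SS partition is exhaustive: terms + residual = total
        G = D**2
        n = len(v)
        ss_total = G[np.triu_indices(n, 1)].sum() / n
        assert ss_terms == pytest.approx(ss_total, rel=1e-9)


class TestNestedPermanova:
    def _sim(self, shift, seed):
        rng = np.random.default_rng(seed)
        fams = [f"f{i}" for i in range(6)]
        pops = ["p1"] * 3 + ["p2"] * 3
        rows, vals = [], []
        for fam, pop in zip(fams, pops):
            fam_eff = rng.normal(0, 0.5) + (shift if pop == "p2" else 0)
            for i in range(4):
                rows.append({"family_id": fam, "population": pop})
                vals.append(fam_eff + rng.normal(0, 0.3))
        return pd.DataFrame(rows), np.asarray(vals)

    def test_power_for_population_shift(self):
        hits = 0
        for seed in range(10):
            design, vals = self._sim(3.0, seed)
            tr = nested_permanova(euclid(vals), design, n_perm=199, seed=seed)
            hits += tr.p_value <= 0.11
        assert hits >= 8

    def test_discrete_floor_with_six_families(self):
        """3+3 families admit C(6,3) = 20 whole-family relabelings; the
        permutation p cannot go below ~1/20 and the floor is reported."""
        design, vals = self._sim(5.0, 0)
        tr = nested_permanova(euclid(vals), design, n_perm=1999, seed=1)
        assert tr.auxiliary["distinct_relabelings"] == 20
        assert tr.p_value >= 1.0 / 20.0 - 0.02

    def test_null_p_roughly_uniform(self):
        ps = []
        for seed in range(20):
            design, vals = self._sim(0.0, 100 + seed)
            ps.append(nested_permanova(euclid(vals), design, n_perm=99,
                                       seed=seed).p_value)
        assert 0.2 < np.mean(ps) < 0.8

    def test_single_family_per_population_impossible(self):
        design = pd.DataFrame({"family_id": list("aabb"),
                               "population": list("ppqq")})
        with pytest.raises(ValueError):
            nested_permanova(np.zeros((4, 4)), design)


class TestMantel:
    def test_identity_correlation_one(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=8)
        D = euclid(v)
        tr = mantel(D, D.copy(), n_perm=99, seed=0)
        assert tr.statistic == pytest.approx(1.0)
        assert tr.p_value <= 0.05

    def test_linear_rescaling_invariance(self):
        rng = np.random.default_rng(9)
        A = euclid(rng.normal(size=7))
        B = euclid(rng.normal(size=7))
        r1 = mantel(A, B, n_perm=9, seed=1).statistic
        r2 = mantel(A, 3.5 * B + 0.0, n_perm=9, seed=1).statistic
        assert r1 == pytest.approx(r2)

    def test_null_p_uniformish(self):
        rng = np.random.default_rng(10)
        ps = []
        for _ in range(60):
            A = euclid(rng.normal(size=8))
            B = euclid(rng.normal(size=8))
            ps.append(mantel(A, B, n_perm=49, seed=0).p_value)
        # under independence p should not pile up near 0
        assert (np.array(ps) <= 0.05).mean() < 0.15
        assert 0.3 < np.mean(ps) < 0.75

    def test_cross_check_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import mantel as sk_mantel
        rng = np.random.default_rng(11)
        A = euclid(rng.normal(size=9))
        B = euclid(rng.normal(size=9))
        r_mine = mantel(A, B, n_perm=9, seed=0).statistic
        r_sk, _, _ = sk_mantel(SkDM(A), SkDM(B), permutations=0)
        assert r_mine == pytest.approx(r_sk)


# --------------------------------------------------------------------------
# precision tests
# --------------------------------------------------------------------------

class TestLeveneMedian:
    def test_all_zero_deviations_degenerate(self):
        vals = np.repeat([3.0, 8.0], 3)
        fish = np.repeat(["f1", "f2"], 3)
        proto = np.tile(["a", "b", "c"], 2)
        tr = levene_median(vals, fish, proto)
        assert tr.p_value == 1.0
        assert tr.auxiliary.get("degenerate")

    def test_hand_computed_toy(self):
        # 2 fish x 3 protocols: deviations from fish medians, then one-way F
        vals = np.array([1.0, 2.0, 4.0, 10.0, 12.0, 11.0])
        fish = np.array(["f1"] * 3 + ["f2"] * 3)
        proto = np.array(["a", "b", "c", "a", "b", "c"])
        dev = np.abs(vals - np.array([2.0, 2, 2, 11, 11, 11]))
        F_expected = stats.f_oneway(dev[[0, 3]], dev[[1, 4]], dev[[2, 5]])[0]
        tr = levene_median(vals, fish, proto)
        assert tr.statistic == pytest.approx(F_expected)

    def test_type_i_error_calibrated(self):
        """Equal spread across protocols: rejection rate ~ 5%."""
        rng = np.random.default_rng(12)
        rej = 0
        reps = 500
        for _ in range(reps):
            fish = np.repeat([f"f{i}" for i in range(6)], 6)
            proto = np.repeat(["a", "b", "c"], 12)
            vals = rng.normal(0, 1, 36) + np.repeat(rng.normal(0, 2, 6), 6)
            rej += levene_median(vals, fish, proto).p_value < 0.05
        assert 0.02 < rej / reps < 0.09


class TestCentroidDistances:
    def test_euclidean_geometry_oracle(self):
        """PCoA centroid distances equal direct point-to-centroid distances
        for Euclidean input."""
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(12, 2))
        groups = np.repeat(list("abc"), 4)
        D = euclid(pts)
        got = centroid_distances(D, groups)
        for g in "abc":
            m = groups == g
            cent = pts[m].mean(axis=0)
            expected = np.sqrt(((pts[m] - cent) ** 2).sum(1))
            np.testing.assert_allclose(np.sort(got[m]), np.sort(expected),
                                       atol=1e-10)

    def test_identical_members_zero(self):
        D = np.zeros((6, 6))
        got = centroid_distances(D, np.repeat(["a", "b"], 3))
        assert np.allclose(got, 0.0)

    def test_negative_eigenvalue_correction(self):
        """A non-Euclidean 4-point dissimilarity exercises the imaginary-axis
        correction; outputs stay real and non-negative."""
        D = np.array([
            [0.0, 1.0, 1.0, 1.9],
            [1.0, 0.0, 1.0, 1.0],
            [1.0, 1.0, 0.0, 1.0],
            [1.9, 1.0, 1.0, 0.0],
        ])
        # confirm non-Euclidean: Gower matrix has a negative eigenvalue
        n = 4
        J = np.eye(n) - np.ones((n, n)) / n
        G = J @ (-0.5 * D**2) @ J
        assert np.linalg.eigvalsh(G).min() < -1e-9
        got = centroid_distances(D, np.array(["g", "g", "g", "g"]))
        assert np.isreal(got).all() and (got >= 0).all()

    def test_singleton_group_zero(self):
        D = euclid(np.array([0.0, 1.0, 2.0]))
        got = centroid_distances(D, np.array(["a", "a", "b"]))
        assert got[2] == 0.0


class TestFeltzMiller:
    def test_equal_cvs_statistic_zero(self):
        tr = feltz_miller_cv_test(cvs=[0.5, 0.5, 0.5], ns=[10, 20, 30])
        assert tr.statistic == pytest.approx(0.0)
        assert tr.p_value == pytest.approx(1.0)

    def test_worked_example(self):
        """CVs (1.244, 0.527), n (52, 144): D'AD ~ 37.3, p ~ 1e-9."""
        tr = feltz_miller_cv_test(cvs=[1.244, 0.527], ns=[52, 144])
        assert tr.statistic == pytest.approx(37.376, rel=0.01)
        assert tr.df == 1
        assert 1e-10 < tr.p_value < 1e-8

    def test_formula_reimplementation_on_random_inputs(self):
        """Statistic equals an independent inline evaluation of the formula."""
        rng = np.random.default_rng(14)
        for _ in range(100):
            k = rng.integers(2, 6)
            cvs = rng.uniform(0.05, 2.0, k)
            ns = rng.integers(2, 200, k)
            tr = feltz_miller_cv_test(cvs=cvs, ns=ns)
            nu = ns - 1
            kbar = (nu * cvs).sum() / nu.sum()
            dad = (nu * (cvs - kbar) ** 2).sum() / (kbar**2 * (0.5 + kbar**2))
            assert tr.statistic == pytest.approx(dad, rel=1e-12)
            assert tr.p_value == pytest.approx(stats.chi2.sf(dad, k - 1))

    def test_from_raw_values(self):
        rng = np.random.default_rng(15)
        v1 = rng.lognormal(1, 0.9, 60)
        v2 = rng.lognormal(1, 0.3, 80)
        vals = np.concatenate([v1, v2])
        grp = np.array(["a"] * 60 + ["b"] * 80)
        tr = feltz_miller_cv_test(values=vals, groups=grp)
        assert tr.p_value < 0.05

    def test_validation(self):
        with pytest.raises(ValueError):
            feltz_miller_cv_test(cvs=[0.5], ns=[10])
        with pytest.raises(ValueError):
            feltz_miller_cv_test(cvs=[0.5, 0.4], ns=[1, 10])
        with pytest.raises(ValueError):
            feltz_miller_cv_test(cvs=[0.0, 0.4], ns=[5, 10])


# --------------------------------------------------------------------------
# per-taxon PLN tests
# --------------------------------------------------------------------------

class TestPlnTaxonTests:
    def test_detects_simulated_protocol_offset(self):
        """A log(1.3) DEP offset on taxon 0 is flagged; the result table
        carries the AIC/BIC/FDR machinery."""
        cfg = SimulationConfig(n_populations=2, families_per_population=1,
                               fish_per_family=6, n_taxa=8,
                               library_depth=20_000, sigma2_A=0.3,
                               sigma2_W=0.02, seed=77,
                               baseline_logabundance_spread=1.0,
                               protocol_offsets={0: {"DEP": np.log(1.3)}})
        sim = simulate_dataset(cfg)
        res = pln_taxon_tests(sim.table, sim.design, "protocol", n_quad=15)
        assert set(["lrt", "p_raw", "p_fdr", "dAIC", "dBIC", "flag_strong",
                    "flag_weak"]) <= set(res.columns)
        assert (res.status == "ok").all()
        hit = res[res.taxon == "t0001"].iloc[0]
        assert hit.p_raw < 0.05
        assert hit.flag_weak

    def test_aic_bic_relation_to_lrt(self):
        """dAIC = LRT - 2*ddf and dBIC = LRT - ddf*ln(n) by definition."""
        cfg = SimulationConfig(n_populations=2, families_per_population=1,
                               fish_per_family=4, n_taxa=3,
                               library_depth=2000, sigma2_A=0.2,
                               sigma2_W=0.05, seed=5)
        sim = simulate_dataset(cfg)
        res = pln_taxon_tests(sim.table, sim.design, "population", n_quad=15)
        n = sim.table.n_libraries
        ok = res[res.status == "ok"]
        np.testing.assert_allclose(ok.dAIC, ok.lrt - 2 * ok.df, atol=1e-6)
        np.testing.assert_allclose(ok.dBIC, ok.lrt - ok.df * np.log(n),
                                   atol=1e-6)
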