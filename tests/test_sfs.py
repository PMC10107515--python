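"""Joint-SFS machinery: tallies, projection, expected spectra, fitting."""

import itertools

import numpy as np
import pandas as pd
import pytest

import crossploidy as cp
from crossploidy import sfs as S

from conftest import STUDY_MODEL, random_matrix


class TestJointSfs:
    def test_single_fixed_difference_lands_in_one_folded_cell(self):
        g = np.array([[0], [0], [2], [2]], dtype=np.int8)
        G = cp.GenotypeMatrix(g, list("abcd"), ["D", "D", "T", "T"],
                              ["s"], [1])
        out = S.joint_sfs(G, fold=True)
        assert out.total == pytest.approx(1.0)
        # count (0, 4) of (4, 4) folds onto (4, 0)
        assert out.data[4, 0] + out.data[0, 4] == pytest.approx(1.0)

    def test_total_mass_equals_number_of_sites(self, study_dataset):
        G, _ = study_dataset
        unprojected = S.joint_sfs(G, fold=True)
        assert unprojected.total == pytest.approx(G.n_sites)
        # projection conserves mass overall; part of it lands on the masked
        # fixed corners (sites effectively monomorphic in the subsample)
        out = S.joint_sfs(G, fold=True, project_to=(24, 24))
        assert out.data.sum() == pytest.approx(G.n_sites, abs=1e-6)

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(3)
        G = random_matrix(rng, n_ind=8, n_sites=40, missing=0.0)
        out = S.joint_sfs(G, fold=False)
        idx_D, idx_T = G.pop_index("D"), G.pop_index("T")
        expect = np.zeros((9, 9))
        for j in range(G.n_sites):
            expect[G.genotypes[idx_D, j].sum(),
                   G.genotypes[idx_T, j].sum()] += 1
        assert np.array_equal(out.data, expect)

    def test_sites_below_projection_size_are_dropped(self):
        g = np.array([[0, -1], [1, -1], [2, 0], [2, 1]], dtype=np.int8)
        G = cp.GenotypeMatrix(g, list("abcd"), ["D", "D", "T", "T"],
                              ["s1", "s2"], [1, 2])
        out = S.joint_sfs(G, fold=False, project_to=(4, 4))
        assert out.data.sum() == pytest.approx(1.0)  # site 2 unusable


class TestProjection:
    def test_projecting_to_current_size_is_identity(self):
        rng = np.random.default_rng(1)
        sp = S.JointSFS(rng.random((7, 7)), 6, 6, folded=False)
        out = S.project_sfs(sp, (6, 6))
        assert np.allclose(out.data, sp.data, atol=1e-12)

    def test_single_entry_image_is_normalized(self):
        sp = S.JointSFS(np.zeros((7, 7)), 6, 6, folded=False)
        sp.data[2, 5] = 1.0
        out = S.project_sfs(sp, (4, 4))
        assert out.data.sum() == pytest.approx(1.0, abs=1e-12)

    def test_target_above_current_rejected(self):
        sp = S.JointSFS(np.zeros((5, 5)), 4, 4)
        with pytest.raises(ValueError):
            S.project_sfs(sp, (6, 4))

    def test_six_to_four_projection_equals_exhaustive_enumeration(self):
        """Hypergeometric projection agrees with brute-force enumeration of
        all without-replacement subsamples of the allele copies (1e-12)."""
        rng = np.random.default_rng(5)
        sp = S.JointSFS(rng.random((7, 7)), 6, 6, folded=False)
        out = S.project_sfs(sp, (4, 4))
        expect = np.zeros((5, 5))
        for i, j in itertools.product(range(7), range(7)):
            mass = sp.data[i, j]
            # enumerate subsets of 4 of the 6 copies in each population
            for subD in itertools.combinations(range(6), 4):
                kD = sum(1 for x in subD if x < i)
                for subT in itertools.combinations(range(6), 4):
                    kT = sum(1 for x in subT if x < j)
                    expect[kD, kT] += mass / 225.0  # C(6,4)^2 subsets
        assert np.allclose(out.data, expect, atol=1e-12)

    def test_projection_and_folding_commute(self):
        rng = np.random.default_rng(6)
        sp = S.JointSFS(rng.random((11, 9)), 10, 8, folded=False)
        a = S.project_sfs(sp.fold(), (6, 4))
        b = S.project_sfs(sp, (6, 4)).fold()
        assert np.allclose(a.data, b.data, atol=1e-12)
        assert a.folded and b.folded


class TestExpectedSfs:
    def test_deep_split_mass_is_private(self):
        m = cp.DemographicModel(family="no_gene_flow", T0=5.0)
        e = S.expected_sfs(m, n=(24, 24), n_trees=4000, seed=1, fold=False)
        keep = ~e.mask
        private = np.zeros_like(e.data, dtype=bool)
        private[0, :] = True
        private[:, 0] = True
        private[24, :] = True
        private[:, 24] = True
        frac = e.data[keep & private].sum() / e.data[keep].sum()
        assert frac > 0.99

    def test_symmetric_model_gives_symmetric_spectrum(self):
        m = cp.DemographicModel(family="constant_gene_flow", nu_D=1.0,
                                nu_T=1.0, T0=1.0, M_DT=0.5, M_TD=0.5,
                                F_D=0.6, F_T=0.6)
        e = S.expected_sfs(m, n=(24, 24), n_trees=20000, seed=2, fold=False)
        err = np.hypot(e.stderr, e.stderr.T)
        diff = np.abs(e.data - e.data.T)
        keep = ~(e.mask | e.mask.T)
        assert (diff[keep] <= 5 * err[keep] + 1e-9).all()

    def test_no_gene_flow_nested_in_constant_flow_at_zero_migration(self):
        m0 = cp.DemographicModel(family="no_gene_flow", nu_D=1.0, nu_T=0.8,
                                 T0=1.0, F_D=0.81, F_T=0.75)
        m1 = cp.DemographicModel(family="constant_gene_flow", nu_D=1.0,
                                 nu_T=0.8, T0=1.0, M_DT=0.0, M_TD=0.0,
                                 F_D=0.81, F_T=0.75)
        e0 = S.expected_sfs(m0, n=(24, 24), n_trees=20000, seed=3)
        e1 = S.expected_sfs(m1, n=(24, 24), n_trees=20000, seed=4)
        keep = ~(e0.mask | e1.mask)
        err = np.hypot(e0.stderr, e1.stderr)
        assert (np.abs(e0.data - e1.data)[keep]
                <= 5 * err[keep] + 1e-9).all()

    def test_historical_flow_with_tiny_recent_epoch_matches_constant(self):
        mc = STUDY_MODEL
        mh = cp.DemographicModel(family="historical_gene_flow", nu_D=1.0,
                                 nu_T=0.8, T0=1.0, T1=1e-6, M_DT=0.3,
                                 M_TD=0.4, F_D=0.81, F_T=0.75)
        ec = S.expected_sfs(mc, n=(24, 24), n_trees=20000, seed=5)
        eh = S.expected_sfs(mh, n=(24, 24), n_trees=20000, seed=6)
        keep = ~(ec.mask | eh.mask)
        err = np.hypot(ec.stderr, eh.stderr)
        assert (np.abs(ec.data - eh.data)[keep]
                <= 5 * err[keep] + 1e-9).all()


class TestCompositeLoglik:
    def _pair(self, seed=0):
        e = S.expected_sfs(STUDY_MODEL, n=(24, 24), n_trees=3000, seed=seed)
        return e

    def test_exact_scaled_data_recovers_theta(self):
        e = self._pair()
        data = S.JointSFS(7.0 * e.data, 24, 24, folded=True)
        lnl, theta = S.composite_loglik(data, e)
        assert theta == pytest.approx(7.0, rel=1e-12)

    def test_analytic_theta_maximizes_likelihood_on_grid(self):
        e = self._pair(1)
        rng = np.random.default_rng(2)
        data = S.JointSFS(rng.poisson(5.0 * e.data / e.data.sum() * 400.0)
                          .astype(float), 24, 24, folded=True)
        _, theta = S.composite_loglik(data, e)

        def lnl_at(scale):
            keep = ~(data.mask | e.mask)
            d = data.data[keep]
            m = np.clip(scale * e.data[keep], 1e-300, None)
            from scipy.special import gammaln
            return (d * np.log(m) - m - gammaln(d + 1)).sum()

        best = lnl_at(theta)
        for mult in (0.8, 0.9, 1.1, 1.25):
            assert lnl_at(theta * mult) < best

    def test_empty_data_spectrum_degenerates_to_zero(self):
        e = self._pair(3)
        empty = S.JointSFS(np.zeros_like(e.data), 24, 24, folded=True)
        lnl, theta = S.composite_loglik(empty, e)
        assert lnl == 0.0 and theta == 0.0

    def test_mismatched_shapes_rejected(self):
        e = self._pair(4)
        bad = S.JointSFS(np.zeros((11, 11)), 10, 10, folded=True)
        with pytest.raises(ValueError):
            S.composite_loglik(bad, e)


@pytest.fixture(scope="module")
def small_fit_data():
    G, _ = cp.simulate_genotypes(
        STUDY_MODEL, cp.SimulationConfig(n_D=20, n_T=20, n_sites=800,
                                         seed=17))
    return S.joint_sfs(G, fold=True, project_to=(24, 24))


class TestFitModel:
    def test_aic_identity_and_restart_log(self, small_fit_data):
        fit = S.fit_model(small_fit_data, "no_gene_flow", n_restarts=2,
                          seed=1, n_trees=600, n_ind=(20, 20))
        assert fit.aic == 2 * 3 - 2 * fit.loglik
        assert fit.k == 3
        assert len(fit.restarts) == 2
        assert fit.restarts["loglik"].notna().all()

    def test_more_restarts_never_hurt_the_search(self, small_fit_data):
        one = S.fit_model(small_fit_data, "no_gene_flow", n_restarts=1,
                          seed=2, n_trees=600, n_ind=(20, 20))
        many = S.fit_model(small_fit_data, "no_gene_flow", n_restarts=4,
                           seed=2, n_trees=600, n_ind=(20, 20))
        assert many.restarts["loglik"].max() >= \
            one.restarts["loglik"].max() - 1e-9

    def test_inbreeding_is_fixed_not_fitted(self, small_fit_data):
        fit = S.fit_model(small_fit_data, "no_gene_flow", n_restarts=1,
                          seed=3, n_trees=600, n_ind=(20, 20),
                          F_D=0.81, F_T=0.75)
        assert fit.model.F_D == 0.81 and fit.model.F_T == 0.75
        assert "F_D" not in fit.params


class TestSubsampleReplicates:
    def test_full_subset_equals_direct_projection(self, study_dataset):
        G, _ = study_dataset
        reps = S.subsample_replicates(G, n_rep=1, seed=1,
                                      n_per_pop=[45, 50], target=(24, 24))
        direct = S.joint_sfs(G, fold=True, project_to=(24, 24))
        assert np.allclose(reps[0].data, direct.data, atol=1e-9)

    def test_replicates_conserve_site_mass(self, study_dataset):
        G, _ = study_dataset
        reps = S.subsample_replicates(G, n_rep=5, seed=2)
        for r in reps:
            assert r.data.sum() == pytest.approx(G.n_sites, abs=1e-6)

    def test_distinct_replicates_draw_distinct_subsets(self, study_dataset):
        G, _ = study_dataset
        reps = S.subsample_replicates(G, n_rep=10, seed=3)
        spectra = {r.data.tobytes() for r in reps}
        assert len(spectra) > 1

    def test_population_too_small_rejected(self):
        rng = np.random.default_rng(4)
        G = random_matrix(rng, n_ind=10, n_sites=20, missing=0.0)
        with pytest.raises(ValueError):
            S.subsample_replicates(G, n_rep=1, target=(24, 24))


def _fake_fit(family, loglik):
    k = cp.DemographicModel(family=family, T0=1.0,
                            T1=0.5 if family in ("historical_gene_flow",
                                                 "secondary_contact")
                            else None).k
    return S.FitResult(family=family, params={}, model=None, loglik=loglik,
                       theta=1.0, k=k, restarts=pd.DataFrame())


class TestCompareModels:
    def test_identical_aic_vectors_give_t0_p1(self):
        lls = [-200.0, -210.0, -205.0]
        fits = {"constant_gene_flow": [_fake_fit("constant_gene_flow", x)
                                       for x in lls],
                "no_gene_flow": [_fake_fit("no_gene_flow", x - 2.0)
                                 for x in lls]}
        # -2 in lnL exactly cancels the k difference (5 vs 3): equal AICs
        comp = S.compare_models(fits)
        t = comp.tests.iloc[0]
        assert t["t"] == 0.0 and t["p"] == 1.0

    def test_shifted_aics_detected_at_99_replicates(self):
        rng = np.random.default_rng(7)
        base = list(-300 + rng.normal(0, 3, 99))
        fits = {"no_gene_flow": [_fake_fit("no_gene_flow", x) for x in base],
                "constant_gene_flow": [_fake_fit("constant_gene_flow", x + 7)
                                       for x in base]}
        # constant flow is 10 AIC units better (lnL +7, k +2) everywhere
        comp = S.compare_models(fits)
        assert comp.best_family == "constant_gene_flow"
        t = comp.tests.iloc[0]
        assert t["p"] < 0.01 and t["t"] < 0
        med = comp.medians
        assert med["no_gene_flow"] - med["constant_gene_flow"] == \
            pytest.approx(10.0, abs=1e-9)

    def test_single_replicate_gives_medians_only(self):
        fits = {"no_gene_flow": [_fake_fit("no_gene_flow", -100.0)],
                "constant_gene_flow": [_fake_fit("constant_gene_flow",
                                                 -90.0)]}
        comp = S.compare_models(fits)
        assert comp.tests is None
        assert comp.best_family == "constant_gene_flow"


from hypothesis import given, settings, strategies as st  # noqa: E402


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(2, 10), st.integers(2, 10), st.integers(0, 2**31 - 1))
def test_folding_conserves_mass_and_clears_noncanonical_cells(nD, nT, seed):
    rng = np.random.default_rng(seed)
    sp = S.JointSFS(rng.random((nD + 1, nT + 1)), nD, nT, folded=False)
    folded = sp.fold()
    assert folded.data.sum() == pytest.approx(sp.data.sum(), rel=1e-12)
    i = np.arange(nD + 1)[:, None]
    j = np.arange(nT + 1)[None, :]
    assert (folded.data[(i + j) > (nD + nT) / 2] == 0).all()


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(3, 8), st.integers(3, 8), st.integers(2, 6),
       st.integers(2, 6), st.integers(0, 2**31 - 1))
def test_projection_is_mass_conserving_and_linear(nD, nT, tD, tT, seed):
    tD, tT = min(tD, nD), min(tT, nT)
    rng = np.random.default_rng(seed)
    a = rng.random((nD + 1, nT + 1))
    b = rng.random((nD + 1, nT + 1))
    pa = S.project_sfs(S.JointSFS(a, nD, nT), (tD, tT))
    pb = S.project_sfs(S.JointSFS(b, nD, nT), (tD, tT))
    pab = S.project_sfs(S.JointSFS(a + 2.0 * b, nD, nT), (tD, tT))
    assert pa.data.sum() == pytest.approx(a.sum(), rel=1e-12)
    assert np.allclose(pab.data, pa.data + 2.0 * pb.data, atol=1e-12)
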