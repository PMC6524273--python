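import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from seromir import (
    CountMatrix,
    bh_adjust,
    estimate_dispersion,
    fit_nb_glm,
    log2cpm,
    lrt_group_effect,
    pairwise_log2fc,
    simulate_cohort,
)
from seromir.diffexp import DISPERSION_FLOOR, _nb_loglik

from _oracles import bh_direct


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
            ((0.5,), (0.5,)),
            ((0.03,), (0.03,)),  # single test: FDR equals the raw p
        ],
    )
    def test_closed_form_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(np.array(p)), expected)

    def test_matches_direct_step_up_formula(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        np.testing.assert_allclose(bh_adjust(p), bh_direct(p))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=40),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_permutation(self, p, rnd):
        p = np.array(p)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        adjusted = bh_adjust(p)
        shuffled = bh_adjust(p[perm])
        np.testing.assert_allclose(shuffled, adjusted[perm])

    def test_fdr_dominates_pvalue(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=60)
        assert np.all(bh_adjust(p) >= p - 1e-12)


# ---------------------------------------------------------------------------
# NB GLM fitting
# ---------------------------------------------------------------------------

class TestFitNbGlm:
    def test_intercept_only_equals_log_mean(self):
        y = np.array([10, 20, 30, 40], dtype=float)
        coef, dev, conv = fit_nb_glm(y, np.ones((4, 1)), dispersion=0.1)
        assert conv
        assert coef[0] == pytest.approx(np.log(y.mean()), abs=1e-8)

    def test_two_group_coefficient_is_log_mean_ratio(self):
        y = np.array([40, 40, 40, 10, 10, 10], dtype=float)
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        coef, dev, conv = fit_nb_glm(y, X, dispersion=0.2)
        assert conv
        assert coef[1] == pytest.approx(np.log(10 / 40), abs=1e-8)
        assert dev == pytest.approx(0.0, abs=1e-8)

    def test_deviance_matches_generic_optimizer(self):
        rng = np.random.default_rng(5)
        n, p, phi = 30, 3, 0.15
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        beta_true = np.array([3.0, 0.5, -0.3])
        mu = np.exp(X @ beta_true)
        y = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu)).astype(float)
        _, dev, conv = fit_nb_glm(y, X, dispersion=phi)
        assert conv

        def negll(beta):
            m = np.exp(np.clip(X @ beta, -30, 30))
            return -_nb_loglik(y[None, :], m[None, :], np.array([phi]))[0]

        res = optimize.minimize(negll, np.zeros(p), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000})
        sat = _nb_loglik(y[None, :], np.maximum(y, 1e-10)[None, :],
                         np.array([phi]))[0]
        dev_oracle = 2 * (sat + res.fun)
        assert dev == pytest.approx(dev_oracle, abs=1e-4)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(ValueError, match="rank"):
            fit_nb_glm(np.arange(5.0) + 1, X)

    def test_lr_invariant_to_spanned_extra_information(self):
        # adding a column already spanned by the design is rejected as
        # rank-deficient rather than silently changing the statistic
        rng = np.random.default_rng(6)
        y = rng.poisson(20, size=8).astype(float)
        X = np.column_stack([np.ones(8), rng.normal(size=8)])
        spanned = np.column_stack([X, X @ np.array([1.0, 2.0])])
        with pytest.raises(ValueError, match="rank"):
            fit_nb_glm(y, spanned)


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

class TestEstimateDispersion:
    def test_poisson_counts_give_near_zero_common_dispersion(self):
        cm, _ = simulate_cohort(
            n_pc=10, n_btc=10, n_hc=10, n_mirna=500, n_de=0,
            dispersion=0.0, seed=10,
        )
        est = estimate_dispersion(cm)
        assert est.common <= 0.05

    def test_nb_dispersion_recovered(self):
        cm, _ = simulate_cohort(
            n_pc=10, n_btc=10, n_hc=10, n_mirna=400, n_de=0,
            dispersion=0.2, seed=11,
        )
        est = estimate_dispersion(cm)
        assert 0.1 <= est.common <= 0.3
        # shrunk tagwise values concentrate around the common estimate
        assert est.tagwise.median() == pytest.approx(est.common, rel=0.5)

    def test_constant_counts_return_floor_with_warning(self):
        counts = pd.DataFrame(
            np.full((5, 6), 7),
            index=[f"m{i}" for i in range(5)],
            columns=[f"S{j}" for j in range(6)],
        )
        meta = pd.DataFrame(
            {
                "group": ["PC", "PC", "BTC", "BTC", "HC", "HC"],
                "age": [40.0, 52.0, 47.0, 61.0, 38.0, 55.0],
                "gender": ["M", "F"] * 3,
                "bmi": [21.0, 27.0, 19.5, 24.0, 30.0, 22.5],
            },
            index=counts.columns,
        )
        with pytest.warns(RuntimeWarning, match="floor"):
            est = estimate_dispersion(CountMatrix(counts, meta))
        assert est.common == DISPERSION_FLOOR
        assert (est.tagwise == DISPERSION_FLOOR).all()


# ---------------------------------------------------------------------------
# likelihood-ratio test
# ---------------------------------------------------------------------------

class TestLrtGroupEffect:
    def test_null_pvalues_approximately_uniform(self):
        cm, _ = simulate_cohort(n_mirna=2000, n_de=0, log2fc=0.0, seed=21)
        res = lrt_group_effect(cm)
        ks = stats.kstest(res["pvalue"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_planted_effects_recovered_with_high_precision(self):
        cm, truth = simulate_cohort(seed=31)  # paper-scale defaults
        res = lrt_group_effect(cm)
        sig = set(res.index[res["fdr"] <= 0.05])
        planted = set(truth.de_ids)
        assert len(sig & planted) / len(planted) >= 0.6
        assert len(sig & planted) / max(len(sig), 1) >= 0.9

    def test_confounded_design_names_collinear_columns(self):
        cm, _ = simulate_cohort(
            n_pc=6, n_btc=4, n_hc=6, n_mirna=30, n_de=0, seed=3
        )
        meta = cm.metadata.copy()
        # make gender a perfect indicator of the PC group
        meta["gender"] = np.where(meta["group"] == "PC", "M", "F")
        meta["age"] = np.where(meta["group"] == "PC", 60.0, 40.0)
        meta.loc[meta.index[:2], "age"] += 1.0  # keep age informative
        confounded = CountMatrix(cm.counts, meta)
        # gender column duplicates group_PC exactly -> rank deficiency
        with pytest.raises(ValueError, match="collinear"):
            lrt_group_effect(confounded)

    def test_fdr_consistent_with_bh_on_pvalues(self):
        cm, _ = simulate_cohort(
            n_pc=8, n_btc=6, n_hc=8, n_mirna=120, n_de=10, seed=8
        )
        res = lrt_group_effect(cm)
        ok = res["converged"].to_numpy()
        np.testing.assert_allclose(
            res.loc[ok, "fdr"].to_numpy(),
            bh_adjust(res.loc[ok, "pvalue"].to_numpy()),
        )
        assert (res["lr"] >= 0).all()


# ---------------------------------------------------------------------------
# descriptive pairwise fold changes
# ---------------------------------------------------------------------------

class TestPairwiseLog2FC:
    def _norm_and_labels(self, seed=4):
        cm, _ = simulate_cohort(
            n_pc=8, n_btc=6, n_hc=8, n_mirna=60, n_de=10, log2fc=2.0,
            seed=seed,
        )
        return log2cpm(cm), cm.groups

    def test_mean_difference_and_flag(self):
        expr, labels = self._norm_and_labels()
        mat = expr.log2cpm.copy()
        mat.loc[:, :] = 5.0
        mat.loc[mat.index[0], (labels == "PC").to_numpy()] = 7.0
        expr2 = expr
        expr2.log2cpm = mat
        res = pairwise_log2fc(expr2, labels)
        assert res.iloc[0]["log2fc_PN"] == pytest.approx(2.0)
        assert bool(res.iloc[0]["flag_PN"])
        assert res.iloc[0]["direction_PN"] == "up"
        assert res.iloc[1]["log2fc_PN"] == 0.0
        assert not bool(res.iloc[1]["flag_PN"])

    def test_flags_match_brute_force(self):
        expr, labels = self._norm_and_labels(seed=5)
        res = pairwise_log2fc(expr, labels)
        for mirna in expr.mirna_ids:
            row = expr.log2cpm.loc[mirna]
            fc = (
                row[(labels == "BTC").to_numpy()].mean()
                - row[(labels == "PC").to_numpy()].mean()
            )
            assert res.loc[mirna, "log2fc_BP"] == pytest.approx(fc)
            assert bool(res.loc[mirna, "flag_BP"]) == (abs(fc) > 1.0)

    def test_unknown_pair_code_rejected(self):
        expr, labels = self._norm_and_labels()
        with pytest.raises(ValueError, match="pair code"):
            pairwise_log2fc(expr, labels, pairs=("XY",))
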