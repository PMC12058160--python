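import numpy as np
import pandas as pd
import pytest

import methdriver as md
from methdriver import methmix


def _fit_two_component(seed, mu_lo=0.10, mu_hi=0.90, phi=20.0, n_each=100):
    rng = np.random.default_rng(seed)
    x = np.concatenate([
        rng.beta(mu_lo * phi, (1 - mu_lo) * phi, n_each),
        rng.beta(mu_hi * phi, (1 - mu_hi) * phi, n_each)])
    return methmix.fit_beta_mixture(x, probe_id=f"sim{seed}", seed=seed)


class TestFitBetaMixture:
    def test_tight_unimodal_selects_k1(self):
        rng = np.random.default_rng(0)
        x = np.clip(rng.normal(0.5, 0.01, 60), 0.01, 0.99)
        fit = methmix.fit_beta_mixture(x, seed=0)
        assert fit.k == 1
        assert 0.45 <= fit.means[0] <= 0.55

    def test_two_well_separated_components_recovered(self):
        # draws from Beta(2,18) and Beta(18,2): means 0.10 and 0.90
        fit = _fit_two_component(seed=123, n_each=150)
        assert fit.k == 2
        lo, hi = sorted(fit.means)
        assert abs(lo - 0.10) <= 0.05
        assert abs(hi - 0.90) <= 0.05

    def test_single_beta_prefers_k1_across_seeds(self):
        # 300 draws from one Beta(5,5): BIC should pick K=1 nearly always
        k1 = 0
        n_rep = 50
        for rep in range(n_rep):
            rng = np.random.default_rng(2000 + rep)
            x = rng.beta(5, 5, 300)
            k1 += methmix.fit_beta_mixture(x, seed=rep).k == 1
        assert k1 >= 0.9 * n_rep

    def test_minimum_sample_count_enforced(self):
        with pytest.raises(ValueError, match="≥10"):
            methmix.fit_beta_mixture(np.full(5, 0.5), seed=0)

    def test_weights_and_responsibilities_normalized(self):
        fit = _fit_two_component(seed=7)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-9)

    def test_loglik_nondecreasing(self):
        for seed in range(5):
            fit = _fit_two_component(seed=seed)
            assert (np.diff(fit.loglik_trajectory) >= -1e-8).all()

    def test_mean_recovery_over_seeded_simulations(self):
        """Over 50 seeded 2-component fits with |mu1-mu2| >= 0.4 and n=200
        the mean absolute error of the recovered means stays <= 0.03."""
        errors = []
        for rep in range(50):
            mu_lo, mu_hi = 0.25, 0.70
            fit = _fit_two_component(3000 + rep, mu_lo, mu_hi, phi=40.0)
            if fit.k != 2:
                errors.append(0.5)  # count a selection failure as a big miss
                continue
            lo, hi = sorted(fit.means)
            errors.extend([abs(lo - mu_lo), abs(hi - mu_hi)])
        assert np.mean(errors) <= 0.03


class TestCallStates:
    def _fit(self, means, weights=None):
        k = len(means)
        weights = np.asarray(weights if weights else [1 / k] * k)
        return methmix.BetaMixtureFit(
            probe_id="p", k=k, weights=weights, means=np.asarray(means),
            precisions=np.full(k, 20.0), log_likelihood=0.0, bic=0.0,
            loglik_trajectory=np.array([0.0]),
            responsibilities=np.tile(weights, (12, 1)))

    def test_hyper_call_from_dm(self):
        fit = methmix.call_states(self._fit([0.8]), np.full(10, 0.3))
        assert fit.dm[0] == pytest.approx(0.5)
        assert fit.component_states == ("hyper",)
        assert fit.probe_state == "Hyper"

    def test_small_dm_is_normal_like(self):
        fit = methmix.call_states(self._fit([0.32]), np.full(10, 0.30))
        assert fit.component_states == ("normal-like",)
        assert fit.probe_state == "None"

    def test_dual_state_when_both_directions_present(self):
        # hypomethylated in part of the cohort, hypermethylated in the rest
        fit = methmix.call_states(self._fit([0.1, 0.9]), np.full(10, 0.5))
        assert fit.probe_state == "Dual"

    def test_monotone_in_dm_min(self):
        # raising dm_min can only turn abnormal calls into normal-like
        for dm_lo, dm_hi in [(0.05, 0.10), (0.10, 0.30)]:
            f1 = methmix.call_states(self._fit([0.35, 0.75]),
                                     np.full(10, 0.5), dm_min=dm_lo)
            f2 = methmix.call_states(self._fit([0.35, 0.75]),
                                     np.full(10, 0.5), dm_min=dm_hi)
            for s1, s2 in zip(f1.component_states, f2.component_states):
                if s1 == "normal-like":
                    assert s2 == "normal-like"


class TestPairWithExpression:
    def _setup(self, shift, n_abn=15, n_ref=15, n_normal=12, two_genes=False,
               seed=0):
        rng = np.random.default_rng(seed)
        tumor = [f"T{i:02d}" for i in range(n_abn + n_ref)]
        normal = [f"N{i:02d}" for i in range(n_normal)]
        cohort = md.AlignedCohort(samples=tuple(sorted(tumor + normal)),
                                  tumor=tuple(tumor), normal=tuple(normal))
        betas = np.concatenate([rng.beta(3, 27, n_abn), rng.beta(15, 15, n_ref)])
        fit = methmix.fit_beta_mixture(betas, probe_id="cg1", seed=0,
                                       sample_ids=tumor)
        fit = methmix.call_states(fit, rng.beta(15, 15, n_normal))
        genes = ["A", "B"] if two_genes else ["A"]
        rows = []
        for g in genes:
            expr_t = rng.normal(8, 0.5, n_abn + n_ref)
            if g == "A":
                abn = fit.samples_in_states({"hypo", "hyper"})
                idx = [i for i, s in enumerate(tumor) if s in abn]
                expr_t[idx] += shift
            rows.append(np.concatenate([expr_t, rng.normal(8, 0.5, n_normal)]))
        expr = pd.DataFrame(rows, index=genes, columns=tumor + normal)
        manifest = pd.DataFrame({
            "probe_id": ["cg1"] * len(genes), "gene_symbol": genes,
            "chrom": "chr1", "start": 0, "end": 2, "region_class": "promoter"})
        return fit, manifest, expr, cohort

    def test_no_shift_is_not_functional(self):
        fit, manifest, expr, cohort = self._setup(shift=0.0)
        pairs, tested = methmix.pair_with_expression([fit], manifest, expr, cohort)
        assert len(tested) == 1
        assert pairs.empty

    def test_planted_shift_is_functional(self):
        fit, manifest, expr, cohort = self._setup(shift=2.0)
        pairs, _ = methmix.pair_with_expression([fit], manifest, expr, cohort)
        assert len(pairs) == 1
        assert pairs.iloc[0].assoc_fdr <= 0.05
        assert pairs.iloc[0].cpg_state == "Hypo"

    def test_multi_gene_probe_only_shifted_gene_functional(self):
        fit, manifest, expr, cohort = self._setup(shift=2.0, two_genes=True)
        pairs, tested = methmix.pair_with_expression([fit], manifest, expr,
                                                     cohort)
        assert len(tested) == 2
        assert list(pairs.gene_symbol) == ["A"]

    def test_promoter_only_filter(self):
        fit, manifest, expr, cohort = self._setup(shift=2.0)
        manifest["region_class"] = "other"
        pairs, tested = methmix.pair_with_expression([fit], manifest, expr,
                                                     cohort)
        assert tested.empty
        pairs, tested = methmix.pair_with_expression(
            [fit], manifest, expr, cohort, promoter_only=False)
        assert len(tested) == 1
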