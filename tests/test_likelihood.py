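import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mknest as mk
from mknest.likelihood import FLAG_OK, FLAG_UNBOUNDED, FLAG_UNINFORMATIVE

from conftest import random_small_dataset

# 6!/(4!2!) * (2/3)^4 * (1/3)^2 = 240/729, the single-gene likelihood at
# its ML success probability 2/3
WORKED_EXAMPLE_LOGLIK = math.log(240 / 729)


class TestGeneLogLikelihood:
    def test_single_gene_at_ml_odds(self):
        # odds 2 <=> P = 2/3, e.g. beta = 2 at alpha = 1
        assert mk.gene_log_likelihood(4, 6, 2.0, 1.0) == pytest.approx(
            WORKED_EXAMPLE_LOGLIK, abs=1e-12
        )

    def test_zero_information_observation_is_exactly_zero(self):
        assert mk.gene_log_likelihood(0, 0, 0.5, 0.3) == 0.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            mk.gene_log_likelihood(7, 6, 1.0, 1.0)
        with pytest.raises(ValueError):
            mk.gene_log_likelihood(1, 2, -1.0, 1.0)
        with pytest.raises(ValueError):
            mk.gene_log_likelihood(1, 2, 1.0, 0.0)

    def test_saturating_monotone_limit(self):
        # all-nonsynonymous observation: loglik increases to 0 as beta grows
        values = [mk.gene_log_likelihood(3, 3, b, 1.0) for b in (1, 10, 100, 1e6)]
        assert all(a < b for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(0.0, abs=1e-5)


class TestModelLogLikelihood:
    def test_single_observation_sum(self):
        ds = mk.dataset_from_records([("g1", "mel", 0, 0, 4, 2)], {"g1": "other"})
        model = mk.PartitionModel.single()
        ll = mk.model_log_likelihood(ds, model, [2.0], 1.0)
        assert ll == pytest.approx(mk.gene_log_likelihood(4, 6, 2.0, 1.0))

    def test_all_zero_dataset_is_zero(self):
        ds = mk.dataset_from_records(
            [("g1", "mel", 0, 0, 0, 0), ("g2", "mel", 0, 0, 0, 0)],
            {"g1": "piRNA", "g2": "other"},
        )
        assert mk.model_log_likelihood(ds, mk.PartitionModel.single(), [0.7], 0.5) == 0.0

    def test_closed_form_beats_grid(self, toy_dataset):
        """Grid-search oracle: no beta on a fine grid beats the closed form."""
        model = mk.PartitionModel.single()
        alpha = 1.0
        beta_hat, flags = mk.closed_form_beta(toy_dataset, model, alpha)
        assert flags == (FLAG_OK,)
        best = mk.model_log_likelihood(toy_dataset, model, beta_hat, alpha)
        for b in np.geomspace(0.05, 50, 400):
            assert mk.model_log_likelihood(toy_dataset, model, [b], alpha) <= best + 1e-12


class TestClosedFormBeta:
    def test_single_gene_four_two(self):
        ds = mk.dataset_from_records([("g1", "mel", 0, 0, 4, 2)], {"g1": "other"})
        beta, flags = mk.closed_form_beta(ds, mk.PartitionModel.single(), alpha=1.0)
        assert beta[0] == pytest.approx(2.0)

    def test_pooled_equal_counts_give_reciprocal_alpha(self):
        ds = mk.dataset_from_records([("g1", "mel", 5, 5, 7, 7)], {"g1": "other"})
        beta, _ = mk.closed_form_beta(ds, mk.PartitionModel.single(), alpha=0.4)
        assert beta[0] == pytest.approx(1 / 0.4)

    def test_self_consistency_of_global_fit(self, structured_dataset):
        """Fitting a single modifier at the dataset's own baseline odds
        returns exactly 1: the baseline is the pooled ML."""
        fit = mk.fit_model(structured_dataset, mk.PartitionModel.single())
        assert fit.beta[0] == pytest.approx(1.0, rel=1e-12)

    def test_degenerate_pools_flagged(self):
        ds = mk.dataset_from_records(
            [("g1", "mel", 3, 0, 0, 0), ("g2", "ana", 0, 0, 0, 0)],
            {"g1": "other", "g2": "other"},
        )
        model = mk.PartitionModel("by-species", [
            mk.Rule.make("mel", species="mel"), mk.Rule.make("ana"),
        ])
        beta, flags = mk.closed_form_beta(ds, model, alpha=1.0)
        assert flags == (FLAG_UNBOUNDED, FLAG_UNINFORMATIVE)
        assert np.isinf(beta[0]) and beta[1] == 1.0


class TestFitModel:
    def test_toy_fit_matches_worked_example(self, toy_dataset):
        # alpha chosen so that beta_hat * alpha = 2 reproduces the
        # single-informative-gene likelihood (g2 contributes 0);
        # divergence and polymorphism pools differ, so use one parameter
        ds = mk.dataset_from_records([("g1", "mel", 0, 0, 4, 2)], {"g1": "other"})
        fit = mk.fit_model(ds, mk.PartitionModel.single(), alpha=0.5)
        assert fit.beta[0] * fit.alpha == pytest.approx(2.0)
        assert fit.loglik == pytest.approx(WORKED_EXAMPLE_LOGLIK, abs=1e-10)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_numerical_matches_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_small_dataset(rng)
        model = mk.PartitionModel("ctx", [
            mk.Rule.make("div", context="divergence"),
            mk.Rule.make("poly"),
        ])
        cf = mk.fit_model(ds, model, method="closed_form")
        num = mk.fit_model(ds, model, method="numerical")
        for k, flag in enumerate(cf.flags):
            if flag == FLAG_OK:
                assert num.beta[k] == pytest.approx(cf.beta[k], rel=1e-6)

    def test_nesting_monotonicity(self, structured_dataset):
        coarse = mk.fit_model(structured_dataset, mk.PartitionModel.single())
        by_ctx = mk.fit_model(structured_dataset, mk.PartitionModel("ctx", [
            mk.Rule.make("div", context="divergence"), mk.Rule.make("poly"),
        ]))
        full = mk.fit_model(structured_dataset, mk.full_model(structured_dataset))
        assert coarse.loglik <= by_ctx.loglik <= full.loglik

    def test_invariance_to_gene_order_and_split(self):
        """Reordering genes, or splitting one gene's counts into two genes
        in the same cell, leaves beta_hat and between-model log-likelihood
        differences unchanged."""
        records = [("g1", "mel", 6, 4, 10, 8), ("g2", "mel", 2, 2, 4, 6)]
        classes = {"g1": "piRNA", "g2": "other"}
        ds = mk.dataset_from_records(records, classes)
        ds_reordered = mk.dataset_from_records(records[::-1], classes)
        ds_split = mk.dataset_from_records(
            [("g1a", "mel", 3, 1, 6, 3), ("g1b", "mel", 3, 3, 4, 5),
             ("g2", "mel", 2, 2, 4, 6)],
            {"g1a": "piRNA", "g1b": "piRNA", "g2": "other"},
        )
        single = mk.PartitionModel.single()
        by_ctx = mk.PartitionModel("ctx", [
            mk.Rule.make("div", context="divergence"), mk.Rule.make("poly"),
        ])
        fits = {name: (mk.fit_model(d, single, alpha=0.5),
                       mk.fit_model(d, by_ctx, alpha=0.5))
                for name, d in [("base", ds), ("reordered", ds_reordered),
                                ("split", ds_split)]}
        base_s, base_c = fits["base"]
        for name in ("reordered", "split"):
            s, c = fits[name]
            np.testing.assert_allclose(s.beta, base_s.beta, rtol=1e-12)
            np.testing.assert_allclose(c.beta, base_c.beta, rtol=1e-12)
            # LRT statistic depends only on the loglik difference
            assert (c.loglik - s.loglik) == pytest.approx(
                base_c.loglik - base_s.loglik, abs=1e-9
            )

    def test_unassigned_cell_is_error(self, toy_dataset):
        model = mk.PartitionModel("partial", [
            mk.Rule.make("div", context="divergence"),
        ])
        with pytest.raises(ValueError, match="no parameter"):
            mk.fit_model(toy_dataset, model)
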