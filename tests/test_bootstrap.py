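import numpy as np
import pandas as pd
import pytest

import mknest as mk
from mknest.bootstrap import _fast_resample_pools


def _tiny_dataset():
    return mk.dataset_from_records(
        [("p1", "mel", 4, 2, 6, 8), ("o1", "mel", 3, 5, 10, 12)],
        {"p1": "piRNA", "o1": "other"},
    )


class TestResampleDataset:
    def test_singleton_strata_reproduce_input(self):
        ds = _tiny_dataset()
        rep = mk.resample_dataset(ds, np.random.default_rng(0))
        orig = ds.counts[["dn", "ds", "pn", "ps"]].sort_values(["dn"]).to_numpy()
        new = rep.counts[["dn", "ds", "pn", "ps"]].sort_values(["dn"]).to_numpy()
        np.testing.assert_array_equal(orig, new)

    def test_stratum_sizes_preserved(self, structured_dataset):
        rep = mk.resample_dataset(structured_dataset, np.random.default_rng(1))
        for gc in ("piRNA", "other"):
            orig = (structured_dataset.gene_classes() == gc).sum()
            new = (rep.gene_classes() == gc).sum()
            assert new == orig
        assert len(rep.counts) == len(structured_dataset.counts)

    def test_genes_carry_all_species_rows(self, structured_dataset):
        rep = mk.resample_dataset(structured_dataset, np.random.default_rng(2))
        per_gene = rep.counts.groupby("gene_id")["species"].nunique()
        assert (per_gene == len(structured_dataset.species_list)).all()

    def test_fast_pool_path_matches_explicit_resampling(self, structured_dataset):
        """The weighted-pool shortcut used inside the bootstrap gives the
        same pooled cell counts as physically rebuilding the replicate
        dataset from the same random draws."""
        ds = structured_dataset
        model = mk.full_model(ds)
        obs = ds.observations()
        assignment = model.assign(obs)
        gene_ids = pd.unique(obs["gene_id"])
        gid_index = pd.Series(np.arange(len(gene_ids)), index=gene_ids)
        gene_index = obs["gene_id"].map(gid_index).to_numpy()
        cls = ds.gene_classes()
        strata = [gid_index[sorted(cls.index[cls == gc])].to_numpy()
                  for gc in ("piRNA", "other")]
        ns_fast, s_fast = _fast_resample_pools(
            obs, assignment, model.K, gene_index, strata,
            np.random.default_rng(42),
        )
        rep = mk.resample_dataset(ds, np.random.default_rng(42))
        for k, pname in enumerate(model.param_names):
            sp, ctx, gc = pname.split(".")
            ctx = "divergence" if ctx == "div" else "polymorphism"
            ns, s = rep.pool_counts(mk.Cell(sp, ctx, gc))
            assert ns == ns_fast[k]
            assert s == s_fast[k]

    def test_empty_stratum_rejected(self):
        ds = mk.dataset_from_records(
            [("o1", "mel", 1, 1, 1, 1)], {"o1": "other"}
        )
        with pytest.raises(ValueError, match="stratum"):
            mk.resample_dataset(ds, np.random.default_rng(0))

    def test_replicate_mean_matches_original_pool(self, structured_dataset):
        """Bootstrap mean of the pooled piRNA divergence NS count matches
        the original pool within 3 standard errors over 2,000 replicates."""
        ds = structured_dataset
        model = mk.full_model(ds)
        obs = ds.observations()
        assignment = model.assign(obs)
        gene_ids = pd.unique(obs["gene_id"])
        gid_index = pd.Series(np.arange(len(gene_ids)), index=gene_ids)
        gene_index = obs["gene_id"].map(gid_index).to_numpy()
        cls = ds.gene_classes()
        strata = [gid_index[sorted(cls.index[cls == gc])].to_numpy()
                  for gc in ("piRNA", "other")]
        k = model.param_names.index("mel.div.piRNA")
        rng = np.random.default_rng(7)
        draws = np.array([
            _fast_resample_pools(obs, assignment, model.K, gene_index,
                                 strata, rng)[0][k]
            for _ in range(2000)
        ])
        target, _ = ds.pool_counts(mk.Cell("mel", "divergence", "piRNA"))
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - target) < 3 * se + 1e-9


class TestSignPvalue:
    def test_unanimous_support_gives_zero(self):
        assert mk.sign_pvalue([0.5, 1.2, 0.1], 2.0) == 0.0

    def test_direct_count(self):
        assert mk.sign_pvalue([+1, -1, +1, +1], +0.5) == pytest.approx(0.25)

    def test_zero_replicates_count_as_opposing(self):
        assert mk.sign_pvalue([+1, 0.0, +1, +1], +0.5) == pytest.approx(0.25)

    def test_zero_observed_contrast_rejected(self):
        with pytest.raises(ValueError):
            mk.sign_pvalue([1.0, -1.0], 0.0)


class TestBootstrapStatistics:
    def test_reproducible_given_seed(self, structured_dataset):
        kw = dict(model=mk.preset_model("selected9"), B=50, seed=9)
        r1 = mk.bootstrap_statistics(structured_dataset, **kw)
        r2 = mk.bootstrap_statistics(structured_dataset, **kw)
        pd.testing.assert_frame_equal(r1.replicate_zeta, r2.replicate_zeta)
        pd.testing.assert_frame_equal(r1.contrasts, r2.contrasts)

    def test_replicate_arrays_have_length_B(self, structured_dataset):
        res = mk.bootstrap_statistics(
            structured_dataset, model_mode="full", B=25, seed=3
        )
        assert len(res.replicate_chi) == 25
        assert len(res.replicate_zeta) == 25
        assert ((res.contrasts["p_value"] >= 0) & (res.contrasts["p_value"] <= 1)).all()

    def test_point_estimates_match_direct_fit(self, structured_dataset):
        model = mk.preset_model("selected9")
        res = mk.bootstrap_statistics(structured_dataset, model=model, B=1, seed=0)
        fit = mk.fit_model(structured_dataset, model)
        for sp in structured_dataset.species_list:
            assert res.point_zeta[sp] == pytest.approx(mk.zeta_statistic(fit, sp))
            assert res.point_chi[sp] == pytest.approx(mk.chi_statistic(fit, sp))

    def test_p_decreases_with_effect_size(self):
        """A strong true mel-vs-ana divergence contrast earns a smaller
        sign p-value than no contrast."""
        common = dict(n_pirna=31, n_other=269,
                      mean_counts={"divergence": 12.0, "polymorphism": 20.0})
        strong = mk.simulate_dataset(mk.SimulationSpec(
            seed=11, beta={("mel", "divergence", "piRNA"): 4.0,
                           ("ana", "divergence", "piRNA"): 1.0}, **common))
        null = mk.simulate_dataset(mk.SimulationSpec(seed=11, **common))

        def zeta_p(ds):
            res = mk.bootstrap_statistics(ds, model_mode="full", B=500, seed=5)
            row = res.contrasts.query(
                "statistic == 'zeta' and species_a == 'mel' and species_b == 'ana'"
            )
            return float(row["p_value"].iloc[0]) if len(row) else 0.5

        p_strong, p_null = zeta_p(strong), zeta_p(null)
        assert p_strong < 0.05
        assert p_strong <= p_null

    def test_degenerate_replicates_dropped_and_counted(self):
        # one piRNA gene with synonymous divergence, one without: about a
        # quarter of replicates draw only the zero gene twice and lose
        # the piRNA divergence odds
        ds = mk.dataset_from_records(
            [("p1", "mel", 4, 2, 6, 8), ("p2", "mel", 0, 0, 5, 5),
             ("o1", "mel", 3, 5, 10, 12), ("o2", "mel", 4, 4, 9, 9)],
            {"p1": "piRNA", "p2": "piRNA", "o1": "other", "o2": "other"},
        )
        res = mk.bootstrap_statistics(ds, model_mode="full", B=400, seed=1)
        assert res.n_dropped > 0
        assert res.replicate_zeta["mel"].isna().sum() == res.n_dropped

    def test_exchangeable_null_p_distribution(self):
        """When two species are simulated identically, the sign p-value is
        approximately Uniform(0, 1/2) over meta-replicates (mean 1/4): the
        tested direction is set by the observed contrast, so under the
        null p ~ min(U, 1-U)."""
        ps = []
        for meta_seed in range(12):
            ds = mk.simulate_dataset(mk.SimulationSpec(
                n_pirna=31, n_other=169, seed=1000 + meta_seed,
                mean_counts={"divergence": 10.0, "polymorphism": 15.0},
            ))
            res = mk.bootstrap_statistics(ds, model_mode="full", B=200,
                                          seed=meta_seed)
            row = res.contrasts.query(
                "statistic == 'zeta' and species_a == 'mel' and species_b == 'ana'"
            )
            if len(row):
                ps.append(float(row["p_value"].iloc[0]))
        assert 0.15 < float(np.mean(ps)) < 0.35
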