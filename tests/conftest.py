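import io

import numpy as np
import pandas as pd
import pytest

import mknest as mk

TOY_COUNTS = (
    "gene_id\tspecies\tdn\tds\tpn\tps\n"
    "g1\tmel\t4\t2\t1\t1\n"
    "g2\tmel\t0\t0\t0\t0\n"
)
TOY_CLASSES = "gene_id\tgene_class\ng1\tpiRNA\ng2\tother\n"


@pytest.fixture
def toy_dataset() -> mk.CountDataset:
    return mk.read_variant_table(io.StringIO(TOY_COUNTS), io.StringIO(TOY_CLASSES))


@pytest.fixture(scope="session")
def null_dataset() -> mk.CountDataset:
    """Medium synthetic dataset with no structure (all true beta = 1)."""
    spec = mk.SimulationSpec(
        n_pirna=31, n_other=269, seed=101,
        mean_counts={"divergence": 10.0, "polymorphism": 20.0},
    )
    return mk.simulate_dataset(spec)


@pytest.fixture(scope="session")
def structured_dataset() -> mk.CountDataset:
    """Synthetic dataset with strong species x context x class structure."""
    spec = mk.SimulationSpec(
        n_pirna=31, n_other=769, seed=202,
        beta={
            ("mel", "divergence", "piRNA"): 3.5,
            ("mel", "divergence", "other"): 1.2,
            ("ana", "divergence", "piRNA"): 1.3,
            ("wil", "divergence", "piRNA"): 1.3,
            ("ana", "divergence", "other"): 0.7,
            ("wil", "divergence", "other"): 0.5,
            ("mel", "polymorphism", "piRNA"): 2.7,
            ("ana", "polymorphism", "piRNA"): 2.7,
            ("wil", "polymorphism", "piRNA"): 2.7,
            ("mel", "polymorphism", "other"): 1.1,
            ("ana", "polymorphism", "other"): 1.2,
            ("wil", "polymorphism", "other"): 1.13,
        },
        mean_counts={"divergence": 12.0, "polymorphism": 25.0},
    )
    return mk.simulate_dataset(spec)


@pytest.fixture(scope="session")
def null_lrt_pvalues() -> np.ndarray:
    """LRT p-values from 500 null simulations (single true beta, df = 1).

    Each dataset has 200 genes with mean total counts >= 20 per gene;
    the tested split (divergence vs polymorphism) adds one parameter to
    the single-modifier baseline.
    """
    spec = mk.SimulationSpec(
        n_pirna=31, n_other=169, seed=77,
        mean_counts={"divergence": 10.0, "polymorphism": 12.0},
    )
    base = mk.PartitionModel.single()
    split = mk.PartitionModel("by-context", [
        mk.Rule.make("div", context="divergence"),
        mk.Rule.make("poly", context="polymorphism"),
    ])
    pvals = []
    for ds in mk.simulate_null_ladder_inputs(spec, 500):
        a = ds.alpha
        lrt = mk.likelihood_ratio_test(
            mk.fit_model(ds, base, alpha=a), mk.fit_model(ds, split, alpha=a)
        )
        pvals.append(lrt.p_value)
    return np.asarray(pvals)


def random_small_dataset(rng: np.random.Generator) -> mk.CountDataset:
    """Small random dataset for property tests (5-20 genes, 1-3 species)."""
    n_species = int(rng.integers(1, 4))
    species = [f"sp{i}" for i in range(n_species)]
    n_genes = int(rng.integers(5, 21))
    records, class_map = [], {}
    for g in range(n_genes):
        gid = f"g{g}"
        class_map[gid] = "piRNA" if rng.random() < 0.3 else "other"
        for sp in species:
            dn, ds, pn, ps = rng.poisson([3.0, 6.0, 5.0, 12.0])
            records.append((gid, sp, int(dn), int(ds), int(pn), int(ps)))
    return mk.dataset_from_records(records, class_map)
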