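"""Synthetic count datasets with the generative structure the model assumes.

Per gene and context a total variant count N is drawn (negative binomial
by default, realised as a gene-specific Gamma intensity shared across
species and contexts, times a context mean, fed to a Poisson — giving
the heavy-tailed per-gene counts seen in real variant tables), then the
nonsynonymous count NS ~ Binomial(N, P) with
P = beta*alpha / (beta*alpha + 1) for the observation's cell, and
S = N - NS.  The generator is the exact inverse of the fitted
likelihood, so fitted modifiers converge to the generative truth as
pooled counts grow.

Default dimensions mirror the study design: three species, 31 piRNA
machinery genes (11 nuclear, 20 cytoplasmic) among 8,747 orthologs, and
baseline odds alpha = 0.308.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

import numpy as np
import pandas as pd

from .count_data import CountDataset

DEFAULT_SPECIES = ("mel", "ana", "wil")
N_PIRNA_DEFAULT = 31
N_NUCLEAR_DEFAULT = 11  # remainder cytoplasmic
N_OTHER_DEFAULT = 8_716  # 8,747 orthologs minus the 31 piRNA genes
ALPHA_DEFAULT = 0.308


@dataclass
class SimulationSpec:
    """Generative truth for one synthetic dataset.

    ``beta`` maps cells to true modifiers with hierarchical fallback:
    the most specific matching key wins, searched as
    (species, context, gene_class, compartment), then
    (species, context, gene_class), (species, context), (context,),
    and finally default 1.0.
    """

    species: tuple[str, ...] = DEFAULT_SPECIES
    n_pirna: int = N_PIRNA_DEFAULT
    n_other: int = N_OTHER_DEFAULT
    n_nuclear: Optional[int] = None  # default: study proportion 11/31
    alpha: float = ALPHA_DEFAULT
    beta: Mapping[tuple, float] = field(default_factory=dict)
    # mean total variants per gene per species, by context; the real
    # tables carry far more polymorphic than divergent variants
    mean_counts: Mapping[str, float] = field(
        default_factory=lambda: {"divergence": 8.0, "polymorphism": 25.0}
    )
    count_family: str = "negbin"  # or "poisson"
    dispersion: float = 0.5  # Gamma shape = 1/dispersion; heavier tail when larger
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_pirna < 1 or self.n_other < 1:
            raise ValueError("need at least one gene per class")
        if self.n_nuclear is None:
            self.n_nuclear = round(
                self.n_pirna * N_NUCLEAR_DEFAULT / N_PIRNA_DEFAULT
            )
        if not 0 <= self.n_nuclear <= self.n_pirna:
            raise ValueError("n_nuclear must lie in [0, n_pirna]")
        if self.count_family not in ("negbin", "poisson"):
            raise ValueError(f"unknown count family {self.count_family!r}")
        if self.count_family == "negbin" and self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for key, b in dict(self.beta).items():
            if b <= 0:
                raise ValueError(f"true beta for {key} must be positive")
        for ctx, m in dict(self.mean_counts).items():
            if m < 0:
                raise ValueError(f"mean count for {ctx} must be >= 0")

    def true_beta(self, species: str, context: str, gene_class: str,
                  compartment: Optional[str] = None) -> float:
        for key in (
            (species, context, gene_class, compartment),
            (species, context, gene_class),
            (species, context),
            (context,),
        ):
            if key in self.beta:
                return float(self.beta[key])
        return 1.0


def _gene_table(spec: SimulationSpec) -> pd.DataFrame:
    rows = []
    for i in range(spec.n_pirna):
        rows.append(
            {
                "gene_id": f"pi{i:04d}",
                "gene_class": "piRNA",
                "compartment": "nuclear" if i < spec.n_nuclear else "cytoplasmic",
            }
        )
    for i in range(spec.n_other):
        rows.append({"gene_id": f"g{i:06d}", "gene_class": "other",
                     "compartment": pd.NA})
    return pd.DataFrame(rows)


def simulate_dataset(spec: SimulationSpec) -> CountDataset:
    """Draw one dataset under the spec's generative truth.

    Deterministic given ``spec.seed``; per-gene random streams are
    spawned from the master seed keyed by gene index, so gene g's counts
    do not change when genes are added after it.
    """
    genes = _gene_table(spec)
    master = np.random.SeedSequence(spec.seed)
    children = master.spawn(len(genes))
    records = []
    for (row, child) in zip(genes.itertuples(index=False), children):
        rng = np.random.default_rng(child)
        # gene-specific intensity shared across species and contexts
        if spec.count_family == "negbin":
            shape = 1.0 / spec.dispersion
            intensity = rng.gamma(shape, spec.dispersion)
        else:
            intensity = 1.0
        for sp in spec.species:
            counts = {}
            for context, (ns_col, s_col) in (
                ("divergence", ("dn", "ds")),
                ("polymorphism", ("pn", "ps")),
            ):
                mean = spec.mean_counts.get(context, 0.0) * intensity
                n = int(rng.poisson(mean)) if mean > 0 else 0
                b = spec.true_beta(sp, context, row.gene_class,
                                   None if pd.isna(row.compartment) else row.compartment)
                odds = b * spec.alpha
                p = odds / (odds + 1.0)
                ns = int(rng.binomial(n, p)) if n > 0 else 0
                counts[ns_col] = ns
                counts[s_col] = n - ns
            records.append({"gene_id": row.gene_id, "species": sp, **counts})
    counts_df = pd.DataFrame.from_records(
        records, columns=["gene_id", "species", "dn", "ds", "pn", "ps"]
    )
    return CountDataset(counts_df, genes)


def simulate_null_ladder_inputs(
    spec: SimulationSpec, n_datasets: int
) -> Iterator[CountDataset]:
    """Independent datasets for type-I-error calibration of the LRT.

    Each dataset is drawn under the spec as given (typically a single
    shared beta across the cells a tested split would separate), with
    per-dataset seeds spawned from ``spec.seed``.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    master = np.random.SeedSequence((spec.seed, 1))
    children = master.spawn(n_datasets)
    for child in children:
        sub = SimulationSpec(
            species=spec.species,
            n_pirna=spec.n_pirna,
            n_other=spec.n_other,
            n_nuclear=spec.n_nuclear,
            alpha=spec.alpha,
            beta=dict(spec.beta),
            mean_counts=dict(spec.mean_counts),
            count_family=spec.count_family,
            dispersion=spec.dispersion,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        yield simulate_dataset(sub)


def dominant_gene_dataset() -> CountDataset:
    """The aggregation thought experiment: one piRNA gene with 100
    divergent variants (75 nonsynonymous), thirty more with 2 each
    (1 nonsynonymous, 1 synonymous).  Pooled N:S divergence odds are
    dominated by the single large gene even though all other genes have
    odds 1."""
    records = []
    records.append(("piBig", "mel", 75, 25, 0, 0))
    for i in range(30):
        records.append((f"piSmall{i:02d}", "mel", 1, 1, 0, 0))
    # a background gene so both strata exist
    records.append(("gBack", "mel", 10, 10, 10, 10))
    counts = pd.DataFrame(
        records, columns=["gene_id", "species", "dn", "ds", "pn", "ps"]
    )
    cm = pd.DataFrame(
        {
            "gene_id": counts["gene_id"].unique(),
            "gene_class": ["piRNA"] * 31 + ["other"],
            "compartment": pd.NA,
        }
    )
    return CountDataset(counts, cm)
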