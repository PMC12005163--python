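"""Odds-ratio summary statistics and the weighted inverse neutrality index.

For each species two contrasts of the piRNA machinery against the
genomic background are defined from fitted (or pooled) N:S odds:

* chi: (divergence odds / polymorphism odds) of piRNA genes divided by
  the same ratio for other genes — an MK-style contrast normalised by
  the background.
* zeta: divergence odds of piRNA genes divided by divergence odds of
  other genes — the divergence-only contrast.

Both are ratios of beta*alpha products, so the baseline alpha cancels.

The neutrality index of a single gene is NI = (Pn/Ps)/(Dn/Ds); its
Tarone–Greenland weighted average over genes,
NI_TG = sum_i[Ds_i*Pn_i/(Ps_i+Ds_i)] / sum_i[Dn_i*Ps_i/(Ps_i+Ds_i)],
reduces the bias of summing sparse 2x2 tables.  The reciprocal 1/NI_TG
is reported here; values above 1 indicate an excess of nonsynonymous
divergence (positive selection).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .count_data import Cell, CountDataset
from .likelihood import FitResult


def _odds(fit: FitResult, species: str, context: str, gene_class: str,
          compartment: Optional[str] = None) -> float:
    cell = Cell(species=species, context=context, gene_class=gene_class,
                compartment=compartment)
    odds = fit.odds_for_cell(cell)
    if odds <= 0:
        raise ValueError(f"nonpositive fitted odds for cell {cell}")
    return odds


def zeta_statistic(fit: FitResult, species: str,
                   compartment: Optional[str] = None) -> float:
    """Divergence-only piRNA/other odds ratio for one species.

    With ``compartment`` given, the numerator is the divergence odds of
    that compartment of the piRNA machinery.
    """
    num = _odds(fit, species, "divergence", "piRNA", compartment)
    den = _odds(fit, species, "divergence", "other")
    return num / den


def chi_statistic(fit: FitResult, species: str) -> float:
    """(div/poly odds ratio of piRNA genes) / (same for other genes)."""
    pi = _odds(fit, species, "divergence", "piRNA") / _odds(
        fit, species, "polymorphism", "piRNA"
    )
    other = _odds(fit, species, "divergence", "other") / _odds(
        fit, species, "polymorphism", "other"
    )
    return pi / other


def _pooled_odds(dataset: CountDataset, cell: Cell) -> float:
    ns, s = dataset.pool_counts(cell)
    if s == 0:
        raise ValueError(f"pooled synonymous count is 0 for cell {cell}")
    return ns / s


def zeta_from_counts(dataset: CountDataset, species: str,
                     compartment: Optional[str] = None) -> float:
    """zeta computed directly from pooled counts (closed-form route)."""
    num = _pooled_odds(
        dataset, Cell(species, "divergence", "piRNA", compartment)
    )
    den = _pooled_odds(dataset, Cell(species, "divergence", "other"))
    return num / den


def chi_from_counts(dataset: CountDataset, species: str) -> float:
    """chi computed directly from pooled counts (closed-form route)."""
    pi = _pooled_odds(dataset, Cell(species, "divergence", "piRNA")) / _pooled_odds(
        dataset, Cell(species, "polymorphism", "piRNA")
    )
    other = _pooled_odds(dataset, Cell(species, "divergence", "other")) / _pooled_odds(
        dataset, Cell(species, "polymorphism", "other")
    )
    return pi / other


@dataclass
class NeutralityIndexResult:
    label: str
    value: float  # 1 / NI_TG
    n_genes: int  # genes contributing
    n_excluded: int  # genes with Ps + Ds = 0


def inverse_ni_tg(counts: pd.DataFrame, label: str = "") -> NeutralityIndexResult:
    """Reciprocal Tarone–Greenland weighted neutrality index of a gene set.

    ``counts`` holds one row per gene with columns dn, ds, pn, ps (one
    species, one gene class).  Genes with Ps + Ds = 0 carry no weight and
    are excluded (their number is reported).  The single-gene case with
    all counts positive reduces to (Dn/Ds)/(Pn/Ps).
    """
    w = counts["ps"] + counts["ds"]
    usable = w > 0
    n_excluded = int((~usable).sum())
    sub = counts.loc[usable]
    if len(sub) == 0:
        raise ValueError("no gene with Ps + Ds > 0")
    wd = sub["ps"] + sub["ds"]
    num = (sub["dn"] * sub["ps"] / wd).sum()  # divergence side
    den = (sub["ds"] * sub["pn"] / wd).sum()  # polymorphism side
    if num == 0:
        raise ValueError("inverse NI_TG undefined: weighted Dn*Ps sum is 0")
    return NeutralityIndexResult(
        label=label,
        value=float(num / den),
        n_genes=int(len(sub)),
        n_excluded=n_excluded,
    )


def inverse_ni_tg_table(dataset: CountDataset) -> pd.DataFrame:
    """1/NI_TG per species x gene class, with the piRNA/other ratio."""
    cls = dataset.gene_classes()
    rows = []
    for sp in dataset.species_list:
        sub = dataset.counts[dataset.counts["species"] == sp]
        values = {}
        for gc in ("piRNA", "other"):
            genes = sub[sub["gene_id"].map(cls) == gc]
            try:
                res = inverse_ni_tg(genes, label=f"{sp}/{gc}")
            except ValueError:
                res = None
            rows.append(
                {
                    "species": sp,
                    "gene_class": gc,
                    "inv_ni_tg": res.value if res else float("nan"),
                    "n_genes": res.n_genes if res else 0,
                    "n_excluded": res.n_excluded if res else len(genes),
                }
            )
            values[gc] = res.value if res else float("nan")
        rows.append(
            {
                "species": sp,
                "gene_class": "piRNA/other",
                "inv_ni_tg": values["piRNA"] / values["other"],
                "n_genes": 0,
                "n_excluded": 0,
            }
        )
    return pd.DataFrame(rows)
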