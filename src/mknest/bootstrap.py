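"""Stratified gene-wise bootstrap of the chi and zeta statistics.

Genes are resampled with replacement within their class stratum (piRNA
machinery and other genes separately), each drawn gene carrying all its
per-species rows jointly so cross-species gene effects are preserved.
For each replicate the chosen model structure is refitted (no
re-selection) and chi and zeta recorded per species; a between-species
contrast gets a sign-based p-value: the proportion of replicates whose
contrast opposes the direction observed on the unresampled data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .count_data import CountDataset
from .likelihood import PartitionModel, fit_model
from .summary_stats import chi_statistic, zeta_statistic

logger = logging.getLogger(__name__)


def resample_dataset(
    dataset: CountDataset,
    rng: np.random.Generator,
    per_species: bool = False,
) -> CountDataset:
    """One stratified gene-wise bootstrap replicate of a dataset.

    Draws genes with replacement within each gene-class stratum,
    preserving stratum sizes.  Each drawn gene carries all its rows
    (every species, all four counts) jointly; with ``per_species=True``
    genes are instead drawn independently within each species.
    Resampled genes receive unique synthetic ids so the replicate is
    itself a valid dataset.
    """
    cls = dataset.gene_classes()
    counts = dataset.counts
    cm = dataset.class_map.set_index("gene_id")

    new_counts, new_map = [], []
    serial = 0
    species_groups = [None] if not per_species else list(dataset.species_list)
    for gene_class in ("piRNA", "other"):
        stratum = sorted(cls.index[cls == gene_class])
        if not stratum:
            raise ValueError(f"empty stratum {gene_class!r}")
        for sp in species_groups:
            drawn = rng.integers(0, len(stratum), size=len(stratum))
            for j in drawn:
                gid = stratum[j]
                rows = counts[counts["gene_id"] == gid]
                if sp is not None:
                    rows = rows[rows["species"] == sp]
                new_id = f"bs{serial:06d}"
                serial += 1
                r = rows.copy()
                r["gene_id"] = new_id
                new_counts.append(r)
                new_map.append(
                    {
                        "gene_id": new_id,
                        "gene_class": gene_class,
                        "compartment": cm.loc[gid, "compartment"],
                    }
                )
    return CountDataset(
        pd.concat(new_counts, ignore_index=True), pd.DataFrame(new_map)
    )


def _fast_resample_pools(
    obs: pd.DataFrame,
    assignment: np.ndarray,
    K: int,
    gene_index: np.ndarray,
    strata: list[np.ndarray],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (NS, S) per parameter for one replicate without rebuilding
    the dataset: resampling genes with replacement is equivalent to
    weighting each gene by its multinomial draw count."""
    n_genes = int(gene_index.max()) + 1
    weights = np.zeros(n_genes, dtype=np.int64)
    for stratum in strata:
        drawn = stratum[rng.integers(0, len(stratum), size=len(stratum))]
        np.add.at(weights, drawn, 1)
    w_obs = weights[gene_index].astype(float)
    ns = np.bincount(assignment, weights=obs["ns"].to_numpy() * w_obs, minlength=K)
    s = np.bincount(assignment, weights=obs["s"].to_numpy() * w_obs, minlength=K)
    return ns, s


def sign_pvalue(replicate_contrasts: Sequence[float], observed_contrast: float) -> float:
    """Share of replicates whose contrast opposes the observed direction.

    Zero-valued replicate contrasts count as opposing (conservative).
    """
    if observed_contrast == 0:
        raise ValueError("observed contrast is 0: direction undefined")
    reps = np.asarray(replicate_contrasts, dtype=float)
    reps = reps[np.isfinite(reps)]
    if len(reps) == 0:
        raise ValueError("no valid replicate contrasts")
    if observed_contrast > 0:
        opposing = np.sum(reps <= 0)
    else:
        opposing = np.sum(reps >= 0)
    return float(opposing / len(reps))


@dataclass
class BootstrapResult:
    B: int
    seed: int
    model_mode: str
    species: tuple[str, ...]
    point_chi: dict
    point_zeta: dict
    replicate_chi: pd.DataFrame  # B rows x species
    replicate_zeta: pd.DataFrame
    contrasts: pd.DataFrame  # statistic, species_a, species_b, observed, p_value
    n_dropped: int = 0
    add_one_correction: bool = False
    notes: list[str] = field(default_factory=list)


def full_model(dataset: CountDataset) -> PartitionModel:
    """The saturated species x context x class partition (12 cells for
    three species)."""
    from .likelihood import Rule

    rules = []
    for sp in dataset.species_list:
        for ctx in ("divergence", "polymorphism"):
            for gc in ("piRNA", "other"):
                rules.append(
                    Rule.make(
                        f"{sp}.{'div' if ctx == 'divergence' else 'poly'}.{gc}",
                        species=sp, context=ctx, gene_class=gc,
                    )
                )
    return PartitionModel("full", rules)


def bootstrap_statistics(
    dataset: CountDataset,
    model: Optional[PartitionModel] = None,
    B: int = 10_000,
    seed: int = 0,
    model_mode: str = "selected",
    threshold: float = 0.05,
    add_one_correction: bool = False,
    per_species: bool = False,
) -> BootstrapResult:
    """Bootstrap distributions of chi and zeta and sign-based contrast
    p-values.

    ``model_mode="full"`` uses the saturated 12-parameter partition;
    ``"selected"`` refits the supplied ``model`` structure on every
    replicate without re-running model selection.  Deterministic given
    ``seed``.  Replicates where a required odds is unidentifiable
    (pooled synonymous count 0) are dropped and counted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if model_mode == "full":
        model = full_model(dataset)
    elif model is None:
        raise ValueError("model_mode='selected' requires a model")

    alpha = dataset.alpha
    species = tuple(dataset.species_list)
    point_fit = fit_model(dataset, model, alpha=alpha)
    point_chi = {sp: chi_statistic(point_fit, sp) for sp in species}
    point_zeta = {sp: zeta_statistic(point_fit, sp) for sp in species}

    # precompute structures for the weighted-pool fast path
    obs = dataset.observations()
    assignment = model.assign(obs)
    gene_ids = pd.unique(obs["gene_id"])
    gid_index = pd.Series(np.arange(len(gene_ids)), index=gene_ids)
    gene_index = obs["gene_id"].map(gid_index).to_numpy()
    cls = dataset.gene_classes()
    strata = [
        gid_index[sorted(cls.index[cls == gc])].to_numpy()
        for gc in ("piRNA", "other")
    ]
    if per_species:
        raise NotImplementedError(
            "per-species resampling requires resample_dataset; use it directly"
        )

    # map each (species, context, class) cell to its parameter index once
    from .count_data import Cell

    def cell_param(sp: str, ctx: str, gc: str) -> int:
        name = model.param_for_cell(Cell(sp, ctx, gc))
        return model.param_names.index(name)

    cell_idx = {
        (sp, ctx, gc): cell_param(sp, ctx, gc)
        for sp in species
        for ctx in ("divergence", "polymorphism")
        for gc in ("piRNA", "other")
    }

    rng = np.random.default_rng(seed)
    chi_rows, zeta_rows = [], []
    n_dropped = 0
    for _ in range(B):
        ns, s = _fast_resample_pools(obs, assignment, model.K, gene_index, strata, rng)
        if np.any(s[list(set(cell_idx.values()))] == 0):
            n_dropped += 1
            chi_rows.append({sp: np.nan for sp in species})
            zeta_rows.append({sp: np.nan for sp in species})
            continue
        odds = ns / s  # beta*alpha; alpha cancels in chi and zeta
        chi_rows.append(
            {
                sp: (
                    odds[cell_idx[(sp, "divergence", "piRNA")]]
                    / odds[cell_idx[(sp, "polymorphism", "piRNA")]]
                )
                / (
                    odds[cell_idx[(sp, "divergence", "other")]]
                    / odds[cell_idx[(sp, "polymorphism", "other")]]
                )
                for sp in species
            }
        )
        zeta_rows.append(
            {
                sp: odds[cell_idx[(sp, "divergence", "piRNA")]]
                / odds[cell_idx[(sp, "divergence", "other")]]
                for sp in species
            }
        )
    rep_chi = pd.DataFrame(chi_rows)
    rep_zeta = pd.DataFrame(zeta_rows)
    if n_dropped:
        logger.warning("dropped %d/%d replicates with unidentifiable odds",
                       n_dropped, B)

    contrast_rows = []
    for stat_name, point, reps in (
        ("chi", point_chi, rep_chi),
        ("zeta", point_zeta, rep_zeta),
    ):
        for i, a in enumerate(species):
            for b in species[i + 1:]:
                observed = point[a] - point[b]
                if observed == 0:
                    continue
                diffs = (reps[a] - reps[b]).to_numpy()
                p = sign_pvalue(diffs, observed)
                if add_one_correction:
                    valid = np.isfinite(diffs).sum()
                    p = (p * valid + 1) / (valid + 1)
                contrast_rows.append(
                    {
                        "statistic": stat_name,
                        "species_a": a,
                        "species_b": b,
                        "observed_a": point[a],
                        "observed_b": point[b],
                        "observed_contrast": observed,
                        "p_value": p,
                        "significant": p < threshold,
                    }
                )

    return BootstrapResult(
        B=B,
        seed=seed,
        model_mode=model_mode,
        species=species,
        point_chi=point_chi,
        point_zeta=point_zeta,
        replicate_chi=rep_chi,
        replicate_zeta=rep_zeta,
        contrasts=pd.DataFrame(contrast_rows),
        n_dropped=n_dropped,
        add_one_correction=add_one_correction,
    )
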