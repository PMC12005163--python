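"""Per-gene variant count tables and gene-class maps.

The data unit is one gene in one species with four nonnegative integer
counts: nonsynonymous divergence (Dn), synonymous divergence (Ds),
nonsynonymous polymorphism (Pn) and synonymous polymorphism (Ps).  A
dataset pools such rows over all genes and species, carries a map from
gene to gene class (piRNA machinery vs other genes, with an optional
nuclear/cytoplasmic compartment for piRNA genes), and exposes the global
baseline N:S odds alpha = (sum Dn + sum Pn) / (sum Ds + sum Ps).
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTEXTS = ("divergence", "polymorphism")
GENE_CLASSES = ("piRNA", "other")
COMPARTMENTS = ("nuclear", "cytoplasmic")

COUNT_COLUMNS = ("dn", "ds", "pn", "ps")


class ValidationError(ValueError):
    """Raised when a count table or class map violates its contract."""


@dataclass(frozen=True)
class Cell:
    """One partition element of the data.

    A (gene, species, context) observation belongs to exactly one cell,
    determined by the species, the context (divergence vs polymorphism),
    the gene class and, for piRNA genes when modelled, the compartment.
    """

    species: str
    context: str
    gene_class: Optional[str] = None
    compartment: Optional[str] = None

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.gene_class is not None and self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.gene_class!r}")
        if self.compartment is not None and self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")


class CountDataset:
    """Validated collection of per-gene, per-species variant counts.

    Parameters
    ----------
    counts
        DataFrame with columns ``gene_id, species, dn, ds, pn, ps``; one
        row per (gene, species), counts nonnegative integers.
    class_map
        DataFrame with columns ``gene_id, gene_class`` and optionally
        ``compartment`` (defined only for piRNA-class genes).
    """

    def __init__(self, counts: pd.DataFrame, class_map: pd.DataFrame):
        self.counts = _validate_counts(counts)
        self.class_map = _validate_class_map(class_map)
        missing = set(self.counts["gene_id"]) - set(self.class_map["gene_id"])
        if missing:
            raise ValidationError(
                f"{len(missing)} gene(s) missing from class map, e.g. "
                f"{sorted(missing)[:5]}"
            )
        extra = set(self.class_map["gene_id"]) - set(self.counts["gene_id"])
        if extra:
            logger.warning(
                "class map contains %d gene(s) absent from the count table; ignored",
                len(extra),
            )
            self.class_map = self.class_map[
                self.class_map["gene_id"].isin(set(self.counts["gene_id"]))
            ].reset_index(drop=True)
        self.species_list: tuple[str, ...] = tuple(
            pd.unique(self.counts["species"])
        )
        self._observations: Optional[pd.DataFrame] = None
        # warn (not error) about genes absent from some species
        per_gene = self.counts.groupby("gene_id")["species"].nunique()
        if per_gene.nunique() > 1:
            logger.warning(
                "gene coverage differs across species (%d genes not in all species)",
                int((per_gene < len(self.species_list)).sum()),
            )

    # ------------------------------------------------------------------
    @property
    def alpha(self) -> float:
        """Global baseline N:S odds pooled over everything."""
        return global_baseline_odds(self)

    @property
    def n_genes(self) -> int:
        return int(self.counts["gene_id"].nunique())

    def gene_classes(self) -> pd.Series:
        """gene_id -> gene_class."""
        return self.class_map.set_index("gene_id")["gene_class"]

    # ------------------------------------------------------------------
    def observations(self) -> pd.DataFrame:
        """Long table: one row per (gene, species, context).

        Columns: gene_id, species, context, gene_class, compartment,
        ns (nonsynonymous count), s (synonymous count), n (= ns + s).
        """
        if self._observations is None:
            cm = self.class_map.set_index("gene_id")
            merged = self.counts.merge(
                cm, left_on="gene_id", right_index=True, how="left"
            )
            frames = []
            for context, ns_col, s_col in (
                ("divergence", "dn", "ds"),
                ("polymorphism", "pn", "ps"),
            ):
                f = merged[["gene_id", "species", "gene_class", "compartment"]].copy()
                f["context"] = context
                f["ns"] = merged[ns_col].to_numpy()
                f["s"] = merged[s_col].to_numpy()
                frames.append(f)
            obs = pd.concat(frames, ignore_index=True)
            obs["n"] = obs["ns"] + obs["s"]
            self._observations = obs
        return self._observations

    def pool_counts(self, cell: Cell) -> tuple[int, int]:
        """Pooled (nonsynonymous, synonymous) totals for one cell.

        An empty cell pools to (0, 0).
        """
        obs = self.observations()
        mask = (obs["species"] == cell.species) & (obs["context"] == cell.context)
        if cell.gene_class is not None:
            mask &= obs["gene_class"] == cell.gene_class
        if cell.compartment is not None:
            mask &= obs["compartment"] == cell.compartment
        sub = obs.loc[mask]
        return int(sub["ns"].sum()), int(sub["s"].sum())

    def subset(
        self,
        species: Optional[Sequence[str]] = None,
        contexts: Optional[Sequence[str]] = None,
        gene_classes: Optional[Sequence[str]] = None,
    ) -> "CountDataset":
        """Restricted copy; dropped contexts have their counts zeroed.

        Zeroing (rather than deleting) a context keeps the row schema
        intact while contributing zero information to every likelihood
        (an observation with n = 0 has log-likelihood 0 by convention).
        """
        counts = self.counts.copy()
        if species is not None:
            counts = counts[counts["species"].isin(list(species))]
        if gene_classes is not None:
            keep = self.class_map.loc[
                self.class_map["gene_class"].isin(list(gene_classes)), "gene_id"
            ]
            counts = counts[counts["gene_id"].isin(set(keep))]
        if contexts is not None:
            if "divergence" not in contexts:
                counts[["dn", "ds"]] = 0
            if "polymorphism" not in contexts:
                counts[["pn", "ps"]] = 0
        counts = counts.reset_index(drop=True)
        cm = self.class_map[
            self.class_map["gene_id"].isin(set(counts["gene_id"]))
        ].reset_index(drop=True)
        return CountDataset(counts, cm)

    # ------------------------------------------------------------------
    def summary(self) -> dict:
        cls = self.gene_classes()
        totals = {
            sp: {
                c: int(self.counts.loc[self.counts["species"] == sp, c].sum())
                for c in COUNT_COLUMNS
            }
            for sp in self.species_list
        }
        return {
            "n_genes": self.n_genes,
            "n_piRNA": int((cls == "piRNA").sum()),
            "n_rows": int(len(self.counts)),
            "species": list(self.species_list),
            "per_species_totals": totals,
            "alpha": self.alpha,
        }

    def write_variant_table(self, path_or_buf) -> None:
        self.counts.to_csv(path_or_buf, sep="\t", index=False)

    def write_class_map(self, path_or_buf) -> None:
        self.class_map.to_csv(path_or_buf, sep="\t", index=False)

    def write_summary(self, path_or_buf) -> None:
        text = json.dumps(self.summary(), indent=2)
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)


# ----------------------------------------------------------------------
def global_baseline_odds(dataset: CountDataset) -> float:
    """(sum Dn + sum Pn) / (sum Ds + sum Ps) over all rows and species."""
    c = dataset.counts
    num = int(c["dn"].sum() + c["pn"].sum())
    den = int(c["ds"].sum() + c["ps"].sum())
    if den == 0:
        raise ValidationError("baseline odds undefined: no synonymous variants")
    return num / den


def _validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    required = ["gene_id", "species", *COUNT_COLUMNS]
    missing = [c for c in required if c not in counts.columns]
    if missing:
        raise ValidationError(f"count table missing columns {missing}")
    counts = counts[required].copy()
    counts["gene_id"] = counts["gene_id"].astype(str)
    counts["species"] = counts["species"].astype(str)
    for c in COUNT_COLUMNS:
        col = counts[c]
        arr = np.asarray(col)
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError(f"column {c} is not numeric")
        if np.any(arr != np.floor(arr)) or np.any(~np.isfinite(arr.astype(float))):
            bad = counts.loc[arr != np.floor(arr)].head(1)
            raise ValidationError(f"non-integer count in column {c}: {bad.to_dict('records')}")
        if np.any(arr < 0):
            bad = counts.loc[arr < 0].head(1)
            raise ValidationError(f"negative count in column {c}: {bad.to_dict('records')}")
        counts[c] = arr.astype(np.int64)
    dup = counts.duplicated(subset=["gene_id", "species"])
    if dup.any():
        rows = counts.loc[dup, ["gene_id", "species"]].head(3)
        raise ValidationError(f"duplicate (gene, species) rows: {rows.to_dict('records')}")
    return counts.reset_index(drop=True)


def _validate_class_map(class_map: pd.DataFrame) -> pd.DataFrame:
    if "gene_id" not in class_map.columns or "gene_class" not in class_map.columns:
        raise ValidationError("class map needs gene_id and gene_class columns")
    cm = class_map.copy()
    cm["gene_id"] = cm["gene_id"].astype(str)
    cm["gene_class"] = cm["gene_class"].astype(str)
    if "compartment" not in cm.columns:
        cm["compartment"] = pd.NA
    cm["compartment"] = cm["compartment"].replace({"": pd.NA, "NA": pd.NA})
    bad_class = set(cm["gene_class"]) - set(GENE_CLASSES)
    if bad_class:
        raise ValidationError(f"unknown gene class label(s) {sorted(bad_class)}")
    has_comp = cm["compartment"].notna()
    bad_comp = set(cm.loc[has_comp, "compartment"]) - set(COMPARTMENTS)
    if bad_comp:
        raise ValidationError(f"unknown compartment label(s) {sorted(bad_comp)}")
    misplaced = has_comp & (cm["gene_class"] != "piRNA")
    if misplaced.any():
        raise ValidationError(
            "compartment labels are only valid for piRNA-class genes: "
            f"{cm.loc[misplaced, 'gene_id'].tolist()[:5]}"
        )
    if cm["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene_id in class map")
    return cm[["gene_id", "gene_class", "compartment"]].reset_index(drop=True)


def read_variant_table(
    source: Union[str, io.TextIOBase],
    class_map_source: Union[str, io.TextIOBase],
    column_map: Optional[Mapping[str, str]] = None,
    class_column_map: Optional[Mapping[str, str]] = None,
) -> CountDataset:
    """Read a TSV variant count table and class map into a dataset.

    ``column_map`` renames nonstandard headers to the canonical
    ``gene_id, species, dn, ds, pn, ps`` (and ``gene_id, gene_class,
    compartment`` for the class map).
    """
    counts = pd.read_csv(source, sep="\t")
    if column_map:
        counts = counts.rename(columns=dict(column_map))
    cm = pd.read_csv(class_map_source, sep="\t")
    if class_column_map:
        cm = cm.rename(columns=dict(class_column_map))
    return CountDataset(counts, cm)


def dataset_from_records(
    records: Iterable[tuple], class_map: Mapping[str, str],
    compartments: Optional[Mapping[str, str]] = None,
) -> CountDataset:
    """Convenience constructor from (gene, species, dn, ds, pn, ps) tuples."""
    counts = pd.DataFrame(
        list(records), columns=["gene_id", "species", *COUNT_COLUMNS]
    )
    cm = pd.DataFrame(
        {
            "gene_id": list(class_map),
            "gene_class": [class_map[g] for g in class_map],
            "compartment": [
                (compartments or {}).get(g, pd.NA) for g in class_map
            ],
        }
    )
    return CountDataset(counts, cm)
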