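"""Nested likelihood-ratio tests and the stepwise model-selection ladder.

A richer model refines a nested one when every parameter class of the
richer model lies wholly inside one class of the nested model.  The test
statistic is 2*(loglik_richer - loglik_nested), compared to the upper
tail of a chi-squared distribution with degrees of freedom equal to the
number of extra (identifiable) parameters.

The ladder walks tiers of increasingly rich candidate models: at each
tier the candidate with the highest likelihood is tested against the
current selection and adopted if significant, mirroring stepwise
forward selection over data partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .count_data import CountDataset
from .likelihood import FLAG_OK, FitResult, PartitionModel, fit_model

logger = logging.getLogger(__name__)


class NestingError(ValueError):
    """Raised when an LRT is requested between non-nested models."""


def is_refinement(richer: FitResult, nested: FitResult) -> bool:
    """True when the richer fit's partition refines the nested fit's.

    Checked structurally on the observation assignments: each richer
    parameter's observations must all fall in a single nested parameter.
    """
    a, b = nested.assignment, richer.assignment
    if len(a) != len(b):
        return False
    for k in range(richer.K):
        parents = np.unique(a[b == k])
        if len(parents) > 1:
            return False
    return True


@dataclass
class LRTResult:
    nested_fit: FitResult
    richer_fit: FitResult
    statistic: float
    df: int
    p_value: float

    def row(self) -> dict:
        return {
            "nested": self.nested_fit.model.name,
            "richer": self.richer_fit.model.name,
            "K_nested": self.nested_fit.K,
            "K_richer": self.richer_fit.K,
            "loglik_nested": self.nested_fit.loglik,
            "loglik_richer": self.richer_fit.loglik,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
        }


def likelihood_ratio_test(nested: FitResult, richer: FitResult) -> LRTResult:
    """LRT of a richer partition against a nested one.

    Degrees of freedom count identifiable parameters only; flagged
    (uninformative/unbounded) parameters added by the richer model are
    excluded with a loud warning.
    """
    if abs(nested.alpha - richer.alpha) > 1e-12:
        raise ValueError("fits use different baseline odds alpha")
    if not is_refinement(richer, nested):
        raise NestingError(
            f"model {richer.model.name!r} does not refine {nested.model.name!r}"
        )
    df = richer.n_identifiable - nested.n_identifiable
    if richer.n_identifiable < richer.K or nested.n_identifiable < nested.K:
        logger.warning(
            "LRT %s vs %s: unidentifiable parameters excluded from df "
            "(richer %d/%d, nested %d/%d identifiable)",
            richer.model.name, nested.model.name,
            richer.n_identifiable, richer.K,
            nested.n_identifiable, nested.K,
        )
    if df < 1:
        raise ValueError(
            f"invalid LRT: {df} additional identifiable parameter(s)"
        )
    statistic = 2.0 * (richer.loglik - nested.loglik)
    if statistic < 0:
        if statistic < -1e-9:
            raise ValueError(
                f"negative LRT statistic {statistic}: fits inconsistent"
            )
        statistic = 0.0
    p = float(stats.chi2.sf(statistic, df))
    return LRTResult(nested, richer, statistic, df, p)


@dataclass
class Ladder:
    """Ordered tiers of candidate models, from coarse to fine."""

    name: str
    tiers: Sequence[Sequence[PartitionModel]]

    def __post_init__(self) -> None:
        if not self.tiers or not self.tiers[0]:
            raise ValueError("ladder needs at least one non-empty tier")


@dataclass
class LadderStep:
    tier: int
    candidates: list[str]
    best_candidate: str
    lrt: Optional[LRTResult]
    accepted: bool
    note: str = ""


@dataclass
class LadderReport:
    ladder_name: str
    threshold: float
    steps: list[LadderStep] = field(default_factory=list)
    selected: Optional[FitResult] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            row = {"tier": s.tier, "best_candidate": s.best_candidate,
                   "accepted": s.accepted, "note": s.note}
            if s.lrt is not None:
                row.update(s.lrt.row())
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "ladder": self.ladder_name,
            "threshold": self.threshold,
            "selected_model": self.selected.model.name if self.selected else None,
            "selected_K": self.selected.K if self.selected else None,
            "selected_loglik": self.selected.loglik if self.selected else None,
            "steps": self.to_frame().to_dict("records"),
        }


def run_ladder(
    dataset: CountDataset,
    ladder: Ladder,
    threshold: float = 0.05,
    alpha: Optional[float] = None,
    method: str = "closed_form",
) -> LadderReport:
    """Stepwise forward selection over the ladder's tiers.

    Tier 0 seeds the selection with its highest-likelihood model.  At
    each later tier every candidate refining the current selection is
    fitted; the best (highest log-likelihood, ties broken by model name)
    is LRT-tested against the current selection and adopted when
    p < threshold, otherwise the walk stops.  Candidates that do not
    refine the current selection are recorded and skipped.
    """
    if alpha is None:
        alpha = dataset.alpha
    report = LadderReport(ladder_name=ladder.name, threshold=threshold)

    tier0 = [fit_model(dataset, m, alpha=alpha, method=method)
             for m in ladder.tiers[0]]
    tier0.sort(key=lambda f: (-f.loglik, f.model.name))
    current = tier0[0]
    report.steps.append(
        LadderStep(
            tier=0,
            candidates=[m.name for m in ladder.tiers[0]],
            best_candidate=current.model.name,
            lrt=None,
            accepted=True,
            note="baseline tier",
        )
    )

    for t, tier in enumerate(ladder.tiers[1:], start=1):
        fits, skipped = [], []
        for m in tier:
            f = fit_model(dataset, m, alpha=alpha, method=method)
            if is_refinement(f, current):
                fits.append(f)
            else:
                skipped.append(m.name)
        if not fits:
            report.steps.append(
                LadderStep(
                    tier=t,
                    candidates=[m.name for m in tier],
                    best_candidate="",
                    lrt=None,
                    accepted=False,
                    note="no candidate refines current selection",
                )
            )
            break
        fits.sort(key=lambda f: (-f.loglik, f.model.name))
        best = fits[0]
        lrt = likelihood_ratio_test(current, best)
        accepted = lrt.p_value < threshold
        note = f"skipped (non-refining): {','.join(skipped)}" if skipped else ""
        report.steps.append(
            LadderStep(
                tier=t,
                candidates=[m.name for m in tier],
                best_candidate=best.model.name,
                lrt=lrt,
                accepted=accepted,
                note=note,
            )
        )
        if not accepted:
            break
        current = best

    report.selected = current
    return report
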