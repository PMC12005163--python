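"""Binomial likelihood of N:S counts under baseline odds and modifiers.

Each (gene, species, context) observation contributes a binomial term:
given n = NS + S total variants, the nonsynonymous count NS is binomial
with success probability P = beta*alpha / (beta*alpha + 1), where alpha
is the global baseline N:S odds and beta the modifier of the cell the
observation falls in.  Observations with n = 0 carry no information and
contribute log-likelihood 0 by convention.

Because every observation sharing a modifier shares the same success
probability, the ML of each modifier has the closed form
beta_hat = (pooled NS / pooled S) / alpha; numerical optimisation on
log(beta) is kept as an independent route and must agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .count_data import Cell, CountDataset

logger = logging.getLogger(__name__)

# per-parameter identifiability flags
FLAG_OK = "ok"
FLAG_UNINFORMATIVE = "uninformative"  # pooled NS = S = 0; beta reported as 1
FLAG_UNBOUNDED = "unbounded"  # pooled S = 0, NS > 0; beta reported as +inf

_WILDCARD = "*"


def _as_set(value) -> Optional[frozenset]:
    if value is None or value == _WILDCARD:
        return None
    if isinstance(value, str):
        return frozenset([value])
    return frozenset(value)


@dataclass(frozen=True)
class Rule:
    """One cell-selector -> parameter-name mapping; None matches anything."""

    param: str
    species: Optional[frozenset] = None
    context: Optional[frozenset] = None
    gene_class: Optional[frozenset] = None
    compartment: Optional[frozenset] = None

    @classmethod
    def make(cls, param: str, species=None, context=None, gene_class=None,
             compartment=None) -> "Rule":
        return cls(
            param=param,
            species=_as_set(species),
            context=_as_set(context),
            gene_class=_as_set(gene_class),
            compartment=_as_set(compartment),
        )

    def mask(self, obs: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(obs), dtype=bool)
        if self.species is not None:
            m &= obs["species"].isin(self.species).to_numpy()
        if self.context is not None:
            m &= obs["context"].isin(self.context).to_numpy()
        if self.gene_class is not None:
            m &= obs["gene_class"].isin(self.gene_class).to_numpy()
        if self.compartment is not None:
            m &= obs["compartment"].isin(self.compartment).to_numpy()
        return m

    def matches_cell(self, cell: Cell) -> bool:
        for attr in ("species", "context", "gene_class", "compartment"):
            sel = getattr(self, attr)
            val = getattr(cell, attr)
            if sel is not None and val not in sel:
                return False
        return True


class PartitionModel:
    """Assignment of every data cell to one modifier parameter.

    Built from an ordered list of selector rules; the first rule matching
    an observation's cell wins.  Parameter order follows first appearance
    in the rule list.
    """

    def __init__(self, name: str, rules: Sequence[Rule]):
        if not rules:
            raise ValueError("a model needs at least one rule")
        self.name = name
        self.rules = tuple(rules)
        seen: list[str] = []
        for r in self.rules:
            if r.param not in seen:
                seen.append(r.param)
        self.param_names: tuple[str, ...] = tuple(seen)

    @property
    def K(self) -> int:
        return len(self.param_names)

    @classmethod
    def from_dicts(cls, name: str, rule_dicts: Sequence[Mapping]) -> "PartitionModel":
        rules = [
            Rule.make(
                param=str(d["param"]),
                species=d.get("species"),
                context=d.get("context"),
                gene_class=d.get("gene_class"),
                compartment=d.get("compartment"),
            )
            for d in rule_dicts
        ]
        return cls(name, rules)

    @classmethod
    def single(cls, name: str = "global") -> "PartitionModel":
        return cls(name, [Rule.make("all")])

    def assign(self, obs: pd.DataFrame) -> np.ndarray:
        """Parameter index (into param_names) for every observation row.

        Raises if any observation matches no rule.  Parameters that match
        no observation are permitted at this stage; fitting flags them.
        """
        idx = np.full(len(obs), -1, dtype=np.int64)
        lookup = {p: i for i, p in enumerate(self.param_names)}
        for rule in self.rules:
            m = rule.mask(obs) & (idx < 0)
            idx[m] = lookup[rule.param]
        if np.any(idx < 0):
            bad = obs.loc[idx < 0].iloc[0]
            raise ValueError(
                f"model {self.name!r} assigns no parameter to cell "
                f"({bad['species']}, {bad['context']}, {bad['gene_class']})"
            )
        return idx

    def param_for_cell(self, cell: Cell) -> str:
        for rule in self.rules:
            if rule.matches_cell(cell):
                return rule.param
        raise ValueError(f"model {self.name!r} has no rule for cell {cell}")

    def __repr__(self) -> str:
        return f"PartitionModel({self.name!r}, K={self.K})"


@dataclass
class FitResult:
    """ML modifier estimates for one model on one dataset."""

    model: PartitionModel
    beta: np.ndarray  # length K, per param_names order
    loglik: float
    alpha: float
    converged: bool
    method: str  # "closed_form" | "numerical"
    flags: tuple[str, ...]  # per-parameter identifiability flags
    pooled_ns: np.ndarray
    pooled_s: np.ndarray
    assignment: np.ndarray = field(repr=False)  # obs -> param index

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.model.param_names

    @property
    def K(self) -> int:
        return self.model.K

    @property
    def n_identifiable(self) -> int:
        return sum(f == FLAG_OK for f in self.flags)

    def beta_for(self, name: str) -> float:
        return float(self.beta[self.param_names.index(name)])

    def odds_for_cell(self, cell: Cell) -> float:
        """Fitted N:S odds (beta_hat * alpha) for a cell."""
        name = self.model.param_for_cell(cell)
        i = self.param_names.index(name)
        if self.flags[i] != FLAG_OK:
            raise ValueError(
                f"odds for cell {cell} rest on parameter {name!r} "
                f"flagged {self.flags[i]!r}"
            )
        return float(self.beta[i] * self.alpha)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "param": self.param_names,
                "beta": self.beta,
                "odds": self.beta * self.alpha,
                "pooled_ns": self.pooled_ns,
                "pooled_s": self.pooled_s,
                "flag": self.flags,
            }
        )


# ----------------------------------------------------------------------
def gene_log_likelihood(ns: int, n: int, beta: float, alpha: float) -> float:
    """Log binomial probability of ns nonsynonymous among n variants.

    Success probability P = beta*alpha / (beta*alpha + 1).  For n = 0 the
    (conditional) likelihood is 1, i.e. log-likelihood exactly 0.
    """
    if ns < 0 or ns > n:
        raise ValueError(f"need 0 <= ns <= n, got ns={ns}, n={n}")
    if beta <= 0 or alpha <= 0:
        raise ValueError("beta and alpha must be positive")
    if n == 0:
        return 0.0
    odds = beta * alpha
    p = odds / (odds + 1.0)
    return float(
        special.gammaln(n + 1)
        - special.gammaln(ns + 1)
        - special.gammaln(n - ns + 1)
        + ns * np.log(p)
        + (n - ns) * np.log1p(-p)
    )


def _loglik_terms(ns: np.ndarray, n: np.ndarray, odds: np.ndarray) -> np.ndarray:
    """Vectorised log binomial pmf at per-observation odds; 0 where n = 0."""
    out = np.zeros(len(ns), dtype=float)
    pos = n > 0
    if np.any(pos):
        nsp, npos, o = ns[pos], n[pos], odds[pos]
        # log p = log(o) - log1p(o); log(1-p) = -log1p(o)
        logp = np.log(o) - np.log1p(o)
        log1mp = -np.log1p(o)
        out[pos] = (
            special.gammaln(npos + 1)
            - special.gammaln(nsp + 1)
            - special.gammaln(npos - nsp + 1)
            + nsp * logp
            + (npos - nsp) * log1mp
        )
    return out


def model_log_likelihood(
    dataset: CountDataset,
    model: PartitionModel,
    beta: Sequence[float],
    alpha: float,
) -> float:
    """Gene-wise summed log-likelihood over every observation."""
    beta = np.asarray(beta, dtype=float)
    if len(beta) != model.K:
        raise ValueError(f"beta has length {len(beta)}, model K = {model.K}")
    if np.any(beta <= 0) or alpha <= 0:
        raise ValueError("beta and alpha must be positive")
    obs = dataset.observations()
    idx = model.assign(obs)
    odds = beta[idx] * alpha
    return float(
        _loglik_terms(obs["ns"].to_numpy(), obs["n"].to_numpy(), odds).sum()
    )


def _pooled(dataset: CountDataset, model: PartitionModel):
    obs = dataset.observations()
    idx = model.assign(obs)
    ns = np.bincount(idx, weights=obs["ns"].to_numpy(), minlength=model.K)
    s = np.bincount(idx, weights=obs["s"].to_numpy(), minlength=model.K)
    return obs, idx, ns.astype(np.int64), s.astype(np.int64)


def closed_form_beta(
    dataset: CountDataset, model: PartitionModel, alpha: float
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Exact per-parameter ML: beta_hat_k = (pooled NS_k / pooled S_k) / alpha.

    Degenerate pools are flagged: NS = S = 0 is uninformative (beta
    reported as 1); S = 0 with NS > 0 has an unbounded ML (beta reported
    as +inf).
    """
    _, _, ns, s = _pooled(dataset, model)
    beta = np.empty(model.K, dtype=float)
    flags = []
    for k in range(model.K):
        if s[k] == 0 and ns[k] == 0:
            beta[k] = 1.0
            flags.append(FLAG_UNINFORMATIVE)
        elif s[k] == 0:
            beta[k] = np.inf
            flags.append(FLAG_UNBOUNDED)
        else:
            beta[k] = (ns[k] / s[k]) / alpha
            flags.append(FLAG_OK)
    if any(f != FLAG_OK for f in flags):
        logger.warning(
            "model %s: %d parameter(s) not identifiable (%s)",
            model.name,
            sum(f != FLAG_OK for f in flags),
            ",".join(f for f in flags if f != FLAG_OK),
        )
    return beta, tuple(flags)


def fit_model(
    dataset: CountDataset,
    model: PartitionModel,
    alpha: Optional[float] = None,
    method: str = "closed_form",
) -> FitResult:
    """Maximise the model log-likelihood over the modifier vector.

    ``method="closed_form"`` (default) uses the exact pooled-count ML;
    ``"numerical"`` optimises on log(beta) with L-BFGS-B and is kept as an
    independent verification route.  The log-likelihood is evaluated at
    the estimate either way; parameters with beta_hat = 0 or +inf would
    make a finite evaluation meaningless, so such parameters contribute
    their limiting terms (0 for uninformative pools).
    """
    if alpha is None:
        alpha = dataset.alpha
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    obs, idx, ns_pool, s_pool = _pooled(dataset, model)
    beta_cf, flags = closed_form_beta(dataset, model, alpha)

    if method == "closed_form":
        beta = beta_cf
        converged = True
    elif method == "numerical":
        free = [k for k in range(model.K) if flags[k] == FLAG_OK]
        beta = beta_cf.copy()
        converged = True
        if free:
            ns_arr = obs["ns"].to_numpy()
            n_arr = obs["n"].to_numpy()
            free_idx = np.asarray(free)
            sub = np.isin(idx, free_idx)
            remap = -np.ones(model.K, dtype=np.int64)
            remap[free_idx] = np.arange(len(free_idx))
            sub_assign = remap[idx[sub]]
            ns_sub, n_sub = ns_arr[sub], n_arr[sub]

            def neg_loglik(log_beta: np.ndarray) -> float:
                odds = np.exp(log_beta)[sub_assign] * alpha
                return -_loglik_terms(ns_sub, n_sub, odds).sum()

            res = optimize.minimize(
                neg_loglik,
                x0=np.zeros(len(free_idx)),
                method="L-BFGS-B",
                options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
            )
            converged = bool(res.success)
            beta[free_idx] = np.exp(res.x)
            if not converged:
                logger.warning("numerical fit of %s did not converge: %s",
                               model.name, res.message)
    else:
        raise ValueError(f"unknown method {method!r}")

    # evaluate loglik at the estimate; unbounded params take their
    # supremum (P -> 1 on an all-NS pool gives limiting term 0)
    odds = np.where(np.isfinite(beta), beta, 1.0)[idx] * alpha
    terms = _loglik_terms(obs["ns"].to_numpy(), obs["n"].to_numpy(), odds)
    unbounded = np.asarray([f == FLAG_UNBOUNDED for f in flags])
    if unbounded.any():
        terms[np.isin(idx, np.flatnonzero(unbounded))] = 0.0
    loglik = float(terms.sum())

    return FitResult(
        model=model,
        beta=beta,
        loglik=loglik,
        alpha=alpha,
        converged=converged,
        method=method,
        flags=flags,
        pooled_ns=ns_pool,
        pooled_s=s_pool,
        assignment=idx,
    )
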