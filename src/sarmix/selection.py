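"""Constrained model enumeration, marginal-AIC ranking and Akaike weights.

The candidate space is the Cartesian product of covariate sets (none, any
single covariate, or any admissible pair from the correlation screen)
with the six latent-component configurations (the one- and two-element
subsets of {day, year, day/year}).  Candidates are ranked by marginal
AIC; non-converged fits (non-positive-definite Hessian or a gradient
above tolerance) are excluded from both the ranking and the weights.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import SARModel, SARResults
from .params import ModelSpec, RANDOM_COMPONENTS

__all__ = [
    "DEFAULT_RANDOM_CONFIGS",
    "enumerate_models",
    "marginal_aic",
    "fit_candidates",
    "ModelTable",
    "covariate_importance",
]

#: The six latent configurations: 1- and 2-subsets of the three processes.
DEFAULT_RANDOM_CONFIGS: tuple[frozenset[str], ...] = tuple(
    frozenset(c) for r in (1, 2)
    for c in combinations(RANDOM_COMPONENTS, r)
)


def enumerate_models(
    covariates: Sequence[str],
    admissible_pairs: Iterable[frozenset[str]] | None = None,
    random_configs: Iterable[frozenset[str]] | None = None,
) -> list[ModelSpec]:
    """All candidate specs under the covariate and complexity constraints.

    ``admissible_pairs`` comes from
    :func:`sarmix.covariates.correlation_screen`; when ``None`` every
    pair is admissible.  Ordering is deterministic: covariate sets in
    (none, singletons, pairs) order, then the latent configurations.
    """
    covariates = list(covariates)
    if admissible_pairs is None:
        admissible_pairs = {frozenset(p)
                            for p in combinations(covariates, 2)}
    else:
        admissible_pairs = {frozenset(p) for p in admissible_pairs}
    configs = (tuple(random_configs) if random_configs is not None
               else DEFAULT_RANDOM_CONFIGS)
    cov_sets: list[tuple[str, ...]] = [()]
    cov_sets += [(c,) for c in covariates]
    cov_sets += [tuple(p) for p in combinations(covariates, 2)
                 if frozenset(p) in admissible_pairs]
    return [ModelSpec(covariates=cs, random=rc)
            for cs in cov_sets for rc in configs]


def n_candidates(n_cov: int, n_admissible_pairs: int,
                 n_configs: int = len(DEFAULT_RANDOM_CONFIGS)) -> int:
    """Closed-form candidate count: (1 + n_cov + admissible pairs) x configs."""
    return (1 + n_cov + n_admissible_pairs) * n_configs


def marginal_aic(fit: SARResults) -> float:
    """AIC = 2k - 2 logL from the Laplace marginal likelihood.

    ``k`` counts the estimated fixed-effect and variance/correlation
    parameters only; latent-effect modes are not parameters.  Undefined
    (error) for a non-converged fit.
    """
    if not fit.converged:
        raise ValueError("marginal AIC is undefined for a non-converged fit")
    return float(2.0 * fit.k_params - 2.0 * fit.llf)


class ModelTable:
    """Ranked candidate fits: the multi-model inference table.

    Converged rows are sorted by ascending delta-AIC (delta relative to
    the best converged model); non-converged rows sink to the bottom with
    missing delta.
    """

    def __init__(self, fits: Sequence[SARResults]):
        self.fits = list(fits)
        rows = []
        for f in self.fits:
            rows.append({
                "covariate_1": (f.spec.covariates[0]
                                if len(f.spec.covariates) > 0 else ""),
                "covariate_2": (f.spec.covariates[1]
                                if len(f.spec.covariates) > 1 else ""),
                "day": "day" in f.spec.random,
                "year": "year" in f.spec.random,
                "dayyear": "dayyear" in f.spec.random,
                "logL": f.llf,
                "k": f.k_params,
                "aic": f.aic if f.converged else np.nan,
                "max_gradient": f.max_gradient,
                "hessian_pd": f.hessian_pd,
                "converged": f.converged,
            })
        frame = pd.DataFrame(rows)
        conv = frame["converged"]
        if conv.any():
            best = frame.loc[conv, "aic"].min()
            frame["delta_aic"] = np.where(conv, frame["aic"] - best, np.nan)
        else:
            frame["delta_aic"] = np.nan
        order = frame["delta_aic"].fillna(np.inf).argsort(kind="stable")
        self.frame = frame.iloc[order].reset_index(drop=True)
        self._fits_sorted = [self.fits[i] for i in order]

    @property
    def best(self) -> SARResults:
        if not self.frame["converged"].any():
            raise ValueError("no converged candidate")
        return self._fits_sorted[0]

    def top(self, delta_cutoff: float = 4.0) -> pd.DataFrame:
        """Converged rows with delta-AIC at or below the reporting cutoff."""
        f = self.frame
        return f[(f["converged"]) & (f["delta_aic"] <= delta_cutoff)]

    def akaike_weights(self) -> pd.Series:
        """exp(-delta/2), normalised over converged rows."""
        d = self.frame.loc[self.frame["converged"], "delta_aic"]
        w = np.exp(-0.5 * d)
        return w / w.sum()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def fit_candidates(specs: Sequence[ModelSpec], data, X,
                   **fit_kwargs) -> ModelTable:
    """Fit every candidate sequentially in the given deterministic order.

    The result is invariant to how the fits would be scheduled: each fit
    depends only on (spec, data, X, fit_kwargs).
    """
    fits = [SARModel(data, X, spec).fit(**fit_kwargs) for spec in specs]
    return ModelTable(fits)


def covariate_importance(table: ModelTable) -> pd.Series:
    """Summed Akaike weight per covariate, plus a "blank" entry.

    The weight of covariate c is the sum of Akaike weights of all
    converged models containing c; "blank" collects the covariate-free
    models.  Weights sum to 1 over models, not over covariates (a
    two-covariate model contributes its weight to both).
    """
    w = table.akaike_weights()
    out: dict[str, float] = {"blank": 0.0}
    for idx, weight in w.items():
        row = table.frame.loc[idx]
        covs = [c for c in (row["covariate_1"], row["covariate_2"]) if c]
        if not covs:
            out["blank"] += float(weight)
        for c in covs:
            out[c] = out.get(c, 0.0) + float(weight)
    return pd.Series(out).sort_values(ascending=False)
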