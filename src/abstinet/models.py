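"""Model-object front end over the contagion and prediction machinery.

``ContagionAnalysis`` is built from a comment network and fitted with
``fit()``, which computes the observed contagion probabilities for the
requested modes and distances, simulates their attribute-randomisation
nulls, and returns a results object carrying estimates, intervals and a
``summary()`` table — the way a statsmodels model hands back results.
``AbstinencePLS`` does the same for the PLS1 predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .contagion import (
    ContagionResult,
    comment_contagion_prob,
    peer_contagion_prob,
)
from .ingest import CommentNetwork
from .nullsim import NullDistribution, SimSpec, category_contagion, simulate_null
from .predict import PLSModel, fit_pls1, select_components


class ContagionAnalysis:
    """Temporal contagion analysis of one comment network."""

    def __init__(self, network: CommentNetwork, reading: str = "after"):
        self.network = network
        self.reading = reading

    def fit(
        self,
        modes: Sequence[str] = ("peers", "comments"),
        distances: Sequence[int] = (1, 2, 3),
        n_null: int = 1000,
        seed: int = 0,
        categories: bool = False,
    ) -> "ContagionAnalysisResults":
        spec = SimSpec(n_sims=n_null, seed=seed)
        observed: dict[tuple[str, int], ContagionResult] = {}
        nulls: dict[tuple[str, int], NullDistribution] = {}
        for mode in modes:
            for dist in distances:
                if mode == "peers":
                    stat = lambda net, rec, d=dist: peer_contagion_prob(net, rec, distance=d)
                elif mode == "comments":
                    stat = lambda net, rec, d=dist: comment_contagion_prob(
                        net, rec, distance=d, reading=self.reading
                    )
                else:
                    raise ValueError(f"unknown mode {mode!r}")
                observed[(mode, dist)] = stat(self.network, self.network.records)
                nulls[(mode, dist)] = simulate_null(self.network, stat, spec)
        cat_results = None
        if categories:
            cat_results = category_contagion(
                self.network, spec, distances=tuple(distances), reading=self.reading
            )
        return ContagionAnalysisResults(observed, nulls, cat_results)


@dataclass
class ContagionAnalysisResults:
    observed: Mapping[tuple[str, int], ContagionResult]
    nulls: Mapping[tuple[str, int], NullDistribution]
    categories: Optional[Mapping[str, Mapping[int, NullDistribution]]] = None

    def summary(self) -> pd.DataFrame:
        """One row per mode x distance: counts, probability, null CI."""
        rows = []
        for (mode, dist), res in self.observed.items():
            null = self.nulls[(mode, dist)]
            rows.append(
                {
                    "mode": mode,
                    "distance": dist,
                    "numerator": res.numerator,
                    "denominator": res.denominator,
                    "probability": res.probability,
                    "null_mean": null.mean,
                    "null_sd": null.sd,
                    "ci_low": null.ci_low,
                    "ci_high": null.ci_high,
                    "exceeds_upper": null.exceeds_upper,
                    "below_lower": null.below_lower,
                }
            )
        return pd.DataFrame(rows)

    def category_summary(self) -> pd.DataFrame:
        if self.categories is None:
            raise ValueError("fit() was run without categories=True")
        rows = []
        for cat, by_dist in self.categories.items():
            for dist, null in by_dist.items():
                rows.append(
                    {
                        "category": cat,
                        "distance": dist,
                        "probability": null.observed,
                        "null_mean": null.mean,
                        "ci_low": null.ci_low,
                        "ci_high": null.ci_high,
                        "exceeds_upper": null.exceeds_upper,
                        "below_lower": null.below_lower,
                    }
                )
        return pd.DataFrame(rows)


class AbstinencePLS:
    """PLS1 predictor of abstinent status from per-user covariates."""

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        feature_names: Optional[Sequence[str]] = None,
    ):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y).astype(int)
        self.feature_names = feature_names

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str) -> "AbstinencePLS":
        cols = [c for c in df.columns if c != outcome]
        return cls(df[cols].to_numpy(float), df[outcome].to_numpy(int), cols)

    def fit(
        self,
        n_components: Optional[int] = None,
        folds: int = 10,
        max_components: int = 40,
        seed: int = 0,
    ) -> PLSModel:
        """Fit with a fixed component count, or select it by tenfold CV."""
        if n_components is None:
            n_components, _ = select_components(
                self.X, self.y, folds=folds, max_components=max_components, seed=seed
            )
        return fit_pls1(self.X, self.y, n_components, feature_names=self.feature_names)
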