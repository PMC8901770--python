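"""Attribute-randomisation null model for the contagion probabilities.

The null holds the comment-network *structure* fixed — the edge multiset,
and with it every user's peer set and degree — while permuting node and
edge attributes: the outcome record (abstinence status and its
achievement date move together), the first-participation date, and the
per-edge comment attributes.  Permutation (sampling without replacement
from the observed attribute multiset) preserves every marginal attribute
distribution exactly.

One thousand replicate networks give a null distribution for each
observed contagion probability; following the study's normality
assumption the 95% interval is ``mean ± 1.96 sd``, with a percentile
interval exported alongside for robustness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .contagion import ContagionResult, comment_contagion_prob
from .corpus import GamblerRecord
from .ingest import CommentNetwork

Statistic = Callable[[CommentNetwork, Mapping[str, GamblerRecord]], ContagionResult]

Z95 = 1.959963984540054


@dataclass(frozen=True)
class SimSpec:
    """How many replicates to draw and which attributes to shuffle."""

    n_sims: int = 1000
    seed: int = 0
    shuffle_outcome: bool = True        # abstinence status + achievement date
    shuffle_first_post: bool = True     # first participation date
    shuffle_comments: bool = True       # per-edge timestamps and categories

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("SimSpec.n_sims must be >= 1")
        if not (self.shuffle_outcome or self.shuffle_first_post or self.shuffle_comments):
            raise ValueError("SimSpec must shuffle at least one attribute")


@dataclass
class NullDistribution:
    """Null replicate probabilities and the observed value they test."""

    values: np.ndarray
    observed: float
    degenerate_share: float = 0.0
    warning: Optional[str] = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0

    @property
    def ci_low(self) -> float:
        return self.mean - Z95 * self.sd

    @property
    def ci_high(self) -> float:
        return self.mean + Z95 * self.sd

    @property
    def percentile_ci(self) -> tuple[float, float]:
        return (
            float(np.percentile(self.values, 2.5)),
            float(np.percentile(self.values, 97.5)),
        )

    @property
    def exceeds_upper(self) -> bool:
        return self.observed > self.ci_high

    @property
    def below_lower(self) -> bool:
        return self.observed < self.ci_low

    def to_dict(self) -> dict:
        lo, hi = self.percentile_ci
        return {
            "observed": self.observed,
            "mean": self.mean,
            "sd": self.sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "percentile_ci_low": lo,
            "percentile_ci_high": hi,
            "exceeds_upper": self.exceeds_upper,
            "below_lower": self.below_lower,
            "n_sims": int(len(self.values)),
            "warning": self.warning,
        }


def permute_attributes(
    network: CommentNetwork,
    rng: np.random.Generator,
    spec: SimSpec,
) -> tuple[CommentNetwork, dict[str, GamblerRecord]]:
    """One replicate: same structure, permuted node/edge attributes.

    Outcome pairs (abstinent, abstinence_date) travel as one unit;
    first-post dates are permuted independently of them, as the null
    randomises each attribute in its own right.
    """
    nodes = list(network.graph.nodes)
    base = network.records
    outcome_perm = rng.permutation(len(nodes)) if spec.shuffle_outcome else np.arange(len(nodes))
    first_perm = rng.permutation(len(nodes)) if spec.shuffle_first_post else np.arange(len(nodes))
    new_records: dict[str, GamblerRecord] = {}
    for i, name in enumerate(nodes):
        src_outcome = base[nodes[int(outcome_perm[i])]]
        src_first = base[nodes[int(first_perm[i])]]
        rec = GamblerRecord(
            username=name,
            abstinent=src_outcome.abstinent,
            abstinence_date=src_outcome.abstinence_date,
            first_post_date=src_first.first_post_date,
            n_symptoms=base[name].n_symptoms,
            is_admin=base[name].is_admin,
        )
        new_records[name] = rec

    graph = network.graph
    if spec.shuffle_comments:
        edges = list(graph.edges(keys=True, data=True))
        attrs = [d for *_, d in edges]
        perm = rng.permutation(len(edges))
        g = nx.MultiDiGraph()
        g.add_nodes_from(graph.nodes)
        for (u, v, _, _), pi in zip(edges, perm):
            d = attrs[int(pi)]
            g.add_edge(u, v, timestamp=d["timestamp"], category=d.get("category"))
        graph = g
    replicate = CommentNetwork(graph=graph, records=new_records)
    return replicate, new_records


def simulate_null(
    network: CommentNetwork,
    statistic: Statistic,
    spec: SimSpec,
    records: Optional[Mapping[str, GamblerRecord]] = None,
) -> NullDistribution:
    """Null distribution of a contagion statistic under attribute shuffling.

    Replicate ``r`` draws its generator from an independent counter-keyed
    substream of the master seed, so results do not depend on execution
    order.  A warning is attached when more than half the replicates have
    a zero denominator.
    """
    records = network.records if records is None else records
    observed = statistic(network, records)
    values = np.empty(spec.n_sims)
    degenerate = 0
    for r in range(spec.n_sims):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(r,))
        )
        replicate, rep_records = permute_attributes(network, rng, spec)
        res = statistic(replicate, rep_records)
        values[r] = res.probability
        degenerate += int(res.denominator == 0)
    share = degenerate / spec.n_sims
    warning = None
    if share > 0.5:
        warning = (
            f"degenerate statistic: zero denominator in {share:.0%} of replicates"
        )
        warnings.warn(warning)
    return NullDistribution(
        values=values,
        observed=observed.probability,
        degenerate_share=share,
        warning=warning,
    )


def category_subnetwork(network: CommentNetwork, category: str) -> CommentNetwork:
    """Restriction of the comment network to one category's edges."""
    g = nx.MultiDiGraph()
    g.add_nodes_from(network.graph.nodes)
    for u, v, d in network.graph.edges(data=True):
        if d.get("category") == category:
            g.add_edge(u, v, timestamp=d["timestamp"], category=category)
    return CommentNetwork(graph=g, records=network.records)


def category_contagion(
    network: CommentNetwork,
    spec: SimSpec,
    categories: Sequence[str] = ("change", "sustain", "general", "acceptive", "neutral", "rejective"),
    distances: Sequence[int] = (1, 2, 3),
    reading: str = "after",
) -> dict[str, dict[int, NullDistribution]]:
    """Comment-mode contagion per category, each against its own null.

    For every category the statistic runs on the category-restricted
    subgraph; categories with no edges are skipped with a warning.
    """
    out: dict[str, dict[int, NullDistribution]] = {}
    for cat in categories:
        sub = category_subnetwork(network, cat)
        if sub.graph.number_of_edges() == 0:
            warnings.warn(f"category {cat!r} absent from network; skipped")
            continue
        out[cat] = {}
        for dist in distances:
            stat = _comment_stat(dist, reading)
            out[cat][dist] = simulate_null(sub, stat, spec)
    return out


def _comment_stat(distance: int, reading: str = "after") -> Statistic:
    def stat(net: CommentNetwork, records: Mapping[str, GamblerRecord]) -> ContagionResult:
        return comment_contagion_prob(net, records, distance=distance, reading=reading)

    return stat
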