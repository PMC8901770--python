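"""Temporal contagion probabilities over the comment network.

Two notions of an "abstinent-contagious" relationship are computed, each
as a conditional (Bayesian) probability at social distances 1-3:

peers mode
    A directed pair sender -> recipient (connected by at least one
    comment) is contagious when the sender achieved three-year continuous
    abstinence strictly before the recipient did.  The distance-1
    probability conditions on the sender being abstinent; distance 2 and
    3 extend only through links already classified contagious at the
    previous step, which enforces the full temporal ordering
    t0 < t1 < t2 < t3 of abstinence-achievement dates along the chain.

comments mode
    A directed pair with at least one comment is contagious when the
    recipient achieved abstinence *after* the sender's third year of
    forum attendance (sender first-post date + 1095 days).  The
    distance-1 probability conditions on the comment's existence; higher
    distances again chain through previously contagious links.  Repeated
    comments between the same pair count once in the probability; their
    multiplicity is recorded separately.

Social distance is shortest-path length in the simple undirected
projection of the comment graph, so a distance-2 chain is only credited
when its endpoints have no direct link in either direction.  Chains are
simple (no repeated users).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional

import networkx as nx

from .corpus import ABSTINENCE_WINDOW, GamblerRecord
from .ingest import CommentNetwork

Mode = Literal["peers", "comments"]


@dataclass(frozen=True)
class ContagionResult:
    """Observed conditional contagion probability at one distance/mode."""

    distance: int
    mode: Mode
    numerator: int
    denominator: int
    degenerate: bool = False

    @property
    def probability(self) -> float:
        if self.denominator == 0:
            return 0.0
        return self.numerator / self.denominator

    def __post_init__(self) -> None:
        if self.numerator > self.denominator:
            raise ValueError("numerator exceeds denominator")
        if self.numerator < 0 or self.denominator < 0:
            raise ValueError("negative count")


# ------------------------------------------------------------------ distance


def social_distance(
    network: CommentNetwork | nx.Graph,
    a: str,
    b: str,
    max_distance: int = 3,
) -> Optional[float]:
    """Shortest-path social distance between two users, reported up to 3.

    Returns 1, 2 or 3; ``inf`` for connected pairs farther than
    ``max_distance``; ``None`` for disconnected pairs.  Distance is taken
    on the simple undirected projection, so "distance 2" certifies the
    absence of any direct comment in either direction.
    """
    if a == b:
        raise ValueError("social distance is undefined for a user with themself")
    g = network.undirected() if isinstance(network, CommentNetwork) else network
    if a not in g or b not in g:
        raise KeyError(f"user not in network: {a if a not in g else b!r}")
    try:
        d = nx.shortest_path_length(g, a, b)
    except nx.NetworkXNoPath:
        return None
    return d if d <= max_distance else float("inf")


def _distances_from(g: nx.Graph, source: str, cutoff: int = 3) -> dict[str, int]:
    return nx.single_source_shortest_path_length(g, source, cutoff=cutoff)


# -------------------------------------------------------------- link checks


def _peer_link_contagious(ra: GamblerRecord, rb: GamblerRecord) -> bool:
    """Sender and recipient both abstinent, sender strictly first."""
    return (
        ra.abstinent
        and rb.abstinent
        and ra.abstinence_date < rb.abstinence_date
    )


def _comment_link_contagious(
    ra: GamblerRecord, rb: GamblerRecord, reading: str = "after"
) -> bool:
    """Recipient abstinent relative to the sender's third forum year.

    ``reading="after"`` (default): the recipient's abstinence date falls
    after the sender's first-post date + 1095 days.  ``reading="within"``
    implements the alternative interpretation in which abstinence inside
    the sender's three-year window counts as contagious.
    """
    if not rb.abstinent:
        return False
    if ra.first_post_date is None:
        return False
    third_year = ra.first_post_date + ABSTINENCE_WINDOW
    if reading == "after":
        return rb.abstinence_date > third_year
    if reading == "within":
        return rb.abstinence_date <= third_year
    raise ValueError(f"unknown temporal reading {reading!r}")


# ------------------------------------------------------------- probabilities


def _chain_counts(
    network: CommentNetwork,
    records: Mapping[str, GamblerRecord],
    distance: int,
    link_contagious,
    seed_condition,
) -> tuple[int, int]:
    """Count (numerator, denominator) chains for one mode at one distance.

    ``seed_condition(record)`` gates the first link's denominator (sender
    abstinent for peers mode, trivially true for comments mode);
    ``link_contagious(ra, rb)`` classifies a directed link.
    """
    if distance not in (1, 2, 3):
        raise ValueError("distance must be 1, 2 or 3")
    g = network.graph
    pairs = network.pair_set()
    out: dict[str, list[str]] = {}
    for u, v in pairs:
        out.setdefault(u, []).append(v)

    if distance == 1:
        denom = num = 0
        for a, b in pairs:
            if not seed_condition(records[a]):
                continue
            denom += 1
            if link_contagious(records[a], records[b]):
                num += 1
        return num, denom

    # distance 2/3: extend contagious prefixes one contagious link at a time
    undirected = network.undirected()
    denom = num = 0
    dist_cache: dict[str, dict[str, int]] = {}

    def dist(a: str, b: str) -> Optional[int]:
        if a not in dist_cache:
            dist_cache[a] = _distances_from(undirected, a, cutoff=3)
        return dist_cache[a].get(b)

    for a, b in pairs:
        if not seed_condition(records[a]):
            continue
        if not link_contagious(records[a], records[b]):
            continue
        for c in out.get(b, ()):
            if c == a or c == b:
                continue
            if dist(a, c) != 2:
                continue
            if distance == 2:
                denom += 1
                if link_contagious(records[b], records[c]):
                    num += 1
            else:
                if not link_contagious(records[b], records[c]):
                    continue
                for d_node in out.get(c, ()):
                    if d_node in (a, b, c):
                        continue
                    if dist(a, d_node) != 3:
                        continue
                    denom += 1
                    if link_contagious(records[c], records[d_node]):
                        num += 1
    return num, denom


def peer_contagion_prob(
    network: CommentNetwork,
    records: Optional[Mapping[str, GamblerRecord]] = None,
    distance: int = 1,
) -> ContagionResult:
    """Peer-mode contagion probability at the given social distance.

    At distance 1 the denominator is the number of directed commenting
    pairs whose sender is abstinent, the numerator those whose recipient
    became abstinent strictly later.  Distances 2 and 3 chain only
    through links already contagious, enforcing t0 < t1 < t2 (< t3).
    """
    records = network.records if records is None else records
    num, denom = _chain_counts(
        network,
        records,
        distance,
        _peer_link_contagious,
        seed_condition=lambda r: r.abstinent,
    )
    return ContagionResult(
        distance=distance,
        mode="peers",
        numerator=num,
        denominator=denom,
        degenerate=denom == 0,
    )


def comment_contagion_prob(
    network: CommentNetwork,
    records: Optional[Mapping[str, GamblerRecord]] = None,
    distance: int = 1,
    reading: str = "after",
) -> ContagionResult:
    """Comment-mode contagion probability at the given social distance.

    At distance 1 the denominator is every directed pair with at least
    one comment; the numerator counts pairs whose recipient achieved
    abstinence after the sender's third forum year.  Higher distances
    chain through previously contagious comment links.
    """
    records = network.records if records is None else records
    num, denom = _chain_counts(
        network,
        records,
        distance,
        lambda ra, rb: _comment_link_contagious(ra, rb, reading=reading),
        seed_condition=lambda r: True,
    )
    return ContagionResult(
        distance=distance,
        mode="comments",
        numerator=num,
        denominator=denom,
        degenerate=denom == 0,
    )


def pair_multiplicities(network: CommentNetwork) -> dict[tuple[str, str], int]:
    """Comment counts per directed pair (exported alongside probabilities)."""
    counts: dict[tuple[str, str], int] = {}
    for u, v, _ in network.graph.edges(keys=True):
        counts[(u, v)] = counts.get((u, v), 0) + 1
    return counts
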