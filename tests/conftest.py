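"""Shared fixtures: tiny hand-built networks and mid-size synthetic corpora."""

from __future__ import annotations

import itertools
from datetime import datetime, timedelta

import networkx as nx
import numpy as np
import pytest

from abstinet import (
    CommentNetwork,
    CommentUnit,
    GamblerRecord,
    SynthConfig,
    build_network,
    generate_forum,
    labeled_units,
)

EPOCH = datetime(2010, 1, 1)


def day(d: float) -> datetime:
    return EPOCH + timedelta(days=d)


def make_records(spec: dict[str, float | None], first_post_day: float = 0.0):
    """Records from a {name: abstinence-day-or-None} mapping."""
    return [
        GamblerRecord(
            username=name,
            abstinent=d is not None,
            abstinence_date=day(d) if d is not None else None,
            first_post_date=day(first_post_day),
            n_symptoms=1,
        )
        for name, d in spec.items()
    ]


def make_network(
    edges: list[tuple[str, str]] | list[tuple[str, str, float]],
    records: list[GamblerRecord],
    category: str | None = None,
) -> CommentNetwork:
    """Network from an explicit directed edge list (optional day stamps)."""
    units = []
    for e in edges:
        a, b, *rest = e
        t = day(rest[0]) if rest else day(1.0)
        units.append(
            CommentUnit(
                sender=a,
                timestamp=t,
                sentences=("x",),
                recipients=frozenset({b}),
                category=category,
            )
        )
    return build_network(units, records)


# ----------------------------------------------- independent contagion oracle


def brute_force_contagion(
    pairs: set[tuple[str, str]],
    records: dict[str, GamblerRecord],
    distance: int,
    mode: str,
    reading: str = "after",
) -> tuple[int, int]:
    """Exhaustive enumeration of contagion chains on a small network.

    Deliberately written from the definitions (tuple enumeration plus a
    networkx shortest path), independent of the package's chain walker.
    """
    g = nx.Graph()
    g.add_nodes_from(records)
    g.add_edges_from(pairs)

    def sd(a, b):
        try:
            return nx.shortest_path_length(g, a, b)
        except nx.NetworkXNoPath:
            return None

    def link(a, b):
        ra, rb = records[a], records[b]
        if mode == "peers":
            return (
                ra.abstinent and rb.abstinent and ra.abstinence_date < rb.abstinence_date
            )
        if not rb.abstinent or ra.first_post_date is None:
            return False
        third = ra.first_post_date + timedelta(days=1095)
        return rb.abstinence_date > third if reading == "after" else rb.abstinence_date <= third

    def seed_ok(a):
        return records[a].abstinent if mode == "peers" else True

    nodes = list(records)
    num = den = 0
    if distance == 1:
        for a, b in pairs:
            if seed_ok(a):
                den += 1
                num += link(a, b)
    elif distance == 2:
        for a, b, c in itertools.permutations(nodes, 3):
            if (
                (a, b) in pairs
                and (b, c) in pairs
                and seed_ok(a)
                and link(a, b)
                and sd(a, c) == 2
            ):
                den += 1
                num += link(b, c)
    elif distance == 3:
        for a, b, c, d in itertools.permutations(nodes, 4):
            if (
                (a, b) in pairs
                and (b, c) in pairs
                and (c, d) in pairs
                and seed_ok(a)
                and link(a, b)
                and link(b, c)
                and sd(a, c) == 2
                and sd(a, d) == 3
            ):
                den += 1
                num += link(c, d)
    return num, den


def random_network(rng: np.random.Generator, n_nodes: int = 8):
    """A random directed network with random outcome records."""
    names = [f"n{i}" for i in range(n_nodes)]
    recs = []
    for name in names:
        abst = rng.random() < 0.5
        recs.append(
            GamblerRecord(
                username=name,
                abstinent=abst,
                abstinence_date=day(float(rng.integers(0, 2000))) if abst else None,
                first_post_date=day(float(rng.integers(-1200, 500))),
                n_symptoms=1,
            )
        )
    edges = [
        (a, b, float(rng.integers(0, 2000)))
        for a in names
        for b in names
        if a != b and rng.random() < 0.3
    ]
    net = make_network(edges, recs)
    return net, {r.username: r for r in recs}


# ------------------------------------------------------- synthetic fixtures


@pytest.fixture(scope="session")
def small_synth():
    """Mid-size synthetic forum reused across test modules."""
    config = SynthConfig(n_users=120, span_months=90, seed=7)
    corpus, records, truth = generate_forum(config)
    units = labeled_units(corpus, truth)
    network = build_network(units, records)
    return config, corpus, records, truth, units, network
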