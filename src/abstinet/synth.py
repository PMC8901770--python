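"""Synthetic self-help-forum generator with a plantable contagion effect.

The generator emulates the statistical structure of a decade-scale
Japanese gambling self-help forum: a roster of users joining at staggered
dates, posts arriving as a homogeneous per-user Poisson process, posts
made of explicit-delimiter sentences that unitize into two-sentence
comments, username mentions that create directed comment edges, a
six-way comment-category label per unit, and a minority of users who
achieve three years of continuous abstinence.

Abstinence is a per-user, per-month Bernoulli trial on the log-odds scale:

    logit p = logit(base_abstinence_hazard)
              + peer_effect      * (# distinct close abstinent peers so far)
              + rejective_effect * (# rejective comments received so far)

A *close peer* is a user with whom at least ``close_peer_threshold``
reciprocal comment exchanges have occurred.  Once a trial succeeds the
user's last-gamble date is fixed and the three-year achievement date
follows 1095 days later; only runs whose achievement date falls inside
the corpus span can succeed, so three-year continuity is always
observable.  Setting ``peer_effect`` and ``rejective_effect`` to zero
turns the mechanism off and yields independent outcomes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np

from .corpus import ABSTINENCE_DAYS, ForumCorpus, GamblerRecord, Post
from .ingest import CommentUnit, resolve_mentions, unitize_posts

CATEGORIES = ("change", "sustain", "general", "acceptive", "neutral", "rejective")

#: mean calendar month, days
MONTH_DAYS = 30.4375

_FILLERS = (
    "One day at a time",
    "The urge passed after a walk",
    "Checked in before work today",
    "Still counting the days",
)
_MENTION_TEMPLATES = (
    "Hang in there {name}",
    "Thanks for the kind words {name}",
    "{name} your story helped me today",
    "Stay strong {name}",
)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic forum.

    Defaults are sized to the study conditions: about 1089 users over an
    11.5-year span, a ~15% abstinent minority, and a comment-category
    mix matching the observed composition of received comments.
    """

    n_users: int = 1089
    span_months: int = 138
    base_post_rate: float = 0.75
    mention_prob: float = 0.7
    category_mix: tuple[float, ...] = (0.045, 0.005, 0.365, 0.16, 0.395, 0.03)
    base_abstinence_hazard: float = 0.0043
    peer_effect: float = 0.15
    rejective_effect: float = -0.05
    seed: int = 0
    # secondary structure knobs; few sticky friendships let close-peer ties
    # (k reciprocal exchanges) form inside the 36-month trial window
    close_peer_threshold: int = 3
    mean_friends: float = 4.0
    friend_mention_prob: float = 0.95
    units_per_post_mean: float = 2.0
    start: datetime = datetime(2008, 9, 1)

    def __post_init__(self) -> None:
        if self.n_users < 0:
            raise ValueError("SynthConfig.n_users must be non-negative")
        if self.span_months < 0:
            raise ValueError("SynthConfig.span_months must be non-negative")
        if self.base_post_rate < 0:
            raise ValueError("SynthConfig.base_post_rate must be non-negative")
        for name in ("mention_prob", "base_abstinence_hazard", "friend_mention_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"SynthConfig.{name} must be a probability in [0, 1]")
        if len(self.category_mix) != len(CATEGORIES):
            raise ValueError("SynthConfig.category_mix needs six probabilities")
        if any(p < 0 or p > 1 for p in self.category_mix):
            raise ValueError("SynthConfig.category_mix entries must be probabilities")
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise ValueError("SynthConfig.category_mix must sum to 1")
        if self.close_peer_threshold < 1:
            raise ValueError("SynthConfig.close_peer_threshold must be >= 1")
        if self.units_per_post_mean < 1:
            raise ValueError("SynthConfig.units_per_post_mean must be >= 1")

    @property
    def end(self) -> datetime:
        return self.start + timedelta(days=self.span_months * MONTH_DAYS)

    def month_date(self, m: int) -> datetime:
        return self.start + timedelta(days=m * MONTH_DAYS)


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery tests."""

    abstinence_date: dict[str, Optional[datetime]]
    run_start: dict[str, Optional[datetime]]
    logit_trajectory: dict[str, np.ndarray]
    influenced_pairs: list[tuple[str, str]]
    categories: list[Optional[str]] = field(default_factory=list)
    """Category label per comment unit, in unitization order of the corpus."""


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def generate_forum(
    config: SynthConfig,
) -> tuple[ForumCorpus, list[GamblerRecord], GroundTruth]:
    """Generate a forum corpus, outcome records and the ground truth.

    Identical configs (including the seed) give identical output.  Every
    user posts at least once; per-user timestamps are strictly
    increasing; comment units carry exactly one or two sentences; mention
    targets are always roster members.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_users
    if n == 0:
        return ForumCorpus(posts=[], start=config.start, end=config.end), [], GroundTruth(
            {}, {}, {}, [], []
        )

    users = [f"u{i:04d}" for i in range(n)]
    span = config.span_months

    # join months leave room for a full 36-month trial window plus the
    # 1095-day runway, so the outcome does not depend on the join date
    join_max = max(1, span - 72)
    join_month = rng.integers(0, join_max, size=n)

    # symmetric friendship structure drives who mentions whom
    p_friend = min(1.0, config.mean_friends / max(1, n - 1))
    friend_graph = nx.fast_gnp_random_graph(
        n, p_friend, seed=int(rng.integers(0, 2**31 - 1))
    )
    friends = {i: sorted(friend_graph.neighbors(i)) for i in range(n)}

    # ---------------------------------------------------------------- posts
    # Each post is a block of two-sentence units; each unit may mention one
    # other user and carries one category label.
    post_user: list[int] = []
    post_day: list[float] = []
    post_units: list[list[tuple[Optional[int], int]]] = []  # (target, category)
    geom_p = 1.0 / config.units_per_post_mean
    for i in range(n):
        active_months = range(int(join_month[i]), span)
        counts = rng.poisson(config.base_post_rate, size=len(list(active_months)))
        days: list[float] = []
        for off, c in enumerate(counts):
            m = int(join_month[i]) + off
            if c == 0:
                continue
            days.extend(m * MONTH_DAYS + rng.random(c) * MONTH_DAYS)
        if not days:  # every user posts at least once, in their join month
            days = [float(join_month[i] * MONTH_DAYS + rng.random() * MONTH_DAYS)]
        days.sort()
        for d in days:
            n_units = int(rng.geometric(geom_p))
            units = []
            for _ in range(n_units):
                target: Optional[int] = None
                if rng.random() < config.mention_prob:
                    if friends[i] and rng.random() < config.friend_mention_prob:
                        target = int(friends[i][rng.integers(0, len(friends[i]))])
                    else:
                        target = int(rng.integers(0, n))
                    if target == i:
                        target = None
                cat = int(rng.choice(len(CATEGORIES), p=config.category_mix))
                units.append((target, cat))
            post_user.append(i)
            post_day.append(d)
            post_units.append(units)

    # strictly increasing per-user timestamps: nudge ties by one second
    order = sorted(range(len(post_day)), key=lambda j: (post_user[j], post_day[j]))
    last_by_user: dict[int, float] = {}
    eps = 1.0 / 86400.0
    for j in order:
        u = post_user[j]
        t = post_day[j]
        if u in last_by_user and t <= last_by_user[u]:
            t = last_by_user[u] + eps
        last_by_user[u] = t
        post_day[j] = t

    # ------------------------------------------------- mention event arrays
    ev_sender: list[int] = []
    ev_target: list[int] = []
    ev_month: list[int] = []
    ev_rejective: list[bool] = []
    rej_idx = CATEGORIES.index("rejective")
    for j in range(len(post_user)):
        m = int(post_day[j] // MONTH_DAYS)
        for target, cat in post_units[j]:
            if target is not None:
                ev_sender.append(post_user[j])
                ev_target.append(target)
                ev_month.append(m)
                ev_rejective.append(cat == rej_idx)

    # cumulative rejective comments received, per user per month
    rej_cum = np.zeros((n, span + 1), dtype=np.int64)
    for s in range(len(ev_sender)):
        if ev_rejective[s]:
            m = min(ev_month[s], span - 1)
            rej_cum[ev_target[s], m + 1 :] += 1

    # month from which a pair counts as "close": the k-th exchange has
    # happened in both directions
    k = config.close_peer_threshold
    pair_months: dict[tuple[int, int], list[int]] = {}
    for s in range(len(ev_sender)):
        pair_months.setdefault((ev_sender[s], ev_target[s]), []).append(ev_month[s])
    close_onset: dict[tuple[int, int], int] = {}
    for (a, b), months_ab in pair_months.items():
        if a > b:
            continue
        months_ba = pair_months.get((b, a))
        if months_ba is None or len(months_ab) < k or len(months_ba) < k:
            continue
        onset = max(sorted(months_ab)[k - 1], sorted(months_ba)[k - 1])
        close_onset[(a, b)] = onset
    close_peers: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    for (a, b), onset in close_onset.items():
        close_peers[a].append((b, onset))
        close_peers[b].append((a, onset))

    # -------------------------------------------------- abstinence process
    # a run can only succeed if its 1095-day achievement fits in the span
    last_start_day = span * MONTH_DAYS - ABSTINENCE_DAYS
    uniforms = rng.random((n, span))
    base_logit = (
        math.log(config.base_abstinence_hazard / (1 - config.base_abstinence_hazard))
        if 0 < config.base_abstinence_hazard < 1
        else -math.inf
    )
    run_start_month = np.full(n, -1, dtype=np.int64)
    logit_traj = np.full((n, span), np.nan)
    influenced: list[tuple[int, int]] = []
    for m in range(span):
        if m * MONTH_DAYS > last_start_day:
            break
        for i in range(n):
            # trials run only during the user's own first 36 months of
            # participation, mirroring the study's observation window
            if (
                run_start_month[i] >= 0
                or m < join_month[i]
                or m >= join_month[i] + 36
            ):
                continue
            abstinent_close = [
                j
                for j, onset in close_peers[i]
                if onset < m and 0 <= run_start_month[j] < m
            ]
            logit = (
                base_logit
                + config.peer_effect * len(abstinent_close)
                + config.rejective_effect * int(rej_cum[i, m])
            )
            logit_traj[i, m] = logit
            if base_logit == -math.inf:
                continue
            p_full = _sigmoid(logit)
            if uniforms[i, m] < p_full:
                run_start_month[i] = m
                p_without_peers = _sigmoid(
                    base_logit + config.rejective_effect * int(rej_cum[i, m])
                )
                if uniforms[i, m] >= p_without_peers:
                    influenced.extend((j, i) for j in abstinent_close)

    # ----------------------------------------------------------- assembly
    posts: list[Post] = []
    categories: list[Optional[str]] = []
    order = sorted(range(len(post_user)), key=lambda j: (post_day[j], post_user[j]))
    for j in order:
        sentences: list[str] = []
        for target, cat in post_units[j]:
            if target is not None:
                tmpl = _MENTION_TEMPLATES[cat % len(_MENTION_TEMPLATES)]
                sentences.append(tmpl.format(name=users[target]))
            else:
                sentences.append(_FILLERS[cat % len(_FILLERS)])
            sentences.append(_FILLERS[(cat + 1) % len(_FILLERS)])
            categories.append(CATEGORIES[cat])
        posts.append(
            Post(
                user=users[post_user[j]],
                timestamp=config.start + timedelta(days=post_day[j]),
                sentences=tuple(sentences),
            )
        )

    first_post_day: dict[int, float] = {}
    for j in range(len(post_user)):
        u = post_user[j]
        if u not in first_post_day or post_day[j] < first_post_day[u]:
            first_post_day[u] = post_day[j]

    records: list[GamblerRecord] = []
    abstinence_date: dict[str, Optional[datetime]] = {}
    run_start: dict[str, Optional[datetime]] = {}
    n_symptoms = 1 + rng.poisson(2.0, size=n).clip(max=9)
    for i in range(n):
        if run_start_month[i] >= 0:
            start_day = run_start_month[i] * MONTH_DAYS + uniforms[i, run_start_month[i]] * MONTH_DAYS
            start_day = min(start_day, last_start_day)
            rs = config.start + timedelta(days=float(start_day))
            ad = rs + timedelta(days=ABSTINENCE_DAYS)
        else:
            rs = ad = None
        abstinence_date[users[i]] = ad
        run_start[users[i]] = rs
        records.append(
            GamblerRecord(
                username=users[i],
                abstinent=ad is not None,
                abstinence_date=ad,
                first_post_date=config.start + timedelta(days=first_post_day[i]),
                n_symptoms=int(n_symptoms[i]),
                is_admin=False,
            )
        )

    corpus = ForumCorpus(posts=posts, start=config.start, end=config.end)
    truth = GroundTruth(
        abstinence_date=abstinence_date,
        run_start=run_start,
        logit_trajectory={users[i]: logit_traj[i] for i in range(n)},
        influenced_pairs=[(users[a], users[b]) for a, b in influenced],
        categories=categories,
    )
    return corpus, records, truth


def labeled_units(corpus: ForumCorpus, truth: GroundTruth) -> list[CommentUnit]:
    """Unitize a synthetic corpus and attach the generator's categories.

    Posts are unitized in corpus order, which matches the order in which
    the generator recorded one category per unit.
    """
    units = unitize_posts(corpus.posts)
    units = resolve_mentions(units, corpus.roster)
    if len(units) != len(truth.categories):
        raise ValueError(
            f"unit/category misalignment: {len(units)} units, "
            f"{len(truth.categories)} categories"
        )
    return [
        CommentUnit(
            sender=u.sender,
            timestamp=u.timestamp,
            sentences=u.sentences,
            recipients=u.recipients,
            category=c,
        )
        for u, c in zip(units, truth.categories)
    ]


def truth_to_json(truth: GroundTruth, path: str | Path) -> None:
    obj = {
        "abstinence_date": {
            u: d.isoformat() if d else None for u, d in truth.abstinence_date.items()
        },
        "run_start": {
            u: d.isoformat() if d else None for u, d in truth.run_start.items()
        },
        "influenced_pairs": truth.influenced_pairs,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1)
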