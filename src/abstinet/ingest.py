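"""From raw posts to a timestamped directed comment network.

The pipeline is the one used for mention-based forum data:

1. split every post into sentences and regroup them into *comment units*
   of two sentences (a trailing odd sentence forms a one-sentence unit);
2. scan each unit for usernames of other forum members — a mention turns
   the unit into a directed comment from its author to the named member;
3. apply the participant-exclusion cascade (too-short/advertising posters,
   posters with no lifetime gambling symptom, users who received no
   comments inside their own three-year window, administrators);
4. assemble the surviving comments into a directed multigraph whose edges
   carry timestamps and comment-category labels.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from datetime import timedelta
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .corpus import (
    ABSTINENCE_WINDOW,
    DEFAULT_SENTENCE_DELIMITERS,
    GamblerRecord,
    Post,
    records_by_name,
)

logger = logging.getLogger(__name__)

#: tokens never treated as username mentions (frequent in casual chat)
DEFAULT_STOP_NAMES = frozenset({"smile"})
#: postscript markers stripped before mention scanning
DEFAULT_POSTSCRIPTS = ("P.S.", "追伸")

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)


@dataclass(frozen=True)
class CommentUnit:
    """A one- or two-sentence segment of a post; the atomic 'comment'."""

    sender: str
    timestamp: "object"  # datetime; kept loose for frozen-dataclass speed
    sentences: tuple[str, ...]
    recipients: frozenset[str] = frozenset()
    category: Optional[str] = None

    @property
    def text(self) -> str:
        return " ".join(self.sentences)


@dataclass
class ExclusionReport:
    """Counts at each stage of the participant-exclusion cascade."""

    initial: int
    excluded: dict[str, int]
    final: int

    STAGES = ("short_or_ads", "no_symptoms", "no_received_comments", "administrator")

    def __post_init__(self) -> None:
        if self.final != self.initial - sum(self.excluded.values()):
            raise ValueError("exclusion report does not reconcile")
        if self.final < 0 or any(v < 0 for v in self.excluded.values()):
            raise ValueError("negative count in exclusion report")


@dataclass
class CommentNetwork:
    """Directed comment multigraph plus the per-user outcome records.

    ``graph`` is a :class:`networkx.MultiDiGraph`; each edge is one
    comment unit sender -> recipient with ``timestamp`` and ``category``
    data.  Node attributes carry the :class:`GamblerRecord`.
    """

    graph: nx.MultiDiGraph
    records: dict[str, GamblerRecord] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def undirected(self) -> nx.Graph:
        """Simple undirected projection used for social distance."""
        return nx.Graph(self.graph.to_undirected(as_view=False))

    def pair_set(self) -> set[tuple[str, str]]:
        """Unique directed sender->recipient pairs with at least one comment."""
        return {(u, v) for u, v, _ in self.graph.edges(keys=True)}

    def edges_received(self, user: str):
        """(sender, timestamp, category) triples of comments received by ``user``."""
        return [
            (u, d["timestamp"], d.get("category"))
            for u, _, d in self.graph.in_edges(user, data=True)
        ]

    def to_edge_csv(self, path) -> None:
        rows = [
            {
                "sender": u,
                "recipient": v,
                "timestamp": d["timestamp"].isoformat(),
                "category": d.get("category") or "",
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    def to_graphml(self, path) -> None:
        g = nx.MultiDiGraph()
        for n in self.graph.nodes:
            r = self.records.get(n)
            g.add_node(
                n,
                abstinent=bool(r.abstinent) if r else False,
                abstinence_date=r.abstinence_date.isoformat() if r and r.abstinence_date else "",
                first_post_date=r.first_post_date.isoformat() if r and r.first_post_date else "",
            )
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(u, v, timestamp=d["timestamp"].isoformat(), category=d.get("category") or "")
        nx.write_graphml(g, path)


# ------------------------------------------------------------ sentence level


def split_sentences(
    text: str, delimiters: Sequence[str] = DEFAULT_SENTENCE_DELIMITERS
) -> list[str]:
    """Split running text on the configured delimiter characters.

    Empty fragments (e.g. from a trailing delimiter) are dropped.
    """
    pattern = "|".join(re.escape(d) for d in delimiters)
    return [s.strip() for s in re.split(pattern, text) if s.strip()]


def unitize_posts(posts: Iterable[Post]) -> list[CommentUnit]:
    """Regroup each post's sentences into two-sentence comment units.

    A post with ``2m`` sentences yields ``m`` units; with ``2m + 1``
    sentences the final unit holds the single leftover sentence.  Posts
    with no sentences are skipped with a warning.
    """
    units: list[CommentUnit] = []
    for post in posts:
        if not post.sentences:
            logger.warning("skipping empty post by %r at %s", post.user, post.timestamp)
            continue
        for i in range(0, len(post.sentences), 2):
            units.append(
                CommentUnit(
                    sender=post.user,
                    timestamp=post.timestamp,
                    sentences=tuple(post.sentences[i : i + 2]),
                )
            )
    return units


# ------------------------------------------------------------- mention level


def _normalize_token(tok: str) -> str:
    return unicodedata.normalize("NFKC", tok).lower()


def extract_mentions(
    unit: CommentUnit | str,
    roster: Iterable[str],
    stop_names: Iterable[str] = DEFAULT_STOP_NAMES,
    postscripts: Sequence[str] = DEFAULT_POSTSCRIPTS,
    sender: Optional[str] = None,
) -> set[str]:
    """Roster usernames mentioned in a comment unit.

    Matching is exact on whitespace/punctuation-delimited tokens after
    NFKC normalisation, case-insensitively for ASCII.  Purely numeric
    tokens, configured postscript markers and the stop-name list are
    never counted as mentions, and a user never mentions themself.
    """
    if isinstance(unit, CommentUnit):
        text = unit.text
        sender = unit.sender if sender is None else sender
    else:
        text = unit
    for marker in postscripts:
        text = text.replace(marker, " ")
    norm_roster = {_normalize_token(name): name for name in roster}
    stop = {_normalize_token(s) for s in stop_names}
    found: set[str] = set()
    for tok in _TOKEN_RE.findall(text):
        norm = _normalize_token(tok)
        if norm.isdigit() or norm in stop:
            continue
        original = norm_roster.get(norm)
        if original is not None and original != sender:
            found.add(original)
    return found


def resolve_mentions(
    units: Iterable[CommentUnit],
    roster: Iterable[str],
    stop_names: Iterable[str] = DEFAULT_STOP_NAMES,
    postscripts: Sequence[str] = DEFAULT_POSTSCRIPTS,
) -> list[CommentUnit]:
    """Return units with ``recipients`` filled in from mention extraction."""
    roster = set(roster)
    out = []
    for u in units:
        rec = extract_mentions(u, roster, stop_names=stop_names, postscripts=postscripts)
        out.append(
            CommentUnit(
                sender=u.sender,
                timestamp=u.timestamp,
                sentences=u.sentences,
                recipients=frozenset(rec),
                category=u.category,
            )
        )
    return out


# ----------------------------------------------------------- exclusion level


@dataclass
class ExclusionFields:
    """Per-user fields read by the exclusion cascade."""

    word_count: int
    ads_only: bool
    n_symptoms: int
    received_comments: int
    is_admin: bool


def derive_exclusion_fields(
    records: Iterable[GamblerRecord],
    units: Sequence[CommentUnit],
) -> dict[str, ExclusionFields]:
    """Compute the cascade's per-user inputs from comment units.

    ``received_comments`` counts comments whose recipient is the user and
    whose timestamp falls inside the user's own half-open three-year
    window, anchored at the user's first unit (or recorded first post).
    ``ads_only`` is true when every unit by the user contains ``http``.
    """
    recmap = records_by_name(records)
    first_ts: dict[str, object] = {}
    for u in units:
        if u.sender not in first_ts or u.timestamp < first_ts[u.sender]:
            first_ts[u.sender] = u.timestamp
    fields: dict[str, ExclusionFields] = {}
    for name, r in recmap.items():
        start = r.first_post_date or first_ts.get(name)
        sent = [u for u in units if u.sender == name]
        words = sum(len(_TOKEN_RE.findall(u.text)) for u in sent)
        ads = bool(sent) and all("http" in u.text for u in sent)
        received = 0
        if start is not None:
            end = start + ABSTINENCE_WINDOW
            received = sum(
                1
                for u in units
                if name in u.recipients and start <= u.timestamp < end
            )
        fields[name] = ExclusionFields(
            word_count=words,
            ads_only=ads,
            n_symptoms=r.n_symptoms,
            received_comments=received,
            is_admin=r.is_admin,
        )
    return fields


def apply_exclusions(
    records: Iterable[GamblerRecord],
    units: Optional[Sequence[CommentUnit]] = None,
    fields: Optional[Mapping[str, ExclusionFields]] = None,
    min_words: int = 3,
) -> tuple[set[str], ExclusionReport]:
    """Run the participant-exclusion cascade and account for every user.

    Stages run in a fixed order — (1) fewer than ``min_words`` words or
    advertisement-only posting, (2) no lifetime gambling symptom, (3) no
    comment received inside the user's own three-year window, (4)
    administrator — and a user failing several stages is charged to the
    first.  ``fields`` may be supplied directly; otherwise it is derived
    from ``units``.
    """
    records = list(records)
    if fields is None:
        if units is None:
            raise ValueError("apply_exclusions needs either units or fields")
        fields = derive_exclusion_fields(records, units)
    for r in records:
        if r.username not in fields:
            raise ValueError(
                f"record {r.username!r}: missing exclusion fields"
            )

    stage_counts = {s: 0 for s in ExclusionReport.STAGES}
    included: set[str] = set()
    for r in records:
        f = fields[r.username]
        if f.word_count < min_words or f.ads_only:
            stage_counts["short_or_ads"] += 1
        elif f.n_symptoms == 0:
            stage_counts["no_symptoms"] += 1
        elif f.received_comments == 0:
            stage_counts["no_received_comments"] += 1
        elif f.is_admin:
            stage_counts["administrator"] += 1
        else:
            included.add(r.username)
    report = ExclusionReport(
        initial=len(records), excluded=stage_counts, final=len(included)
    )
    return included, report


# ------------------------------------------------------------- network level


def build_network(
    units: Iterable[CommentUnit],
    records: Iterable[GamblerRecord],
    strict: bool = False,
) -> CommentNetwork:
    """Assemble the directed comment multigraph.

    One multi-edge is added per (unit, recipient) pair, so the total edge
    count equals the sum of recipient-set sizes over units.  Recipients
    (or senders) without a record are dropped with a log message, or raise
    in ``strict`` mode.
    """
    recmap = records_by_name(records)
    g = nx.MultiDiGraph()
    g.add_nodes_from(recmap)
    dropped = 0
    for unit in units:
        for recipient in unit.recipients:
            if unit.sender not in recmap or recipient not in recmap:
                if strict:
                    missing = recipient if recipient not in recmap else unit.sender
                    raise KeyError(f"no record for comment endpoint {missing!r}")
                dropped += 1
                continue
            g.add_edge(
                unit.sender,
                recipient,
                timestamp=unit.timestamp,
                category=unit.category,
            )
    if dropped:
        logger.info("dropped %d comment edges with unknown endpoints", dropped)
    return CommentNetwork(graph=g, records=recmap)
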