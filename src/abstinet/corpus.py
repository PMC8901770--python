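"""Core data containers for forum corpora and per-user abstinence records.

A corpus is a flat sequence of timestamped posts; each post belongs to one
user and carries an ordered list of sentences.  Outcome data live in
:class:`GamblerRecord`: whether the user achieved three years (1095 days) of
continuous gambling abstinence, the date the three-year mark was reached,
and the date of the user's first post (which anchors the observation
window used throughout the analysis).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

#: length of the continuous-abstinence criterion, in days
ABSTINENCE_DAYS = 1095
ABSTINENCE_WINDOW = timedelta(days=ABSTINENCE_DAYS)

#: sentence delimiters recognised by the default splitter
DEFAULT_SENTENCE_DELIMITERS = ("。", ".")


@dataclass(frozen=True)
class Post:
    """A single forum post: one user, one timestamp, ordered sentences."""

    user: str
    timestamp: datetime
    sentences: tuple[str, ...]

    def __post_init__(self) -> None:
        if not isinstance(self.timestamp, datetime):
            raise TypeError(f"timestamp of post by {self.user!r} is not a datetime")


@dataclass
class GamblerRecord:
    """One user's outcome state.

    ``abstinent`` is true iff the user's relapse-reset day counter crossed
    1095 days; ``abstinence_date`` is the calendar date that happened.
    The two fields are jointly present or jointly absent.
    """

    username: str
    abstinent: bool
    abstinence_date: Optional[datetime] = None
    first_post_date: Optional[datetime] = None
    n_symptoms: int = 0
    is_admin: bool = False

    def __post_init__(self) -> None:
        if self.abstinent != (self.abstinence_date is not None):
            raise ValueError(
                f"record {self.username!r}: abstinent flag and abstinence_date "
                "must be jointly present or jointly absent"
            )


@dataclass
class ForumCorpus:
    """A collection of posts plus the corpus time span."""

    posts: list[Post] = field(default_factory=list)
    start: Optional[datetime] = None
    end: Optional[datetime] = None

    @property
    def roster(self) -> set[str]:
        return {p.user for p in self.posts}

    def __len__(self) -> int:
        return len(self.posts)

    # ------------------------------------------------------------------ io

    def to_jsonl(self, path: str | Path, delimiter: str = ".") -> None:
        """Write posts as JSON lines (user, ISO-8601 timestamp, text).

        Sentences are joined back into running text with ``delimiter``
        terminating each sentence, so a delimiter-based splitter recovers
        them exactly.
        """
        with open(path, "w", encoding="utf-8") as fh:
            for p in self.posts:
                text = "".join(s + delimiter + " " for s in p.sentences).rstrip()
                fh.write(
                    json.dumps(
                        {
                            "user": p.user,
                            "timestamp": p.timestamp.isoformat(),
                            "text": text,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )

    @classmethod
    def from_jsonl(
        cls,
        path: str | Path,
        delimiters: Sequence[str] = DEFAULT_SENTENCE_DELIMITERS,
    ) -> "ForumCorpus":
        from .ingest import split_sentences  # local import to avoid a cycle

        posts: list[Post] = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                obj = json.loads(line)
                sentences = tuple(split_sentences(obj["text"], delimiters))
                posts.append(
                    Post(
                        user=obj["user"],
                        timestamp=datetime.fromisoformat(obj["timestamp"]),
                        sentences=sentences,
                    )
                )
        start = min((p.timestamp for p in posts), default=None)
        end = max((p.timestamp for p in posts), default=None)
        return cls(posts=posts, start=start, end=end)


# ---------------------------------------------------------------- records io


def records_to_csv(records: Iterable[GamblerRecord], path: str | Path) -> None:
    rows = [
        {
            "username": r.username,
            "abstinent": r.abstinent,
            "abstinence_date": r.abstinence_date.isoformat() if r.abstinence_date else "",
            "first_post_date": r.first_post_date.isoformat() if r.first_post_date else "",
            "n_symptoms": r.n_symptoms,
            "is_admin": r.is_admin,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def records_from_csv(path: str | Path) -> list[GamblerRecord]:
    df = pd.read_csv(path, dtype={"username": str}, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            GamblerRecord(
                username=row.username,
                abstinent=_as_bool(row.abstinent),
                abstinence_date=_parse_date(row.abstinence_date),
                first_post_date=_parse_date(row.first_post_date),
                n_symptoms=int(row.n_symptoms),
                is_admin=_as_bool(getattr(row, "is_admin", False)),
            )
        )
    return records


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in {"true", "1", "yes"}
    return bool(v)


def _parse_date(v) -> Optional[datetime]:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return datetime.fromisoformat(str(v))


def records_by_name(records: Iterable[GamblerRecord]) -> dict[str, GamblerRecord]:
    out: dict[str, GamblerRecord] = {}
    for r in records:
        if r.username in out:
            raise ValueError(f"duplicate record for user {r.username!r}")
        out[r.username] = r
    return out
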