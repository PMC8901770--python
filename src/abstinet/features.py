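"""Observation windows, monthly feature matrices and group comparisons.

Every user is observed for exactly three years (1095 days) from their
first post; comments received after the window are discarded.  The
window is cut into 36 equal bins of 1095/36 days, and four cumulative
series are built per user: distinct commenting peers, distinct senior
abstinent commenting peers (senders who had already achieved three-year
abstinence when they commented), received comments, and received
rejective comments.  Month 36 therefore always equals the full-window
total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import ABSTINENCE_WINDOW, GamblerRecord
from .ingest import CommentNetwork

N_MONTHS = 36
FEATURES = ("peers", "senior_abstinent_peers", "received_comments", "rejective_comments")


@dataclass(frozen=True)
class WindowSpec:
    """A user's half-open three-year observation window."""

    user: str
    start: datetime

    @property
    def end(self) -> datetime:
        return self.start + ABSTINENCE_WINDOW

    def month_edge(self, m: int) -> datetime:
        """Upper edge of cumulative month ``m`` (1..36)."""
        return self.start + timedelta(days=m * ABSTINENCE_WINDOW.days / N_MONTHS)


def observation_window(
    user: str, network: CommentNetwork
) -> tuple[WindowSpec, list[tuple[str, datetime, Optional[str]]]]:
    """The user's window and the comments they received inside it.

    The window starts at the user's first post and is half-open: a
    comment at exactly day 1095 is excluded.
    """
    record = network.records.get(user)
    if record is None:
        raise KeyError(f"no record for user {user!r}")
    if record.first_post_date is None:
        raise ValueError(f"user {user!r} never commented; window undefined")
    spec = WindowSpec(user=user, start=record.first_post_date)
    received = [
        (sender, ts, cat)
        for sender, ts, cat in network.edges_received(user)
        if spec.start <= ts < spec.end
    ]
    return spec, received


def monthly_features(user: str, network: CommentNetwork) -> np.ndarray:
    """The user's 4 x 36 cumulative monthly feature matrix.

    Rows follow :data:`FEATURES`.  A sender counts as a senior abstinent
    peer when their recorded abstinence-achievement date strictly
    precedes the comment's timestamp.
    """
    spec, received = observation_window(user, network)
    out = np.zeros((len(FEATURES), N_MONTHS), dtype=float)
    records = network.records
    for m in range(1, N_MONTHS + 1):
        edge = spec.month_edge(m)
        senders = set()
        seniors = set()
        n_comments = 0
        n_rejective = 0
        for sender, ts, cat in received:
            if ts >= edge:
                continue
            n_comments += 1
            senders.add(sender)
            if cat == "rejective":
                n_rejective += 1
            r = records.get(sender)
            if (
                r is not None
                and r.abstinent
                and r.abstinence_date < ts
            ):
                seniors.add(sender)
        out[0, m - 1] = len(senders)
        out[1, m - 1] = len(seniors)
        out[2, m - 1] = n_comments
        out[3, m - 1] = n_rejective
    return out


def feature_matrix(
    network: CommentNetwork, users: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Wide per-user feature matrix: one row per (user, feature), m1..m36."""
    if users is None:
        users = [
            u
            for u, r in network.records.items()
            if r.first_post_date is not None
        ]
    rows = []
    for user in users:
        mat = monthly_features(user, network)
        for fi, feat in enumerate(FEATURES):
            rows.append(
                {"user": user, "feature": feat}
                | {f"m{m}": mat[fi, m - 1] for m in range(1, N_MONTHS + 1)}
            )
    return pd.DataFrame(rows)


def stacked_features(matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Flatten the per-user 4 x 36 matrix to one 144-vector per user.

    Concatenation is feature-major: all 36 months of the first feature,
    then the second, and so on.
    """
    users = list(dict.fromkeys(matrix["user"]))
    cols = [f"m{m}" for m in range(1, N_MONTHS + 1)]
    X = np.zeros((len(users), len(FEATURES) * N_MONTHS))
    for ui, user in enumerate(users):
        sub = matrix[matrix["user"] == user].set_index("feature")
        for fi, feat in enumerate(FEATURES):
            X[ui, fi * N_MONTHS : (fi + 1) * N_MONTHS] = sub.loc[feat, cols].to_numpy(
                dtype=float
            )
    return X, users


# ------------------------------------------------------------- comparisons


@dataclass(frozen=True)
class GroupComparison:
    """Two-group descriptive and inferential summary (one variable)."""

    mean1: float
    se1: float
    n1: int
    mean2: float
    se2: float
    n2: int
    t: Optional[float]
    cohens_d: Optional[float]
    p: Optional[float]


def group_compare(
    group1: Sequence[float],
    group2: Sequence[float],
    equal_var: bool = False,
) -> GroupComparison:
    """Welch (default) or pooled t test plus pooled-SD Cohen's d.

    With fewer than two observations in either group the test statistics
    are suppressed but the descriptive means are still reported.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    n1, n2 = len(x), len(y)
    mean1 = float(np.mean(x)) if n1 else float("nan")
    mean2 = float(np.mean(y)) if n2 else float("nan")
    se1 = float(np.std(x, ddof=1) / np.sqrt(n1)) if n1 > 1 else float("nan")
    se2 = float(np.std(y, ddof=1) / np.sqrt(n2)) if n2 > 1 else float("nan")
    if n1 < 2 or n2 < 2:
        warnings.warn("group with < 2 observations: t, d and p suppressed")
        return GroupComparison(mean1, se1, n1, mean2, se2, n2, None, None, None)
    if np.array_equal(x, y):
        # identical samples: define the degenerate comparison exactly
        return GroupComparison(mean1, se1, n1, mean2, se2, n2, 0.0, 0.0, 1.0)
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    pooled_sd = np.sqrt(
        ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    )
    d = float((mean1 - mean2) / pooled_sd) if pooled_sd > 0 else 0.0
    return GroupComparison(
        mean1, se1, n1, mean2, se2, n2, float(t), d, float(p)
    )


def compare_table(
    matrix: pd.DataFrame,
    records: dict[str, GamblerRecord],
    month: int = N_MONTHS,
) -> pd.DataFrame:
    """Abstinent-vs-non-abstinent comparison of the four features.

    Mirrors the study's descriptive table layout: per-group mean and
    standard error, Welch t, Cohen's d and two-sided p, taken at the
    cumulative ``month`` (default: the full window).
    """
    col = f"m{month}"
    rows = []
    for feat in FEATURES:
        sub = matrix[matrix["feature"] == feat]
        g1 = sub[sub["user"].map(lambda u: records[u].abstinent)][col]
        g2 = sub[sub["user"].map(lambda u: not records[u].abstinent)][col]
        c = group_compare(g1.to_numpy(), g2.to_numpy())
        rows.append(
            {
                "variable": feat,
                "M_abstinent": c.mean1,
                "SE_abstinent": c.se1,
                "M_non_abstinent": c.mean2,
                "SE_non_abstinent": c.se2,
                "t": c.t,
                "d": c.cohens_d,
                "p": c.p,
            }
        )
    return pd.DataFrame(rows)
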