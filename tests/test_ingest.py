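"""Unitization, mention extraction, exclusion cascade and network assembly."""

import re
from datetime import timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abstinet import (
    ExclusionFields,
    GamblerRecord,
    Post,
    apply_exclusions,
    build_network,
    extract_mentions,
    resolve_mentions,
    split_sentences,
    unitize_posts,
)
from abstinet.ingest import CommentUnit

from conftest import EPOCH, day


def make_post(sentences, user="A", t=0.0):
    return Post(user=user, timestamp=day(t), sentences=tuple(sentences))


class TestUnitize:
    def test_worked_example_every_unit_names_b(self):
        """A 100-sentence post naming B in each unit sends B 50 comments."""
        sentences = [f"Hello B number {i}" if i % 2 == 0 else "keep going" for i in range(100)]
        units = resolve_mentions(unitize_posts([make_post(sentences)]), {"A", "B"})
        received = sum(1 for u in units if "B" in u.recipients)
        assert len(units) == 50
        assert received == 50

    def test_worked_example_b_named_once(self):
        sentences = ["Hello B"] + ["keep going"] * 99
        units = resolve_mentions(unitize_posts([make_post(sentences)]), {"A", "B"})
        assert len(units) == 50
        assert sum(1 for u in units if "B" in u.recipients) == 1

    def test_single_sentence_post(self):
        units = unitize_posts([make_post(["only one"])])
        assert len(units) == 1
        assert units[0].sentences == ("only one",)

    @pytest.mark.parametrize("n,expected", [(1, 1), (2, 1), (3, 2), (100, 50), (101, 51)])
    def test_unit_counts(self, n, expected):
        units = unitize_posts([make_post([f"s{i}" for i in range(n)])])
        assert len(units) == expected
        assert all(1 <= len(u.sentences) <= 2 for u in units)

    def test_empty_post_skipped(self, caplog):
        units = unitize_posts([make_post([])])
        assert units == []

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.lists(st.text(alphabet="abc ", min_size=1), min_size=0, max_size=9), max_size=6))
    def test_sentence_conservation(self, posts_sentences):
        posts = [make_post(s, user=f"U{i}", t=i) for i, s in enumerate(posts_sentences)]
        units = unitize_posts(posts)
        assert sum(len(u.sentences) for u in units) == sum(len(s) for s in posts_sentences)
        # order within each post is preserved
        for i, s in enumerate(posts_sentences):
            mine = [x for u in units if u.sender == f"U{i}" for x in u.sentences]
            assert mine == list(s)


class TestMentions:
    def test_direct_occurrence(self):
        assert extract_mentions("Thanks B. See you.", {"A", "B", "C"}) == {"B"}

    def test_numeral_username_excluded(self):
        assert extract_mentions("I won 100 yen", {"A", "100"}) == set()

    def test_stop_name_smile(self):
        assert extract_mentions("that made me smile", {"smile", "A"}) == set()

    def test_postscript_marker_removed(self):
        assert extract_mentions("bye P.S. hello", {"P", "S", "hello"}) == {"hello"}

    def test_self_mention_ignored(self):
        unit = CommentUnit(sender="A", timestamp=EPOCH, sentences=("A and B met",))
        assert extract_mentions(unit, {"A", "B"}) == {"B"}

    def test_ascii_case_insensitive_and_idempotent(self):
        r = extract_mentions("hello BOB", {"bob"})
        assert r == {"bob"}
        assert extract_mentions("hello bob", {"bob"}) == r

    def test_substring_is_not_a_mention(self):
        # whole-token matching: "Bob" inside "Bobby" does not count
        assert extract_mentions("hi Bobby", {"Bob", "Bobby"}) == {"Bobby"}

    def test_matches_brute_force_token_scan(self):
        """1e3 random units agree with a regex-free token-scan oracle."""
        rng = np.random.default_rng(3)
        roster = [f"name{i}" for i in range(40)] + [str(i) for i in range(10)]
        vocab = roster + ["the", "won", "yen", "smile", "ok"]
        for _ in range(1000):
            words = rng.choice(vocab, size=rng.integers(1, 12))
            text = " ".join(words)
            # oracle: plain loop over whitespace tokens, no regex
            expected = set()
            for tok in text.split():
                t = tok.lower()
                if t.isdigit() or t == "smile":
                    continue
                for name in roster:
                    if t == name.lower():
                        expected.add(name)
            assert extract_mentions(text, set(roster)) == expected


def fields(wc=10, ads=False, sym=1, rec=1, admin=False):
    return ExclusionFields(
        word_count=wc, ads_only=ads, n_symptoms=sym, received_comments=rec, is_admin=admin
    )


class TestExclusions:
    def _records(self, n):
        return [
            GamblerRecord(username=f"u{i}", abstinent=False, first_post_date=day(0))
            for i in range(n)
        ]

    def test_study_flow_counts(self):
        """Disjoint stage sets 1139/936/802/1 out of 3967 leave 1089."""
        n = 3967
        records = self._records(n)
        f = {}
        i = 0
        for _ in range(1139):
            f[f"u{i}"] = fields(wc=2)
            i += 1
        for _ in range(936):
            f[f"u{i}"] = fields(sym=0)
            i += 1
        for _ in range(802):
            f[f"u{i}"] = fields(rec=0)
            i += 1
        f[f"u{i}"] = fields(admin=True)
        i += 1
        while i < n:
            f[f"u{i}"] = fields()
            i += 1
        included, report = apply_exclusions(records, fields=f)
        assert report.final == len(included) == 1089
        assert report.excluded == {
            "short_or_ads": 1139,
            "no_symptoms": 936,
            "no_received_comments": 802,
            "administrator": 1,
        }

    def test_all_pass(self):
        records = self._records(5)
        f = {r.username: fields() for r in records}
        included, report = apply_exclusions(records, fields=f)
        assert report.final == report.initial == 5
        assert all(v == 0 for v in report.excluded.values())

    def test_overlapping_eligibility_matches_sequential_oracle(self):
        """Random overlapping failure sets reconcile with a brute-force
        first-failing-stage filter."""
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(5, 60))
            records = self._records(n)
            f = {
                r.username: fields(
                    wc=int(rng.integers(0, 6)),
                    ads=bool(rng.random() < 0.1),
                    sym=int(rng.integers(0, 3)),
                    rec=int(rng.integers(0, 3)),
                    admin=bool(rng.random() < 0.1),
                )
                for r in records
            }
            included, report = apply_exclusions(records, fields=f)
            # oracle: independent sequential filter
            stages = {k: 0 for k in report.excluded}
            keep = set()
            for r in records:
                x = f[r.username]
                if x.word_count < 3 or x.ads_only:
                    stages["short_or_ads"] += 1
                elif x.n_symptoms == 0:
                    stages["no_symptoms"] += 1
                elif x.received_comments == 0:
                    stages["no_received_comments"] += 1
                elif x.is_admin:
                    stages["administrator"] += 1
                else:
                    keep.add(r.username)
            assert included == keep
            assert report.excluded == stages
            assert report.final == report.initial - sum(stages.values())

    def test_missing_fields_error(self):
        records = self._records(2)
        with pytest.raises(ValueError, match="u1"):
            apply_exclusions(records, fields={"u0": fields()})


class TestBuildNetwork:
    def test_edge_count_is_sum_of_recipient_sets(self):
        records = [
            GamblerRecord(username=n, abstinent=False, first_post_date=day(0))
            for n in "ABC"
        ]
        units = [
            CommentUnit("A", day(1), ("x",), frozenset({"B", "C"})),
            CommentUnit("B", day(2), ("x",), frozenset({"C"})),
            CommentUnit("A", day(3), ("x",), frozenset()),
        ]
        net = build_network(units, records)
        assert net.n_edges == 3

    def test_group_totals_add_up(self):
        """Edges received by two groups sum to the grand total."""
        rng = np.random.default_rng(5)
        names = [f"u{i}" for i in range(20)]
        records = [
            GamblerRecord(
                username=n,
                abstinent=i < 5,
                abstinence_date=day(100 + i) if i < 5 else None,
                first_post_date=day(0),
            )
            for i, n in enumerate(names)
        ]
        units = [
            CommentUnit(
                names[int(rng.integers(0, 20))],
                day(float(rng.integers(1, 50))),
                ("x",),
                frozenset({names[int(rng.integers(0, 20))]}),
            )
            for _ in range(500)
        ]
        net = build_network(units, records)
        by_group = {True: 0, False: 0}
        for u, v, _ in net.graph.edges(keys=True):
            by_group[net.records[v].abstinent] += 1
        assert by_group[True] + by_group[False] == net.n_edges

    def test_no_units_gives_nodes_only(self):
        records = [GamblerRecord(username="A", abstinent=False, first_post_date=day(0))]
        net = build_network([], records)
        assert net.n_edges == 0 and set(net.graph.nodes) == {"A"}

    def test_unknown_recipient_dropped_or_strict(self):
        records = [GamblerRecord(username="A", abstinent=False, first_post_date=day(0))]
        units = [CommentUnit("A", day(1), ("x",), frozenset({"ghost"}))]
        assert build_network(units, records).n_edges == 0
        with pytest.raises(KeyError):
            build_network(units, records, strict=True)

    def test_edge_multiset_matches_recount_oracle(self, small_synth):
        *_, units, net = small_synth
        expected = {}
        for u in units:
            for r in u.recipients:
                expected[(u.sender, r)] = expected.get((u.sender, r), 0) + 1
        got = {}
        for a, b, _ in net.graph.edges(keys=True):
            got[(a, b)] = got.get((a, b), 0) + 1
        assert got == expected


def test_split_sentences_delimiters():
    assert split_sentences("Hi there. Bye.") == ["Hi there", "Bye"]
    assert split_sentences("こんにちは。さようなら。") == ["こんにちは", "さようなら"]
    assert split_sentences("...") == []
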