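"""Distances and the composite UTR-to-riboswitch similarity score."""

from functools import lru_cache

import numpy as np
import pytest

from riboscreen.features import STRUCT_SLICE, featurize, fit_normalizer
from riboscreen.similarity import (
    SimilarityContext, j_sim, length_distance, levenshtein, matches_to_frame,
    struct_distance, top_matches,
)
from riboscreen.simulate import random_dot
from riboscreen.structure import SecondaryStructure


def naive_levenshtein(a: str, b: str) -> int:
    """The textbook recursive edit-distance definition (memoized)."""
    @lru_cache(maxsize=None)
    def lev(x, y):
        if not y:
            return len(x)
        if not x:
            return len(y)
        if x[0] == y[0]:
            return lev(x[1:], y[1:])
        return 1 + min(lev(x[1:], y), lev(x, y[1:]), lev(x[1:], y[1:]))
    return lev(a, b)


@pytest.mark.parametrize("pair, expected", [
    ((300, 100), 200), ((25, 25), 0), ((476, 25), 451), ((100, 300), 200),
])
def test_length_distance(pair, expected):
    assert length_distance(*pair) == expected


class TestStructDistance:
    def test_identical_vectors_give_zero(self, rng):
        v = rng.random(74)
        assert struct_distance(v, v) == 0.0

    def test_unit_difference_in_one_structural_entry(self):
        a = np.zeros(74)
        b = np.zeros(74)
        b[65] = 1.0
        assert struct_distance(a, b) == 1.0

    def test_sums_squared_diffs_over_structural_block_only(self, rng):
        a, b = rng.random(74), rng.random(74)
        expected = float(np.sum((a[65:74] - b[65:74]) ** 2))
        assert struct_distance(a, b) == pytest.approx(expected)
        # sequence block must not contribute
        b2 = b.copy()
        b2[:65] = 0.0
        assert struct_distance(a, b2) == pytest.approx(
            float(np.sum((a[65:74] - b2[65:74]) ** 2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            struct_distance(np.zeros(74), np.zeros(9))


class TestLevenshtein:
    @pytest.mark.parametrize("a, b, d", [
        ("", "((..))", 6), ("((..))", "", 6), ("", "", 0),
        ("((.))", "((.))", 0), ("((.))", "(...)", 2),
    ])
    def test_known_values(self, a, b, d):
        assert levenshtein(a, b) == d

    def test_equals_recursive_definition_on_sampled_strings(self, rng):
        chars = np.array(list("()."))
        for _ in range(500):
            a = "".join(rng.choice(chars, int(rng.integers(0, 9))))
            b = "".join(rng.choice(chars, int(rng.integers(0, 9))))
            assert levenshtein(a, b) == naive_levenshtein(a, b)

    def test_metric_properties(self, rng):
        dots = [random_dot(rng, int(rng.integers(3, 25))) for _ in range(30)]
        for _ in range(200):
            x, y, z = (dots[i] for i in rng.integers(0, len(dots), 3))
            assert levenshtein(x, y) == levenshtein(y, x)
            assert levenshtein(x, z) <= levenshtein(x, y) + levenshtein(y, z)
            assert levenshtein(x, x) == 0


def _mini_reference(rng, n=5):
    """Hand-built featurized riboswitch reference corpus."""
    entries = []
    sss = []
    for i in range(n):
        dot = random_dot(rng, int(rng.integers(30, 80)))
        ss = SecondaryStructure(dot=dot, mfe=float(-rng.uniform(1, 20)))
        sss.append(ss)
        entries.append({"id": f"rs{i:02d}", "length": len(dot), "dot": dot,
                        "ligand": ["TPP", "SAM", "FMN"][i % 3], "ss": ss})
    norm = fit_normalizer(sss)
    for e in entries:
        seq = "".join(rng.choice(list("ACGU"), e["length"]))
        e["seq"] = seq
        e["features"] = featurize(seq, e["ss"], norm)
    return entries, norm


class TestJSim:
    def test_self_comparison_scores_one(self, rng):
        entries, norm = _mini_reference(rng)
        q = entries[0]
        ctx = SimilarityContext(max_rs_length=476, min_length=25)
        matches = j_sim(q["id"], q["length"], q["dot"], q["features"],
                        [{k: e[k] for k in ("id", "length", "dot", "features", "ligand")}
                         for e in entries], ctx)
        self_match = next(m for m in matches if m.rs_id == q["id"])
        assert self_match.j_sim == 1.0
        assert self_match.d_l == self_match.d_lev == 0
        assert self_match.d_struct == 0.0

    def test_scores_bounded_and_match_arithmetic_oracle(self, rng):
        entries, _ = _mini_reference(rng, n=6)
        refs = [{k: e[k] for k in ("id", "length", "dot", "features", "ligand")}
                for e in entries]
        ctx = SimilarityContext(max_rs_length=476, min_length=25)
        q = entries[3]
        matches = j_sim(q["id"], q["length"], q["dot"], q["features"], refs, ctx)
        max_dstruct = max(struct_distance(q["features"], r["features"]) for r in refs)
        for m, r in zip(matches, refs):
            expected = 1 - (
                length_distance(q["length"], r["length"]) / ctx.max_dl
                + levenshtein(q["dot"], r["dot"]) / ctx.max_dlev(q["length"])
                + struct_distance(q["features"], r["features"]) / max_dstruct
            ) / 3
            assert m.j_sim == pytest.approx(max(0.0, min(1.0, expected)))
            assert 0.0 <= m.j_sim <= 1.0

    def test_empty_reference_rejected(self, rng):
        ctx = SimilarityContext(max_rs_length=476, min_length=25)
        with pytest.raises(ValueError, match="empty"):
            j_sim("q", 100, ".." * 20, np.zeros(74), [], ctx)

    def test_context_normalizers_follow_corpus_conventions(self):
        ctx = SimilarityContext.from_corpus(rs_lengths=[100, 476, 30],
                                            utr_lengths=[25, 300])
        assert ctx.max_dl == 476 - 25
        assert ctx.max_dlev(100) == max(451 - 100, 100)
        assert ctx.max_dlev(400) == 400


class TestTopMatches:
    def test_ranking_matches_brute_force_and_ties_break_by_id(self, rng):
        entries, _ = _mini_reference(rng, n=5)
        refs = [{k: e[k] for k in ("id", "length", "dot", "features", "ligand")}
                for e in entries]
        ctx = SimilarityContext(max_rs_length=476, min_length=25)
        q = entries[1]
        top, _ = top_matches(q["id"], q["length"], q["dot"], q["features"],
                             refs, ctx, k=3)
        all_matches = j_sim(q["id"], q["length"], q["dot"], q["features"], refs, ctx)
        brute = sorted(all_matches, key=lambda m: (-m.j_sim, m.rs_id))[:3]
        assert [m.rs_id for m in top] == [m.rs_id for m in brute]
        assert top[0].rs_id == q["id"] and top[0].j_sim == 1.0

    def test_invariant_to_reference_order(self, rng):
        entries, _ = _mini_reference(rng, n=6)
        refs = [{k: e[k] for k in ("id", "length", "dot", "features", "ligand")}
                for e in entries]
        ctx = SimilarityContext(max_rs_length=476, min_length=25)
        q = entries[2]
        args = (q["id"], q["length"], q["dot"], q["features"])
        a, _ = top_matches(*args, refs, ctx, k=4)
        b, _ = top_matches(*args, refs[::-1], ctx, k=4)
        assert [m.rs_id for m in a] == [m.rs_id for m in b]

    def test_tally_conserves_counts_and_k_overflow_warns(self, rng):
        entries, _ = _mini_reference(rng, n=5)
        refs = [{k: e[k] for k in ("id", "length", "dot", "features", "ligand")}
                for e in entries]
        ctx = SimilarityContext(max_rs_length=476, min_length=25)
        q = entries[0]
        with pytest.warns(UserWarning, match="exceeds"):
            top, tally = top_matches(q["id"], q["length"], q["dot"],
                                     q["features"], refs, ctx, k=10, tally=5)
        assert len(top) == 5
        assert sum(tally.values()) == 5
        frame = matches_to_frame(top)
        assert list(frame["rank"]) == [1, 2, 3, 4, 5]
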