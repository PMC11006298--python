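"""GMT IO and hypergeometric over-representation."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from ppidiffuse.enrichment import (
    GeneSetCollection,
    enrich,
    enrichment_report,
    hypergeom_upper_tail,
    read_gmt,
    write_gmt,
)
from ppidiffuse.network import NetworkParseError


def hypergeom_tail_exact(k, K, n, N) -> Fraction:
    """Exact upper tail by big-rational summation of the pmf."""
    if k <= 0:
        return Fraction(1)
    hi = min(K, n)
    total = sum(
        Fraction(math.comb(K, j) * math.comb(N - K, n - j))
        for j in range(k, hi + 1)
    )
    return Fraction(total, math.comb(N, n))


def hypergeom_tail_enumerate(k, K, n, N) -> Fraction:
    """Exact upper tail by exhaustive enumeration of all n-subsets."""
    marked = set(range(K))
    hits = sum(
        1 for subset in itertools.combinations(range(N), n)
        if len(marked.intersection(subset)) >= k
    )
    return Fraction(hits, math.comb(N, n))


class TestReadGmt:
    def test_two_line_fixture(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tfirst\ta\tb\tc\nS2\tsecond\tc\td\n")
        coll = read_gmt(p)
        assert len(coll) == 2
        assert coll.members("S1") == ("a", "b", "c")
        assert coll.members("S2") == ("c", "d")

    def test_duplicate_member_deduplicated(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tdesc\ta\tb\ta\n")
        assert read_gmt(p).members("S1") == ("a", "b")

    def test_short_line_and_duplicate_id_errors(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tonly-desc\n")
        with pytest.raises(NetworkParseError, match="line 1"):
            read_gmt(p)
        p.write_text("S1\td\ta\nS1\td\tb\n")
        with pytest.raises(NetworkParseError, match="duplicate"):
            read_gmt(p)

    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection(
            sets={"B": ("two", ("x", "y")), "A": ("one", ("a", "b", "c"))}
        )
        p1, p2 = tmp_path / "a.gmt", tmp_path / "b.gmt"
        write_gmt(coll, p1)
        back = read_gmt(p1)
        assert back.sets == coll.sets
        write_gmt(back, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestHypergeomUpperTail:
    def test_k_zero_is_one(self):
        assert hypergeom_upper_tail(0, 5, 4, 10) == 1.0

    def test_small_closed_form(self):
        # all 4 draws marked out of 5 marked in 10: C(5,4)/C(10,4) = 5/210
        assert hypergeom_upper_tail(4, 5, 4, 10) == pytest.approx(
            5 / 210, rel=1e-12
        )

    def test_matches_exhaustive_enumeration_small(self):
        for N in (4, 7, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        p = hypergeom_upper_tail(k, K, n, N)
                        exact = hypergeom_tail_enumerate(k, K, n, N)
                        assert p == pytest.approx(float(exact), rel=1e-10)

    def test_matches_big_rational_oracle_large(self):
        rng = np.random.default_rng(99)
        for _ in range(20)  :
            N = int(rng.integers(500, 2500))
            K = int(rng.integers(1, N // 5))
            n = int(rng.integers(1, N // 5))
            lam = K * n / N
            k = int(rng.integers(1, max(2, min(K, n, int(3 * lam) + 5))))
            exact = hypergeom_tail_exact(k, K, n, N)
            assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
                float(exact), rel=1e-12
            )

    def test_monotone_in_k(self):
        ps = [hypergeom_upper_tail(k, 40, 169, 2000) for k in range(0, 30)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_bound_violations_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(3, 11, 4, 10)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 5, 4, 10)


class TestEnrich:
    def coll(self, **sets):
        return GeneSetCollection(
            sets={k: (k.lower(), tuple(v)) for k, v in sets.items()}
        )

    def test_min_overlap_boundary(self):
        universe = [f"u{i}" for i in range(100)]
        coll = self.coll(P=["u0", "u1", "u50", "u60"])
        recs = enrich(["u0", "u1", "u2"], "POSITIVE", coll, universe)
        (r,) = recs
        assert r.k == 2 and not r.passes_filters  # needs >= 3 overlap

    def test_pathway_equal_to_selection(self):
        universe = [f"u{i}" for i in range(50)]
        sel = ["u0", "u1", "u2", "u3"]
        coll = self.coll(P=sel)
        (r,) = enrich(sel, "POSITIVE", coll, universe)
        assert r.k == r.n == 4 and r.K == 4
        assert r.p == pytest.approx(1 / math.comb(50, 4), rel=1e-9)
        assert r.passes_filters

    def test_K_is_in_universe_size(self):
        universe = [f"u{i}" for i in range(20)]
        coll = self.coll(P=["u0", "u1", "ghost1", "ghost2"])
        (r,) = enrich(["u0", "u1"], "POSITIVE", coll, universe, min_overlap=1)
        assert r.K == 2

    def test_sorted_by_p_then_id(self):
        universe = [f"u{i}" for i in range(200)]
        sel = [f"u{i}" for i in range(10)]
        coll = self.coll(
            B=["u0", "u1", "u2"], A=["u0", "u1", "u2"], C=["u0", "u100"]
        )
        recs = enrich(sel, "POSITIVE", coll, universe)
        assert [r.pathway for r in recs] == ["A", "B", "C"]

    def test_results_independent_of_file_order(self, tmp_path):
        a = tmp_path / "a.gmt"
        b = tmp_path / "b.gmt"
        a.write_text("S1\td\tu0\tu1\tu2\nS2\td\tu5\tu6\n")
        b.write_text("S2\td\tu5\tu6\nS1\td\tu0\tu1\tu2\n")
        universe = [f"u{i}" for i in range(30)]
        sel = ["u0", "u1", "u2", "u5"]
        ra = enrich(sel, "P", read_gmt(a), universe, min_overlap=1)
        rb = enrich(sel, "P", read_gmt(b), universe, min_overlap=1)
        assert ra == rb

    def test_empty_universe_and_bad_selection(self):
        coll = self.coll(P=["a"])
        with pytest.raises(ValueError, match="universe"):
            enrich(["a"], "P", coll, [])
        with pytest.raises(ValueError, match="subset"):
            enrich(["zz"], "P", coll, ["a", "b"])

    def test_type_one_error_controlled_on_random_selections(self):
        # decoy pathways vs random selections: P(p < 0.05) should be ~<= 0.05
        rng = np.random.default_rng(123)
        universe = [f"u{i}" for i in range(500)]
        n_tests = 0
        n_hits = 0
        for rep in range(40):
            sel = [universe[i]
                   for i in rng.choice(500, size=25, replace=False)]
            sets = {}
            for j in range(25):
                members = [universe[i]
                           for i in rng.choice(500, size=30, replace=False)]
                sets[f"D{j}"] = ("decoy", tuple(members))
            recs = enrich(sel, "P", GeneSetCollection(sets=sets), universe,
                          min_overlap=1)
            got = {r.pathway: r for r in recs}
            for j in range(25):
                n_tests += 1
                r = got.get(f"D{j}")
                if r is not None and r.p < 0.05:
                    n_hits += 1
        rate = n_hits / n_tests
        se = math.sqrt(0.05 * 0.95 / n_tests)
        assert rate <= 0.05 + 3 * se


class TestEnrichmentReport:
    def test_zero_passing_warns_but_writes_header(self, tmp_path):
        out = tmp_path / "r.tsv"
        with pytest.warns(UserWarning, match="no enrichment"):
            n = enrichment_report([], [], out)
        assert n == 0
        assert out.read_text().startswith("pathway\tdirection")

    def test_row_count_equals_nonzero_overlap_pathways(self, tmp_path):
        universe = [f"u{i}" for i in range(100)]
        sel = [f"u{i}" for i in range(8)]
        coll = GeneSetCollection(sets={
            "A": ("a", ("u0", "u1", "u2")),
            "B": ("b", ("u90", "u91")),          # no overlap -> no record
            "C": ("c", ("u3", "u50", "u51")),
        })
        recs = enrich(sel, "POSITIVE", coll, universe, min_overlap=1)
        out = tmp_path / "r.tsv"
        enrichment_report(recs, [], out)
        rows = out.read_text().strip().splitlines()[1:]
        assert len(rows) == len(recs) == 2

    def test_shared_pathway_two_directions(self, tmp_path):
        universe = [f"u{i}" for i in range(60)]
        coll = GeneSetCollection(sets={"A": ("a", ("u0", "u1", "u2", "u3"))})
        pos = enrich(["u0", "u1", "u2"], "POSITIVE", coll, universe)
        neg = enrich(["u2", "u3", "u4"], "NEGATIVE", coll, universe,
                     min_overlap=1)
        out = tmp_path / "r.tsv"
        enrichment_report(pos, neg, out)
        rows = [l.split("\t") for l in out.read_text().strip().splitlines()[1:]]
        assert {(r[0], r[1]) for r in rows} == {
            ("A", "POSITIVE"), ("A", "NEGATIVE")
        }
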