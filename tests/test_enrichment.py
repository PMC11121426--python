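"""Fisher exact enrichment, odds ratios, rank calibration, combined score."""

from __future__ import annotations

import math

import numpy as np
import pytest

from afmeta import (EnrichrOverlap, GeneSetLibrary, calibrate_expected_ranks,
                    combined_score, enrich, fisher_exact_pvalue, odds_ratio,
                    zscore)


def hypergeom_upper_tail_brute(a, B, C, N):
    """Enumeration oracle: P(X >= a) from the exact hypergeometric mass."""
    total = math.comb(N, C)
    return sum(math.comb(B, x) * math.comb(N - B, C - x)
               for x in range(a, min(B, C) + 1)) / total


class TestFisherExact:
    @pytest.mark.parametrize("a,B,C,N,expected", [
        (0, 3, 3, 10, 1.0),
        (2, 3, 3, 10, 22 / 120),
        (3, 3, 3, 10, 1 / 120),
    ])
    def test_enumerated_examples(self, a, B, C, N, expected):
        assert fisher_exact_pvalue(a, B, C, N) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("N", [5, 10, 17, 25])
    def test_exhaustive_against_enumeration(self, N):
        """Every consistent table up to the given universe size."""
        for B in range(1, N + 1):
            for C in range(1, N + 1):
                for a in range(max(0, B + C - N), min(B, C) + 1):
                    assert fisher_exact_pvalue(a, B, C, N) == pytest.approx(
                        hypergeom_upper_tail_brute(a, B, C, N), rel=1e-9), (a, B, C, N)

    def test_monotone_in_overlap(self):
        ps = [fisher_exact_pvalue(a, 40, 30, 200) for a in range(0, 31)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_pvalue(5, 3, 10, 100)
        with pytest.raises(ValueError):
            fisher_exact_pvalue(1, 300, 10, 100)


class TestOddsRatio:
    @pytest.mark.parametrize("a,B,C,expected,decimals", [
        (17, 243, 565, 2.637, 3),   # receptor-4 KO down vs disease up
        (27, 246, 565, 4.40, 2),    # adaptor KO down vs disease up
        (9, 246, 287, 2.660, 3),    # receptor-4 KO up vs disease down
    ])
    def test_published_contingency_tables(self, a, B, C, expected, decimals):
        """Sample odds ratios on the 20k-gene universe match printed values."""
        assert round(odds_ratio(a, B, C, 20_000), decimals) == expected

    def test_zero_overlap(self):
        assert odds_ratio(0, 10, 10, 100) == 0.0

    def test_exhausted_margin_is_infinite(self):
        assert odds_ratio(10, 10, 20, 100) == math.inf

    def test_matches_cell_formula(self):
        a, B, C, N = 7, 50, 40, 500
        b, c, d = B - a, C - a, N - B - C + a
        assert odds_ratio(a, B, C, N) == pytest.approx(a * d / (b * c))


def _library(n_terms=6, set_size=30, universe=400, seed=2):
    rng = np.random.default_rng(seed)
    genes = [f"U{i}" for i in range(universe)]
    sets = {}
    for t in range(n_terms):
        pick = rng.choice(universe, size=set_size, replace=False)
        sets[f"T{t}_ko Down"] = ("synthetic", frozenset(genes[i] for i in pick))
    return GeneSetLibrary("toy", sets, universe_size=universe), genes


class TestRankCalibration:
    def test_exchangeable_terms_center_on_mid_rank(self):
        lib, _ = _library()
        calib = calibrate_expected_ranks(lib, C=50, n_random=300, seed=4)
        mid = (len(lib.terms) + 1) / 2.0
        for mu, _sd in calib.values():
            assert mu == pytest.approx(mid, abs=0.6)

    def test_seed_determinism(self):
        lib, _ = _library()
        assert calibrate_expected_ranks(lib, 40, n_random=20, seed=9) == \
               calibrate_expected_ranks(lib, 40, n_random=20, seed=9)

    def test_single_repetition_rejected(self):
        lib, _ = _library()
        with pytest.raises(ValueError):
            calibrate_expected_ranks(lib, 40, n_random=1, seed=0)

    def test_single_term_library_rejected(self):
        lib = GeneSetLibrary("one", {"T_ko Down": ("d", frozenset({"A", "B"}))},
                             universe_size=50)
        with pytest.raises(ValueError):
            calibrate_expected_ranks(lib, 10, n_random=10, seed=0)


class TestScores:
    @pytest.mark.parametrize("rank,mu,sd,expected", [
        (50.0, 50.0, 10.0, 0.0),
        (30.0, 50.0, 10.0, -2.0),
        (30.0, 50.0, 0.0, 0.0),
    ])
    def test_zscore(self, rank, mu, sd, expected):
        assert zscore(rank, mu, sd) == expected

    @pytest.mark.parametrize("p,z,expected", [
        (1.0, -3.0, 0.0),
        (0.01, -2.0, 9.2103),
        (0.5, 0.0, 0.0),
    ])
    def test_combined_score(self, p, z, expected):
        assert combined_score(p, z) == pytest.approx(expected, abs=1e-4)

    def test_combined_rejects_bad_p(self):
        with pytest.raises(ValueError):
            combined_score(0.0, 1.0)


class TestEnrich:
    def test_planted_term_recovered(self, fitted_chain, planted_library):
        """The term seeded with true disease genes ranks first with q < 0.05."""
        _, _, sig = fitted_chain
        rows = enrich(sig.up, "Fibrillation Up", planted_library,
                      n_random=100, seed=21)
        assert rows[0].term == "RCPT1_ko Down"
        assert rows[0].q < 0.05
        others = [r for r in rows if r.term != "RCPT1_ko Down"]
        assert all(r.p > rows[0].p for r in others)

    def test_disjoint_query_is_flat(self):
        lib, _ = _library()
        rows = enrich({"ZZZ1", "ZZZ2", "ZZZ3"}, "q", lib, n_random=10, seed=0)
        assert all(r.a == 0 and r.p == 1.0 and r.oddsratio == 0.0 for r in rows)

    def test_p_and_or_independent_of_calibration_depth(self):
        lib, genes = _library()
        query = set(genes[:60])
        r1 = enrich(query, "q", lib, n_random=10, seed=3)
        r2 = enrich(query, "q", lib, n_random=20, seed=3)
        for a, b in zip(sorted(r1, key=lambda r: r.term),
                        sorted(r2, key=lambda r: r.term)):
            assert a.p == b.p and a.oddsratio == b.oddsratio

    def test_row_invariants(self, fitted_chain, planted_library):
        _, _, sig = fitted_chain
        rows = enrich(sig.up, "Fibrillation Up", planted_library,
                      n_random=50, seed=2)
        for r in rows:
            assert 0 <= r.a <= min(r.B, r.C)
            assert len(r.overlap_genes) == r.a
            assert r.combined == pytest.approx(math.log(r.p) * r.z, abs=1e-9)
        qs = [r.q for r in rows]
        assert qs == sorted(qs)

    def test_empty_query_rejected(self):
        lib, _ = _library()
        with pytest.raises(ValueError):
            EnrichrOverlap(set(), lib).fit(seed=0)

    def test_effective_query_size_override(self):
        lib, genes = _library()
        rows = enrich(set(genes[:60]), "q", lib, n_random=10, seed=0,
                      effective_query_size=80)
        assert all(r.C == 80 for r in rows)
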