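"""Probe collapse, Fisher combination, BH adjustment and signature selection."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from afmeta import (bh_adjust, collapse_probes, combine_studies, fisher_combine,
                    select_signature)


def _de_frame(rows: dict) -> pd.DataFrame:
    """rows: feature -> (beta, p); fills the remaining DE columns."""
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=["beta", "p"])
    frame.index.name = "feature"
    for col, val in [("s2", 0.1), ("d", 4.0), ("v", 0.5), ("t", 0.0),
                     ("df", 8.0), ("q", 1.0)]:
        frame[col] = val
    return frame[["beta", "s2", "d", "v", "t", "df", "p", "q"]]


class TestCollapseProbes:
    def test_lowest_p_probe_kept_verbatim(self):
        de = _de_frame({"p1": (0.7, 0.01), "p2": (-0.2, 0.5)})
        out = collapse_probes(de, {"p1": "GENE1", "p2": "GENE1"})
        assert list(out.index) == ["GENE1"]
        assert out.loc["GENE1", "beta"] == 0.7
        assert out.loc["GENE1", "p"] == 0.01

    def test_single_probe_gene_unchanged(self):
        de = _de_frame({"p1": (0.3, 0.2)})
        out = collapse_probes(de, {"p1": "G"})
        assert out.loc["G", "beta"] == 0.3

    def test_p_tie_broken_by_larger_abs_beta_then_probe_id(self):
        de = _de_frame({"a2": (0.5, 0.1), "a1": (-0.9, 0.1)})
        out = collapse_probes(de, {"a1": "G", "a2": "G"})
        assert out.loc["G", "beta"] == -0.9
        de2 = _de_frame({"b2": (0.5, 0.1), "b1": (0.5, 0.1)})
        out2 = collapse_probes(de2, {"b1": "G", "b2": "G"})
        # residual tie: lexicographically smallest probe wins (identical rows here)
        assert out2.loc["G", "beta"] == 0.5

    def test_unmapped_features_dropped(self):
        de = _de_frame({"p1": (0.1, 0.2), "p2": (0.3, 0.4)})
        out = collapse_probes(de, {"p1": "G1"})
        assert list(out.index) == ["G1"]


class TestFisherCombine:
    def test_single_p_identity(self):
        S, p_meta = fisher_combine([0.3])
        assert S == pytest.approx(-2.0 * np.log(0.3), rel=1e-6)
        assert p_meta == pytest.approx(0.3, rel=1e-9)

    def test_all_ones(self):
        assert fisher_combine([1.0, 1.0]) == (0.0, 1.0)

    def test_chi2_4df_closed_form(self):
        """For k=2 the upper tail is (1 + S/2) * exp(-S/2)."""
        S, p_meta = fisher_combine([0.05, 0.05])
        assert S == pytest.approx(11.9829, abs=1e-4)
        assert p_meta == pytest.approx((1 + S / 2) * np.exp(-S / 2), rel=1e-12)
        assert p_meta == pytest.approx(0.017479, abs=1e-5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
           st.data())
    def test_monotone_in_each_p(self, pvals, data):
        i = data.draw(st.integers(0, len(pvals) - 1))
        smaller = list(pvals)
        smaller[i] = pvals[i] / 2.0
        assert fisher_combine(smaller)[1] < fisher_combine(pvals)[1]


def bh_brute_force(pvals):
    """Independent step-up oracle straight from the definition:
    q_i = min over {j : p_(j) >= p_i} of min(1, m * p_(j) / rank_j)."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    rank = {}
    for r, i in enumerate(order, start=1):
        rank[i] = r
    out = []
    for i in range(m):
        candidates = [min(1.0, m * p[j] / rank[j]) for j in range(m) if p[j] >= p[i]]
        out.append(min(candidates))
    return out


class TestBhAdjust:
    @pytest.mark.parametrize("pvals,expected", [
        ([0.04], [0.04]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.5], [0.01, 0.5]),
    ])
    def test_hand_worked(self, pvals, expected):
        np.testing.assert_allclose(bh_adjust(pvals), expected, rtol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_matches_brute_force(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), bh_brute_force(pvals),
                                   rtol=1e-10, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCombineStudies:
    def _three_study_tables(self):
        s1 = _de_frame({"G1": (0.2, 0.04), "G2": (1.0, 0.5)})
        s2 = _de_frame({"G1": (0.6, 0.03), "G2": (0.9, 0.6), "G3": (0.1, 0.9)})
        s3 = _de_frame({"G1": (0.7, 0.02)})
        return [s1, s2, s3]

    def test_df_bookkeeping_and_medians(self):
        meta = combine_studies(self._three_study_tables()).table
        assert meta.loc["G1", "k"] == 3
        assert meta.loc["G2", "k"] == 2
        assert "G3" not in meta.index  # measured once only
        # p_meta refers S to chi2 on 2k df
        assert meta.loc["G2", "p_meta"] == pytest.approx(
            stats.chi2.sf(meta.loc["G2", "S"], 4), rel=1e-12)
        assert meta.loc["G1", "median_lfc"] == pytest.approx(0.6)   # odd count
        assert meta.loc["G2", "median_lfc"] == pytest.approx(0.95)  # even: mean of middle

    def test_no_shared_gene_rejected(self):
        s1 = _de_frame({"A": (0.1, 0.5)})
        s2 = _de_frame({"B": (0.1, 0.5)})
        with pytest.raises(ValueError, match=">= 2 cohorts"):
            combine_studies([s1, s2])

    def test_requires_two_studies(self):
        with pytest.raises(ValueError):
            combine_studies([_de_frame({"A": (0.1, 0.5)})])

    def test_null_meta_pvalues_uniform(self, null_sim):
        """Under no signal the combined p-values are uniform (KS < 0.025)."""
        _, meta = null_sim
        ks = stats.kstest(meta.table["p_meta"], "uniform").statistic
        assert ks < 0.025


class TestSelectSignature:
    def _meta(self, rows):
        frame = pd.DataFrame(rows, columns=["gene", "q_meta", "median_lfc"])
        return frame.set_index("gene")

    def test_threshold_boundaries_strict(self):
        meta = self._meta([
            ("UP", 0.04, 0.6), ("EDGE_LFC", 0.04, 0.5), ("EDGE_Q", 0.05, 2.0),
            ("MISS", 0.06, 2.0), ("DN", 0.01, -0.8),
        ])
        sig = select_signature(meta)
        assert sig.up == frozenset({"UP"})
        assert sig.down == frozenset({"DN"})

    def test_empty_signature_allowed(self):
        sig = select_signature(self._meta([("G", 0.9, 0.1)]))
        assert len(sig) == 0

    def test_up_down_disjoint_on_fitted_chain(self, fitted_chain):
        _, _, sig = fitted_chain
        assert not (sig.up & sig.down)
        assert len(sig.up) > 0 and len(sig.down) > 0
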