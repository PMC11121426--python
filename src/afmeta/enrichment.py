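"""Gene-list over-representation against a gene-set library, EnrichR style.

Each (query list, gene set) pair is a 2x2 contingency table on a fixed gene
universe of size N:

                in set   not in set
    in query      a        C - a
    not in query  B - a    N - B - C + a

The p-value is the one-sided (enrichment) Fisher exact / hypergeometric upper
tail P(X >= a); the effect size is the sample odds ratio a*d / (b*c). A
term's z-score measures the deviation of its observed enrichment rank from
the rank it attains on random query lists of the same size (Monte-Carlo
calibration), and the combined score is ln(p) * z — positive for terms
enriched beyond expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import GeneSetLibrary, normalize_symbol
from .meta import bh_adjust


def _check_counts(a: int, B: int, C: int, N: int) -> None:
    if not (0 <= a <= min(B, C)):
        raise ValueError(f"inconsistent counts: a={a} not in [0, min(B={B}, C={C})]")
    if B > N or C > N:
        raise ValueError(f"inconsistent counts: B={B}, C={C} exceed universe N={N}")
    if N - B - C + a < 0:
        raise ValueError(f"inconsistent counts: empty cell negative for a={a}, B={B}, C={C}, N={N}")


def fisher_exact_pvalue(a: int, B: int, C: int, N: int) -> float:
    """One-sided enrichment p-value: P(X >= a), X ~ Hypergeom(N, B, C)."""
    _check_counts(a, B, C, N)
    if a == 0:
        return 1.0
    return float(stats.hypergeom.sf(a - 1, N, B, C))


def odds_ratio(a: int, B: int, C: int, N: int) -> float:
    """Sample odds ratio of the 2x2 enrichment table.

    Returns 0 when there is no overlap and +inf when a margin is exhausted
    with a non-empty diagonal.
    """
    _check_counts(a, B, C, N)
    if a == 0:
        return 0.0
    b, c, d = B - a, C - a, N - B - C + a
    if b * c == 0:
        return math.inf if a * d > 0 else 0.0
    return (a * d) / (b * c)


def combined_score(p: float, z: float) -> float:
    """EnrichR combined score, ln(p) * z; 0 when p = 1 or z = 0."""
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    return math.log(p) * z


def zscore(observed_rank: float, mu_rank: float, sd_rank: float) -> float:
    """Standardized deviation of the observed rank from its null expectation."""
    if sd_rank < 0:
        raise ValueError("sd_rank must be non-negative")
    if sd_rank == 0:
        return 0.0
    return (observed_rank - mu_rank) / sd_rank


def _rank_terms(pvals: dict[str, float]) -> dict[str, int]:
    """1-based ordinal ranks by ascending p, ties broken by term name."""
    order = sorted(pvals, key=lambda t: (pvals[t], t))
    return {term: i + 1 for i, term in enumerate(order)}


def calibrate_expected_ranks(library: GeneSetLibrary, C: int,
                             n_random: int = 100,
                             seed: int | None = None) -> dict[str, tuple[float, float]]:
    """Per-term expected enrichment rank under random query lists of size C.

    Draws ``n_random`` uniform random gene lists of size C from the universe,
    ranks every term by its Fisher exact p on each list, and returns the
    per-term (mean, sd) of those ranks. Only the portion of a random list
    falling inside the library's named genes can create overlap; the size of
    that portion is itself hypergeometric in N, which the sampler respects so
    that between-term rank correlations are preserved.
    """
    terms = library.terms
    if len(terms) < 2:
        raise ValueError("rank calibration needs a library with >= 2 terms")
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    N = library.universe_size
    if C > N:
        raise ValueError(f"query size C={C} exceeds universe N={N}")

    rng = np.random.default_rng(seed)
    named = sorted(library.all_genes())
    u = len(named)
    named_arr = np.array(named)
    term_sets = {t: library.genes(t) for t in terms}

    ranks = {t: np.empty(n_random) for t in terms}
    for i in range(n_random):
        # number of query genes landing inside the named portion of the universe
        h = int(rng.hypergeometric(u, N - u, C)) if u < N else C
        hit = set(named_arr[rng.choice(u, size=h, replace=False)]) if h else set()
        pvals = {
            t: fisher_exact_pvalue(len(hit & genes), len(genes), C, N)
            for t, genes in term_sets.items()
        }
        for t, r in _rank_terms(pvals).items():
            ranks[t][i] = r
    return {t: (float(r.mean()), float(r.std(ddof=0))) for t, r in ranks.items()}


@dataclass
class EnrichmentRow:
    """One (query list, gene set) over-representation test."""

    query_name: str
    term: str
    a: int
    B: int
    C: int
    N: int
    p: float
    q: float
    oddsratio: float
    z: float
    combined: float
    overlap_genes: list[str] = field(default_factory=list)


class EnrichrOverlap:
    """Over-representation model for one query gene list against a library.

    Parameters
    ----------
    query : set of str
        Gene symbols of the query list (e.g. the disease up-signature).
    library : GeneSetLibrary
        Terms to test; carries the universe size N.
    query_name : str
        Label carried into the result rows.
    effective_query_size : int, optional
        Override for C, the query size entering the 2x2 tables. By default C
        is the size of the query after intersecting with the universe
        (everything, since only |universe| = N is known, not its members).
    """

    def __init__(self, query, library: GeneSetLibrary, query_name: str = "query",
                 effective_query_size: int | None = None):
        self.query = frozenset(normalize_symbol(g) for g in query)
        self.library = library
        self.query_name = query_name
        self.effective_query_size = effective_query_size

    def fit(self, n_random: int = 100, seed: int | None = None) -> "EnrichmentResults":
        if not self.query:
            raise ValueError("empty query gene list")
        lib = self.library
        C = self.effective_query_size if self.effective_query_size is not None \
            else len(self.query)
        if C <= 0:
            raise ValueError("effective query size must be positive")

        overlaps = {t: sorted(self.query & lib.genes(t)) for t in lib.terms}
        pvals = {t: fisher_exact_pvalue(len(overlaps[t]), len(lib.genes(t)), C,
                                        lib.universe_size)
                 for t in lib.terms}
        observed_rank = _rank_terms(pvals)
        calib = calibrate_expected_ranks(lib, C, n_random=n_random, seed=seed)
        qvals = dict(zip(lib.terms, bh_adjust([pvals[t] for t in lib.terms])))

        rows = []
        for t in lib.terms:
            a, B = len(overlaps[t]), len(lib.genes(t))
            mu, sd = calib[t]
            z = zscore(observed_rank[t], mu, sd)
            rows.append(EnrichmentRow(
                query_name=self.query_name, term=t, a=a, B=B, C=C,
                N=lib.universe_size, p=pvals[t], q=qvals[t],
                oddsratio=odds_ratio(a, B, C, lib.universe_size),
                z=z, combined=combined_score(pvals[t], z),
                overlap_genes=overlaps[t],
            ))
        rows.sort(key=lambda r: (r.q, r.p, r.term))
        return EnrichmentResults(rows)


class EnrichmentResults:
    """Sorted enrichment rows with a DataFrame view and a summary."""

    def __init__(self, rows: list[EnrichmentRow]):
        self.rows = rows

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([{
            "query_name": r.query_name, "term": r.term, "overlap": f"{r.a}/{r.B}",
            "C": r.C, "N": r.N, "p": r.p, "q": r.q, "oddsratio": r.oddsratio,
            "z": r.z, "combined": r.combined,
            "overlap_genes": ";".join(r.overlap_genes),
        } for r in self.rows])

    def significant(self, alpha: float = 0.05) -> list[EnrichmentRow]:
        return [r for r in self.rows if r.q < alpha]

    def summary(self) -> str:
        lines = [f"Enrichment of {self.rows[0].query_name!r}: "
                 f"{len(self.rows)} terms, {len(self.significant())} with q < 0.05"]
        for r in self.rows[:10]:
            lines.append(f"  {r.term:<24} {r.a}/{r.B}  p={r.p:.3g}  q={r.q:.3g}  "
                         f"OR={r.oddsratio:.3g}  CS={r.combined:.3g}")
        return "\n".join(lines)


def enrich(query, query_name: str, library: GeneSetLibrary,
           n_random: int = 100, seed: int | None = None,
           effective_query_size: int | None = None) -> list[EnrichmentRow]:
    """Functional wrapper: run the over-representation test, return sorted rows."""
    model = EnrichrOverlap(query, library, query_name=query_name,
                           effective_query_size=effective_query_size)
    return model.fit(n_random=n_random, seed=seed).rows
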