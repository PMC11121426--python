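"""Disease-signature vs knockout-signature concordance.

For a receptor with knockout consensus "Up" and "Down" sets, the disease
up/down signature crosses them in four cells. A disease-up gene inside the
knockout-down set (or disease-down inside knockout-up) is *consensual*: its
expression falls when the receptor is removed and rises in disease,
consistent with receptor-driven regulation. The mirror cells are *opposite*.
A receptor is called specific when only consensual cells reach significance,
non-specific when both orientations do.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datatypes import DEFAULT_UNIVERSE_SIZE, GeneSetLibrary, GeneSignature
from .enrichment import fisher_exact_pvalue, odds_ratio
from .meta import bh_adjust

#: (query direction, knockout direction) cell keys in fixed order.
CELL_KEYS = (("up", "down"), ("up", "up"), ("down", "down"), ("down", "up"))
CONSENSUAL_CELLS = (("up", "down"), ("down", "up"))
OPPOSITE_CELLS = (("up", "up"), ("down", "down"))


@dataclass
class ConcordanceCell:
    query_direction: str
    ko_direction: str
    a: int
    B: int
    C: int
    N: int
    p: float
    q: float
    oddsratio: float
    genes: list[str]


@dataclass
class ConcordanceSummary:
    """Four-cell cross-tabulation of a disease signature against one receptor."""

    receptor: str
    cells: dict[tuple[str, str], ConcordanceCell]

    @property
    def consensual_total(self) -> int:
        return sum(self.cells[k].a for k in CONSENSUAL_CELLS)

    @property
    def opposite_total(self) -> int:
        return sum(self.cells[k].a for k in OPPOSITE_CELLS)

    @property
    def consensual_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for k in CONSENSUAL_CELLS:
            out |= set(self.cells[k].genes)
        return frozenset(out)

    @property
    def opposite_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for k in OPPOSITE_CELLS:
            out |= set(self.cells[k].genes)
        return frozenset(out)


def cross_tabulate(signature: GeneSignature,
                   receptor_sets: tuple[frozenset[str], frozenset[str]],
                   N: int = DEFAULT_UNIVERSE_SIZE,
                   receptor: str = "receptor",
                   effective_up_size: int | None = None,
                   effective_down_size: int | None = None) -> ConcordanceSummary:
    """Cross the disease up/down signature with a receptor's KO up/down sets.

    ``receptor_sets`` is (KO-up genes, KO-down genes). BH adjustment is over
    the receptor's own four cells (m = 4), mirroring per-receptor reporting.
    """
    ko_up, ko_down = receptor_sets
    if not ko_up or not ko_down:
        raise ValueError(f"{receptor}: both KO-up and KO-down sets are required")

    query = {"up": signature.up, "down": signature.down}
    csize = {"up": effective_up_size if effective_up_size is not None else len(signature.up),
             "down": effective_down_size if effective_down_size is not None
             else len(signature.down)}
    ko = {"up": frozenset(ko_up), "down": frozenset(ko_down)}

    raw = {}
    for qdir, kdir in CELL_KEYS:
        genes = sorted(query[qdir] & ko[kdir])
        a, B, C = len(genes), len(ko[kdir]), csize[qdir]
        p = fisher_exact_pvalue(a, B, C, N) if C > 0 else 1.0
        orat = odds_ratio(a, B, C, N) if C > 0 else 0.0
        raw[(qdir, kdir)] = (a, B, C, p, orat, genes)

    qvals = bh_adjust([raw[k][3] for k in CELL_KEYS])
    cells = {}
    for key, q in zip(CELL_KEYS, qvals):
        a, B, C, p, orat, genes = raw[key]
        cells[key] = ConcordanceCell(
            query_direction=key[0], ko_direction=key[1],
            a=a, B=B, C=C, N=N, p=p, q=float(q), oddsratio=orat, genes=genes,
        )
    return ConcordanceSummary(receptor=receptor, cells=cells)


def assess_specificity(summary: ConcordanceSummary, alpha: float = 0.05) -> str:
    """Classify a receptor's association: 'specific', 'non-specific' or 'none'.

    Specific: at least one consensual cell significant and no opposite cell.
    Non-specific: significant cells in both orientations. None: no cell.
    """
    consensual_sig = any(summary.cells[k].q < alpha for k in CONSENSUAL_CELLS)
    opposite_sig = any(summary.cells[k].q < alpha for k in OPPOSITE_CELLS)
    if consensual_sig and not opposite_sig:
        return "specific"
    if consensual_sig and opposite_sig:
        return "non-specific"
    if opposite_sig:
        return "non-specific"
    return "none"


def overlap_matrix(signature: GeneSignature, library: GeneSetLibrary) -> pd.DataFrame:
    """Boolean gene x set membership table for UpSet/Venn-style rendering.

    Rows are the union of signature genes and library genes; columns are
    AF-up, AF-down, then each library term.
    """
    genes = sorted(signature.up | signature.down | library.all_genes())
    columns = {"AF-up": signature.up, "AF-down": signature.down}
    for term in library.terms:
        columns[term] = library.genes(term)
    data = {name: [g in members for g in genes] for name, members in columns.items()}
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"))


def summaries_to_rows(summaries: list[ConcordanceSummary],
                      alpha: float = 0.05) -> pd.DataFrame:
    """Flatten per-receptor summaries to one TSV-ready row per receptor."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {"receptor": s.receptor,
                                  "specificity": assess_specificity(s, alpha=alpha),
                                  "consensual_total": s.consensual_total,
                                  "opposite_total": s.opposite_total}
        for qdir, kdir in CELL_KEYS:
            c = s.cells[(qdir, kdir)]
            stem = f"{qdir}_vs_ko_{kdir}"
            row[f"{stem}_overlap"] = f"{c.a}/{c.B}"
            row[f"{stem}_p"] = c.p
            row[f"{stem}_q"] = c.q
            row[f"{stem}_or"] = c.oddsratio
            row[f"{stem}_genes"] = ";".join(c.genes)
        rows.append(row)
    return pd.DataFrame(rows)
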