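"""Cross-cohort meta-analysis: probe collapse, Fisher's method, FDR, signature selection.

Per-gene evidence from independent cohorts is combined with Fisher's inverse
chi-square method, S = -2 * sum(ln p_i) ~ chi2 on 2k df under the null. The
method is direction-blind, so effect direction comes from the median of the
per-cohort log2 fold changes, and the disease signature is the set of genes
with meta FDR < 0.05 and |median log2FC| > 0.5 (strict inequalities).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSignature, normalize_symbol
from .diffexpr import DEResults

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order preserved)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_combine(pvals) -> tuple[float, float]:
    """Fisher's inverse chi-square combination of independent p-values.

    Returns (S, p_meta) with S = -2 * sum(ln p_i) referred to chi2_{2k}.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("cannot combine an empty p-value list")
    p = np.clip(p, P_FLOOR, 1.0)
    S = float(-2.0 * np.log(p).sum())
    p_meta = float(stats.chi2.sf(S, 2 * p.size))
    return S, p_meta


def collapse_probes(de: DEResults | pd.DataFrame,
                    feature_to_gene: dict[str, str] | None = None) -> pd.DataFrame:
    """Collapse probe-level rows to genes, keeping each gene's lowest-p probe.

    Ties on p are broken by larger |beta|, then by lexicographically smallest
    probe ID, so the collapse is deterministic. Features without a gene
    mapping are dropped (count logged).
    """
    if isinstance(de, DEResults):
        table = de.table
        if feature_to_gene is None:
            feature_to_gene = de.feature_to_gene
    else:
        table = de

    features = table.index.to_numpy()
    if feature_to_gene is None:
        genes = np.array([normalize_symbol(f) for f in features])
        keep = np.ones(len(features), dtype=bool)
    else:
        genes = np.array([
            normalize_symbol(feature_to_gene.get(f, "")) for f in features
        ])
        keep = genes != ""
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("collapse_probes: dropped %d unmapped feature(s)", n_dropped)

    work = table.loc[keep].copy()
    work["gene"] = genes[keep]
    work["_absbeta"] = work["beta"].abs()
    work["_feature"] = work.index.astype(str)
    # lowest p wins; ties: larger |beta|, then smallest probe ID
    work = work.sort_values(["p", "_absbeta", "_feature"],
                            ascending=[True, False, True], kind="mergesort")
    collapsed = work.drop_duplicates("gene", keep="first")
    collapsed = collapsed.set_index("gene").drop(columns=["_absbeta", "_feature"])
    return collapsed.sort_index()


class FisherMetaAnalysis:
    """Fisher's-method meta-analysis across per-cohort DE results.

    Parameters
    ----------
    de_results : list of DEResults (or gene-indexed DataFrames)
        One per cohort. Probe-level results are collapsed to genes first.
    min_datasets : int
        Minimum number of cohorts a gene must be measured in (default 2;
        single-cohort genes would not be meta-analysed at all).
    """

    def __init__(self, de_results, min_datasets: int = 2):
        if len(de_results) < 2:
            raise ValueError("meta-analysis requires at least 2 cohorts")
        self.min_datasets = min_datasets
        self.tables: list[pd.DataFrame] = []
        self.study_ids: list[str] = []
        for i, de in enumerate(de_results):
            if isinstance(de, DEResults):
                self.study_ids.append(de.study_id)
                self.tables.append(collapse_probes(de))
            else:
                self.study_ids.append(f"study{i + 1}")
                self.tables.append(de)

    def fit(self) -> "MetaAnalysisResults":
        long = pd.concat(
            [t[["beta", "p"]].assign(_study=i) for i, t in enumerate(self.tables)]
        )
        rows = []
        for gene, sub in long.groupby(level=0, sort=True):
            if len(sub) < self.min_datasets:
                continue
            S, p_meta = fisher_combine(sub["p"].to_numpy())
            betas = sub["beta"].to_numpy()
            rows.append({
                "gene": gene,
                "k": len(sub),
                "S": S,
                "p_meta": p_meta,
                "median_lfc": float(np.median(betas)),
                "lfc_by_study": ";".join(f"{b:.6g}" for b in betas),
            })
        if not rows:
            raise ValueError(
                f"no gene is measured in >= {self.min_datasets} cohorts"
            )
        table = pd.DataFrame(rows).set_index("gene").sort_index()
        table["q_meta"] = bh_adjust(table["p_meta"].to_numpy())
        table = table[["k", "S", "p_meta", "q_meta", "median_lfc", "lfc_by_study"]]
        return MetaAnalysisResults(table=table, study_ids=self.study_ids,
                                   min_datasets=self.min_datasets)


class MetaAnalysisResults:
    """Combined per-gene meta-analysis table with signature selection."""

    def __init__(self, table: pd.DataFrame, study_ids: list[str], min_datasets: int):
        self.table = table
        self.study_ids = study_ids
        self.min_datasets = min_datasets

    def select_signature(self, fdr_max: float = 0.05,
                         lfc_min: float = 0.5) -> GeneSignature:
        return select_signature(self.table, fdr_max=fdr_max, lfc_min=lfc_min)

    def summary(self) -> str:
        sig = self.select_signature()
        lines = [
            f"Fisher meta-analysis over {len(self.study_ids)} cohorts "
            f"({', '.join(self.study_ids)})",
            f"  genes combined (k >= {self.min_datasets}): {len(self.table)}",
            f"  q_meta < 0.05:                 {int((self.table['q_meta'] < 0.05).sum())}",
            "  signature (q<0.05, |median log2FC|>0.5): "
            f"{len(sig.up)} up / {len(sig.down)} down",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.6g")


def combine_studies(de_by_study, min_datasets: int = 2) -> MetaAnalysisResults:
    """Functional wrapper around :class:`FisherMetaAnalysis`."""
    return FisherMetaAnalysis(de_by_study, min_datasets=min_datasets).fit()


def select_signature(meta_table: pd.DataFrame, fdr_max: float = 0.05,
                     lfc_min: float = 0.5) -> GeneSignature:
    """Select the disease signature: q_meta < fdr_max and |median lfc| > lfc_min.

    Both inequalities are strict; an empty signature is allowed (logged).
    """
    if meta_table.empty:
        raise ValueError("empty meta-analysis table")
    sig_mask = meta_table["q_meta"] < fdr_max
    up = meta_table.index[sig_mask & (meta_table["median_lfc"] > lfc_min)]
    down = meta_table.index[sig_mask & (meta_table["median_lfc"] < -lfc_min)]
    if len(up) == 0 and len(down) == 0:
        logger.warning("signature selection yielded no genes "
                       "(fdr_max=%g, lfc_min=%g)", fdr_max, lfc_min)
    return GeneSignature(up=frozenset(up), down=frozenset(down))
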