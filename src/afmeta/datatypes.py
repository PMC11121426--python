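"""Shared domain containers for the atrial-fibrillation meta-analysis pipeline.

Three objects travel between pipeline stages: a per-cohort expression study
(log2 intensities with a case/control phenotype), a gene-set library carrying
knockout consensus signatures, and the up/down disease gene signature selected
by the meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CASE = "case"
CONTROL = "control"
VALID_GROUPS = frozenset({CASE, CONTROL})

#: Background gene count assumed by enrichment 2x2 tables when a library
#: carries no explicit universe (roughly the protein-coding human genome).
DEFAULT_UNIVERSE_SIZE = 20_000


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: whitespace-trimmed and uppercased."""
    return symbol.strip().upper()


@dataclass
class ExpressionStudy:
    """One cohort's log2 expression matrix with a two-group phenotype.

    Parameters
    ----------
    study_id : str
        Short cohort identifier.
    features : list of str
        Probe or gene identifiers, one per matrix row.
    samples : list of str
        Sample identifiers, one per matrix column.
    values : ndarray, shape (n_features, n_samples)
        Log2-scale expression intensities.
    groups : list of str
        Per-sample label, ``"case"`` (disease) or ``"control"``.
    feature_to_gene : dict, optional
        Probe-to-gene-symbol map; identity when features are gene symbols.
    log_transformed : bool
        True when the reader applied the log2(x+1) linear-scale heuristic.
    """

    study_id: str
    features: list[str]
    samples: list[str]
    values: np.ndarray
    groups: list[str]
    feature_to_gene: dict[str, str] | None = None
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.features), len(self.samples)):
            raise ValueError(
                f"study {self.study_id!r}: matrix shape {self.values.shape} does not "
                f"match {len(self.features)} features x {len(self.samples)} samples"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError(f"study {self.study_id!r}: duplicate sample IDs")
        if len(set(self.features)) != len(self.features):
            raise ValueError(f"study {self.study_id!r}: duplicate feature IDs")
        if len(self.groups) != len(self.samples):
            raise ValueError(f"study {self.study_id!r}: one group label per sample required")
        bad = sorted(set(self.groups) - VALID_GROUPS)
        if bad:
            raise ValueError(
                f"study {self.study_id!r}: group labels must be 'case'/'control', got {bad}"
            )
        for label in (CASE, CONTROL):
            n = self.groups.count(label)
            if n < 2:
                raise ValueError(
                    f"study {self.study_id!r}: group {label!r} has {n} samples; "
                    "at least 2 are required for a residual variance"
                )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"study {self.study_id!r}: non-finite expression values")

    @property
    def n_case(self) -> int:
        return self.groups.count(CASE)

    @property
    def n_control(self) -> int:
        return self.groups.count(CONTROL)

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([g == CASE for g in self.groups])

    @property
    def control_mask(self) -> np.ndarray:
        return np.array([g == CONTROL for g in self.groups])

    def gene_of(self, feature: str) -> str:
        if self.feature_to_gene is None:
            return normalize_symbol(feature)
        return normalize_symbol(self.feature_to_gene[feature])


@dataclass
class GeneSetLibrary:
    """Named collection of gene sets over a fixed background universe.

    ``sets`` maps a term name (e.g. ``"TLR4_ko Down"``) to a
    ``(description, genes)`` pair. ``universe_size`` is the background gene
    count N used in enrichment contingency tables.
    """

    name: str
    sets: dict[str, tuple[str, frozenset[str]]]
    universe_size: int = DEFAULT_UNIVERSE_SIZE

    def __post_init__(self) -> None:
        if self.universe_size <= 0:
            raise ValueError("universe_size must be positive")
        clean: dict[str, tuple[str, frozenset[str]]] = {}
        for term, (desc, genes) in self.sets.items():
            genes = frozenset(normalize_symbol(g) for g in genes)
            if not genes:
                raise ValueError(f"library {self.name!r}: term {term!r} has an empty gene set")
            if len(genes) > self.universe_size:
                raise ValueError(
                    f"library {self.name!r}: term {term!r} larger than universe "
                    f"({len(genes)} > {self.universe_size})"
                )
            clean[term] = (desc, genes)
        self.sets = clean

    @property
    def terms(self) -> list[str]:
        return list(self.sets)

    def genes(self, term: str) -> frozenset[str]:
        return self.sets[term][1]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out |= genes
        return frozenset(out)


@dataclass
class GeneSignature:
    """Disease signature: the up- and down-regulated gene symbol sets."""

    up: frozenset[str] = field(default_factory=frozenset)
    down: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.up = frozenset(normalize_symbol(g) for g in self.up)
        self.down = frozenset(normalize_symbol(g) for g in self.down)
        shared = self.up & self.down
        if shared:
            raise ValueError(f"genes in both up and down signature: {sorted(shared)[:5]}")

    def __len__(self) -> int:
        return len(self.up) + len(self.down)
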