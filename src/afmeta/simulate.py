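"""Synthetic five-cohort expression collections and knockout-signature libraries.

The generator emulates the statistical world the analysis assumes: each
cohort is a small two-group microarray study on the log2 scale, gene-wise
variances follow a scaled inverse-chi-square prior (the moderated-t model's
own prior), a fixed fraction of genes carries a planted disease effect shared
across cohorts, and each cohort misses a random subset of genes to emulate
platform differences. A companion generator builds a knockout-style gene-set
library with one term deliberately overlapping the planted up-regulated
genes, so enrichment and concordance recovery can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionStudy, GeneSetLibrary

#: Case/control sizes of the five left-atrial-appendage cohorts the analysis targets.
DEFAULT_COHORT_SIZES: tuple[tuple[int, int], ...] = ((7, 6), (2, 2), (5, 5), (5, 5), (16, 3))


@dataclass
class SimulationConfig:
    """Stated world of the synthetic collection.

    Defaults mirror the target study design: five cohorts with group sizes
    7/6, 2/2, 5/5, 5/5 and 16/3; 5% truly differential genes with log2
    effects around 0.8; variance prior d0=4, s0^2=0.05; 10% of genes
    unmeasured per cohort.
    """

    n_genes: int = 5_000
    cohort_sizes: tuple[tuple[int, int], ...] = DEFAULT_COHORT_SIZES
    frac_de: float = 0.05
    effect_mean: float = 0.8
    effect_sd: float = 0.2
    d0_true: float = 4.0
    s0sq_true: float = 0.05
    missing_frac: float = 0.1
    heterogeneity_sd: float = 0.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for frac, name in ((self.frac_de, "frac_de"), (self.missing_frac, "missing_frac")):
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for (n1, n2) in self.cohort_sizes:
            if n1 < 2 or n2 < 2:
                raise ValueError("each cohort needs >= 2 samples per group")
        if self.effect_mean < 0:
            raise ValueError("effect_mean must be >= 0")
        if self.d0_true <= 0 or self.s0sq_true <= 0:
            raise ValueError("variance prior parameters must be positive")


@dataclass
class TruthTable:
    """Ground truth of a simulated collection: which genes are differential."""

    genes: list[str]
    is_de: np.ndarray
    direction: np.ndarray
    effect: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.is_de = np.asarray(self.is_de, dtype=bool)
        self.direction = np.asarray(self.direction, dtype=int)
        self.effect = np.asarray(self.effect, dtype=float)
        if not ((self.effect != 0) == self.is_de).all():
            raise ValueError("effect must be non-zero exactly for DE genes")

    @property
    def de_genes(self) -> frozenset[str]:
        return frozenset(np.array(self.genes)[self.is_de])

    @property
    def up_genes(self) -> frozenset[str]:
        return frozenset(np.array(self.genes)[self.is_de & (self.direction > 0)])

    @property
    def down_genes(self) -> frozenset[str]:
        return frozenset(np.array(self.genes)[self.is_de & (self.direction < 0)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"is_de": self.is_de, "direction": self.direction, "effect": self.effect},
            index=pd.Index(self.genes, name="gene"),
        )


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def simulate_collection(config: SimulationConfig) -> tuple[list[ExpressionStudy], TruthTable]:
    """Generate the cohort collection and its ground truth.

    Per cohort, each gene draws a variance sigma2_g from
    s0sq * d0 / chi2_{d0}; controls are Normal(baseline_g, sigma2_g) and
    cases are shifted by the gene's planted effect. A seeded per-cohort
    subset of genes (``missing_frac``) is dropped. Identical seeds give
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)

    n_de = round(config.frac_de * config.n_genes)
    is_de = np.zeros(config.n_genes, dtype=bool)
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    is_de[de_idx] = True
    direction = np.zeros(config.n_genes, dtype=int)
    direction[de_idx] = rng.choice([-1, 1], size=n_de)
    magnitude = rng.normal(config.effect_mean, config.effect_sd, size=config.n_genes)
    magnitude = np.abs(magnitude)  # planted effects never change sign by noise
    effect = np.where(is_de, direction * magnitude, 0.0)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)

    studies = []
    for ci, (n_case, n_control) in enumerate(config.cohort_sizes):
        sigma2 = config.s0sq_true * config.d0_true / rng.chisquare(
            config.d0_true, size=config.n_genes)
        sigma = np.sqrt(sigma2)
        cohort_effect = effect
        if config.heterogeneity_sd > 0:
            cohort_effect = effect + np.where(
                is_de, rng.normal(0.0, config.heterogeneity_sd, size=config.n_genes), 0.0)
        ctrl = rng.normal(baseline[:, None], sigma[:, None],
                          size=(config.n_genes, n_control))
        case = rng.normal((baseline + cohort_effect)[:, None], sigma[:, None],
                          size=(config.n_genes, n_case))
        values = np.hstack([case, ctrl])

        n_missing = round(config.missing_frac * config.n_genes)
        missing = np.zeros(config.n_genes, dtype=bool)
        if n_missing:
            missing[rng.choice(config.n_genes, size=n_missing, replace=False)] = True
        keep = ~missing

        study_id = f"cohort{ci + 1}"
        samples = [f"{study_id}_case{j + 1}" for j in range(n_case)] + \
                  [f"{study_id}_ctrl{j + 1}" for j in range(n_control)]
        studies.append(ExpressionStudy(
            study_id=study_id,
            features=[g for g, k in zip(genes, keep) if k],
            samples=samples,
            values=values[keep],
            groups=["case"] * n_case + ["control"] * n_control,
        ))

    truth = TruthTable(genes=genes, is_de=is_de, direction=direction, effect=effect)
    return studies, truth


def feasible_library_params(truth: TruthTable, set_size: int = 245,
                            planted_overlap_frac: float = 0.2) -> tuple[int, float]:
    """Scale the KO-library defaults down to what a small collection supports.

    Keeps set_size at most a tenth of the universe and the planted overlap
    within the available true up-regulated genes.
    """
    n = len(truth.genes)
    set_size = min(set_size, max(10, n // 10))
    n_up = len(truth.up_genes)
    frac = min(planted_overlap_frac, n_up / set_size if set_size else 0.0)
    return set_size, frac


def simulate_ko_library(truth: TruthTable, n_terms: int = 8, set_size: int = 245,
                        planted_term: str = "RCPT1", planted_overlap_frac: float = 0.2,
                        universe: list[str] | None = None,
                        seed: int | None = None) -> GeneSetLibrary:
    """Knockout-style library with one term planted to overlap the disease genes.

    Each of ``n_terms`` receptors contributes an "X_ko Down" and an "X_ko Up"
    set of ``set_size`` genes drawn uniformly from the universe, except that
    the planted receptor's Down set holds
    ``round(planted_overlap_frac * set_size)`` genes sampled from the truly
    up-regulated disease genes (the consensual orientation).
    """
    if not 0 <= planted_overlap_frac <= 1:
        raise ValueError("planted_overlap_frac must lie in [0, 1]")
    universe = list(universe) if universe is not None else list(truth.genes)
    if set_size > len(universe):
        raise ValueError(f"set_size {set_size} exceeds universe size {len(universe)}")
    n_planted = round(planted_overlap_frac * set_size)
    up_pool = sorted(truth.up_genes)
    if n_planted > len(up_pool):
        raise ValueError(
            f"requested {n_planted} planted genes but only {len(up_pool)} "
            "true up-regulated genes exist"
        )

    rng = np.random.default_rng(seed)
    universe_arr = np.array(sorted(universe))
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    receptors = [planted_term] + [f"RND{i + 1}" for i in range(n_terms - 1)]
    for receptor in receptors:
        for direction in ("Down", "Up"):
            term = f"{receptor}_ko {direction}"
            if receptor == planted_term and direction == "Down" and n_planted:
                planted = rng.choice(len(up_pool), size=n_planted, replace=False)
                planted_genes = {up_pool[i] for i in planted}
                remainder = np.setdiff1d(universe_arr, np.array(sorted(planted_genes)))
                fill = rng.choice(len(remainder), size=set_size - n_planted, replace=False)
                genes = planted_genes | set(remainder[fill])
            else:
                pick = rng.choice(len(universe_arr), size=set_size, replace=False)
                genes = set(universe_arr[pick])
            sets[term] = (f"synthetic {receptor} knockout consensus", frozenset(genes))

    return GeneSetLibrary(name="synthetic_ko", sets=sets, universe_size=len(universe))
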