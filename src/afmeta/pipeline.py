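"""End-to-end orchestration: simulate/read -> DE -> meta -> signature -> enrichment -> concordance.

A single :class:`PipelineConfig` (loadable from YAML) drives the whole run;
all artifacts are TSV/text files in the output directory plus a JSON manifest
(seed, thresholds, input digests) sufficient to reproduce the run. One global
seed fans out to per-stage seeds through a fixed offset table so stages stay
individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .concordance import cross_tabulate, overlap_matrix, summaries_to_rows
from .datatypes import DEFAULT_UNIVERSE_SIZE, GeneSetLibrary, GeneSignature
from .diffexpr import run_de
from .enrichment import EnrichrOverlap
from .io import read_expression_tsv, read_gmt, write_gene_list, write_gmt
from .meta import combine_studies
from .simulate import (SimulationConfig, feasible_library_params,
                       simulate_collection, simulate_ko_library)

logger = logging.getLogger(__name__)

#: Fixed per-stage seed offsets derived from the global seed.
STAGE_SEED_OFFSETS = {"simulate": 0, "ko_library": 101, "enrich": 211}


def stage_seed(seed: int, stage: str) -> int:
    return (seed + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run."""

    output_dir: str = "afmeta_run"
    seed: int = 0
    fdr_max: float = 0.05
    lfc_min: float = 0.5
    min_datasets: int = 2
    universe_size: int = DEFAULT_UNIVERSE_SIZE
    n_random: int = 100
    #: (expression TSV, phenotype TSV) pairs; empty means simulate instead.
    cohorts: list[tuple[str, str]] = field(default_factory=list)
    library_path: str | None = None
    simulation: SimulationConfig | None = None

    def __post_init__(self) -> None:
        if self.fdr_max < 0 or self.lfc_min < 0:
            raise ValueError("thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cohorts = [tuple(pair) for pair in raw.pop("cohorts", [])]
        cfg = cls(**raw, cohorts=cohorts)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write all artifacts; returns the output directory.

    Identical config + seed gives byte-identical outputs. Any stage failure
    raises with the stage name attached.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "afmeta_version": __version__,
        "seed": config.seed,
        "thresholds": {"fdr_max": config.fdr_max, "lfc_min": config.lfc_min},
        "universe_size": config.universe_size,
        "n_random": config.n_random,
        "inputs": {},
        "stages": [],
    }

    def stage(name: str):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("inputs")
        truth = None
        if config.cohorts:
            studies = []
            for expr_path, pheno_path in config.cohorts:
                studies.append(read_expression_tsv(expr_path, pheno_path))
                manifest["inputs"][expr_path] = _digest(Path(expr_path))
        else:
            sim = config.simulation or SimulationConfig(seed=stage_seed(config.seed, "simulate"))
            studies, truth = simulate_collection(sim)
            truth.to_frame().to_csv(out / "truth.tsv", sep="\t")
            manifest["inputs"]["simulation"] = dataclasses.asdict(sim)

        if config.library_path:
            library = read_gmt(config.library_path, universe_size=config.universe_size)
            manifest["inputs"][config.library_path] = _digest(Path(config.library_path))
        elif truth is not None:
            set_size, frac = feasible_library_params(truth)
            library = simulate_ko_library(
                truth, set_size=set_size, planted_overlap_frac=frac,
                universe=list(truth.genes),
                seed=stage_seed(config.seed, "ko_library"))
            write_gmt(library, out / "ko_library.gmt")
        else:
            library = None
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'inputs' failed: {exc}") from exc

    try:
        stage("differential_expression")
        de_results = []
        for study in studies:
            de = run_de(study)
            de.to_tsv(out / f"de_{study.study_id}.tsv")
            de_results.append(de)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'differential_expression' failed: {exc}") from exc

    try:
        stage("meta_analysis")
        meta = combine_studies(de_results, min_datasets=config.min_datasets)
        meta.to_tsv(out / "meta.tsv")
        signature = meta.select_signature(fdr_max=config.fdr_max, lfc_min=config.lfc_min)
        write_gene_list(sorted(signature.up), out / "up.txt")
        write_gene_list(sorted(signature.down), out / "down.txt")
        if len(signature) == 0:
            logger.warning("empty disease signature at fdr_max=%g, lfc_min=%g",
                           config.fdr_max, config.lfc_min)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'meta_analysis' failed: {exc}") from exc

    if library is not None:
        try:
            stage("enrichment")
            frames = []
            for name, genes in (("Fibrillation Up", signature.up),
                                ("Fibrillation Down", signature.down)):
                if not genes:
                    continue
                res = EnrichrOverlap(genes, library, query_name=name).fit(
                    n_random=config.n_random, seed=stage_seed(config.seed, "enrich"))
                frames.append(res.to_frame())
            if frames:
                import pandas as pd

                pd.concat(frames, ignore_index=True).to_csv(
                    out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'enrichment' failed: {exc}") from exc

        try:
            stage("concordance")
            receptors = _receptors_of(library)
            summaries = []
            for receptor, (up_term, down_term) in sorted(receptors.items()):
                summaries.append(cross_tabulate(
                    signature, (library.genes(up_term), library.genes(down_term)),
                    N=library.universe_size, receptor=receptor))
            if summaries:
                summaries_to_rows(summaries).to_csv(
                    out / "concordance.tsv", sep="\t", index=False, float_format="%.6g")
            overlap_matrix(signature, library).to_csv(out / "membership.tsv", sep="\t")
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'concordance' failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def _receptors_of(library: GeneSetLibrary) -> dict[str, tuple[str, str]]:
    """Pair '<X>_ko Up'/'<X>_ko Down' terms by receptor X."""
    ups, downs = {}, {}
    for term in library.terms:
        if term.endswith("_ko Up"):
            ups[term[: -len("_ko Up")]] = term
        elif term.endswith("_ko Down"):
            downs[term[: -len("_ko Down")]] = term
    return {r: (ups[r], downs[r]) for r in ups if r in downs}
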