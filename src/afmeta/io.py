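"""Readers and writers: expression TSVs, phenotype files, GMT libraries, result tables.

Expression input is a tab-separated matrix (first column feature ID, header of
sample IDs) paired with a two-column phenotype file mapping sample ID to
``case``/``control``. Gene sets travel as GMT (term, description, genes...).
Result rows are written as TSV with the field conventions of published
enrichment tables: an ``a/B``-style overlap column and semicolon-delimited
gene lists.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionStudy, GeneSetLibrary, normalize_symbol

logger = logging.getLogger(__name__)

#: Matrices whose maximum exceeds this are treated as linear-scale intensities
#: and log2(x+1)-transformed; log2 microarray data rarely exceeds ~20.
LINEAR_SCALE_MAX = 50.0


def read_expression_tsv(path: str | Path, phenotype_path: str | Path,
                        study_id: str | None = None) -> ExpressionStudy:
    """Read one cohort: an expression matrix plus its phenotype file.

    Values whose maximum exceeds ``LINEAR_SCALE_MAX`` are assumed to be linear
    intensities and are log2(x+1)-transformed (``log_transformed`` is set).
    Every sample in the matrix must appear in the phenotype file.
    """
    path, phenotype_path = Path(path), Path(phenotype_path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if not phenotype_path.exists():
        raise FileNotFoundError(str(phenotype_path))

    frame = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric expression cell: {exc}") from exc

    pheno = pd.read_csv(phenotype_path, sep="\t", header=None,
                        names=["sample", "group"], dtype=str)
    group_of = dict(zip(pheno["sample"], pheno["group"]))
    samples = [str(s) for s in frame.columns]
    missing = [s for s in samples if s not in group_of]
    if missing:
        raise ValueError(
            f"{phenotype_path}: no group label for sample(s) {missing}"
        )

    log_transformed = False
    if values.size and np.nanmax(values) > LINEAR_SCALE_MAX:
        logger.warning(
            "%s: max value %.3g > %g, treating as linear scale and applying log2(x+1)",
            path, np.nanmax(values), LINEAR_SCALE_MAX,
        )
        values = np.log2(values + 1.0)
        log_transformed = True

    return ExpressionStudy(
        study_id=study_id or path.stem,
        features=[str(f) for f in frame.index],
        samples=samples,
        values=values,
        groups=[group_of[s] for s in samples],
        log_transformed=log_transformed,
    )


def read_gmt(path: str | Path, name: str | None = None,
             universe_size: int | None = None) -> GeneSetLibrary:
    """Parse a GMT gene-set library (term TAB description TAB gene...).

    Gene symbols are uppercased and deduplicated; empty lines are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
        term, desc = fields[0], fields[1]
        if term in sets:
            raise ValueError(f"{path}:{lineno}: duplicate term name {term!r}")
        genes = frozenset(normalize_symbol(g) for g in fields[2:] if g.strip())
        sets[term] = (desc, genes)
    kwargs: dict[str, Any] = {}
    if universe_size is not None:
        kwargs["universe_size"] = universe_size
    return GeneSetLibrary(name=name or path.stem, sets=sets, **kwargs)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    """Write a library as GMT with deterministic (sorted) gene order."""
    lines = []
    for term, (desc, genes) in library.sets.items():
        lines.append("\t".join([term, desc, *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _format_value(value: Any) -> str:
    if isinstance(value, float):
        if math.isinf(value):
            return "inf" if value > 0 else "-inf"
        return f"{value:.6g}"
    if isinstance(value, (frozenset, set)):
        return ";".join(sorted(value))
    if isinstance(value, (list, tuple)):
        return ";".join(str(v) for v in value)
    return str(value)


def write_table(rows: Sequence[Any], path: str | Path,
                columns: Sequence[str] | None = None) -> None:
    """Write dataclass (or mapping) rows as a TSV with a header.

    Floats use 6 significant digits; gene collections are semicolon-joined.
    Rows exposing both ``a`` and ``B`` fields (enrichment rows) get a combined
    ``overlap`` column rendered ``a/B`` in place of the two counts.
    """
    path = Path(path)
    if not rows:
        header = list(columns) if columns else []
        path.write_text("\t".join(header) + "\n")
        return

    def as_dict(row: Any) -> dict[str, Any]:
        if dataclasses.is_dataclass(row):
            return {f.name: getattr(row, f.name) for f in dataclasses.fields(row)}
        return dict(row)

    dicts = [as_dict(r) for r in rows]
    fieldnames = list(dicts[0])
    combine_overlap = "a" in fieldnames and "B" in fieldnames
    if combine_overlap:
        out_fields = []
        for f in fieldnames:
            if f == "a":
                out_fields.append("overlap")
            elif f == "B":
                continue
            else:
                out_fields.append(f)
    else:
        out_fields = fieldnames

    lines = ["\t".join(out_fields)]
    for d in dicts:
        cells = []
        for f in out_fields:
            if combine_overlap and f == "overlap":
                cells.append(f"{d['a']}/{d['B']}")
            else:
                cells.append(_format_value(d[f]))
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")


def read_enrichment_table(path: str | Path) -> pd.DataFrame:
    """Read back an enrichment TSV, splitting ``overlap`` into ``a`` and ``B``
    and the semicolon gene list into a Python list."""
    frame = pd.read_csv(path, sep="\t")
    if "overlap" in frame.columns:
        parts = frame["overlap"].astype(str).str.split("/", expand=True)
        frame["a"] = parts[0].astype(int)
        frame["B"] = parts[1].astype(int)
    if "overlap_genes" in frame.columns:
        frame["overlap_genes"] = [
            [] if (isinstance(v, float) and math.isnan(v)) or v == "" else str(v).split(";")
            for v in frame["overlap_genes"]
        ]
    return frame


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + ("\n" if genes else ""))


def read_gene_list(path: str | Path) -> frozenset[str]:
    text = Path(path).read_text()
    return frozenset(normalize_symbol(g) for g in text.splitlines() if g.strip())
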