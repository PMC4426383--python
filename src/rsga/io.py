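"""Readers and writers for every file format the pipeline touches.

Formats: per-colony measurement tables (TSV), GO annotations (GAF 2.x),
plain-text gene lists, and flattened two-column yeast-to-human ortholog
tables. Readers enforce structural invariants and never silently drop rows:
anything excluded is counted and logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DataIntegrityError, FileFormatError

logger = logging.getLogger(__name__)

#: Canonical colony-table header, in writing order.
COLONY_COLUMNS = [
    "plate",
    "condition",
    "replicate",
    "row",
    "col",
    "strain_id",
    "gene",
    "gfp",
    "tdtomato",
    "area_px",
]

#: Columns identifying a physical grid position; unique per table.
POSITION_KEY = ["plate", "condition", "replicate", "row", "col"]

_INT_COLUMNS = ["replicate", "row", "col", "area_px"]
_FLOAT_COLUMNS = ["gfp", "tdtomato"]

_ASPECT_CODES = {"P": "BP", "F": "MF", "C": "CC"}


def read_colony_table(path: str | Path) -> pd.DataFrame:
    """Read a per-colony measurement TSV into canonical column order.

    The header must contain every canonical column (order-insensitive);
    extra columns are dropped. Raises :class:`FileFormatError` for a
    missing column or non-numeric measurement (with line number) and
    :class:`DataIntegrityError` for a duplicated grid position.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in COLONY_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    df = df[COLONY_COLUMNS].copy()
    for col in _INT_COLUMNS + _FLOAT_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FileFormatError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column '{col}' at line {line}"
            )
        if numeric.isna().any():
            line = int(numeric.isna().idxmax()) + 2
            raise FileFormatError(f"{path}: empty value in column '{col}' at line {line}")
        df[col] = numeric
    for col in _INT_COLUMNS:
        df[col] = df[col].astype(int)
    if (df[["gfp", "tdtomato"]] < 0).any().any() or (df["area_px"] < 0).any():
        raise DataIntegrityError(f"{path}: negative intensity or area")
    dup = df.duplicated(subset=POSITION_KEY)
    if dup.any():
        key = df.loc[dup.idxmax(), POSITION_KEY].tolist()
        raise DataIntegrityError(f"{path}: duplicate grid position {tuple(key)}")
    logger.info("read %d colony records from %s", len(df), path)
    return df


def write_colony_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write colony records as TSV with the canonical header."""
    records[COLONY_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass
class AnnotationSet:
    """Gene Ontology annotations: term ↔ gene mappings plus term aspects.

    ``aspect`` values are ``BP`` (biological process), ``MF`` (molecular
    function) or ``CC`` (cellular component).
    """

    term_to_genes: dict[str, set[str]] = field(default_factory=dict)
    term_aspect: dict[str, str] = field(default_factory=dict)
    gene_to_terms: dict[str, set[str]] = field(default_factory=dict)

    def add(self, gene: str, term: str, aspect: str) -> None:
        if aspect not in ("BP", "MF", "CC"):
            raise DataIntegrityError(f"invalid GO aspect {aspect!r}")
        prev = self.term_aspect.setdefault(term, aspect)
        if prev != aspect:
            raise DataIntegrityError(
                f"term {term} annotated with conflicting aspects {prev}/{aspect}"
            )
        self.term_to_genes.setdefault(term, set()).add(gene)
        self.gene_to_terms.setdefault(gene, set()).add(term)

    @property
    def genes(self) -> set[str]:
        return set(self.gene_to_terms)

    @property
    def terms(self) -> set[str]:
        return set(self.term_to_genes)

    def __len__(self) -> int:
        return len(self.term_to_genes)


def read_gaf(path: str | Path, taxon_filter: str | None = None) -> AnnotationSet:
    """Parse a GAF 2.x annotation file.

    Comment lines start with ``!``. Aspect comes from column 9 (P/F/C);
    annotations with a ``NOT`` qualifier are excluded, duplicate gene-term
    pairs collapsed. ``taxon_filter`` (e.g. ``"taxon:559292"``) keeps only
    rows listing that taxon. An empty result is a warning, not an error.
    """
    path = Path(path)
    annotations = AnnotationSet()
    n_not = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < 15:
                raise FileFormatError(
                    f"{path}: line {lineno}: expected >= 15 tab-separated "
                    f"columns, got {len(fields)}"
                )
            qualifier, term, aspect = fields[3], fields[4], fields[8]
            if "NOT" in qualifier.split("|"):
                n_not += 1
                continue
            if taxon_filter is not None:
                taxa = {t.strip() for t in fields[12].split("|")}
                wanted = taxon_filter if taxon_filter.startswith("taxon:") else f"taxon:{taxon_filter}"
                if wanted not in taxa:
                    continue
            if aspect not in _ASPECT_CODES:
                raise FileFormatError(
                    f"{path}: line {lineno}: invalid aspect code {aspect!r}"
                )
            gene = fields[2].strip().upper()
            if not gene or not term:
                raise FileFormatError(f"{path}: line {lineno}: empty gene or term")
            annotations.add(gene, term, _ASPECT_CODES[aspect])
    if n_not:
        logger.info("excluded %d NOT-qualified annotations from %s", n_not, path)
    if len(annotations) == 0:
        warnings.warn(f"no annotations parsed from {path}", stacklevel=2)
    return annotations


def write_gaf(annotations: AnnotationSet, path: str | Path, taxon: str = "taxon:4932") -> None:
    """Write an AnnotationSet as a minimal valid GAF 2.2 file."""
    code = {v: k for k, v in _ASPECT_CODES.items()}
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for term in sorted(annotations.term_to_genes):
            aspect = code[annotations.term_aspect[term]]
            for gene in sorted(annotations.term_to_genes[term]):
                fields = [
                    "SGD", gene, gene, "involved_in", term, "PMID:0", "IEA", "",
                    aspect, gene, "", "protein", taxon, "20140923", "SGD", "", "",
                ]
                fh.write("\t".join(fields) + "\n")


def read_gene_set(path: str | Path, name: str = "gene_set") -> set[str]:
    """Read a plain-text gene list: one gene per line, ``#`` comments allowed.

    Genes are upper-cased and deduplicated. An empty result is a warning.
    """
    path = Path(path)
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if entry:
                genes.add(entry.upper())
    if not genes:
        warnings.warn(f"gene set {name!r} from {path} is empty", stacklevel=2)
    logger.info("read %d genes for set %r from %s", len(genes), name, path)
    return genes


def write_gene_set(genes: set[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(genes):
            fh.write(gene + "\n")


def read_ortholog_table(path: str | Path) -> dict[str, set[str]]:
    """Read a flattened two-column (yeast gene, human gene) TSV.

    Many-to-many pairs are aggregated into a yeast gene → set-of-human-genes
    map. Wrong column count raises :class:`FileFormatError` with the line
    number; an empty result is a warning.
    """
    path = Path(path)
    orthologs: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FileFormatError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(fields)}"
                )
            yeast, human = fields[0].strip().upper(), fields[1].strip().upper()
            orthologs.setdefault(yeast, set()).add(human)
    if not orthologs:
        warnings.warn(f"ortholog table {path} is empty", stacklevel=2)
    return orthologs


def write_ortholog_table(orthologs: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for yeast in sorted(orthologs):
            for human in sorted(orthologs[yeast]):
                fh.write(f"{yeast}\t{human}\n")
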