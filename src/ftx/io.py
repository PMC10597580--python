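"""Readers and writers for the package's plain-text formats.

Counts and metadata travel as TSV (GEO supplementary style), result
tables as CSV, gene sets as GMT. Parsers validate aggressively and
report the offending line/cell in the error message.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .diffexpr import CountMatrix
from .enrichment import GeneSetCollection
from .errors import DomainError, ParseError

REQUIRED_META_COLUMNS = ("animal_id", "age_group", "run")


def read_counts_tsv(path) -> CountMatrix:
    """Gene x sample integer count matrix from TSV (first column gene_id)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse counts TSV: {exc}") from exc
    if frame.empty:
        raise ParseError(f"{path}: empty count matrix")
    try:
        return CountMatrix(frame)
    except DomainError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_counts_tsv(counts, path) -> None:
    frame = counts.frame if isinstance(counts, CountMatrix) else counts
    frame.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata_tsv(path) -> pd.DataFrame:
    """Per-sample metadata table indexed by sample_id."""
    path = Path(path)
    try:
        meta = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse metadata TSV: {exc}") from exc
    if meta.index.has_duplicates:
        dupes = meta.index[meta.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate sample ids {dupes[:5]}")
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"{path}: metadata missing required columns {missing}")
    meta["age_group"] = meta["age_group"].astype(str)
    return meta


def write_metadata_tsv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path) -> GeneSetCollection:
    """GMT gene sets: tab-separated ``term <TAB> description <TAB> genes...``."""
    path = Path(path)
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected term, description and >=1 gene")
            term, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: term {term!r} has no genes")
            if term in sets:
                raise ParseError(f"{path}:{lineno}: duplicate term {term!r}")
            sets[term] = frozenset(genes)
            descriptions[term] = desc
    if not sets:
        raise ParseError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(sets: Mapping[str, tuple[str, Sequence[str]]], path) -> None:
    """Write ``{term: (description, genes)}`` as GMT."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for term, (desc, genes) in sets.items():
            writer.writerow([term, desc, *genes])


def write_truth(truth, genes_path, samples_path) -> None:
    """Persist a SimulationTruth as two TSV tables."""
    truth.genes.to_csv(genes_path, sep="\t", index_label="gene_id")
    frame = truth.size_factors.to_frame()
    frame.to_csv(samples_path, sep="\t", index_label="sample_id")
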