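"""Readers and writers for DepMap-style tabular inputs.

Three CSV dialects are handled: the gene-effect matrix (cell lines x genes,
headers ``SYMBOL (ENTREZ)``), the long-format mutation table, and the
sample-info annotation table. Identifier harmonization across files produces
the analysis universe used by every downstream stage.

Cell lines are identified by their screen-sample id (DepMap style
``ACH-######``), never by human-readable name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Input file does not match the expected dialect."""


class ValidationError(ValueError):
    """Input parsed but violates a structural invariant."""


@dataclass(frozen=True)
class GeneLabel:
    """A gene column identity: HUGO symbol plus optional Entrez id."""

    symbol: str
    entrez_id: int | None = None

    def __str__(self) -> str:  # round-trips through the depmap dialect
        if self.entrez_id is None:
            return self.symbol
        return f"{self.symbol} ({self.entrez_id})"


@dataclass
class GeneEffectMatrix:
    """Cell-line x gene matrix of knockout dependency scores.

    More negative scores mean the line depends more strongly on the gene;
    a score below -0.5 marks a sensitive line and -1 corresponds to the
    median of common-essential genes. Missing entries (lines not screened
    for a gene) are NaN and are excluded pairwise by every operation --
    never imputed.

    Attributes
    ----------
    scores : pandas.DataFrame
        Index = cell-line ids, columns = gene symbols, float64 values.
    gene_labels : list of GeneLabel
        One per column, preserving the Entrez id parsed from the header.
    n_coerced_missing : int
        Count of non-numeric cells turned into NaN at load time.
    """

    scores: pd.DataFrame
    gene_labels: list[GeneLabel]
    n_coerced_missing: int = 0

    def __post_init__(self) -> None:
        ids = self.scores.index
        if ids.has_duplicates:
            dups = sorted(ids[ids.duplicated()].unique())
            raise ValidationError(f"duplicate cell-line ids: {dups}")
        pairs = [(g.symbol, g.entrez_id) for g in self.gene_labels]
        if len(set(pairs)) != len(pairs):
            seen: set[tuple[str, int | None]] = set()
            dup = [p for p in pairs if p in seen or seen.add(p)]  # type: ignore[func-returns-value]
            raise ValidationError(f"duplicate gene labels: {sorted(set(dup))}")
        if len(self.gene_labels) != self.scores.shape[1]:
            raise ValidationError("gene_labels length does not match matrix width")
        present = self.scores.to_numpy()
        if np.isinf(present).any():
            raise ValidationError("gene-effect scores must be finite or missing")

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def gene_symbols(self) -> list[str]:
        return [g.symbol for g in self.gene_labels]

    def profile(self, gene: str) -> pd.Series:
        """Dependency-score profile of one gene across all lines."""
        if gene not in self.scores.columns:
            raise KeyError(gene_lookup_message(gene, self.gene_symbols))
        return self.scores[gene]


def gene_lookup_message(gene: str, symbols: Sequence[str]) -> str:
    """Error text for a missing gene, naming the nearest symbols."""
    import difflib

    near = difflib.get_close_matches(gene, symbols, n=3, cutoff=0.6)
    hint = f"; nearest symbols: {', '.join(near)}" if near else ""
    return f"gene {gene!r} not present in the matrix{hint}"


# DepMap release-to-release column renames are handled by this mapping.
DEPMAP_MUTATION_COLUMNS: Mapping[str, str] = {
    "gene_symbol": "Hugo_Symbol",
    "entrez_id": "Entrez_Gene_Id",
    "variant_classification": "Variant_Classification",
    "cell_line_id": "DepMap_ID",
}

#: Columns that must be resolvable in a mutation file (entrez is optional).
_REQUIRED_MUTATION_FIELDS = ("gene_symbol", "variant_classification", "cell_line_id")


@dataclass
class MutationTable:
    """Long-format mutation records: one row per documented variant call.

    Duplicates are allowed; collapsing to per-(line, gene) presence is a
    screen-stage decision. ``nonsilent_filtered`` marks tables that already
    passed the silent-variant filter.
    """

    records: pd.DataFrame  # columns: cell_line_id, gene_symbol, entrez_id, variant_classification
    nonsilent_filtered: bool = False

    def __post_init__(self) -> None:
        req = ["cell_line_id", "gene_symbol", "variant_classification"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise ValidationError(f"mutation records missing columns {missing}")
        if len(self.records):
            if (self.records["cell_line_id"].astype(str).str.len() == 0).any():
                raise ValidationError("empty cell_line_id in mutation records")
            if (self.records["variant_classification"].astype(str).str.len() == 0).any():
                raise ValidationError("empty variant_classification in mutation records")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SampleInfo:
    """Per-cell-line annotations (name, primary disease, lineage, free-form)."""

    table: pd.DataFrame  # indexed by cell_line_id

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = sorted(self.table.index[self.table.index.duplicated()].unique())
            raise ValidationError(f"duplicate cell-line ids in sample info: {dups}")

    def annotate(self, cell_line_ids: Sequence[str], column: str) -> pd.Series:
        """Look up one annotation column; missing lines yield NaN."""
        return self.table.reindex(cell_line_ids)[column]


@dataclass
class AnalysisUniverse:
    """The harmonized set of cell lines shared by all inputs."""

    cell_line_ids: list[str]
    dropped_from_matrix: int
    dropped_from_mutations: int
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.cell_line_ids)

    @property
    def id_set(self) -> frozenset[str]:
        return frozenset(self.cell_line_ids)


def parse_depmap_header(header: str) -> GeneLabel:
    """Split a ``SYMBOL (ENTREZ)`` header at its last `` (`` occurrence."""
    head, sep, tail = header.rpartition(" (")
    if not sep or not tail.endswith(")"):
        raise FormatError(f"malformed gene header {header!r}: expected 'SYMBOL (ENTREZ)'")
    entrez_text = tail[:-1]
    try:
        entrez = int(entrez_text)
    except ValueError:
        raise FormatError(
            f"malformed gene header {header!r}: Entrez id {entrez_text!r} is not an integer"
        ) from None
    return GeneLabel(head, entrez)


def load_gene_effect(path: str | Path, dialect: str = "depmap") -> GeneEffectMatrix:
    """Read a gene-effect CSV (first column = cell-line ids).

    ``dialect="depmap"`` parses headers of the form ``SYMBOL (ENTREZ)``;
    ``dialect="plain"`` takes headers as bare symbols. Non-numeric score
    cells become missing and are counted in the load report (never silently
    coerced to a number).
    """
    if dialect not in ("depmap", "plain"):
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(
        path, index_col=0, keep_default_na=False, na_values=[""],
        float_precision="round_trip",
    )
    raw.index = raw.index.astype(str)

    if dialect == "depmap":
        labels = [parse_depmap_header(h) for h in raw.columns]
    else:
        labels = [GeneLabel(str(h)) for h in raw.columns]

    # Empty cells are missing; anything else must parse as a finite number.
    # Columns the fast parser left as objects get element-wise conversion so
    # numeric precision is never degraded by a stray token elsewhere.
    coerced = 0
    converted: dict[int, np.ndarray] = {}
    for pos, column in enumerate(raw.columns):
        series = raw[column]
        if series.dtype == object:
            values = np.empty(len(series), dtype=float)
            for i, cell in enumerate(series.to_numpy()):
                try:
                    values[i] = float(cell)
                except (TypeError, ValueError):
                    values[i] = np.nan
                    coerced += 1
            converted[pos] = values
        else:
            converted[pos] = series.to_numpy(dtype=float)
    if coerced:
        logger.warning("%d non-numeric score cells coerced to missing in %s", coerced, path)
    numeric = pd.DataFrame(
        {lab.symbol: converted[pos] for pos, lab in enumerate(labels)},
        index=raw.index,
    )
    numeric.index.name = raw.index.name
    return GeneEffectMatrix(numeric.astype(float), labels, n_coerced_missing=coerced)


def write_gene_effect(matrix: GeneEffectMatrix, path: str | Path, dialect: str = "depmap") -> None:
    """Write a gene-effect matrix back to CSV in the requested dialect."""
    out = matrix.scores.copy()
    if dialect == "depmap":
        out.columns = [str(lab) for lab in matrix.gene_labels]
    elif dialect == "plain":
        out.columns = [lab.symbol for lab in matrix.gene_labels]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out.index.name = out.index.name or "DepMap_ID"
    out.to_csv(path)


def load_mutations(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> MutationTable:
    """Read a long-format mutation CSV; one record per row, no filtering.

    ``columns`` maps internal field names to the file's column names
    (DepMap defaults: Hugo_Symbol / Variant_Classification / DepMap_ID).
    """
    colmap = dict(DEPMAP_MUTATION_COLUMNS)
    if columns:
        colmap.update(columns)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, low_memory=False)
    missing = [colmap[f] for f in _REQUIRED_MUTATION_FIELDS if colmap[f] not in frame.columns]
    if missing:
        raise FormatError(
            f"mutation file missing required columns {missing}; found {list(frame.columns)}"
        )
    records = pd.DataFrame(
        {
            "cell_line_id": frame[colmap["cell_line_id"]],
            "gene_symbol": frame[colmap["gene_symbol"]],
            "variant_classification": frame[colmap["variant_classification"]],
        }
    )
    entrez_col = colmap["entrez_id"]
    if entrez_col in frame.columns:
        records["entrez_id"] = pd.to_numeric(frame[entrez_col], errors="coerce").astype("Int64")
    else:
        records["entrez_id"] = pd.array([pd.NA] * len(frame), dtype="Int64")
    return MutationTable(records)


def write_mutations(table: MutationTable, path: str | Path) -> None:
    """Write mutation records using the DepMap default column names."""
    out = pd.DataFrame(
        {
            "DepMap_ID": table.records["cell_line_id"],
            "Hugo_Symbol": table.records["gene_symbol"],
            "Entrez_Gene_Id": table.records.get("entrez_id"),
            "Variant_Classification": table.records["variant_classification"],
        }
    )
    out.to_csv(path, index=False)


def load_sample_info(path: str | Path, id_column: str = "DepMap_ID") -> SampleInfo:
    """Read a sample-info CSV keyed by cell-line id."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if id_column not in frame.columns:
        raise FormatError(
            f"sample-info file missing id column {id_column!r}; found {list(frame.columns)}"
        )
    return SampleInfo(frame.set_index(id_column))


def harmonize(
    matrix: GeneEffectMatrix,
    mutations: MutationTable,
    info: SampleInfo | None = None,
) -> AnalysisUniverse:
    """Intersect cell-line ids across the score matrix and mutation table.

    The universe is the set of lines present in both sources, annotated
    from the sample info when given. Counts dropped from each side are
    reported; an empty intersection is an error.
    """
    matrix_ids = set(matrix.cell_line_ids)
    mutation_ids = set(mutations.records["cell_line_id"].unique())
    shared = matrix_ids & mutation_ids
    if not shared:
        raise ValidationError("no cell lines shared between gene-effect matrix and mutations")
    universe = sorted(shared)
    annotations = (
        info.table.reindex(universe) if info is not None else pd.DataFrame(index=universe)
    )
    dropped_matrix = len(matrix_ids) - len(shared)
    dropped_mutations = len(mutation_ids) - len(shared)
    logger.info(
        "analysis universe: %d lines (%d dropped from matrix, %d from mutations)",
        len(universe), dropped_matrix, dropped_mutations,
    )
    return AnalysisUniverse(universe, dropped_matrix, dropped_mutations, annotations)
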