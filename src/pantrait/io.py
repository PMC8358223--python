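"""Readers and writers for every external format the pipeline touches.

Formats: tab/comma-delimited subsystem-annotation tables (the shape of RAST
exports), Roary-style ``gene_presence_absence.csv`` and OrthoFinder-style
``Orthogroups.tsv`` matrices, plain 0/1 matrices, Newick trees and FASTA
alignments.  Readers normalize into the in-memory types of
:mod:`pantrait.datatypes`; every reader/writer pair round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from ._util import logger
from .datatypes import (
    FUNCTION_COLUMNS,
    AlignmentBlock,
    DistanceMatrix,
    FormatError,
    FunctionTable,
    PresenceAbsenceMatrix,
)

# Fixed leading metadata columns that identify a Roary export.
_ROARY_META = [
    "Gene",
    "Non-unique Gene name",
    "Annotation",
    "No. isolates",
    "No. sequences",
    "Avg sequences per isolate",
    "Genes in fragment",
    "Fragment",
    "Order within fragment",
    "Accessory Fragment",
    "Accessory Order with Fragment",
    "QC",
    "Min group size nuc",
    "Max group size nuc",
    "Avg group size nuc",
]


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_function_table(
    path,
    delimiter: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> FunctionTable:
    """Read a subsystem-annotation table with the 5 hierarchy columns.

    ``column_map`` renames file headers to the canonical names
    ``genome_id, category, subcategory, subsystem, role``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delimiter = delimiter or _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty function table: {path}") from exc
    if column_map:
        df = df.rename(columns=dict(column_map))
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in FUNCTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise FormatError(f"function table has headers but no records: {path}")
    return FunctionTable(df)


def write_function_table(table: FunctionTable, path, delimiter: str = "\t") -> None:
    table.records.to_csv(path, sep=delimiter, index=False)


def read_presence_absence(path, dialect: str) -> PresenceAbsenceMatrix:
    """Read a gene/orthogroup presence-absence matrix.

    dialect: ``roary_csv`` | ``orthofinder_tsv`` | ``plain_matrix``.
    In gene-list dialects a nonempty cell means presence; multi-copy cells
    collapse to 1 with the total multiplicity logged.  The plain 0/1 matrix
    must be requested explicitly: silent misdetection would corrupt counts.
    """
    path = Path(path)
    if dialect == "roary_csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        meta = [c for c in _ROARY_META if c in df.columns]
        if "Gene" not in df.columns or "No. isolates" not in df.columns:
            raise FormatError(
                f"{path}: not a Roary gene_presence_absence.csv "
                "(missing 'Gene'/'No. isolates' metadata columns)"
            )
        strains = [c for c in df.columns if c not in _ROARY_META]
        return _from_gene_lists(df["Gene"], df[strains], path)
    if dialect == "orthofinder_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        first = df.columns[0]
        strains = list(df.columns[1:])
        if not strains:
            raise FormatError(f"{path}: no strain columns after '{first}'")
        return _from_gene_lists(df[first], df[strains], path)
    if dialect == "plain_matrix":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
        else:
            dup = None
        if dup is not None:
            raise FormatError(f"{path}: duplicate gene id {dup!r}")
        return PresenceAbsenceMatrix(df)
    raise ValueError(f"unknown presence/absence dialect: {dialect!r}")


def _from_gene_lists(gene_ids: pd.Series, cells: pd.DataFrame, path) -> PresenceAbsenceMatrix:
    gene_ids = gene_ids.astype(str).str.strip()
    if gene_ids.duplicated().any():
        dup = gene_ids[gene_ids.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    # count entries per cell: comma/semicolon/tab separated gene names
    def n_entries(cell: str) -> int:
        cell = cell.strip().strip('"')
        if not cell:
            return 0
        return len([g for g in cell.replace(";", ",").replace("\t", ",").split(",") if g.strip()])

    counts = cells.map(n_entries)
    multi = int((counts.to_numpy() > 1).sum())
    if multi:
        logger.info(
            "%s: %d cells contained multiple gene copies; collapsed to presence",
            path,
            multi,
        )
    binary = (counts > 0).astype(np.int8)
    binary.index = gene_ids
    return PresenceAbsenceMatrix(binary)


def write_presence_absence(pa: PresenceAbsenceMatrix, path, delimiter: str = "\t") -> None:
    pa.cells.to_csv(path, sep=delimiter, index_label="gene_id")


def read_plain_presence_absence(path) -> PresenceAbsenceMatrix:
    return read_presence_absence(path, "plain_matrix")


def read_newick(path_or_string):
    """Parse a Newick tree into a :class:`pantrait.trees.PhyloTree`.

    Missing branch lengths are read as 0 and counted; distance-based
    operations refuse trees with imputed lengths.
    """
    from .trees import PhyloTree  # local import to avoid a cycle

    src = str(path_or_string)
    try:
        is_file = Path(src).exists()
    except OSError:
        is_file = False
    text = Path(src).read_text() if is_file else src
    try:
        tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"Newick parse error: {exc}") from exc
    n_imputed = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            n_imputed += 1
        elif edge.length < 0:
            raise FormatError("negative branch length in Newick input")
    if n_imputed:
        logger.warning("%d branch lengths missing; imputed as 0", n_imputed)
    return PhyloTree(tree, n_imputed_lengths=n_imputed)


def write_newick(tree, path) -> None:
    Path(path).write_text(tree.to_newick())


def read_fasta_alignment(path, alphabet: str) -> AlignmentBlock:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no sequences in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    return AlignmentBlock(ids, seqs, alphabet)


def write_fasta_alignment(aln: AlignmentBlock, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.sequences):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_distance_matrix(d: DistanceMatrix, path, delimiter: str = "\t") -> None:
    d.to_dataframe().to_csv(path, sep=delimiter, index_label="")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return DistanceMatrix.from_dataframe(df)


def write_test_results(results, path) -> None:
    """Serialize a TestResult or a list of them as JSON."""
    if not isinstance(results, (list, tuple)):
        results = [results]
    payload = [r.to_dict() for r in results]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (set, frozenset)):
        return sorted(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def label_report(**label_sets: Sequence[str]) -> dict[str, dict[str, list[str]]]:
    """Pre-flight check of label consistency across inputs.

    Returns, for each named input, the labels it lacks relative to the union
    of all inputs.  Joins downstream are by exact string match.
    """
    sets = {name: set(labels) for name, labels in label_sets.items()}
    union = set().union(*sets.values()) if sets else set()
    report = {}
    for name, s in sets.items():
        missing = sorted(union - s)
        report[name] = {"n": len(s), "missing": missing}
        if missing:
            logger.warning("input %r lacks %d labels: %s", name, len(missing), missing[:5])
    return report
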