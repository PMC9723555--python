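"""Readers and writers for the package's external formats.

Count tables and sample metadata are plain TSV, representative sequences
are FASTA, trees are Newick. All readers validate domain invariants on
entry (unique ids, non-negative counts, restricted alphabet, unique leaf
labels) and all writers preserve input order, so write -> read is the
identity on valid objects.

In memory, a count table is a pandas ``DataFrame`` with taxa as the row
index and samples as columns (float64 values; integer-ness is asserted
only by operations that require raw counts). Sequence sets are plain
``dict[str, str]`` with uppercase sequences. Trees are
``skbio.TreeNode``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import skbio
from Bio import SeqIO

from .errors import FormatError, ValidationError

DNA_ALPHABET = frozenset("ACGTN")

#: header cell written in the top-left corner of count-table TSVs
TAXON_HEADER = "#TaxonID"

METADATA_COLUMNS = ("run_id", "subject_id", "replicate_group", "category", "timepoint")


# ---------------------------------------------------------------------------
# count tables


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check CountTable invariants and return the table as float64.

    Raises ValidationError on duplicate ids, negative or non-numeric
    entries, or an empty sample set.
    """
    if table.shape[1] < 1:
        raise ValidationError("count table must contain at least one sample")
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate taxon ids: {dups}")
    if table.columns.has_duplicates:
        dups = table.columns[table.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dups}")
    try:
        values = table.astype(np.float64)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric entry in count table: {exc}") from exc
    if values.isna().any().any():
        raise FormatError("count table contains missing values (ragged rows?)")
    if (values.to_numpy() < 0).any():
        raise ValidationError("count table contains negative entries")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    values.index.name = None
    values.columns.name = None
    return values


def read_count_table(path, orientation: str = "taxa-in-rows") -> pd.DataFrame:
    """Read a TSV count table.

    Parameters
    ----------
    path:
        Tab-separated file with one header row of ids; the top-left cell
        is ignored (conventionally ``#TaxonID``).
    orientation:
        ``"taxa-in-rows"`` (default) or ``"samples-in-rows"``; the
        returned frame is always taxa x samples.
    """
    if orientation not in ("taxa-in-rows", "samples-in-rows"):
        raise ValidationError(f"unknown orientation: {orientation!r}")
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise FormatError(f"{path}: empty count table")
    rows = [ln.split("\t") for ln in lines]
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise FormatError(f"{path}: ragged row {i} ({len(row)} fields, expected {width})")
    header = rows[0][1:]
    if len(set(header)) != len(header):
        raise FormatError(f"{path}: duplicate ids in header row")
    ids = [row[0] for row in rows[1:]]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate ids in first column")
    table = pd.read_csv(_io.StringIO(text), sep="\t", index_col=0, comment=None)
    if orientation == "samples-in-rows":
        table = table.T
    return validate_count_table(table)


def write_count_table(table: pd.DataFrame, path) -> None:
    validate_count_table(table).to_csv(path, sep="\t", index_label=TAXON_HEADER)


# ---------------------------------------------------------------------------
# sequences


def validate_sequences(seqs: dict) -> dict:
    out = {}
    for name, seq in seqs.items():
        if name in out:
            raise FormatError(f"duplicate sequence id: {name}")
        seq = str(seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for id {name}")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {name} contains characters outside ACGTN: {sorted(bad)}"
            )
        out[name] = seq
    return out


def read_fasta(path) -> dict:
    """Read a FASTA file into ``{id: uppercase sequence}``.

    The id is the header up to the first whitespace; multi-line records
    are concatenated. Duplicate ids, empty sequences and characters
    outside {A,C,G,T,N} are rejected.
    """
    seqs = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise FormatError(f"{path}: duplicate FASTA header {record.id}")
        seqs[record.id] = str(record.seq)
    return validate_sequences(seqs)


def write_fasta(seqs: dict, path, width: int = 80) -> None:
    seqs = validate_sequences(seqs)
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# trees


def _validate_tree(tree: skbio.TreeNode) -> skbio.TreeNode:
    names = [tip.name for tip in tree.tips()]
    if any(n is None for n in names):
        raise FormatError("tree contains unnamed leaves")
    if len(set(names)) != len(names):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise FormatError(f"duplicate leaf labels in tree: {dups}")
    for node in tree.traverse():
        if node.length is None:
            node.length = 0.0  # missing branch length contributes nothing
        elif node.length < 0:
            raise ValidationError(f"negative branch length at node {node.name!r}")
    return tree


def read_newick(path) -> skbio.TreeNode:
    """Read a rooted Newick tree; missing branch lengths become 0.0."""
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise FormatError(f"{path}: not a valid Newick tree: {exc}") from exc
    return _validate_tree(tree)


def parse_newick(text: str) -> skbio.TreeNode:
    """Parse a Newick string (convenience wrapper for tests/small inputs)."""
    try:
        tree = skbio.TreeNode.read(_io.StringIO(text), format="newick")
    except Exception as exc:
        raise FormatError(f"not a valid Newick tree: {exc}") from exc
    return _validate_tree(tree)


def write_newick(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# sample metadata


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    if meta.index.has_duplicates:
        raise ValidationError("duplicate sample ids in metadata")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata is missing columns: {missing}")
    meta = meta.copy()
    meta.index = meta.index.astype(str)
    for col in METADATA_COLUMNS:
        if col != "timepoint":
            meta[col] = meta[col].fillna("").astype(str)
    return meta


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    validate_metadata(meta).to_csv(path, sep="\t", index_label="#SampleID")
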