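"""Readers and writers for every external format the pipeline touches.

All parsing is strict: malformed input raises :class:`FormatError` (with a
line number where that helps) and is never silently repaired.  Down-stream
modules only ever see the in-memory types defined here and in
:mod:`symscreen.tree_ops`.

Formats: FASTA (protein/CDS/alignments), Newick trees (IQ-TREE style support
labels and ``#1`` foreground marks tolerated), orthogroup TSV (header of taxon
names, one family per row, comma-separated sequence ids per taxon), 12-column
tabular similarity-search results, two-column gene->term annotation TSV, and
collinear-block gene-pair TSV.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import dendropy
from Bio import SeqIO

from .errors import FormatError
from .tree_ops import Node, Phylogeny

__all__ = [
    "SequenceRecord",
    "HitRecord",
    "CollinearPair",
    "parse_fasta",
    "write_fasta",
    "parse_newick",
    "write_newick",
    "parse_orthogroups",
    "write_orthogroups",
    "parse_hits",
    "parse_annotations",
    "parse_collinear_pairs",
]

SEQUENCE_KINDS = ("protein", "cds", "aligned_protein", "aligned_cds")
GAP_CHARS = frozenset("-.")


@dataclass
class SequenceRecord:
    """One FASTA record with its taxon label and sequence kind."""

    id: str
    residues: str
    kind: str = "protein"
    taxon: str = ""

    def __post_init__(self) -> None:
        if self.kind not in SEQUENCE_KINDS:
            raise ValueError(f"unknown sequence kind {self.kind!r}")

    @property
    def ungapped(self) -> str:
        return "".join(c for c in self.residues if c not in GAP_CHARS)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class HitRecord:
    """One row of a 12-column tabular similarity search."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    evalue: float
    bitscore: float
    extra: tuple[str, ...] = field(default_factory=tuple)  # columns 5-10 verbatim


@dataclass
class CollinearPair:
    """A homologous gene pair inside a syntenic collinear block."""

    block_id: str
    gene_a: str
    gene_b: str
    genome_a: str = ""
    genome_b: str = ""

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise FormatError(f"collinear pair with identical genes: {self.gene_a}")


def _as_stream(source: str | TextIO) -> TextIO:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def parse_fasta(
    source: str | TextIO, kind: str = "protein", taxon: str = ""
) -> list[SequenceRecord]:
    """Parse FASTA text into :class:`SequenceRecord` objects.

    Residues are upper-cased and record order is preserved.  Duplicate ids and
    empty sequences are format errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(_as_stream(source), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if not residues:
            raise FormatError(f"empty sequence for id {rec.id!r}")
        records.append(SequenceRecord(rec.id, residues, kind=kind, taxon=taxon))
    return records


def write_fasta(records: Iterable[SequenceRecord], width: int = 60) -> str:
    """Serialise records as FASTA with lines wrapped at ``width`` characters."""
    chunks: list[str] = []
    for rec in records:
        chunks.append(f">{rec.id}")
        for i in range(0, len(rec.residues), width):
            chunks.append(rec.residues[i : i + width])
    return "\n".join(chunks) + "\n"


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_FG_MARK = re.compile(r"#\d+$")


def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick statement into a :class:`Phylogeny`.

    Internal (support) labels are retained, missing branch lengths default to
    0, and ``#1``-style suffixes on labels become foreground branch marks.
    Square-bracket comments are rejected (format error), as are unbalanced
    parentheses and duplicate tip labels.
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise FormatError("Newick statement must end with ';'")
    if "[" in stripped or "]" in stripped:
        raise FormatError("bracket comments are not supported")
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"malformed Newick: {exc}") from exc

    def convert(dnode: dendropy.Node) -> Node:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        foreground = False
        if label and _FG_MARK.search(label):
            foreground = True
            label = _FG_MARK.sub("", label)
        node = Node(
            label=label or None,
            length=float(dnode.edge.length) if dnode.edge.length is not None else 0.0,
            foreground=foreground,
        )
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    try:
        return Phylogeny(root)
    except Exception as exc:
        raise FormatError(str(exc)) from exc


def write_newick(tree: Phylogeny, foreground_marks: bool = False) -> str:
    return tree.to_newick(lengths=True, foreground_marks=foreground_marks)


# ---------------------------------------------------------------------------
# Orthogroup table
# ---------------------------------------------------------------------------


def parse_orthogroups(source: str | TextIO) -> list[dict]:
    """Parse an orthogroup TSV into family dicts.

    Layout: header row ``family_id<TAB>taxon1<TAB>taxon2...``; each data row
    has a family id then comma-separated sequence ids per taxon (cells may be
    empty).  Returns dicts with keys ``family_id`` and ``members`` (list of
    ``(sequence_id, taxon)``).  A sequence id in two families is a format
    error.
    """
    stream = _as_stream(source)
    header = stream.readline().rstrip("\n")
    if not header:
        raise FormatError("empty orthogroup table")
    cols = header.split("\t")
    if len(cols) < 2:
        raise FormatError("orthogroup header must list at least one taxon")
    taxa = cols[1:]
    families: list[dict] = []
    seen_ids: dict[str, str] = {}
    for lineno, line in enumerate(stream, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        cells = line.split("\t")
        if len(cells) != len(cols):
            raise FormatError(
                f"line {lineno}: expected {len(cols)} columns, found {len(cells)}"
            )
        family_id = cells[0]
        members: list[tuple[str, str]] = []
        for taxon, cell in zip(taxa, cells[1:]):
            for seq_id in filter(None, (s.strip() for s in cell.split(","))):
                if seq_id in seen_ids:
                    raise FormatError(
                        f"line {lineno}: sequence {seq_id!r} already in family "
                        f"{seen_ids[seq_id]!r}"
                    )
                seen_ids[seq_id] = family_id
                members.append((seq_id, taxon))
        families.append({"family_id": family_id, "members": members})
    return families


def write_orthogroups(families: Iterable[dict], taxa: list[str]) -> str:
    lines = ["\t".join(["family_id", *taxa])]
    for fam in families:
        by_taxon: dict[str, list[str]] = {t: [] for t in taxa}
        for seq_id, taxon in fam["members"]:
            by_taxon[taxon].append(seq_id)
        lines.append(
            "\t".join([fam["family_id"], *(",".join(by_taxon[t]) for t in taxa)])
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Tabular similarity hits / annotations / collinear pairs
# ---------------------------------------------------------------------------


def parse_hits(source: str | TextIO) -> list[HitRecord]:
    """Parse 12-column tab-separated similarity results (BLAST outfmt-6 style)."""
    hits: list[HitRecord] = []
    for lineno, line in enumerate(_as_stream(source), start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        cells = line.split("\t")
        if len(cells) != 12:
            raise FormatError(f"line {lineno}: expected 12 columns, found {len(cells)}")
        try:
            pident = float(cells[2])
            alen = int(cells[3])
            evalue = float(cells[10])
            bits = float(cells[11])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
        if evalue < 0:
            raise FormatError(f"line {lineno}: negative E-value")
        if alen < 1:
            raise FormatError(f"line {lineno}: alignment length < 1")
        hits.append(
            HitRecord(cells[0], cells[1], pident, alen, evalue, bits, tuple(cells[4:10]))
        )
    return hits


def parse_annotations(source: str | TextIO) -> dict[str, set[str]]:
    """Parse a two-column gene-id<TAB>term-id table, aggregating duplicates."""
    out: dict[str, set[str]] = {}
    for lineno, line in enumerate(_as_stream(source), start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        cells = line.split("\t")
        if len(cells) != 2:
            raise FormatError(f"line {lineno}: expected 2 columns, found {len(cells)}")
        out.setdefault(cells[0], set()).add(cells[1])
    return out


def parse_collinear_pairs(source: str | TextIO) -> list[CollinearPair]:
    """Parse collinear gene pairs: block_id, gene_a, gene_b[, genome_a, genome_b]."""
    pairs: list[CollinearPair] = []
    for lineno, line in enumerate(_as_stream(source), start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        cells = line.split("\t")
        if len(cells) not in (3, 5):
            raise FormatError(f"line {lineno}: expected 3 or 5 columns, found {len(cells)}")
        try:
            pairs.append(CollinearPair(*cells))
        except FormatError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
    return pairs


def sequences_by_id(records: Iterable[SequenceRecord]) -> Mapping[str, SequenceRecord]:
    return {rec.id: rec for rec in records}
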