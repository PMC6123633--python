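"""Composition and alignment-quality filters for homologous protein sets.

The screen keeps only families that (a) contain at least ``min_size`` proteins
including one from the focal genus, and (b) after column trimming retain at
least ``min_cols`` aligned positions over at least ``min_rows`` sequences.
Families are additionally sorted into single-copy (<=1 sequence per taxon) and
multi-copy classes; multi-copy families face the tree-congruence paralog
filter downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ConfigurationError, FormatError
from .io_formats import GAP_CHARS, SequenceRecord

__all__ = [
    "HomologFamily",
    "FilterDecision",
    "drop_short_sequences",
    "family_passes_composition",
    "trim_gappy_columns",
    "alignment_passes_length",
    "classify_copy_number",
]

# copy classes
UNCLASSIFIED = "unclassified"
SINGLE_COPY = "single_copy"
MULTI_COPY = "multi_copy"

# decision reasons
OK = "ok"
TOO_SMALL = "too_small"
NO_FOCAL_MEMBER = "no_focal_member"
SHORT_ALIGNMENT = "short_alignment"
EMPTY_AFTER_TRIM = "empty_after_trim"


@dataclass
class HomologFamily:
    """One putatively homologous protein set with per-sequence taxon labels."""

    family_id: str
    members: list[tuple[str, str]]  # (sequence_id, taxon)
    proteins: dict[str, str] = field(default_factory=dict)  # id -> residues
    copy_class: str = UNCLASSIFIED

    @property
    def sequence_ids(self) -> list[str]:
        return [seq_id for seq_id, _ in self.members]

    @property
    def taxa(self) -> list[str]:
        return [taxon for _, taxon in self.members]

    def taxon_of(self) -> dict[str, str]:
        return dict(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class FilterDecision:
    family_id: str
    passed: bool
    reason: str

    def __post_init__(self) -> None:
        assert self.passed == (self.reason == OK)


def drop_short_sequences(
    records: Sequence[SequenceRecord], min_len: int = 30
) -> list[SequenceRecord]:
    """Remove proteins whose ungapped length is below ``min_len`` residues.

    Applied before clustering; the boundary is inclusive (a 30-residue protein
    is kept under the default).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [rec for rec in records if len(rec.ungapped) >= min_len]


def family_passes_composition(
    family: HomologFamily,
    genus_map: Mapping[str, str],
    focal_genus: str,
    min_size: int = 4,
) -> FilterDecision:
    """Family passes iff it has >= ``min_size`` proteins, >=1 from the focal genus."""
    for taxon in family.taxa:
        if taxon not in genus_map:
            raise ConfigurationError(f"taxon {taxon!r} missing from genus map")
    if len(family) < min_size:
        return FilterDecision(family.family_id, False, TOO_SMALL)
    if not any(genus_map[taxon] == focal_genus for taxon in family.taxa):
        return FilterDecision(family.family_id, False, NO_FOCAL_MEMBER)
    return FilterDecision(family.family_id, True, OK)


def _check_rectangular(alignment: Sequence[SequenceRecord]) -> int:
    lengths = {len(rec.residues) for rec in alignment}
    if len(lengths) > 1:
        raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
    return lengths.pop() if lengths else 0


def gappy_column_keep_indices(
    alignment: Sequence[SequenceRecord], max_gap_fraction: float = 0.5
) -> list[int]:
    """Indices of columns whose gap fraction is <= ``max_gap_fraction``."""
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    n_cols = _check_rectangular(alignment)
    if not alignment:
        return []
    n_rows = len(alignment)
    return [
        col
        for col in range(n_cols)
        if sum(rec.residues[col] in GAP_CHARS for rec in alignment) / n_rows
        <= max_gap_fraction
    ]


def trim_gappy_columns(
    alignment: Sequence[SequenceRecord], max_gap_fraction: float = 0.5
) -> list[SequenceRecord]:
    """Drop columns whose gap fraction exceeds ``max_gap_fraction``.

    Gap characters are '-' and '.'; ambiguity codes count as residues.  A
    column exactly at the threshold is kept.  Stand-in for an automated
    alignment-trimming heuristic: explicit, deterministic and testable.
    """
    keep = gappy_column_keep_indices(alignment, max_gap_fraction)
    if not alignment:
        return list(alignment)
    return [
        SequenceRecord(
            rec.id,
            "".join(rec.residues[c] for c in keep),
            kind=rec.kind,
            taxon=rec.taxon,
        )
        for rec in alignment
    ]


def alignment_passes_length(
    alignment: Sequence[SequenceRecord],
    family_id: str = "",
    min_cols: int = 60,
    min_rows: int = 4,
) -> FilterDecision:
    """Alignment passes iff it keeps >= ``min_cols`` columns and >= ``min_rows`` rows."""
    n_cols = _check_rectangular(alignment)
    if len(alignment) < min_rows:
        return FilterDecision(family_id, False, TOO_SMALL)
    if n_cols == 0:
        return FilterDecision(family_id, False, EMPTY_AFTER_TRIM)
    if n_cols < min_cols:
        return FilterDecision(family_id, False, SHORT_ALIGNMENT)
    return FilterDecision(family_id, True, OK)


def classify_copy_number(family: HomologFamily) -> str:
    """``single_copy`` iff no taxon contributes more than one sequence."""
    counts: dict[str, int] = {}
    for taxon in family.taxa:
        counts[taxon] = counts.get(taxon, 0) + 1
    return SINGLE_COPY if all(c <= 1 for c in counts.values()) else MULTI_COPY
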