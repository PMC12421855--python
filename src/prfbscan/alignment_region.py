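"""Projecting motif coordinates through a multiple sequence alignment.

Genes without a premature stop still carry the region where the frameshift
motif *would* sit.  Given a user-supplied nucleotide alignment of the gene
family, the stop positions of the motif-positive rows are mapped to
alignment columns, the modal column anchors the expected region, and the
corresponding (gap-free) stretch of any target row is extracted -- the
input for the "no frameshift" logo.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Optional

from Bio import SeqIO

from .genome_io import FormatError

__all__ = [
    "Alignment",
    "ColumnInterval",
    "ExpectedRegion",
    "read_alignment",
    "pos_to_col",
    "col_to_pos",
    "expected_region",
    "write_regions_fasta",
]

GAP = "-"


@dataclass
class Alignment:
    """A parsed nucleotide alignment: ordered ids and equal-length gapped rows."""

    ids: list
    rows: list
    n_cols: int

    def row(self, id: str) -> str:
        try:
            return self.rows[self.ids.index(id)]
        except ValueError:
            raise KeyError(f"sequence id {id!r} not in alignment") from None


class ColumnInterval(NamedTuple):
    start_col: int  # 1-based inclusive
    end_col: int


class ExpectedRegion(NamedTuple):
    sequence: str  # gap-free target residues in the interval
    interval: ColumnInterval
    anchor_col: int
    notes: tuple = ()


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA (>= 2 records, equal lengths, unique ids)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise FormatError(f"{path}: alignment needs >= 2 records, found {len(records)}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise FormatError(f"{path}: duplicate sequence id {dup!r}")
    rows = [str(r.seq).upper() for r in records]
    n_cols = len(rows[0])
    for rid, row in zip(ids, rows):
        if len(row) != n_cols:
            raise FormatError(
                f"{path}: ragged alignment: row {rid!r} has length {len(row)}, expected {n_cols}"
            )
    return Alignment(ids=ids, rows=rows, n_cols=n_cols)


def pos_to_col(alignment: Alignment, id: str, ungapped_pos: int) -> int:
    """Alignment column (1-based) holding the ``ungapped_pos``-th residue of a row."""
    if ungapped_pos < 1:
        raise ValueError("ungapped_pos is 1-based and must be >= 1")
    row = alignment.row(id)
    seen = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            seen += 1
            if seen == ungapped_pos:
                return col
    raise ValueError(
        f"position {ungapped_pos} beyond ungapped length {seen} of row {id!r}"
    )


def col_to_pos(alignment: Alignment, id: str, col: int) -> int:
    """Ungapped residue position (1-based) at an alignment column; gap -> error."""
    row = alignment.row(id)
    if not 1 <= col <= alignment.n_cols:
        raise ValueError(f"column {col} outside 1..{alignment.n_cols}")
    if row[col - 1] == GAP:
        raise ValueError(f"column {col} of row {id!r} is a gap")
    return sum(1 for ch in row[:col] if ch != GAP)


def expected_region(
    alignment: Alignment,
    motif_calls: Mapping[str, int],
    target_id: str,
    flank_up: int = 15,
    flank_down: int = 4,
) -> ExpectedRegion:
    """Extract the expected motif region of a target row.

    ``motif_calls`` maps motif-positive ids to the 0-based nt offset of
    their premature-stop start (as reported by the scanner).  Each offset is
    projected to its alignment column; the modal column (ties -> smallest)
    anchors a ``[anchor - flank_up, anchor + flank_down]`` column interval,
    clipped to the alignment; the target's residues in the interval are
    returned with gaps removed.
    """
    present = {i: off for i, off in motif_calls.items() if i in alignment.ids}
    if not present:
        raise ValueError("no motif-positive ids present in the alignment")
    target_row = alignment.row(target_id)  # raises KeyError if absent

    cols = [pos_to_col(alignment, i, off + 1) for i, off in sorted(present.items())]
    counts = Counter(cols)
    top = max(counts.values())
    anchor = min(c for c, n in counts.items() if n == top)

    notes = []
    start = anchor - flank_up
    end = anchor + flank_down
    if start < 1 or end > alignment.n_cols:
        notes.append("interval clipped at alignment bounds")
        start = max(1, start)
        end = min(alignment.n_cols, end)
    interval = ColumnInterval(start, end)
    region = target_row[start - 1 : end].replace(GAP, "")
    if not region:
        notes.append("target row is all gaps in the expected interval")
    return ExpectedRegion(region, interval, anchor, tuple(notes))


def write_regions_fasta(regions: Mapping[str, str], path) -> None:
    """Write extracted regions as FASTA (ids in sorted order for determinism)."""
    with open(path, "w") as fh:
        for rid in sorted(regions):
            fh.write(f">{rid}\n{regions[rid]}\n")
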