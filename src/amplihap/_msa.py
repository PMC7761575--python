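"""Projection of pairwise reference alignments into one reference-anchored MSA.

Shared by the contig layout step (contigs aligned to the working reference)
and by the star alignment used to prepare allele sets for phylogenetics.
Rows are described by their reference start plus cigar-style ops
('=', 'X' consume both; 'I' consumes query only; 'D' consumes reference
only) and the oriented query sequence.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from ._seq import GAP_CODE, encode

ABSENT = 255
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if not ops or sum(n for _, n in ops) == 0:
        raise ValueError(f"unparseable cigar {cigar!r}")
    return ops


def cigar_identity(cigar: str) -> tuple[int, int]:
    """(matches, alignment columns) from an extended cigar string."""
    matches = 0
    cols = 0
    for op, n in parse_cigar(cigar):
        cols += n
        if op == "=":
            matches += n
    return matches, cols


@dataclass
class AlignedRow:
    row_id: str
    ref_start: int
    ops: list[tuple[str, int]]
    query: str  # oriented query sequence (the part that aligns)


@dataclass
class ProjectedMsa:
    """Reference plus rows projected into common columns.

    ``col_ref`` holds the reference position of each column, or -1 for
    insertion columns.  Row arrays use base codes 0..4, GAP_CODE for a gap
    inside the row's extent and ABSENT outside it.
    """

    ref_id: str
    col_ref: np.ndarray
    ref_row: np.ndarray
    row_ids: list[str]
    rows: list[np.ndarray]
    extents: list[tuple[int, int]]

    @property
    def n_cols(self) -> int:
        return int(self.col_ref.size)

    def gapped_strings(self) -> list[tuple[str, str]]:
        """(row_id, gapped sequence) pairs, reference first; '-' covers both
        gaps and columns outside a row's extent."""
        lookup = np.frombuffer(b"ACGTN-", dtype=np.uint8)
        out = []
        ref = self.ref_row.copy()
        out.append((self.ref_id, lookup[np.minimum(ref, 5)].tobytes().decode()))
        for rid, arr in zip(self.row_ids, self.rows):
            a = np.where(arr == ABSENT, GAP_CODE, arr)
            out.append((rid, lookup[np.minimum(a, 5)].tobytes().decode()))
        return out


def project_rows(reference: str, rows: list[AlignedRow], ref_id: str = "reference") -> ProjectedMsa:
    L = len(reference)
    ins_width: dict[int, int] = {}
    for row in rows:
        r = row.ref_start
        for op, n in row.ops:
            if op == "I":
                ins_width[r] = max(ins_width.get(r, 0), n)
            elif op in "=XM":
                r += n
            elif op == "D":
                r += n

    # column layout: [insertions before ref pos p][ref base p] for p in 0..L
    base_col = np.zeros(L, dtype=np.int64)
    ins_col: dict[int, int] = {}
    c = 0
    for p in range(L + 1):
        w = ins_width.get(p, 0)
        if w:
            ins_col[p] = c
            c += w
        if p < L:
            base_col[p] = c
            c += 1
    n_cols = c

    col_ref = np.full(n_cols, -1, dtype=np.int64)
    col_ref[base_col] = np.arange(L)
    ref_row = np.full(n_cols, GAP_CODE, dtype=np.uint8)
    ref_row[base_col] = encode(reference)

    out_rows: list[np.ndarray] = []
    extents: list[tuple[int, int]] = []
    for row in rows:
        arr = np.full(n_cols, ABSENT, dtype=np.uint8)
        q = encode(row.query)
        r = row.ref_start
        qi = 0
        for op, n in row.ops:
            if op in "=XM":
                arr[base_col[r : r + n]] = q[qi : qi + n]
                r += n
                qi += n
            elif op == "D":
                arr[base_col[r : r + n]] = GAP_CODE
                r += n
            elif op == "I":
                c0 = ins_col[r]
                arr[c0 : c0 + n] = q[qi : qi + n]
                qi += n
        filled = np.nonzero(arr != ABSENT)[0]
        lo, hi = int(filled[0]), int(filled[-1]) + 1
        arr[lo:hi][arr[lo:hi] == ABSENT] = GAP_CODE  # unused insertion columns
        out_rows.append(arr)
        extents.append((lo, hi))

    return ProjectedMsa(
        ref_id=ref_id,
        col_ref=col_ref,
        ref_row=ref_row,
        row_ids=[r.row_id for r in rows],
        rows=out_rows,
        extents=extents,
    )
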