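"""Per-plant gene reconstruction from short reads.

The chain follows the reference-assisted de novo assembly idea: reads are
assembled into contigs (greedy overlap/layout/consensus at desk scale), the
contigs are laid out against the reference gene, a consensus is extracted
*discarding the reference row*, and the draft is then polished by an
iterative map -> call -> filter -> apply loop (default 6 iterations).
Variant calls are kept when QUAL > 20 at every iteration and additionally
require allele balance AB > 0.25 on the last two iterations, which removes
random sequencing errors while still letting true variants through.

QUAL here is a Phred-scaled binomial tail statistic:
``-10 log10 P(>= k alt reads | depth n, per-base error e)`` with ``e``
derived from the mean Phred quality of the read set.  The caller is haploid
(one alternate allele per site), matching one consensus per selfed plant.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np
from scipy.stats import binom

from ._msa import ABSENT, AlignedRow, ProjectedMsa, cigar_identity, parse_cigar, project_rows
from ._seq import GAP_CODE, decode, encode, revcomp_codes
from .io_formats import FastqRecord, GeneModel, ValidationError


class AssemblyError(RuntimeError):
    pass


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str
    support: int


@dataclass
class LayoutConfig:
    """Contig-vs-reference layout settings (mild, tolerant of divergence).

    A contig is accepted when its best local alignment reaches the percent
    identity cutoff over the aligned columns *and* covers at least
    ``min_aligned_frac`` of the contig (so a short spurious high-identity
    segment of an unrelated contig does not slip through).
    """

    match_score: float = 40.0
    min_identity_pct: float = 70.0
    gap_penalty: float = 1.0
    min_aligned_frac: float = 0.5

    def __post_init__(self):
        if not (0 < self.min_identity_pct <= 100):
            raise ValidationError("identity cutoff must be in (0, 100]")
        if not (0 < self.min_aligned_frac <= 1):
            raise ValidationError("min_aligned_frac must be in (0, 1]")


@dataclass(frozen=True)
class VariantCall:
    """A candidate edit to the current reference (0-based position).

    For substitutions ``ref``/``alt`` are equal-length; deletions have empty
    ``alt``; insertions have empty ``ref`` and are placed before ``position``.
    """

    position: int
    ref: str
    alt: str
    qual: float
    ab: float
    depth: int


@dataclass
class PolishConfig:
    iterations: int = 6
    qual_min: float = 20.0   # strict >
    ab_min: float = 0.25     # strict >, last two iterations only
    k_map: int = 16
    asm_min_overlap: int = 40
    asm_min_identity: float = 0.9
    asm_coverage: float = 15.0
    map_min_identity: float = 0.8
    early_stop: bool = True

    def __post_init__(self):
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if self.qual_min < 0 or self.ab_min < 0:
            raise ValidationError("thresholds must be >= 0")


@dataclass
class ReadAlignment:
    """One mapped read: gapless (cigar None) or with extended-cigar ops."""

    ref_start: int
    codes: np.ndarray  # oriented query codes participating in the alignment
    cigar: list[tuple[str, int]] | None
    nm: int
    strand: int


# ---------------------------------------------------------------------------
# Greedy overlap assembly


def _read_sequences(reads) -> list[str]:
    return [r.sequence if isinstance(r, FastqRecord) else str(r) for r in reads]


def assemble_contigs(
    reads,
    min_overlap: int = 40,
    min_identity: float = 0.9,
    k: int = 16,
) -> list[Contig]:
    """Greedy overlap-layout-consensus assembly of substitution-only reads.

    Candidate suffix/prefix overlaps are found through shared k-mers (both
    orientations), verified gaplessly, and merged best-overlap-first with a
    union-find over rigid read placements; contig bases are per-column
    majorities.  Worst case (no overlaps) one contig per read.
    """
    seqs = _read_sequences(reads)
    if not seqs:
        raise AssemblyError("no reads to assemble")
    n = len(seqs)
    fwd = [encode(s) for s in seqs]
    rc = [revcomp_codes(a) for a in fwd]
    lens = [len(s) for s in seqs]

    index: dict[bytes, list[tuple[int, int]]] = {}
    step = 4
    for i, arr in enumerate(fwd):
        for off in range(0, len(arr) - k + 1, step):
            index.setdefault(arr[off : off + k].tobytes(), []).append((i, off))

    edges = []
    qstep = 7
    for i in range(n):
        for o, arr in ((0, fwd[i]), (1, rc[i])):
            votes: dict[tuple[int, int], int] = {}
            for off in range(0, len(arr) - k + 1, qstep):
                for j, boff in index.get(arr[off : off + k].tobytes(), ()):
                    if j <= i:
                        continue
                    key = (j, boff - off)
                    votes[key] = votes.get(key, 0) + 1
            best: dict[int, tuple[int, int]] = {}
            for (j, d), v in votes.items():
                if j not in best or v > best[j][1]:
                    best[j] = (d, v)
            for j, (d, _) in best.items():
                xs = max(0, -d)
                xe = min(lens[i], lens[j] - d)
                ol = xe - xs
                if ol < min_overlap:
                    continue
                a = arr[xs:xe]
                b = fwd[j][xs + d : xe + d]
                matches = int(np.count_nonzero(a == b))
                if matches / ol < min_identity:
                    continue
                edges.append((matches, i, j, o, d))
    edges.sort(key=lambda e: (-e[0], e[1], e[2], e[3], e[4]))

    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # root -> list of (read index, strand, position in contig frame)
    members: dict[int, list[tuple[int, int, int]]] = {i: [(i, 0, 0)] for i in range(n)}
    placement: dict[int, tuple[int, int]] = {i: (0, 0) for i in range(n)}  # strand, pos

    def rebase(root_from, flip: bool, const: int, shift: int):
        moved = []
        for m, s, p in members.pop(root_from):
            if flip:
                s2, p2 = 1 - s, const - p - lens[m] + 1
            else:
                s2, p2 = s, p + shift
            placement[m] = (s2, p2)
            moved.append((m, s2, p2))
        return moved

    for matches, i, j, o, d in edges:
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        s_i, p_i = placement[i]
        s_j, p_j = placement[j]
        Li, Lj = lens[i], lens[j]
        if o == s_i:
            # j forward maps into frame(i) at p_i - d, same orientation
            if s_j == 0:
                flip, const, shift = False, 0, (p_i - d) - p_j
            else:
                flip, const, shift = True, p_j + Lj - 1 + p_i - d, 0
        else:
            c2 = p_i + Li - 1 + d
            if s_j == 0:
                flip, const, shift = True, p_j + c2, 0
            else:
                flip, const, shift = False, 0, c2 - p_j - Lj + 1
        moved = rebase(rj, flip, const, shift)
        members[ri].extend(moved)
        parent[rj] = ri

    contigs = []
    for root, group in members.items():
        minpos = min(p for _, _, p in group)
        length = max(p - minpos + lens[m] for m, _, p in group)
        counts = np.zeros((length, 5), dtype=np.int32)
        eye = np.eye(5, dtype=np.int32)
        for m, s, p in group:
            arr = fwd[m] if s == 0 else rc[m]
            np.add.at(counts, np.arange(p - minpos, p - minpos + lens[m]), eye[arr])
        seq = decode(np.argmax(counts[:, :4], axis=1).astype(np.uint8))
        contigs.append((length, len(group), seq))
    contigs.sort(key=lambda t: (-t[0], t[2]))
    return [
        Contig(id=f"contig{idx + 1}", sequence=seq, support=sup)
        for idx, (_, sup, seq) in enumerate(contigs)
    ]


# ---------------------------------------------------------------------------
# Layout against the reference and consensus extraction


class LayoutMsa(ProjectedMsa):
    """Reference-anchored contig MSA (reference row first)."""

    @property
    def rows_with_reference(self) -> list[tuple[str, str]]:
        return self.gapped_strings()


def _layout_aligner(config: LayoutConfig):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    # match weight proportional to the match score factor m (m=40 -> +2);
    # gap costs proportional to the gap penalty factor g
    aligner.match_score = config.match_score / 20.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -8.0 * config.gap_penalty
    aligner.extend_gap_score = -1.0 * config.gap_penalty
    return aligner


def layout_against_reference(
    contigs: list[Contig], reference: str, config: LayoutConfig | None = None
) -> LayoutMsa:
    """Align each contig to the reference in its better orientation and
    project the accepted alignments into one reference-coordinate MSA.

    Each contig is locally aligned with affine gaps (Smith-Waterman);
    contigs whose best alignment identity falls below the percent cutoff
    are discarded (mild layout: substantial divergence is still accepted).
    """
    config = config or LayoutConfig()
    if not reference:
        raise ValidationError("empty reference")
    aligner = _layout_aligner(config)
    rows: list[AlignedRow] = []
    for contig in contigs:
        best = None
        for strand, seq in ((0, contig.sequence), (1, decode(revcomp_codes(encode(contig.sequence))))):
            alns = aligner.align(seq, reference)
            if alns.score > (best.score if best is not None else -math.inf):
                best = alns[0]
                best_seq = seq
        qblocks, tblocks = best.aligned
        if len(qblocks) == 0:
            continue
        ops: list[tuple[str, int]] = []
        matches = cols = 0
        for k in range(len(qblocks)):
            qs, qe = map(int, qblocks[k])
            ts, te = map(int, tblocks[k])
            ops.append(("M", qe - qs))
            cols += qe - qs
            matches += sum(a == b for a, b in zip(best_seq[qs:qe], reference[ts:te]))
            if k + 1 < len(qblocks):
                dq = int(qblocks[k + 1][0]) - qe
                dt = int(tblocks[k + 1][0]) - te
                if dq:
                    ops.append(("I", dq))
                    cols += dq
                if dt:
                    ops.append(("D", dt))
                    cols += dt
        qstart = int(qblocks[0][0])
        qend = int(qblocks[-1][1])
        if 100.0 * matches / cols < config.min_identity_pct:
            continue
        if (qend - qstart) < config.min_aligned_frac * len(contig.sequence):
            continue
        rows.append(
            AlignedRow(
                row_id=contig.id,
                ref_start=int(tblocks[0][0]),
                ops=ops,
                query=best_seq[qstart:qend],
            )
        )
    if not rows:
        raise AssemblyError("no layout: every contig fell below the identity cutoff")
    proj = project_rows(reference, rows)
    return LayoutMsa(**proj.__dict__)


def consensus_from_msa(msa: ProjectedMsa, discard_reference: bool = True) -> str:
    """Per-column majority consensus after removing the reference row.

    Gaps within a row's extent vote for a deletion; columns not covered by
    any non-reference row emit N (reference-only coverage); insertion
    columns with no coverage are dropped; ties go to the reference base.
    """
    if not msa.rows:
        raise AssemblyError("empty MSA")
    n_cols = msa.n_cols
    counts = np.zeros((n_cols, 5), dtype=np.int32)  # A C G T N
    gap = np.zeros(n_cols, dtype=np.int32)
    rows = msa.rows if discard_reference else msa.rows + [np.where(msa.ref_row == GAP_CODE, np.uint8(GAP_CODE), msa.ref_row)]
    for arr in rows:
        present = arr != ABSENT
        isgap = present & (arr == GAP_CODE)
        gap += isgap
        basemask = present & ~isgap
        idx = np.nonzero(basemask)[0]
        np.add.at(counts, (idx, arr[idx]), 1)
    covered = counts.sum(axis=1) + gap
    top = np.argmax(counts, axis=1)
    topc = counts[np.arange(n_cols), top]

    out = []
    lookup = "ACGTN"
    ref_has_base = msa.ref_row != GAP_CODE
    for c in range(n_cols):
        if covered[c] == 0:
            if ref_has_base[c]:
                out.append("N")
            continue  # uncovered insertion column: drop
        if gap[c] > topc[c]:
            continue  # deletion wins
        if gap[c] == topc[c]:
            if ref_has_base[c]:
                out.append(lookup[int(msa.ref_row[c])])
            continue
        # tie between bases resolved toward the reference base when tied
        tied = np.nonzero(counts[c] == topc[c])[0]
        if tied.size > 1 and ref_has_base[c] and msa.ref_row[c] in tied:
            out.append(lookup[int(msa.ref_row[c])])
        else:
            out.append(lookup[int(tied[0])])
    return "".join(out)


# ---------------------------------------------------------------------------
# Read mapping (seed and extend)


def _build_index(ref: np.ndarray, k: int) -> dict[bytes, list[int]]:
    index: dict[bytes, list[int]] = {}
    for off in range(0, len(ref) - k + 1):
        key = ref[off : off + k].tobytes()
        lst = index.get(key)
        if lst is None:
            index[key] = [off]
        elif len(lst) < 8:
            lst.append(off)
    return index


def _seed_diag(arr: np.ndarray, index, k: int) -> tuple[int, int]:
    """Best diagonal (read start on reference) and its vote count."""
    L = len(arr)
    offsets = [0, (L - k) // 2, L - k] if L > k else [0]
    votes: dict[int, int] = {}
    for off in offsets:
        for pos in index.get(arr[off : off + k].tobytes(), ()):
            d = pos - off
            votes[d] = votes.get(d, 0) + 1
    if not votes:
        for off in range(0, L - k + 1, k):
            for pos in index.get(arr[off : off + k].tobytes(), ()):
                d = pos - off
                votes[d] = votes.get(d, 0) + 1
        if not votes:
            return (0, 0)
    d = max(votes, key=lambda key: (votes[key], -abs(key)))
    return (d, votes[d])


def map_reads(
    reads,
    reference: str,
    k_map: int = 16,
    min_identity: float = 0.8,
) -> list[ReadAlignment]:
    """Seed-and-extend mapping of reads against both strands of a reference.

    Exact k-mers vote for a diagonal; the placement is verified gaplessly
    and falls back to a banded edit-distance alignment of the read against
    a local reference window when substitutions alone cannot explain it.
    Reads with no seed or identity below ``min_identity`` are dropped.
    """
    ref = encode(reference)
    refL = len(ref)
    if refL < k_map:
        raise ValidationError("reference shorter than the seed length")
    index = _build_index(ref, k_map)
    out: list[ReadAlignment] = []
    for read in reads:
        seq = read.sequence if isinstance(read, FastqRecord) else str(read)
        f = encode(seq)
        candidates = []
        for strand, arr in ((0, f), (1, revcomp_codes(f))):
            d, v = _seed_diag(arr, index, k_map)
            if v > 0:
                candidates.append((v, strand, arr, d))
        if not candidates:
            continue
        candidates.sort(key=lambda t: -t[0])
        placed = False
        evaluated = []
        for _, strand, arr, d in candidates:
            L = len(arr)
            rs, re_ = max(0, d), min(refL, d + L)
            if re_ - rs < 0.5 * L:
                continue
            qoff = rs - d
            seg = arr[qoff : qoff + re_ - rs]
            mm = int(np.count_nonzero(ref[rs:re_] != seg))
            evaluated.append((mm, strand, arr, d, rs, re_, qoff))
        for mm, strand, arr, d, rs, re_, qoff in sorted(evaluated, key=lambda t: t[0]):
            if mm <= 0.08 * (re_ - rs):
                out.append(ReadAlignment(ref_start=rs, codes=arr[qoff : qoff + re_ - rs],
                                         cigar=None, nm=mm, strand=strand))
                placed = True
                break
        if placed or not candidates:
            continue
        # banded fallback around the best-voted diagonal
        _, strand, arr, d = candidates[0]
        pad = 40
        ws = max(0, d - pad)
        we = min(refL, d + len(arr) + pad)
        window = decode(ref[ws:we])
        res = edlib.align(decode(arr), window, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        matches, cols = cigar_identity(res["cigar"])
        if matches / cols < min_identity:
            continue
        out.append(ReadAlignment(ref_start=ws + res["locations"][0][0], codes=arr,
                                 cigar=parse_cigar(res["cigar"]), nm=cols - matches, strand=strand))
    return out


# ---------------------------------------------------------------------------
# Pileup calling, filtering, applying


def _phred_from_sf(sf: np.ndarray) -> np.ndarray:
    return np.minimum(-10.0 * np.log10(np.maximum(sf, 1e-300)), 1000.0)


def _left_normalize_del(seq: str, pos: int, length: int) -> int:
    while pos > 0 and seq[pos - 1] == seq[pos + length - 1]:
        pos -= 1
    return pos


def _left_normalize_ins(seq: str, pos: int, ins: str) -> tuple[int, str]:
    while pos > 0 and ins[-1] == seq[pos - 1]:
        ins = seq[pos - 1] + ins[:-1]
        pos -= 1
    return pos, ins


def pileup_and_call(
    alignments: list[ReadAlignment],
    reference: str,
    mean_qual: float = 30.0,
) -> list[VariantCall]:
    """Haploid pileup caller over a set of read alignments.

    Per column the top non-reference base is a substitution candidate;
    maximal runs where a deletion is the plurality become single left-
    aligned deletion calls; recurring identical insertions become insertion
    calls.  QUAL is the Phred-scaled binomial tail with per-base error
    ``e = 10**(-mean_qual/10)``; AB is alt support over spanning depth.
    Adjacent substitution calls are *not* merged here.
    """
    ref = encode(reference)
    L = len(ref)
    counts = np.zeros((L, 5), dtype=np.int32)  # A C G T del
    insertions: dict[tuple[int, str], int] = {}

    pos_chunks, code_chunks = [], []
    for aln in alignments:
        if aln.cigar is None:
            pos_chunks.append(np.arange(aln.ref_start, aln.ref_start + len(aln.codes)))
            code_chunks.append(aln.codes)
        else:
            r, q = aln.ref_start, 0
            for op, n in aln.cigar:
                if op in "=XM":
                    pos_chunks.append(np.arange(r, r + n))
                    code_chunks.append(aln.codes[q : q + n])
                    r += n
                    q += n
                elif op == "D":
                    counts[r : r + n, 4] += 1
                    r += n
                elif op == "I":
                    key = (r, decode(aln.codes[q : q + n]))
                    insertions[key] = insertions.get(key, 0) + 1
                    q += n
    if pos_chunks:
        allpos = np.concatenate(pos_chunks)
        allcodes = np.concatenate(code_chunks).astype(np.int64)
        keep = allcodes < 4  # N in reads does not vote
        np.add.at(counts, (allpos[keep], allcodes[keep]), 1)

    depth = counts.sum(axis=1)
    e = 10.0 ** (-mean_qual / 10.0)
    calls: list[VariantCall] = []

    base_counts = counts[:, :4]
    alt_counts = base_counts.copy()
    ref_is_base = ref < 4
    idx = np.nonzero(ref_is_base)[0]
    alt_counts[idx, ref[idx]] = 0
    top = np.argmax(alt_counts, axis=1)
    topc = alt_counts[np.arange(L), top]
    delc = counts[:, 4]

    sub_cols = np.nonzero((topc >= 1) & (topc >= delc))[0]
    if sub_cols.size:
        quals = _phred_from_sf(binom.sf(topc[sub_cols] - 1, depth[sub_cols], e))
        for c, q in zip(sub_cols, quals):
            calls.append(
                VariantCall(
                    position=int(c),
                    ref="ACGTN"[int(ref[c])],
                    alt="ACGT"[int(top[c])],
                    qual=float(q),
                    ab=float(topc[c] / depth[c]) if depth[c] else 0.0,
                    depth=int(depth[c]),
                )
            )

    # deletion runs where the gap is the plurality alternative
    del_cols = (delc >= 1) & (delc > topc)
    c = 0
    while c < L:
        if not del_cols[c]:
            c += 1
            continue
        run_start = c
        while c < L and del_cols[c]:
            c += 1
        run = slice(run_start, c)
        support = int(delc[run].min())
        run_depth = int(depth[run].max())
        pos = _left_normalize_del(reference, run_start, c - run_start)
        qual = float(_phred_from_sf(binom.sf(np.array([support - 1]), run_depth, e))[0])
        calls.append(
            VariantCall(
                position=pos,
                ref=reference[pos : pos + (c - run_start)],
                alt="",
                qual=qual,
                ab=support / run_depth if run_depth else 0.0,
                depth=run_depth,
            )
        )

    best_ins: dict[int, tuple[int, str]] = {}
    for (pos, seq), cnt in insertions.items():
        cur = best_ins.get(pos)
        if cur is None or (cnt, seq) > cur:
            best_ins[pos] = (cnt, seq)
    for pos, (cnt, seq) in sorted(best_ins.items()):
        dcol = min(max(pos, 0), L - 1)
        d = int(depth[dcol])
        npos, nseq = _left_normalize_ins(reference, pos, seq)
        qual = float(_phred_from_sf(binom.sf(np.array([cnt - 1]), max(d, cnt), e))[0])
        calls.append(
            VariantCall(position=npos, ref="", alt=nseq, qual=qual,
                        ab=cnt / d if d else 0.0, depth=max(d, cnt))
        )

    calls.sort(key=lambda v: (v.position, len(v.ref), v.alt))
    return calls


def filter_calls(calls: list[VariantCall], iteration_index: int, config: PolishConfig) -> list[VariantCall]:
    """QUAL > qual_min always; AB > ab_min only on the last two iterations.

    Both inequalities are strict.  Pure function: the result is a subset of
    the input in the original order.
    """
    if not (1 <= iteration_index <= config.iterations):
        raise ValidationError(
            f"iteration index {iteration_index} outside 1..{config.iterations}"
        )
    ab_active = iteration_index > config.iterations - 2
    out = []
    for c in calls:
        if not (c.qual > config.qual_min):
            continue
        if ab_active and not (c.ab > config.ab_min):
            continue
        out.append(c)
    return out


def _intervals_conflict(a: tuple[int, int], b: tuple[int, int]) -> bool:
    s1, e1 = a
    s2, e2 = b
    if s1 == e1 and s2 == e2:  # two insertions at the same point
        return s1 == s2
    if s1 == e1:  # insertion strictly inside the other edit
        return s2 < s1 < e2
    if s2 == e2:
        return s1 < s2 < e1
    return s1 < e2 and s2 < e1


def apply_calls(reference: str, calls: list[VariantCall]) -> str:
    """Apply calls right-to-left; overlaps resolved toward the higher QUAL."""
    accepted: list[VariantCall] = []
    occupied: list[tuple[int, int]] = []
    for call in sorted(calls, key=lambda v: (-v.qual, v.position)):
        iv = (call.position, call.position + len(call.ref))
        if any(_intervals_conflict(iv, o) for o in occupied):
            continue
        accepted.append(call)
        occupied.append(iv)
    out = reference
    for call in sorted(accepted, key=lambda v: -v.position):
        i = call.position
        if call.ref and out[i : i + len(call.ref)] != call.ref:
            raise ValidationError(
                f"internal inconsistency applying call at {i}: reference changed"
            )
        out = out[:i] + call.alt + out[i + len(call.ref) :]
    return out


# ---------------------------------------------------------------------------
# Polishing loop and full reconstruction


@dataclass
class ReconstructionResult:
    sequence: str
    iteration_report: list[dict] = field(default_factory=list)
    n_contigs: int = 0
    initial_consensus: str = ""


def polish(
    reads,
    initial_consensus: str,
    config: PolishConfig | None = None,
) -> ReconstructionResult:
    """Iterative map/call/filter/apply polishing of a draft consensus.

    Runs up to ``config.iterations`` rounds.  A round with zero kept calls
    before the allele-balance regime fast-forwards to the first AB-filtered
    round (remapping identical reads to an identical reference reproduces
    the same calls, so the skipped rounds are no-ops); with early stop
    enabled, an AB-filtered round with zero kept calls terminates the loop.
    """
    config = config or PolishConfig()
    quals = [q for r in reads if isinstance(r, FastqRecord) for q in r.qualities]
    mean_qual = float(np.mean(quals)) if quals else 30.0
    ref = initial_consensus
    report: list[dict] = []
    it = 1
    while it <= config.iterations:
        alns = map_reads(reads, ref, k_map=config.k_map, min_identity=config.map_min_identity)
        calls = pileup_and_call(alns, ref, mean_qual=mean_qual)
        kept = filter_calls(calls, it, config)
        ab_active = it > config.iterations - 2
        n_ambiguous = sum(1 for c in kept if ab_active and 0.25 < c.ab < 0.75)
        report.append(
            {
                "iteration": it,
                "n_mapped": len(alns),
                "n_candidates": len(calls),
                "n_kept": len(kept),
                "ab_filtered": ab_active,
                "n_ambiguous_ab": n_ambiguous,
            }
        )
        if kept:
            ref = apply_calls(ref, kept)
            it += 1
            continue
        if ab_active:
            if config.early_stop:
                break
            it += 1
        else:
            it = config.iterations - 1 if config.iterations > 1 else it + 1
    return ReconstructionResult(sequence=ref, iteration_report=report, initial_consensus=initial_consensus)


def reconstruct(
    reads,
    reference,
    polish_config: PolishConfig | None = None,
    layout_config: LayoutConfig | None = None,
) -> ReconstructionResult:
    """Full reference-assisted reconstruction of one gene from one plant.

    assemble_contigs -> layout_against_reference -> consensus_from_msa
    (reference discarded) -> polish.  Assembly uses a systematic subsample
    of the reads (the draft only seeds polishing, which always uses the
    full read set).
    """
    polish_config = polish_config or PolishConfig()
    ref_seq = reference.sequence if isinstance(reference, GeneModel) else str(reference)
    seqs = _read_sequences(reads)
    if not seqs:
        raise AssemblyError("no reads")
    mean_len = sum(len(s) for s in seqs) / len(seqs)
    n_needed = max(10, int(math.ceil(polish_config.asm_coverage * len(ref_seq) / mean_len)))
    stride = max(1, len(seqs) // n_needed)
    subsample = seqs[::stride]
    contigs = assemble_contigs(
        subsample,
        min_overlap=polish_config.asm_min_overlap,
        min_identity=polish_config.asm_min_identity,
    )
    msa = layout_against_reference(contigs, ref_seq, layout_config)
    draft = consensus_from_msa(msa, discard_reference=True)
    result = polish(reads, draft, polish_config)
    result.n_contigs = len(contigs)
    return result
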