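"""From finished sequences to named alleles and protein isoforms.

Finished per-plant gene sequences are compared to the annotated reference
by global alignment; differences are enumerated as single-nucleotide
substitutions (SNS), multiple-nucleotide substitutions (MNS: a maximal run
of two or more adjacent substituted columns with no length change) and
InDels (frameshifting iff the length difference is not a multiple of 3
inside the CDS), each assigned to promoter / exon-CDS / intron / UTR.

Identical sequences across samples form one allele.  Alleles keep registry
names when the sequence was described before; new alleles are named either
by lowercase letters in descending population frequency (a = most frequent)
or by integers continuing the registry numbering.  Alleles translating to
the same protein share an isoform, named with capital letters in descending
summed frequency; amino-acid differences are labelled refAA+position+altAA
against a supplied reference protein.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .consensus import _left_normalize_del, _left_normalize_ins
from .io_formats import AlleleRegistry, GeneModel, ValidationError

REGIONS = ("promoter", "exon-CDS", "intron", "UTR")


@dataclass(frozen=True)
class Scoring:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -7.0   # cost of the first gap column
    gap_extend: float = -2.0


@dataclass
class PairwiseAlignment:
    query: str    # gapped
    subject: str  # gapped
    score: float
    scoring: Scoring

    def __post_init__(self):
        if len(self.query) != len(self.subject):
            raise ValidationError("gapped rows differ in length")


@dataclass(frozen=True)
class Variant:
    gene_position: int            # 1-based on the reference gene
    ref: str
    alt: str
    var_class: str                # SNS | MNS | InDel
    region: str
    cds_position: int | None = None  # 1-based from the A of the start codon
    frameshift: bool = False


@dataclass(frozen=True)
class AlleleEntry:
    name: str
    sequence: str
    count: int
    frequency: float


@dataclass
class AlleleCatalog:
    gene_id: str
    entries: list[AlleleEntry]
    naming_scheme: str
    n_samples: int

    def __post_init__(self):
        total = sum(e.frequency for e in self.entries)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"allele frequencies sum to {total}, not 1")
        if sum(e.count for e in self.entries) != self.n_samples:
            raise ValidationError("allele counts do not sum to the sample size")
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate allele names")

    def sequence_of(self, name: str) -> str:
        for e in self.entries:
            if e.name == name:
                return e.sequence
        raise KeyError(name)


@dataclass(frozen=True)
class ProteinIsoform:
    isoform_name: str
    sequence: str
    frequency: float
    member_alleles: tuple[str, ...]


@dataclass(frozen=True)
class AaVariant:
    position: int
    ref_aa: str
    alt_aa: str

    @property
    def label(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


class CdsError(ValidationError):
    """CDS extraction failed validation; partial output is attached."""

    def __init__(self, message: str, partial: str = ""):
        super().__init__(message)
        self.partial = partial


class TranslationError(ValidationError):
    pass


# ---------------------------------------------------------------------------
# Pairwise global alignment


def _aligner(scoring: Scoring, mode: str = "global") -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = scoring.match
    al.mismatch_score = scoring.mismatch
    al.open_gap_score = scoring.gap_open
    al.extend_gap_score = scoring.gap_extend
    return al


def global_align(query: str, subject: str, scoring: Scoring | None = None) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps (Needleman-Wunsch/Gotoh).

    A gap of length L scores ``gap_open + (L - 1) * gap_extend``.  The
    first optimal alignment in the aligner's deterministic enumeration
    order is returned.
    """
    if not query or not subject:
        raise ValidationError("cannot align empty sequences")
    scoring = scoring or Scoring()
    aln = _aligner(scoring).align(query, subject)
    best = aln[0]
    return PairwiseAlignment(query=best[0], subject=best[1], score=float(aln.score), scoring=scoring)


# ---------------------------------------------------------------------------
# Variant enumeration


def _region_maps(gene: GeneModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-position region index (into REGIONS) and 1-based CDS position (0 = none)."""
    L = gene.length
    region = np.full(L, 3, dtype=np.int8)  # default UTR
    first = min(s for s, _ in gene.exon_spans)
    last = max(e for _, e in gene.exon_spans)
    region[first:last] = 2  # intron unless covered by an exon below
    for s, e in gene.exon_spans:
        region[s:e] = 3
    cds_index = np.zeros(L, dtype=np.int64)
    pos = 0
    for s, e in gene.cds_spans:
        region[s:e] = 1
        cds_index[s:e] = np.arange(pos + 1, pos + 1 + (e - s))
        pos += e - s
    s, e = gene.promoter_span
    region[s:e] = 0
    return region, cds_index


def enumerate_variants(alignment: PairwiseAlignment, gene: GeneModel) -> list[Variant]:
    """Classify the differences in a finished-vs-reference alignment.

    Maximal runs of adjacent substituted columns become one MNS (length >= 2)
    or an SNS; gap runs become left-aligned InDels.  CDS positions count
    coding bases from the A of the start codon; the frameshift flag follows
    the mod-3 rule for InDels inside the CDS.
    """
    qg, sg = alignment.query, alignment.subject
    if sg.replace("-", "") != gene.sequence:
        raise ValidationError("alignment subject row is not the reference gene sequence")
    region, cds_index = _region_maps(gene)
    ref_seq = gene.sequence

    events: list[tuple[str, int, str, str]] = []  # kind, ref0, ref, alt
    run_kind = None
    run_ref0 = 0
    run_ref: list[str] = []
    run_alt: list[str] = []
    rpos = 0

    def close():
        nonlocal run_kind
        if run_kind:
            events.append((run_kind, run_ref0, "".join(run_ref), "".join(run_alt)))
        run_kind = None

    for qc, sc in zip(qg, sg):
        if sc != "-" and qc != "-":
            if qc == sc:
                close()
            else:
                if run_kind != "sub":
                    close()
                    run_kind, run_ref0, run_ref, run_alt = "sub", rpos, [], []
                run_ref.append(sc)
                run_alt.append(qc)
            rpos += 1
        elif sc == "-":
            if run_kind != "ins":
                close()
                run_kind, run_ref0, run_ref, run_alt = "ins", rpos, [], []
            run_alt.append(qc)
        else:  # qc == '-'
            if run_kind != "del":
                close()
                run_kind, run_ref0, run_ref, run_alt = "del", rpos, [], []
            run_ref.append(sc)
            rpos += 1
    close()

    variants: list[Variant] = []
    for kind, ref0, ref, alt in events:
        if kind == "sub":
            pos0 = ref0
            var_class = "SNS" if len(ref) == 1 else "MNS"
            fs = False
        elif kind == "del":
            pos0 = _left_normalize_del(ref_seq, ref0, len(ref))
            ref = ref_seq[pos0 : pos0 + len(ref)]
            var_class = "InDel"
            fs = len(ref) % 3 != 0
        else:
            pos0, alt = _left_normalize_ins(ref_seq, ref0, alt)
            ref = ""
            var_class = "InDel"
            fs = len(alt) % 3 != 0
        reg = REGIONS[int(region[min(pos0, gene.length - 1)])]
        cdsp = int(cds_index[pos0]) if pos0 < gene.length else 0
        variants.append(
            Variant(
                gene_position=pos0 + 1,
                ref=ref,
                alt=alt,
                var_class=var_class,
                region=reg,
                cds_position=cdsp if (cdsp and reg == "exon-CDS") else None,
                frameshift=fs if (var_class == "InDel" and reg == "exon-CDS") else False,
            )
        )
    variants.sort(key=lambda v: v.gene_position)
    return variants


# ---------------------------------------------------------------------------
# Allele grouping and naming

_TRAILING_INT = re.compile(r"(\d+)$")


def group_alleles(
    sequences: Mapping[str, str] | Sequence[tuple[str, str]],
    scheme: str = "letter-suffix",
    registry: AlleleRegistry | None = None,
    name_prefix: str = "",
    gene_id: str | None = None,
) -> AlleleCatalog:
    """Group byte-identical sequences into frequency-ranked named alleles.

    Registry sequences keep their published names.  Novel alleles are named
    in descending frequency order (ties broken by first occurrence in the
    sample input order): letter-suffix continues a, b, c, ...; numbered-
    continuation continues after the registry's largest integer suffix.
    """
    if scheme not in ("letter-suffix", "numbered-continuation"):
        raise ValidationError(f"unknown naming scheme {scheme!r}")
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    ids = [s for s, _ in items]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample ids")
    if not items:
        raise ValidationError("no samples")

    order: dict[str, int] = {}
    counts: dict[str, int] = {}
    for idx, (_, seq) in enumerate(items):
        counts[seq] = counts.get(seq, 0) + 1
        order.setdefault(seq, idx)
    ranked = sorted(counts, key=lambda s: (-counts[s], order[s]))

    registry = registry or AlleleRegistry(gene_id=gene_id or "gene", entries=[])
    taken = {name for name, _ in registry.entries}

    if scheme == "numbered-continuation":
        start = 0
        for name, _ in registry.entries:
            m = _TRAILING_INT.search(name)
            if m:
                start = max(start, int(m.group(1)))
        counter = start + 1

        def next_name():
            nonlocal counter
            while f"{name_prefix}{counter}" in taken:
                counter += 1
            name = f"{name_prefix}{counter}"
            counter += 1
            return name

    else:
        letters = iter("abcdefghijklmnopqrstuvwxyz")

        def next_name():
            for letter in letters:
                cand = f"{name_prefix}{letter}"
                if cand not in taken:
                    return cand
            raise ValidationError("ran out of letters for allele names")

    n = len(items)
    entries = []
    for seq in ranked:
        known = registry.name_of(seq)
        name = known if known is not None else next_name()
        taken.add(name)
        entries.append(AlleleEntry(name=name, sequence=seq, count=counts[seq], frequency=counts[seq] / n))
    return AlleleCatalog(
        gene_id=gene_id or registry.gene_id,
        entries=entries,
        naming_scheme=scheme,
        n_samples=n,
    )


def round_half_up(x: float, digits: int) -> float:
    factor = 10**digits
    return np.floor(x * factor + 0.5) / factor


# ---------------------------------------------------------------------------
# CDS extraction and translation


def extract_cds(finished: str, gene: GeneModel, scoring: Scoring | None = None) -> str:
    """Lift the annotated CDS spans through a finished-vs-reference alignment.

    Insertions strictly inside a span are included; a lifted CDS that lacks
    the ATG start or terminal stop, breaks frame, or contains N raises
    :class:`CdsError` with the partial sequence attached.
    """
    if finished == gene.sequence:
        return gene.cds_sequence()
    aln = global_align(finished, gene.sequence, scoring)
    L = gene.length
    ref2q = np.full(L, -1, dtype=np.int64)
    ins_before: dict[int, str] = {}
    rpos = qpos = 0
    for qc, sc in zip(aln.query, aln.subject):
        if sc != "-" and qc != "-":
            ref2q[rpos] = qpos
            rpos += 1
            qpos += 1
        elif sc == "-":
            ins_before[rpos] = ins_before.get(rpos, "") + qc
            qpos += 1
        else:
            rpos += 1

    parts: list[str] = []
    for s, e in gene.cds_spans:
        for r in range(s, e):
            if r > s and r in ins_before:
                parts.append(ins_before[r])
            q = ref2q[r]
            if q >= 0:
                parts.append(finished[q])
    cds = "".join(parts)
    problems = []
    if "N" in cds:
        problems.append("contains N")
    if len(cds) % 3 != 0:
        problems.append(f"length {len(cds)} breaks frame")
    if not cds.startswith("ATG"):
        problems.append("does not start with ATG")
    if len(cds) >= 3 and cds[-3:] not in ("TAA", "TAG", "TGA"):
        problems.append("does not end with a stop codon")
    if problems:
        raise CdsError(f"{gene.gene_id}: lifted CDS " + "; ".join(problems), partial=cds)
    return cds


def translate(cds: str) -> str:
    """Standard-code translation of a CDS with a single trailing stop.

    Returns the protein without the stop; an internal stop appears as '*'
    in the returned protein (candidate loss of function, reported rather
    than dropped).
    """
    if len(cds) % 3 != 0:
        raise TranslationError(f"CDS length {len(cds)} not a multiple of 3")
    if not set(cds) <= set("ACGT"):
        raise TranslationError("CDS contains non-ACGT characters")
    protein = str(Seq(cds).translate())
    if not protein.endswith("*"):
        raise TranslationError("CDS does not end with a stop codon")
    return protein[:-1]


def cds_pos_to_codon(cds_position: int) -> tuple[int, int]:
    """Map a 1-based CDS position to (1-based codon/residue index, offset 0-2)."""
    if cds_position < 1:
        raise ValidationError("CDS position must be >= 1")
    return (cds_position - 1) // 3 + 1, (cds_position - 1) % 3


# ---------------------------------------------------------------------------
# Isoforms and amino-acid variants


def group_isoforms(catalog: AlleleCatalog, gene: GeneModel) -> list[ProteinIsoform]:
    """Group alleles by identical protein; name A, B, ... by summed frequency."""
    proteins: dict[str, str] = {}
    for entry in catalog.entries:
        proteins[entry.name] = translate(extract_cds(entry.sequence, gene))
    groups: dict[str, list[str]] = {}
    for entry in catalog.entries:  # catalog order = descending allele frequency
        groups.setdefault(proteins[entry.name], []).append(entry.name)
    freq = {p: sum(e.frequency for e in catalog.entries if e.name in names)
            for p, names in groups.items()}
    first = {p: min(i for i, e in enumerate(catalog.entries) if e.name in names)
             for p, names in groups.items()}
    ranked = sorted(groups, key=lambda p: (-freq[p], first[p]))
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    return [
        ProteinIsoform(
            isoform_name=letters[i],
            sequence=p,
            frequency=freq[p],
            member_alleles=tuple(groups[p]),
        )
        for i, p in enumerate(ranked)
    ]


def call_aa_variants(protein: str, reference_protein: str) -> list[AaVariant]:
    """Positional amino-acid differences against a reference protein.

    Equal-length proteins are compared residue by residue; otherwise the
    proteins are globally aligned first and substituted columns reported at
    the reference residue index.
    """
    out: list[AaVariant] = []
    if len(protein) == len(reference_protein):
        for i, (a, r) in enumerate(zip(protein, reference_protein), start=1):
            if a != r:
                out.append(AaVariant(position=i, ref_aa=r, alt_aa=a))
        return out
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1.0
    al.mismatch_score = -1.0
    al.open_gap_score = -5.0
    al.extend_gap_score = -1.0
    best = al.align(protein, reference_protein)[0]
    qg, sg = best[0], best[1]
    rpos = 0
    for qc, sc in zip(qg, sg):
        if sc != "-":
            rpos += 1
            if qc != "-" and qc != sc:
                out.append(AaVariant(position=rpos, ref_aa=sc, alt_aa=qc))
    return out


def variant_presence_matrix(
    isoforms: Sequence[ProteinIsoform], reference_protein: str
) -> pd.DataFrame:
    """'+'/'-' matrix of amino-acid variations (rows) per isoform (columns)."""
    per_iso = {iso.isoform_name: {v.label for v in call_aa_variants(iso.sequence, reference_protein)}
               for iso in isoforms}
    labels: list[str] = []
    seen = set()
    all_variants = []
    for iso in isoforms:
        for v in call_aa_variants(iso.sequence, reference_protein):
            if v.label not in seen:
                seen.add(v.label)
                all_variants.append(v)
    all_variants.sort(key=lambda v: v.position)
    labels = [v.label for v in all_variants]
    data = {
        iso.isoform_name: ["+" if lab in per_iso[iso.isoform_name] else "-" for lab in labels]
        for iso in isoforms
    }
    return pd.DataFrame(data, index=labels)
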