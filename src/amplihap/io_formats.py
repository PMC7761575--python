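"""Readers and writers for the formats the pipeline touches.

FASTA/FASTQ input, BED-like gene annotations, allele registries (TSV),
Newick trees and plain TSV tables.  Coordinates on disk are 0-based
half-open (BED convention); human-facing variant labels elsewhere in the
package are 1-based.

Only A, C, G, T and N are accepted in nucleotide input; other IUPAC
ambiguity codes are rejected because the downstream pileup logic is defined
over the plain alphabet.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._seq import is_valid_alphabet

STOP_CODONS = {"TAA", "TAG", "TGA"}


class FormatError(ValueError):
    """Malformed input file; message names the offending line."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


@dataclass(frozen=True)
class FastaRecord:
    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValidationError("FASTA record with empty id")
        if not self.sequence:
            raise ValidationError(f"FASTA record {self.id!r} has empty sequence")
        if not is_valid_alphabet(self.sequence):
            raise ValidationError(
                f"FASTA record {self.id!r} contains characters outside A/C/G/T/N"
            )


@dataclass(frozen=True)
class FastqRecord:
    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self):
        if len(self.qualities) != len(self.sequence):
            raise ValidationError(
                f"FASTQ record {self.id!r}: {len(self.sequence)} bases but "
                f"{len(self.qualities)} quality values"
            )
        if self.qualities and not (0 <= min(self.qualities) <= max(self.qualities) <= 93):
            raise ValidationError(f"FASTQ record {self.id!r}: Phred values outside [0, 93]")


@dataclass(frozen=True)
class GeneModel:
    """A reference gene: genomic sequence plus promoter/exon/CDS spans.

    Spans are 0-based half-open intervals on ``sequence``; the sequence is
    stored in gene orientation (forward strand), promoter through 3'-UTR.
    """

    gene_id: str
    sequence: str
    promoter_span: tuple[int, int]
    exon_spans: tuple[tuple[int, int], ...]
    cds_spans: tuple[tuple[int, int], ...]

    def __post_init__(self):
        n = len(self.sequence)
        if not is_valid_alphabet(self.sequence, allow_n=False):
            raise ValidationError(f"{self.gene_id}: reference sequence must be A/C/G/T only")
        for name, spans in (("exon", self.exon_spans), ("CDS", self.cds_spans)):
            prev_end = -1
            for s, e in spans:
                if not (0 <= s < e <= n):
                    raise ValidationError(f"{self.gene_id}: {name} span ({s},{e}) out of bounds")
                if s < prev_end:
                    raise ValidationError(f"{self.gene_id}: {name} spans overlap or are unsorted")
                prev_end = e
        s, e = self.promoter_span
        if not (0 <= s <= e <= n):
            raise ValidationError(f"{self.gene_id}: promoter span out of bounds")
        for cs, ce in self.cds_spans:
            if not any(es <= cs and ce <= ee for es, ee in self.exon_spans):
                raise ValidationError(f"{self.gene_id}: CDS span ({cs},{ce}) not inside an exon")
        cds = self.cds_sequence()
        if len(cds) % 3 != 0:
            raise ValidationError(f"{self.gene_id}: CDS length {len(cds)} not a multiple of 3")
        if not cds.startswith("ATG"):
            raise ValidationError(f"{self.gene_id}: CDS does not begin with ATG")
        if cds[-3:] not in STOP_CODONS:
            raise ValidationError(f"{self.gene_id}: CDS does not end with a stop codon")

    def cds_sequence(self) -> str:
        return "".join(self.sequence[s:e] for s, e in self.cds_spans)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AlleleRegistry:
    """Previously named alleles of one gene (name -> full sequence)."""

    gene_id: str
    entries: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        names = [n for n, _ in self.entries]
        seqs = [s for _, s in self.entries]
        if len(set(names)) != len(names):
            raise ValidationError(f"{self.gene_id}: duplicate allele names in registry")
        if len(set(seqs)) != len(seqs):
            raise ValidationError(f"{self.gene_id}: duplicate allele sequences in registry")

    def name_of(self, sequence: str) -> str | None:
        for name, seq in self.entries:
            if seq == sequence:
                return name
        return None


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> list[FastaRecord]:
    records: list[FastaRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(line_no):
        if header is None:
            return
        seq = "".join(chunks).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"{path}: record at line {header_line} has no sequence")
        if any(c.isspace() for c in seq):
            raise FormatError(f"{path}: whitespace inside sequence near line {line_no}")
        fid, _, desc = header.partition(" ")
        try:
            records.append(FastaRecord(id=fid, sequence=seq, description=desc))
        except ValidationError as exc:
            raise FormatError(f"{path}: line {header_line}: {exc}") from exc

    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush(i)
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}: empty FASTA header at line {i}")
                header_line = i
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"{path}: sequence before any header at line {i}")
                chunks.append(line.strip())
        flush(i if records or header else 0)
    return records


def read_fastq(path) -> list[FastqRecord]:
    records: list[FastqRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if len(lines) % 4 != 0:
        raise FormatError(f"{path}: truncated FASTQ (line count not a multiple of 4)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        line_no = i + 1
        if not head.startswith("@"):
            raise FormatError(f"{path}: line {line_no}: expected '@' header")
        if not plus.startswith("+"):
            raise FormatError(f"{path}: line {line_no + 2}: expected '+' separator")
        if len(seq) != len(qual):
            raise FormatError(
                f"{path}: line {line_no}: sequence and quality lengths differ "
                f"({len(seq)} vs {len(qual)})"
            )
        quals = tuple(ord(c) - 33 for c in qual)
        try:
            records.append(FastqRecord(id=head[1:].split()[0], sequence=seq.upper(), qualities=quals))
        except ValidationError as exc:
            raise FormatError(f"{path}: line {line_no}: {exc}") from exc
    return records


def write_fasta(records: Iterable[FastaRecord], path, wrap: int = 60):
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[i : i + wrap] + "\n")
    return path


def write_fastq(records: Iterable[FastqRecord], path):
    with open(path, "w") as fh:
        for rec in records:
            qual = "".join(chr(q + 33) for q in rec.qualities)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
    return path


# ---------------------------------------------------------------------------
# Gene models and registries


def read_gene_model(fasta_path, annotation_path) -> GeneModel:
    """Load a gene reference (FASTA) plus its BED-like annotation TSV.

    The annotation has columns gene_id, feature in {promoter, exon, CDS},
    start, end with 0-based half-open coordinates.
    """
    recs = read_fasta(fasta_path)
    if len(recs) != 1:
        raise FormatError(f"{fasta_path}: expected exactly one reference record")
    rec = recs[0]
    promoter = None
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    with open(annotation_path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{annotation_path}: line {i}: expected 4 tab-separated fields")
            gene_id, feature, start, end = parts
            if gene_id != rec.id:
                raise FormatError(
                    f"{annotation_path}: line {i}: gene id {gene_id!r} does not match {rec.id!r}"
                )
            try:
                span = (int(start), int(end))
            except ValueError as exc:
                raise FormatError(f"{annotation_path}: line {i}: non-integer coordinate") from exc
            if feature == "promoter":
                promoter = span
            elif feature == "exon":
                exons.append(span)
            elif feature == "CDS":
                cds.append(span)
            else:
                raise FormatError(f"{annotation_path}: line {i}: unknown feature {feature!r}")
    if promoter is None:
        raise FormatError(f"{annotation_path}: no promoter span")
    return GeneModel(
        gene_id=rec.id,
        sequence=rec.sequence,
        promoter_span=promoter,
        exon_spans=tuple(sorted(exons)),
        cds_spans=tuple(sorted(cds)),
    )


def write_gene_model(model: GeneModel, fasta_path, annotation_path):
    write_fasta([FastaRecord(id=model.gene_id, sequence=model.sequence)], fasta_path)
    rows = [[model.gene_id, "promoter", *model.promoter_span]]
    rows += [[model.gene_id, "exon", s, e] for s, e in model.exon_spans]
    rows += [[model.gene_id, "CDS", s, e] for s, e in model.cds_spans]
    with open(annotation_path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return fasta_path, annotation_path


def read_allele_registry(path, gene_id: str | None = None) -> AlleleRegistry:
    """Registry TSV: columns allele_name, sequence (header optional)."""
    entries: list[tuple[str, str]] = []
    gid = gene_id
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "allele_name":
                continue
            if len(parts) < 2:
                raise FormatError(f"{path}: line {i}: expected allele_name<TAB>sequence")
            entries.append((parts[0], parts[1].upper()))
    return AlleleRegistry(gene_id=gid or Path(path).stem, entries=entries)


def write_allele_registry(registry: AlleleRegistry, path):
    with open(path, "w") as fh:
        fh.write("allele_name\tsequence\n")
        for name, seq in registry.entries:
            fh.write(f"{name}\t{seq}\n")
    return path


# ---------------------------------------------------------------------------
# Tables and trees


def write_table(rows: Sequence[Sequence], path):
    """Write rows (header first) as a UTF-8 TSV; rows must have equal arity."""
    rows = [list(r) for r in rows]
    if rows:
        arity = len(rows[0])
        for i, row in enumerate(rows):
            if len(row) != arity:
                raise ValidationError(f"ragged row {i}: {len(row)} fields, expected {arity}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerows(rows)
    return path


def read_table(path) -> list[list[str]]:
    with open(path, encoding="utf-8", newline="") as fh:
        return [row for row in csv.reader(fh, delimiter="\t")]


def _newick_node(node) -> str:
    children = getattr(node, "children", None) or []
    length = getattr(node, "length", None)
    suffix = "" if length is None else f":{length:.9g}"
    if not children:
        name = getattr(node, "name", None)
        if not name:
            raise ValidationError("unnamed leaf cannot be serialized to Newick")
        return f"{_escape_label(name)}{suffix}"
    inner = ",".join(_newick_node(c) for c in children)
    support = getattr(node, "support", None)
    label = "" if support is None else str(int(round(support)))
    return f"({inner}){label}{suffix}"


def _escape_label(name: str) -> str:
    if any(c in name for c in " ():;,'[]"):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree, path):
    """Serialize a tree (root node or object with .root) to a Newick file.

    Branch lengths become ``:length`` suffixes; integer bootstrap supports
    are written as internal node labels.
    """
    root = getattr(tree, "root", tree)
    with open(path, "w") as fh:
        fh.write(newick_string(root) + "\n")
    return path


def newick_string(root) -> str:
    children = getattr(root, "children", None) or []
    inner = ",".join(_newick_node(c) for c in children)
    if not children:
        return _newick_node(root) + ";"
    return f"({inner});"
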