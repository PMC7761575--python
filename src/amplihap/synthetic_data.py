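"""Synthetic study generator.

Emulates the data-generating process of a diploid selfing-grass amplicon
resequencing survey: three gibberellin-pathway genes (a DELLA growth
repressor *Rht-D1*, the gibberellin receptor gene *Gid1-D* and the F-box
gene *Gid2-D*), each sequenced as overlapping 1.1-2.0 kb amplicons covering
promoter plus coding sequence, in 24 accessions with two plants per
accession.  Accessions are fully homozygous (self-pollination), so both
plants of an accession carry the same haplotype of every gene.

The preset panels carry 7 / 13 / 8 haplotypes for the three genes with
population frequencies in units of 1/24, four RHT protein isoforms and two
isoforms each for GID1 and GID2, and a non-random joint distribution of
isoform combinations (certain combinations never occur).  Reads are
paired-end with i.i.d. substitution errors; indel sequencing errors are not
modelled (substitution-dominated short-read error profile).
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import BASES
from .io_formats import (
    AlleleRegistry,
    FastqRecord,
    GeneModel,
    ValidationError,
)

VAR_CLASSES = ("SNS", "MNS", "INS", "DEL")


@dataclass(frozen=True)
class VariantSpec:
    """One difference from the reference gene, 1-based coordinates.

    For SNS/MNS/DEL the variant replaces ``ref`` starting at ``position``;
    for INS, ``alt`` is inserted immediately before ``position``.
    """

    position: int
    ref: str
    alt: str
    var_class: str

    def __post_init__(self):
        if self.var_class not in VAR_CLASSES:
            raise ValidationError(f"unknown variant class {self.var_class!r}")
        r, a = len(self.ref), len(self.alt)
        ok = {
            "SNS": r == a == 1 and self.ref != self.alt,
            "MNS": r == a and r > 1,
            "INS": r == 0 and a > 0,
            "DEL": r > 0 and a == 0,
        }[self.var_class]
        if not ok:
            raise ValidationError(
                f"{self.var_class} with ref={self.ref!r} alt={self.alt!r} is inconsistent"
            )
        if self.position < 1:
            raise ValidationError("variant position must be 1-based and positive")

    @property
    def end(self) -> int:
        """One past the last 1-based reference position consumed."""
        return self.position + len(self.ref)


@dataclass(frozen=True)
class HaplotypeSpec:
    name: str
    variants: tuple[VariantSpec, ...]
    target_frequency: float


@dataclass
class ReadSimConfig:
    """Paired-end amplicon read simulator settings.

    The defaults are the study conditions: 250 bp reads, ~500 bp fragments,
    50x coverage per amplicon, 1% substitution error with a matching mean
    Phred of 20 (the quality model is calibrated to the injected error
    rate), no indel errors.
    """

    read_length: int = 250
    fragment_mean: float = 500.0
    fragment_sd: float = 50.0
    coverage: float = 50.0
    error_rate: float = 0.01
    qual_mean: float = 20.0
    qual_sd: float = 3.0
    amplicons: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.fragment_mean < self.read_length:
            raise ValidationError("fragment_mean must be >= read_length")
        if self.coverage <= 0:
            raise ValidationError("coverage must be positive")


@dataclass
class PopulationSpec:
    """Population layout plus the joint distribution of isoform combinations.

    ``joint_isoform_weights`` maps tuples of isoform names (one per gene, in
    ``genes`` order) to non-negative weights; combinations with zero weight
    are never sampled.  When absent, genes are sampled independently from
    the panels' target frequencies.
    """

    n_accessions: int
    panels: Mapping[str, tuple[HaplotypeSpec, ...]]
    isoform_of: Mapping[str, Mapping[str, str]]
    plants_per_accession: int = 2
    joint_isoform_weights: Mapping[tuple[str, ...], float] | None = None
    height_means: Mapping[str, float] = field(default_factory=dict)
    height_sd: float = 10.0
    height_gene: str | None = None
    seed: int = 0

    @property
    def genes(self) -> list[str]:
        return list(self.panels)


# ---------------------------------------------------------------------------
# Haplotype construction


def _check_sorted_nonoverlapping(variants: Sequence[VariantSpec]):
    prev_end = 0
    for v in variants:
        if v.position < prev_end or (v.var_class != "INS" and v.position == prev_end):
            raise ValidationError(
                f"variants overlap or are unsorted near position {v.position}"
            )
        prev_end = max(prev_end, v.end if v.var_class != "INS" else v.position)


def apply_variants(gene, variants: Sequence[VariantSpec]) -> str:
    """Apply sorted, non-overlapping variants to a gene (or raw sequence).

    Edits are applied right-to-left so earlier coordinates stay valid.  The
    result length is ``len(reference) + sum(len(alt) - len(ref))``.
    """
    seq = gene.sequence if isinstance(gene, GeneModel) else str(gene)
    variants = sorted(variants, key=lambda v: (v.position, v.var_class != "INS"))
    _check_sorted_nonoverlapping(variants)
    out = seq
    for v in reversed(variants):
        i = v.position - 1
        if v.ref and out[i : i + len(v.ref)] != v.ref:
            raise ValidationError(
                f"reference mismatch at position {v.position}: expected {v.ref!r}, "
                f"found {out[i : i + len(v.ref)]!r}"
            )
        out = out[:i] + v.alt + out[i + len(v.ref) :]
    return out


def lift_spans(
    spans: Iterable[tuple[int, int]], variants: Sequence[VariantSpec]
) -> list[tuple[int, int]]:
    """Lift 0-based half-open reference spans through a variant set."""
    variants = sorted(variants, key=lambda v: v.position)

    def lift(x: int) -> int:
        shift = 0
        for v in variants:
            start0 = v.position - 1
            if v.var_class == "INS":
                if start0 <= x:
                    shift += len(v.alt)
            else:
                end0 = start0 + len(v.ref)
                if end0 <= x:
                    shift += len(v.alt) - len(v.ref)
                elif start0 < x < end0:
                    return start0 + min(len(v.alt), x - start0) + shift
        return x + shift

    return [(lift(s), lift(e)) for s, e in spans]


# ---------------------------------------------------------------------------
# Population sampling


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of `total` proportional to `fractions` (sum ~1)."""
    quota = fractions * total
    counts = np.floor(quota).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def sample_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw homozygous multi-gene genotypes for every accession.

    Quota allocation: the number of accessions per isoform combination (and
    per allele within an isoform) follows the weights by largest-remainder
    rounding, and the seed permutes which accession receives which genotype.
    Both plants of an accession share the genotype.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng([spec.seed, 0])
    genes = spec.genes
    n = spec.n_accessions
    accessions = [f"acc{i + 1:02d}" for i in range(n)]

    if spec.joint_isoform_weights is not None:
        combos = sorted(spec.joint_isoform_weights)
        weights = np.array([spec.joint_isoform_weights[c] for c in combos], dtype=float)
        if (weights < 0).any():
            raise ValidationError("joint isoform weights must be non-negative")
        if weights.sum() <= 0:
            raise ValidationError("joint isoform weights sum to zero")
        counts = _largest_remainder(weights / weights.sum(), n)
        combo_list: list[tuple[str, ...]] = []
        for combo, c in zip(combos, counts):
            combo_list += [combo] * int(c)
        combo_list = [combo_list[i] for i in rng.permutation(n)]
        iso_by_acc = {g: [combo_list[a][gi] for a in range(n)] for gi, g in enumerate(genes)}
    else:
        iso_by_acc = {}
        for g in genes:
            haps = spec.panels[g]
            freqs = np.array([h.target_frequency for h in haps])
            counts = _largest_remainder(freqs / freqs.sum(), n)
            haplist: list[str] = []
            for h, c in zip(haps, counts):
                haplist += [h.name] * int(c)
            haplist = [haplist[i] for i in rng.permutation(n)]
            iso_by_acc[g] = [spec.isoform_of[g][h] for h in haplist]
            iso_by_acc[f"_hap_{g}"] = haplist  # reuse the draw below

    hap_by_acc: dict[str, list[str]] = {}
    for g in genes:
        if f"_hap_{g}" in iso_by_acc:
            hap_by_acc[g] = iso_by_acc.pop(f"_hap_{g}")
            continue
        haps = spec.panels[g]
        assignment: list[str | None] = [None] * n
        isoforms = iso_by_acc[g]
        for iso in sorted(set(isoforms)):
            members = [h for h in haps if spec.isoform_of[g][h.name] == iso]
            idx = [a for a in range(n) if isoforms[a] == iso]
            freqs = np.array([h.target_frequency for h in members])
            counts = _largest_remainder(freqs / freqs.sum(), len(idx))
            pool: list[str] = []
            for h, c in zip(members, counts):
                pool += [h.name] * int(c)
            pool = [pool[i] for i in rng.permutation(len(pool))]
            for a, hname in zip(idx, pool):
                assignment[a] = hname
        hap_by_acc[g] = assignment  # type: ignore[assignment]

    rows = []
    for a, acc in enumerate(accessions):
        for plant in range(1, spec.plants_per_accession + 1):
            for g in genes:
                hap = hap_by_acc[g][a]
                rows.append(
                    {
                        "accession": acc,
                        "plant": f"{acc}_p{plant}",
                        "gene": g,
                        "haplotype": hap,
                        "isoform": spec.isoform_of[g][hap],
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Read simulation

_CODE = {b: i for i, b in enumerate(BASES)}


def simulate_reads(
    haplotype: str,
    config: ReadSimConfig,
    rng: np.random.Generator | None = None,
    id_prefix: str = "read",
) -> tuple[list[FastqRecord], list[FastqRecord]]:
    """Simulate paired-end reads from each amplicon of one haplotype.

    Amplicon spans are 0-based half-open coordinates on the *haplotype*
    (lift reference spans through the variant set with :func:`lift_spans`).
    Fragment start positions extend past the amplicon ends and are clipped,
    so terminal bases are covered as they are in sheared PCR products; the
    expected pair count per amplicon is coverage * length / (2 * read_length).
    Mate 2 is the reverse complement of the fragment end.  Substitution
    errors are injected i.i.d. at ``error_rate``; no indel errors.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rl = config.read_length
    reads1: list[FastqRecord] = []
    reads2: list[FastqRecord] = []
    for ai, (s, e) in enumerate(config.amplicons, start=1):
        amp = haplotype[s:e]
        L = len(amp)
        if L < rl:
            raise ValidationError(
                f"amplicon {ai} length {L} is shorter than the read length {rl}"
            )
        n_pairs = max(1, int(round(config.coverage * L / (2 * rl))))
        codes = np.array([_CODE[b] for b in amp], dtype=np.int8)
        flen = np.clip(
            np.rint(rng.normal(config.fragment_mean, config.fragment_sd, n_pairs)),
            rl,
            None,
        ).astype(int)
        lo = -(flen - rl)
        hi = L - rl  # inclusive
        start = np.floor(rng.random(n_pairs) * (hi - lo + 1)).astype(int) + lo
        w1 = np.maximum(start, 0)
        w2 = np.minimum(start + flen, L)
        ar = np.arange(rl)
        m1 = codes[w1[:, None] + ar]
        m2 = codes[(w2 - rl)[:, None] + ar]
        m2 = 3 - m2[:, ::-1]  # reverse complement
        for m in (m1, m2):
            err = rng.random(m.shape) < config.error_rate
            shift = rng.integers(1, 4, size=m.shape)
            m[err] = (m[err] + shift[err]) % 4
        q1 = np.clip(np.rint(rng.normal(config.qual_mean, config.qual_sd, m1.shape)), 2, 41).astype(int)
        q2 = np.clip(np.rint(rng.normal(config.qual_mean, config.qual_sd, m2.shape)), 2, 41).astype(int)
        base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
        for j in range(n_pairs):
            rid = f"{id_prefix}:amp{ai}:{j}"
            s1 = base_arr[m1[j]].tobytes().decode()
            s2 = base_arr[m2[j]].tobytes().decode()
            reads1.append(FastqRecord(id=rid + "/1", sequence=s1, qualities=tuple(q1[j])))
            reads2.append(FastqRecord(id=rid + "/2", sequence=s2, qualities=tuple(q2[j])))
    return reads1, reads2


def simulate_heights(
    genotypes: pd.DataFrame,
    spec: PopulationSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-accession plant heights: isoform mean plus Gaussian noise (cm)."""
    if rng is None:
        rng = np.random.default_rng([spec.seed, 1])
    gene = spec.height_gene or spec.genes[0]
    sub = genotypes[genotypes["gene"] == gene].drop_duplicates("accession")
    rows = []
    for _, rec in sub.iterrows():
        iso = rec["isoform"]
        if iso not in spec.height_means:
            raise ValidationError(f"no height mean defined for isoform {iso!r}")
        h = spec.height_means[iso] + rng.normal(0.0, spec.height_sd)
        rows.append({"accession": rec["accession"], "isoform": iso, "height_cm": h})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# The preset study


@dataclass
class StudyPreset:
    gene_models: dict[str, GeneModel]
    panels: dict[str, tuple[HaplotypeSpec, ...]]
    isoform_of: dict[str, dict[str, str]]
    population: PopulationSpec
    registries: dict[str, AlleleRegistry]
    naming: dict[str, tuple[str, str]]  # gene -> (scheme, name prefix)
    amplicons: dict[str, tuple[tuple[int, int], ...]]
    outgroups: dict[str, tuple[str, str]]  # gene -> (outgroup name, sequence)
    read_config: ReadSimConfig

    def haplotype_sequence(self, gene: str, name: str) -> str:
        for h in self.panels[gene]:
            if h.name == name:
                return apply_variants(self.gene_models[gene], h.variants)
        raise KeyError(name)

    def haplotype_sequences(self, gene: str) -> dict[str, str]:
        return {h.name: apply_variants(self.gene_models[gene], h.variants) for h in self.panels[gene]}


_NONSTOP = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [_NONSTOP[i] for i in rng.integers(0, len(_NONSTOP), n)]


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return [BASES[i] for i in rng.integers(0, 4, n)]


def _sns(seq: list[str], pos1: int, alt: str) -> VariantSpec:
    ref = seq[pos1 - 1]
    assert ref != alt, f"SNS at {pos1} would be silent ({ref})"
    return VariantSpec(position=pos1, ref=ref, alt=alt, var_class="SNS")


def _build_rht(rng: np.random.Generator):
    promoter = _random_seq(rng, 600)
    utr5 = _random_seq(rng, 40)
    codons = ["ATG"] + _random_codons(rng, 622) + ["TAA"]
    utr3 = _random_seq(rng, 188)
    # Codons that carry the coding polymorphisms (1-based residue index).
    codons[99] = "CTT"   # synonymous site, CDS pos 300
    codons[161] = "ACC"  # Thr162; the 2-nt MNS turns it into Val
    codons[333] = "GGC"  # Gly334; G->A at CDS pos 1000 gives Ser (GRAS domain)
    codons[399] = "GCA"  # synonymous site, CDS pos 1200
    codons[621] = "GGC"  # Gly622; G->C at CDS pos 1865 gives Ala
    forced = {
        100: "G", 150: "C", 200: "A", 250: "G", 300: "C",
        350: "T", 400: "T", 450: "A", 500: "G", 550: "C",
        # contexts that pin the promoter indels in place (no shift ambiguity)
        209: "A", 210: "G", 213: "C", 214: "T",
        519: "A", 520: "G",
    }
    for i, b in forced.items():
        promoter[i] = b
    seq = "".join(promoter) + "".join(utr5) + "".join(codons) + "".join(utr3)
    model = GeneModel(
        gene_id="Rht-D1",
        sequence=seq,
        promoter_span=(0, 600),
        exon_spans=((600, 2700),),
        cds_spans=((640, 2512),),
    )
    s = seq

    def cds(p):  # 1-based CDS position -> 1-based gene position
        return 640 + p

    g334s = _sns(list(s), cds(1000), "A")
    g622a = _sns(list(s), cds(1865), "C")
    t162v = VariantSpec(position=cds(484), ref=s[cds(484) - 1 : cds(484) + 1], alt="GT", var_class="MNS")
    syn1 = _sns(list(s), cds(300), "C")
    syn2 = _sns(list(s), cds(1200), "G")
    p = {i: _sns(list(s), i, a) for i, a in
         [(101, "T"), (151, "G"), (201, "C"), (251, "C"), (301, "T"),
          (351, "G"), (401, "A"), (451, "T"), (501, "A"), (551, "A")]}
    del4 = VariantSpec(position=211, ref=s[210:214], alt="", var_class="DEL")
    ins3 = VariantSpec(position=521, ref="", alt="TGC", var_class="INS")

    def hap(name, count, variants):
        return HaplotypeSpec(
            name=name,
            variants=tuple(sorted(variants, key=lambda v: v.position)),
            target_frequency=count / 24,
        )

    panel = (
        hap("Rht-D1a_7", 10, [p[301], p[401], t162v, syn2, g622a]),
        hap("Rht-D1a_5", 8, [p[101], syn1, g334s]),
        hap("Rht-D1a_8", 2, [p[201], g334s]),
        hap("Rht-D1a_9", 1, [del4, g334s]),
        hap("Rht-D1a_10", 1, [p[151]]),
        hap("Rht-D1a_11", 1, [p[501], t162v, g622a]),
        hap("Rht-D1a_12", 1, [ins3, t162v]),
    )
    isoform_of = {
        "Rht-D1a_7": "B", "Rht-D1a_5": "A", "Rht-D1a_8": "A", "Rht-D1a_9": "A",
        "Rht-D1a_10": "C", "Rht-D1a_11": "B", "Rht-D1a_12": "D",
    }
    registry_defs = {
        "Rht-D1a_1": [p[251]],
        "Rht-D1a_2": [p[351]],
        "Rht-D1a_3": [p[451]],
        "Rht-D1a_4": [p[551]],
        "Rht-D1a_5": [p[101], syn1, g334s],
        "Rht-D1a_6": [p[451], p[551]],
        "Rht-D1a_7": [p[301], p[401], t162v, syn2, g622a],
    }
    registry = AlleleRegistry(
        gene_id="Rht-D1",
        entries=[(n, apply_variants(model, sorted(v, key=lambda x: x.position)))
                 for n, v in registry_defs.items()],
    )
    amplicons = ((0, 1150), (1000, 2700))
    return model, panel, isoform_of, registry, ("numbered-continuation", "Rht-D1a_"), amplicons


def _build_gid1(rng: np.random.Generator):
    promoter = _random_seq(rng, 700)
    utr5 = _random_seq(rng, 60)          # 700..760
    codons = ["ATG"] + _random_codons(rng, 344) + ["TGA"]
    intron = _random_seq(rng, 200)       # 1200..1400
    utr3 = _random_seq(rng, 402)         # 1998..2400
    codons[49] = "GTT"    # synonymous site, CDS pos 150
    codons[199] = "ACA"   # synonymous site, CDS pos 600
    codons[249] = "CCG"   # synonymous site, CDS pos 750
    codons[308] = "GGT"   # Gly309; G->C at CDS pos 926 gives Ala
    cds_full = "".join(codons)
    forced = {80: "A", 160: "C", 240: "G", 320: "T", 410: "A",
              480: "C", 560: "G", 640: "T",
              349: "A", 350: "C",          # pins the 19-bp promoter insertion
              609: "G", 610: "A", 611: "C", 612: "T"}  # pins the 2-bp deletion
    for i, b in forced.items():
        promoter[i] = b
    seq = ("".join(promoter) + "".join(utr5) + cds_full[:440] + "".join(intron)
           + cds_full[440:] + "".join(utr3))
    seq = seq[:2200] + "C" + seq[2201:]  # UTR SNS site context
    model = GeneModel(
        gene_id="Gid1-D",
        sequence=seq,
        promoter_span=(0, 700),
        exon_spans=((700, 1200), (1400, 2400)),
        cds_spans=((760, 1200), (1400, 1998)),
    )
    s = model.sequence

    def cds(p):  # 1-based CDS position -> 1-based gene position
        return 760 + p if p <= 440 else 960 + p

    g926c = _sns(list(s), cds(926), "C")
    s1 = _sns(list(s), cds(150), "G")
    s2 = _sns(list(s), cds(600), "T")
    s3 = _sns(list(s), cds(750), "A")
    q = {i: _sns(list(s), i, a) for i, a in
         [(81, "G"), (161, "T"), (241, "A"), (321, "C"),
          (411, "C"), (481, "A"), (561, "T"), (641, "A")]}
    u1 = _sns(list(s), 2201, "G")
    ins19 = VariantSpec(position=351, ref="", alt="ACGTTGCAAGGTTACGGAT", var_class="INS")
    del2 = VariantSpec(position=611, ref=s[610:612], alt="", var_class="DEL")

    def hap(name, count, variants):
        return HaplotypeSpec(
            name=name,
            variants=tuple(sorted(variants, key=lambda v: v.position)),
            target_frequency=count / 24,
        )

    panel = (
        hap("Gid1-D1a", 6, [q[81]]),
        hap("Gid1-D1b", 3, [q[161], g926c]),
        hap("Gid1-D1c", 3, [q[241], s1]),
        hap("Gid1-D1d", 2, []),
        hap("Gid1-D1e", 2, [ins19, g926c]),
        hap("Gid1-D1f", 1, [q[321], s2]),
        hap("Gid1-D1g", 1, [q[411]]),
        hap("Gid1-D1h", 1, [del2]),
        hap("Gid1-D1i", 1, [q[481], s3, u1]),
        hap("Gid1-D1j", 1, [q[561]]),
        hap("Gid1-D1k", 1, [q[641]]),
        hap("Gid1-D1l", 1, [q[161], q[411], g926c]),
        hap("Gid1-D1m", 1, [q[81], q[321]]),
    )
    isoform_of = {h.name: ("B" if any(v.position == cds(926) for v in h.variants) else "A")
                  for h in panel}
    registry = AlleleRegistry(gene_id="Gid1-D", entries=[])
    amplicons = ((0, 1150), (700, 1900), (1300, 2400))
    return model, panel, isoform_of, registry, ("letter-suffix", "Gid1-D1"), amplicons


def _build_gid2(rng: np.random.Generator):
    promoter = _random_seq(rng, 700)
    utr5 = _random_seq(rng, 100)         # 700..800
    codons = ["ATG"] + _random_codons(rng, 211) + ["TAA"]
    codons[29] = "GGA"    # synonymous site, CDS pos 90
    codons[156] = "GAA"   # Glu157; A->G at CDS pos 470 gives Gly
    codons[157] = "CGA"   # Arg158; G->A at CDS pos 473 gives Gln
    cds_full = "".join(codons)
    intron = _random_seq(rng, 250)       # 1000..1250
    utr3 = _random_seq(rng, 405)         # 1689..2094
    forced = {85: "G", 170: "A", 255: "C", 340: "T", 425: "G",
              499: "A", 500: "G", 501: "C",          # pins the 1-bp deletion
              599: "G", 600: "A"}                     # pins the 3-bp insertion
    for i, b in forced.items():
        promoter[i] = b
    intron[99] = "A"   # context around the 18-bp intron deletion (gene 1100)
    intron[100] = "G"
    intron[117] = "C"
    intron[118] = "T"
    seq = ("".join(promoter) + "".join(utr5) + cds_full[:200] + "".join(intron)
           + cds_full[200:] + "".join(utr3))
    model = GeneModel(
        gene_id="Gid2-D",
        sequence=seq,
        promoter_span=(0, 700),
        exon_spans=((700, 1000), (1250, 2094)),
        cds_spans=((800, 1000), (1250, 1689)),
    )
    s = model.sequence

    def cds(p):
        return 800 + p if p <= 200 else 1050 + p

    t1 = _sns(list(s), cds(90), "C")
    e157g = _sns(list(s), cds(470), "G")
    r158q = _sns(list(s), cds(473), "A")
    r = {i: _sns(list(s), i, a) for i, a in
         [(86, "A"), (171, "T"), (256, "G"), (341, "C"), (426, "C")]}
    del18 = VariantSpec(position=1101, ref=s[1100:1118], alt="", var_class="DEL")
    del1 = VariantSpec(position=501, ref=s[500], alt="", var_class="DEL")
    ins3 = VariantSpec(position=601, ref="", alt="CAT", var_class="INS")

    def hap(name, count, variants):
        return HaplotypeSpec(
            name=name,
            variants=tuple(sorted(variants, key=lambda v: v.position)),
            target_frequency=count / 24,
        )

    panel = (
        hap("Gid2-D1a", 8, [r[86]]),
        hap("Gid2-D1b", 4, [r[171], e157g, r158q]),
        hap("Gid2-D1c", 3, [r[256]]),
        hap("Gid2-D1d", 3, [r[341], t1]),
        hap("Gid2-D1e", 3, [del18]),
        hap("Gid2-D1f", 1, [r[426]]),
        hap("Gid2-D1g", 1, [del1]),
        hap("Gid2-D1h", 1, [ins3]),
    )
    isoform_of = {h.name: ("B" if h.name == "Gid2-D1b" else "A") for h in panel}
    registry = AlleleRegistry(gene_id="Gid2-D", entries=[])
    amplicons = ((0, 1100), (850, 2094))
    return model, panel, isoform_of, registry, ("letter-suffix", "Gid2-D1"), amplicons


def _outgroup(rng: np.random.Generator, model: GeneModel, name: str, divergence: float = 0.03) -> str:
    """A diverged homeolog (substitutions only) used to root the allele trees."""
    seq = list(model.sequence)
    n_mut = int(round(divergence * len(seq)))
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    for i in positions:
        choices = [b for b in BASES if b != seq[i]]
        seq[i] = choices[rng.integers(0, 3)]
    return "".join(seq)


# Accession-level joint counts of (RHT, GID1, GID2) isoform combinations.
# Doubling to 48 plants reproduces the study's contingency-table structure:
# the GID1/RHT block (10,22,2,2 / 12,0,0,0) and GID2/RHT block
# (14,22,2,2 / 8,0,0,0) exactly; combinations absent there have zero weight.
_JOINT_COMBO_COUNTS = {
    ("A", "A", "A"): 3,
    ("A", "A", "B"): 2,
    ("A", "B", "A"): 4,
    ("A", "B", "B"): 2,
    ("B", "A", "A"): 11,
    ("C", "A", "A"): 1,
    ("D", "A", "A"): 1,
}


def preset_study(seed: int = 0) -> StudyPreset:
    """Gene models, haplotype panels and population spec of the emulated study.

    Three genes with 7/13/8 haplotypes, panel frequencies in units of 1/24,
    four RHT isoforms and two isoforms each for GID1/GID2, and joint isoform
    weights with structural zeros.  The gene sequences themselves are fixed
    (internal constant seeds); ``seed`` only drives population sampling.
    """
    gene_models: dict[str, GeneModel] = {}
    panels: dict[str, tuple[HaplotypeSpec, ...]] = {}
    isoform_of: dict[str, dict[str, str]] = {}
    registries: dict[str, AlleleRegistry] = {}
    naming: dict[str, tuple[str, str]] = {}
    amplicons: dict[str, tuple[tuple[int, int], ...]] = {}
    outgroups: dict[str, tuple[str, str]] = {}
    builders = [
        (_build_rht, 101, "Rht-B1-like"),
        (_build_gid1, 102, "Gid1-B-like"),
        (_build_gid2, 103, "Gid2-B-like"),
    ]
    for build, const_seed, og_name in builders:
        rng = np.random.default_rng(const_seed)
        model, panel, iso, registry, nm, amps = build(rng)
        g = model.gene_id
        gene_models[g] = model
        panels[g] = panel
        isoform_of[g] = iso
        registries[g] = registry
        naming[g] = nm
        amplicons[g] = amps
        outgroups[g] = (og_name, _outgroup(rng, model, og_name))
        total = sum(h.target_frequency for h in panel)
        assert abs(total - 1.0) < 1e-9, f"{g}: panel frequencies sum to {total}"
        seqs = [apply_variants(model, h.variants) for h in panel]
        assert len(set(seqs)) == len(seqs), f"{g}: duplicate haplotype sequences"

    weights = {k: v / 24 for k, v in _JOINT_COMBO_COUNTS.items()}
    population = PopulationSpec(
        n_accessions=24,
        plants_per_accession=2,
        panels=panels,
        isoform_of=isoform_of,
        joint_isoform_weights=weights,
        height_means={"A": 100.0, "B": 100.0, "C": 100.0, "D": 100.0},
        height_sd=10.0,
        height_gene="Rht-D1",
        seed=seed,
    )
    return StudyPreset(
        gene_models=gene_models,
        panels=panels,
        isoform_of=isoform_of,
        population=population,
        registries=registries,
        naming=naming,
        amplicons=amplicons,
        outgroups=outgroups,
        read_config=ReadSimConfig(),
    )


def plant_read_seed(base_seed: int, plant: str, gene: str) -> list:
    """A named substream for one (plant, gene) read simulation."""
    tag = zlib.crc32(f"{plant}|{gene}".encode()) % (2**31)
    return [base_seed, 2, tag]
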