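"""Study orchestration: reads -> finished sequences -> alleles/isoforms ->
co-occurrence statistics -> trees, with a one-command synthetic demo.

All randomness flows from one global seed through named substreams
(population sampling, heights, per-plant read simulation, bootstrap), so a
run is reproducible end to end.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference_tables
from .allele_typing import (
    AlleleCatalog,
    enumerate_variants,
    global_align,
    group_alleles,
    group_isoforms,
    round_half_up,
    translate,
    variant_presence_matrix,
)
from .consensus import LayoutConfig, PolishConfig, reconstruct
from .cooccurrence import (
    anova_one_way,
    build_contingency,
    fisher_exact_2x2,
    fisher_exact_rxc,
    isoform_marginals,
    round_p,
)
from .io_formats import (
    AlleleRegistry,
    FastaRecord,
    FormatError,
    GeneModel,
    ValidationError,
    read_fastq,
    write_fasta,
    write_fastq,
    write_gene_model,
    write_newick,
    write_table,
)
from .phylogeny import bootstrap_supports, build_alignment, root_with_outgroup
from .synthetic_data import (
    ReadSimConfig,
    StudyPreset,
    apply_variants,
    lift_spans,
    plant_read_seed,
    preset_study,
    sample_population,
    simulate_heights,
    simulate_reads,
)

log = logging.getLogger("amplihap")


@dataclass
class RunConfig:
    """Everything one study run needs.

    ``sample_sheet`` maps plant id -> gene -> either a pair of FASTQ paths
    or an in-memory list of FastqRecord.  ``accession_of`` maps plant id to
    its accession (both plants of an accession are independent samples of
    the same selfed genotype).
    """

    gene_models: dict[str, GeneModel]
    sample_sheet: dict[str, dict[str, object]]
    accession_of: dict[str, str]
    registries: dict[str, AlleleRegistry] = field(default_factory=dict)
    naming: dict[str, tuple[str, str]] = field(default_factory=dict)
    outgroups: dict[str, tuple[str, str]] = field(default_factory=dict)
    polish: PolishConfig = field(default_factory=PolishConfig)
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    bootstrap_replicates: int = 100
    build_trees: bool = True
    heights: pd.DataFrame | None = None
    out_dir: Path = Path("amplihap_run")
    seed: int = 0


@dataclass
class RunResult:
    out_dir: Path
    finished: dict[str, dict[str, str]]            # gene -> plant -> sequence
    catalogs: dict[str, AlleleCatalog]             # per-plant denominators
    accession_catalogs: dict[str, AlleleCatalog]   # per-accession denominators
    isoforms: dict[str, list]
    genotypes: pd.DataFrame
    contingency: dict[str, dict]
    anova: dict[str, dict]
    trees: dict[str, object]
    failures: list[tuple[str, str, str]]
    manifest_path: Path | None = None


def _load_reads(entry) -> list:
    if isinstance(entry, (tuple, list)) and len(entry) == 2 and all(
        isinstance(p, (str, Path)) for p in entry
    ):
        return read_fastq(entry[0]) + read_fastq(entry[1])
    return list(entry)


def run_study(config: RunConfig) -> RunResult:
    """Execute the full analysis; per-sample failures are logged and
    skipped, and the run fails only if every sample fails."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    finished: dict[str, dict[str, str]] = {g: {} for g in config.gene_models}
    failures: list[tuple[str, str, str]] = []
    n_ok = 0
    for plant, genes in sorted(config.sample_sheet.items()):
        for gene, entry in sorted(genes.items()):
            model = config.gene_models[gene]
            try:
                reads = _load_reads(entry)
                res = reconstruct(reads, model, config.polish, config.layout)
                finished[gene][plant] = res.sequence
                n_ok += 1
            except (FormatError, ValidationError, RuntimeError, OSError) as exc:
                log.warning("sample %s gene %s failed: %s", plant, gene, exc)
                failures.append((plant, gene, str(exc)))
    if n_ok == 0:
        raise RuntimeError("every sample failed reconstruction")

    for gene, plants in finished.items():
        write_fasta(
            [FastaRecord(id=p, sequence=s) for p, s in sorted(plants.items())],
            out / f"finished_{gene}.fasta",
        )

    catalogs: dict[str, AlleleCatalog] = {}
    accession_catalogs: dict[str, AlleleCatalog] = {}
    isoforms: dict[str, list] = {}
    genotype_rows = []
    for gene, model in config.gene_models.items():
        plants = finished[gene]
        if not plants:
            continue
        scheme, prefix = config.naming.get(gene, ("letter-suffix", f"{gene}_"))
        registry = config.registries.get(gene)
        catalog = group_alleles(plants, scheme=scheme, registry=registry,
                                name_prefix=prefix, gene_id=gene)
        catalogs[gene] = catalog
        by_acc: dict[str, str] = {}
        for plant, seq in plants.items():
            by_acc.setdefault(config.accession_of.get(plant, plant), seq)
        accession_catalogs[gene] = group_alleles(
            by_acc, scheme=scheme, registry=registry, name_prefix=prefix, gene_id=gene
        )
        isos = group_isoforms(catalog, model)
        isoforms[gene] = isos
        iso_of_allele = {a: iso.isoform_name for iso in isos for a in iso.member_alleles}
        allele_of_seq = {e.sequence: e.name for e in catalog.entries}
        for plant, seq in plants.items():
            allele = allele_of_seq[seq]
            genotype_rows.append(
                {
                    "plant": plant,
                    "accession": config.accession_of.get(plant, plant),
                    "gene": gene,
                    "allele": allele,
                    "isoform": iso_of_allele[allele],
                }
            )

        # Table-shaped outputs
        acc_freq = {e.sequence: e.frequency for e in accession_catalogs[gene].entries}
        rows = [["allele", "count_plants", "freq_plants", "freq_accessions", "protein_isoform"]]
        for e in catalog.entries:
            rows.append([
                e.name,
                e.count,
                f"{round_half_up(e.frequency, 2):.2f}",
                f"{round_half_up(acc_freq.get(e.sequence, float('nan')), 2):.2f}",
                iso_of_allele[e.name],
            ])
        write_table(rows, out / f"alleles_{gene}.tsv")
        rows = [["isoform", "frequency", "member_alleles"]]
        for iso in isos:
            rows.append([iso.isoform_name, f"{round_half_up(iso.frequency, 2):.2f}",
                         ",".join(iso.member_alleles)])
        write_table(rows, out / f"isoforms_{gene}.tsv")

        ref_protein = translate(model.cds_sequence())
        matrix = variant_presence_matrix(isos, ref_protein)
        matrix.to_csv(out / f"aa_variants_{gene}.tsv", sep="\t", index_label="variation")

        vrows = [["allele", "POS", "REF", "ALT", "CLASS", "REGION", "CDS_POS", "FRAMESHIFT"]]
        for e in catalog.entries:
            if e.sequence == model.sequence:
                continue
            for v in enumerate_variants(global_align(e.sequence, model.sequence), model):
                vrows.append([e.name, v.gene_position, v.ref or ".", v.alt or ".",
                              v.var_class, v.region, v.cds_position or ".", v.frameshift])
        write_table(vrows, out / f"variants_{gene}.tsv")

    genotypes = pd.DataFrame(genotype_rows)
    genotypes.to_csv(out / "genotypes.tsv", sep="\t", index=False)

    contingency = _cooccurrence_block(genotypes, config, out)
    anova = _anova_block(genotypes, config, out)
    trees = _tree_block(catalogs, config, out) if config.build_trees else {}

    manifest_path = _write_manifest(config, out, t_start)
    return RunResult(
        out_dir=out,
        finished=finished,
        catalogs=catalogs,
        accession_catalogs=accession_catalogs,
        isoforms=isoforms,
        genotypes=genotypes,
        contingency=contingency,
        anova=anova,
        trees=trees,
        failures=failures,
        manifest_path=manifest_path,
    )


def _cooccurrence_block(genotypes: pd.DataFrame, config: RunConfig, out: Path) -> dict:
    genes = [g for g in config.gene_models if g in set(genotypes.get("gene", []))]
    results: dict[str, dict] = {}
    if len(genes) < 2:
        return results
    rows = [["pair", "restriction", "p_value", "p_rounded", "table"]]
    pairs = []
    if len(genes) >= 2:
        primary = genes[0]  # by convention the growth-repressor gene is first
        for other in genes[1:]:
            pairs.append((other, primary, ["A", "B"]))
        if len(genes) >= 3:
            pairs.append((genes[2], genes[1], None))
    for gx, gy, restrict_y in pairs:
        table = build_contingency(genotypes, gx, gy, restrict_y=restrict_y)
        counts = table.counts
        if counts.shape == (2, 2):
            res = fisher_exact_2x2(counts)
        else:
            res = fisher_exact_rxc(counts)
        marg = isoform_marginals(table)
        key = f"{gx}_by_{gy}"
        results[key] = {
            "table": table,
            "p": res.p_two_sided,
            "p_rounded": round_p(res.p_two_sided),
            "marginals": marg,
        }
        rows.append([key, ",".join(restrict_y) if restrict_y else "none",
                     f"{res.p_two_sided:.6g}", f"{round_p(res.p_two_sided):.4f}",
                     json.dumps(table.full.to_numpy().tolist())])
    write_table(rows, out / "cooccurrence.tsv")
    return results


def _anova_block(genotypes: pd.DataFrame, config: RunConfig, out: Path) -> dict:
    results: dict[str, dict] = {}
    if config.heights is None or genotypes.empty:
        return results
    heights = config.heights.set_index("accession")["height_cm"]
    rows = [["gene", "F", "df_between", "df_within", "p", "group_means"]]
    for gene in config.gene_models:
        sub = genotypes[genotypes["gene"] == gene].drop_duplicates("accession")
        groups: dict[str, list[float]] = {}
        for _, rec in sub.iterrows():
            if rec["accession"] in heights.index:
                groups.setdefault(rec["isoform"], []).append(float(heights[rec["accession"]]))
        try:
            res = anova_one_way(groups)
        except ValidationError as exc:
            log.warning("ANOVA for %s skipped: %s", gene, exc)
            continue
        results[gene] = {"F": res.f_statistic, "p": res.p_value, "means": res.group_means}
        rows.append([gene, f"{res.f_statistic:.4f}", res.df_between, res.df_within,
                     f"{res.p_value:.4g}", json.dumps(res.group_means)])
    write_table(rows, out / "anova_height.tsv")
    return results


def _tree_block(catalogs: dict[str, AlleleCatalog], config: RunConfig, out: Path) -> dict:
    trees: dict[str, object] = {}
    rows = [["gene", "n_taxa", "log_likelihood", "kappa"]]
    for gene, catalog in catalogs.items():
        seqs = {e.name: e.sequence for e in catalog.entries}
        if gene in config.outgroups:
            og_name, og_seq = config.outgroups[gene]
            seqs[og_name] = og_seq
        else:
            og_name = None
        if len(seqs) < 3:
            log.warning("tree for %s skipped: fewer than 3 taxa", gene)
            continue
        aln = build_alignment(seqs)
        tree = bootstrap_supports(
            aln,
            n_replicates=config.bootstrap_replicates,
            seed=int(np.random.default_rng([config.seed, 3]).integers(2**31)),
        )
        if og_name is not None:
            try:
                tree = root_with_outgroup(tree, [og_name])
            except ValidationError as exc:
                log.warning("rooting for %s failed: %s", gene, exc)
        trees[gene] = tree
        write_newick(tree, out / f"tree_{gene}.nwk")
        params = getattr(tree, "params", None)
        rows.append([gene, len(seqs),
                     f"{getattr(tree, 'log_likelihood', float('nan')) or float('nan'):.4f}"
                     if getattr(tree, "log_likelihood", None) is not None else ".",
                     f"{params.kappa:.3f}" if params else "."])
    write_table(rows, out / "trees.tsv")
    return trees


def _write_manifest(config: RunConfig, out: Path, t_start: float) -> Path:
    files = {}
    for p in sorted(out.glob("*")):
        if p.name == "manifest.json" or p.is_dir():
            continue
        files[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "seed": config.seed,
        "genes": sorted(config.gene_models),
        "n_samples": len(config.sample_sheet),
        "polish": dataclasses.asdict(config.polish),
        "layout": dataclasses.asdict(config.layout),
        "bootstrap_replicates": config.bootstrap_replicates,
        "files": files,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# Synthetic demo


def simulate_study_inputs(
    preset: StudyPreset,
    seed: int,
    read_config: ReadSimConfig | None = None,
    out_dir: Path | None = None,
    write_reads: bool = False,
):
    """Sample the population and simulate reads (optionally to FASTQ files).

    Returns (genotypes, heights, sample_sheet, accession_of); sample_sheet
    holds in-memory reads unless ``write_reads``.
    """
    population = dataclasses.replace(preset.population, seed=seed)
    genotypes = sample_population(population)
    heights = simulate_heights(genotypes, population)
    read_config = read_config or preset.read_config
    sample_sheet: dict[str, dict[str, object]] = {}
    accession_of: dict[str, str] = {}
    if write_reads and out_dir is not None:
        reads_dir = Path(out_dir) / "reads"
        reads_dir.mkdir(parents=True, exist_ok=True)
    for (plant, accession), sub in genotypes.groupby(["plant", "accession"], sort=True):
        accession_of[plant] = accession
        sample_sheet[plant] = {}
        for _, rec in sub.iterrows():
            gene = rec["gene"]
            hap = next(h for h in preset.panels[gene] if h.name == rec["haplotype"])
            hseq = apply_variants(preset.gene_models[gene], hap.variants)
            amps = lift_spans(preset.amplicons[gene], hap.variants)
            cfg = dataclasses.replace(read_config, amplicons=tuple(amps))
            rng = np.random.default_rng(plant_read_seed(seed, plant, gene))
            r1, r2 = simulate_reads(hseq, cfg, rng=rng, id_prefix=f"{plant}:{gene}")
            if write_reads and out_dir is not None:
                p1 = reads_dir / f"{plant}_{gene}_R1.fastq"
                p2 = reads_dir / f"{plant}_{gene}_R2.fastq"
                write_fastq(r1, p1)
                write_fastq(r2, p2)
                sample_sheet[plant][gene] = (p1, p2)
            else:
                sample_sheet[plant][gene] = r1 + r2
    return genotypes, heights, sample_sheet, accession_of


def demo(
    seed: int = 0,
    out_dir: Path | str = "amplihap_demo",
    bootstrap_replicates: int = 100,
    build_trees: bool = True,
    write_reads: bool = True,
    read_config: ReadSimConfig | None = None,
) -> RunResult:
    """Generate the preset study and run the full pipeline on it."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    preset = preset_study(seed=seed)
    for gene, model in preset.gene_models.items():
        write_gene_model(model, out / f"ref_{gene}.fasta", out / f"ref_{gene}.bed")
    genotypes, heights, sample_sheet, accession_of = simulate_study_inputs(
        preset, seed=seed, read_config=read_config, out_dir=out, write_reads=write_reads
    )
    genotypes.to_csv(out / "truth_genotypes.tsv", sep="\t", index=False)
    heights.to_csv(out / "heights.tsv", sep="\t", index=False)
    config = RunConfig(
        gene_models=preset.gene_models,
        sample_sheet=sample_sheet,
        accession_of=accession_of,
        registries=preset.registries,
        naming=preset.naming,
        outgroups=preset.outgroups,
        bootstrap_replicates=bootstrap_replicates,
        build_trees=build_trees,
        heights=heights,
        out_dir=out,
        seed=seed,
    )
    return run_study(config)


# ---------------------------------------------------------------------------
# Verification against the published summary tables


def verify_targets(run_dir: Path | str) -> pd.DataFrame:
    """Recompute the published-table checks and report pass/fail.

    Checks are computed from the packaged printed contingency tables (not
    from the run), plus presence checks for the expected run outputs.
    """
    from .allele_typing import cds_pos_to_codon

    run_dir = Path(run_dir)
    rows = []

    def add(name, computed, expected, ok):
        rows.append({"check": name, "computed": computed, "expected": expected,
                     "status": "pass" if ok else "FAIL"})

    p1 = round_p(fisher_exact_2x2(reference_tables.RESTRICTED_GID1_BY_RHT).p_two_sided)
    add("fisher_gid1_by_rht", p1, reference_tables.PUBLISHED_P["gid1_by_rht"],
        p1 == reference_tables.PUBLISHED_P["gid1_by_rht"])
    p2 = round_p(fisher_exact_2x2(reference_tables.RESTRICTED_GID2_BY_RHT).p_two_sided)
    add("fisher_gid2_by_rht", p2, reference_tables.PUBLISHED_P["gid2_by_rht"],
        p2 == reference_tables.PUBLISHED_P["gid2_by_rht"])
    p3 = round_p(fisher_exact_2x2(reference_tables.GID2_BY_GID1).p_two_sided)
    add("fisher_gid2_by_gid1", p3, reference_tables.PUBLISHED_P["gid2_by_gid1"],
        p3 == reference_tables.PUBLISHED_P["gid2_by_gid1"])

    m = isoform_marginals(reference_tables.GID1_BY_RHT)
    add("marginal_gid1_B", float(m["row_rounded"]["B"]), 0.25,
        float(m["row_rounded"]["B"]) == 0.25)
    add("marginal_rht_A", float(m["col_rounded"]["A"]), 0.46,
        float(m["col_rounded"]["A"]) == 0.46)
    m2 = isoform_marginals(reference_tables.GID2_BY_RHT)
    add("marginal_gid2_B", float(m2["row_rounded"]["B"]), 0.17,
        float(m2["row_rounded"]["B"]) == 0.17)

    add("codon_of_cds_1000", cds_pos_to_codon(1000)[0], 334, cds_pos_to_codon(1000)[0] == 334)
    add("codon_of_cds_926", cds_pos_to_codon(926)[0], 309, cds_pos_to_codon(926)[0] == 309)

    for fname in ("genotypes.tsv", "cooccurrence.tsv", "manifest.json"):
        present = (run_dir / fname).exists()
        add(f"output_{fname}", "present" if present else "missing", "present", present)

    df = pd.DataFrame(rows)
    df.to_csv(run_dir / "verify.tsv", sep="\t", index=False)
    return df
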