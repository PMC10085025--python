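"""End-to-end orchestration: simulate -> filter -> scan -> annotate -> report.

A :class:`RunConfig` collects every stage parameter with defaults matching
the study design the simulator emulates (25 founders from 5 ancestral
populations, 7 intercross rounds, 181 sampled strains replicated across 3
mitotypes, 500-colony petite assays, ~25k markers). The run is
deterministic given the master seed: each stage draws from an independent
child stream derived from it.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import assoc, mito_features, pheno, popgen_sim, snp_table

__all__ = ["RunConfig", "run_end_to_end", "cli"]

log = logging.getLogger("mitonuclear")


@dataclass
class RunConfig:
    """All stage parameters for a reproducible end-to-end run."""

    seed: int = 1
    # --- genetic map / founders ---
    n_chromosomes: int = 16
    markers_per_chromosome: int = 1560
    chromosome_length_bp: int = 750_000
    cm_per_kb: float = 0.4
    n_founders: int = 25
    n_populations: int = 5
    F: float = 0.2
    # --- intercross / collection ---
    rounds: int = 7
    progeny_per_round: int = 10_000
    sample_size: int = 181
    mitotypes: list[str] = field(default_factory=lambda: ["RC1", "RC2", "RC3"])
    # --- phenotype architecture (planted) ---
    baseline_pct: float = 5.0
    beta_main: float = 1.0
    n_interaction: int = 3
    delta: float = 1.5
    target_maf: float = 0.3
    mito_effects: dict = field(default_factory=dict)
    overdispersion: float = 1.0
    colonies_per_assay: int = 500
    replicates: int = 1
    # --- SNP filtering ---
    telomere_mask_bp: int = 20_000
    maf_threshold: float = 0.05
    merge_adjacent: bool = True
    # --- association scan ---
    n_pcs: int = 10
    family: str = "gaussian"
    response: str = "petite_pct"  # or "petite_logit" (empirical logit)
    condition_on_main: bool = False
    main_fdr: float = 0.001
    interaction_fdr: float = 0.05
    qtl_merge_window_bp: int = 25_000
    # --- optional real inputs (paths); simulated when absent ---
    genotypes_path: str | None = None
    phenotype_path: str | None = None
    gff_path: str | None = None
    mtdna_fasta_path: str | None = None
    motif_library_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"invalid config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers = [h for h in log.handlers if not isinstance(h, logging.FileHandler)]
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler(sys.stderr))


def simulate_collection(config: RunConfig):
    """Simulate the recombinant collection, planted architecture and counts.

    Returns ``(rc, arch, planted_info, counts)`` where ``rc`` is the
    mitotype-replicated collection.
    """
    gmap = popgen_sim.GeneticMap.yeast_like(
        n_chromosomes=config.n_chromosomes,
        markers_per_chromosome=config.markers_per_chromosome,
        chromosome_length_bp=config.chromosome_length_bp,
        cm_per_kb=config.cm_per_kb,
    )
    panel = popgen_sim.simulate_founders(
        n_founders=config.n_founders,
        n_populations=config.n_populations,
        gmap=gmap,
        F=config.F,
        seed=popgen_sim.stage_rng(config.seed, "founders"),
    )
    rc1 = popgen_sim.advanced_intercross(
        panel,
        rounds=config.rounds,
        progeny_per_round=config.progeny_per_round,
        sample_size=config.sample_size,
        seed=popgen_sim.stage_rng(config.seed, "intercross"),
    )
    rc = popgen_sim.replicate_with_mitotypes(rc1, config.mitotypes)
    arch, planted = popgen_sim.plant_architecture(
        rc,
        baseline_pct=config.baseline_pct,
        beta_main=config.beta_main,
        n_interaction=config.n_interaction,
        delta=config.delta,
        target_maf=config.target_maf,
        mito_effects=config.mito_effects,
        seed=popgen_sim.stage_rng(config.seed, "architecture"),
    )
    arch.overdispersion = config.overdispersion
    design = popgen_sim.AssayDesign(
        colonies_per_assay=config.colonies_per_assay, replicates=config.replicates
    )
    counts = popgen_sim.simulate_petite_counts(
        rc, arch, design, seed=popgen_sim.stage_rng(config.seed, "counts")
    )
    return rc, arch, planted, counts


def scan_collection(
    config: RunConfig,
    table: snp_table.SNPTable,
    counts: pd.DataFrame,
    strain_meta: pd.DataFrame | None = None,
    condition_on: list[int] | None = None,
) -> pd.DataFrame:
    """Run the mitonuclear scan on a filtered table + colony counts.

    Computes strain means, PCA covariates, runs the nested-model scan,
    and attaches Storey q-values (``q_main``, ``q_int``) and the
    allele-frequency-weighted effect size ``delta``. ``strain_meta``
    optionally supplies per-strain covariate columns (mating type,
    auxotrophy flags) keyed by ``strain_id``.
    """
    means = pheno.strain_petite_means(counts)
    scores, _ = assoc.genotype_pca(table, k=config.n_pcs)
    phenotype = means.merge(scores.reset_index(), on="strain_id", how="left")
    meta_cols: list[str] = []
    if strain_meta is not None:
        meta = strain_meta.drop_duplicates("strain_id")
        meta_cols = [c for c in meta.columns if c not in {"strain_id", "mitotype"}]
        phenotype = phenotype.merge(meta[["strain_id"] + meta_cols], on="strain_id", how="left")
    pc_cols = [f"PC{j + 1}" for j in range(config.n_pcs)]
    spec = assoc.ModelSpec(
        response=config.response,
        covariates=pc_cols + meta_cols,
        conditioning_snps=list(condition_on or []),
        family=config.family,
    )
    result = assoc.scan_mitonuclear(phenotype, table, spec)
    for col, src in (("q_main", "p_main"), ("q_int", "p_int")):
        adj = assoc.adjust_pvalues(result[src].to_numpy(), method="storey")
        result[col] = adj.adjusted
    strain_means = means.groupby("strain_id")["petite_pct"].mean()
    result["delta"] = assoc.effect_sizes(table, strain_means)
    return result


def run_end_to_end(config: RunConfig, outdir: str | Path) -> dict:
    """Simulate (or load), filter, scan, annotate and report.

    Writes every stage table as TSV plus a plain-text report and a log to
    ``outdir``, and returns the in-memory objects keyed by stage name.
    Deterministic given ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    config.to_yaml(outdir / "config.yaml")
    log.info("run started (seed=%d)", config.seed)
    out: dict = {"config": config}

    planted = None
    strain_meta = None
    if config.genotypes_path is not None:
        gpath = Path(config.genotypes_path)
        if not gpath.exists():
            raise FileNotFoundError(f"genotype input not found: {gpath}")
        raw = (
            snp_table.read_vcf(gpath)
            if gpath.suffix.lower() == ".vcf"
            else snp_table.read_tsv(gpath)
        )
        if config.phenotype_path is None:
            raise ValueError("phenotype_path is required with genotypes_path")
        ppath = Path(config.phenotype_path)
        if not ppath.exists():
            raise FileNotFoundError(f"phenotype input not found: {ppath}")
        counts = pd.read_csv(ppath, sep="\t")
        chrom_lengths = (
            raw.variants.groupby("chrom")["pos"].max() + config.telomere_mask_bp + 1
        ).to_dict()
        log.info("loaded %d raw variants, %d strains", raw.n_variants, raw.n_strains)
    else:
        rc, arch, planted, counts = simulate_collection(config)
        log.info(
            "simulated collection: %d rows (%d strains x %d mitotypes), %d markers",
            rc.n_rows, config.sample_size, len(config.mitotypes), rc.gmap.n_markers,
        )
        raw = snp_table.from_collection(rc)
        chrom_lengths = rc.gmap.chrom_lengths
        strain_meta = rc.strains
        planted.to_csv(outdir / "planted_loci.tsv", sep="\t", index=False)
    counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)

    table, report = snp_table.build_snp_table(
        raw,
        chromosome_lengths=chrom_lengths,
        telomere_mask_bp=config.telomere_mask_bp,
        maf_threshold=config.maf_threshold,
        merge_adjacent=config.merge_adjacent,
    )
    report.to_frame().to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    snp_table.write_tsv(table, outdir / "filtered_snps.tsv")
    for stage in report.stages:
        log.info(
            "filter %-16s %d -> %d", stage["filter"], stage["variants_in"], stage["variants_out"]
        )
    out.update(raw=raw, table=table, filter_report=report, counts=counts, planted=planted)

    condition_on = None
    result = scan_collection(config, table, counts, strain_meta=strain_meta)
    if config.condition_on_main:
        top = result.loc[result["p_main"].idxmin(), "marker"]
        condition_on = [int(top)]
        log.info("conditioning on top main-effect marker %s", condition_on)
        result = scan_collection(
            config, table, counts, strain_meta=strain_meta, condition_on=condition_on
        )
    result.to_csv(outdir / "scan_results.tsv", sep="\t", index=False)
    out["scan"] = result

    sig_main = result[result["q_main"] <= config.main_fdr].copy()
    sig_int = result[result["q_int"] <= config.interaction_fdr].copy()
    sig_main.to_csv(outdir / "significant_main.tsv", sep="\t", index=False)
    sig_int.to_csv(outdir / "significant_interaction.tsv", sep="\t", index=False)
    qtls_main = annotate_mod.collapse_qtls(
        sig_main, merge_window_bp=config.qtl_merge_window_bp, p_col="p_main"
    )
    qtls_int = annotate_mod.collapse_qtls(
        sig_int, merge_window_bp=config.qtl_merge_window_bp, p_col="p_int"
    )
    qtls_main.to_csv(outdir / "qtls_main.tsv", sep="\t", index=False)
    qtls_int.to_csv(outdir / "qtls_interaction.tsv", sep="\t", index=False)
    out.update(sig_main=sig_main, sig_int=sig_int, qtls_main=qtls_main, qtls_int=qtls_int)

    if config.gff_path is not None:
        genes = annotate_mod.read_gff3(config.gff_path)
        hits = annotate_mod.assign_snp_to_genes(
            pd.concat([sig_main, sig_int]).drop_duplicates("marker"), genes,
            strict_chroms=False,
        )
        hits.to_csv(outdir / "gene_hits.tsv", sep="\t", index=False)
        out["gene_hits"] = hits

    if config.mtdna_fasta_path is not None:
        library = (
            mito_features.read_motif_library(config.motif_library_path)
            if config.motif_library_path
            else mito_features.example_motif_library()
        )
        seqs = mito_features.read_fasta_sequences(config.mtdna_fasta_path)
        feats = mito_features.build_feature_table(seqs, library)
        feats.to_csv(outdir / "mtdna_features.tsv", sep="\t")
        out["mtdna_features"] = feats

    bonf = assoc.adjust_pvalues(
        result["p_main"].to_numpy(), method="bonferroni", alpha=0.05
    )
    with open(outdir / "report.txt", "w") as fh:
        fh.write("mitonuclear association run report\n")
        fh.write(f"seed: {config.seed}\n\n")
        fh.write("SNP filter pipeline:\n")
        fh.write(report.to_frame().to_string(index=False) + "\n")
        for note in report.notes:
            fh.write(f"note: {note}\n")
        fh.write(f"\nvariants scanned: {len(result)}\n")
        fh.write(f"Bonferroni per-test threshold (alpha=0.05): {bonf.threshold:.2g}\n")
        fh.write(
            f"main-effect SNPs at FDR {config.main_fdr:g}: {len(sig_main)}"
            f" in {len(qtls_main)} QTLs\n"
        )
        fh.write(
            f"interaction SNPs at FDR {config.interaction_fdr:g}: {len(sig_int)}"
            f" in {len(qtls_int)} QTLs\n"
        )
        if condition_on is not None:
            fh.write(f"conditioned on marker(s): {condition_on}\n")
    log.info(
        "scan done: %d main-effect and %d interaction SNPs significant",
        len(sig_main), len(sig_int),
    )
    return out


# ------------------------------------------------------ study scenarios ----


def study_config(seed: int = 1, **overrides) -> RunConfig:
    """Config for the simulation studies that validate the scan.

    Keeps the study design of the emulated collection (25 founders, 5
    ancestral populations, 7 intercross rounds, 181 strains × 3 mitotypes,
    500-colony assays) but runs on a reduced marker grid (16 × 75 markers)
    and intercross census (1,000 haploids/round) so that replicated runs
    complete quickly; the empirical-logit response matches the logit-scale
    generative architecture (see docs/methods.md).
    """
    params = dict(
        seed=seed,
        markers_per_chromosome=75,
        progeny_per_round=1_000,
        response="petite_logit",
    )
    params.update(overrides)
    return RunConfig(**params)


def _simulate_and_filter(config: RunConfig):
    rc, arch, planted, counts = simulate_collection(config)
    raw = snp_table.from_collection(rc)
    table, _ = snp_table.build_snp_table(
        raw,
        chromosome_lengths=rc.gmap.chrom_lengths,
        telomere_mask_bp=config.telomere_mask_bp,
        maf_threshold=config.maf_threshold,
        merge_adjacent=config.merge_adjacent,
    )
    return rc, planted, counts, table


def run_golden(seed: int, **overrides) -> dict:
    """One golden-scenario replicate: planted-QTL recovery bookkeeping.

    Simulates the default planted architecture (one beta=1 logit
    main-effect locus, three delta=1.5 logit interaction loci at MAF~0.3),
    scans, and reports per-locus recovery (a significant interaction SNP at
    q<0.05 within 25 kb of the planted position) plus the interaction
    q-value at the main-effect locus (which should behave like a null
    interaction test).
    """
    config = study_config(seed=seed, **overrides)
    rc, planted, counts, table = _simulate_and_filter(config)
    result = scan_collection(config, table, counts, strain_meta=rc.strains)
    sig = result[result["q_int"] <= config.interaction_fdr]
    recovered = []
    for _, row in planted[planted["role"] == "interaction"].iterrows():
        near = sig[
            (sig["chrom"] == row["chrom"])
            & ((sig["pos"] - row["pos"]).abs() <= config.qtl_merge_window_bp)
        ]
        recovered.append(bool(len(near)))
    main = planted[planted["role"] == "main"].iloc[0]
    main_row = result[(result["chrom"] == main["chrom"]) & (result["pos"] == main["pos"])]
    main_q = float(main_row["q_int"].iloc[0]) if len(main_row) else np.nan
    return {
        "scan": result,
        "planted": planted,
        "recovered": recovered,
        "n_interaction_hits": int(len(sig)),
        "main_locus_q_int": main_q,
    }


def run_null_calibration(seed: int, **overrides) -> tuple[float, int]:
    """Type-I error of the interaction test on a null collection.

    Simulates the default collection with no planted effects (binomial
    colony sampling only), scans ~1,000 SNPs with the Gaussian family on
    percent strain means, and returns the fraction of interaction p-values
    below 0.05 with the number of tests.
    """
    config = study_config(
        seed=seed,
        markers_per_chromosome=70,
        beta_main=0.0,
        n_interaction=0,
        response="petite_pct",
        **overrides,
    )
    rc, _, counts, table = _simulate_and_filter(config)
    result = scan_collection(config, table, counts, strain_meta=rc.strains)
    p = result["p_int"].dropna()
    return float((p < 0.05).mean()), int(len(p))


def run_conditioning_pair(seed: int, **overrides) -> tuple[int, int]:
    """Interaction hit counts without vs with large-effect conditioning.

    Simulates one large main-effect locus (beta = 2 logit) plus five small
    interaction loci (delta = 0.5 logit), then counts interaction hits at
    q < 0.05 in a plain scan and in a scan conditioning on the top
    main-effect marker. Mirrors the power gain expected when a large
    nuclear effect is absorbed into the covariates.
    """
    config = study_config(
        seed=seed, beta_main=2.0, n_interaction=5, delta=0.5, **overrides
    )
    rc, _, counts, table = _simulate_and_filter(config)
    res0 = scan_collection(config, table, counts, strain_meta=rc.strains)
    top = int(res0.loc[res0["p_main"].idxmin(), "marker"])
    res1 = scan_collection(
        config, table, counts, strain_meta=rc.strains, condition_on=[top]
    )
    thr = config.interaction_fdr
    return int((res0["q_int"] <= thr).sum()), int((res1["q_int"] <= thr).sum())


# ----------------------------------------------------------------- CLI ----


@click.group()
def cli() -> None:
    """Mitonuclear association mapping pipeline."""


def _load_config(config_path: str | None, seed: int | None) -> RunConfig:
    cfg = RunConfig.from_yaml(config_path) if config_path else RunConfig()
    if seed is not None:
        cfg.seed = seed
    return cfg


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", "outdir", type=click.Path(), required=True)
def simulate(config_path, seed, outdir):
    """Simulate a recombinant collection and petite colony counts."""
    cfg = _load_config(config_path, seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rc, arch, planted, counts = simulate_collection(cfg)
    raw = snp_table.from_collection(rc)
    snp_table.write_tsv(raw, outdir / "genotypes.tsv")
    snp_table.write_vcf(raw, outdir / "genotypes.vcf")
    rc.strains.to_csv(outdir / "strains.tsv", sep="\t", index=False)
    counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)
    planted.to_csv(outdir / "planted_loci.tsv", sep="\t", index=False)
    click.echo(f"wrote collection ({raw.n_strains} strains, {raw.n_variants} markers) to {outdir}")


@cli.command("filter")
@click.option("--genotypes", type=click.Path(exists=True), required=True)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", "outdir", type=click.Path(), required=True)
def filter_cmd(genotypes, config_path, outdir):
    """Filter raw calls into the biallelic association SNP table."""
    cfg = _load_config(config_path, None)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gpath = Path(genotypes)
    raw = snp_table.read_vcf(gpath) if gpath.suffix.lower() == ".vcf" else snp_table.read_tsv(gpath)
    chrom_lengths = (
        raw.variants.groupby("chrom")["pos"].max() + cfg.telomere_mask_bp + 1
    ).to_dict()
    table, report = snp_table.build_snp_table(
        raw, chromosome_lengths=chrom_lengths,
        telomere_mask_bp=cfg.telomere_mask_bp,
        maf_threshold=cfg.maf_threshold,
        merge_adjacent=cfg.merge_adjacent,
    )
    snp_table.write_tsv(table, outdir / "filtered_snps.tsv")
    report.to_frame().to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    click.echo(report.to_frame().to_string(index=False))


@cli.command()
@click.option("--genotypes", type=click.Path(exists=True), required=True)
@click.option("--phenotype", type=click.Path(exists=True), required=True,
              help="TSV of strain_id, mitotype, replicate, petite_count, total_count")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", "outdir", type=click.Path(), required=True)
def scan(genotypes, phenotype, config_path, outdir):
    """Run the mitonuclear association scan on filtered genotypes."""
    cfg = _load_config(config_path, None)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gpath = Path(genotypes)
    table = snp_table.read_vcf(gpath) if gpath.suffix.lower() == ".vcf" else snp_table.read_tsv(gpath)
    counts = pd.read_csv(phenotype, sep="\t")
    result = scan_collection(cfg, table, counts)
    result.to_csv(outdir / "scan_results.tsv", sep="\t", index=False)
    click.echo(f"scanned {len(result)} variants -> {outdir / 'scan_results.tsv'}")


@cli.command("annotate")
@click.option("--results", type=click.Path(exists=True), required=True)
@click.option("--gff", type=click.Path(exists=True), required=True)
@click.option("--upstream", type=int, default=250, show_default=True)
@click.option("--out", "outdir", type=click.Path(), required=True)
def annotate_cmd(results, gff, upstream, outdir):
    """Assign scan hits to genes (CDS or upstream window)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    snps = pd.read_csv(results, sep="\t")
    genes = annotate_mod.read_gff3(gff)
    hits = annotate_mod.assign_snp_to_genes(snps, genes, upstream_window=upstream,
                                            strict_chroms=False)
    hits.to_csv(outdir / "gene_hits.tsv", sep="\t", index=False)
    click.echo(f"{len(hits)} SNP-gene assignments -> {outdir / 'gene_hits.tsv'}")


@cli.command()
@click.option("--fasta", type=click.Path(exists=True), required=True)
@click.option("--library", "library_path", type=click.Path(exists=True), default=None)
@click.option("--out", "outdir", type=click.Path(), required=True)
def mitofeat(fasta, library_path, outdir):
    """Compute mtDNA features (GC%, GC-cluster class counts)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    library = (
        mito_features.read_motif_library(library_path)
        if library_path
        else mito_features.example_motif_library()
    )
    seqs = mito_features.read_fasta_sequences(fasta)
    feats = mito_features.build_feature_table(seqs, library)
    feats.to_csv(outdir / "mtdna_features.tsv", sep="\t")
    click.echo(feats.to_string())


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", "outdir", type=click.Path(), required=True)
def run(config_path, seed, outdir):
    """Full pipeline: simulate (or load), filter, scan, annotate, report."""
    cfg = _load_config(config_path, seed)
    try:
        run_end_to_end(cfg, outdir)
    except FileNotFoundError as exc:
        raise click.ClickException(str(exc)) from exc
    click.echo(f"report written to {Path(outdir) / 'report.txt'}")
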