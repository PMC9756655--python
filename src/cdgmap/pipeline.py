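"""One-command orchestration: ingest -> classify -> geometry -> stats ->
auxiliary/replicon analyses, with a deterministic manifest.

Genomes whose primary-chromosome ori is ambiguous are excluded from all
positional statistics (classification and replicon accounting still run);
the exclusion count is logged and recorded in the manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from . import __version__
from .auxdomains import (
    aux_count_categories,
    build_cooccurrence_network,
    length_threshold,
    network_edge_table,
    venn_partition_weighted,
    venn_table,
    write_network,
)
from .classify import classification_table, classify_genome
from .geometry import estimate_ori_gcskew, normalized_position
from .io import (
    read_domain_table,
    read_genome_annotation,
    read_ori_table,
    read_taxonomy_table,
    write_ori_table,
    write_results,
)
from .model import (
    CDG_CLASSES,
    CdgmapError,
    ClassifiedProtein,
    DependencyError,
    DomainHit,
    EnzymeClass,
    GenomeRecord,
    OriCall,
)
from .replicons import (
    classify_replicons,
    gene_location_proportions,
    genome_location_summary,
)
from .stats import (
    genus_mean_ratios,
    kde_circular,
    ks_two_sample,
    median_counts,
    per_genus_mean_counts,
    size_count_correlation,
)

logger = logging.getLogger("cdgmap")


@dataclass
class RunConfig:
    domain_table: Path
    annotation_dir: Path
    taxonomy_table: Path
    out_dir: Path
    protein_fasta: Optional[Path] = None
    ori_table: Optional[Path] = None  # None -> GC-skew estimation
    kde_bandwidth: Optional[float] = None
    ks_method: str = "asymptotic"
    secondary_cutoff: int = 800_000
    skew_window: int = 1000
    evalue_ceiling: Optional[float] = None
    motif_scope: str = "whole"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for p in (self.domain_table, self.annotation_dir, self.taxonomy_table):
            if not Path(p).exists():
                raise DependencyError(f"required input missing: {p}")
        for p in (self.protein_fasta, self.ori_table):
            if p is not None and not Path(p).exists():
                raise DependencyError(f"required input missing: {p}")


def read_protein_fasta(path) -> dict[str, str]:
    """Protein sequences keyed by id (first whitespace-delimited token)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def load_genomes(cfg: RunConfig) -> list[GenomeRecord]:
    """Assemble GenomeRecords from the annotation directory, the domain-hit
    table, the optional protein FASTA and the taxonomy table."""
    from .io import filter_hits_by_evalue

    hits = filter_hits_by_evalue(read_domain_table(cfg.domain_table), cfg.evalue_ceiling)
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    sequences = read_protein_fasta(cfg.protein_fasta) if cfg.protein_fasta else {}
    tax = read_taxonomy_table(cfg.taxonomy_table).set_index("genome_id")

    ann_dir = Path(cfg.annotation_dir)
    genomes: list[GenomeRecord] = []
    paths = sorted(
        p for p in ann_dir.iterdir()
        if p.suffix.lower() in (".gff", ".gff3", ".gb", ".gbk", ".gbff", ".genbank")
    )
    if not paths:
        raise DependencyError(f"no annotation files found in {ann_dir}")
    for path in paths:
        fasta = None
        for ext in (".fasta", ".fa", ".fna"):
            cand = path.with_suffix(ext)
            if cand.exists():
                fasta = cand
                break
        g = read_genome_annotation(path, fasta)
        for p in g.proteins:
            p.hits = by_protein.get(p.protein_id, [])
            seq = sequences.get(p.protein_id)
            if seq is not None:
                if len(seq) != p.length:
                    p.length = len(seq)
                p.sequence = seq
        if g.genome_id in tax.index:
            g.order = tax.at[g.genome_id, "order"]
            g.genus = tax.at[g.genome_id, "genus"]
            g.species_or_strain = tax.at[g.genome_id, "species_or_strain"]
        genomes.append(g)
    return genomes


def resolve_ori_calls(
    genomes: Iterable[GenomeRecord], cfg: RunConfig
) -> dict[str, OriCall]:
    """Use the curated ori table when given, otherwise the GC-skew estimator
    on every replicon with a sequence."""
    if cfg.ori_table is not None:
        return read_ori_table(cfg.ori_table)
    calls: dict[str, OriCall] = {}
    for g in genomes:
        for r in g.replicons:
            if r.sequence is None or len(r.sequence) < 10 * cfg.skew_window:
                continue
            calls[r.replicon_id] = estimate_ori_gcskew(
                r.sequence, window=cfg.skew_window, replicon_id=r.replicon_id)
    return calls


@dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    networks: dict[str, object] = field(default_factory=dict)
    positions: dict[tuple[str, str], list[float]] = field(default_factory=dict)
    genome_class_counts: dict[str, dict[EnzymeClass, int]] = field(default_factory=dict)
    n_excluded_ambiguous: int = 0
    manifest_files: dict[str, str] = field(default_factory=dict)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute every stage and write all result tables + manifest."""
    logging.basicConfig(level=cfg.log_level)
    cfg.validate()
    result = PipelineResult()

    genomes = load_genomes(cfg)
    logger.info("loaded %d genomes", len(genomes))

    # --- classification -----------------------------------------------------
    classified_by_genome: dict[str, list[ClassifiedProtein]] = {}
    for g in genomes:
        classified, counts = classify_genome(g, motif_scope=cfg.motif_scope)
        classified_by_genome[g.genome_id] = classified
        result.genome_class_counts[g.genome_id] = counts
    result.tables["classified_proteins"] = classification_table(
        (g, classified_by_genome[g.genome_id]) for g in genomes
    )

    taxonomy = pd.DataFrame(
        [{"genome_id": g.genome_id, "order": g.order, "genus": g.genus,
          "species_or_strain": g.species_or_strain} for g in genomes]
    )

    # --- geometry -----------------------------------------------------------
    ori_calls = resolve_ori_calls(genomes, cfg)
    write_ori_table(ori_calls.values(), Path(cfg.out_dir) / "ori_calls.tsv") \
        if ori_calls and _ensure_dir(cfg.out_dir) else None
    pos_rows = []
    excluded = 0
    for g in genomes:
        for cp in classified_by_genome[g.genome_id]:
            if cp.enzyme_class is EnzymeClass.NONE or cp.protein.locus is None:
                continue
            rid = cp.protein.locus.replicon_id
            call = ori_calls.get(rid)
            if call is None or call.ambiguous:
                excluded += 1
                continue
            rep = g.replicon(rid)
            np_ = normalized_position(cp.protein.locus, call.ori, rep.length_bp)
            pos_rows.append({"genome_id": g.genome_id, "order": g.order,
                             "protein_id": cp.protein.protein_id,
                             "class": cp.enzyme_class.value, "replicon_id": rid,
                             "position_pct": np_.value})
            result.positions.setdefault((g.order, cp.enzyme_class.value), []).append(
                np_.value)
    result.n_excluded_ambiguous = excluded
    if excluded:
        logger.info("excluded %d genes lacking an unambiguous ori", excluded)
    result.tables["positions"] = pd.DataFrame(
        pos_rows, columns=["genome_id", "order", "protein_id", "class",
                           "replicon_id", "position_pct"])

    # --- distribution statistics -------------------------------------------
    kde_rows, ks_rows = [], []
    for (order, cls), vals in sorted(result.positions.items()):
        if len(vals) >= 2:
            est = kde_circular(vals, bandwidth=cfg.kde_bandwidth)
            for gpt, den in zip(est.grid, est.density):
                kde_rows.append({"order": order, "class": cls,
                                 "position_pct": float(gpt), "density": float(den)})
    orders = sorted({o for o, _ in result.positions})
    for order in orders:
        classes = [c.value for c in CDG_CLASSES]
        for i, ca in enumerate(classes):
            for cb in classes[i + 1:]:
                xa = result.positions.get((order, ca), [])
                xb = result.positions.get((order, cb), [])
                if xa and xb:
                    if cfg.ks_method == "exact" and len(xa) + len(xb) <= 16:
                        ks = ks_two_sample(xa, xb, method="exact_permutation")
                    else:
                        ks = ks_two_sample(xa, xb, method="asymptotic")
                    ks_rows.append({"order": order, "class_a": ca, "class_b": cb,
                                    "d": ks.d_statistic, "p_value": ks.p_value,
                                    "n_a": ks.n_x, "n_b": ks.n_y,
                                    "method": ks.method})
    result.tables["kde_grid"] = pd.DataFrame(
        kde_rows, columns=["order", "class", "position_pct", "density"])
    result.tables["ks_tests"] = pd.DataFrame(
        ks_rows, columns=["order", "class_a", "class_b", "d", "p_value",
                          "n_a", "n_b", "method"])

    totals = {gid: sum(c.values()) for gid, c in result.genome_class_counts.items()}
    result.tables["genus_means"] = per_genus_mean_counts(totals, taxonomy)
    result.tables["ratios"] = genus_mean_ratios(result.genome_class_counts, taxonomy)

    med_rows = []
    for order in sorted({g.order for g in genomes}):
        gids = [g.genome_id for g in genomes if g.order == order]
        for cls in CDG_CLASSES:
            counts = [result.genome_class_counts[gid][cls] for gid in gids]
            med_rows.append({"order": order, "class": cls.value,
                             "median_count": median_counts(counts)})
    result.tables["median_counts"] = pd.DataFrame(
        med_rows, columns=["order", "class", "median_count"])

    # Spearman: largest replicon per genome only
    corr_rows = []
    for order in sorted({g.order for g in genomes}):
        sub = [g for g in genomes if g.order == order]
        if len(sub) >= 3:
            lengths = [max(r.length_bp for r in g.replicons) for g in sub]
            counts = [totals[g.genome_id] for g in sub]
            c = size_count_correlation(lengths, counts)
            corr_rows.append({"order": order, "rho": c.rho, "p_value": c.p_value,
                              "n": c.n, "defined": c.defined})
    result.tables["correlations"] = pd.DataFrame(
        corr_rows, columns=["order", "rho", "p_value", "n", "defined"])

    # --- auxiliary-domain analytics ----------------------------------------
    all_classified = [cp for cps in classified_by_genome.values() for cp in cps]
    primary_venn, weighted_venn = venn_partition_weighted(all_classified)
    vt = venn_table(primary_venn)
    vt["n_sequences_weighted"] = venn_table(weighted_venn)["n_domains"]
    result.tables["venn"] = vt

    cat_rows, thr_rows = [], []
    for order in sorted({g.order for g in genomes}):
        for cls in CDG_CLASSES:
            group = [cp for g in genomes if g.order == order
                     for cp in classified_by_genome[g.genome_id]
                     if cp.enzyme_class is cls]
            if group:
                cat = aux_count_categories(group)
                cat_rows.append({"order": order, "class": cls.value,
                                 "n_sequences": cat.n_sequences,
                                 "pct_none": cat.pct_none, "pct_one": cat.pct_one,
                                 "pct_more": cat.pct_more})
                try:
                    thr = length_threshold(group)
                    thr_rows.append({"order": order, "class": cls.value,
                                     "min_len_with_aux": thr.min_len_with_aux,
                                     "pct_noaux_below": thr.pct_noaux_below,
                                     "pct_noaux_at_or_above": thr.pct_noaux_at_or_above})
                except CdgmapError:
                    pass  # one side empty: threshold undefined for this panel
            net = build_cooccurrence_network(group)
            if net.number_of_nodes():
                result.networks[f"{order}__{cls.value}"] = net
    result.tables["aux_categories"] = pd.DataFrame(
        cat_rows, columns=["order", "class", "n_sequences", "pct_none",
                           "pct_one", "pct_more"])
    result.tables["length_thresholds"] = pd.DataFrame(
        thr_rows, columns=["order", "class", "min_len_with_aux",
                           "pct_noaux_below", "pct_noaux_at_or_above"])

    # --- replicon analysis --------------------------------------------------
    calls_by_genome = {g.genome_id: classify_replicons(g, cutoff=cfg.secondary_cutoff)
                       for g in genomes}
    rep_rows = [
        {"genome_id": gid, "replicon_id": c.replicon_id, "length_bp": c.length_bp,
         "class": c.replicon_class.value, "tie_flagged": c.tie_flagged}
        for gid, calls in calls_by_genome.items() for c in calls.values()
    ]
    result.tables["replicon_classes"] = pd.DataFrame(
        rep_rows, columns=["genome_id", "replicon_id", "length_bp", "class",
                           "tie_flagged"])
    summaries = [
        genome_location_summary(g, classified_by_genome[g.genome_id],
                                calls_by_genome[g.genome_id])
        for g in genomes
    ]
    per_genome, per_order = gene_location_proportions(
        summaries, taxonomy, calls_by_genome, cutoff=cfg.secondary_cutoff)
    result.tables["location_proportions"] = per_genome
    result.tables["location_proportions_by_order"] = per_order

    # --- write --------------------------------------------------------------
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    for name, net in sorted(result.networks.items()):
        write_network(net, net_dir / f"{name}.edges.tsv", net_dir / f"{name}.graphml")
    manifest_extra = {
        "package_version": __version__,
        "parameters": {
            "domain_table": str(cfg.domain_table),
            "annotation_dir": str(cfg.annotation_dir),
            "taxonomy_table": str(cfg.taxonomy_table),
            "protein_fasta": str(cfg.protein_fasta) if cfg.protein_fasta else None,
            "ori_table": str(cfg.ori_table) if cfg.ori_table else None,
            "ori_method": "table" if cfg.ori_table else "gc_skew",
            "kde_bandwidth": cfg.kde_bandwidth,
            "ks_method": cfg.ks_method,
            "secondary_cutoff": cfg.secondary_cutoff,
            "skew_window": cfg.skew_window,
            "evalue_ceiling": cfg.evalue_ceiling,
            "motif_scope": cfg.motif_scope,
            "seed": cfg.seed,
        },
        "n_genomes": len(genomes),
        "n_genes_excluded_ambiguous_ori": excluded,
    }
    result.manifest_files = write_results(result.tables, out, manifest_extra)
    return result


def _ensure_dir(path) -> bool:
    Path(path).mkdir(parents=True, exist_ok=True)
    return True
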