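"""Synthetic genomes with planted c-di-GMP gene structure.

The generator emits exactly the inputs the pipeline reads — a domain-hit
TSV, per-genome GFF3 + nucleotide FASTA, a protein FASTA, a taxonomy TSV
and an ori TSV — together with a machine-readable truth record, so every
stage of the analysis can be tested against known ground truth without any
downloads.

What is planted, per genome: per-class gene counts (Poisson), gene
positions on the ori-anchored 0-100% circle (wrapped-normal mixtures per
class), auxiliary-domain architectures (per-class alphabets, per-sequence
count distributions, optional pairwise co-occurrence boosts), the
HHExxxxxGYP motif in a configurable fraction of HD proteins, protein-length
structure for the length-threshold analysis, occasional secondary
chromosomes, and a GC-skew switch at the planted ori of every emitted
chromosome sequence so the skew estimator can recover it.

Deliberately not emulated: codon usage, real ORFs under the gene
coordinates, GC content beyond the skew switch, and phylogenetic
correlation between genomes.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    EAL_ACC,
    GGDEF_ACC,
    HD_ACC,
    ClassifiedProtein,
    DomainHit,
    EnzymeClass,
    GeneLocus,
    GenerationError,
    GenomeRecord,
    ProteinRecord,
    Replicon,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"

# catalytic-domain hit lengths (aa) used when laying out architectures
_CDG_HIT_LEN = {"GGDEF": 120, "EAL": 150, "HD": 130}
_AUX_HIT_LEN = 40
_HIT_PAD = 5

#: minimum spacing between planted genes (bp)
GENE_SPACING_BP = 50

_CLASS_NAMES = ("GGDEF", "EAL", "GGDEF_EAL", "HD-GYP")


@dataclass
class PositionMixture:
    """Mixture of wrapped normals on the 0-100% circle."""

    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.means) == len(self.sds) == len(self.weights)):
            raise GenerationError("mixture components must align")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise GenerationError("mixture weights must sum to 1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=np.asarray(self.weights))
        mu = np.asarray(self.means)[comp]
        sd = np.asarray(self.sds)[comp]
        return (rng.normal(mu, sd)) % 100.0


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    n_orders: int = 1
    n_genera_per_order: int = 5
    n_genomes_per_genus: int = 4
    replicon_length_bp: int = 4_000_000
    # per-class Poisson means for gene counts per genome; GGDEF and hybrid
    # genes dominate, EAL at half the GGDEF level, HD-GYP the smallest share
    class_count_means: dict[str, float] = field(
        default_factory=lambda: {"GGDEF": 3.0, "EAL": 1.5, "GGDEF_EAL": 3.0, "HD-GYP": 0.5}
    )
    # per-class positional model on the ori-anchored circle
    position_models: dict[str, PositionMixture] = field(
        default_factory=lambda: {
            "GGDEF": PositionMixture((25.0, 50.0, 75.0), (5.0, 5.0, 5.0),
                                     (1 / 3, 1 / 3, 1 / 3)),
            "EAL": PositionMixture((5.0,), (6.0,), (1.0,)),
            "GGDEF_EAL": PositionMixture((3.0,), (7.0,), (1.0,)),
            "HD-GYP": PositionMixture((50.0,), (30.0,), (1.0,)),
        }
    )
    # per-class auxiliary-domain alphabet (uniform weights unless boosted)
    aux_alphabets: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "GGDEF": ("REC", "PAS", "PAS_3", "PAS_4", "GAF", "HAMP",
                      "dCache_1", "CHASE3", "PHY", "HisKA"),
            "EAL": ("REC", "CSS-motif", "GAF_2", "HisKA", "Hpt", "HAMP", "HATPase_c"),
            "GGDEF_EAL": ("PAS_3", "PAS_4", "PAS_7", "PAS_9", "MHYT", "REC", "GAF"),
            "HD-GYP": ("HD_5", "DUF3369", "DUF3391", "REC"),
        }
    )
    # per-class P(no aux), P(one aux), P(>1 aux)
    aux_count_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "GGDEF": (0.40, 0.35, 0.25),
            "EAL": (0.55, 0.30, 0.15),
            "GGDEF_EAL": (0.30, 0.35, 0.35),
            "HD-GYP": (0.25, 0.45, 0.30),
        }
    )
    # multiplicative weight boost for a partner domain given the first pick
    cooccurrence_boosts: dict[tuple[str, str], float] = field(default_factory=dict)
    #: fraction of single-HD proteins that carry the HHExxxxxGYP motif
    motif_rate: float = 0.8
    secondary_chromosome_prob: float = 0.15
    secondary_length_bp: int = 1_200_000
    #: probability a c-di-GMP gene sits on the secondary chromosome when present
    secondary_gene_fraction: float = 0.3
    #: minimum protein length (aa) of aux-bearing sequences, per class
    aux_min_length: dict[str, int] = field(
        default_factory=lambda: {"GGDEF": 275, "EAL": 375, "GGDEF_EAL": 450, "HD-GYP": 350}
    )
    #: fraction of aux-free sequences drawn shorter than the class threshold
    short_noaux_fraction: float = 0.49
    #: mean count of aux-only decoy proteins (class NONE) per genome
    decoy_none_mean: float = 2.0
    emit_sequences: bool = True
    #: G/C probabilities on the G-rich (ori->ter) half; swapped on the other
    skew_gc: tuple[float, float] = (0.35, 0.15)
    seed: int = 0

    def validate(self) -> None:
        for cls in _CLASS_NAMES:
            for m in (self.class_count_means, self.position_models,
                      self.aux_alphabets, self.aux_count_probs, self.aux_min_length):
                if cls not in m:
                    raise GenerationError(f"config missing class {cls!r}")
        for probs in self.aux_count_probs.values():
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise GenerationError("aux count probabilities must be a distribution")
        if not (0.0 <= self.motif_rate <= 1.0):
            raise GenerationError("motif_rate must be in [0, 1]")


def default_paper_profile(seed: int = 0) -> SyntheticConfig:
    """The qualitative Rhodobacterales-like pattern: EAL and hybrid genes
    concentrated near ori, GGDEF genes tri-modal with modes mid-way between
    ori and ter (25%, 75%) and at ter (50%), and a 2:1 GGDEF:EAL mean-count
    ratio. These are the package defaults; this constructor only pins the
    seed."""
    return SyntheticConfig(seed=seed)


def sample_class_positions(
    cfg: SyntheticConfig, enzyme_class: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n normalized positions from a class's planted positional model."""
    return cfg.position_models[enzyme_class].sample(n, rng)


# ---------------------------------------------------------------------------
# protein architecture construction


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AA), size=n))


def _motif_free_aa(rng: np.random.Generator, n: int) -> str:
    # astronomically unlikely to loop, but the guarantee matters
    while True:
        seq = _random_aa(rng, n)
        if "HHE" not in seq or re.search("HHE.{5}GYP", seq) is None:
            return seq


def _embed_motif(seq: str, rng: np.random.Generator) -> str:
    motif = "HHE" + _random_aa(rng, 5) + "GYP"
    pos = int(rng.integers(0, len(seq) - len(motif) + 1))
    return seq[:pos] + motif + seq[pos + len(motif):]


def _sample_aux_set(
    cfg: SyntheticConfig, enzyme_class: str, rng: np.random.Generator,
    force_k: Optional[int] = None,
) -> list[str]:
    alphabet = list(cfg.aux_alphabets[enzyme_class])
    if force_k is None:
        p0, p1, p2 = cfg.aux_count_probs[enzyme_class]
        cat = rng.choice(3, p=[p0, p1, p2])
        k = 0 if cat == 0 else (1 if cat == 1 else int(rng.integers(2, 4)))
    else:
        k = force_k
    k = min(k, len(alphabet))
    chosen: list[str] = []
    weights = np.ones(len(alphabet))
    for _ in range(k):
        p = weights / weights.sum()
        i = int(rng.choice(len(alphabet), p=p))
        dom = alphabet[i]
        chosen.append(dom)
        weights[i] = 0.0
        for j, other in enumerate(alphabet):
            boost = cfg.cooccurrence_boosts.get((dom, other)) or \
                cfg.cooccurrence_boosts.get((other, dom))
            if boost and weights[j] > 0:
                weights[j] *= boost
    return chosen


def _required_length(cdg_domains: list[str], n_aux: int) -> int:
    total = sum(_CDG_HIT_LEN[d] for d in cdg_domains) + n_aux * _AUX_HIT_LEN
    return total + _HIT_PAD * (len(cdg_domains) + n_aux + 1)


def _sample_length(
    cfg: SyntheticConfig, enzyme_class: str, has_aux: bool, n_aux: int,
    cdg_domains: list[str], rng: np.random.Generator, force_short: Optional[bool] = None,
) -> int:
    thr = cfg.aux_min_length[enzyme_class]
    need = _required_length(cdg_domains, n_aux)
    if has_aux:
        return max(thr + int(rng.integers(0, 301)), need)
    short = force_short if force_short is not None else bool(rng.random() < cfg.short_noaux_fraction)
    if short:
        lo = max(need, thr - 150)
        hi = thr - 1
        if lo > hi:
            lo = hi = thr - 1
        return int(rng.integers(lo, hi + 1))
    return max(thr + int(rng.integers(0, 301)), need)


def _layout_hits(
    protein_id: str, cdg_domains: list[str], aux_domains: list[str],
    rng: np.random.Generator,
) -> list[DomainHit]:
    hits: list[DomainHit] = []
    cursor = _HIT_PAD + 1
    for name in cdg_domains:
        ln = _CDG_HIT_LEN[name]
        acc = {"GGDEF": GGDEF_ACC, "EAL": EAL_ACC, "HD": HD_ACC}[name]
        hits.append(DomainHit(protein_id, acc, name, cursor, cursor + ln - 1,
                              evalue=float(10.0 ** -rng.integers(10, 40))))
        cursor += ln + _HIT_PAD
    for name in aux_domains:
        hits.append(DomainHit(protein_id, "", name, cursor, cursor + _AUX_HIT_LEN - 1,
                              evalue=float(10.0 ** -rng.integers(5, 30))))
        cursor += _AUX_HIT_LEN + _HIT_PAD
    return hits


def make_protein(
    cfg: SyntheticConfig,
    protein_id: str,
    enzyme_class: str,
    rng: np.random.Generator,
    with_motif: bool = True,
    force_aux: Optional[int] = None,
    force_length: Optional[int] = None,
    force_short: Optional[bool] = None,
) -> tuple[ProteinRecord, list[str]]:
    """Build one protein of a given class: domain hits, length, and (for
    HD-bearing proteins) an amino-acid sequence with or without the motif.
    Returns the record and its planted auxiliary-domain list."""
    cdg = {"GGDEF": ["GGDEF"], "EAL": ["EAL"], "GGDEF_EAL": ["GGDEF", "EAL"],
           "HD-GYP": ["HD"]}[enzyme_class]
    aux = _sample_aux_set(cfg, enzyme_class, rng, force_k=force_aux)
    length = force_length if force_length is not None else _sample_length(
        cfg, enzyme_class, bool(aux), len(aux), cdg, rng, force_short=force_short)
    hits = _layout_hits(protein_id, cdg, aux, rng)
    sequence = None
    if enzyme_class == "HD-GYP" or "HD" in cdg:
        sequence = _motif_free_aa(rng, length)
        if with_motif:
            sequence = _embed_motif(sequence, rng)
    return ProteinRecord(protein_id=protein_id, length=length, sequence=sequence,
                         hits=hits), aux


def planted_length_group(
    cfg: SyntheticConfig,
    enzyme_class: str,
    n_with_aux: int,
    n_without: int,
    rng: np.random.Generator,
) -> list[ClassifiedProtein]:
    """A single-class protein group with an exactly planted length structure:
    the minimum length among aux-bearing sequences equals the configured
    class threshold, and exactly round(short_noaux_fraction * n_without)
    aux-free sequences are shorter than it. Used to exercise the
    length-threshold analysis against known truth."""
    from .classify import classify_protein

    thr = cfg.aux_min_length[enzyme_class]
    proteins: list[ProteinRecord] = []
    for i in range(n_with_aux):
        p, _ = make_protein(cfg, f"{enzyme_class}_aux{i:04d}", enzyme_class, rng,
                            force_aux=1 if i == 0 else None,
                            force_length=thr if i == 0 else None)
        if not p.hits or all(h.domain_name in ("GGDEF", "EAL", "HD") for h in p.hits):
            p, _ = make_protein(cfg, p.protein_id, enzyme_class, rng, force_aux=1)
        proteins.append(p)
    n_short = round(cfg.short_noaux_fraction * n_without)
    for i in range(n_without):
        p, _ = make_protein(cfg, f"{enzyme_class}_noaux{i:04d}", enzyme_class, rng,
                            force_aux=0, force_short=i < n_short)
        proteins.append(p)
    return [classify_protein(p) for p in proteins]


# ---------------------------------------------------------------------------
# genome assembly


def _skewed_sequence(length: int, ori: int, gc: tuple[float, float],
                     rng: np.random.Generator) -> str:
    """Random nucleotide sequence with a GC-skew switch at the planted ori:
    the ori->ter half is G-rich, the ter->ori half C-rich."""
    pg, pc = gc
    pa = pt = (1.0 - pg - pc) / 2.0
    phase = (np.arange(1, length + 1) - ori) % length
    g_rich = phase < length // 2
    bases = np.empty(length, dtype="<U1")
    n_rich = int(g_rich.sum())
    bases[g_rich] = rng.choice(list("GCAT"), size=n_rich, p=[pg, pc, pa, pt])
    bases[~g_rich] = rng.choice(list("GCAT"), size=length - n_rich, p=[pc, pg, pa, pt])
    return "".join(bases)


def _place_genes(
    targets: list[tuple[str, float, int]],  # (protein_id, position_pct, gene_len_nt)
    ori: int,
    length_bp: int,
) -> dict[str, GeneLocus]:
    """Convert sampled normalized positions to non-overlapping nt intervals.

    Genes are anchored at round(position/100 * L) rotated by ori, then
    resolved greedily left-to-right with >= 50 bp spacing. Raises
    GenerationError when the replicon cannot hold them."""
    total = sum(g + GENE_SPACING_BP for _, _, g in targets)
    if total > length_bp:
        raise GenerationError(
            f"{len(targets)} genes need {total} bp but replicon is {length_bp} bp"
        )
    anchored = []
    for pid, pos, glen in targets:
        mid = (ori - 1 + round(pos / 100.0 * length_bp)) % length_bp + 1
        start = mid - glen // 2
        if start < 1:
            start += length_bp
        anchored.append((start, pid, glen))
    anchored.sort()
    if not anchored:
        return {}
    # place greedily around the circle starting just after the largest anchor
    # gap, so a gene cluster straddling the coordinate seam stays intact
    n = len(anchored)
    gaps = [(anchored[(i + 1) % n][0] - anchored[i][0]) % length_bp for i in range(n)]
    first = (int(np.argmax(gaps)) + 1) % n
    placed: dict[str, GeneLocus] = {}
    prev_end: Optional[int] = None
    first_start: Optional[int] = None
    for j in range(n):
        start, pid, glen = anchored[(first + j) % n]
        if first_start is not None and start < first_start:
            start += length_bp  # unwrapped frame past the seam
        if prev_end is not None:
            start = max(start, prev_end + GENE_SPACING_BP + 1)
        if first_start is None:
            first_start = start
        end = start + glen - 1
        if end - first_start >= length_bp - GENE_SPACING_BP:
            raise GenerationError("genes wrap fully around the replicon")
        start_mod = (start - 1) % length_bp + 1
        placed[pid] = GeneLocus(replicon_id="", start=start_mod,
                                end=start_mod + glen - 1, strand="+")
        prev_end = end
    return placed


@dataclass
class TruthRecord:
    """Ground truth for one generated dataset, consistent with the emitted
    files; serializable to JSON."""

    config: dict
    genomes: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "genomes": self.genomes}, fh,
                      indent=2, sort_keys=True)
            fh.write("\n")

    def class_counts(self, genome_id: str) -> dict[str, int]:
        for g in self.genomes:
            if g["genome_id"] == genome_id:
                return dict(g["class_counts"])
        raise KeyError(genome_id)


def _config_snapshot(cfg: SyntheticConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["position_models"] = {
        k: {"means": list(v.means), "sds": list(v.sds), "weights": list(v.weights)}
        for k, v in cfg.position_models.items()
    }
    d["cooccurrence_boosts"] = {f"{a}|{b}": w for (a, b), w in
                                cfg.cooccurrence_boosts.items()}
    return d


def generate_genomes(cfg: SyntheticConfig) -> tuple[list[GenomeRecord], TruthRecord]:
    """Generate the in-memory dataset: genome records (with taxonomy,
    replicons, planted genes) plus the truth record. Deterministic given
    ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genomes: list[GenomeRecord] = []
    truth = TruthRecord(config=_config_snapshot(cfg))
    g_index = 0
    for o in range(cfg.n_orders):
        order = f"SimOrder{o + 1:02d}"
        for ge in range(cfg.n_genera_per_order):
            genus = f"{order}_Genus{ge + 1:02d}"
            for sp in range(cfg.n_genomes_per_genus):
                g_index += 1
                genome_id = f"G{g_index:04d}"
                genome, g_truth = _generate_one_genome(
                    cfg, genome_id, order, genus, f"sp{sp + 1:02d}", rng)
                genomes.append(genome)
                truth.genomes.append(g_truth)
    return genomes, truth


def _generate_one_genome(
    cfg: SyntheticConfig, genome_id: str, order: str, genus: str, species: str,
    rng: np.random.Generator,
) -> tuple[GenomeRecord, dict]:
    replicons: list[Replicon] = []
    primary_id = f"{genome_id}_c1"
    ori1 = int(rng.integers(1, cfg.replicon_length_bp + 1))
    replicons.append(Replicon(primary_id, cfg.replicon_length_bp, ori=ori1))
    has_secondary = bool(rng.random() < cfg.secondary_chromosome_prob)
    if has_secondary:
        sec_id = f"{genome_id}_c2"
        ori2 = int(rng.integers(1, cfg.secondary_length_bp + 1))
        replicons.append(Replicon(sec_id, cfg.secondary_length_bp, ori=ori2))

    class_counts = {c: int(rng.poisson(cfg.class_count_means[c])) for c in _CLASS_NAMES}
    n_hd_gyp = class_counts["HD-GYP"]
    n_hd_decoy = round(n_hd_gyp * (1 - cfg.motif_rate) / cfg.motif_rate) \
        if cfg.motif_rate > 0 else 0
    n_decoy_none = int(rng.poisson(cfg.decoy_none_mean))

    proteins: list[ProteinRecord] = []
    gene_truth: list[dict] = []
    pid_counter = 0
    # (replicon_idx -> list of (protein_id, pos, nt_len))
    targets: dict[int, list[tuple[str, float, int]]] = {i: [] for i in range(len(replicons))}

    def _assign_replicon() -> int:
        if has_secondary and rng.random() < cfg.secondary_gene_fraction:
            return 1
        return 0

    for cls in _CLASS_NAMES:
        for _ in range(class_counts[cls]):
            pid_counter += 1
            pid = f"{genome_id}_p{pid_counter:04d}"
            prot, aux = make_protein(cfg, pid, cls, rng, with_motif=True)
            pos = float(sample_class_positions(cfg, cls, 1, rng)[0])
            ridx = _assign_replicon()
            targets[ridx].append((pid, pos, 3 * prot.length + 3))
            proteins.append(prot)
            gene_truth.append({"protein_id": pid, "class": cls,
                               "position_pct": pos, "aux": sorted(aux),
                               "length": prot.length,
                               "replicon_id": replicons[ridx].replicon_id})
    for _ in range(n_hd_decoy):
        pid_counter += 1
        pid = f"{genome_id}_p{pid_counter:04d}"
        prot, aux = make_protein(cfg, pid, "HD-GYP", rng, with_motif=False)
        pos = float(rng.uniform(0, 100))
        ridx = _assign_replicon()
        targets[ridx].append((pid, pos, 3 * prot.length + 3))
        proteins.append(prot)
        gene_truth.append({"protein_id": pid, "class": "NONE", "position_pct": pos,
                           "aux": sorted(set(aux) | {"HD"}), "length": prot.length,
                           "replicon_id": replicons[ridx].replicon_id})
    for _ in range(n_decoy_none):
        pid_counter += 1
        pid = f"{genome_id}_p{pid_counter:04d}"
        aux = _sample_aux_set(cfg, "GGDEF", rng, force_k=int(rng.integers(1, 3)))
        length = int(rng.integers(150, 600))
        hits = _layout_hits(pid, [], aux, rng)
        prot = ProteinRecord(protein_id=pid, length=length, hits=hits)
        pos = float(rng.uniform(0, 100))
        ridx = _assign_replicon()
        targets[ridx].append((pid, pos, 3 * length + 3))
        proteins.append(prot)
        gene_truth.append({"protein_id": pid, "class": "NONE", "position_pct": pos,
                           "aux": sorted(set(aux)), "length": length,
                           "replicon_id": replicons[ridx].replicon_id})

    # resolve nt coordinates per replicon
    loci: dict[str, GeneLocus] = {}
    for ridx, reps in targets.items():
        rep = replicons[ridx]
        placed = _place_genes(reps, rep.ori, rep.length_bp)
        for pid, locus in placed.items():
            loci[pid] = GeneLocus(replicon_id=rep.replicon_id, start=locus.start,
                                  end=locus.end, strand="+" if rng.random() < 0.5 else "-")
    for prot in proteins:
        prot.locus = loci[prot.protein_id]

    if cfg.emit_sequences:
        for rep in replicons:
            rep.sequence = _skewed_sequence(rep.length_bp, rep.ori, cfg.skew_gc, rng)

    genome = GenomeRecord(genome_id=genome_id, order=order, genus=genus,
                          species_or_strain=species, replicons=replicons,
                          proteins=proteins)
    g_truth = {
        "genome_id": genome_id,
        "order": order,
        "genus": genus,
        "species_or_strain": species,
        "class_counts": class_counts,
        "replicons": [
            {"replicon_id": r.replicon_id, "length_bp": r.length_bp, "ori": r.ori}
            for r in replicons
        ],
        "genes": gene_truth,
    }
    return genome, g_truth


# ---------------------------------------------------------------------------
# file emission


@dataclass
class SyntheticDataset:
    out_dir: Path
    domain_table: Path
    taxonomy_table: Path
    ori_table: Path
    protein_fasta: Path
    annotation_dir: Path
    truth_json: Path
    genomes: list[GenomeRecord]
    truth: TruthRecord


def generate_dataset(cfg: SyntheticConfig, out_dir) -> SyntheticDataset:
    """Generate and write a full dataset in the formats the pipeline reads.
    Byte-identical across runs with the same config and seed."""
    genomes, truth = generate_genomes(cfg)
    out = Path(out_dir)
    ann_dir = out / "annotations"
    ann_dir.mkdir(parents=True, exist_ok=True)

    hit_rows = []
    tax_rows = []
    ori_rows = []
    faa_lines: list[str] = []
    for g in genomes:
        tax_rows.append({"genome_id": g.genome_id, "order": g.order, "genus": g.genus,
                         "species_or_strain": g.species_or_strain})
        for r in g.replicons:
            ori_rows.append({"replicon_id": r.replicon_id, "ori": r.ori,
                             "method": "user_supplied", "ambiguous": "false"})
        gff_lines = ["##gff-version 3"]
        for r in g.replicons:
            gff_lines.append(f"##sequence-region {r.replicon_id} 1 {r.length_bp}")
        for p in g.proteins:
            for h in p.hits:
                hit_rows.append({"protein_id": h.protein_id, "domain_acc": h.domain_acc,
                                 "domain_name": h.domain_name, "start": h.start,
                                 "end": h.end, "evalue": f"{h.evalue:.2e}"})
            if p.sequence is not None:
                faa_lines.append(f">{p.protein_id}")
                faa_lines.append(p.sequence)
            loc = p.locus
            length = g.replicon(loc.replicon_id).length_bp
            end_out = loc.end if loc.end <= length else (loc.end - 1) % length + 1
            gff_lines.append(
                "\t".join([loc.replicon_id, "cdgmap_sim", "CDS", str(loc.start),
                           str(end_out), ".", loc.strand, "0",
                           f"ID={p.protein_id};protein_id={p.protein_id};"
                           f"aa_length={p.length}"])
            )
        (ann_dir / f"{g.genome_id}.gff3").write_text("\n".join(gff_lines) + "\n")
        if cfg.emit_sequences:
            with open(ann_dir / f"{g.genome_id}.fasta", "w") as fh:
                for r in g.replicons:
                    fh.write(f">{r.replicon_id}\n")
                    for i in range(0, r.length_bp, 80):
                        fh.write(r.sequence[i : i + 80] + "\n")

    domain_table = out / "domains.tsv"
    pd.DataFrame(hit_rows, columns=["protein_id", "domain_acc", "domain_name",
                                    "start", "end", "evalue"]).to_csv(
        domain_table, sep="\t", index=False)
    taxonomy_table = out / "taxonomy.tsv"
    pd.DataFrame(tax_rows).to_csv(taxonomy_table, sep="\t", index=False)
    ori_table = out / "ori.tsv"
    pd.DataFrame(ori_rows).to_csv(ori_table, sep="\t", index=False)
    protein_fasta = out / "proteins.faa"
    protein_fasta.write_text("\n".join(faa_lines) + ("\n" if faa_lines else ""))
    truth_json = out / "truth.json"
    truth.to_json(truth_json)
    return SyntheticDataset(
        out_dir=out, domain_table=domain_table, taxonomy_table=taxonomy_table,
        ori_table=ori_table, protein_fasta=protein_fasta, annotation_dir=ann_dir,
        truth_json=truth_json, genomes=genomes, truth=truth,
    )
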