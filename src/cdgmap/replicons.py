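"""Replicon classification and the whereabouts of c-di-GMP genes.

The largest replicon of a genome is its primary chromosome; any other
replicon larger than 800 kb is a secondary chromosome; the rest are
extrachromosomal (plasmids by size, with no further biological typing).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import CdgmapError, ClassifiedProtein, EnzymeClass, GenomeRecord

#: secondary-chromosome size cutoff (bp)
SECONDARY_CHROMOSOME_CUTOFF = 800_000


class RepliconClass(str, Enum):
    PRIMARY = "primary_chromosome"
    SECONDARY = "secondary_chromosome"
    EXTRACHROMOSOMAL = "extrachromosomal"


@dataclass(frozen=True)
class RepliconCall:
    replicon_id: str
    length_bp: int
    replicon_class: RepliconClass
    tie_flagged: bool = False


def classify_replicons(
    g: GenomeRecord, cutoff: int = SECONDARY_CHROMOSOME_CUTOFF
) -> dict[str, RepliconCall]:
    """Largest replicon -> primary chromosome; other replicons > cutoff ->
    secondary chromosome; remainder -> extrachromosomal. Ties for largest
    are broken by lexicographic replicon id and flagged."""
    if not g.replicons:
        raise CdgmapError(f"genome {g.genome_id!r} has no replicons")
    ranked = sorted(g.replicons, key=lambda r: (-r.length_bp, r.replicon_id))
    top_len = ranked[0].length_bp
    tie = sum(1 for r in ranked if r.length_bp == top_len) > 1
    calls: dict[str, RepliconCall] = {}
    for i, r in enumerate(ranked):
        if i == 0:
            cls = RepliconClass.PRIMARY
        elif r.length_bp > cutoff:
            cls = RepliconClass.SECONDARY
        else:
            cls = RepliconClass.EXTRACHROMOSOMAL
        calls[r.replicon_id] = RepliconCall(
            replicon_id=r.replicon_id,
            length_bp=r.length_bp,
            replicon_class=cls,
            tie_flagged=tie and r.length_bp == top_len,
        )
    return calls


@dataclass(frozen=True)
class GenomeLocationSummary:
    genome_id: str
    n_cdg_genes: int
    n_on_primary: int
    n_on_secondary: int
    n_extrachromosomal: int

    @property
    def frac_primary(self) -> float:
        return self.n_on_primary / self.n_cdg_genes if self.n_cdg_genes else float("nan")

    @property
    def frac_non_primary(self) -> float:
        return 1.0 - self.frac_primary if self.n_cdg_genes else float("nan")


def genome_location_summary(
    g: GenomeRecord,
    classified: Iterable[ClassifiedProtein],
    replicon_calls: Mapping[str, RepliconCall],
) -> GenomeLocationSummary:
    """Count where a genome's c-di-GMP genes sit across replicon classes.
    Proteins without a locus are excluded."""
    tally = {cls: 0 for cls in RepliconClass}
    total = 0
    for cp in classified:
        if cp.enzyme_class is EnzymeClass.NONE or cp.protein.locus is None:
            continue
        call = replicon_calls.get(cp.protein.locus.replicon_id)
        if call is None:
            raise CdgmapError(
                f"locus on unclassified replicon {cp.protein.locus.replicon_id!r}"
            )
        tally[call.replicon_class] += 1
        total += 1
    return GenomeLocationSummary(
        genome_id=g.genome_id,
        n_cdg_genes=total,
        n_on_primary=tally[RepliconClass.PRIMARY],
        n_on_secondary=tally[RepliconClass.SECONDARY],
        n_extrachromosomal=tally[RepliconClass.EXTRACHROMOSOMAL],
    )


def gene_location_proportions(
    summaries: Sequence[GenomeLocationSummary],
    taxonomy: pd.DataFrame,
    genome_replicon_calls: Mapping[str, Mapping[str, RepliconCall]],
    cutoff: int = SECONDARY_CHROMOSOME_CUTOFF,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genome and per-order location accounting.

    Returns ``(per_genome, per_order)``. Per genome: gene counts and the
    non-primary fraction. Per order: share of genomes with at least one
    c-di-GMP gene off the primary chromosome, and the shares of genomes with
    1, 2, or >2 replicons larger than the secondary-chromosome cutoff
    (the three shares sum to 100%).
    """
    tax = taxonomy.set_index("genome_id")
    rows = []
    for s in summaries:
        rows.append({
            "genome_id": s.genome_id,
            "order": tax.at[s.genome_id, "order"],
            "n_cdg_genes": s.n_cdg_genes,
            "n_on_primary": s.n_on_primary,
            "n_on_secondary": s.n_on_secondary,
            "n_extrachromosomal": s.n_extrachromosomal,
            "frac_non_primary": s.frac_non_primary,
        })
    per_genome = pd.DataFrame(rows).sort_values("genome_id", kind="mergesort")

    order_rows = []
    for order, sub in per_genome.groupby("order"):
        n = len(sub)
        with_offsite = (sub["n_on_secondary"] + sub["n_extrachromosomal"] > 0).sum()
        big_counts = []
        for gid in sub["genome_id"]:
            calls = genome_replicon_calls[gid]
            big = sum(1 for c in calls.values() if c.length_bp > cutoff)
            # the primary counts as "big" here whatever its size bin suggests:
            # the per-order shares bin genomes by replicons above the cutoff
            big_counts.append(big)
        one = sum(1 for b in big_counts if b == 1)
        two = sum(1 for b in big_counts if b == 2)
        more = sum(1 for b in big_counts if b > 2)
        other = n - one - two - more  # genomes whose largest replicon <= cutoff
        order_rows.append({
            "order": order,
            "n_genomes": n,
            "pct_genomes_offsite_cdg": 100.0 * with_offsite / n,
            "pct_one_big_replicon": 100.0 * one / n,
            "pct_two_big_replicons": 100.0 * two / n,
            "pct_more_big_replicons": 100.0 * more / n,
            "pct_no_big_replicon": 100.0 * other / n,
        })
    per_order = pd.DataFrame(order_rows).sort_values("order", kind="mergesort")
    return per_genome.reset_index(drop=True), per_order.reset_index(drop=True)
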