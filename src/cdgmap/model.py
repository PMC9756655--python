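"""Shared data model for the c-di-GMP comparative-genomics pipeline.

Coordinates follow the GenBank/GFF3 convention throughout: 1-based,
inclusive on both ends, for amino acids and nucleotides alike. Internal
arithmetic that needs half-open intervals converts at the call site and
converts back before anything is stored. Wrap-around CDSs on circular
replicons are normalized at read time to ``start..end+length`` so that
``start <= end`` always holds while the midpoint on the circle is
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class CdgmapError(Exception):
    """Base class for all package errors."""


class FormatError(CdgmapError):
    """A file does not conform to its expected format."""


class ValidationError(CdgmapError):
    """A record violates a data-model invariant."""


class ClassificationError(CdgmapError):
    """A protein cannot be assigned an enzyme class."""


class GenerationError(CdgmapError):
    """A synthetic-data configuration is infeasible."""


class DependencyError(CdgmapError):
    """A pipeline stage is missing an upstream output."""


# aa alphabet accepted by the motif scanner: 20 canonical + ambiguity codes
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZU")

# Pfam accessions of the three catalytic c-di-GMP domains
GGDEF_ACC = "PF00990"
EAL_ACC = "PF00563"
HD_ACC = "PF01966"

GGDEF_NAME = "GGDEF"
EAL_NAME = "EAL"
HD_NAME = "HD"


class EnzymeClass(str, Enum):
    """Mutually exclusive enzyme groups.

    GGDEF marks diguanylate cyclases, EAL and HD_GYP phosphodiesterases,
    GGDEF_EAL the synthesis/degradation hybrids carrying both catalytic
    domains; NONE is everything else.
    """

    GGDEF = "GGDEF"
    EAL = "EAL"
    GGDEF_EAL = "GGDEF_EAL"
    HD_GYP = "HD-GYP"
    NONE = "NONE"


#: the four catalytic groups, in canonical reporting order
CDG_CLASSES = (
    EnzymeClass.GGDEF,
    EnzymeClass.EAL,
    EnzymeClass.GGDEF_EAL,
    EnzymeClass.HD_GYP,
)


@dataclass(frozen=True)
class DomainHit:
    """One annotated domain interval on one protein (aa, 1-based inclusive)."""

    protein_id: str
    domain_acc: str
    domain_name: str
    start: int
    end: int
    evalue: Optional[float] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"domain hit on {self.protein_id!r}: need 1 <= start <= end, "
                f"got start={self.start}, end={self.end}"
            )
        if self.evalue is not None and self.evalue < 0:
            raise ValidationError(
                f"domain hit on {self.protein_id!r}: negative e-value {self.evalue}"
            )

    @property
    def identity(self) -> str:
        """Domain identity used everywhere downstream: accession if present,
        else name. Pfam subfamilies (PAS_3, PAS_4, ...) stay distinct."""
        return self.domain_acc if self.domain_acc else self.domain_name


@dataclass(frozen=True)
class GeneLocus:
    """CDS location on a replicon (nt, 1-based inclusive; end may exceed the
    replicon length for wrap-normalized genes)."""

    replicon_id: str
    start: int
    end: int
    strand: str  # "+" or "-"; recorded but ignored by positional analysis

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValidationError(
                f"locus on {self.replicon_id!r}: need 1 <= start <= end, "
                f"got {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        """Representative point of the gene on the (unwrapped) circle."""
        return self.start + (self.end - self.start) / 2.0


@dataclass
class ProteinRecord:
    protein_id: str
    length: int
    sequence: Optional[str] = None
    hits: list[DomainHit] = field(default_factory=list)
    locus: Optional[GeneLocus] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"protein {self.protein_id!r}: non-positive length")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(
                f"protein {self.protein_id!r}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )
        for h in self.hits:
            if h.protein_id != self.protein_id:
                raise ValidationError(
                    f"hit for {h.protein_id!r} attached to protein {self.protein_id!r}"
                )


@dataclass
class Replicon:
    replicon_id: str
    length_bp: int
    topology: str = "circular"
    ori: Optional[int] = None
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValidationError(f"replicon {self.replicon_id!r}: non-positive length")
        if self.ori is not None and not (1 <= self.ori <= self.length_bp):
            raise ValidationError(
                f"replicon {self.replicon_id!r}: ori {self.ori} outside [1, {self.length_bp}]"
            )


@dataclass
class GenomeRecord:
    genome_id: str
    order: str = ""
    genus: str = ""
    species_or_strain: str = ""
    replicons: list[Replicon] = field(default_factory=list)
    proteins: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.replicon_id for r in self.replicons]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"genome {self.genome_id!r}: duplicate replicon ids")
        known = set(ids)
        for p in self.proteins:
            if p.locus is not None and p.locus.replicon_id not in known:
                raise ValidationError(
                    f"genome {self.genome_id!r}: protein {p.protein_id!r} on unknown "
                    f"replicon {p.locus.replicon_id!r}"
                )

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.replicon_id == replicon_id:
                return r
        raise KeyError(replicon_id)


@dataclass
class ClassifiedProtein:
    """A protein with its enzyme group and deduplicated auxiliary-domain set.

    ``cdg_domains`` holds the catalytic domain names present ({GGDEF, EAL},
    plus HD on HD-GYP proteins); ``auxiliary_domains`` everything else, one
    entry per distinct domain identity no matter how often it repeats.
    """

    protein: ProteinRecord
    enzyme_class: EnzymeClass
    cdg_domains: frozenset[str]
    auxiliary_domains: frozenset[str]

    def __post_init__(self) -> None:
        if self.cdg_domains & self.auxiliary_domains:
            raise ValidationError("catalytic and auxiliary domain sets overlap")
        if self.enzyme_class is EnzymeClass.NONE and self.cdg_domains:
            raise ValidationError("NONE-class protein with catalytic domains")


@dataclass(frozen=True)
class OriCall:
    """A replication-origin call for one replicon. Ambiguous calls exclude
    the replicon from all positional analysis."""

    replicon_id: str
    ori: int
    method: str  # "user_supplied" | "gc_skew"
    ambiguous: bool = False


@dataclass(frozen=True)
class NormalizedPosition:
    """Gene position on the 0-100% circle anchored at ori; ter sits at 50
    by the ter-opposite-ori construction."""

    value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.value < 100.0):
            raise ValidationError(f"normalized position {self.value} outside [0, 100)")

    def __float__(self) -> float:
        return self.value
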