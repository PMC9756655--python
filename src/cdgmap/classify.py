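"""Enzyme-group classification from protein domain architectures.

Every protein lands in exactly one of five groups. GGDEF marks a
diguanylate cyclase domain, EAL a phosphodiesterase domain; a protein
carrying both is a GGDEF_EAL hybrid and forms its own group. HD-superfamily
hits count as catalytic (HD-GYP phosphodiesterases) only when the protein
also carries the HHExxxxxGYP sequence motif AND has no GGDEF or EAL domain;
an HD domain without the motif, or on a GGDEF/EAL protein, is an ordinary
auxiliary domain. GGDEF/EAL never co-occur with the HD-GYP class by
construction.

Auxiliary domains are all remaining distinct domain identities on the
protein; repeated occurrences of the same domain count once.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Iterable, Optional

from .model import (
    AA_ALPHABET,
    CDG_CLASSES,
    EAL_ACC,
    EAL_NAME,
    GGDEF_ACC,
    GGDEF_NAME,
    HD_ACC,
    HD_NAME,
    ClassificationError,
    ClassifiedProtein,
    DomainHit,
    EnzymeClass,
    GenomeRecord,
    ProteinRecord,
    ValidationError,
)

_MOTIF = re.compile("HHE.{5}GYP")


def scan_hdgyp_motif(sequence: str) -> bool:
    """True iff the HHExxxxxGYP signature occurs anywhere in the sequence.

    The pattern is H, H, E, five arbitrary residues, G, Y, P; matching is
    case-insensitive and "x" matches any residue including the ambiguity
    code X. Characters outside the 20 amino acids + X/B/Z/U raise a
    :class:`ValidationError`.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValidationError(f"non-amino-acid characters in sequence: {sorted(bad)}")
    return _MOTIF.search(seq) is not None


def _is_ggdef(hit: DomainHit) -> bool:
    return hit.domain_acc == GGDEF_ACC or hit.domain_name == GGDEF_NAME


def _is_eal(hit: DomainHit) -> bool:
    return hit.domain_acc == EAL_ACC or hit.domain_name == EAL_NAME


def _is_hd(hit: DomainHit) -> bool:
    return hit.domain_acc == HD_ACC or hit.domain_name == HD_NAME


def _motif_in_hd_windows(p: ProteinRecord, margin: int = 10) -> bool:
    # restricted scan: motif must fall within an HD hit interval +/- margin
    assert p.sequence is not None
    for h in p.hits:
        if _is_hd(h):
            lo = max(h.start - margin, 1)
            hi = min(h.end + margin, p.length)
            if _MOTIF.search(p.sequence.upper()[lo - 1 : hi]):
                return True
    return False


def classify_protein(p: ProteinRecord, motif_scope: str = "whole") -> ClassifiedProtein:
    """Assign one enzyme group and the auxiliary-domain set to a protein.

    Rules, applied in order: GGDEF and EAL both present -> GGDEF_EAL;
    GGDEF only -> GGDEF; EAL only -> EAL; otherwise an HD hit whose protein
    carries the HHExxxxxGYP motif -> HD_GYP; otherwise NONE.

    ``motif_scope`` is ``"whole"`` (scan the full sequence, the default) or
    ``"hd_hit"`` (motif must lie within an HD hit interval +/- 10 aa).

    Raises :class:`ClassificationError` when the class hinges on the motif
    (HD hit, no GGDEF/EAL) but no sequence is available.
    """
    if motif_scope not in ("whole", "hd_hit"):
        raise ValueError(f"motif_scope must be 'whole' or 'hd_hit', got {motif_scope!r}")
    has_ggdef = any(_is_ggdef(h) for h in p.hits)
    has_eal = any(_is_eal(h) for h in p.hits)
    has_hd = any(_is_hd(h) for h in p.hits)

    is_hdgyp = False
    if has_hd and not has_ggdef and not has_eal:
        if p.sequence is None:
            raise ClassificationError(
                f"protein {p.protein_id!r}: HD hit present but no sequence available; "
                "motif check impossible"
            )
        if motif_scope == "whole":
            is_hdgyp = scan_hdgyp_motif(p.sequence)
        else:
            is_hdgyp = _motif_in_hd_windows(p)

    if has_ggdef and has_eal:
        cls = EnzymeClass.GGDEF_EAL
    elif has_ggdef:
        cls = EnzymeClass.GGDEF
    elif has_eal:
        cls = EnzymeClass.EAL
    elif is_hdgyp:
        cls = EnzymeClass.HD_GYP
    else:
        cls = EnzymeClass.NONE

    cdg: set[str] = set()
    aux: set[str] = set()
    for h in p.hits:
        if _is_ggdef(h) or _is_eal(h):
            cdg.add(h.domain_name)
        elif _is_hd(h):
            # HD is catalytic only on HD-GYP proteins; elsewhere auxiliary,
            # recorded under its conventional name
            (cdg if cls is EnzymeClass.HD_GYP else aux).add(HD_NAME)
        else:
            aux.add(h.identity)
    if cls is EnzymeClass.NONE:
        cdg = set()  # NONE-class proteins have no catalytic domains by definition

    return ClassifiedProtein(
        protein=p,
        enzyme_class=cls,
        cdg_domains=frozenset(cdg),
        auxiliary_domains=frozenset(aux),
    )


def classify_genome(
    g: GenomeRecord, motif_scope: str = "whole"
) -> tuple[list[ClassifiedProtein], dict[EnzymeClass, int]]:
    """Classify every protein of a genome and tally per-class counts.

    Counts cover the four catalytic classes only (NONE is excluded), and a
    protein contributes at most once to its class regardless of how many
    copies of the catalytic domain it carries.
    """
    classified = [classify_protein(p, motif_scope=motif_scope) for p in g.proteins]
    counter = Counter(cp.enzyme_class for cp in classified)
    counts = {cls: counter.get(cls, 0) for cls in CDG_CLASSES}
    return classified, counts


def classification_table(
    genomes_classified: Iterable[tuple[GenomeRecord, list[ClassifiedProtein]]],
):
    """Long-form classified_proteins table (one row per protein)."""
    import pandas as pd

    rows = []
    for g, classified in genomes_classified:
        for cp in classified:
            locus = cp.protein.locus
            rows.append(
                {
                    "genome_id": g.genome_id,
                    "protein_id": cp.protein.protein_id,
                    "class": cp.enzyme_class.value,
                    "cdg_domains": ",".join(sorted(cp.cdg_domains)),
                    "aux_domains": ",".join(sorted(cp.auxiliary_domains)),
                    "length": cp.protein.length,
                    "replicon_id": locus.replicon_id if locus else "",
                    "start": locus.start if locus else "",
                    "end": locus.end if locus else "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "protein_id", "class", "cdg_domains", "aux_domains",
            "length", "replicon_id", "start", "end",
        ],
    )
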