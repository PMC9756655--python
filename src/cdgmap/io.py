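"""Readers and writers for the pipeline's on-disk formats.

Inputs: a per-protein domain-hit table (TSV), genome annotations as GenBank
flat files or GFF3(+FASTA) pairs, a taxonomy table (TSV), and an optional
per-replicon ori table (TSV). Outputs: deterministic TSV result tables plus
a JSON run manifest.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd
from Bio import SeqIO

from .model import (
    DomainHit,
    FormatError,
    GeneLocus,
    GenomeRecord,
    OriCall,
    ProteinRecord,
    Replicon,
    ValidationError,
)

PathLike = Union[str, Path]

DOMAIN_TABLE_COLUMNS = ["protein_id", "domain_acc", "domain_name", "start", "end"]
TAXONOMY_COLUMNS = ["genome_id", "order", "genus", "species_or_strain"]
ORI_TABLE_COLUMNS = ["replicon_id", "ori", "method", "ambiguous"]


# ---------------------------------------------------------------------------
# domain-hit table


def read_domain_table(path: PathLike) -> list[DomainHit]:
    """Read a TSV of per-protein domain hits into :class:`DomainHit` rows.

    Required columns: protein_id, domain_acc, domain_name, start, end;
    an ``evalue`` column is optional. Coordinates are 1-based inclusive
    amino-acid positions; rows violating ``1 <= start <= end`` raise a
    :class:`ValidationError` carrying the offending line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in DOMAIN_TABLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    has_evalue = "evalue" in df.columns
    hits: list[DomainHit] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line_no = idx + 2  # header is line 1
        try:
            start = int(getattr(row, "start"))
            end = int(getattr(row, "end"))
        except ValueError as exc:
            raise ValidationError(f"{path}, line {line_no}: non-integer coordinate") from exc
        ev_raw = getattr(row, "evalue", "") if has_evalue else ""
        evalue = float(ev_raw) if ev_raw not in ("", "NA", "nan") else None
        try:
            hits.append(
                DomainHit(
                    protein_id=row.protein_id,
                    domain_acc=row.domain_acc,
                    domain_name=row.domain_name,
                    start=start,
                    end=end,
                    evalue=evalue,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, line {line_no}: {exc}") from exc
    return hits


def filter_hits_by_evalue(hits: Iterable[DomainHit], ceiling: Optional[float]) -> list[DomainHit]:
    """Optional e-value ceiling; ``None`` (the default) keeps every hit,
    including hits without an e-value."""
    if ceiling is None:
        return list(hits)
    return [h for h in hits if h.evalue is None or h.evalue <= ceiling]


# ---------------------------------------------------------------------------
# genome annotations


def _normalize_wraparound(start: int, end: int, length: int) -> tuple[int, int]:
    # wrap-around CDS on a circular replicon: keep start <= end by unwrapping
    if end < start:
        end += length
    return start, end


def read_genome_annotation(
    annotation_path: PathLike,
    fasta_path: Optional[PathLike] = None,
    genome_id: Optional[str] = None,
) -> GenomeRecord:
    """Read a GenBank flat file, or a GFF3 file plus FASTA, into a GenomeRecord.

    Replicon lengths come from the LOCUS line (GenBank) or the
    ``##sequence-region`` pragma / FASTA (GFF3). One GeneLocus is created per
    CDS carrying a ``protein_id`` qualifier (GenBank) or ``protein_id=`` /
    ``ID=`` attribute (GFF3); CDSs without one are skipped with a warning.
    """
    annotation_path = Path(annotation_path)
    gid = genome_id or annotation_path.stem
    suffix = annotation_path.suffix.lower()
    if suffix in (".gb", ".gbk", ".gbff", ".genbank"):
        genome = _read_genbank(annotation_path, gid)
    elif suffix in (".gff", ".gff3"):
        genome = _read_gff3(annotation_path, fasta_path, gid)
    else:
        raise FormatError(f"{annotation_path}: unrecognized annotation format {suffix!r}")
    return genome


def _read_genbank(path: Path, genome_id: str) -> GenomeRecord:
    replicons: list[Replicon] = []
    proteins: list[ProteinRecord] = []
    skipped = 0
    for rec in SeqIO.parse(str(path), "genbank"):
        length = len(rec.seq)
        if length == 0:
            raise FormatError(f"{path}: record {rec.id!r} has no length")
        try:
            seq_str = str(rec.seq)
            seq = seq_str if len(set(seq_str)) > 1 else None
        except Exception:  # LOCUS declares a length but ORIGIN is empty
            seq = None
        replicons.append(Replicon(replicon_id=rec.id, length_bp=length, sequence=seq))
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            pids = feat.qualifiers.get("protein_id")
            if not pids:
                skipped += 1
                continue
            start = int(feat.location.start) + 1  # Biopython is 0-based half-open
            end = int(feat.location.end)
            start, end = _normalize_wraparound(start, end, length)
            strand = "-" if feat.location.strand == -1 else "+"
            locus = GeneLocus(replicon_id=rec.id, start=start, end=end, strand=strand)
            aa_len = (end - start + 1) // 3 - 1 or 1
            translation = feat.qualifiers.get("translation", [None])[0]
            if translation:
                aa_len = len(translation)
            proteins.append(
                ProteinRecord(
                    protein_id=pids[0],
                    length=max(aa_len, 1),
                    sequence=translation,
                    locus=locus,
                )
            )
    if not replicons:
        raise FormatError(f"{path}: no GenBank records found")
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} CDS feature(s) without protein_id")
    return GenomeRecord(genome_id=genome_id, replicons=replicons, proteins=proteins)


def _parse_gff_attributes(field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in field.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gff3(path: Path, fasta_path: Optional[PathLike], genome_id: str) -> GenomeRecord:
    lengths: dict[str, int] = {}
    sequences: dict[str, str] = {}
    if fasta_path is not None:
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            sequences[rec.id] = str(rec.seq)
            lengths[rec.id] = len(rec.seq)
    cds_rows: list[tuple[str, int, int, str, dict[str, str]]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    lengths.setdefault(parts[1], int(parts[3]))
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}: malformed GFF3 line: {line[:80]!r}")
            if fields[2] != "CDS":
                continue
            cds_rows.append(
                (fields[0], int(fields[3]), int(fields[4]), fields[6],
                 _parse_gff_attributes(fields[8]))
            )
    if not lengths:
        raise FormatError(f"{path}: no replicon lengths (need ##sequence-region or FASTA)")
    replicons = [
        Replicon(replicon_id=rid, length_bp=ln, sequence=sequences.get(rid))
        for rid, ln in lengths.items()
    ]
    proteins: list[ProteinRecord] = []
    skipped = 0
    for rid, start, end, strand, attrs in cds_rows:
        if rid not in lengths:
            raise FormatError(f"{path}: CDS references unknown replicon {rid!r}")
        pid = attrs.get("protein_id") or attrs.get("ID")
        if not pid:
            skipped += 1
            continue
        start, end = _normalize_wraparound(start, end, lengths[rid])
        locus = GeneLocus(replicon_id=rid, start=start, end=end,
                          strand=strand if strand in ("+", "-") else "+")
        aa_len = max((end - start + 1) // 3 - 1, 1)
        proteins.append(ProteinRecord(protein_id=pid, length=aa_len, locus=locus))
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} CDS feature(s) without protein_id/ID")
    return GenomeRecord(genome_id=genome_id, replicons=replicons, proteins=proteins)


# ---------------------------------------------------------------------------
# taxonomy and ori tables


def read_taxonomy_table(path: PathLike) -> pd.DataFrame:
    """Genome metadata TSV: genome_id, order, genus, species_or_strain."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in TAXONOMY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df[TAXONOMY_COLUMNS]


def read_ori_table(path: PathLike) -> dict[str, OriCall]:
    """Per-replicon ori coordinates replacing the GC-skew estimator.

    Columns: replicon_id, ori; optional method and ambiguous columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("replicon_id", "ori"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    calls: dict[str, OriCall] = {}
    for row in df.itertuples(index=False):
        ambiguous = str(getattr(row, "ambiguous", "false")).lower() in ("true", "1", "yes")
        calls[row.replicon_id] = OriCall(
            replicon_id=row.replicon_id,
            ori=int(row.ori),
            method=str(getattr(row, "method", "user_supplied")) or "user_supplied",
            ambiguous=ambiguous,
        )
    return calls


def write_ori_table(calls: Iterable[OriCall], path: PathLike) -> None:
    df = pd.DataFrame(
        [
            {"replicon_id": c.replicon_id, "ori": c.ori, "method": c.method,
             "ambiguous": str(c.ambiguous).lower()}
            for c in calls
        ],
        columns=ORI_TABLE_COLUMNS,
    ).sort_values("replicon_id", kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result tables + manifest


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: PathLike,
    manifest_extra: Optional[Mapping[str, object]] = None,
) -> dict[str, str]:
    """Write named result tables as deterministic TSVs plus a JSON manifest.

    Rows are sorted lexicographically over all columns and columns keep their
    given order, so identical inputs produce byte-identical files. Returns a
    manifest mapping table name -> written file name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = dict(manifest_extra or {})
    files: dict[str, str] = {}
    for name in sorted(tables):
        df = tables[name]
        for col in df.columns:
            if not isinstance(col, str) or not col:
                raise ValidationError(f"table {name!r}: unnamed column {col!r}")
        out = df.copy()
        if len(out):
            out = out.sort_values(list(out.columns), kind="mergesort")
        fname = f"{name}.tsv"
        out.to_csv(out_dir / fname, sep="\t", index=False)
        files[name] = fname
    manifest["tables"] = files
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return files
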