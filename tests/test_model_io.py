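import pandas as pd
import pytest

from cdgmap.io import (
    read_domain_table,
    read_genome_annotation,
    read_ori_table,
    read_taxonomy_table,
    write_ori_table,
    write_results,
)
from cdgmap.model import (
    DomainHit,
    FormatError,
    GeneLocus,
    GenomeRecord,
    OriCall,
    ProteinRecord,
    Replicon,
    ValidationError,
)


# ---------------------------------------------------------------------------
# domain-hit table


def _write(tmp_path, text, name="hits.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "protein_id\tdomain_acc\tdomain_name\tstart\tend\n"


def test_domain_table_row_maps_to_fields(tmp_path):
    p = _write(tmp_path, HEADER + "p1\tPF00990\tGGDEF\t10\t170\n")
    hits = read_domain_table(p)
    assert hits == [DomainHit("p1", "PF00990", "GGDEF", 10, 170)]


def test_domain_table_header_only_gives_empty_list(tmp_path):
    assert read_domain_table(_write(tmp_path, HEADER)) == []


def test_domain_table_row_count_equals_wellformed_rows(tmp_path):
    rows = "".join(f"p{i}\tPF00990\tGGDEF\t{i}\t{i + 50}\n" for i in range(1, 20))
    assert len(read_domain_table(_write(tmp_path, HEADER + rows))) == 19


@pytest.mark.parametrize(
    "row,err",
    [
        ("p1\tPF00990\tGGDEF\t0\t170\n", ValidationError),   # 1-based violated
        ("p1\tPF00990\tGGDEF\t200\t170\n", ValidationError),  # start > end
        ("p1\tPF00990\tGGDEF\tten\t170\n", ValidationError),
    ],
)
def test_domain_table_bad_coordinates_rejected_with_line(tmp_path, row, err):
    with pytest.raises(err, match="line 2"):
        read_domain_table(_write(tmp_path, HEADER + row))


def test_domain_table_missing_column_names_it(tmp_path):
    p = _write(tmp_path, "protein_id\tdomain_acc\tstart\tend\np1\tPF\t1\t2\n")
    with pytest.raises(FormatError, match="domain_name"):
        read_domain_table(p)


def test_domain_table_optional_evalue(tmp_path):
    p = _write(tmp_path, HEADER.rstrip("\n") + "\tevalue\n"
               + "p1\tPF00990\tGGDEF\t10\t170\t1.5e-30\n"
               + "p2\tPF00563\tEAL\t5\t160\t\n")
    hits = read_domain_table(p)
    assert hits[0].evalue == pytest.approx(1.5e-30)
    assert hits[1].evalue is None


# ---------------------------------------------------------------------------
# genome annotations

GENBANK = """LOCUS       repA                   10000 bp    DNA     circular BCT 01-JAN-2020
DEFINITION  synthetic test replicon.
ACCESSION   repA
VERSION     repA
FEATURES             Location/Qualifiers
     source          1..10000
     CDS             101..400
                     /protein_id="pA"
                     /translation="MKKLLVT"
     CDS             complement(501..800)
                     /protein_id="pB"
ORIGIN
//
"""


def test_genbank_replicon_and_loci(tmp_path):
    p = _write(tmp_path, GENBANK, "g.gbk")
    g = read_genome_annotation(p)
    assert len(g.replicons) == 1
    assert g.replicons[0].length_bp == 10000
    assert len(g.proteins) == 2
    pa = {pr.protein_id: pr for pr in g.proteins}
    assert pa["pA"].locus == GeneLocus("repA", 101, 400, "+")
    assert pa["pB"].locus.strand == "-"


GFF = """##gff-version 3
##sequence-region chr1 1 10000
chr1\tsrc\tCDS\t101\t400\t.\t+\t0\tID=c1;protein_id=pA
chr1\tsrc\tCDS\t501\t800\t.\t-\t0\tID=c2;protein_id=pB
"""


def test_gff3_coordinates_are_one_based_inclusive(tmp_path):
    g = read_genome_annotation(_write(tmp_path, GFF, "g.gff3"))
    pa = {pr.protein_id: pr for pr in g.proteins}
    assert pa["pA"].locus == GeneLocus("chr1", 101, 400, "+")


def test_gff3_wraparound_cds_normalized(tmp_path):
    gff = ("##gff-version 3\n##sequence-region chr1 1 10000\n"
           "chr1\tsrc\tCDS\t9901\t300\t.\t+\t0\tID=c1;protein_id=pA\n")
    g = read_genome_annotation(_write(tmp_path, gff, "g.gff3"))
    locus = g.proteins[0].locus
    assert (locus.start, locus.end) == (9901, 10300)
    assert locus.midpoint == pytest.approx(10100.5)


def test_gff3_unknown_replicon_is_fatal(tmp_path):
    gff = ("##gff-version 3\n##sequence-region chr1 1 10000\n"
           "chrX\tsrc\tCDS\t1\t300\t.\t+\t0\tID=c1;protein_id=pA\n")
    with pytest.raises(FormatError, match="chrX"):
        read_genome_annotation(_write(tmp_path, gff, "g.gff3"))


def test_gff3_missing_lengths_is_fatal(tmp_path):
    gff = "##gff-version 3\nchr1\tsrc\tCDS\t1\t300\t.\t+\t0\tID=c1\n"
    with pytest.raises(FormatError, match="length"):
        read_genome_annotation(_write(tmp_path, gff, "g.gff3"))


def test_cds_without_protein_id_skipped_with_warning(tmp_path):
    gff = ("##gff-version 3\n##sequence-region chr1 1 10000\n"
           "chr1\tsrc\tCDS\t1\t300\t.\t+\t0\tNote=orphan\n")
    with pytest.warns(UserWarning, match="skipped 1"):
        g = read_genome_annotation(_write(tmp_path, gff, "g.gff3"))
    assert g.proteins == []


# ---------------------------------------------------------------------------
# taxonomy / ori tables


def test_taxonomy_and_ori_roundtrip(tmp_path):
    tax = _write(tmp_path, "genome_id\torder\tgenus\tspecies_or_strain\n"
                           "G1\tO1\tGen1\tsp1\n", "tax.tsv")
    df = read_taxonomy_table(tax)
    assert list(df.columns) == ["genome_id", "order", "genus", "species_or_strain"]
    calls = [OriCall("r1", 123, "user_supplied", False),
             OriCall("r2", 99, "gc_skew", True)]
    path = tmp_path / "ori.tsv"
    write_ori_table(calls, path)
    back = read_ori_table(path)
    assert back["r1"].ori == 123 and back["r2"].ambiguous is True


# ---------------------------------------------------------------------------
# result writing


def test_write_results_deterministic_bytes(tmp_path):
    df = pd.DataFrame({"b": [2, 1], "a": ["y", "x"]})
    d1, d2 = tmp_path / "o1", tmp_path / "o2"
    write_results({"t": df}, d1, {"seed": 0})
    write_results({"t": df.iloc[::-1]}, d2, {"seed": 0})  # same rows, other order
    assert (d1 / "t.tsv").read_bytes() == (d2 / "t.tsv").read_bytes()
    assert (d1 / "manifest.json").exists()


def test_write_results_empty_tables_manifest_only(tmp_path):
    files = write_results({}, tmp_path / "o")
    assert files == {}
    assert (tmp_path / "o" / "manifest.json").exists()


def test_write_results_unnamed_column_rejected(tmp_path):
    df = pd.DataFrame([[1, 2]])  # integer column labels
    with pytest.raises(ValidationError):
        write_results({"t": df}, tmp_path / "o")


def test_classification_table_roundtrips(tmp_path):
    from cdgmap.classify import classification_table, classify_genome

    g = GenomeRecord(
        genome_id="G1",
        replicons=[Replicon("r1", 10_000)],
        proteins=[
            ProteinRecord("p1", 400, hits=[
                DomainHit("p1", "PF00990", "GGDEF", 10, 120),
                DomainHit("p1", "", "PAS", 200, 260),
            ], locus=GeneLocus("r1", 100, 1300, "+")),
        ],
    )
    classified, _ = classify_genome(g)
    table = classification_table([(g, classified)])
    write_results({"classified_proteins": table}, tmp_path)
    back = pd.read_csv(tmp_path / "classified_proteins.tsv", sep="\t")
    assert back.loc[0, "class"] == "GGDEF"
    assert back.loc[0, "aux_domains"] == "PAS"
    assert int(back.loc[0, "start"]) == 100


# ---------------------------------------------------------------------------
# model invariants


def test_sequence_length_mismatch_rejected():
    with pytest.raises(ValidationError):
        ProteinRecord("p1", 10, sequence="MK")


def test_replicon_ori_bounds():
    with pytest.raises(ValidationError):
        Replicon("r1", 1000, ori=1001)


def test_genome_cross_reference_enforced():
    with pytest.raises(ValidationError):
        GenomeRecord("G1", replicons=[Replicon("r1", 1000)],
                     proteins=[ProteinRecord("p1", 10,
                                             locus=GeneLocus("rX", 1, 30, "+"))])
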