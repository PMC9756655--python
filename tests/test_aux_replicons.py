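"""Auxiliary-domain analytics and replicon classification."""

import itertools

import numpy as np
import pytest

from cdgmap.auxdomains import (
    aux_count_categories,
    build_cooccurrence_network,
    length_threshold,
    venn_partition,
)
from cdgmap.classify import classify_protein
from cdgmap.model import (
    CdgmapError,
    DomainHit,
    EnzymeClass,
    GenomeRecord,
    ProteinRecord,
    Replicon,
)
from cdgmap.replicons import RepliconClass, classify_replicons
from conftest import make_protein

GROUPS = ("GGDEF", "EAL", "GGDEF_EAL", "HD-GYP")


def _classified(aux_sets, cls=("PF00990", "GGDEF")):
    """Build single-group classified proteins with the given aux sets."""
    out = []
    for i, aux in enumerate(aux_sets):
        p = make_protein(f"p{i}", [cls] + [("", a) for a in aux])
        out.append(classify_protein(p))
    return out


# ---------------------------------------------------------------------------
# Venn partition


def test_venn_shared_pair():
    regions = venn_partition({"GGDEF": {"PAS"}, "EAL": {"PAS"},
                              "GGDEF_EAL": set(), "HD-GYP": set()})
    assert regions[frozenset({"GGDEF", "EAL"})] == 1
    assert sum(regions.values()) == 1


def test_venn_center_region():
    regions = venn_partition({g: {"REC"} for g in GROUPS})
    assert regions[frozenset(GROUPS)] == 1
    assert sum(regions.values()) == 1


def test_venn_matches_brute_force_enumeration(rng):
    domains = [f"D{i}" for i in range(30)]
    sets = {g: set(rng.choice(domains, size=rng.integers(0, 15), replace=False))
            for g in GROUPS}
    regions = venn_partition(sets)
    # brute-force oracle: per-domain membership enumeration
    for combo_size in range(1, 5):
        for combo in itertools.combinations(GROUPS, combo_size):
            expected = sum(
                1 for d in domains
                if all(d in sets[g] for g in combo)
                and all(d not in sets[g] for g in GROUPS if g not in combo)
            )
            assert regions[frozenset(combo)] == expected
    observed = set().union(*sets.values())
    assert sum(regions.values()) == len(observed)


# ---------------------------------------------------------------------------
# aux-count categories


def test_aux_categories_thirds():
    cps = _classified([set(), {"PAS"}, {"PAS", "REC"}])
    cat = aux_count_categories(cps)
    assert cat.pct_none == pytest.approx(100 / 3)
    assert cat.pct_one == pytest.approx(100 / 3)
    assert cat.pct_more == pytest.approx(100 / 3)
    assert cat.pct_none + cat.pct_one + cat.pct_more == pytest.approx(100.0)


def test_distinct_pas_subfamilies_count_separately():
    cat = aux_count_categories(_classified([{"PAS", "PAS_3"}]))
    assert cat.pct_more == 100.0


def test_repeated_domain_counts_once():
    p = make_protein("p0", [("PF00990", "GGDEF"), ("", "PAS"), ("", "PAS")])
    cat = aux_count_categories([classify_protein(p)])
    assert cat.pct_one == 100.0


def test_empty_group_flagged():
    with pytest.raises(CdgmapError):
        aux_count_categories([])


# ---------------------------------------------------------------------------
# co-occurrence network


def test_network_simple_pair_counts():
    g = build_cooccurrence_network(_classified([{"PAS", "REC"}, {"PAS", "GAF"}]))
    assert g["PAS"]["REC"]["weight"] == 1
    assert g["PAS"]["GAF"]["weight"] == 1
    assert g.nodes["PAS"]["count"] == 2
    assert not g.has_edge("REC", "GAF")


def test_network_triple_expands_pairwise():
    g = build_cooccurrence_network(_classified([{"A1", "B1", "C1"}]))
    assert {frozenset(e) for e in g.edges} == {
        frozenset({"A1", "B1"}), frozenset({"A1", "C1"}), frozenset({"B1", "C1"})}
    assert all(d["weight"] == 1 for _, _, d in g.edges(data=True))


def test_network_matches_exhaustive_pair_counting(rng):
    domains = [f"D{i}" for i in range(12)]
    archs = [set(rng.choice(domains, size=rng.integers(0, 5), replace=False))
             for _ in range(50)]
    g = build_cooccurrence_network(_classified(archs))
    for a, b in itertools.combinations(domains, 2):
        expected = sum(1 for s in archs if a in s and b in s)
        got = g[a][b]["weight"] if g.has_edge(a, b) else 0
        assert got == expected
    for d in domains:
        expected = sum(1 for s in archs if d in s)
        got = g.nodes[d]["count"] if g.has_node(d) else 0
        assert got == expected
    # conservation: edge weights total exactly sum of C(k, 2) over sequences
    total_w = sum(d["weight"] for _, _, d in g.edges(data=True))
    assert total_w == sum(len(s) * (len(s) - 1) // 2 for s in archs)
    # weight bounded by both endpoint counts; no self-edges
    for a, b, d in g.edges(data=True):
        assert a != b
        assert d["weight"] <= min(g.nodes[a]["count"], g.nodes[b]["count"])


# ---------------------------------------------------------------------------
# length threshold


def _with_lengths(pairs):
    out = []
    for i, (length, aux) in enumerate(pairs):
        p = ProteinRecord(f"p{i}", length, hits=[
            DomainHit(f"p{i}", "PF00563", "EAL", 10, 100)]
            + [DomainHit(f"p{i}", "", a, 150, 200) for a in aux])
        out.append(classify_protein(p))
    return out


def test_length_threshold_worked_example():
    cps = _with_lengths([(400, {"PAS"}), (380, {"REC"}), (200, set()), (390, set())])
    res = length_threshold(cps)
    assert res.min_len_with_aux == 380
    assert res.pct_noaux_below == 50.0
    assert res.pct_noaux_below + res.pct_noaux_at_or_above == pytest.approx(100.0)


def test_length_threshold_no_short_sequences():
    cps = _with_lengths([(380, {"PAS"}), (390, set()), (400, set())])
    assert length_threshold(cps).pct_noaux_below == 0.0


def test_length_threshold_one_side_empty_flagged():
    with pytest.raises(CdgmapError):
        length_threshold(_with_lengths([(400, {"PAS"})]))


# ---------------------------------------------------------------------------
# replicon classification


def _genome(lengths):
    return GenomeRecord("G1", replicons=[
        Replicon(f"r{i}", ln) for i, ln in enumerate(lengths)])


def test_worked_replicon_fixture():
    calls = classify_replicons(_genome([3_000_000, 1_200_000, 500_000]))
    assert calls["r0"].replicon_class is RepliconClass.PRIMARY
    assert calls["r1"].replicon_class is RepliconClass.SECONDARY
    assert calls["r2"].replicon_class is RepliconClass.EXTRACHROMOSOMAL


def test_single_replicon_is_primary_regardless_of_size():
    calls = classify_replicons(_genome([2_000_000]))
    assert calls["r0"].replicon_class is RepliconClass.PRIMARY


def test_tie_for_largest_flagged():
    calls = classify_replicons(_genome([900_000, 900_000]))
    assert calls["r0"].replicon_class is RepliconClass.PRIMARY  # lexicographic
    assert calls["r1"].replicon_class is RepliconClass.SECONDARY
    assert calls["r0"].tie_flagged and calls["r1"].tie_flagged


def test_cutoff_is_strict():
    calls = classify_replicons(_genome([2_000_000, 800_000]))
    assert calls["r1"].replicon_class is RepliconClass.EXTRACHROMOSOMAL


def test_location_proportions_even_split():
    from cdgmap.replicons import genome_location_summary

    g = GenomeRecord("G1", replicons=[Replicon("c1", 3_000_000),
                                      Replicon("c2", 1_000_000)])
    calls = classify_replicons(g)
    cps = []
    for i in range(8):
        rid = "c1" if i < 4 else "c2"
        p = ProteinRecord(f"p{i}", 300,
                          hits=[DomainHit(f"p{i}", "PF00990", "GGDEF", 10, 100)])
        from cdgmap.model import GeneLocus
        p.locus = GeneLocus(rid, 1000 * (i + 1), 1000 * (i + 1) + 900, "+")
        cps.append(classify_protein(p))
    s = genome_location_summary(g, cps, calls)
    assert s.frac_non_primary == pytest.approx(0.5)
    assert s.frac_primary + s.frac_non_primary == pytest.approx(1.0)
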