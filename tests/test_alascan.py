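"""Alanine-scan design rule, capture normalization, disruption flags,
structure clustering vs a brute-force oracle, and epitope distances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iabkit.alascan import (
    BindingRecord,
    EctodomainConstruct,
    ScanVariant,
    cluster_on_structure,
    design_scan,
    epitope_distance,
    flag_disruptive,
    normalize_binding,
)
from iabkit.errors import MissingWT, NoCoordinates
from iabkit.fixtures import il2rb_ecd_synthetic, il2rg_ecd_synthetic
from iabkit.io import StructureModel

AA = "ACDEFGHIKLMNPQRSTVWY"


def _ecd(seq: str, start: int = 1) -> EctodomainConstruct:
    return EctodomainConstruct(
        id="t", sequence=seq,
        start_label=f"{seq[0]}{start}", end_label=f"{seq[-1]}{start + len(seq) - 1}")


def test_design_rule_examples():
    assert design_scan(_ecd("CCCC")) == []
    variants = design_scan(_ecd("AKA"))
    assert [(v.wild_type, v.substituted) for v in variants] == \
        [("A", "G"), ("K", "A"), ("A", "G")]
    assert [v.position for v in variants] == [1, 2, 3]


def test_scan_variant_rule_enforced():
    with pytest.raises(ValueError):
        ScanVariant(position=1, wild_type="A", substituted="A")
    with pytest.raises(ValueError):
        ScanVariant(position=1, wild_type="C", substituted="A")


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.text(alphabet=AA, min_size=2, max_size=80))
def test_scan_count_identity(seq):
    """|variants| + #Cys == length for any sequence (scan-count identity)."""
    ecd = _ecd(seq)
    assert len(design_scan(ecd)) + seq.count("C") == len(seq)


def test_construct_boundary_validation():
    with pytest.raises(ValueError):
        EctodomainConstruct(id="x", sequence="AKT", start_label="A27", end_label="T30")
    with pytest.raises(ValueError):
        EctodomainConstruct(id="x", sequence="AKT", start_label="G27", end_label="T29")


def test_synthetic_receptor_scan_counts():
    """The synthetic IL-2Rβ stand-in (214 aa, 8 Cys, A27-T240) yields 206
    variants; the IL-2Rγ stand-in spans L23-A262 (240 aa)."""
    beta = il2rb_ecd_synthetic()
    assert len(beta.sequence) == 214
    assert beta.sequence.count("C") == 8
    assert len(design_scan(beta)) == 206
    gamma = il2rg_ecd_synthetic()
    assert len(gamma.sequence) == 240
    assert len(design_scan(gamma)) == 240 - gamma.sequence.count("C")


def test_normalization_hand_computed():
    records = [
        BindingRecord("WT", 200.0, 100.0),
        BindingRecord("m1", 100.0, 50.0, position=1),   # same ratio as WT -> 1.0
        BindingRecord("m2", 100.0, 0.0, position=2),    # no binding -> 0.0
        BindingRecord("m3", 400.0, 100.0, position=3),  # half ratio -> 0.5
        BindingRecord("m4", 5.0, 50.0, position=4),     # capture below 10% WT
    ]
    table, excluded = normalize_binding(records)
    rel = dict(zip(table["variant_id"], table["relative"]))
    assert rel["WT"] == 1.0
    assert rel["m1"] == pytest.approx(1.0)
    assert rel["m2"] == 0.0
    assert rel["m3"] == pytest.approx(0.5)
    assert list(excluded["variant_id"]) == ["m4"]
    with pytest.raises(MissingWT):
        normalize_binding(records[1:])


def test_normalization_scale_invariance():
    records = [BindingRecord("WT", 200.0, 80.0)] + [
        BindingRecord(f"m{i}", 150.0 + 10 * i, 60.0 - 5 * i, position=i)
        for i in range(5)
    ]
    base, _ = normalize_binding(records)
    scaled_records = [
        BindingRecord(r.variant_id, r.capture_RU * 7.5, r.analyte_RU * 7.5, r.position)
        for r in records
    ]
    scaled, _ = normalize_binding(scaled_records)
    assert np.allclose(base["relative"], scaled["relative"])


def test_flag_threshold_semantics():
    table = pd.DataFrame({
        "variant_id": ["a", "b", "c"], "position": [1, 2, 3],
        "relative": [0.1, 0.5, 0.9],
    })
    assert len(flag_disruptive(table, rel_threshold=0.0)) == 0
    flags = flag_disruptive(table, rel_threshold=0.33)
    assert list(flags["variant_id"]) == ["a"]
    # monotone: lowering the threshold never adds flags
    low = set(flag_disruptive(table, 0.2)["variant_id"])
    high = set(flag_disruptive(table, 0.6)["variant_id"])
    assert low <= high


def _brute_force_components(positions, coords, cutoff):
    remaining = set(positions)
    comps = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        grew = True
        while grew:
            grew = False
            for p in list(remaining):
                if any(np.linalg.norm(coords[p] - coords[q]) <= cutoff for q in comp):
                    comp.add(p)
                    remaining.discard(p)
                    grew = True
        comps.append(tuple(sorted(comp)))
    return sorted(comps)


@pytest.mark.parametrize("cutoff", [0.0, 6.0, 10.0, 25.0])
def test_clustering_equals_brute_force(cutoff):
    """Single-linkage components match a transitive-closure oracle on random
    instances of up to 50 residues."""
    rng = np.random.default_rng(5)
    for trial in range(5):
        n = int(rng.integers(4, 50))
        positions = list(range(1, n + 1))
        coords = {p: rng.uniform(0, 40, size=3) for p in positions}
        structure = StructureModel({("A", str(p)): coords[p] for p in positions})
        table = pd.DataFrame({
            "variant_id": [f"m{p}" for p in positions],
            "position": positions,
            "relative": [0.1] * n,
        })
        emap = cluster_on_structure(table, structure, chain="A",
                                    cutoff_A=cutoff, min_cluster_size=1)
        assert sorted(emap.clusters) == _brute_force_components(positions, coords, cutoff)
        # clusters are disjoint and exhaustive
        flat = [p for c in emap.clusters for p in c]
        assert sorted(flat) == positions


def test_toy_cluster_with_outlier():
    coords = {("A", "1"): (0, 0, 0), ("A", "2"): (5, 0, 0), ("A", "3"): (0, 5, 0),
              ("A", "4"): (5, 5, 0), ("A", "5"): (300, 0, 0)}
    structure = StructureModel({k: np.array(v, float) for k, v in coords.items()})
    table = pd.DataFrame({"variant_id": list("abcde"), "position": [1, 2, 3, 4, 5],
                          "relative": [0.1] * 5})
    emap = cluster_on_structure(table, structure, chain="A", cutoff_A=6.0,
                                min_cluster_size=3)
    assert emap.epitope_positions == (1, 2, 3, 4)
    assert (5,) in emap.clusters       # sub-threshold cluster still reported
    # degenerate cutoff: all singletons, nothing called
    none = cluster_on_structure(table, structure, chain="A", cutoff_A=0.0,
                                min_cluster_size=3)
    assert none.epitope_positions == ()
    assert all(len(c) == 1 for c in none.clusters)


def test_single_flag_below_min_size():
    structure = StructureModel({("A", "1"): np.zeros(3)})
    table = pd.DataFrame({"variant_id": ["a"], "position": [1], "relative": [0.1]})
    emap = cluster_on_structure(table, structure, chain="A")
    assert emap.epitope_positions == ()
    assert emap.clusters == ((1,),)


def test_unresolvable_positions_reported_not_dropped():
    structure = StructureModel({("A", "1"): np.zeros(3), ("A", "2"): np.ones(3)})
    table = pd.DataFrame({"variant_id": ["a", "b", "c"], "position": [1, 2, 99],
                          "relative": [0.1, 0.1, 0.1]})
    emap = cluster_on_structure(table, structure, chain="A", min_cluster_size=1)
    assert emap.unresolved == (99,)
    with pytest.raises(NoCoordinates):
        cluster_on_structure(table.iloc[2:], structure, chain="A")


def test_epitope_distance_345_triangle():
    s = StructureModel({("A", "1"): np.array([0.0, 0.0, 0.0]),
                        ("B", "1"): np.array([30.0, 40.0, 0.0])})
    t1 = pd.DataFrame({"variant_id": ["a"], "position": [1], "relative": [0.1]})
    m1 = cluster_on_structure(t1, s, chain="A", min_cluster_size=1)
    m2 = cluster_on_structure(t1, s, chain="B", min_cluster_size=1)
    assert epitope_distance(m1, m2, s) == pytest.approx(5.0)
    assert epitope_distance(m2, m1, s) == epitope_distance(m1, m2, s)
    assert epitope_distance(m1, m1, s) == 0.0


def test_epitope_distance_centroid_by_hand():
    coords = {("A", "1"): np.array([0.0, 0, 0]), ("A", "2"): np.array([10.0, 0, 0]),
              ("B", "5"): np.array([5.0, 24.0, 0]), ("B", "6"): np.array([5.0, 30.0, 0])}
    s = StructureModel(coords)
    ta = pd.DataFrame({"variant_id": ["a", "b"], "position": [1, 2], "relative": [0.1] * 2})
    tb = pd.DataFrame({"variant_id": ["c", "d"], "position": [5, 6], "relative": [0.1] * 2})
    ma = cluster_on_structure(ta, s, chain="A", cutoff_A=12.0, min_cluster_size=2)
    mb = cluster_on_structure(tb, s, chain="B", cutoff_A=12.0, min_cluster_size=2)
    # centroids (5,0,0) and (5,27,0): distance 27 A = 2.7 nm
    assert epitope_distance(ma, mb, s) == pytest.approx(2.7)


def test_planted_epitope_recovered_end_to_end(toy_receptor):
    """Default-parameter pipeline recovers exactly the planted epitope from
    the synthetic scan; the spatially isolated decoy is excluded."""
    ecd, structure, records, epitope, decoy = toy_receptor
    table, excluded = normalize_binding(records)
    flagged = flag_disruptive(table)
    emap = cluster_on_structure(flagged, structure, chain="R")
    assert emap.epitope_positions == tuple(sorted(epitope))
    assert decoy in emap.flagged
    assert decoy not in emap.epitope_positions
    assert len(excluded) == 1
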