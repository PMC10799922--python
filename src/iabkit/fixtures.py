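"""Seeded synthetic-fixture generators.

Everything the toolkit analyzes can be generated here without downloads: a
panel of VH acceptor clones derived from the bundled references, a toy
receptor ectodomain with a planted spatial epitope plus the matching scan
dataset and Cα structure, a synthetic stand-in for the IL-2Rβ ectodomain,
and track-simulation presets.  Generation is fully deterministic: the same
seed reproduces byte-identical files.

The VH panel emulates the study design of grafting a fixed residue set onto
clones with varying conservation at the graft positions: half the clones
carry random substitutions only away from graft positions (so they need the
full set of mutations), the other half additionally carry some graft-target
residues already (so mutation counts vary clone to clone).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alascan import BindingRecord, EctodomainConstruct
from .grafting import load_graft_sets
from .io import StructureModel, write_fasta, write_structure_pdb
from .numbering import AntibodySequence, load_references

_AA_POOL = "ADEFGHIKLMNPQRSTVWY"  # no cysteine in random substitutions

# graft-coincidence plan: clone index -> (set planted, number of positions).
# Fixed a priori so per-clone mutation counts span the 4-8 range with a
# panel mean near 7 while half the clones need the full set.
_COINCIDENCE_PLAN = {5: ("iAb_aff1", 1), 6: ("iAb_aff2", 1), 7: ("iAb_aff1", 2),
                     8: ("iAb_aff2", 3), 9: ("iAb_aff1", 4)}


@dataclass(frozen=True)
class FixtureBundle:
    vh_panel: tuple[AntibodySequence, ...]
    toy_ecd: EctodomainConstruct
    toy_structure: StructureModel
    toy_scan_records: tuple[BindingRecord, ...]
    planted_epitope: tuple[int, ...]
    track_presets: dict
    seed: int


def make_vh_panel(seed: int, n_clones: int = 10) -> tuple[AntibodySequence, ...]:
    """Synthetic VH acceptor panel built from the bundled references.

    Each clone carries 3-5 seeded substitutions away from graft positions
    and CDRs; clones in the coincidence plan additionally carry graft-target
    residues at some graft positions.
    """
    rng = np.random.default_rng(seed)
    refs = load_references()
    graft_sets = load_graft_sets()
    graft_labels = set()
    for gs in graft_sets.values():
        graft_labels.update(gs.substitutions)
    anchors = {"22", "36", "92", "103"}

    panel = []
    for i in range(n_clones):
        ref = refs[i % len(refs)]
        residues = list(ref.sequence)
        mutable = [
            j for j, lab in enumerate(ref.kabat_positions)
            if lab not in graft_labels and lab not in anchors
            and ref.region_track()[j].startswith("FR") and residues[j] != "C"
        ]
        for j in rng.choice(mutable, size=int(rng.integers(3, 6)), replace=False):
            choices = [a for a in _AA_POOL if a != residues[j]]
            residues[j] = choices[int(rng.integers(len(choices)))]
        if i in _COINCIDENCE_PLAN:
            set_name, k = _COINCIDENCE_PLAN[i]
            gs = graft_sets[set_name]
            core = gs.labels(include_strengthening=False)
            planted = rng.choice(core, size=k, replace=False)
            index = {lab: j for j, lab in enumerate(ref.kabat_positions)}
            for lab in planted:
                residues[index[lab]] = gs.substitutions[lab]
        panel.append(AntibodySequence(
            id=f"clone_{i + 1:02d}", chain_kind="heavy", residues="".join(residues)
        ))
    return tuple(panel)


def il2rb_ecd_synthetic() -> EctodomainConstruct:
    """Synthetic stand-in for the human IL-2Rβ extracellular domain.

    This is NOT the canonical receptor sequence (which would require a
    database download): it is a deterministic synthetic 214-residue chain
    with the documented construct boundaries (A27-T240) and eight cysteines,
    which is all the scan-design arithmetic depends on.
    """
    rng = np.random.default_rng(21474)
    length = 240 - 27 + 1  # 214
    cys_positions = {30, 59, 62, 96, 122, 168, 183, 191}  # full-length numbering
    residues = []
    for pos in range(27, 241):
        if pos == 27:
            residues.append("A")
        elif pos == 240:
            residues.append("T")
        elif pos in cys_positions:
            residues.append("C")
        else:
            residues.append(_AA_POOL[int(rng.integers(len(_AA_POOL)))])
    return EctodomainConstruct(
        id="il2rb_ecd_synthetic", sequence="".join(residues),
        start_label="A27", end_label="T240", tag="His6",
    )


def il2rg_ecd_synthetic() -> EctodomainConstruct:
    """Synthetic stand-in for the IL-2Rγ ectodomain (L23-A262, 240 residues,
    six cysteines); same caveats as :func:`il2rb_ecd_synthetic`."""
    rng = np.random.default_rng(21475)
    cys_positions = {62, 70, 104, 115, 160, 182}
    residues = []
    for pos in range(23, 263):
        if pos == 23:
            residues.append("L")
        elif pos == 262:
            residues.append("A")
        elif pos in cys_positions:
            residues.append("C")
        else:
            residues.append(_AA_POOL[int(rng.integers(len(_AA_POOL)))])
    return EctodomainConstruct(
        id="il2rg_ecd_synthetic", sequence="".join(residues),
        start_label="L23", end_label="A262", tag="His6",
    )


def make_toy_receptor(seed: int):
    """Toy 60-residue ECD (A27-T86) with a planted 5-residue spatial epitope
    plus one isolated disruptive decoy.

    Returns ``(ecd, structure, records, epitope_positions, decoy_position)``.
    The epitope residues sit in a tight spatial blob (pairwise < 8 Å) far
    from the rest of the chain, which is laid out as a straight line so
    nothing else clusters; the decoy is disruptive in the scan but spatially
    isolated, so default clustering (min size 3) excludes it.
    """
    rng = np.random.default_rng(seed)
    length = 60
    start = 27
    epitope = (35, 48, 52, 61, 70)
    decoy = 80
    residues = []
    for pos in range(start, start + length):
        if pos == start:
            residues.append("A")
        elif pos == start + length - 1:
            residues.append("T")
        else:
            residues.append(_AA_POOL[int(rng.integers(len(_AA_POOL)))])
    ecd = EctodomainConstruct(
        id="toy_receptor", sequence="".join(residues),
        start_label=f"A{start}", end_label=f"T{start + length - 1}",
    )

    coords = {}
    blob_center = np.array([0.0, 120.0, 0.0])
    blob_offsets = [(0, 0, 0), (3.5, 0, 0), (0, 3.5, 0), (0, 0, 3.5), (2.5, 2.5, 0)]
    for k, pos in enumerate(range(start, start + length)):
        if pos in epitope:
            coords[("R", str(pos))] = blob_center + np.array(blob_offsets[epitope.index(pos)])
        else:
            coords[("R", str(pos))] = np.array([12.0 * k, 0.0, 0.0])
    structure = StructureModel(coords, source_id="toy_receptor_synthetic")

    wt_capture = 200.0
    records = [BindingRecord(variant_id="WT", capture_RU=wt_capture, analyte_RU=100.0)]
    disrupted = set(epitope) | {decoy}
    for pos in range(start, start + length):
        wt_aa = ecd.residue_at(pos)
        if wt_aa == "C":
            continue
        sub = "G" if wt_aa == "A" else "A"
        capture = float(wt_capture * rng.uniform(0.8, 1.2))
        if pos == start + 5:          # one non-captured mutant, excluded downstream
            capture = 2.0
        if pos in disrupted:
            relative = float(rng.uniform(0.02, 0.20))
        else:
            relative = float(rng.uniform(0.70, 1.10))
        analyte = relative * (100.0 / wt_capture) * capture
        records.append(BindingRecord(
            variant_id=f"{wt_aa}{pos}{sub}", capture_RU=capture,
            analyte_RU=analyte, position=pos,
        ))
    return ecd, structure, tuple(records), epitope, decoy


def default_track_presets(seed: int) -> dict:
    """Simulation presets for the two-condition intensity comparison:
    all-monomer versus half 4-mer, matched otherwise."""
    return {
        "monomeric": {"D_um2_s": 0.1, "n_particles": 100, "n_frames": 100,
                      "multimer_fraction": 0.0, "multimer_size": 4,
                      "sigma_nm": 20.0, "unit_intensity": 100.0,
                      "background": 50.0, "seed": seed},
        "clustered": {"D_um2_s": 0.1, "n_particles": 100, "n_frames": 100,
                      "multimer_fraction": 0.5, "multimer_size": 4,
                      "sigma_nm": 20.0, "unit_intensity": 100.0,
                      "background": 50.0, "seed": seed + 1},
    }


def make_fixtures(seed: int, outdir: str | Path | None = None) -> FixtureBundle:
    """Generate the full fixture bundle; optionally write it to ``outdir``
    (FASTA, CSV, PDB, JSON — byte-identical for identical seeds)."""
    panel = make_vh_panel(seed)
    ecd, structure, records, epitope, _decoy = make_toy_receptor(seed + 1)
    presets = default_track_presets(seed + 2)
    bundle = FixtureBundle(
        vh_panel=panel, toy_ecd=ecd, toy_structure=structure,
        toy_scan_records=records, planted_epitope=epitope,
        track_presets=presets, seed=seed,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(panel, outdir / "vh_panel.fasta")
        write_structure_pdb(structure, outdir / "toy_receptor.pdb")
        pd.DataFrame(
            [{"variant_id": r.variant_id,
              "position": "" if r.position is None else r.position,
              "capture_RU": round(r.capture_RU, 6),
              "analyte_RU": round(r.analyte_RU, 6)} for r in records]
        ).to_csv(outdir / "toy_scan.csv", index=False)
        (outdir / "track_presets.json").write_text(
            json.dumps(presets, indent=2, sort_keys=True) + "\n")
        (outdir / "toy_ecd.fasta").write_text(
            f">{ecd.id} {ecd.start_label}-{ecd.end_label}\n{ecd.sequence}\n")
    return bundle
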