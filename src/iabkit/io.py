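"""Readers and writers for the formats the toolkit consumes and emits.

FASTA goes through Biopython, structure coordinates through gemmi (legacy
PDB and mmCIF, alpha-carbons only), tabular data through pandas.  All
writers are deterministic: stable ordering and fixed float formatting.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import MalformedRecord, NoCAAtoms, UnknownChain
from .numbering import AMINO_ACIDS, AntibodySequence

logger = logging.getLogger("iabkit")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, chain_kind: str = "heavy") -> list[AntibodySequence]:
    """Read antibody sequences from FASTA; ids are parsed up to the first
    whitespace.  Mixed-case input is normalized to uppercase with a log note."""
    sequences = []
    for i, record in enumerate(SeqIO.parse(str(path), "fasta")):
        raw = str(record.seq)
        if raw != raw.upper():
            logger.info("record %s: lowercase residues normalized to uppercase", record.id)
            raw = raw.upper()
        bad = set(raw) - AMINO_ACIDS
        if bad:
            raise MalformedRecord(
                f"record {i + 1} ({record.id}): non-canonical residues {sorted(bad)}"
            )
        try:
            sequences.append(AntibodySequence(id=record.id, chain_kind=chain_kind, residues=raw))
        except ValueError as exc:
            raise MalformedRecord(f"record {i + 1} ({record.id}): {exc}") from exc
    return sequences


def write_fasta(sequences: Iterable[AntibodySequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# structures (Cα only)
# ---------------------------------------------------------------------------

class StructureModel:
    """Alpha-carbon coordinates keyed by (chain, residue label).

    Residue labels include the insertion code when present ("100A").
    Coordinates are in Angstroms.
    """

    def __init__(self, coords: Mapping[tuple[str, str], np.ndarray], source_id: str = ""):
        self.coords = {k: np.asarray(v, dtype=float) for k, v in coords.items()}
        self.source_id = source_id
        for key, xyz in self.coords.items():
            if not np.all(np.isfinite(xyz)):
                raise ValueError(f"non-finite coordinate at {key}")

    def __len__(self) -> int:
        return len(self.coords)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.coords

    def get(self, chain: str, residue: str | int) -> np.ndarray | None:
        return self.coords.get((chain, str(residue)))

    def chains(self) -> set[str]:
        return {c for c, _ in self.coords}


def read_structure_ca(path: str | Path, chains: Sequence[str] | None = None) -> StructureModel:
    """Read one Cα per residue from a PDB or mmCIF file.

    Altlocs are resolved by highest occupancy, then first listed.  ``chains``
    restricts to the named chains; asking only for absent chains raises
    :class:`UnknownChain`.
    """
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    if len(structure) == 0:
        raise NoCAAtoms(f"{path}: empty structure")
    model = structure[0]
    available = {chain.name for chain in model}
    if chains is not None:
        missing = set(chains) - available
        if missing and not (set(chains) & available):
            raise UnknownChain(f"{path}: chains {sorted(missing)} not in {sorted(available)}")
    coords: dict[tuple[str, str], np.ndarray] = {}
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for residue in chain:
            best = None
            for atom in residue:
                if atom.name != "CA":
                    continue
                if best is None or atom.occ > best.occ:
                    best = atom
            if best is None:
                continue
            label = str(residue.seqid.num) + (residue.seqid.icode.strip() or "")
            key = (chain.name, label)
            if key not in coords:  # first-listed wins among duplicates
                coords[key] = np.array([best.pos.x, best.pos.y, best.pos.z])
    if not coords:
        raise NoCAAtoms(f"{path}: no alpha-carbon atoms in requested chains")
    return StructureModel(coords, source_id=Path(path).stem)


def write_structure_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a minimal Cα-only PDB file (one ATOM record per residue)."""
    lines = []
    serial = 1
    def sort_key(item):
        (chain, label), _ = item
        num = "".join(ch for ch in label if ch.isdigit())
        ins = label[len(num):]
        return (chain, int(num), ins)
    for (chain, label), xyz in sorted(model.coords.items(), key=sort_key):
        num = "".join(ch for ch in label if ch.isdigit())
        icode = label[len(num):] or " "
        lines.append(
            f"ATOM  {serial:5d}  CA  GLY {chain:1.1s}{int(num):4d}{icode:1.1s}   "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# tables and metadata sidecars
# ---------------------------------------------------------------------------

def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", dtype={"kabat_label": str})


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False, float_format="%.6g")


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_metadata_sidecar(
    output_path: str | Path,
    parameters: Mapping,
    seeds: Mapping | None = None,
    inputs: Sequence[str | Path] = (),
) -> Path:
    """Write a JSON sidecar recording parameters, seeds and input hashes
    next to an output file (``<output>.meta.json``)."""
    from . import __version__

    sidecar = Path(str(output_path) + ".meta.json")
    payload = {
        "iabkit_version": __version__,
        "parameters": {k: _jsonable(v) for k, v in parameters.items()},
        "seeds": dict(seeds or {}),
        "input_hashes": {str(p): file_sha256(p) for p in inputs if Path(p).exists()},
    }
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return sidecar


def _jsonable(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, Path):
        return str(value)
    return value
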