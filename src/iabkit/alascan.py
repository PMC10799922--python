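"""Alanine-scan design, SPR normalization, and structure-based epitope calls.

The scan rule is the standard one for receptor ectodomains: every non-
cysteine residue is mutated to alanine, and positions that are already
alanine are mutated to glycine (cysteines are never touched, to preserve
disulfides).  SPR binding records are normalized by ligand capture level and
expressed relative to wild type; positions whose relative binding falls
below a threshold are "disruptive".  Epitopes are called by single-linkage
clustering of disruptive positions on the receptor structure: connected
components of the graph linking alpha-carbons within a distance cutoff, with
small components discarded.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .errors import AllExcluded, MissingWT, NoCoordinates
from .io import StructureModel
from .numbering import AMINO_ACIDS

logger = logging.getLogger("iabkit")

_BOUNDARY = re.compile(r"^([A-Z])(\d+)$")


@dataclass(frozen=True)
class EctodomainConstruct:
    """A receptor ECD with its boundaries in full-length numbering.

    Boundary labels are like "A27" / "T240": the residue letter must match
    the sequence ends and the length must equal end - start + 1.
    """

    id: str
    sequence: str
    start_label: str
    end_label: str
    tag: str = ""

    def __post_init__(self):
        s_aa, s_idx = _parse_boundary(self.start_label)
        e_aa, e_idx = _parse_boundary(self.end_label)
        if len(self.sequence) != e_idx - s_idx + 1:
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"{self.end_label}-{self.start_label} span {e_idx - s_idx + 1}"
            )
        if self.sequence[0] != s_aa or self.sequence[-1] != e_aa:
            raise ValueError(f"{self.id}: boundary residues do not match sequence ends")

    @property
    def start_index(self) -> int:
        return _parse_boundary(self.start_label)[1]

    @property
    def end_index(self) -> int:
        return _parse_boundary(self.end_label)[1]

    def residue_at(self, position: int) -> str:
        return self.sequence[position - self.start_index]


def _parse_boundary(label: str) -> tuple[str, int]:
    m = _BOUNDARY.match(label)
    if not m:
        raise ValueError(f"malformed boundary label {label!r} (expected like 'A27')")
    return m.group(1), int(m.group(2))


@dataclass(frozen=True)
class ScanVariant:
    """One alanine-scan point mutation in full-length numbering."""

    position: int
    wild_type: str
    substituted: str

    def __post_init__(self):
        if self.wild_type == "C":
            raise ValueError("cysteines are never mutated in the scan")
        expected = "G" if self.wild_type == "A" else "A"
        if self.substituted != expected:
            raise ValueError(
                f"{self.wild_type}{self.position}: substitution must be {expected}"
            )

    @property
    def variant_id(self) -> str:
        return f"{self.wild_type}{self.position}{self.substituted}"


def design_scan(ecd: EctodomainConstruct) -> list[ScanVariant]:
    """One variant per non-cysteine residue of the ECD (Ala, or Gly where the
    wild type is already Ala).  The count is length minus the cysteine
    count."""
    variants = []
    for offset, aa in enumerate(ecd.sequence):
        if aa == "C":
            continue
        variants.append(
            ScanVariant(
                position=ecd.start_index + offset,
                wild_type=aa,
                substituted="G" if aa == "A" else "A",
            )
        )
    return variants


# ---------------------------------------------------------------------------
# SPR normalization and disruption calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingRecord:
    """One SPR cycle: variant capture level and analyte response at the end
    of the association phase, both in response units."""

    variant_id: str
    capture_RU: float
    analyte_RU: float
    position: int | None = None

    def __post_init__(self):
        if self.capture_RU < 0 or self.analyte_RU < 0:
            raise ValueError(f"{self.variant_id}: negative response units")


def normalize_binding(
    records: Sequence[BindingRecord],
    wt_id: str = "WT",
    min_capture: float | None = None,
    min_capture_fraction: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Capture-normalized, WT-relative binding.

    ``normalized = analyte/capture``; ``relative = normalized / normalized_WT``
    so the wild type is exactly 1.  Records with capture at or below the
    threshold (default: 10% of the WT capture level) are excluded and
    returned separately.

    Returns ``(table, excluded)`` DataFrames with columns
    (variant_id, position, capture_RU, analyte_RU, normalized, relative).
    """
    wt = [r for r in records if r.variant_id == wt_id]
    if not wt:
        raise MissingWT(f"no record with variant_id {wt_id!r}")
    wt = wt[0]
    if min_capture is None:
        min_capture = min_capture_fraction * wt.capture_RU
    if wt.capture_RU <= min_capture or wt.capture_RU == 0:
        raise MissingWT(f"WT capture {wt.capture_RU} RU at or below threshold {min_capture}")
    wt_norm = wt.analyte_RU / wt.capture_RU
    if wt_norm == 0:
        raise MissingWT("WT analyte response is zero; cannot normalize")

    rows, dropped = [], []
    for r in records:
        row = {
            "variant_id": r.variant_id,
            "position": r.position,
            "capture_RU": r.capture_RU,
            "analyte_RU": r.analyte_RU,
        }
        if r.capture_RU <= min_capture:
            dropped.append(row)
            continue
        norm = r.analyte_RU / r.capture_RU
        row["normalized"] = norm
        row["relative"] = norm / wt_norm
        rows.append(row)
    if not rows:
        raise AllExcluded("every record fell below the capture threshold")
    cols = ["variant_id", "position", "capture_RU", "analyte_RU", "normalized", "relative"]
    table = pd.DataFrame(rows, columns=cols)
    excluded = pd.DataFrame(dropped, columns=cols[:4])
    return table, excluded


def flag_disruptive(table: pd.DataFrame, rel_threshold: float = 0.33) -> pd.DataFrame:
    """Rows of the normalized table whose relative binding is strictly below
    ``rel_threshold`` (the wild type itself is never flagged)."""
    mask = (table["relative"] < rel_threshold) & (table["variant_id"] != "WT")
    return table.loc[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# structure clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpitopeMap:
    """Structure-clustered disruptive positions.

    ``clusters`` holds every connected component over flagged+resolvable
    positions (disjoint, exhaustive); ``epitope_positions`` is the union of
    clusters meeting the minimum size.  ``unresolved`` lists flagged
    positions without a coordinate.
    """

    flagged: tuple[int, ...]
    relative_binding: Mapping[int, float]
    clusters: tuple[tuple[int, ...], ...]
    epitope_positions: tuple[int, ...]
    unresolved: tuple[int, ...]
    structure_id: str
    chain: str
    cutoff_A: float
    min_cluster_size: int
    rel_threshold: float | None = None

    def centroid(self, structure: StructureModel, offset: int = 0) -> np.ndarray:
        coords = [structure.get(self.chain, p + offset) for p in self.epitope_positions]
        coords = [c for c in coords if c is not None]
        if not coords:
            raise NoCoordinates("no epitope position resolves to a coordinate")
        return np.mean(coords, axis=0)


def cluster_on_structure(
    flagged_table: pd.DataFrame,
    structure: StructureModel,
    chain: str,
    cutoff_A: float = 10.0,
    min_cluster_size: int = 3,
    residue_offset: int = 0,
) -> EpitopeMap:
    """Single-linkage clustering of flagged positions on the structure.

    Positions are mapped to (chain, position + residue_offset) alpha-carbon
    coordinates; components of the <= cutoff adjacency graph are the
    clusters, and components smaller than ``min_cluster_size`` are excluded
    from the called epitope (but still reported).  Flagged positions that do
    not resolve to a coordinate are reported in ``unresolved``, never
    dropped silently; if none resolve, :class:`NoCoordinates` is raised.
    """
    positions = [int(p) for p in flagged_table["position"].dropna()]
    rel = dict(zip(positions, flagged_table.loc[flagged_table["position"].notna(), "relative"]))
    resolved, unresolved, coords = [], [], []
    for p in positions:
        xyz = structure.get(chain, p + residue_offset)
        if xyz is None:
            unresolved.append(p)
        else:
            resolved.append(p)
            coords.append(xyz)
    if unresolved:
        logger.warning("flagged positions without coordinates on chain %s: %s",
                       chain, unresolved)
    if not resolved:
        raise NoCoordinates(f"no flagged position resolves on chain {chain}")

    xyz = np.asarray(coords)
    dist = cdist(xyz, xyz)
    adjacency = csr_matrix(dist <= cutoff_A)
    n_comp, labels = connected_components(adjacency, directed=False)
    clusters = []
    for k in range(n_comp):
        members = tuple(sorted(p for p, lab in zip(resolved, labels) if lab == k))
        clusters.append(members)
    clusters.sort(key=lambda c: (-len(c), c))
    epitope = tuple(
        sorted(p for c in clusters if len(c) >= min_cluster_size for p in c)
    )
    return EpitopeMap(
        flagged=tuple(sorted(positions)),
        relative_binding=rel,
        clusters=tuple(clusters),
        epitope_positions=epitope,
        unresolved=tuple(sorted(unresolved)),
        structure_id=structure.source_id,
        chain=chain,
        cutoff_A=cutoff_A,
        min_cluster_size=min_cluster_size,
    )


def epitope_distance(
    map_a: EpitopeMap,
    map_b: EpitopeMap,
    structure: StructureModel,
    offset_a: int = 0,
    offset_b: int = 0,
) -> float:
    """Distance in nm between the alpha-carbon centroids of two called
    epitopes on a (complex) structure.  Symmetric by construction."""
    ca = map_a.centroid(structure, offset_a)
    cb = map_b.centroid(structure, offset_b)
    return float(np.linalg.norm(ca - cb) / 10.0)  # Angstrom -> nm


def epitope_annotation_table(emap: EpitopeMap) -> pd.DataFrame:
    """Per-residue annotation (chain, resi, value) for structure-viewer
    coloring; value is the relative binding of the flagged position."""
    rows = [
        {"chain": emap.chain, "resi": p,
         "value": float(emap.relative_binding.get(p, np.nan)),
         "in_epitope": p in set(emap.epitope_positions)}
        for p in emap.flagged
    ]
    return pd.DataFrame(rows, columns=["chain", "resi", "value", "in_epitope"])
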