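"""Residue-set grafting onto numbered VH domains and rarity analysis.

A graft set is a named mapping of Kabat positions to target residues.  The
three shipped sets (iAb_dx, iAb_aff1, iAb_aff2) promote the compact i-shaped
IgG conformation: iAb_dx drives VH domain exchange and is the only set
allowed a single CDRH2 position; the two affinity-interface sets place
hydrophobic residues on the framework beta-strands A/B/D/E that form the
Fab-Fab contact, and each carries two optional "strengthening" substitutions
that are excluded unless requested.  Grafting substitutes — it never inserts
or deletes — so the engineered sequence is always the same length as the
parent and the CDRs of the affinity sets are untouched.

Mutation rarity is scored against a positional amino-acid frequency table
(abYsis-style): a mutation is rare when its target residue occurs at that
Kabat position in fewer than 1% of deposited human sequences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInput,
    MissingPosition,
    UnknownFormat,
    UnknownLabel,
    UnresolvedPosition,
)
from .numbering import AMINO_ACIDS, NumberedDomain, label_sort_key

logger = logging.getLogger("iabkit")

GRAFT_SET_NAMES = ("iAb_dx", "iAb_aff1", "iAb_aff2")

#: Fab valency of each antibody format discussed in the i-shaped antibody work
FORMAT_VALENCY = {
    "Fab": 1,
    "IgG": 2,
    "F(ab')2": 2,
    "iAb_IgG": 2,
    "contorsbody": 2,
    "hexamer": 12,
}


def format_valency(format_name: str) -> int:
    """Number of Fab arms presented by a named antibody format."""
    try:
        return FORMAT_VALENCY[format_name]
    except KeyError:
        raise UnknownFormat(
            f"unknown format {format_name!r}; known: {sorted(FORMAT_VALENCY)}"
        )


@dataclass(frozen=True)
class GraftSet:
    """A named Kabat-position -> residue substitution set."""

    name: str
    substitutions: Mapping[str, str]
    strengthening: frozenset[str] = frozenset()
    cdr_exception_labels: frozenset[str] = frozenset()

    def __post_init__(self):
        for label, res in self.substitutions.items():
            if res not in AMINO_ACIDS:
                raise ValueError(f"{self.name}: non-canonical target {res!r} at {label}")
        for group, labels in (("strengthening", self.strengthening),
                              ("cdr_exception", self.cdr_exception_labels)):
            extra = set(labels) - set(self.substitutions)
            if extra:
                raise ValueError(f"{self.name}: {group} labels not in set: {sorted(extra)}")

    def labels(self, include_strengthening: bool = False) -> list[str]:
        labs = [
            l for l in self.substitutions
            if include_strengthening or l not in self.strengthening
        ]
        return sorted(labs, key=label_sort_key)


@dataclass(frozen=True)
class MutationRecord:
    kabat_label: str
    parent_residue: str
    new_residue: str
    region: str
    frequency: float | None = None
    rare: bool | None = None


@dataclass(frozen=True)
class GraftResult:
    """Outcome of engrafting one residue set onto one acceptor domain."""

    parent_id: str
    graft_name: str
    grafted_sequence: str
    mutations: tuple[MutationRecord, ...]
    include_strengthening: bool = False

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)

    @property
    def n_cdr_mutations(self) -> int:
        return sum(1 for m in self.mutations if m.region.startswith("CDR"))


def load_graft_sets(path=None) -> dict[str, GraftSet]:
    """Load graft sets from a TSV (set_name, kabat_label, target_residue,
    strengthening_flag, cdr_exception_flag).  Defaults to the bundled
    synthetic reconstruction of the published sets."""
    if path is None:
        source = resources.files("iabkit.data").joinpath("graft_sets_synthetic.tsv")
        df = pd.read_csv(source.open(), sep="\t", comment="#", dtype={"kabat_label": str})
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"kabat_label": str})
    sets = {}
    for name, group in df.groupby("set_name", sort=False):
        subs = dict(zip(group["kabat_label"], group["target_residue"]))
        strengthening = frozenset(group.loc[group["strengthening_flag"] == 1, "kabat_label"])
        cdr_exc = frozenset(group.loc[group["cdr_exception_flag"] == 1, "kabat_label"])
        sets[name] = GraftSet(
            name=name, substitutions=subs,
            strengthening=strengthening, cdr_exception_labels=cdr_exc,
        )
    return sets


def apply_graft(
    domain: NumberedDomain,
    graft: GraftSet,
    include_strengthening: bool = False,
) -> GraftResult:
    """Substitute the graft-set residues into a numbered acceptor domain.

    Positions already carrying the target residue produce no mutation record
    (the operation is idempotent).  A required label that does not resolve in
    the domain raises :class:`UnresolvedPosition`.
    """
    wanted = graft.labels(include_strengthening)
    missing = [l for l in wanted if l not in domain]
    if missing:
        raise UnresolvedPosition(
            f"{domain.source_id}: graft {graft.name} labels absent from domain: {missing}"
        )
    residues = list(domain.residues)
    index = {lab: i for i, lab in enumerate(domain.labels)}
    mutations = []
    for label in wanted:
        i = index[label]
        target = graft.substitutions[label]
        if residues[i] != target:
            mutations.append(
                MutationRecord(
                    kabat_label=label,
                    parent_residue=residues[i],
                    new_residue=target,
                    region=domain.regions[i],
                )
            )
            residues[i] = target
    return GraftResult(
        parent_id=domain.source_id,
        graft_name=graft.name,
        grafted_sequence="".join(residues),
        mutations=tuple(mutations),
        include_strengthening=include_strengthening,
    )


def summarize_grafts(results: Sequence[GraftResult]) -> pd.DataFrame:
    """Per-clone mutation counts with per-set and overall means.

    Returns a DataFrame with one row per input result plus the grand mean in
    ``df.attrs``: ``overall_mean`` (arithmetic mean of n_mutations) and
    ``per_set_mean``.
    """
    if not results:
        raise EmptyInput("summarize_grafts requires at least one result")
    df = pd.DataFrame(
        {
            "clone": [r.parent_id for r in results],
            "graft_set": [r.graft_name for r in results],
            "n_mutations": [r.n_mutations for r in results],
            "n_cdr_mutations": [r.n_cdr_mutations for r in results],
        }
    )
    df.attrs["overall_mean"] = float(df["n_mutations"].mean())
    df.attrs["per_set_mean"] = df.groupby("graft_set")["n_mutations"].mean().to_dict()
    return df


# ---------------------------------------------------------------------------
# positional frequencies, rarity, logos
# ---------------------------------------------------------------------------

class PositionFrequencyTable:
    """Relative amino-acid frequencies per Kabat position.

    Frequencies at every position must sum to 1 (within 1e-9) and lie in
    [0, 1].
    """

    def __init__(self, frequencies: Mapping[str, Mapping[str, float]], source: str = "",
                 version: str = "", n_sequences: int | None = None):
        self.frequencies = {str(k): dict(v) for k, v in frequencies.items()}
        self.source = source
        self.version = version
        self.n_sequences = n_sequences
        for label, dist in self.frequencies.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {label} sum to {total!r}, not 1")
            if any(not 0.0 <= f <= 1.0 for f in dist.values()):
                raise ValueError(f"frequency outside [0,1] at {label}")

    def __contains__(self, label: str) -> bool:
        return str(label) in self.frequencies

    def frequency(self, label: str, residue: str) -> float:
        try:
            dist = self.frequencies[str(label)]
        except KeyError:
            raise MissingPosition(f"frequency table lacks Kabat position {label!r}")
        return dist.get(residue, 0.0)

    @classmethod
    def from_tsv(cls, path=None) -> "PositionFrequencyTable":
        """Read a (kabat_label, residue, frequency) TSV; defaults to the
        bundled synthetic toy table."""
        if path is None:
            source = resources.files("iabkit.data").joinpath("frequency_table_synthetic.tsv")
            df = pd.read_csv(source.open(), sep="\t", comment="#", dtype={"kabat_label": str})
            meta = "iabkit_toy"
        else:
            df = pd.read_csv(path, sep="\t", comment="#", dtype={"kabat_label": str})
            meta = str(path)
        freqs: dict[str, dict[str, float]] = {}
        for _, row in df.iterrows():
            freqs.setdefault(row["kabat_label"], {})[row["residue"]] = float(row["frequency"])
        return cls(freqs, source=meta)


def rarity_flags(
    result: GraftResult,
    table: PositionFrequencyTable,
    threshold: float = 0.01,
) -> GraftResult:
    """Annotate each mutation with the frequency of its new residue and a
    rarity flag (frequency strictly below ``threshold``).

    A mutated label missing from the table is reported with a warning and
    left unflagged (frequency ``None``).
    """
    annotated = []
    for m in result.mutations:
        if m.kabat_label in table:
            f = table.frequency(m.kabat_label, m.new_residue)
            annotated.append(replace(m, frequency=f, rare=f < threshold))
        else:
            logger.warning(
                "%s %s: Kabat position %s absent from frequency table; mutation unflagged",
                result.parent_id, result.graft_name, m.kabat_label,
            )
            annotated.append(replace(m, frequency=None, rare=None))
    return replace(result, mutations=tuple(annotated))


def logo_matrix(table: PositionFrequencyTable, labels: Sequence[str]) -> pd.DataFrame:
    """Sequence-logo letter heights (bits) for the given Kabat positions.

    Column information content is ``IC = log2(20) - H`` with ``H`` the
    Shannon entropy of the position's distribution; each letter's height is
    ``frequency x IC``, so heights are non-negative and sum to IC per column.
    Rows are amino acids, columns are labels.
    """
    unknown = [l for l in labels if l not in table]
    if unknown:
        raise UnknownLabel(f"labels absent from frequency table: {unknown}")
    aas = sorted(AMINO_ACIDS)
    data = np.zeros((len(aas), len(labels)))
    for j, label in enumerate(labels):
        dist = table.frequencies[str(label)]
        h = -sum(f * math.log2(f) for f in dist.values() if f > 0.0)
        ic = math.log2(20) - h
        for i, aa in enumerate(aas):
            data[i, j] = dist.get(aa, 0.0) * ic
    return pd.DataFrame(data, index=aas, columns=list(labels))
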