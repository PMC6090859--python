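"""Ortholog-group clade partitioning and the conserved CAM-specific screen.

Every ortholog group gets a clade label formed from the photosynthesis types
(NVP, C3, CAM, C4) of the species it contains — e.g. ``NVP:C3:CAM:C4`` for a
group spanning all four types, ``CAM-only`` for a group restricted to CAM
species.  A type counts as present as soon as one gene from one species of
that type is in the group.

The CAM-specific screen takes candidate genes drawn from the intersection of
CAM-only ortholog groups and CAM-only tribes and keeps those with a homolog
in every independent CAM lineage of an extended panel but in none of its
non-CAM species.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PHOTOSYNTHESIS_TYPES",
    "OrthologGroup",
    "clade_label",
    "partition_groups",
    "cam_specific_screen",
    "canonical_species",
]

#: canonical ordering of photosynthesis types in clade labels
PHOTOSYNTHESIS_TYPES = ("NVP", "C3", "CAM", "C4")


def canonical_species(label: str) -> str:
    """Case-insensitive, whitespace-stripped species label."""
    return label.strip().lower()


@dataclass(frozen=True)
class OrthologGroup:
    """One ortholog group: species label -> member gene ids."""

    group_id: str
    members: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        genes = [g for gs in self.members.values() for g in gs]
        if len(genes) < 2:
            raise ValueError(f"{self.group_id}: groups need >= 2 genes")
        dup = [g for g, c in Counter(genes).items() if c > 1]
        if dup:
            raise ValueError(f"{self.group_id}: duplicate gene ids {dup[:3]}")

    def species(self) -> tuple[str, ...]:
        return tuple(self.members)

    def genes(self) -> tuple[str, ...]:
        return tuple(g for gs in self.members.values() for g in gs)


def clade_label(group: OrthologGroup, types: Mapping[str, str]) -> str:
    """Clade label of a group from the photosynthesis types of its species.

    Types are ordered NVP, C3, CAM, C4 and joined with ``:``; a group whose
    species all share one type is labelled ``<type>-only``.
    """
    canon = {canonical_species(s): t for s, t in types.items()}
    present: set[str] = set()
    for sp in group.species():
        key = canonical_species(sp)
        if key not in canon:
            raise KeyError(f"{group.group_id}: species {sp!r} has no type mapping")
        t = canon[key]
        if t not in PHOTOSYNTHESIS_TYPES:
            raise ValueError(f"unknown photosynthesis type {t!r} for {sp!r}")
        present.add(t)
    ordered = [t for t in PHOTOSYNTHESIS_TYPES if t in present]
    if len(ordered) == 1:
        return f"{ordered[0]}-only"
    return ":".join(ordered)


def partition_groups(
    groups: Sequence[OrthologGroup], types: Mapping[str, str]
) -> tuple[dict[str, list[OrthologGroup]], pd.DataFrame]:
    """Partition groups by clade label; tabulate per-species gene fractions.

    Returns (clade -> groups, per-species table).  The table has one row per
    species and one column per clade; each cell is the fraction of that
    species' clustered genes falling in groups of that clade, so rows sum
    to 1.
    """
    by_clade: dict[str, list[OrthologGroup]] = {}
    gene_counts: dict[str, Counter] = {}
    for g in groups:
        label = clade_label(g, types)
        by_clade.setdefault(label, []).append(g)
        for sp, genes in g.members.items():
            gene_counts.setdefault(sp, Counter())[label] += len(genes)
    clade_order = sorted(by_clade)
    rows = {}
    for sp, counts in sorted(gene_counts.items()):
        total = sum(counts.values())
        rows[sp] = {c: counts.get(c, 0) / total for c in clade_order}
    table = pd.DataFrame.from_dict(rows, orient="index", columns=clade_order).fillna(0.0)
    table.index.name = "species"
    return by_clade, table


def cam_specific_screen(
    candidates: Iterable[str],
    presence: pd.DataFrame,
    cam_lineages: Sequence[Sequence[str]],
    non_cam: Sequence[str],
) -> list[str]:
    """Screen candidate genes for conservation across independent CAM lineages.

    ``presence`` is a boolean gene x panel-species matrix (homolog detected at
    the BLASTp E-value cutoff).  A candidate passes iff it has a homolog in at
    least one species of *each* CAM lineage and in *none* of the non-CAM panel
    species.  Candidates are expected to come from the intersection of
    CAM-only ortholog groups and CAM-only tribes; membership is the caller's
    input, not recomputed here.
    """
    cols = {canonical_species(c): c for c in presence.columns}

    def col(sp: str) -> str:
        key = canonical_species(sp)
        if key not in cols:
            raise KeyError(f"panel species {sp!r} missing from presence matrix")
        return cols[key]

    lineage_cols = [[col(s) for s in lineage] for lineage in cam_lineages]
    non_cam_cols = [col(s) for s in non_cam]
    kept = []
    for gene in candidates:
        if gene not in presence.index:
            raise KeyError(f"candidate {gene!r} missing from presence matrix")
        row = presence.loc[gene]
        in_all_lineages = all(bool(row[cs].any()) for cs in lineage_cols)
        in_no_non_cam = not bool(row[non_cam_cols].any())
        if in_all_lineages and in_no_non_cam:
            kept.append(gene)
    return kept
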