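"""Ortholog-group extraction from species-labeled gene family trees.

An ortholog group (OG) is a maximal species-unique clade: a clade whose
tip species are all distinct and whose parent clade (if any) is not.
These clades partition the tips of a family tree, and each OG contains
zero to one representative gene per species.  The OG with most members
in a family is flagged primary (ties: deepest node, then lexicographic
smallest member gene id).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import GENOME, FormatError, GeneFamilyTree, PresenceMatrix


@dataclass(frozen=True)
class OrthologGroup:
    og_id: str
    members: frozenset[tuple[str, str]]  # (species id, gene id)
    family_id: str
    primary: bool = False

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ortholog group must be non-empty")
        species = [sp for sp, _ in self.members]
        if len(species) != len(set(species)):
            raise ValueError(
                f"OG {self.og_id} has more than one gene for a species"
            )

    @property
    def species(self) -> set[str]:
        return {sp for sp, _ in self.members}


def extract_ortholog_groups(
    family: GeneFamilyTree, family_id: str = "fam"
) -> list[OrthologGroup]:
    """Partition a family tree's tips into maximal species-unique clades.

    A single post-order pass records, per node, its tip count and tip
    species set; the node is species-unique iff the two are equal in
    size.  OGs are the species-unique nodes whose parent is not
    species-unique (the root included when unique), numbered in
    pre-order.
    """
    tree = family.tree
    n_tips: dict[int, int] = {}
    species_sets: dict[int, set[str]] = {}
    members: dict[int, set[tuple[str, str]]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            gene = node.taxon.label if node.taxon else ""
            if gene not in family.species_map:
                raise FormatError(f"tip {gene!r} has no species annotation")
            sp = family.species_map[gene]
            n_tips[id(node)] = 1
            species_sets[id(node)] = {sp}
            members[id(node)] = {(sp, gene)}
        else:
            kids = node.child_nodes()
            n_tips[id(node)] = sum(n_tips[id(c)] for c in kids)
            species_sets[id(node)] = set().union(*(species_sets[id(c)] for c in kids))
            members[id(node)] = set().union(*(members[id(c)] for c in kids))

    def unique(node) -> bool:
        return len(species_sets[id(node)]) == n_tips[id(node)]

    depth: dict[int, int] = {id(tree.seed_node): 0}
    og_nodes = []
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depth[id(node)] = depth[id(node.parent_node)] + 1
        if unique(node) and (node.parent_node is None or not unique(node.parent_node)):
            og_nodes.append(node)

    def tiebreak(node):
        return (
            -n_tips[id(node)],
            -depth[id(node)],
            min(g for _, g in members[id(node)]),
        )

    primary_node = min(og_nodes, key=tiebreak) if og_nodes else None
    return [
        OrthologGroup(
            og_id=f"{family_id}.OG{k+1}",
            members=frozenset(members[id(node)]),
            family_id=family_id,
            primary=node is primary_node,
        )
        for k, node in enumerate(og_nodes)
    ]


def og_presence_matrix(
    ogs: Sequence[OrthologGroup],
    panel: Sequence[str],
    source_map: Mapping[str, str] | None = None,
) -> PresenceMatrix:
    """OG x species presence: present where the OG has a member gene of
    that species, absent otherwise.  Source tags default to genome."""
    panel = list(panel)
    panel_set = set(panel)
    for og in ogs:
        outside = og.species - panel_set
        if outside:
            raise ValueError(
                f"OG {og.og_id} has members outside the panel: {sorted(outside)}"
            )
    data = pd.DataFrame(
        0.0, index=[og.og_id for og in ogs], columns=panel, dtype=float
    )
    for og in ogs:
        for sp in og.species:
            data.at[og.og_id, sp] = 1.0
    if data.index.has_duplicates:
        raise ValueError("duplicate OG identifiers")
    source = dict(source_map) if source_map else {s: GENOME for s in panel}
    return PresenceMatrix(data, source)
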