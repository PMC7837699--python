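"""Patristic-distance species assignment of sequence variants.

Query leaves are clustered with reference leaves by single linkage at a
patristic-distance threshold; cluster composition determines the label:
one reference species gives its name, two give a joined dual name, more
than two give a curated group name when available, otherwise a cluster
number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import dendropy
import numpy as np
import yaml

from .community import DistanceMatrix

__all__ = [
    "SpeciesAssignment",
    "load_tree",
    "patristic_distances",
    "assign_species",
    "default_curated_groups",
]


@dataclass
class SpeciesAssignment:
    query_id: str
    label: str | None
    rule: str  # single_ref | dual_ref | named_group | cluster_number | unassigned
    cluster_members: list = field(default_factory=list)


def default_curated_groups() -> dict[frozenset, str]:
    """Curated closely-related species groups shipped with the package."""
    text = resources.files("starterscope").joinpath("data/curated_groups.yaml").read_text()
    raw = yaml.safe_load(text)
    return {frozenset(members): name for name, members in raw.items()}


def load_tree(source: str) -> dendropy.Tree:
    """Read a newick tree from a path or a literal newick string."""
    if source.lstrip().startswith("("):
        return dendropy.Tree.get(data=source, schema="newick")
    return dendropy.Tree.get(path=source, schema="newick")


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distance matrix."""
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            child = edge.head_node
            name = child.taxon.label if child.taxon else "<internal>"
            raise ValueError(f"edge above node {name!r} has no branch length")
        if edge.length < 0:
            raise ValueError("negative branch length in tree")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(labels, d, "patristic")


def _single_linkage_clusters(d: DistanceMatrix, threshold: float) -> list[set]:
    """Connected components of the graph with edges where distance <= threshold."""
    n = len(d.ids)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if d.d[i, j] <= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    comps: dict[int, set] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(d.ids[i])
    return list(comps.values())


def assign_species(
    d: DistanceMatrix,
    queries: set,
    references: dict[str, str],
    threshold: float = 0.97,
    curated_groups: dict[frozenset, str] | None = None,
) -> list[SpeciesAssignment]:
    """Label query leaves from reference species sharing their cluster.

    Clusters are single-linkage components at the patristic
    ``threshold``. A query clustering with exactly one reference species
    takes that name; with two, both names joined by "/"; with more than
    two, the curated group name when the cluster's species are all
    members of one curated group, else a stable cluster number. Queries
    with no reference in their cluster are unassigned.
    """
    queries = set(queries)
    if queries & set(references):
        both = sorted(queries & set(references))
        raise ValueError(f"ids cannot be both query and reference: {both}")
    missing = (queries | set(references)) - set(d.ids)
    if missing:
        raise ValueError(f"leaves absent from the distance matrix: {sorted(missing)}")
    if curated_groups is None:
        curated_groups = default_curated_groups()

    clusters = _single_linkage_clusters(d, threshold)
    # stable cluster numbering by smallest member id
    clusters.sort(key=lambda c: min(c))

    assignments = []
    for num, cluster in enumerate(clusters, start=1):
        ref_species = sorted({references[m] for m in cluster if m in references})
        members = sorted(cluster)
        for q in sorted(cluster & queries):
            if not ref_species:
                assignments.append(SpeciesAssignment(q, None, "unassigned", members))
            elif len(ref_species) == 1:
                assignments.append(SpeciesAssignment(q, ref_species[0], "single_ref", members))
            elif len(ref_species) == 2:
                label = "/".join(ref_species)
                assignments.append(SpeciesAssignment(q, label, "dual_ref", members))
            else:
                group = next(
                    (name for gset, name in curated_groups.items()
                     if set(ref_species) <= gset),
                    None,
                )
                if group is not None:
                    assignments.append(SpeciesAssignment(q, group, "named_group", members))
                else:
                    assignments.append(
                        SpeciesAssignment(q, f"cluster_{num}", "cluster_number", members)
                    )
    assignments.sort(key=lambda a: a.query_id)
    return assignments
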