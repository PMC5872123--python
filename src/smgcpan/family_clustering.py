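"""Clustering of SMGCs into non-redundant families.

Each cluster region is reduced to its set of ortholog group ids; pairs of
regions at binary Jaccard dissimilarity <= threshold (default 0.4) are
linked, and families are the connected components of the resulting graph.
Components (rather than cliques or average linkage) are the minimal
membership assumption and match a network presentation of sharing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .smgc_io import SmgcRecord


@dataclass(frozen=True)
class SmgcProfile:
    """Ortholog-group content of one cluster region."""

    cluster_id: str
    genome_id: str
    group_set: frozenset[str]

    def __post_init__(self) -> None:
        if not self.group_set:
            raise ValueError(f"cluster {self.cluster_id}: empty group set")


@dataclass(frozen=True)
class FamilyClusteringConfig:
    jaccard_threshold: float = 0.4
    linkage: str = "components"

    def __post_init__(self) -> None:
        if not (0 <= self.jaccard_threshold <= 1):
            raise ValueError("jaccard_threshold must lie in [0, 1]")
        if self.linkage != "components":
            raise ValueError(f"unsupported linkage {self.linkage!r}")


@dataclass
class FamilyAssignment:
    """Partition of cluster regions into families.

    ``members`` maps each family id to its sorted (cluster_id, genome_id)
    pairs; family ids are the lexicographically smallest member cluster id,
    so assignment is independent of input order. ``consensus_class`` is the
    majority class among members, ties broken lexicographically.
    """

    cluster_to_family: dict[str, str]
    members: dict[str, list[tuple[str, str]]]
    consensus_class: dict[str, str]

    @property
    def family_ids(self) -> list[str]:
        return sorted(self.members)

    def __len__(self) -> int:
        return len(self.members)


def jaccard_dissimilarity(a: Iterable[str], b: Iterable[str]) -> float:
    """1 - |a n b| / |a u b| on non-empty sets."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValueError("Jaccard dissimilarity undefined for empty sets")
    return 1.0 - len(sa & sb) / len(sa | sb)


_EPS = 1e-9  # edge inclusion is "<= threshold"; guard float rounding


def build_smgc_graph(
    profiles: Sequence[SmgcProfile], config: FamilyClusteringConfig | None = None
) -> nx.Graph:
    """Pairwise Jaccard graph over cluster profiles.

    Nodes are cluster ids (annotated with genome_id); an edge joins two
    clusters whose group-content dissimilarity is <= the threshold, with
    the dissimilarity as edge weight. Pairwise comparison is vectorized via
    a binary membership matrix.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    config = config or FamilyClusteringConfig()
    profiles = sorted(profiles, key=lambda p: p.cluster_id)
    ids = [p.cluster_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cluster ids in profiles")
    g = nx.Graph()
    for p in profiles:
        g.add_node(p.cluster_id, genome_id=p.genome_id)
    universe = sorted(set().union(*(p.group_set for p in profiles)))
    col = {grp: i for i, grp in enumerate(universe)}
    B = np.zeros((len(profiles), len(universe)), dtype=np.float64)
    for r, p in enumerate(profiles):
        for grp in p.group_set:
            B[r, col[grp]] = 1.0
    inter = B @ B.T
    sizes = B.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    diss = 1.0 - inter / union
    ii, jj = np.nonzero(np.triu(diss <= config.jaccard_threshold + _EPS, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        g.add_edge(ids[i], ids[j], jaccard_dissimilarity=float(diss[i, j]))
    return g


def assign_families(
    graph: nx.Graph, classes: Mapping[str, str] | None = None
) -> FamilyAssignment:
    """Families are the connected components of the Jaccard graph.

    ``classes`` optionally maps cluster_id -> smgc_class for consensus
    labels (majority vote, ties broken lexicographically; "other" when no
    classes are supplied).
    """
    cluster_to_family: dict[str, str] = {}
    members: dict[str, list[tuple[str, str]]] = {}
    consensus: dict[str, str] = {}
    for comp in nx.connected_components(graph):
        names = sorted(comp)
        fid = names[0]
        memb = []
        for cid in names:
            cluster_to_family[cid] = fid
            memb.append((cid, graph.nodes[cid].get("genome_id", "")))
        members[fid] = sorted(memb)
        if classes:
            votes: dict[str, int] = {}
            for cid in names:
                c = classes.get(cid, "other")
                votes[c] = votes.get(c, 0) + 1
            top = max(votes.values())
            consensus[fid] = min(c for c, v in votes.items() if v == top)
        else:
            consensus[fid] = "other"
    return FamilyAssignment(
        cluster_to_family=cluster_to_family,
        members=members,
        consensus_class=consensus,
    )


def cluster_families(
    profiles: Sequence[SmgcProfile],
    config: FamilyClusteringConfig | None = None,
    classes: Mapping[str, str] | None = None,
) -> FamilyAssignment:
    """Convenience: graph construction followed by component assignment."""
    return assign_families(build_smgc_graph(profiles, config), classes)


def threshold_sweep(
    profiles: Sequence[SmgcProfile], thresholds: Sequence[float]
) -> pd.DataFrame:
    """Family counts across a sweep of dissimilarity thresholds.

    The count is non-increasing in the threshold (more edges can only merge
    components). Thresholds must be sorted ascending.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for t in thresholds:
        assignment = cluster_families(
            profiles, FamilyClusteringConfig(jaccard_threshold=float(t))
        )
        rows.append({"threshold": float(t), "family_count": len(assignment)})
    return pd.DataFrame(rows)


def profiles_from_ortholog_table(table: pd.DataFrame) -> list[SmgcProfile]:
    """Build cluster profiles from an ortholog table
    (gene_id, genome_id, cluster_id, group_id)."""
    out = []
    for (genome_id, cluster_id), sub in sorted(
        table.groupby(["genome_id", "cluster_id"], sort=True)
    ):
        out.append(
            SmgcProfile(
                cluster_id=str(cluster_id),
                genome_id=str(genome_id),
                group_set=frozenset(sub["group_id"].astype(str)),
            )
        )
    return out


def write_family_table(
    assignment: FamilyAssignment, path: str | Path
) -> None:
    rows = []
    for fid, memb in sorted(assignment.members.items()):
        for cid, gid in memb:
            rows.append(
                {
                    "cluster_id": cid,
                    "genome_id": gid,
                    "family_id": fid,
                    "consensus_class": assignment.consensus_class[fid],
                }
            )
    rows.sort(key=lambda r: (r["genome_id"], r["cluster_id"]))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_family_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cluster_id", "genome_id", "family_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def assignment_from_table(df: pd.DataFrame) -> FamilyAssignment:
    """Reconstruct a FamilyAssignment from a family table frame."""
    cluster_to_family: dict[str, str] = {}
    members: dict[str, list[tuple[str, str]]] = {}
    consensus: dict[str, str] = {}
    for row in df.itertuples(index=False):
        cluster_to_family[row.cluster_id] = row.family_id
        members.setdefault(row.family_id, []).append((row.cluster_id, row.genome_id))
        consensus[row.family_id] = getattr(row, "consensus_class", "other")
    for m in members.values():
        m.sort()
    return FamilyAssignment(
        cluster_to_family=cluster_to_family,
        members=members,
        consensus_class=consensus,
    )
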