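"""Parsimony inference of family gain and loss on a phylogeny.

Two criteria are provided: Fitch small parsimony on the binary
presence/absence character (minimum total state changes) and Dollo
parsimony (exactly one gain, on the branch above the most recent common
ancestor of the present leaves, plus the minimal set of losses below it).
A frequency-based heuristic classifies families within each clade as
recent-acquisition or recent-deletion candidates from occupancy alone.

Trees must be rooted for event polarity; an unrooted tree is midpoint
rooted with a warning, and helpers are provided to root on a named clade
split or outgroup instead. Fitch ties at the root are resolved by
preferring absence (the acquisition-biased resolution); the set of
ambiguous nodes is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .pan_analysis import PanConfig, PresenceAbsenceMatrix
from .smgc_io import Phylogeny

ABSENT, PRESENT, EITHER = 1, 2, 3  # bitmask state sets


@dataclass
class GainLossReconstruction:
    """Ancestral states and branch events for one family.

    ``node_states`` maps node id -> 0/1; ``events`` lists
    (child-node id, "gain" | "loss") pairs, one per branch with a state
    change (for Dollo a root-edge gain uses the root node id as branch).
    """

    family_id: str
    criterion: str  # "fitch" | "dollo"
    node_states: dict[str, int]
    events: tuple[tuple[str, str], ...]
    n_events: int
    ambiguous_nodes: frozenset[str] = frozenset()

    @property
    def gains(self) -> list[str]:
        return [b for b, e in self.events if e == "gain"]

    @property
    def losses(self) -> list[str]:
        return [b for b, e in self.events if e == "loss"]


def label_nodes(phylo: Phylogeny) -> None:
    """Assign deterministic ids: leaves keep taxon labels; an internal node
    is named ``anc:<smallest descendant leaf>:<descendant leaf count>``,
    which is unique on a tree and stable across node orderings."""
    for node in phylo.tree.postorder_node_iter():
        if node.is_leaf():
            node.node_id = node.taxon.label
            node.leafset = frozenset([node.taxon.label])
        else:
            ls = frozenset().union(*(c.leafset for c in node.child_nodes()))
            node.leafset = ls
            node.node_id = f"anc:{min(ls)}:{len(ls)}"


def ensure_rooted(
    phylo: Phylogeny,
    method: str = "midpoint",
    outgroup: Sequence[str] | None = None,
) -> Phylogeny:
    """Return a rooted copy of the tree (or the tree itself if rooted).

    ``method="midpoint"`` roots at the midpoint of the longest path;
    ``method="outgroup"`` (or ``"clade"``) roots on the branch separating
    ``outgroup`` leaves from the rest, which is how a tree is polarized on
    the split between two named clades.
    """
    if phylo.is_rooted and outgroup is None:
        return phylo
    clone = phylo.clone()
    tree = clone.tree
    tree.is_rooted = True
    if method == "midpoint" and outgroup is None:
        tree.reroot_at_midpoint(update_bipartitions=False)
    elif method in ("outgroup", "clade"):
        if not outgroup:
            raise ValueError("outgroup rooting requires leaf names")
        group = frozenset(outgroup)
        target = None
        for node in tree.postorder_node_iter():
            if node is tree.seed_node:
                continue
            below = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
            if below == group:
                target = node
                break
        if target is None:
            raise ValueError(f"no branch separates {sorted(group)} from the rest")
        edge = target.edge
        half = (edge.length or 0.0) / 2
        tree.reroot_at_edge(edge, length1=half, length2=half)
    else:
        raise ValueError(f"unknown rooting method {method!r}")
    tree.suppress_unifurcations()
    return Phylogeny(tree=tree, is_rooted=True)


def _rooted(phylo: Phylogeny) -> Phylogeny:
    if phylo.is_rooted:
        return phylo
    warnings.warn("unrooted tree supplied; midpoint rooting applied")
    return ensure_rooted(phylo, method="midpoint")


def _presence_states(phylo: Phylogeny, presence) -> dict[str, int]:
    leaves = set(phylo.leaf_names)
    if isinstance(presence, Mapping):
        if set(presence) != leaves:
            missing = sorted(leaves - set(presence))
            extra = sorted(set(presence) - leaves)
            raise ValueError(
                f"presence vector mismatch; leaves without state: {missing}; "
                f"states without leaves: {extra}"
            )
        return {k: int(bool(v)) for k, v in presence.items()}
    present = set(presence)
    extra = sorted(present - leaves)
    if extra:
        raise ValueError(f"present genomes not on the tree: {extra}")
    return {leaf: int(leaf in present) for leaf in leaves}


def fitch_reconstruct(
    phylo: Phylogeny, presence, family_id: str = ""
) -> GainLossReconstruction:
    """Fitch minimum-change reconstruction of a binary character.

    ``presence`` is either a dict leaf -> 0/1 covering every leaf, or an
    iterable of present leaf names. The event count equals the Fitch
    minimum (number of union steps in the bottom-up pass); ties are broken
    by preferring absence at the root and the parent state elsewhere.
    """
    phylo = _rooted(phylo)
    label_nodes(phylo)
    states = _presence_states(phylo, presence)
    sets: dict[str, int] = {}
    n_unions = 0
    ambiguous = set()
    for node in phylo.tree.postorder_node_iter():
        if node.is_leaf():
            sets[node.node_id] = PRESENT if states[node.node_id] else ABSENT
            continue
        acc = None
        for child in node.child_nodes():
            s = sets[child.node_id]
            if acc is None:
                acc = s
            elif acc & s:
                acc &= s
            else:
                acc |= s
                n_unions += 1
        sets[node.node_id] = acc
        if acc == EITHER:
            ambiguous.add(node.node_id)
    node_states: dict[str, int] = {}
    events: list[tuple[str, str]] = []
    for node in phylo.tree.preorder_node_iter():
        s = sets[node.node_id]
        if node.parent_node is None:
            node_states[node.node_id] = 0 if s & ABSENT else 1
        else:
            ps = node_states[node.parent_node.node_id]
            pbit = ABSENT if ps == 0 else PRESENT
            node_states[node.node_id] = ps if s & pbit else (1 - ps)
            cs = node_states[node.node_id]
            if cs != ps:
                events.append((node.node_id, "gain" if cs == 1 else "loss"))
    return GainLossReconstruction(
        family_id=family_id,
        criterion="fitch",
        node_states=node_states,
        events=tuple(events),
        n_events=n_unions,
        ambiguous_nodes=frozenset(ambiguous),
    )


def dollo_reconstruct(
    phylo: Phylogeny, presence, family_id: str = ""
) -> GainLossReconstruction:
    """Single-origin reconstruction: one gain above the MRCA of present
    leaves, losses on the minimal branch set covering absent leaves."""
    phylo = _rooted(phylo)
    label_nodes(phylo)
    states = _presence_states(phylo, presence)
    present = {leaf for leaf, s in states.items() if s}
    if not present:
        node_states = {
            n.node_id: 0 for n in phylo.tree.preorder_node_iter()
        }
        return GainLossReconstruction(
            family_id=family_id,
            criterion="dollo",
            node_states=node_states,
            events=(),
            n_events=0,
        )
    # MRCA = shallowest node whose leafset contains all present leaves
    mrca = phylo.tree.seed_node
    changed = True
    while changed:
        changed = False
        for child in mrca.child_nodes():
            if present <= child.leafset:
                mrca = child
                changed = True
                break
    mrca_leafset = mrca.leafset
    node_states: dict[str, int] = {}
    events: list[tuple[str, str]] = [(mrca.node_id, "gain")]
    for node in phylo.tree.preorder_node_iter():
        if not node.leafset <= mrca_leafset:
            node_states[node.node_id] = 0  # above or outside the gain subtree
            continue
        has_present = bool(node.leafset & present)
        node_states[node.node_id] = 1 if has_present else 0
        if not has_present:
            parent = node.parent_node
            # loss only at the root of a maximal all-absent subtree
            if parent is not None and node_states.get(parent.node_id) == 1:
                events.append((node.node_id, "loss"))
    return GainLossReconstruction(
        family_id=family_id,
        criterion="dollo",
        node_states=node_states,
        events=tuple(events),
        n_events=len(events),
    )


def heuristic_calls(
    matrix: PresenceAbsenceMatrix,
    config: PanConfig | None = None,
    clade_groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Frequency-based classification of families within each clade.

    Occupancy between 1 and ``low_freq_max`` (default 3) flags a
    recent-acquisition candidate; occupancy within ``near_core_missing_max``
    of the clade size but below it flags a recent-deletion candidate
    ("near core"); everything else, including absent and fully present
    families, is "neither". When both ranges overlap (very small clades)
    the low-frequency rule wins.
    """
    config = config or PanConfig()
    if clade_groups is None:
        clade_groups = {
            clade: matrix.clade_genomes(clade)
            for clade in sorted(set(matrix.clades.values()))
            if clade not in ("INT", "OTHER") and len(matrix.clade_genomes(clade)) >= 2
        }
    rows = []
    for clade, genomes in sorted(clade_groups.items()):
        occ = matrix.occupancy(genomes)
        n = len(genomes)
        for fid in matrix.family_ids:
            k = int(occ[fid])
            if 1 <= k <= config.low_freq_max:
                label = "recent_acquisition_candidate"
            elif n - config.near_core_missing_max <= k < n:
                label = "recent_deletion_candidate"
            else:
                label = "neither"
            rows.append({"family_id": fid, "clade": clade, "occupancy": k, "label": label})
    return pd.DataFrame(rows)


def reconstruct_all(
    phylo: Phylogeny, matrix: PresenceAbsenceMatrix, criterion: str = "fitch"
) -> list[GainLossReconstruction]:
    """Reconstruct every family in the matrix under one criterion."""
    fn = {"fitch": fitch_reconstruct, "dollo": dollo_reconstruct}[criterion]
    out = []
    for fid in matrix.family_ids:
        row = matrix.df.loc[fid]
        presence = {g: int(row[g]) for g in matrix.genome_ids}
        out.append(fn(phylo, presence, family_id=fid))
    return out


def event_summary(
    reconstructions: Sequence[GainLossReconstruction],
    phylo: Phylogeny,
    clades: Mapping[str, str],
    core_families: Iterable[str] | None = None,
) -> dict:
    """Per-branch event table and per-clade gain/loss totals.

    A branch lies "inside" a clade when every leaf below it belongs to that
    clade (terminal branches included). When ``core_families`` is given,
    the per-clade count of core families with at least one loss on an
    internal-to-clade branch is reported (the strain-level core-deletion
    figure).
    """
    phylo = _rooted(phylo)
    label_nodes(phylo)
    branch_clade: dict[str, str | None] = {}
    for node in phylo.tree.preorder_node_iter():
        labels = {clades[lf] for lf in node.leafset if lf in clades}
        branch_clade[node.node_id] = labels.pop() if len(labels) == 1 else None
    rows = []
    clade_totals: dict[str, dict[str, int]] = {}
    core = set(core_families) if core_families is not None else None
    core_lost: dict[str, set[str]] = {}
    for rec in reconstructions:
        for branch, event in rec.events:
            rows.append(
                {
                    "family_id": rec.family_id,
                    "criterion": rec.criterion,
                    "branch": branch,
                    "event": event,
                }
            )
            clade = branch_clade.get(branch)
            if clade is not None:
                tot = clade_totals.setdefault(clade, {"gain": 0, "loss": 0})
                tot[event] += 1
                if core is not None and event == "loss" and rec.family_id in core:
                    core_lost.setdefault(clade, set()).add(rec.family_id)
    per_branch = pd.DataFrame(
        rows, columns=["family_id", "criterion", "branch", "event"]
    ).sort_values(["family_id", "branch"], kind="stable").reset_index(drop=True)
    out = {
        "per_branch": per_branch,
        "per_clade": {
            clade: dict(totals) for clade, totals in sorted(clade_totals.items())
        },
    }
    if core is not None:
        out["core_families_with_loss"] = {
            clade: len(fams) for clade, fams in sorted(core_lost.items())
        }
    return out
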