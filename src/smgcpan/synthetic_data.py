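"""Synthetic inputs: phylogenies, evolving cluster repertoires, and a
deterministic fixture reproducing the printed pan-SMGC summary counts.

The evolutionary model is intentionally simple: families are gained along
branches as a Poisson process and lost with an exponential survival
probability; genes within surviving families undergo residue substitution
(uniform random replacement — only recoverability matters, not realism)
and bounded gene turnover. Turnover is capped per root-to-leaf lineage at
a fixed fraction of the founding gene count, which guarantees that any two
leaf copies of one family stay within Jaccard dissimilarity 0.4 of each
other by construction, so the planted family partition is recoverable
exactly at the default clustering threshold.

All randomness flows through one integer-seeded generator; a fixed seed
reproduces every output byte-for-byte.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gainloss import label_nodes
from .pan_analysis import PresenceAbsenceMatrix
from .smgc_io import (
    CLASS_VOCAB,
    GeneRecord,
    GenomeMetadata,
    Phylogeny,
    SmgcRecord,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Rough class proportions (abundant NRPS/terpene, a tail of rare classes).
_CLASS_WEIGHTS = {
    "nrps": 0.17, "terpene": 0.15, "t1pks": 0.08, "hybrid": 0.08,
    "bacteriocin": 0.07, "lantipeptide": 0.06, "siderophore": 0.05,
    "t2pks": 0.04, "t3pks": 0.04, "ectoine": 0.04, "melanin": 0.04,
    "lassopeptide": 0.03, "ladderane": 0.03, "butyrolactone": 0.03,
    "transatpks": 0.02, "linaridin": 0.02, "thiopeptide": 0.02,
    "arylpolyene": 0.02, "phosphonate": 0.02, "indole": 0.02,
    "nucleoside": 0.02, "other": 0.05,
}
_CLASSES = list(_CLASS_WEIGHTS)
_WEIGHTS = np.array([_CLASS_WEIGHTS[c] for c in _CLASSES])
_WEIGHTS = _WEIGHTS / _WEIGHTS.sum()


@dataclass(frozen=True)
class SimulationConfig:
    n_ndr: int = 10
    n_sdr: int = 10
    n_int: int = 4
    ancestral_families: int = 25
    gain_rate: float = 8.0  # family gains per unit branch length
    loss_rate: float = 0.1  # family loss hazard per unit branch length
    genes_per_family: tuple[int, int] = (5, 30)
    gene_gain_prob: float = 0.15  # per family per branch
    gene_loss_prob: float = 0.15
    turnover_budget_frac: float = 0.1  # per-lineage cap on gains and losses
    substitution_rate: float = 0.01  # per residue per unit branch length
    protein_length: tuple[int, int] = (100, 400)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ndr + self.n_sdr + self.n_int < 2:
            raise ValueError("need at least two genomes")
        for name in ("gain_rate", "loss_rate", "substitution_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class SimulationTruth:
    """Ground truth for recovery tests.

    ``events`` lists dicts with keys branch (child-node id), family_id and
    event ("gain"/"loss"); node ids follow :func:`gainloss.label_nodes`.
    """

    family_of_cluster: dict[str, str]
    group_of_gene: dict[str, str]  # "genome|gene_id" -> lineage id
    events: list[dict]
    gain_branch: dict[str, str]  # family_id -> branch of its gain
    clades: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "family_of_cluster": self.family_of_cluster,
                "group_of_gene": self.group_of_gene,
                "events": self.events,
                "gain_branch": self.gain_branch,
                "clades": self.clades,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        d = json.loads(text)
        return cls(
            family_of_cluster=d["family_of_cluster"],
            group_of_gene=d["group_of_gene"],
            events=d["events"],
            gain_branch=d["gain_branch"],
            clades=d["clades"],
        )


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------


def _yule_newick(names: list[str], rng: np.random.Generator, birth: float = 1.0) -> str:
    """Forward Yule simulation over a fixed leaf count; returns newick."""
    if len(names) == 1:
        return names[0] + ":0.1"
    # the root splits at time 0 into lineages 0 and 1; each active lineage
    # is (id, birth time); splits recorded as id -> (left, right, t_split)
    active: list[tuple[int, float]] = [(0, 0.0), (1, 0.0)]
    nodes: dict[int, tuple | None] = {0: None, 1: None}
    nxt = 2
    t = 0.0
    while len(active) < len(names):
        k = len(active)
        t += float(rng.exponential(1.0 / (birth * k)))
        idx = int(rng.integers(k))
        lineage_id, _born = active[idx]
        a, b = nxt, nxt + 1
        nxt += 2
        nodes[lineage_id] = (a, b, t)
        nodes[a] = nodes[b] = None
        active[idx] = (a, t)
        active.append((b, t))
    t_end = t + float(rng.exponential(1.0 / (birth * len(names))))
    # assign leaf names to active lineages in order
    leaf_name = {lid: names[i] for i, (lid, _) in enumerate(active)}

    def render(lid: int, born: float) -> str:
        if nodes.get(lid) is None:
            return f"{leaf_name[lid]}:{t_end - born:.6f}"
        a, b, ts = nodes[lid]
        return f"({render(a, ts)},{render(b, ts)}):{ts - born:.6f}"

    return f"({render(0, 0.0)},{render(1, 0.0)})"


def simulate_tree(
    config: SimulationConfig,
) -> tuple[Phylogeny, dict[str, str]]:
    """Rooted binary tree: two monophyletic sister clades plus a basal
    ladder of intermediate taxa. Returns the tree and genome -> clade map."""
    rng = np.random.default_rng(config.seed)
    ndr = [f"ndr{i + 1:02d}" for i in range(config.n_ndr)]
    sdr = [f"sdr{i + 1:02d}" for i in range(config.n_sdr)]
    intr = [f"int{i + 1:02d}" for i in range(config.n_int)]
    clades = {g: "NDR" for g in ndr}
    clades.update({g: "SDR" for g in sdr})
    clades.update({g: "INT" for g in intr})
    parts = []
    if ndr and sdr:
        stem_a = 0.3 + float(rng.exponential(0.2))
        stem_b = 0.3 + float(rng.exponential(0.2))
        core = (
            f"({_yule_newick(ndr, rng)}:{stem_a:.6f},"
            f"{_yule_newick(sdr, rng)}:{stem_b:.6f})"
        )
    elif ndr or sdr:
        core = _yule_newick(ndr or sdr, rng)
    else:
        core = None
    current = core
    for leaf in intr:
        pend = 0.5 + float(rng.exponential(0.3))
        if current is None:
            current = f"{leaf}:{pend:.6f}"
            continue
        current = f"({current}:0.2,{leaf}:{pend:.6f})"
    newick = current + ";"
    phylo = Phylogeny.from_newick(newick)
    phylo.is_rooted = True
    return phylo, clades


# ---------------------------------------------------------------------------
# Evolution simulation
# ---------------------------------------------------------------------------


class _Family:
    __slots__ = ("fid", "smgc_class", "genes", "founding", "lost", "gained", "counter")

    def __init__(self, fid, smgc_class, genes, founding, lost=0, gained=0, counter=0):
        self.fid = fid
        self.smgc_class = smgc_class
        self.genes = genes  # list of (lineage_id, seq)
        self.founding = founding
        self.lost = lost
        self.gained = gained
        self.counter = counter

    def clone(self):
        return _Family(
            self.fid, self.smgc_class, list(self.genes), self.founding,
            self.lost, self.gained, self.counter,
        )


def _random_protein(rng: np.random.Generator, config: SimulationConfig) -> str:
    lo, hi = config.protein_length
    n = int(rng.integers(lo, hi + 1))
    return "".join(AA20[i] for i in rng.integers(0, 20, size=n))


def _mutate(seq: str, rng: np.random.Generator, p: float) -> str:
    if p <= 0:
        return seq
    k = int(rng.binomial(len(seq), p))
    if k == 0:
        return seq
    chars = list(seq)
    positions = rng.choice(len(seq), size=k, replace=False)
    for pos in positions:
        old = chars[pos]
        choices = AA20.replace(old, "")
        chars[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


def _new_family(fid: str, rng: np.random.Generator, config: SimulationConfig) -> _Family:
    lo, hi = config.genes_per_family
    n = int(rng.integers(lo, hi + 1))
    genes = [(f"{fid}:g{j:03d}", _random_protein(rng, config)) for j in range(n)]
    smgc_class = _CLASSES[int(rng.choice(len(_CLASSES), p=_WEIGHTS))]
    return _Family(fid, smgc_class, genes, founding=n)


def simulate_evolution(
    phylo: Phylogeny,
    config: SimulationConfig,
    clades: Mapping[str, str] | None = None,
) -> tuple[list[SmgcRecord], SimulationTruth]:
    """Evolve family repertoires down the tree and emit leaf cluster records.

    Ancestral families sit at the root; along each branch families are
    lost with probability 1 - exp(-loss_rate * length), gained as
    Poisson(gain_rate * length) fresh families, and surviving families
    accumulate substitutions and capped gene turnover. Every emitted gene
    carries a true ortholog lineage id recorded in the returned truth.
    """
    rng = np.random.default_rng(config.seed + 1)
    label_nodes(phylo)
    clades = dict(clades or {})
    fam_counter = [0]

    def fresh_fid() -> str:
        fam_counter[0] += 1
        return f"fam{fam_counter[0]:04d}"

    root = phylo.tree.seed_node
    root_families = [
        _new_family(fresh_fid(), rng, config)
        for _ in range(config.ancestral_families)
    ]
    events: list[dict] = []
    gain_branch: dict[str, str] = {f.fid: root.node_id for f in root_families}
    records: list[SmgcRecord] = []
    family_of_cluster: dict[str, str] = {}
    group_of_gene: dict[str, str] = {}
    cap = lambda fam: int(math.floor(config.turnover_budget_frac * fam.founding))

    def evolve_branch(families: list[_Family], node) -> list[_Family]:
        t = float(node.edge.length or 0.0)
        out: list[_Family] = []
        p_sub = 1.0 - math.exp(-config.substitution_rate * t)
        p_loss = 1.0 - math.exp(-config.loss_rate * t)
        for fam in families:
            if rng.random() < p_loss:
                events.append(
                    {"branch": node.node_id, "family_id": fam.fid, "event": "loss"}
                )
                continue
            fam = fam.clone()
            fam.genes = [
                (lid, _mutate(seq, rng, p_sub)) for lid, seq in fam.genes
            ]
            if (
                rng.random() < config.gene_loss_prob
                and fam.lost < cap(fam)
                and len(fam.genes) > 1
            ):
                del fam.genes[int(rng.integers(len(fam.genes)))]
                fam.lost += 1
            if rng.random() < config.gene_gain_prob and fam.gained < cap(fam):
                fam.counter += 1
                fam.genes.append(
                    (
                        f"{fam.fid}:x{node.node_id}:{fam.counter:02d}",
                        _random_protein(rng, config),
                    )
                )
                fam.gained += 1
            out.append(fam)
        n_gains = int(rng.poisson(config.gain_rate * t))
        for _ in range(n_gains):
            fam = _new_family(fresh_fid(), rng, config)
            events.append(
                {"branch": node.node_id, "family_id": fam.fid, "event": "gain"}
            )
            gain_branch[fam.fid] = node.node_id
            out.append(fam)
        return out

    def recurse(node, families: list[_Family]) -> None:
        if node.is_leaf():
            genome = node.node_id
            offset_records = []
            for i, fam in enumerate(sorted(families, key=lambda f: f.fid)):
                cluster_id = f"{genome}.r{i + 1:03d}"
                genes = []
                pos = 1
                for k, (lid, seq) in enumerate(fam.genes):
                    span = 3 * len(seq) + 3
                    gene_id = f"{cluster_id}.{k + 1:02d}"
                    genes.append(
                        GeneRecord(
                            gene_id=gene_id,
                            genome_id=genome,
                            cluster_id=cluster_id,
                            start=pos,
                            end=pos + span - 1,
                            strand="+" if rng.random() < 0.5 else "-",
                            protein_seq=seq,
                        )
                    )
                    group_of_gene[f"{genome}|{gene_id}"] = lid
                    pos += span + 50
                offset_records.append(
                    SmgcRecord(
                        cluster_id=cluster_id,
                        genome_id=genome,
                        smgc_class=fam.smgc_class,
                        length_bp=pos + 50,
                        genes=tuple(genes),
                    )
                )
                family_of_cluster[cluster_id] = fam.fid
            records.extend(offset_records)
            return
        for child in node.child_nodes():
            recurse(child, evolve_branch(families, child))

    recurse(root, root_families)
    if not records:
        warnings.warn("all families extinct at every leaf; consider lower loss_rate")
    truth = SimulationTruth(
        family_of_cluster=family_of_cluster,
        group_of_gene=group_of_gene,
        events=events,
        gain_branch=gain_branch,
        clades=clades,
    )
    return records, truth


def simulate_metadata(
    records: Sequence[SmgcRecord],
    clades: Mapping[str, str],
    seed: int = 0,
) -> list[GenomeMetadata]:
    """Genome metadata with sizes/ORF counts coupled to cluster counts so
    that the size-vs-count correlation is positive, as on real data."""
    rng = np.random.default_rng(seed + 2)
    counts: dict[str, int] = {g: 0 for g in clades}
    for rec in records:
        counts[rec.genome_id] = counts.get(rec.genome_id, 0) + 1
    base_size = {"NDR": 7.9e6, "SDR": 7.2e6, "INT": 7.5e6, "OTHER": 7.5e6}
    base_orf = {"NDR": 7000, "SDR": 6400, "INT": 6700, "OTHER": 6700}
    out = []
    for genome in sorted(counts):
        clade = clades.get(genome, "OTHER")
        n = counts[genome]
        size = base_size[clade] + 20000 * n + float(rng.normal(0, 50000))
        orfs = base_orf[clade] + 20 * n + float(rng.normal(0, 60))
        out.append(
            GenomeMetadata(
                genome_id=genome,
                clade=clade,
                genome_size_bp=int(size),
                orf_count=int(orfs),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Paper-shaped fixture
# ---------------------------------------------------------------------------

_FIXTURE_TOTAL = 310
_FIXTURE_SINGLETONS = 177
_FIXTURE_CONSERVED = 9
_FIXTURE_ALL24 = 2
_FIXTURE_NDR_ONLY_CORE = 2
_FIXTURE_SDR_ONLY_CORE = 6


def paper_fixture(seed: int = 0) -> tuple[PresenceAbsenceMatrix, list[GenomeMetadata]]:
    """Deterministic 310-family presence/absence matrix over 24 genomes.

    Encodes the published pan-SMGC summary exactly: 177 occupancy-1
    families; 9 families in >= 80% of all 24 genomes, of which 2 occupy all
    24; 2 further NDR-core and 6 further SDR-core families; the remaining
    116 families at occupancies 2-18 below every core threshold. The
    arrangement of which genomes carry which family is randomized by the
    seed; the summary counts are invariant and verified before returning.
    """
    rng = np.random.default_rng(seed)
    ndr = [f"ndr{i + 1:02d}" for i in range(10)]
    sdr = [f"sdr{i + 1:02d}" for i in range(10)]
    intr = [f"int{i + 1:02d}" for i in range(4)]
    genomes = ndr + sdr + intr
    clades = {g: "NDR" for g in ndr}
    clades.update({g: "SDR" for g in sdr})
    clades.update({g: "INT" for g in intr})
    presence: list[set[str]] = []

    # conserved core: 2 in all 24, 7 more at occupancy 20-23
    for _ in range(_FIXTURE_ALL24):
        presence.append(set(genomes))
    for _ in range(_FIXTURE_CONSERVED - _FIXTURE_ALL24):
        occ = int(rng.integers(20, 24))
        presence.append(set(rng.choice(genomes, size=occ, replace=False)))
    # clade-specific cores: >= 8 of the clade's 10, light spillover only
    for _ in range(_FIXTURE_NDR_ONLY_CORE):
        n_own = int(rng.integers(8, 11))
        n_int = int(rng.integers(0, 3))
        fam = set(rng.choice(ndr, size=n_own, replace=False))
        fam |= set(rng.choice(intr, size=n_int, replace=False))
        presence.append(fam)
    for _ in range(_FIXTURE_SDR_ONLY_CORE):
        n_own = int(rng.integers(8, 11))
        n_int = int(rng.integers(0, 3))
        fam = set(rng.choice(sdr, size=n_own, replace=False))
        fam |= set(rng.choice(intr, size=n_int, replace=False))
        presence.append(fam)
    # accessory: occupancy 2-18, below core thresholds in both clades
    n_accessory = (
        _FIXTURE_TOTAL
        - _FIXTURE_SINGLETONS
        - _FIXTURE_CONSERVED
        - _FIXTURE_NDR_ONLY_CORE
        - _FIXTURE_SDR_ONLY_CORE
    )
    occupancies = np.arange(2, 19)
    weights = 0.72 ** occupancies
    weights /= weights.sum()
    for _ in range(n_accessory):
        occ = int(rng.choice(occupancies, p=weights))
        while True:
            n_n = int(rng.integers(0, min(7, occ) + 1))
            n_i = int(rng.integers(0, min(4, occ - n_n) + 1))
            n_s = occ - n_n - n_i
            if 0 <= n_s <= 7:
                break
        fam = set(rng.choice(ndr, size=n_n, replace=False))
        fam |= set(rng.choice(sdr, size=n_s, replace=False))
        fam |= set(rng.choice(intr, size=n_i, replace=False))
        presence.append(fam)
    # strain-specific: 1-19 exclusive families per genome, 177 total
    per_genome = {g: 1 for g in genomes}
    remaining = _FIXTURE_SINGLETONS - len(genomes)
    while remaining > 0:
        g = genomes[int(rng.integers(len(genomes)))]
        if per_genome[g] < 19:
            per_genome[g] += 1
            remaining -= 1
    for g in genomes:
        for _ in range(per_genome[g]):
            presence.append({g})

    fams = [f"fam{i + 1:03d}" for i in range(len(presence))]
    df = pd.DataFrame(0, index=fams, columns=genomes, dtype=int)
    for fid, members in zip(fams, presence):
        df.loc[fid, sorted(members)] = 1

    occ_all = df.sum(axis=1)
    if len(df) != _FIXTURE_TOTAL:
        raise RuntimeError("fixture family count drifted")
    if int((occ_all == 1).sum()) != _FIXTURE_SINGLETONS:
        raise RuntimeError("fixture singleton count drifted")
    if int((occ_all >= 20).sum()) != _FIXTURE_CONSERVED:
        raise RuntimeError("fixture conserved-core count drifted")
    if int((occ_all == 24).sum()) != _FIXTURE_ALL24:
        raise RuntimeError("fixture all-genome count drifted")
    ndr_core = (df[ndr].sum(axis=1) >= 8) & (occ_all < 20)
    sdr_core = (df[sdr].sum(axis=1) >= 8) & (occ_all < 20)
    if int(ndr_core.sum()) != _FIXTURE_NDR_ONLY_CORE:
        raise RuntimeError("fixture NDR core count drifted")
    if int(sdr_core.sum()) != _FIXTURE_SDR_ONLY_CORE:
        raise RuntimeError("fixture SDR core count drifted")

    matrix = PresenceAbsenceMatrix(df=df, clades=clades)
    rng2 = np.random.default_rng(seed + 3)
    metadata = []
    base = {"NDR": (8.7e6, 0.25e6, 7775, 196), "SDR": (7.9e6, 0.21e6, 7093, 205),
            "INT": (8.3e6, 0.23e6, 7400, 200)}
    for g in genomes:
        mu_s, sd_s, mu_o, sd_o = base[clades[g]]
        metadata.append(
            GenomeMetadata(
                genome_id=g,
                clade=clades[g],
                genome_size_bp=int(rng2.normal(mu_s, sd_s)),
                orf_count=int(rng2.normal(mu_o, sd_o)),
            )
        )
    return matrix, metadata
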