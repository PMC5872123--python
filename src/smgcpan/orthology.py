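"""Ortholog grouping of cluster genes.

All genes from all cluster regions are compared by local protein alignment
(Smith-Waterman with affine gaps, BLOSUM62 by default), scores are
normalized by the larger self-alignment score ("maxbit" normalization,
score(a,b) / max(score(a,a), score(b,b))), pairs at or above the cutoff
(default 0.04) become edges of a weighted gene graph, and the graph is
partitioned with the Markov cluster (MCL) algorithm at inflation 2.0.

Raw Smith-Waterman scores stand in for bit scores in the normalization; no
Karlin-Altschul parameters are applied, which is monotone-equivalent for
thresholding purposes.

Two alignment engines are provided: a pure-Python affine-gap DP (the
reference implementation, always available) and Biopython's C
``PairwiseAligner`` (used by default for speed; both produce identical
scores). A gap of length k costs ``gap_open + (k - 1) * gap_extend``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .smgc_io import AA_ALPHABET, GeneRecord

logger = logging.getLogger(__name__)


@lru_cache(maxsize=4)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=4)
def _matrix_lookup(name: str) -> dict[tuple[str, str], int]:
    mat = _load_matrix(name)
    letters = mat.alphabet
    return {
        (a, b): int(mat[a, b]) for a in letters for b in letters
    }


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (both positive)."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 10
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")

    @property
    def lookup(self) -> dict[tuple[str, str], int]:
        return _matrix_lookup(self.matrix_name)


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    aligned_identity: float
    query_coverage: float
    target_coverage: float


@dataclass(frozen=True)
class OrthologyConfig:
    score_cutoff: float = 0.04
    inflation: float = 2.0
    normalization: str = "maxbit"

    def __post_init__(self) -> None:
        if not (0 < self.score_cutoff <= 1):
            raise ValueError("score_cutoff must be in (0, 1]")
        if self.inflation <= 1:
            raise ValueError("inflation must exceed 1")
        if self.normalization != "maxbit":
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class OrthologGroups:
    """A partition of genes into ortholog groups.

    Group ids are the lexicographically smallest member gene id, so the
    result does not depend on input order.
    """

    gene_to_group: dict[str, str]

    def __post_init__(self) -> None:
        self.groups: dict[str, list[str]] = {}
        for gene, grp in self.gene_to_group.items():
            self.groups.setdefault(grp, []).append(gene)
        for members in self.groups.values():
            members.sort()

    def __len__(self) -> int:
        return len(self.groups)

    def group_of(self, gene_id: str) -> str:
        return self.gene_to_group[gene_id]


def _check_sequence(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    for i, c in enumerate(seq):
        if c not in AA_ALPHABET:
            raise ValueError(f"{label}: illegal character {c!r} at position {i}")


def local_align(a: str, b: str, scoring: ScoringScheme | None = None) -> AlignmentResult:
    """Reference Smith-Waterman with affine gaps (Gotoh), with traceback.

    Returns the optimal local score together with identity and coverage of
    one optimal alignment. When no positive-scoring local alignment exists
    the score is 0 and identity/coverage are reported as 0.
    """
    scoring = scoring or ScoringScheme()
    _check_sequence(a, "sequence a")
    _check_sequence(b, "sequence b")
    sub = scoring.lookup
    go, ge = scoring.gap_open, scoring.gap_extend
    n, m = len(a), len(b)
    NEG = float("-inf")
    # H: best local alignment ending at (i, j); E: ending with gap in a
    # (consuming b); F: gap in b. Traceback pointers recorded per state.
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    ptr: dict[tuple[str, int, int], tuple[str, int, int] | None] = {}
    best, best_pos = 0.0, None
    for i in range(1, n + 1):
        ai = a[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1 = E[i], F[i], F[i - 1]
        for j in range(1, m + 1):
            e = max(Hi[j - 1] - go, Ei[j - 1] - ge)
            Ei[j] = e
            ptr[("E", i, j)] = (
                ("H", i, j - 1) if Hi[j - 1] - go >= Ei[j - 1] - ge else ("E", i, j - 1)
            )
            f = max(Hi1[j] - go, Fi1[j] - ge)
            Fi[j] = f
            ptr[("F", i, j)] = (
                ("H", i - 1, j) if Hi1[j] - go >= Fi1[j] - ge else ("F", i - 1, j)
            )
            diag = Hi1[j - 1] + sub[(ai, b[j - 1])]
            h = max(0.0, diag, e, f)
            Hi[j] = h
            if h == 0:
                ptr[("H", i, j)] = None
            elif h == diag:
                ptr[("H", i, j)] = ("H", i - 1, j - 1)
            elif h == e:
                ptr[("H", i, j)] = ("E", i, j)
            else:
                ptr[("H", i, j)] = ("F", i, j)
            if h > best:
                best, best_pos = h, (i, j)
    if best_pos is None:
        return AlignmentResult(0.0, 0.0, 0.0, 0.0)
    # traceback one optimal alignment
    matches = cols = 0
    i_hi, j_hi = best_pos
    state: tuple[str, int, int] | None = ("H", *best_pos)
    i_lo, j_lo = best_pos
    while state is not None:
        kind, i, j = state
        nxt = ptr.get(state)
        if kind == "H":
            if nxt is not None and nxt[0] == "H" and nxt[1] == i - 1 and nxt[2] == j - 1:
                cols += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i_lo, j_lo = i - 1, j - 1
            elif nxt is None:
                i_lo, j_lo = i, j
        else:
            cols += 1
            if kind == "E":
                j_lo = j - 1
            else:
                i_lo = i - 1
        state = nxt
    identity = matches / cols if cols else 0.0
    return AlignmentResult(
        score=best,
        aligned_identity=identity,
        query_coverage=(i_hi - i_lo) / n,
        target_coverage=(j_hi - j_lo) / m,
    )


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = _load_matrix(matrix_name)
    al.open_gap_score = -gap_open
    al.extend_gap_score = -gap_extend
    return al


def sw_score(
    a: str, b: str, scoring: ScoringScheme | None = None, engine: str = "biopython"
) -> float:
    """Optimal local alignment score under the scheme.

    ``engine="biopython"`` uses the C aligner; ``engine="python"`` uses the
    pure reference DP. Scores are identical.
    """
    scoring = scoring or ScoringScheme()
    if engine == "python":
        return local_align(a, b, scoring).score
    _check_sequence(a, "sequence a")
    _check_sequence(b, "sequence b")
    al = _aligner(scoring.matrix_name, scoring.gap_open, scoring.gap_extend)
    return float(al.score(a, b))


def maxbit_score(
    a: str,
    b: str,
    scoring: ScoringScheme | None = None,
    engine: str = "biopython",
    self_a: float | None = None,
    self_b: float | None = None,
) -> float:
    """score(a, b) normalized by the larger self score; in [0, 1].

    Symmetric, and equal to 1 exactly when the sequences are identical.
    Self scores may be supplied to avoid recomputation.
    """
    scoring = scoring or ScoringScheme()
    saa = sw_score(a, a, scoring, engine) if self_a is None else self_a
    sbb = sw_score(b, b, scoring, engine) if self_b is None else self_b
    sab = sw_score(a, b, scoring, engine)
    return sab / max(saa, sbb)


def build_gene_graph(
    genes: Sequence[GeneRecord],
    config: OrthologyConfig | None = None,
    scoring: ScoringScheme | None = None,
    engine: str = "biopython",
) -> nx.Graph:
    """All-vs-all maxbit comparison of genes into a weighted graph.

    Nodes are ``(genome_id, gene_id)`` composite strings ``genome|gene``
    when gene ids collide across genomes, otherwise plain gene ids; to keep
    downstream bookkeeping simple we always key nodes by
    ``f"{genome_id}|{gene_id}"``. Edges connect pairs whose maxbit score
    meets the cutoff, weighted by that score. Identical sequences are
    deduplicated before alignment.
    """
    if not genes:
        raise ValueError("no genes supplied")
    config = config or OrthologyConfig()
    scoring = scoring or ScoringScheme()
    g = nx.Graph()
    node_ids = []
    for gene in genes:
        nid = f"{gene.genome_id}|{gene.gene_id}"
        if g.has_node(nid):
            raise ValueError(f"duplicate gene node {nid}")
        g.add_node(nid, genome_id=gene.genome_id, cluster_id=gene.cluster_id)
        node_ids.append(nid)
    # dedupe identical sequences: align unique representatives only
    seq_of = {nid: gene.protein_seq for nid, gene in zip(node_ids, genes)}
    uniq: dict[str, list[str]] = {}
    for nid in node_ids:
        uniq.setdefault(seq_of[nid], []).append(nid)
    seqs = sorted(uniq)
    selfs = {s: sw_score(s, s, scoring, engine) for s in seqs}
    # edges among identical-sequence copies: maxbit exactly 1
    for s, members in uniq.items():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                g.add_edge(members[i], members[j], weight=1.0)
    for i in range(len(seqs)):
        si = seqs[i]
        for j in range(i + 1, len(seqs)):
            sj = seqs[j]
            mb = sw_score(si, sj, scoring, engine) / max(selfs[si], selfs[sj])
            if mb >= config.score_cutoff:
                for u in uniq[si]:
                    for v in uniq[sj]:
                        g.add_edge(u, v, weight=mb)
    return g


def mcl(
    adjacency: np.ndarray,
    inflation: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 100,
    prune: float = 1e-5,
    add_self_loops: bool = True,
) -> list[set[int]]:
    """Markov cluster algorithm on a dense nonnegative adjacency matrix.

    Expansion is matrix squaring; inflation is the entrywise power followed
    by column renormalization. Iterates until the max entry change falls
    below ``tol`` or ``max_iter`` is reached (with a warning). Clusters are
    read off the limit matrix as connected components of its support.
    """
    A = np.array(adjacency, dtype=float)
    n = A.shape[0]
    if n == 0:
        return []
    if add_self_loops:
        np.fill_diagonal(A, 1.0)
    M = A / A.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        M2 = M @ M
        np.power(M2, inflation, out=M2)
        M2[M2 < prune] = 0.0
        colsum = M2.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M2 /= colsum
        if np.max(np.abs(M2 - M)) < tol:
            M = M2
            converged = True
            break
        M = M2
    if not converged:
        warnings.warn(
            f"MCL did not converge within {max_iter} iterations; "
            f"emitting current clustering"
        )
    support = (M > prune) | (M.T > prune)
    np.fill_diagonal(support, True)
    comp_graph = nx.from_numpy_array(support.astype(int))
    return [set(c) for c in nx.connected_components(comp_graph)]


def mcl_partition(
    graph: nx.Graph, inflation: float = 2.0, **kwargs
) -> OrthologGroups:
    """Partition a weighted gene graph with MCL.

    Singleton (isolated) nodes form singleton groups. Group ids are named
    by the lexicographically smallest member, making the output independent
    of node insertion order.
    """
    nodes = sorted(graph.nodes())
    idx = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        A[idx[u], idx[v]] = w
        A[idx[v], idx[u]] = w
    clusters = mcl(A, inflation=inflation, **kwargs)
    mapping: dict[str, str] = {}
    for members in clusters:
        names = sorted(nodes[i] for i in members)
        gid = names[0]
        for name in names:
            mapping[name] = gid
    return OrthologGroups(gene_to_group=mapping)


def group_genes(
    genes: Sequence[GeneRecord],
    config: OrthologyConfig | None = None,
    scoring: ScoringScheme | None = None,
    engine: str = "biopython",
) -> OrthologGroups:
    """Convenience: alignment graph construction followed by MCL."""
    config = config or OrthologyConfig()
    graph = build_gene_graph(genes, config, scoring, engine)
    return mcl_partition(graph, inflation=config.inflation)


def write_ortholog_table(
    groups: OrthologGroups, genes: Sequence[GeneRecord], path: str | Path
) -> None:
    rows = []
    for gene in genes:
        nid = f"{gene.genome_id}|{gene.gene_id}"
        rows.append(
            {
                "gene_id": gene.gene_id,
                "genome_id": gene.genome_id,
                "cluster_id": gene.cluster_id,
                "group_id": groups.group_of(nid),
            }
        )
    rows.sort(key=lambda r: (r["genome_id"], r["cluster_id"], r["gene_id"]))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    """Load a precomputed ortholog table (gene_id, genome_id, cluster_id, group_id).

    Lets users bypass alignment with externally computed orthology.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "genome_id", "cluster_id", "group_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
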