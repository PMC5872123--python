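"""Readers and writers for all external formats.

Handles secondary metabolite gene cluster (SMGC) region files in three
dialects (GenBank flat files, a flat TSV schema, and a JSON mirror of the
TSV schema), genome metadata tables, newick phylogenies, presence/absence
matrices, and similarity networks (GraphML / SIF for Cytoscape import).

Coordinates are 1-based inclusive throughout (GenBank convention); the TSV
and JSON dialects adopt the same convention so there is a single one.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import networkx as nx
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

# Closed controlled vocabulary of cluster classes. Free-form labels are
# normalized onto it; anything unrecognized maps to "other" with a warning,
# and multi-class labels (e.g. "nrps-t1pks") map to "hybrid".
CLASS_VOCAB: tuple[str, ...] = (
    "nrps",
    "t1pks",
    "t2pks",
    "t3pks",
    "transatpks",
    "terpene",
    "bacteriocin",
    "lantipeptide",
    "lassopeptide",
    "linaridin",
    "thiopeptide",
    "siderophore",
    "ectoine",
    "melanin",
    "ladderane",
    "butyrolactone",
    "arylpolyene",
    "phosphonate",
    "indole",
    "nucleoside",
    "hybrid",
    "other",
)

CLADE_LABELS: tuple[str, ...] = ("NDR", "SDR", "INT", "OTHER")

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class FormatError(ValueError):
    """Raised when an input file violates its dialect contract."""


def normalize_class(label: str) -> str:
    """Map a free-form cluster-class label onto the controlled vocabulary.

    Unknown labels map to ``"other"`` with a logged warning; compound
    labels (containing ``-`` or the word "hybrid") map to ``"hybrid"``.
    """
    raw = label.strip()
    low = raw.lower().replace("_", "-")
    if low in CLASS_VOCAB:
        return low
    compact = low.replace("-", "")
    if compact in CLASS_VOCAB:
        return compact
    if "hybrid" in low or "-" in low:
        return "hybrid"
    logger.warning("unknown SMGC class label %r mapped to 'other'", label)
    return "other"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRecord:
    """A single called gene inside one cluster region.

    Coordinates are 1-based inclusive within the region. ``strand`` is
    retained for provenance only; downstream analyses use the protein
    sequence exclusively.
    """

    gene_id: str
    genome_id: str
    cluster_id: str
    start: int
    end: int
    strand: str
    protein_seq: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if not self.protein_seq:
            raise ValueError(f"gene {self.gene_id}: empty protein sequence")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        bad = set(self.protein_seq) - AA_ALPHABET
        if bad:
            pos = next(
                i for i, c in enumerate(self.protein_seq) if c in bad
            )
            raise ValueError(
                f"gene {self.gene_id}: illegal residue "
                f"{self.protein_seq[pos]!r} at position {pos}"
            )


@dataclass(frozen=True)
class SmgcRecord:
    """One predicted cluster region with its ordered genes."""

    cluster_id: str
    genome_id: str
    smgc_class: str
    length_bp: int
    genes: tuple[GeneRecord, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"cluster {self.cluster_id}: no genes")
        if self.length_bp < max(g.end for g in self.genes):
            raise ValueError(
                f"cluster {self.cluster_id}: length_bp {self.length_bp} "
                f"smaller than last gene end"
            )
        for g in self.genes:
            if g.genome_id != self.genome_id or g.cluster_id != self.cluster_id:
                raise ValueError(
                    f"cluster {self.cluster_id}: gene {g.gene_id} carries "
                    f"mismatched genome/cluster ids"
                )
        object.__setattr__(
            self, "genes", tuple(sorted(self.genes, key=lambda g: (g.start, g.gene_id)))
        )

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.genes)


@dataclass(frozen=True)
class GenomeMetadata:
    genome_id: str
    clade: str
    genome_size_bp: int
    orf_count: int

    def __post_init__(self) -> None:
        if self.clade not in CLADE_LABELS:
            raise ValueError(
                f"genome {self.genome_id}: unknown clade {self.clade!r} "
                f"(expected one of {CLADE_LABELS})"
            )
        if self.genome_size_bp <= 0 or self.orf_count <= 0:
            raise ValueError(f"genome {self.genome_id}: non-positive size/ORF count")


@dataclass
class Phylogeny:
    """A phylogeny over genome ids, backed by a dendropy tree.

    ``is_rooted`` is True when the seed node is bifurcating; a basal
    trifurcation is accepted and flagged unrooted.
    """

    tree: dendropy.Tree
    is_rooted: bool = True

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        rooted = len(tree.seed_node.child_nodes()) == 2
        return cls(tree=tree, is_rooted=rooted)

    @property
    def leaf_names(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def newick(self) -> str:
        return (
            self.tree.as_string(schema="newick", unquoted_underscores=True)
            .strip()
        )

    def clone(self) -> "Phylogeny":
        return Phylogeny(tree=self.tree.clone(depth=1), is_rooted=self.is_rooted)


# ---------------------------------------------------------------------------
# Cluster regions
# ---------------------------------------------------------------------------

TSV_COLUMNS = [
    "genome_id",
    "cluster_id",
    "smgc_class",
    "length_bp",
    "gene_id",
    "start",
    "end",
    "strand",
    "protein_seq",
]


def read_cluster_regions(
    paths: Sequence[str | Path], dialect: str = "tsv"
) -> list[SmgcRecord]:
    """Read cluster regions from one or more files.

    Returns one :class:`SmgcRecord` per distinct ``(genome_id, cluster_id)``
    with genes ordered by start coordinate and class labels normalized onto
    the controlled vocabulary. Ordering of the result is deterministic
    (sorted by genome id then cluster id).
    """
    readers = {
        "tsv": _read_tsv_regions,
        "json": _read_json_regions,
        "genbank": _read_genbank_regions,
    }
    if dialect not in readers:
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[SmgcRecord] = []
    for p in paths:
        records.extend(readers[dialect](Path(p)))
    _check_unique_gene_ids(records)
    records.sort(key=lambda r: (r.genome_id, r.cluster_id))
    return records


def _check_unique_gene_ids(records: Iterable[SmgcRecord]) -> None:
    seen: dict[tuple[str, str], str] = {}
    for rec in records:
        for g in rec.genes:
            key = (g.genome_id, g.gene_id)
            if key in seen and seen[key] != g.cluster_id:
                raise FormatError(
                    f"duplicate gene_id {g.gene_id!r} within genome "
                    f"{g.genome_id!r} (clusters {seen[key]!r} and "
                    f"{g.cluster_id!r})"
                )
            seen[key] = g.cluster_id


def _assemble(rows_by_cluster: dict[tuple[str, str], dict]) -> list[SmgcRecord]:
    out = []
    for (genome_id, cluster_id), info in sorted(rows_by_cluster.items()):
        out.append(
            SmgcRecord(
                cluster_id=cluster_id,
                genome_id=genome_id,
                smgc_class=normalize_class(info["smgc_class"]),
                length_bp=int(info["length_bp"]),
                genes=tuple(info["genes"]),
            )
        )
    return out


def _read_tsv_regions(path: Path) -> list[SmgcRecord]:
    if path.stat().st_size == 0:
        warnings.warn(f"empty cluster file {path}", stacklevel=3)
        return []
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing TSV columns {sorted(missing)}")
    if df.empty:
        warnings.warn(f"no data rows in cluster file {path}", stacklevel=3)
        return []
    clusters: dict[tuple[str, str], dict] = {}
    for row in df.itertuples(index=False):
        if not isinstance(row.protein_seq, str) or not row.protein_seq:
            raise FormatError(
                f"{path}: gene {row.gene_id} in cluster {row.cluster_id} "
                f"has no protein sequence"
            )
        key = (row.genome_id, row.cluster_id)
        info = clusters.setdefault(
            key,
            {"smgc_class": row.smgc_class, "length_bp": row.length_bp, "genes": []},
        )
        info["genes"].append(
            GeneRecord(
                gene_id=row.gene_id,
                genome_id=row.genome_id,
                cluster_id=row.cluster_id,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                protein_seq=row.protein_seq,
            )
        )
    return _assemble(clusters)


def _read_json_regions(path: Path) -> list[SmgcRecord]:
    if path.stat().st_size == 0:
        warnings.warn(f"empty cluster file {path}", stacklevel=3)
        return []
    data = json.loads(path.read_text())
    clusters: dict[tuple[str, str], dict] = {}
    for entry in data:
        key = (entry["genome_id"], entry["cluster_id"])
        genes = []
        for g in entry["genes"]:
            if not g.get("protein_seq"):
                raise FormatError(
                    f"{path}: gene {g.get('gene_id')} in cluster "
                    f"{entry['cluster_id']} has no protein sequence"
                )
            genes.append(
                GeneRecord(
                    gene_id=g["gene_id"],
                    genome_id=entry["genome_id"],
                    cluster_id=entry["cluster_id"],
                    start=int(g["start"]),
                    end=int(g["end"]),
                    strand=g["strand"],
                    protein_seq=g["protein_seq"],
                )
            )
        clusters[key] = {
            "smgc_class": entry["smgc_class"],
            "length_bp": entry["length_bp"],
            "genes": genes,
        }
    return _assemble(clusters)


def _read_genbank_regions(path: Path) -> list[SmgcRecord]:
    """GenBank flat-file dialect: one region per record.

    The record LOCUS name is the cluster id. The genome id is taken from a
    ``genome_id`` or ``strain`` qualifier on the ``source`` feature, falling
    back to the file stem. The class label comes from a ``product``
    qualifier on a ``region``/``cluster``/``protocluster`` feature when
    present. CDS features must carry ``translation`` qualifiers.
    """
    if path.stat().st_size == 0:
        warnings.warn(f"empty cluster file {path}", stacklevel=3)
        return []
    out: list[SmgcRecord] = []
    default_genome = path.stem.split(".")[0]
    for rec in SeqIO.parse(str(path), "genbank"):
        genome_id = default_genome
        smgc_class = "other"
        genes: list[GeneRecord] = []
        cluster_id = rec.name
        for feat in rec.features:
            if feat.type == "source":
                q = feat.qualifiers
                genome_id = (q.get("genome_id") or q.get("strain") or [genome_id])[0]
            elif feat.type in ("region", "cluster", "protocluster"):
                q = feat.qualifiers
                if "product" in q:
                    smgc_class = q["product"][0]
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            q = feat.qualifiers
            gene_id = (q.get("locus_tag") or q.get("protein_id") or q.get("gene") or [None])[0]
            if gene_id is None:
                raise FormatError(
                    f"{path}: CDS at {feat.location} in {cluster_id} has no "
                    f"locus_tag/protein_id/gene qualifier"
                )
            if "translation" not in q:
                raise FormatError(
                    f"{path}: CDS {gene_id} in record {cluster_id} lacks a "
                    f"translation qualifier"
                )
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    cluster_id=cluster_id,
                    start=int(feat.location.start) + 1,  # to 1-based inclusive
                    end=int(feat.location.end),
                    strand="-" if feat.location.strand == -1 else "+",
                    protein_seq=q["translation"][0].upper(),
                )
            )
        if not genes:
            raise FormatError(f"{path}: record {cluster_id} contains no CDS features")
        out.append(
            SmgcRecord(
                cluster_id=cluster_id,
                genome_id=genome_id,
                smgc_class=normalize_class(smgc_class),
                length_bp=len(rec.seq),
                genes=tuple(genes),
            )
        )
    return out


def write_cluster_regions(
    records: Sequence[SmgcRecord], path: str | Path, dialect: str = "tsv"
) -> None:
    """Serialize cluster regions in the TSV or JSON dialect."""
    path = Path(path)
    records = sorted(records, key=lambda r: (r.genome_id, r.cluster_id))
    if dialect == "tsv":
        rows = []
        for rec in records:
            for g in rec.genes:
                rows.append(
                    {
                        "genome_id": rec.genome_id,
                        "cluster_id": rec.cluster_id,
                        "smgc_class": rec.smgc_class,
                        "length_bp": rec.length_bp,
                        "gene_id": g.gene_id,
                        "start": g.start,
                        "end": g.end,
                        "strand": g.strand,
                        "protein_seq": g.protein_seq,
                    }
                )
        pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    elif dialect == "json":
        data = [
            {
                "genome_id": rec.genome_id,
                "cluster_id": rec.cluster_id,
                "smgc_class": rec.smgc_class,
                "length_bp": rec.length_bp,
                "genes": [
                    {
                        "gene_id": g.gene_id,
                        "start": g.start,
                        "end": g.end,
                        "strand": g.strand,
                        "protein_seq": g.protein_seq,
                    }
                    for g in rec.genes
                ],
            }
            for rec in records
        ]
        path.write_text(json.dumps(data, indent=1) + "\n")
    else:
        raise ValueError(f"unsupported output dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------


def read_metadata(path: str | Path) -> list[GenomeMetadata]:
    """Parse the genome metadata TSV (genome_id, clade, genome_size_bp, orf_count)."""
    df = pd.read_csv(path, sep="\t", dtype=str, skipinitialspace=True)
    required = ["genome_id", "clade", "genome_size_bp", "orf_count"]
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    out: list[GenomeMetadata] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        gid = row.genome_id.strip()
        if gid in seen:
            raise FormatError(f"{path}: duplicated genome_id {gid!r}")
        seen.add(gid)
        try:
            size = int(row.genome_size_bp)
            orfs = int(row.orf_count)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-integer size/ORF count for {gid!r}") from exc
        out.append(
            GenomeMetadata(
                genome_id=gid,
                clade=row.clade.strip(),
                genome_size_bp=size,
                orf_count=orfs,
            )
        )
    return out


def write_metadata(metadata: Sequence[GenomeMetadata], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "genome_id": m.genome_id,
                "clade": m.clade,
                "genome_size_bp": m.genome_size_bp,
                "orf_count": m.orf_count,
            }
            for m in sorted(metadata, key=lambda m: m.genome_id)
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def read_newick(
    path: str | Path, metadata: Sequence[GenomeMetadata] | None = None
) -> Phylogeny:
    """Read a newick tree; optionally cross-check leaves against metadata.

    A mismatch raises an error listing the offending names on both sides.
    """
    phylo = Phylogeny.from_newick(Path(path).read_text())
    if metadata is not None:
        leaves = set(phylo.leaf_names)
        genomes = {m.genome_id for m in metadata}
        missing = sorted(genomes - leaves)
        extra = sorted(leaves - genomes)
        if missing or extra:
            raise FormatError(
                f"{path}: tree/metadata mismatch; genomes without leaves: "
                f"{missing}; leaves without metadata: {extra}"
            )
    return phylo


def write_newick(phylo: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(phylo.newick() + "\n")


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a families x genomes matrix as TSV (family_id index column)."""
    df.to_csv(path, sep="\t", index_label="family_id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="family_id")


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


def write_network(graph: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Export a similarity network for Cytoscape import.

    GraphML round-trips node and edge attributes; SIF carries topology only
    (isolated nodes are written as single-column lines, the Cytoscape
    convention).
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, path, named_key_ids=True)
    elif format == "sif":
        with open(path, "w") as fh:
            written: set[str] = set()
            for u, v in sorted(graph.edges()):
                fh.write(f"{u}\tsim\t{v}\n")
                written.update((u, v))
            for node in sorted(graph.nodes()):
                if node not in written:
                    fh.write(f"{node}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "sif":
        g = nx.Graph()
        for line in path.read_text().splitlines():
            parts = line.split("\t")
            if len(parts) >= 3:
                g.add_edge(parts[0], parts[2])
            elif parts and parts[0]:
                g.add_node(parts[0])
        return g
    raise ValueError(f"unknown network format {format!r}")
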