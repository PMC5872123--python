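"""Pan-SMGC structure and summary statistics.

Presence/absence matrix over families x genomes, the core/accessory/
strain-specific partition at the 80% prevalence rule, clade-specific cores,
occupancy frequency spectra, within/between-clade sharing tabulations,
per-genome class tallies with clade enrichment tests, count statistics, and
known-cluster coverage against a user-supplied reference set.

Statistical conventions: "t-test" means two-sided Welch (unequal variance)
by default, with a pooled-variance option; the prevalence threshold uses a
ceiling rule on each group's own genome count (>=80% of 10 means >=8
genomes); Bonferroni correction divides alpha by the number of classes
tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .family_clustering import FamilyAssignment
from .orthology import OrthologyConfig, ScoringScheme, sw_score
from .smgc_io import CLASS_VOCAB, GenomeMetadata, SmgcRecord


@dataclass(frozen=True)
class PanConfig:
    core_fraction: float = 0.8
    known_cluster_min_frac: float = 0.7
    low_freq_max: int = 3
    near_core_missing_max: int = 3
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("core_fraction", "known_cluster_min_frac", "alpha"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass
class PresenceAbsenceMatrix:
    """Binary families x genomes occupancy with clade annotations.

    ``copy_counts`` preserves multi-copy information (several members of
    one family in the same genome) that the binary matrix collapses.
    """

    df: pd.DataFrame  # families x genomes, entries 0/1
    clades: dict[str, str]  # genome_id -> clade label
    copy_counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.df = self.df.astype(int)
        if ((self.df != 0) & (self.df != 1)).any().any():
            raise ValueError("matrix entries must be 0/1")
        if (self.df.sum(axis=1) == 0).any():
            raise ValueError("every family must be present in at least one genome")
        missing = set(self.df.columns) - set(self.clades)
        if missing:
            raise ValueError(f"genomes without clade annotation: {sorted(missing)}")

    @property
    def family_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.df.columns)

    def clade_genomes(self, clade: str) -> list[str]:
        return sorted(g for g in self.df.columns if self.clades[g] == clade)

    def occupancy(self, genomes: Sequence[str] | None = None) -> pd.Series:
        sub = self.df if genomes is None else self.df[list(genomes)]
        return sub.sum(axis=1)


@dataclass
class PanPartition:
    """Family categories plus per-genome summaries.

    ``category`` maps family -> {"conserved_core", "clade_core",
    "accessory", "strain_specific"}; ``core_clades`` lists, for clade_core
    families, every clade whose own core threshold they meet.
    """

    category: dict[str, str]
    core_clades: dict[str, tuple[str, ...]]
    per_genome: pd.DataFrame  # columns: smgc_count, exclusive_count
    config: PanConfig

    def families_in(self, cat: str, clade: str | None = None) -> list[str]:
        out = []
        for fid, c in self.category.items():
            if c != cat:
                continue
            if clade is not None and clade not in self.core_clades.get(fid, ()):
                continue
            out.append(fid)
        return sorted(out)

    def counts(self) -> dict[str, int]:
        c: dict[str, int] = {}
        for cat in self.category.values():
            c[cat] = c.get(cat, 0) + 1
        return c


def _core_threshold(fraction: float, n: int) -> int:
    """Minimum genome count for core status: ceiling of fraction * n."""
    return int(math.ceil(fraction * n - 1e-9))


def build_matrix(
    assignment: FamilyAssignment, metadata: Sequence[GenomeMetadata]
) -> PresenceAbsenceMatrix:
    """Binary occupancy from a family assignment.

    Multi-copy families (two clusters of one family in the same genome)
    collapse to presence 1; copy counts are retained separately. A cluster
    from a genome absent from the metadata is an error.
    """
    if not assignment.members:
        raise ValueError("empty family assignment")
    genomes = sorted(m.genome_id for m in metadata)
    known = set(genomes)
    clades = {m.genome_id: m.clade for m in metadata}
    fams = sorted(assignment.members)
    counts = pd.DataFrame(0, index=fams, columns=genomes, dtype=int)
    for fid, memb in assignment.members.items():
        for cid, gid in memb:
            if gid not in known:
                raise ValueError(f"cluster {cid}: genome {gid!r} not in metadata")
            counts.loc[fid, gid] += 1
    return PresenceAbsenceMatrix(
        df=(counts > 0).astype(int), clades=clades, copy_counts=counts
    )


def classify_families(
    matrix: PresenceAbsenceMatrix,
    config: PanConfig | None = None,
    clade_groups: Mapping[str, Sequence[str]] | None = None,
) -> PanPartition:
    """Partition families into conserved core / clade core / accessory /
    strain-specific.

    ``clade_groups`` maps clade label -> genome ids; by default every clade
    annotation except ``INT`` and ``OTHER`` with >= 2 genomes forms a
    group. Conserved core takes precedence over clade core; strain-specific
    means occupancy exactly 1 over all genomes; everything else is
    accessory. Clade-core status is judged against each clade's own genome
    count (ceiling rule), and INT genomes count only toward the all-genome
    denominator, not toward any clade core.
    """
    config = config or PanConfig()
    if clade_groups is None:
        clade_groups = {
            clade: matrix.clade_genomes(clade)
            for clade in sorted(set(matrix.clades.values()))
            if clade not in ("INT", "OTHER") and len(matrix.clade_genomes(clade)) >= 2
        }
    for clade, genomes in clade_groups.items():
        if len(genomes) < 2:
            raise ValueError(f"clade {clade!r} needs >= 2 genomes for a clade core")
    n_all = len(matrix.genome_ids)
    thr_all = _core_threshold(config.core_fraction, n_all)
    occ_all = matrix.occupancy()
    category: dict[str, str] = {}
    core_clades: dict[str, tuple[str, ...]] = {}
    clade_occ = {
        clade: matrix.occupancy(genomes) for clade, genomes in clade_groups.items()
    }
    clade_thr = {
        clade: _core_threshold(config.core_fraction, len(genomes))
        for clade, genomes in clade_groups.items()
    }
    for fid in matrix.family_ids:
        if occ_all[fid] >= thr_all:
            category[fid] = "conserved_core"
            continue
        hits = tuple(
            sorted(
                clade
                for clade in clade_groups
                if clade_occ[clade][fid] >= clade_thr[clade]
            )
        )
        if hits:
            category[fid] = "clade_core"
            core_clades[fid] = hits
        elif occ_all[fid] == 1:
            category[fid] = "strain_specific"
        else:
            category[fid] = "accessory"
    smgc_count = (
        matrix.copy_counts.sum(axis=0)
        if matrix.copy_counts is not None
        else matrix.df.sum(axis=0)
    )
    strain_specific = [f for f, c in category.items() if c == "strain_specific"]
    excl = matrix.df.loc[strain_specific].sum(axis=0) if strain_specific else (
        pd.Series(0, index=matrix.genome_ids)
    )
    per_genome = pd.DataFrame(
        {"smgc_count": smgc_count, "exclusive_count": excl}
    ).fillna(0).astype(int)
    return PanPartition(
        category=category,
        core_clades=core_clades,
        per_genome=per_genome,
        config=config,
    )


def frequency_spectrum(
    matrix: PresenceAbsenceMatrix, genomes: Sequence[str] | None = None
) -> dict[int, int]:
    """Counts of families by occupancy 1..n within a genome subset.

    Families absent from the whole subset are excluded; the spectrum sums
    to the number of families present in >= 1 subset genome.
    """
    if genomes is not None and len(genomes) == 0:
        raise ValueError("genome subset must be non-empty")
    occ = matrix.occupancy(genomes)
    occ = occ[occ > 0]
    spectrum: dict[int, int] = {}
    for v in occ:
        spectrum[int(v)] = spectrum.get(int(v), 0) + 1
    return dict(sorted(spectrum.items()))


def sharing_summary(
    matrix: PresenceAbsenceMatrix, clade_a: str = "NDR", clade_b: str = "SDR"
) -> dict[str, int]:
    """Within- and between-clade sharing counts, in both tabulations.

    Overlapping counts: ``shared_within_<X>`` is families in >= 2 genomes
    of clade X; ``shared_across`` is families in >= 1 genome of each clade
    (a family can contribute to all three). Exclusive counts restrict the
    within-clade figures to families absent from the other clade, and
    ``across`` stays as defined.
    """
    ga = matrix.clade_genomes(clade_a)
    gb = matrix.clade_genomes(clade_b)
    if not ga or not gb:
        raise ValueError("both clades must contain genomes")
    occ_a = matrix.occupancy(ga)
    occ_b = matrix.occupancy(gb)
    within_a = occ_a >= 2
    within_b = occ_b >= 2
    across = (occ_a >= 1) & (occ_b >= 1)
    return {
        f"shared_within_{clade_a}": int(within_a.sum()),
        f"shared_within_{clade_b}": int(within_b.sum()),
        "shared_across": int(across.sum()),
        f"shared_within_{clade_a}_exclusive": int((within_a & (occ_b == 0)).sum()),
        f"shared_within_{clade_b}_exclusive": int((within_b & (occ_a == 0)).sum()),
        "shared_within_both": int((within_a & within_b).sum()),
    }


def class_tally(
    smgcs: Sequence[SmgcRecord], metadata: Sequence[GenomeMetadata]
) -> pd.DataFrame:
    """Per-genome counts of clusters in each class (genomes x classes).

    Every vocabulary class is retained as a column even when absent
    genome-wide, so row sums equal per-genome cluster counts and columns
    are comparable across datasets.
    """
    genomes = sorted(m.genome_id for m in metadata)
    tally = pd.DataFrame(0, index=genomes, columns=list(CLASS_VOCAB), dtype=int)
    for rec in smgcs:
        if rec.genome_id not in tally.index:
            raise ValueError(f"cluster {rec.cluster_id}: genome not in metadata")
        tally.loc[rec.genome_id, rec.smgc_class] += 1
    return tally


def class_tally_from_table(
    table: pd.DataFrame, metadata: Sequence[GenomeMetadata]
) -> pd.DataFrame:
    """Class tally from a family table frame with a consensus_class column."""
    genomes = sorted(m.genome_id for m in metadata)
    tally = pd.DataFrame(0, index=genomes, columns=list(CLASS_VOCAB), dtype=int)
    for row in table.itertuples(index=False):
        tally.loc[row.genome_id, row.consensus_class] += 1
    return tally


def _welch(x: np.ndarray, y: np.ndarray, pooled: bool = False) -> tuple[float, float]:
    """Two-sided t-test robust to zero-variance degenerate inputs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return math.inf if x.mean() > y.mean() else -math.inf, 0.0
    t, p = stats.ttest_ind(x, y, equal_var=pooled)
    return float(t), float(p)


def class_enrichment(
    tally: pd.DataFrame,
    clades: Mapping[str, str],
    clade_a: str = "NDR",
    clade_b: str = "SDR",
    alpha: float = 0.05,
    n_classes: int | None = None,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-class two-sample t-test between clades with Bonferroni control.

    Returns a frame indexed by class with columns t, p, significant; the
    significance threshold is ``alpha / n_classes`` (0.05 / 22 ~ 0.00227 at
    the defaults). Classes with zero variance and equal means in both
    clades give p = 1.
    """
    ga = sorted(g for g in tally.index if clades.get(g) == clade_a)
    gb = sorted(g for g in tally.index if clades.get(g) == clade_b)
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each clade needs >= 2 genomes")
    n_classes = n_classes or tally.shape[1]
    cutoff = alpha / n_classes
    rows = []
    for cls in tally.columns:
        t, p = _welch(tally.loc[ga, cls].values, tally.loc[gb, cls].values, pooled)
        rows.append({"class": cls, "t": t, "p": p, "significant": p < cutoff})
    return pd.DataFrame(rows).set_index("class")


def count_statistics(
    metadata: Sequence[GenomeMetadata],
    smgc_counts: Mapping[str, int],
    clade_a: str = "NDR",
    clade_b: str = "SDR",
    pooled: bool = False,
) -> dict:
    """Clade means/SDs and tests for cluster counts, ORF counts, genome
    size; Pearson correlation of genome size vs cluster count over all
    genomes; and the cluster:ORF ratio test.

    SDs are sample SDs (ddof=1); tests are two-sided Welch by default.
    Requires >= 3 genomes per clade.
    """
    meta = {m.genome_id: m for m in metadata}
    ga = sorted(g for g, m in meta.items() if m.clade == clade_a)
    gb = sorted(g for g, m in meta.items() if m.clade == clade_b)
    if len(ga) < 3 or len(gb) < 3:
        raise ValueError("count_statistics requires >= 3 genomes per clade")

    def vectors(genomes: list[str]):
        return {
            "smgc_count": np.array([float(smgc_counts[g]) for g in genomes]),
            "orf_count": np.array([float(meta[g].orf_count) for g in genomes]),
            "genome_size_bp": np.array(
                [float(meta[g].genome_size_bp) for g in genomes]
            ),
        }

    va, vb = vectors(ga), vectors(gb)
    va["smgc_per_orf"] = va["smgc_count"] / va["orf_count"]
    vb["smgc_per_orf"] = vb["smgc_count"] / vb["orf_count"]
    out: dict = {}
    for key in ("smgc_count", "orf_count", "genome_size_bp", "smgc_per_orf"):
        t, p = _welch(va[key], vb[key], pooled)
        out[key] = {
            f"{clade_a}_mean": float(va[key].mean()),
            f"{clade_a}_sd": float(va[key].std(ddof=1)),
            f"{clade_b}_mean": float(vb[key].mean()),
            f"{clade_b}_sd": float(vb[key].std(ddof=1)),
            "t": t,
            "p": p,
        }
    all_genomes = sorted(meta)
    sizes = np.array([float(meta[g].genome_size_bp) for g in all_genomes])
    counts = np.array([float(smgc_counts[g]) for g in all_genomes])
    if np.ptp(sizes) == 0 or np.ptp(counts) == 0:
        out["size_vs_smgc"] = {"pearson_r": float("nan"), "p": float("nan")}
    else:
        r, rp = stats.pearsonr(sizes, counts)
        out["size_vs_smgc"] = {"pearson_r": float(r), "p": float(rp)}
    return out


def ks_compare(
    spectrum_a: Mapping[int, int], spectrum_b: Mapping[int, int]
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on occupancy spectra.

    Spectra (occupancy -> family count) are expanded to observation lists;
    exact p-values are used where scipy's auto policy allows.
    """
    if not spectrum_a or not spectrum_b:
        raise ValueError("spectra must be non-empty")
    xs = [occ for occ, cnt in sorted(spectrum_a.items()) for _ in range(cnt)]
    ys = [occ for occ, cnt in sorted(spectrum_b.items()) for _ in range(cnt)]
    res = stats.ks_2samp(xs, ys, method="auto")
    return float(res.statistic), float(res.pvalue)


def known_cluster_coverage(
    smgc: SmgcRecord,
    reference_clusters: Sequence[SmgcRecord],
    config: OrthologyConfig | None = None,
    pan_config: PanConfig | None = None,
    scoring: ScoringScheme | None = None,
    engine: str = "biopython",
) -> dict:
    """Fraction of a cluster's genes with a hit in the best reference.

    A gene "hits" a reference cluster when its maxbit score against any
    reference gene meets the orthology cutoff; the best reference maximizes
    the hit fraction (ties broken by smallest reference cluster id). The
    well-characterized flag is true when the fraction meets
    ``known_cluster_min_frac`` (default 0.7). With an empty reference set
    the fraction is None and the flag false.
    """
    config = config or OrthologyConfig()
    pan_config = pan_config or PanConfig()
    scoring = scoring or ScoringScheme()
    if not reference_clusters:
        return {"fraction": None, "well_characterized": False, "best_reference": None}
    self_scores = {
        g.protein_seq: sw_score(g.protein_seq, g.protein_seq, scoring, engine)
        for rec in (smgc, *reference_clusters)
        for g in rec.genes
    }
    best_frac, best_ref = -1.0, None
    for ref in sorted(reference_clusters, key=lambda r: r.cluster_id):
        hits = 0
        for gene in smgc.genes:
            sg = self_scores[gene.protein_seq]
            for rgene in ref.genes:
                sr = self_scores[rgene.protein_seq]
                mb = sw_score(gene.protein_seq, rgene.protein_seq, scoring, engine) / max(
                    sg, sr
                )
                if mb >= config.score_cutoff:
                    hits += 1
                    break
        frac = hits / len(smgc.genes)
        if frac > best_frac:
            best_frac, best_ref = frac, ref.cluster_id
    return {
        "fraction": best_frac,
        "well_characterized": best_frac >= pan_config.known_cluster_min_frac,
        "best_reference": best_ref,
    }
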