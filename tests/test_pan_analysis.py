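"""Tests for the pan-SMGC partition and summary statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from smgcpan import pan_analysis as pan
from smgcpan.family_clustering import FamilyAssignment
from smgcpan.orthology import OrthologyConfig
from smgcpan.smgc_io import GenomeMetadata
from smgcpan.synthetic_data import paper_fixture
from tests.conftest import make_cluster


def matrix_from(presence: dict[str, list[str]], clades: dict[str, str],
                genomes=None):
    genomes = genomes or sorted(clades)
    df = pd.DataFrame(0, index=sorted(presence), columns=genomes, dtype=int)
    for fid, gs in presence.items():
        df.loc[fid, gs] = 1
    return pan.PresenceAbsenceMatrix(df=df, clades=clades)


def clades_10_10_4():
    clades = {f"n{i:02d}": "NDR" for i in range(10)}
    clades.update({f"s{i:02d}": "SDR" for i in range(10)})
    clades.update({f"i{i:02d}": "INT" for i in range(4)})
    return clades


class TestBuildMatrix:
    def _assignment(self):
        return FamilyAssignment(
            cluster_to_family={"c1": "f1", "c2": "f1", "c3": "f1"},
            members={"f1": [("c1", "g1"), ("c2", "g2"), ("c3", "g2")]},
            consensus_class={"f1": "nrps"},
        )

    def _meta(self):
        return [
            GenomeMetadata("g1", "NDR", 8_000_000, 7000),
            GenomeMetadata("g2", "SDR", 8_000_000, 7000),
            GenomeMetadata("g3", "SDR", 8_000_000, 7000),
        ]

    def test_row_sum_and_multicopy(self):
        m = pan.build_matrix(self._assignment(), self._meta())
        assert int(m.df.loc["f1"].sum()) == 2  # g1 and g2
        assert m.df.loc["f1", "g2"] == 1  # presence collapses
        assert m.copy_counts.loc["f1", "g2"] == 2  # copies retained

    def test_orphan_genome_errors(self):
        asg = self._assignment()
        asg.members["f1"].append(("c9", "nowhere"))
        with pytest.raises(ValueError, match="nowhere"):
            pan.build_matrix(asg, self._meta())

    def test_empty_assignment_errors(self):
        empty = FamilyAssignment({}, {}, {})
        with pytest.raises(ValueError):
            pan.build_matrix(empty, self._meta())


class TestClassify:
    def test_83_percent_is_conserved_core(self):
        clades = clades_10_10_4()
        genomes = sorted(clades)
        fam_in_20 = genomes[:20]  # 20/24 = 83% >= 80%
        m = matrix_from({"f1": fam_in_20, "f2": [genomes[0]]}, clades)
        part = pan.classify_families(m)
        assert part.category["f1"] == "conserved_core"
        assert part.category["f2"] == "strain_specific"

    def test_19_of_24_not_conserved_core(self):
        clades = clades_10_10_4()
        genomes = sorted(clades)
        m = matrix_from({"f1": genomes[:19], "f2": [genomes[0]]}, clades)
        part = pan.classify_families(m)
        assert part.category["f1"] != "conserved_core"

    def test_nine_of_ten_ndr_is_clade_core(self):
        clades = clades_10_10_4()
        ndr = sorted(g for g, c in clades.items() if c == "NDR")
        m = matrix_from({"f1": ndr[:9], "f2": [ndr[0]]}, clades)
        part = pan.classify_families(m)
        assert part.category["f1"] == "clade_core"
        assert part.core_clades["f1"] == ("NDR",)

    def test_categories_partition(self):
        matrix, _ = paper_fixture(3)
        part = pan.classify_families(matrix)
        counts = part.counts()
        assert sum(counts.values()) == len(matrix.family_ids)

    def test_core_fraction_one_requires_all_genomes(self):
        clades = clades_10_10_4()
        genomes = sorted(clades)
        m = matrix_from({"f1": genomes, "f2": genomes[:23]}, clades)
        part = pan.classify_families(m, pan.PanConfig(core_fraction=1.0))
        assert part.category["f1"] == "conserved_core"
        assert part.category["f2"] != "conserved_core"

    def test_exclusive_counts(self):
        clades = clades_10_10_4()
        genomes = sorted(clades)
        m = matrix_from(
            {"f1": [genomes[0]], "f2": [genomes[0]], "f3": genomes[:2]}, clades
        )
        part = pan.classify_families(m)
        assert part.per_genome.loc[genomes[0], "exclusive_count"] == 2


class TestSpectrum:
    def test_three_singletons(self):
        clades = {"a": "NDR", "b": "NDR", "c": "SDR"}
        m = matrix_from({"f1": ["a"], "f2": ["b"], "f3": ["c"]}, clades)
        assert pan.frequency_spectrum(m) == {1: 3}

    def test_one_family_everywhere(self):
        clades = {"a": "NDR", "b": "NDR", "c": "SDR"}
        m = matrix_from({"f1": ["a", "b", "c"]}, clades)
        assert pan.frequency_spectrum(m) == {3: 1}

    def test_fixture_has_177_singletons(self):
        matrix, _ = paper_fixture(0)
        spec = pan.frequency_spectrum(matrix)
        assert spec[1] == 177
        assert sum(spec.values()) == 310

    def test_subset_spectrum_sums_to_present_families(self):
        matrix, _ = paper_fixture(1)
        ndr = matrix.clade_genomes("NDR")
        spec = pan.frequency_spectrum(matrix, ndr)
        present = int((matrix.df[ndr].sum(axis=1) > 0).sum())
        assert sum(spec.values()) == present


class TestSharing:
    def test_definitions(self):
        clades = clades_10_10_4()
        ndr = sorted(g for g, c in clades.items() if c == "NDR")
        sdr = sorted(g for g, c in clades.items() if c == "SDR")
        m = matrix_from(
            {
                "f_within_ndr": ndr[:2],
                "f_across": [ndr[0], sdr[0]],
                "f_both": ndr[:2] + sdr[:2],
            },
            clades,
        )
        s = pan.sharing_summary(m)
        assert s["shared_within_NDR"] == 2  # f_within_ndr, f_both
        assert s["shared_within_SDR"] == 1  # f_both
        assert s["shared_across"] == 2  # f_across, f_both
        assert s["shared_within_NDR_exclusive"] == 1
        assert s["shared_within_both"] == 1


class TestClassTally:
    def _meta(self):
        return [
            GenomeMetadata("g1", "NDR", 8_000_000, 7000),
            GenomeMetadata("g2", "SDR", 8_000_000, 7000),
        ]

    def test_counts_and_row_sums(self):
        smgcs = [
            make_cluster(f"c{i}", "g1", ["MKL"], "terpene") for i in range(3)
        ] + [make_cluster(f"d{i}", "g1", ["MKL"], "nrps") for i in range(2)]
        tally = pan.class_tally(smgcs, self._meta())
        assert tally.loc["g1", "terpene"] == 3
        assert tally.loc["g1", "nrps"] == 2
        assert int(tally.loc["g1"].sum()) == 5

    def test_absent_class_column_retained(self):
        tally = pan.class_tally(
            [make_cluster("c1", "g1", ["MKL"], "nrps")], self._meta()
        )
        assert "ladderane" in tally.columns
        assert int(tally["ladderane"].sum()) == 0

    def test_total_conservation(self):
        smgcs = [
            make_cluster(f"c{i}", "g1", ["MKL"], "nrps") for i in range(4)
        ] + [make_cluster(f"d{i}", "g2", ["MKL"], "terpene") for i in range(3)]
        tally = pan.class_tally(smgcs, self._meta())
        assert int(tally.values.sum()) == len(smgcs)


class TestEnrichment:
    def _clades(self, n=10):
        out = {f"n{i:02d}": "NDR" for i in range(n)}
        out.update({f"s{i:02d}": "SDR" for i in range(n)})
        return out

    def _tally(self, clades, fill):
        genomes = sorted(clades)
        tally = pd.DataFrame(0, index=genomes, columns=["melanin", "nrps"], dtype=int)
        for g in genomes:
            tally.loc[g] = fill(clades[g])
        return tally

    def test_identical_distributions_nothing_significant(self):
        clades = self._clades()
        tally = self._tally(clades, lambda c: [2, 5])
        res = pan.class_enrichment(tally, clades, n_classes=22)
        assert not res["significant"].any()
        assert (res["p"] == 1.0).all()

    def test_clean_separation_significant(self):
        # 3 in every NDR genome, 0 in every SDR genome (n=10, 10): the
        # zero-variance rule gives p ~ 0, significant after Bonferroni
        clades = self._clades()
        tally = self._tally(clades, lambda c: [3 if c == "NDR" else 0, 5])
        res = pan.class_enrichment(tally, clades, n_classes=22)
        assert bool(res.loc["melanin", "significant"])
        assert not bool(res.loc["nrps", "significant"])

    def test_matches_reference_welch(self, rng):
        clades = self._clades(6)
        genomes = sorted(clades)
        tally = pd.DataFrame(
            rng.poisson(3.0, size=(12, 2)), index=genomes,
            columns=["melanin", "nrps"],
        )
        from scipy import stats as ss

        res = pan.class_enrichment(tally, clades, n_classes=2)
        ndr = [g for g in genomes if clades[g] == "NDR"]
        sdr = [g for g in genomes if clades[g] == "SDR"]
        for cls in ("melanin", "nrps"):
            t, p = ss.ttest_ind(
                tally.loc[ndr, cls], tally.loc[sdr, cls], equal_var=False
            )
            assert res.loc[cls, "t"] == pytest.approx(t)
            assert res.loc[cls, "p"] == pytest.approx(p)

    def test_permutation_of_genome_order_invariant(self, rng):
        clades = self._clades(5)
        genomes = sorted(clades)
        tally = pd.DataFrame(
            rng.poisson(2.0, size=(10, 2)), index=genomes,
            columns=["melanin", "nrps"],
        )
        res1 = pan.class_enrichment(tally, clades)
        perm = list(genomes)
        rng.shuffle(perm)
        res2 = pan.class_enrichment(tally.loc[perm], clades)
        pd.testing.assert_frame_equal(res1, res2)


class TestCountStatistics:
    def _meta(self, sizes_a, sizes_b):
        out = []
        for i, s in enumerate(sizes_a):
            out.append(GenomeMetadata(f"n{i}", "NDR", s, 7000 + i))
        for i, s in enumerate(sizes_b):
            out.append(GenomeMetadata(f"s{i}", "SDR", s, 7000 + i))
        return out

    def test_identical_clades(self):
        meta = self._meta([8_000_000] * 3, [8_000_000] * 3)
        counts = {m.genome_id: 40 for m in meta}
        out = pan.count_statistics(meta, counts)
        assert out["smgc_count"]["t"] == 0.0
        assert out["smgc_count"]["p"] == 1.0

    def test_hand_welch_oracle(self):
        meta = self._meta(
            [8_100_000, 8_200_000, 8_050_000], [7_900_000, 7_850_000, 7_950_000]
        )
        counts = dict(zip([m.genome_id for m in meta], [40, 41, 40, 33, 34, 34]))
        out = pan.count_statistics(meta, counts)
        x, y = np.array([40.0, 41, 40]), np.array([33.0, 34, 34])
        vx, vy = x.var(ddof=1) / 3, y.var(ddof=1) / 3
        t_hand = (x.mean() - y.mean()) / math.sqrt(vx + vy)
        assert out["smgc_count"][f"NDR_mean"] == pytest.approx(40.3333, abs=1e-3)
        assert out["smgc_count"][f"SDR_mean"] == pytest.approx(33.6667, abs=1e-3)
        assert out["smgc_count"]["t"] == pytest.approx(t_hand)
        assert out["smgc_count"]["p"] < 0.01

    def test_perfect_linear_correlation(self):
        meta = self._meta(
            [8_000_000, 8_200_000, 8_400_000], [7_400_000, 7_600_000, 7_800_000]
        )
        counts = {m.genome_id: m.genome_size_bp // 200_000 for m in meta}
        out = pan.count_statistics(meta, counts)
        assert out["size_vs_smgc"]["pearson_r"] == pytest.approx(1.0)

    def test_too_few_genomes_errors(self):
        meta = self._meta([8_000_000] * 2, [8_000_000] * 3)
        with pytest.raises(ValueError):
            pan.count_statistics(meta, {m.genome_id: 1 for m in meta})


class TestKs:
    def test_identical_spectra(self):
        assert pan.ks_compare({1: 5, 3: 2}, {1: 5, 3: 2}) == (0.0, 1.0)

    def test_disjoint_supports(self):
        d, p = pan.ks_compare({1: 10}, {10: 10})
        assert d == 1.0

    def test_matches_manual_ecdf(self, rng):
        sa = {int(k): int(v) for k, v in zip(range(1, 6), rng.integers(1, 8, 5))}
        sb = {int(k): int(v) for k, v in zip(range(2, 7), rng.integers(1, 8, 5))}
        d, _ = pan.ks_compare(sa, sb)
        xs = [k for k, v in sa.items() for _ in range(v)]
        ys = [k for k, v in sb.items() for _ in range(v)]
        grid = sorted(set(xs + ys))
        d_manual = max(
            abs(
                sum(x <= g for x in xs) / len(xs)
                - sum(y <= g for y in ys) / len(ys)
            )
            for g in grid
        )
        assert d == pytest.approx(d_manual)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pan.ks_compare({}, {1: 1})


class TestKnownClusterCoverage:
    def _smgc(self, rng, n_hit, n_total):
        from tests.conftest import random_protein

        shared = [random_protein(rng, 60, 90) for _ in range(n_hit)]
        private = ["W" * 120 for _ in range(n_total - n_hit)]
        smgc = make_cluster("query", "g1", shared + private)
        ref = make_cluster("ref1", "REF", shared + ["P" * 120])
        return smgc, [ref]

    def test_identical_full_coverage(self, rng):
        smgc, refs = self._smgc(rng, 5, 5)
        out = pan.known_cluster_coverage(smgc, refs)
        assert out["fraction"] == 1.0
        assert out["well_characterized"]

    def test_seven_of_ten_passes(self, rng):
        smgc, refs = self._smgc(rng, 7, 10)
        out = pan.known_cluster_coverage(smgc, refs)
        assert out["fraction"] == pytest.approx(0.7)
        assert out["well_characterized"]

    def test_six_of_ten_fails(self, rng):
        smgc, refs = self._smgc(rng, 6, 10)
        out = pan.known_cluster_coverage(smgc, refs)
        assert out["fraction"] == pytest.approx(0.6)
        assert not out["well_characterized"]

    def test_empty_reference_set(self, rng):
        smgc, _ = self._smgc(rng, 2, 2)
        out = pan.known_cluster_coverage(smgc, [])
        assert out["fraction"] is None
        assert not out["well_characterized"]
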