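import numpy as np
import pytest

from chromarch.annotation import AnnotationError
from chromarch.clusters import (
    FamilySpec,
    average_distribution_number,
    average_spacing_kb,
    clustered_fraction,
    detect_clusters,
    detect_secretome_clusters,
    permutation_test,
    window_parameters,
)

from .conftest import brute_force_max_gap_clusters, toy_annotation


def make_spec(ann, label="FAM", **kw):
    return FamilySpec.from_annotation(ann, label, **kw)


class TestDistributionNumbers:
    def test_worked_example(self):
        # 9194 ORFs over 184 family genes: the "value was 50" example
        assert average_distribution_number(9194, 184) == pytest.approx(49.967, abs=0.01)
        assert average_distribution_number(100, 100) == 1.0
        assert average_distribution_number(9194, 228) == pytest.approx(40.32, abs=0.01)

    def test_zero_members_errors(self):
        with pytest.raises(ValueError):
            average_distribution_number(9194, 0)
        with pytest.raises(ValueError):
            average_spacing_kb(1000, 0)

    def test_spacing_kb(self):
        # 33.3 Mb genome, 228 CAZymes -> one per 146.052 kb
        assert average_spacing_kb(33_300, 228) == 146.052
        assert average_spacing_kb(1000, 10) == 100.0
        # at one gene per 3.56 kb that is one CAZyme per 41 ORFs
        assert round(146.052 / 3.56) == 41

    def test_window_parameters(self):
        assert window_parameters(50, 3) == (10, 30)
        assert window_parameters(41, 3)[0] == 8
        assert window_parameters(5, 3) == (1, 3)
        with pytest.raises(ValueError):
            window_parameters(0, 3)


class TestDetectClusters:
    def test_close_members_form_cluster(self):
        ann = toy_annotation(40, {"FAM": {1, 5, 9}})
        spec = make_spec(ann, gap_threshold=8)
        (c,) = detect_clusters(ann, spec)
        assert c.n_members == 3
        assert (c.first_ordinal, c.last_ordinal) == (1, 9)

    def test_spread_members_do_not(self):
        ann = toy_annotation(40, {"FAM": {1, 15, 30}})
        spec = make_spec(ann, gap_threshold=8)
        assert detect_clusters(ann, spec) == []

    def test_unknown_label_errors(self):
        ann = toy_annotation(10, {"FAM": {1}})
        with pytest.raises(AnnotationError):
            make_spec(ann, "NOPE")

    def test_span_is_member_envelope(self):
        ann = toy_annotation(40, {"FAM": {2, 4, 6}})
        (c,) = detect_clusters(ann, make_spec(ann, gap_threshold=3))
        assert c.span_bp == (2 * 1000, 6 * 1000 + 500)

    def test_never_spans_chromosomes(self):
        # members at the tail of chrA and head of chrB: junction must break them
        ann = toy_annotation(10, {"FAM": {7, 8, 9}}, extra_chroms={"chrB": 10})
        from chromarch.annotation import GeneRecord, build_annotation

        genes = [g for g in ann.genes()]
        relabeled = []
        for g in genes:
            if g.chrom_id == "chrB" and g.ordinal in (0, 1, 2):
                relabeled.append(
                    GeneRecord(g.gene_id, g.chrom_id, g.start, g.end, g.strand,
                               labels=frozenset({"FAM"}))
                )
            else:
                relabeled.append(g)
        ann2 = build_annotation(
            relabeled, {"chrA": 10_500, "chrB": 10_500}
        )
        clusters = detect_clusters(ann2, make_spec(ann2, gap_threshold=8))
        assert all(len({c.chrom_id}) == 1 for c in clusters)
        assert sorted(c.chrom_id for c in clusters) == ["chrA", "chrB"]

    def test_membership_ignores_bp_coordinates(self):
        a1 = toy_annotation(50, {"FAM": {3, 6, 9, 30}}, spacing=1000)
        a2 = toy_annotation(50, {"FAM": {3, 6, 9, 30}}, spacing=7777, gene_len=123)
        s1, s2 = make_spec(a1, gap_threshold=4), make_spec(a2, gap_threshold=4)
        m1 = [c.first_ordinal for c in detect_clusters(a1, s1)]
        m2 = [c.first_ordinal for c in detect_clusters(a2, s2)]
        assert m1 == m2 == [3]

    def test_monotone_in_gap_threshold(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(30, 120))
            members = set(map(int, rng.choice(n, size=int(rng.integers(5, 15)),
                                              replace=False)))
            ann = toy_annotation(n, {"FAM": members})
            counts = []
            for gap in range(0, 12):
                spec = make_spec(ann, gap_threshold=gap)
                counts.append(sum(c.n_members for c in detect_clusters(ann, spec)))
            assert counts == sorted(counts)

    def test_matches_bruteforce_oracle_quick(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(20, 200))
            k = int(rng.integers(4, min(n, 25)))
            members = set(map(int, rng.choice(n, size=k, replace=False)))
            gap = int(rng.integers(1, 9))
            ann = toy_annotation(n, {"FAM": members})
            got = [
                tuple(ann.gene(g).ordinal for g in c.member_ids)
                for c in detect_clusters(ann, make_spec(ann, gap_threshold=gap))
            ]
            assert sorted(got) == brute_force_max_gap_clusters(members, gap)


class TestMeanGapMode:
    def test_mean_gap_admits_one_large_gap(self):
        # gaps 1 and 8: mean 4.5 < 5 passes mean-gap but fails max_gap at 4
        ann = toy_annotation(40, {"FAM": {0, 2, 11}})
        spec = FamilySpec("FAM", "FAM", 3, D=25.0, gap_threshold=4, mode="mean_gap")
        (c,) = detect_clusters(ann, spec)
        assert c.n_members == 3
        spec_max = FamilySpec("FAM", "FAM", 3, D=25.0, gap_threshold=4, mode="max_gap")
        assert detect_clusters(ann, spec_max) == []

    def test_mean_gap_runs_satisfy_bound(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(30, 150))
            members = set(map(int, rng.choice(n, size=int(rng.integers(5, 20)),
                                              replace=False)))
            ann = toy_annotation(n, {"FAM": members})
            D = float(rng.uniform(10, 60))
            spec = FamilySpec("FAM", "FAM", len(members), D=D,
                              gap_threshold=D / 5, mode="mean_gap")
            for c in detect_clusters(ann, spec):
                ords = [ann.gene(g).ordinal for g in c.member_ids]
                gaps = [b - a - 1 for a, b in zip(ords, ords[1:])]
                assert sum(gaps) / len(gaps) < D / 5


class TestSecretomeRule:
    @pytest.mark.parametrize(
        "pattern,expected",
        [
            ("SSS", [(3, 0)]),        # (n secreted members, n interruptions)
            ("SSNSS", [(4, 1)]),
            ("SNSNS", []),
            ("NSSSN", [(3, 0)]),
            ("SSSNSS", [(5, 1)]),     # merged group, boundaries secreted
            ("SSNSSNSS", [(4, 1)]),   # greedy left-to-right merge, then S S too short
            ("SSNS", []),             # only 3 secreted with an interruption
        ],
    )
    def test_patterns(self, pattern, expected):
        ords = {i for i, ch in enumerate(pattern) if ch == "S"}
        ann = toy_annotation(len(pattern), {"SECRETED": ords})
        got = [
            (c.n_members, (c.last_ordinal - c.first_ordinal + 1) - c.n_members)
            for c in detect_secretome_clusters(ann)
        ]
        assert got == expected

    def test_boundaries_always_secreted(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n = 40
            members = set(map(int, rng.choice(n, size=12, replace=False)))
            ann = toy_annotation(n, {"SECRETED": members})
            for c in detect_secretome_clusters(ann):
                assert c.first_ordinal in members and c.last_ordinal in members


class TestClusteredFraction:
    def test_all_in_one_cluster_is_100(self):
        ann = toy_annotation(30, {"FAM": {5, 6, 7}})
        spec = make_spec(ann, gap_threshold=2)
        assert clustered_fraction(ann, spec) == 100.0

    def test_planted_fraction_recovered(self, dataset):
        ann = dataset.annotation
        spec = FamilySpec.from_annotation(ann, "CAZYME")
        clusters = detect_clusters(ann, spec)
        clustered = {g for c in clusters for g in c.member_ids}
        planted = {
            g for p in dataset.manifest["planted_clusters"]
            if p["family"] == "CAZYME" for g in p["gene_ids"]
        }
        assert planted <= clustered
        assert clustered_fraction(ann, spec, clusters) >= 100.0 * len(planted) / spec.n_members

    def test_over_30_percent_threshold_flag(self, dataset):
        ann = dataset.annotation
        spec = FamilySpec.from_annotation(ann, "CAZYME")
        frac = clustered_fraction(ann, spec)
        assert (frac > 30.0) is True  # planted genome clusters a third+ of CAZymes


class TestPermutationTest:
    def test_requires_enough_permutations(self):
        ann = toy_annotation(30, {"FAM": {1, 2, 3}})
        with pytest.raises(ValueError):
            permutation_test(ann, make_spec(ann, gap_threshold=2), n_perm=10)

    def test_packed_family_attains_minimal_p(self):
        ann = toy_annotation(200, {"FAM": {10, 11, 12, 13, 14}})
        spec = make_spec(ann, gap_threshold=1)
        res = permutation_test(ann, spec, n_perm=99, seed=0)
        assert res.observed_clustered_fraction == 100.0
        assert res.p_value == pytest.approx(1 / 100)

    def test_seeded_determinism(self):
        ann = toy_annotation(100, {"FAM": {5, 30, 31, 60, 90}})
        spec = make_spec(ann, gap_threshold=3)
        r1 = permutation_test(ann, spec, n_perm=199, seed=42)
        r2 = permutation_test(ann, spec, n_perm=199, seed=42)
        assert r1.p_value == r2.p_value
        assert r1.null_fractions == r2.null_fractions

    def test_p_in_valid_range(self):
        ann = toy_annotation(100, {"FAM": {5, 30, 55, 80, 95}})
        spec = make_spec(ann, gap_threshold=3)
        res = permutation_test(ann, spec, n_perm=99, seed=1)
        assert 1 / 100 <= res.p_value <= 1.0
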