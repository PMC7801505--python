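"""Sponge screen: cluster intersection, orthology, duplex scan, overlap removal."""

import numpy as np
import pytest

from circpipe import simulate as sim
from circpipe.sponge import (
    BindingSite,
    MirnaRecord,
    SpongeCluster,
    duplex_profile,
    filter_orthology,
    intersect_clusters,
    per_base_ratio,
    remove_overlaps,
    scan_binding_sites,
)
from circpipe.types import GenomicInterval


def cluster(start, end, mirna="miR-7"):
    return SpongeCluster(GenomicInterval("hchr1", start, end), mirna, 10)


class TestIntersectClusters:
    def test_cluster_fully_inside_circ(self):
        pairs = intersect_clusters([("c1", GenomicInterval("hchr1", 0, 1000))],
                                   [cluster(100, 200)])
        assert [(c, cl.mirna) for c, cl in pairs] == [("c1", "miR-7")]

    def test_half_overlap_below_threshold(self):
        pairs = intersect_clusters([("c1", GenomicInterval("hchr1", 0, 150))],
                                   [cluster(100, 200)])
        assert pairs == []

    def test_exactly_75_percent_is_inclusive(self):
        pairs = intersect_clusters([("c1", GenomicInterval("hchr1", 0, 175))],
                                   [cluster(100, 200)])
        assert len(pairs) == 1
        # one base less -> excluded
        assert intersect_clusters([("c1", GenomicInterval("hchr1", 0, 174))],
                                  [cluster(100, 200)]) == []

    def test_different_chromosome_never_overlaps(self):
        assert intersect_clusters([("c1", GenomicInterval("hchr2", 0, 1000))],
                                  [cluster(100, 200)]) == []


class TestFilterOrthology:
    PAIRS = [("c1", cluster(0, 100, "m1")), ("c2", cluster(0, 100, "m2")),
             ("c3", cluster(0, 100, "m3")), ("c4", cluster(0, 100, "m4"))]

    def test_thresholds(self):
        mirnas = [
            MirnaRecord("m1", "ACGUACGUACGUACGUACGUA", orthology_confident=True),
            MirnaRecord("m2", "ACGUACGUACGUACGUACGUA", hairpin_identity=0.89,
                        hairpin_coverage=0.99),
            MirnaRecord("m3", "ACGUACGUACGUACGUACGUA", hairpin_identity=0.90,
                        hairpin_coverage=0.95),
            MirnaRecord("m4", "ACGUACGUACGUACGUACGUA"),
        ]
        kept = filter_orthology(self.PAIRS, mirnas)
        assert [c for c, _ in kept] == ["c1", "c3"]

    def test_missing_mirna_is_an_error(self):
        with pytest.raises(KeyError):
            filter_orthology(self.PAIRS, [MirnaRecord("m1", "ACGU" * 5, True)])


def revcomp_rna(seq):
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return "".join(comp[b] for b in reversed(seq))


class TestScan:
    def test_perfect_duplex_found_with_zero_mismatches(self, mirna):
        target = "A" * 30 + revcomp_rna(mirna.sequence) + "A" * 30
        sites = scan_binding_sites("c", target, mirna)
        perfect = [s for s in sites if s.mismatches == 0]
        assert perfect
        s = perfect[0]
        # the duplex window sits at the seed-proximal end of the embed
        assert s.end == 30 + len(mirna.sequence)
        assert s.end - s.start == 20
        assert s.seed_pairs == 8

    def test_dna_input_transcribed(self, mirna):
        target = ("A" * 30 + revcomp_rna(mirna.sequence) + "A" * 30).replace("U", "T")
        assert any(s.mismatches == 0 for s in scan_binding_sites("c", target, mirna))

    def test_alphabet_violation_rejected(self, mirna):
        with pytest.raises(ValueError):
            scan_binding_sites("c", "ACGXACGU" * 5, mirna)

    def test_score_threshold_monotonicity(self, mirna):
        """Relaxing the threshold never reduces the raw site count."""
        rng = np.random.default_rng(3)
        target = "".join(rng.choice(list("ACGU"), size=500))
        prev = -1
        for thr in (-40, -30, -20, -10, -5, 0):
            n = len(scan_binding_sites("c", target, mirna, score_threshold=thr))
            assert n >= prev
            prev = n

    def test_reverse_orientation_mirrors_coordinates(self, mirna):
        seq, _ = sim.gen_sponge_fixture(31, 900, mirna, n_planted_sites=3)
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        rc = "".join(comp[b] for b in reversed(seq))
        fwd = scan_binding_sites("c", seq, mirna)
        rev = scan_binding_sites("c", rc, mirna, orientation="reverse")
        n = len(seq)
        assert sorted((n - s.end, n - s.start, s.score) for s in fwd) == sorted(
            (s.start, s.end, s.score) for s in rev
        )


class TestRemoveOverlaps:
    def site(self, start, end, score):
        return BindingSite("c", start, end, "m", score, 8, 0)

    def test_stronger_site_wins(self):
        kept = remove_overlaps([self.site(0, 20, -15), self.site(10, 30, -12)])
        assert [(s.start, s.end) for s in kept] == [(0, 20)]

    def test_disjoint_sites_all_kept(self):
        sites = [self.site(0, 20, -15), self.site(30, 50, -12), self.site(60, 80, -20)]
        assert len(remove_overlaps(sites)) == 3

    def test_empty_input(self):
        assert remove_overlaps([]) == []

    def test_matches_greedy_oracle_on_random_sites(self):
        """Greedy-by-score selection equals an independent reimplementation."""

        def oracle(sites):
            chosen = []
            pool = sorted(sites, key=lambda s: (s.score, s.start, s.end - s.start))
            for s in pool:
                if not any(s.start < k.end and k.start < s.end for k in chosen):
                    chosen.append(s)
            return sorted(chosen, key=lambda s: s.start)

        rng = np.random.default_rng(9)
        for _ in range(300):
            n = int(rng.integers(0, 20))
            sites = [
                self.site(int(rng.integers(0, 200)),
                          int(rng.integers(0, 200)) + 201,  # unused placeholder
                          int(rng.integers(-40, 0)))
                for _ in range(n)
            ]
            sites = [
                BindingSite("c", s.start, s.start + int(rng.integers(5, 25)),
                            "m", s.score, 8, 0)
                for s in sites
            ]
            assert remove_overlaps(sites) == oracle(sites)


class TestRatioAndProfile:
    def test_per_base_ratio_definition(self):
        sites = [BindingSite("c", i * 20, i * 20 + 15, "m", -12, 8, 0) for i in range(44)]
        assert per_base_ratio(sites, 1000) == pytest.approx(0.044)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            per_base_ratio([], 0)

    def test_exact_reverse_complement_has_no_mismatch(self, mirna):
        seed_canon, mismatches, marks = duplex_profile(mirna, revcomp_rna(mirna.sequence))
        assert mismatches == 0
        assert set(marks[:8]) == {"|"}  # every seed position canonical
        assert seed_canon == 8

    def test_planted_single_mismatch_detected(self, mirna):
        site = list(revcomp_rna(mirna.sequence))
        # flip the base pairing miRNA position 12 (0-based index 11)
        j = len(site) - 1 - 11
        site[j] = {"A": "C", "C": "A", "G": "U", "U": "G"}[site[j]]
        seed_canon, mismatches, marks = duplex_profile(mirna, "".join(site))
        assert mismatches + marks.count(":") == 1  # one non-canonical position
        assert marks[11] != "|"

    def test_wobble_counts_as_pair_but_not_canonical(self):
        m = MirnaRecord("m", "GGGGGGGG")
        # G pairs U as wobble: site of all U
        seed_canon, mismatches, marks = duplex_profile(m, "UUUUUUUU")
        assert mismatches == 0
        assert seed_canon == 0
        assert set(marks) == {":"}


def test_planted_site_recall_and_background_specificity(mirna):
    """100% recall of planted sites, zero sites on seed-free background."""
    seq, expected = sim.gen_sponge_fixture(41, 2500, mirna, n_planted_sites=6, spacing=40)
    found = remove_overlaps(scan_binding_sites("c", seq, mirna))
    assert [(s.start, s.end) for s in found] == [(s, e) for _, s, e in expected]
    bg, _ = sim.gen_sponge_fixture(43, 2000, mirna, n_planted_sites=0)
    assert scan_binding_sites("c", bg, mirna) == []
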