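"""Nearest-gene assignment, metagene classification and occupancy binning.

The assignment tests compare against an exhaustive all-pairs brute-force
oracle; the partition and conservation invariants run on the shared synthetic
fixture.
"""

import math

import numpy as np
import pytest

from tboxscan.annotate import (
    REGION_CLASSES, SUBCLASSES, assign_nearest_gene, bin_occupancy,
    classify_region, distance_histogram, gene_occupancies, heatmap_value,
    region_distribution, signed_tss_distance, tss_of, window_sum,
)
from tboxscan.core import FORWARD, REVERSE, GeneModel, GenomicInterval, Peak
from tboxscan.simulate import SimConfig, simulate_genome, simulate_peaks


def _gene(gene_id, scaffold, start, end, strand, **kw):
    return GeneModel(gene_id, GenomicInterval(scaffold, start, end, strand),
                     **kw)


def _peak(scaffold, summit, score=1.0):
    return Peak(GenomicInterval(scaffold, max(0, summit - 50), summit + 51),
                summit, score)


def brute_force_nearest(peaks, genes):
    """All-pairs oracle: for each peak, scan every gene on its scaffold."""
    out = {}
    for i, pk in enumerate(peaks):
        best = None
        for g in genes:
            if g.body.scaffold != pk.scaffold:
                continue
            d = abs(pk.summit - g.tss)
            key = (d, g.gene_id)
            if best is None or key < best:
                best = key
        if best is not None:
            out[i] = best[1]
    return out


class TestTss:
    def test_strand_convention(self):
        assert tss_of(_gene("g", "s", 100, 500, FORWARD)) == 100
        assert tss_of(_gene("g", "s", 100, 500, REVERSE)) == 499

    def test_single_bp_gene_tss_inside_body(self):
        g = _gene("g", "s", 100, 101, FORWARD)
        assert g.body.contains(tss_of(g))


class TestAssignment:
    def test_nearest_of_two(self):
        genes = [_gene("a", "s", 900, 2000, FORWARD),
                 _gene("b", "s", 1200, 3000, FORWARD)]
        (a,), _ = assign_nearest_gene([_peak("s", 1000)], genes)
        assert a.gene_id == "a"
        assert a.signed_distance == 100  # downstream of a + strand TSS

    def test_summit_at_tss(self):
        genes = [_gene("a", "s", 1000, 2000, FORWARD)]
        (a,), _ = assign_nearest_gene([_peak("s", 1000)], genes)
        assert a.signed_distance == 0

    def test_equidistant_tie_breaks_lexicographically(self):
        genes = [_gene("zz", "s", 950, 2000, FORWARD),
                 _gene("aa", "s", 1050, 3000, FORWARD)]
        (a,), _ = assign_nearest_gene([_peak("s", 1000)], genes)
        assert a.gene_id == "aa"

    def test_upstream_distance_negative_on_minus_strand(self):
        g = _gene("a", "s", 1000, 2000, REVERSE)  # TSS at 1999
        assert signed_tss_distance(g, 2100) == -101  # upstream for - strand
        assert signed_tss_distance(g, 1900) == 99

    def test_peak_on_geneless_scaffold_unassigned(self):
        genes = [_gene("a", "s1", 0, 100, FORWARD)]
        assigned, unassigned = assign_nearest_gene([_peak("s2", 50)], genes)
        assert assigned == [] and len(unassigned) == 1

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_oracle(self, seed):
        cfg = SimConfig(seed=seed, n_scaffolds=2, n_genes=50,
                        target_fraction=0.8, n_background_peaks=160,
                        tss_peak_sd=5_000.0)
        genes, _ = simulate_genome(cfg)
        peaks, _ = simulate_peaks(genes, cfg)  # 200 peaks at most
        assignments, _ = assign_nearest_gene(peaks, genes)
        oracle = brute_force_nearest(peaks, genes)
        assert len(assignments) == len(oracle)
        for i, a in enumerate(assignments):
            assert a.gene_id == oracle[i], f"peak {i} (seed {seed})"


class TestRegionClassification:
    BODY = _gene("g", "s", 10_000, 20_000, FORWARD,
                 exons=(GenomicInterval("s", 10_000, 11_000),
                        GenomicInterval("s", 15_000, 16_000)),
                 utr5=(GenomicInterval("s", 10_000, 10_200),))

    @pytest.mark.parametrize("summit,expected", [
        (9_500, ("proximal_up", None)),       # 500 bp upstream
        (7_000, ("intermediate_up", None)),   # 3 kb upstream
        (3_000, ("distal_up", None)),         # 7 kb upstream
        (20_500, ("proximal_down", None)),
        (26_000, ("distal_down", None)),      # 6 kb downstream
        (12_000, ("gene_body", "intron")),
        (15_500, ("gene_body", "exon")),
        (10_100, ("gene_body", "utr5")),
    ])
    def test_bands_and_subclasses(self, summit, expected):
        assert classify_region(self.BODY, summit) == expected

    def test_minus_strand_orientation_flips(self):
        g = _gene("g", "s", 10_000, 20_000, REVERSE)
        assert classify_region(g, 20_500) == ("proximal_up", None)
        assert classify_region(g, 9_500) == ("proximal_down", None)

    def test_distribution_partitions_peaks(self, small_assignments):
        assignments, _ = small_assignments
        counts = region_distribution(assignments)
        assert sum(counts[rc] for rc in REGION_CLASSES) == len(assignments)

    def test_intron_subtraction_rule(self, small_assignments):
        assignments, _ = small_assignments
        counts = region_distribution(assignments)
        exonic = counts["exon"] + counts["utr5"] + counts["utr3"]
        assert counts["intron"] == counts["gene_body"] - exonic
        assert counts["intron"] >= 0

    def test_empty_input_all_zero(self):
        counts = region_distribution([])
        assert all(v == 0 for v in counts.values())


class TestOccupancy:
    G = _gene("g", "s", 100_000, 110_000, FORWARD)

    def _assign(self, *summit_scores):
        peaks = [_peak("s", s, score) for s, score in summit_scores]
        assignments, _ = assign_nearest_gene(peaks, [self.G])
        return assignments

    def test_peak_just_upstream(self):
        occ = bin_occupancy(self.G, self._assign((99_999, 30.0)))
        assert occ.bins[24] == 30.0  # upstream bin adjacent to the TSS
        assert occ.total == 30.0

    def test_overflow_bin(self):
        occ = bin_occupancy(self.G, self._assign((88_000, 7.0)))  # -12 kb
        assert occ.bins[50] == 7.0

    def test_bin_additivity(self):
        occ = bin_occupancy(self.G, self._assign((100_100, 10.0),
                                                 (100_200, 20.0)))
        assert occ.bins[25] == 30.0

    def test_total_conserves_scores(self, small_genome, small_assignments,
                                    small_occupancies):
        assignments, _ = small_assignments
        total_scores = sum(a.peak.score for a in assignments)
        total_bins = sum(o.total for o in small_occupancies.values())
        assert total_bins == pytest.approx(total_scores)
        for occ in small_occupancies.values():
            assert occ.total == pytest.approx(occ.bins.sum())
            assert np.all(occ.bins >= 0)

    def test_window_sums(self):
        occ = bin_occupancy(self.G, self._assign((99_200, 12.0),
                                                 (97_000, 5.0)))
        assert window_sum(occ, "proximal_lt1kb", "up") == 12.0
        assert window_sum(occ, "intermediate_1to5kb", "up") == 5.0
        assert window_sum(occ, "proximal_lt1kb", "down") == 0.0

    def test_unknown_band_raises(self):
        occ = bin_occupancy(self.G, [])
        with pytest.raises(KeyError, match="unknown band"):
            window_sum(occ, "megabase", "up")

    def test_modal_bin_adjacent_to_tss_when_binding_is_proximal(self):
        cfg = SimConfig(seed=11, n_genes=120, target_fraction=1.0,
                        tss_peak_sd=100.0, n_background_peaks=0)
        genes, _ = simulate_genome(cfg)
        peaks, _ = simulate_peaks(genes, cfg)
        assignments, _ = assign_nearest_gene(peaks, genes)
        profile = np.zeros(52)
        for occ in gene_occupancies(genes, assignments).values():
            profile += occ.bins
        assert np.argmax(profile[:50]) in (24, 25)


class TestDistanceHistogram:
    def test_all_zero_distances_in_central_bin(self):
        genes = [_gene("g", "s", 1_000, 2_000, FORWARD)]
        assignments, _ = assign_nearest_gene([_peak("s", 1_000)] * 5, genes)
        edges, counts, oor = distance_histogram(assignments)
        assert counts[np.searchsorted(edges, 0, "right") - 1] == 5
        assert counts.sum() == 5 and oor == 0

    def test_out_of_range_counted_not_dropped(self):
        genes = [_gene("g", "s", 100_000, 101_000, FORWARD)]
        peaks = [_peak("s", 100_000), _peak("s", 160_000)]  # +60 kb
        assignments, _ = assign_nearest_gene(peaks, genes)
        _, counts, oor = distance_histogram(assignments)
        assert counts.sum() + oor == len(assignments)
        assert oor == 1

    def test_empty_input(self):
        edges, counts, oor = distance_histogram([])
        assert counts.sum() == 0 and oor == 0
        assert edges[0] == -20_000 and edges[-1] == 20_000


class TestHeatmapTransform:
    @pytest.mark.parametrize("score,expected", [
        (0.0, 0.0),
        (math.e - 1.0, 1.0),
        (30.0, math.log(31.0)),
    ])
    def test_values(self, score, expected):
        assert heatmap_value(score) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            heatmap_value(-0.1)
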