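"""Insulation, boundary calling, pileups, strength, inter-TAD proportions."""

import numpy as np
import pandas as pd
import pytest

from hicarch import (
    ContactMatrix,
    GenomeSpec,
    StageSpec,
    domain_strength,
    find_boundaries,
    insulation_score,
    inter_tad_distance_proportions,
    observed_over_expected,
    plant_tads,
    simulate_contact_matrix,
    strength_dynamics,
    tad_pileup,
)
from hicarch.tads import InsulationTrack, insulation_raw

from conftest import random_matrix, uniform_matrix


def brute_insulation_raw(mat, w):
    """Independent block-mean oracle."""
    vals = mat.values("auto").astype(float)
    out = np.full(mat.nbins, np.nan)
    for chrom in mat.genome.chromosomes:
        sl = mat.genome.chrom_slice(chrom)
        n = sl.stop - sl.start
        for i in range(w, n - w):
            acc = []
            for a in range(i - w, i):
                for b in range(i + 1, i + 1 + w):
                    if mat.mask[sl.start + a] and mat.mask[sl.start + b]:
                        acc.append(vals[sl.start + a, sl.start + b])
            if acc:
                out[sl.start + i] = np.mean(acc)
    return out


@pytest.fixture
def tad_genome():
    return GenomeSpec({"chr1": 10_000_000}, 50_000)  # 200 bins at 50 kb


class TestInsulation:
    def test_uniform_matrix_gives_zero_zscores(self, tad_genome):
        mat = uniform_matrix(tad_genome)
        track = insulation_score(mat, (250_000, 500_000))
        finite = track.values[np.isfinite(track.values)]
        np.testing.assert_allclose(finite, 0.0, atol=1e-12)

    def test_raw_score_matches_bruteforce_oracle(self):
        g = GenomeSpec({"chr1": 5_000_000}, 50_000)  # 100 bins
        mat = random_matrix(g, seed=1)
        for w in (3, 5):
            np.testing.assert_allclose(
                insulation_raw(mat, w),
                brute_insulation_raw(mat, w),
                atol=1e-9,
                equal_nan=True,
            )

    def test_invariant_to_global_rescaling(self, tad_genome):
        mat = random_matrix(tad_genome, seed=2)
        scaled = ContactMatrix(tad_genome, mat.counts * 7)
        a = insulation_score(mat).values
        b = insulation_score(scaled).values
        np.testing.assert_allclose(a, b, atol=1e-10, equal_nan=True)

    def test_planted_boundary_is_local_minimum(self, tad_genome):
        tads = [("chr1", 2_000_000, 2_400_000), ("chr1", 2_400_000, 2_850_000)]
        mat = simulate_contact_matrix(
            tad_genome, StageSpec("s", tads=tads, tad_boost=3.0, depth=5e6, seed=3)
        )
        track = insulation_score(mat).values
        b = 2_400_000 // 50_000
        window = track[b - 3 : b + 4]
        assert np.nanargmin(window) in (2, 3, 4)  # minimum at boundary ±1 bin


class TestBoundaries:
    def test_constant_track_gives_no_boundaries(self, tad_genome):
        track = InsulationTrack(np.zeros(tad_genome.nbins), (250_000,))
        ts = find_boundaries(track, tad_genome)
        assert len(ts.boundaries) == 0 and len(ts.domains) == 0

    def test_invariant_to_adding_constant(self, tad_genome):
        rng = np.random.default_rng(4)
        values = rng.normal(size=tad_genome.nbins)
        a = find_boundaries(values, tad_genome)
        b = find_boundaries(values + 5.0, tad_genome)
        pd.testing.assert_frame_equal(a.boundaries, b.boundaries)

    def test_oversized_domains_excluded_but_boundaries_kept(self, tad_genome):
        # two deep minima 12 bins (600 kb) apart with max size 500 kb
        values = np.zeros(tad_genome.nbins)
        values[50] = -1.0
        values[62] = -1.0
        ts = find_boundaries(values, tad_genome, min_size_bp=150_000, max_size_bp=500_000)
        assert list(ts.boundaries["bin"]) == [50, 62]
        assert len(ts.domains) == 0

    def test_flat_minimum_resolved_to_leftmost_bin(self, tad_genome):
        values = np.zeros(tad_genome.nbins)
        values[30:33] = -1.0
        ts = find_boundaries(values, tad_genome)
        assert list(ts.boundaries["bin"]) == [30]

    def test_shallow_minima_below_delta_rejected(self, tad_genome):
        values = np.zeros(tad_genome.nbins)
        values[40] = -0.005
        assert len(find_boundaries(values, tad_genome, delta=0.01).boundaries) == 0
        assert len(find_boundaries(values, tad_genome, delta=0.001).boundaries) == 1

    @pytest.mark.parametrize("boost", [1.25, 1.5, 2.0])
    def test_recovery_improves_with_boost(self, tad_genome, boost):
        # sanity curve: recovery should not be catastrophic at b >= 1.5
        tads = plant_tads(tad_genome, 200_000, 500_000, gap_bp=0, seed=5)
        mat = simulate_contact_matrix(
            tad_genome, StageSpec("s", tads=tads, tad_boost=boost, depth=8e6, seed=5)
        )
        ts = find_boundaries(insulation_score(mat), tad_genome)
        planted = sorted(
            {t[1] // 50_000 for t in tads} | {t[2] // 50_000 for t in tads}
        )
        planted = [b for b in planted if 10 <= b <= tad_genome.nbins - 10]
        called = ts.boundaries["bin"].to_numpy()
        hit = sum(any(abs(b - c) <= 1 for c in called) for b in planted)
        rate = hit / len(planted)
        if boost >= 1.5:
            assert rate >= 0.8


class TestPileup:
    def test_uniform_matrix_flat_pileup(self):
        g = GenomeSpec({"chr1": 5_000_000}, 50_000)
        n = g.nbins
        oe = np.ones((n, n))
        np.fill_diagonal(oe, np.nan)
        doms = pd.DataFrame([{"chrom": "chr1", "start": 2_000_000, "end": 2_500_000}])
        pile, skipped = tad_pileup(oe, g, doms)
        assert not skipped
        np.testing.assert_allclose(pile, 1.0, atol=1e-12)

    def test_identical_domains_average_to_single_domain(self):
        g = GenomeSpec({"chr1": 5_000_000}, 50_000)
        rng = np.random.default_rng(6)
        n = g.nbins
        oe = rng.uniform(0.5, 2.0, (n, n))
        oe = (oe + oe.T) / 2
        dom = {"chrom": "chr1", "start": 2_000_000, "end": 2_500_000}
        one, _ = tad_pileup(oe, g, pd.DataFrame([dom]))
        three, _ = tad_pileup(oe, g, pd.DataFrame([dom, dom, dom]))
        np.testing.assert_allclose(one, three)

    def test_edge_domain_skipped_with_log(self):
        g = GenomeSpec({"chr1": 5_000_000}, 50_000)
        n = g.nbins
        oe = np.ones((n, n))
        doms = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 0, "end": 500_000},  # no left flank
                {"chrom": "chr1", "start": 2_000_000, "end": 2_500_000},
            ]
        )
        pile, skipped = tad_pileup(oe, g, doms)
        assert skipped == ["chr1:0-500000"]


class TestStrength:
    def test_uniform_matrix_zero_strength(self):
        g = GenomeSpec({"chr1": 5_000_000}, 50_000)
        n = g.nbins
        oe = np.ones((n, n))
        np.fill_diagonal(oe, np.nan)
        dom = {"chrom": "chr1", "start": 2_000_000, "end": 2_500_000}
        assert domain_strength(oe, g, dom) == pytest.approx(0.0)

    def test_edge_domain_raises(self):
        g = GenomeSpec({"chr1": 5_000_000}, 50_000)
        oe = np.ones((g.nbins, g.nbins))
        with pytest.raises(ValueError, match="chromosome edge"):
            domain_strength(oe, g, {"chrom": "chr1", "start": 0, "end": 500_000})

    def test_planted_boost_gives_log2_boost_strength(self):
        g = GenomeSpec({"chr1": 40_000_000}, 50_000)
        tads = plant_tads(g, 300_000, 500_000, gap_bp=3_700_000, seed=7)
        mat = simulate_contact_matrix(
            g, StageSpec("s", tads=tads, tad_boost=2.0, depth=4e7, seed=7)
        )
        oe = observed_over_expected(mat, use="raw")
        doms = pd.DataFrame([{"chrom": c, "start": s, "end": e} for c, s, e in tads])
        strengths = [domain_strength(oe, g, d) for _, d in doms.iterrows()]
        assert np.mean(strengths) == pytest.approx(1.0, abs=0.15)

    def test_constant_boost_has_zero_relative_variance(self):
        g = GenomeSpec({"chr1": 5_000_000}, 50_000)
        rng = np.random.default_rng(8)
        n = g.nbins
        oe = rng.uniform(0.5, 2.0, (n, n))
        oe = (oe + oe.T) / 2
        doms = pd.DataFrame([{"chrom": "chr1", "start": 2_000_000, "end": 2_500_000}])
        dyn = strength_dynamics([oe, oe, oe], g, doms)
        assert dyn["relative_variance"].iloc[0] == pytest.approx(0.0, abs=1e-12)


class TestInterTAD:
    def test_single_covering_domain_gives_zero_proportions(self, tad_genome):
        mat = uniform_matrix(tad_genome)
        doms = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 10_000_000}])
        props = inter_tad_distance_proportions(mat, doms, (0, 2_000_000))
        assert (props["proportion"] == 0).all()

    def test_two_domains_match_bruteforce(self, tad_genome):
        mat = uniform_matrix(tad_genome)
        doms = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 1_000_000, "end": 3_000_000},
                {"chrom": "chr1", "start": 6_000_000, "end": 7_500_000},
            ]
        )
        edges = (0, 4_000_000)
        props = inter_tad_distance_proportions(mat, doms, edges)
        # brute-force enumeration
        res = tad_genome.resolution
        dom_of = np.full(tad_genome.nbins, -1)
        for k, (_, d) in enumerate(doms.iterrows()):
            dom_of[d["start"] // res : d["end"] // res] = k
        total = inter_short = inter_long = 0
        n = tad_genome.nbins
        for i in range(n):
            for j in range(i + 1, n):
                total += 1
                if dom_of[i] >= 0 and dom_of[j] >= 0 and dom_of[i] != dom_of[j]:
                    sep = (j - i) * res
                    if sep <= 4_000_000:
                        inter_short += 1
                    else:
                        inter_long += 1
        np.testing.assert_allclose(
            props["proportion"], [inter_short / total, inter_long / total], atol=1e-12
        )

    def test_overlapping_domains_raise(self, tad_genome):
        mat = uniform_matrix(tad_genome)
        doms = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 0, "end": 3_000_000},
                {"chrom": "chr1", "start": 2_000_000, "end": 5_000_000},
            ]
        )
        with pytest.raises(ValueError, match="overlapping"):
            inter_tad_distance_proportions(mat, doms, (0, 1_000_000))
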