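"""Generator contracts: expectation model, determinism, planted truth."""

import numpy as np
import pytest

from hicarch import (
    EnsembleSpec,
    GenomeSpec,
    StageSpec,
    make_annotation_fixture,
    random_compartment_profile,
    simulate_bead_ensemble,
    simulate_contact_matrix,
    simulate_stage_series,
)
from hicarch.synthetic import expected_matrix
from hicarch.annotation import write_bed


class TestContactMatrix:
    def test_emitted_matrix_is_symmetric_integer_nonneg_zero_diag(self, toy_genome):
        mat = simulate_contact_matrix(
            toy_genome, StageSpec("s", strength=0.3, trans_level=0.05, depth=1e6, seed=1)
        )
        np.testing.assert_array_equal(mat.counts, mat.counts.T)
        assert mat.counts.dtype.kind == "i"
        assert (mat.counts >= 0).all()
        assert np.diagonal(mat.counts).sum() == 0

    def test_plain_decay_diagonal_means_match_theory(self, one_chrom_100):
        # s=0, b=1, lam=1, tau=0, alpha=1: expectation constant per diagonal
        spec = StageSpec("s", alpha=1.0, depth=5e6, seed=2)
        E = expected_matrix(one_chrom_100, spec)
        mat = simulate_contact_matrix(one_chrom_100, spec)
        for d in (1, 10, 50):
            diag_exp = np.diagonal(E, d)
            assert np.allclose(diag_exp, diag_exp[0])
            realized = np.diagonal(mat.counts, d).astype(float)
            se = np.sqrt(diag_exp[0] / realized.size)
            assert abs(realized.mean() - diag_exp[0]) < 3 * se + 1e-9

    def test_expected_diagonal_means_non_increasing_without_longrange_boost(
        self, one_chrom_100
    ):
        # decay + TAD components only: the compartment term adds per-diagonal
        # fluctuation from the profile's autocorrelation, so it is off here
        tads = [("chr1", 10_000_000, 14_000_000), ("chr1", 30_000_000, 33_000_000)]
        E = expected_matrix(
            one_chrom_100, StageSpec("s", alpha=0.7, tads=tads, tad_boost=2.0, seed=3)
        )
        means = [np.diagonal(E, d).mean() for d in range(1, one_chrom_100.nbins)]
        assert all(a >= b - 1e-12 for a, b in zip(means, means[1:]))

    def test_checkerboard_oe_matches_one_plus_minus_s(self):
        # Monte-Carlo over 20 seeds with fresh random profiles each time:
        # distance-normalized same-label pairs ~ 1+s, opposite ~ 1-s
        g = GenomeSpec({"chr1": 200_000_000}, 1_000_000)
        idx = np.arange(g.nbins)
        d = np.abs(idx[:, None] - idx[None, :])
        off = ~np.eye(g.nbins, dtype=bool)
        ratios_same, ratios_opp = [], []
        for seed in range(20):
            p = random_compartment_profile(g, block_bins=1, seed=100 + seed)
            same = np.outer(p, p) > 0
            mat = simulate_contact_matrix(
                g, StageSpec("s", profile=p, strength=0.5, depth=2e7, seed=seed)
            )
            per_diag = np.array(
                [np.diagonal(mat.counts, k).mean() for k in range(g.nbins)]
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                oe = mat.counts / per_diag[d]
            ratios_same.append(np.nanmean(oe[same & off]))
            ratios_opp.append(np.nanmean(oe[~same & off]))
        assert np.mean(ratios_same) == pytest.approx(1.5, rel=0.03)
        assert np.mean(ratios_opp) == pytest.approx(0.5, rel=0.03)

    def test_same_seed_is_bit_identical(self, toy_genome):
        spec = StageSpec("s", strength=0.2, trans_level=0.02, depth=1e6, seed=7)
        a = simulate_contact_matrix(toy_genome, spec)
        b = simulate_contact_matrix(toy_genome, spec)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_profile_length_mismatch_and_bad_strength_raise(self, toy_genome):
        with pytest.raises(ValueError, match="profile length"):
            expected_matrix(toy_genome, StageSpec("s", profile=np.ones(3), seed=0))
        with pytest.raises(ValueError, match="strength"):
            StageSpec("s", strength=1.0)


class TestStageSeries:
    def test_no_switching_when_fraction_zero(self, one_chrom_100):
        stages = [StageSpec(l, depth=1e5, seed=k) for k, l in enumerate("ab")]
        _, _, truth = simulate_stage_series(one_chrom_100, stages, 0.0, seed=1)
        assert set(truth["category"]) <= {"A->A", "B->B"}

    def test_exact_flip_count(self):
        g = GenomeSpec({"chr1": 1_000_000_000, "chr2": 1_000_000_000}, 1_000_000)
        assert g.nbins == 2000
        stages = [StageSpec(l, depth=1e5, seed=k) for k, l in enumerate("ab")]
        _, profiles, truth = simulate_stage_series(g, stages, 0.02, seed=3)
        flipped = (profiles[0] != profiles[1]).sum()
        assert flipped == 40
        switched = truth["category"].isin(["A->B", "B->A"]).sum()
        assert switched == 40

    def test_flipped_sets_differ_across_seeds(self, one_chrom_100):
        stages = [StageSpec(l, depth=1e5, seed=k) for k, l in enumerate("ab")]
        sets = []
        for seed in (1, 2, 3):
            _, profiles, _ = simulate_stage_series(one_chrom_100, stages, 0.1, seed=seed)
            sets.append(frozenset(np.flatnonzero(profiles[0] != profiles[1])))
        assert len(set(sets)) == 3

    def test_empty_stage_list_raises(self, one_chrom_100):
        with pytest.raises(ValueError, match="empty stage list"):
            simulate_stage_series(one_chrom_100, [], 0.0)

    def test_asymmetric_switching_respects_direction_bias(self, one_chrom_100):
        stages = [StageSpec(l, depth=1e5, seed=k) for k, l in enumerate("ab")]
        _, _, truth = simulate_stage_series(
            one_chrom_100, stages, 0.2, a_to_b_fraction=0.8, seed=5
        )
        ab = (truth["category"] == "A->B").sum()
        ba = (truth["category"] == "B->A").sum()
        assert ab == 16 and ba == 4


class TestBeadEnsemble:
    def test_uniform_ball_mean_radius_is_three_quarters(self):
        g = GenomeSpec({"chr1": 100_000_000}, 1000)  # 1e5 beads in one model
        ens = simulate_bead_ensemble(EnsembleSpec(n_models=1, genome=g, seed=1))
        coords = ens.models[0].valid_coords()
        r = np.linalg.norm(coords, axis=1)
        assert r.mean() == pytest.approx(0.75, rel=0.01)

    def test_degraded_count_contract(self):
        g = GenomeSpec({"chr1": 100_000_000}, 1_000_000)
        ens = simulate_bead_ensemble(
            EnsembleSpec(n_models=100, genome=g, degraded_fraction=0.1, seed=2)
        )
        from hicarch import qc_filter

        _, exclusions = qc_filter(ens)
        assert len(exclusions) == 10

    def test_peripheral_bias_pushes_lad_beads_outward(self):
        g = GenomeSpec({"chr1": 20_000_000}, 100_000)
        lad = np.zeros(g.nbins, dtype=bool)
        lad[: g.nbins // 2] = True
        ens = simulate_bead_ensemble(
            EnsembleSpec(n_models=20, genome=g, lad_flags=lad, peripheral_bias=4.0, seed=3)
        )
        r_lad, r_other = [], []
        for m in ens.models:
            coords = m.beads[["x", "y", "z"]].to_numpy(float)
            r = np.linalg.norm(coords, axis=1)
            r_lad.append(r[lad].mean())
            r_other.append(r[~lad].mean())
        assert np.mean(r_lad) > np.mean(r_other)

    def test_same_seed_identical_ensemble(self):
        g = GenomeSpec({"chr1": 10_000_000}, 1_000_000)
        spec = EnsembleSpec(n_models=3, genome=g, seed=9)
        a = simulate_bead_ensemble(spec)
        b = simulate_bead_ensemble(spec)
        for ma, mb in zip(a.models, b.models):
            np.testing.assert_array_equal(
                ma.beads[["x", "y", "z"]].to_numpy(), mb.beads[["x", "y", "z"]].to_numpy()
            )


class TestAnnotationFixture:
    def test_seeded_output_bytes_identical(self, toy_genome, tmp_path):
        paths = []
        for k in (1, 2):
            fx = make_annotation_fixture(toy_genome, seed=42)
            p = tmp_path / f"lads{k}.bed"
            write_bed(fx["lads"], str(p))
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_intervals_within_chromosome_bounds(self, toy_genome):
        fx = make_annotation_fixture(toy_genome, seed=0)
        for key in ("states", "features", "lads"):
            df = fx[key].intervals
            for chrom, length in toy_genome.chromosomes.items():
                sub = df[df["chrom"] == chrom]
                assert (sub["start"] >= 0).all() and (sub["end"] <= length).all()

    def test_lad_sizes_span_a_decade(self, toy_genome):
        fx = make_annotation_fixture(toy_genome, seed=0)
        sizes = fx["lads"].intervals.eval("end - start")
        assert sizes.max() / sizes.min() >= 10

    def test_states_partition_each_chromosome(self, toy_genome):
        fx = make_annotation_fixture(toy_genome, seed=0)
        df = fx["states"].intervals
        for chrom, length in toy_genome.chromosomes.items():
            sub = df[df["chrom"] == chrom].sort_values("start")
            assert sub["start"].iloc[0] == 0 and sub["end"].iloc[-1] == length
            assert (sub["end"].to_numpy()[:-1] == sub["start"].to_numpy()[1:]).all()
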