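"""The proportion model: variant enumeration, superposition, fitting,
and the two-site joint-deletion identity."""

import numpy as np
import pytest

from conftest import make_direct_norm, normalized_from_expected, site_index
from tracemix.intrinsic import IndelSite, IntrinsicProfile
from tracemix.mixture import (
    LengthVariant,
    LengthVariantSet,
    ShiftStateSpace,
    enumerate_variants,
    fit_proportions,
    infer_joint_site_proportions,
    simulate_mixture,
)
from tracemix.pipeline import fit_site_lengths


def toy_profile(seq="ACGTACGTAC" * 3, track=(4, 7)):
    """A small fully calibrated profile with distinct per-position values."""
    n = len(seq)
    rng = np.random.default_rng(42)
    return IntrinsicProfile(
        reference=seq,
        expected=rng.uniform(600, 1400, n),
        sd=np.zeros(n),
        n_clones=np.full(n, 5),
        consensus=list(seq),
        min_clones_calibrated=3,
    )


class TestEnumerateVariants:
    def test_tttt_track_max_one(self):
        ref = "AC" + "TTTT" + "GACA"
        vs = enumerate_variants(ref, IndelSite(2, 6, "T"), max_indel=1)
        assert vs.shifts == [-1, 0, 1]

    def test_tt_track_max_two(self):
        ref = "AC" + "TT" + "GACA"
        vs = enumerate_variants(ref, IndelSite(2, 4, "T"), max_indel=2)
        assert vs.shifts == [-2, -1, 0, 1, 2]

    def test_its1_labels_252_through_256(self, reference, its1_site):
        vs = enumerate_variants(
            reference.amplicon, its1_site, max_indel=2, region_length=reference.annotation.its1_length
        )
        assert vs.labels == ["252", "253", "254", "255", "256"]

    def test_non_maximal_site_warns(self):
        ref = "ACTTTTGACA"
        with pytest.warns(UserWarning, match="maximal"):
            enumerate_variants(ref, IndelSite(2, 5, "T"), max_indel=1)

    def test_reference_variant_required(self):
        with pytest.raises(ValueError, match="shift 0"):
            LengthVariantSet(
                site=IndelSite(2, 4, "T"), variants=[LengthVariant("x", -1), LengthVariant("y", 1)]
            )


class TestShiftStateSpace:
    def test_cumulative_shifts(self):
        sites = [IndelSite(2, 4, "T"), IndelSite(10, 12, "T")]
        space = ShiftStateSpace.from_site_shifts(sites, [[-1, 0], [-1, 0]])
        assert len(space.states) == 4
        assert space.cumulative_shift((-1, 0), 0) == -1
        assert space.total_shift((-1, -1)) == -2


class TestSimulateMixture:
    def test_pure_variant_equals_shifted_profile(self):
        prof = toy_profile()
        site = IndelSite(4, 7, prof.reference[4])
        vs = LengthVariantSet(site=site, variants=[LengthVariant("d1", -1), LengthVariant("r", 0)])
        sim = simulate_mixture(prof, vs, [1.0, 0.0], positions=np.arange(10, 25))
        for i, u in enumerate(range(10, 25)):
            ref_pos = u + 1  # deletion shifts the frame forward by one
            base = prof.consensus[ref_pos]
            assert sim.values[i, "ACGT".index(base)] == pytest.approx(prof.expected[ref_pos])

    def test_fifty_fifty_brute_force_superposition(self):
        prof = toy_profile()
        site = IndelSite(4, 7, prof.reference[4])
        vs = LengthVariantSet(site=site, variants=[LengthVariant("d1", -1), LengthVariant("r", 0)])
        sim = simulate_mixture(prof, vs, [0.5, 0.5], positions=np.arange(10, 20))
        for i, u in enumerate(range(10, 20)):
            expect = np.zeros(4)
            for shift, p in ((-1, 0.5), (0, 0.5)):
                rp = u - shift
                expect["ACGT".index(prof.consensus[rp])] += p * prof.expected[rp]
            np.testing.assert_allclose(sim.values[i], expect)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 0.5, 1.0])
    def test_linear_in_proportions(self, alpha):
        prof = toy_profile()
        site = IndelSite(4, 7, prof.reference[4])
        vs = LengthVariantSet(
            site=site,
            variants=[LengthVariant("d1", -1), LengthVariant("r", 0), LengthVariant("i1", 1)],
        )
        rng = np.random.default_rng(1)
        p1 = rng.dirichlet([1, 1, 1])
        p2 = rng.dirichlet([1, 1, 1])
        pos = np.arange(12, 26)
        mix = simulate_mixture(prof, vs, alpha * p1 + (1 - alpha) * p2, positions=pos)
        m1 = simulate_mixture(prof, vs, p1, positions=pos)
        m2 = simulate_mixture(prof, vs, p2, positions=pos)
        np.testing.assert_allclose(mix.values, alpha * m1.values + (1 - alpha) * m2.values, atol=1e-9)

    def test_proportions_must_sum_to_one(self):
        prof = toy_profile()
        site = IndelSite(4, 7, prof.reference[4])
        vs = LengthVariantSet(site=site, variants=[LengthVariant("r", 0)])
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_mixture(prof, vs, [0.9])


class TestFitProportions:
    def test_noiseless_self_consistency_oracle(self, reference, noiseless_profile, its1_site):
        vs = enumerate_variants(
            reference.amplicon, its1_site, 1, region_length=reference.annotation.its1_length
        )
        truth = np.array([0.0, 0.75, 0.25])
        sim = simulate_mixture(noiseless_profile, vs, truth)
        obs = normalized_from_expected(sim.values, reference.amplicon)
        est = fit_proportions(obs, noiseless_profile, vs, grid_step=0.01)
        for lab, t in zip(vs.labels, truth):
            assert est.grid_proportions[lab] == pytest.approx(t, abs=1e-9)
        assert est.objective == pytest.approx(0.0, abs=1.0)

    def test_pure_reference_recovered(self, reference, noiseless_cfg, noiseless_profile, its1_site):
        rng = np.random.default_rng(0)
        i1 = site_index(reference, its1_site)
        obs = make_direct_norm(reference, noiseless_cfg, [({i1: 0}, 1.0)], rng)
        est = fit_site_lengths(
            obs, noiseless_profile, its1_site, reference.annotation.its1_length, max_indel=2
        )
        assert est.proportions["254"] == pytest.approx(1.0, abs=1e-6)

    def test_noiseless_generator_recovery_exact(
        self, reference, noiseless_cfg, noiseless_profile, its1_site
    ):
        rng = np.random.default_rng(1)
        i1 = site_index(reference, its1_site)
        obs = make_direct_norm(reference, noiseless_cfg, [({i1: -1}, 0.25), ({i1: 0}, 0.75)], rng)
        est = fit_site_lengths(
            obs, noiseless_profile, its1_site, reference.annotation.its1_length, max_indel=2
        )
        assert est.percentages["253"] == pytest.approx(25.0, abs=0.01)
        assert est.percentages["254"] == pytest.approx(75.0, abs=0.01)

    def test_noisy_recovery_within_permitted_error(
        self, reference, noisy_cfg, noisy_profile, its1_site
    ):
        # the 5%-noise study conditions; permitted length error is 5 points
        i1 = site_index(reference, its1_site)
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(3000 + seed)
            obs = make_direct_norm(reference, noisy_cfg, [({i1: -1}, 0.25), ({i1: 0}, 0.75)], rng)
            est = fit_site_lengths(
                obs, noisy_profile, its1_site, reference.annotation.its1_length, max_indel=2
            )
            errs.append(abs(100 * est.proportions["253"] - 25.0))
        assert max(errs) < 5.0

    def test_recovery_error_shrinks_with_window_length(
        self, reference, noisy_cfg, noiseless_profile, its1_site
    ):
        # noiseless calibration isolates the read-noise averaging effect:
        # error should fall roughly as 1/sqrt(window length)
        i1 = site_index(reference, its1_site)
        start = its1_site.end + 3
        fits = {
            win: []
            for win in (50, 100, 200)
        }
        for seed in range(40):
            rng = np.random.default_rng(7000 + seed)
            obs = make_direct_norm(reference, noisy_cfg, [({i1: -1}, 0.4), ({i1: 0}, 0.6)], rng)
            for win in fits:
                est = fit_site_lengths(
                    obs,
                    noiseless_profile,
                    its1_site,
                    reference.annotation.its1_length,
                    shifts=[-1, 0],
                    window=(start, start + win),
                )
                fits[win].append((100 * est.proportions["253"] - 40.0) ** 2)
        rmse = {win: np.sqrt(np.mean(v)) for win, v in fits.items()}
        assert rmse[200] < rmse[100] < rmse[50]

    def test_window_shorter_than_fifty_refused(self, reference, noiseless_profile, its1_site, noiseless_cfg):
        rng = np.random.default_rng(2)
        i1 = site_index(reference, its1_site)
        obs = make_direct_norm(reference, noiseless_cfg, [({i1: 0}, 1.0)], rng)
        with pytest.raises(ValueError, match="usable window"):
            fit_site_lengths(
                obs,
                noiseless_profile,
                its1_site,
                reference.annotation.its1_length,
                shifts=[-1, 0],
                window=(its1_site.start, its1_site.end + 30),
            )


class TestJointSiteInference:
    def test_published_two_site_rows(self):
        # length distribution + one measured site reproduce the derived site
        assert infer_joint_site_proportions({321: 54, 322: 19, 323: 27}, 62) == pytest.approx(65)
        assert infer_joint_site_proportions({321: 87, 322: 8, 323: 5}, 87) == pytest.approx(95)

    def test_no_deletions_anywhere(self):
        assert infer_joint_site_proportions({323: 100}, 0) == 0.0

    def test_clamped_to_valid_range(self):
        assert infer_joint_site_proportions({321: 100, 322: 0, 323: 0}, 100) == 100.0
        assert infer_joint_site_proportions({323: 100}, 100) == 0.0

    def test_validation_errors(self):
        with pytest.raises(ValueError, match="sums to"):
            infer_joint_site_proportions({321: 50, 323: 20}, 10)
        with pytest.raises(ValueError, match="outside"):
            infer_joint_site_proportions({323: 100}, 120)

    def test_total_deletion_conservation(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            d1, d2 = rng.uniform(0, 1, 2)
            # independent per-site deletions over a pool of molecules
            p2 = d1 * d2
            p1 = d1 * (1 - d2) + d2 * (1 - d1)
            dist = {321: 100 * p2, 322: 100 * p1, 323: 100 * (1 - p1 - p2)}
            inferred = infer_joint_site_proportions(dist, 100 * d1)
            assert inferred == pytest.approx(100 * d2, abs=1e-9)
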