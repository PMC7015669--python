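import json

import numpy as np
import pytest
from scipy import stats

from axonmap import (SphericalMeanDecay, composite_voxel_signal, default_truth,
                     end_to_end_recovery, generate_dwi_phantom,
                     generate_radius_sample)
from axonmap.phantom import PhantomGroundTruth
from axonmap.radius import effective_radius, mean_radius
from axonmap.signals import IntraAxonalParams, VoxelParams


class TestGroundTruth:
    def test_fraction_validation(self, connectom):
        with pytest.raises(ValueError, match="sum to 1"):
            default_truth(connectom, shape=(2, 2, 1), f=0.5, f_im=0.2, f_extra=0.5)

    def test_seed_mandatory(self, connectom):
        with pytest.raises(ValueError):
            default_truth(connectom, shape=(2, 2, 1), seed=None)

    def test_stripes_cover_radii(self, connectom):
        t = default_truth(connectom, shape=(6, 2, 1), radii=(0.5, 1.5, 3.0))
        assert set(np.unique(t.radius)) == {0.5, 1.5, 3.0}


class TestGenerateDwiPhantom:
    def test_noiseless_equals_forward_model(self, connectom):
        t = default_truth(connectom, shape=(2, 1, 1), radii=(1.5,),
                          snr=np.inf, seed=1)
        data = generate_dwi_phantom(t, n_b0=2)
        vox = VoxelParams(
            IntraAxonalParams(f=0.6, Da_par=2.4, Da_perp=float(t.Da_perp[0, 0, 0])),
            f_extra=0.4, De_par=2.0, De_perp=0.5)
        # pick the last shell's block of volumes
        idx = np.where(np.isclose(data["bvals"], 25.0))[0]
        expected = composite_voxel_signal(vox, 25.0, data["bvecs"][:, idx].T)
        assert data["dwi"][0, 0, 0, idx] == pytest.approx(expected, rel=1e-12)
        assert data["dwi"][..., 0] == pytest.approx(1.0)

    def test_fixed_seed_bit_identical(self, connectom):
        t = default_truth(connectom, shape=(2, 2, 1), radii=(1.0,), snr=52.0, seed=7)
        a = generate_dwi_phantom(t, n_b0=2)
        b = generate_dwi_phantom(t, n_b0=2)
        assert np.array_equal(a["dwi"], b["dwi"])

    def test_b0_rician_moments(self, connectom):
        """b=0 magnitudes have mean ~1 (plus the small Rician bias) and
        SD ~ sigma across a uniform region."""
        t = default_truth(connectom, shape=(10, 10, 2), radii=(1.0,),
                          snr=52.0, seed=9)
        data = generate_dwi_phantom(t, n_b0=4)
        b0 = data["dwi"][..., :4].ravel()
        sigma = 1 / 52
        # Rician mean for nu >> sigma: nu + sigma^2/(2 nu)
        assert b0.mean() == pytest.approx(1.0 + sigma ** 2 / 2, abs=3 * sigma / np.sqrt(b0.size) + 1e-4)
        assert b0.std() == pytest.approx(sigma, rel=0.05)

    def test_write_and_overwrite_protection(self, connectom, tmp_path):
        t = default_truth(connectom, shape=(2, 2, 1), radii=(1.0,), snr=52.0, seed=2)
        generate_dwi_phantom(t, outdir=tmp_path / "ph", n_b0=2)
        assert (tmp_path / "ph" / "dwi.nii.gz").exists()
        sidecar = json.loads((tmp_path / "ph" / "truth.json").read_text())
        assert sidecar["seed"] == 2
        with pytest.raises(FileExistsError):
            generate_dwi_phantom(t, outdir=tmp_path / "ph", n_b0=2)
        generate_dwi_phantom(t, outdir=tmp_path / "ph", n_b0=2, force=True)


class TestRadiusSample:
    def test_point_mass_gamma(self):
        h = generate_radius_sample("gamma", {"a": 1e9, "scale": 1e-9}, 50, seed=0)
        assert np.allclose(h.bin_centers, 1.0, atol=1e-3)

    def test_gev_sample_moments_match_population(self):
        """Sample r_bar and r_eff vs population values by numeric integration.

        Gumbel member (c=0): all moments finite, so the sample statistics
        must converge to the integrals."""
        params = {"c": 0.0, "loc": 1.0, "scale": 0.25}
        h = generate_radius_sample("gev", params, 100000, seed=12)
        dist = stats.genextreme(**params)
        from scipy.integrate import quad
        lo, hi = 1e-9, dist.ppf(1 - 1e-10)
        mom = {k: quad(lambda r: r ** k * dist.pdf(r), lo, hi, limit=200)[0]
               for k in (1, 2, 6)}
        # normalize by the mass on r > 0
        mass = 1.0 - dist.cdf(0.0)
        pop_mean = mom[1] / mass
        pop_reff = (mom[6] / mom[2]) ** 0.25
        assert mean_radius(h) == pytest.approx(pop_mean, rel=0.01)
        assert effective_radius(h) == pytest.approx(pop_reff, rel=0.02)

    def test_seed_reproducibility(self):
        a = generate_radius_sample("gamma", {"a": 3.0, "scale": 0.3}, 100, seed=5)
        b = generate_radius_sample("gamma", {"a": 3.0, "scale": 0.3}, 100, seed=5)
        assert np.array_equal(a.bin_centers, b.bin_centers)

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            generate_radius_sample("lognormal", {}, 10, seed=0)


class TestEndToEndRecovery:
    def test_noiseless_recovery_is_tight(self, connectom):
        t = default_truth(connectom, shape=(2, 2, 1), radii=(2.5,),
                          f_extra=0.0, f=1.0, snr=np.inf, seed=1)
        rep = end_to_end_recovery(t)
        # no extra-axonal water, no noise: only SH-truncation error remains
        assert abs(rep["median_rel_err"]) < 0.02

    def test_connectom_snr_recovery(self, connectom):
        t = default_truth(connectom, shape=(4, 4, 1), radii=(2.5,),
                          snr=52.0, seed=3)
        rep = end_to_end_recovery(t)
        assert abs(rep["median_rel_err"]) < 0.10

    def test_aeon_dot_corrected_recovery(self, aeon):
        t = default_truth(aeon, shape=(4, 4, 1), radii=(1.0,), f=0.47,
                          Da_par=0.8, f_im=0.13, f_extra=0.4, De_par=0.8,
                          De_perp=0.25, snr=195.0, seed=4)
        rep = end_to_end_recovery(t, b_min=20.0, dot_correction="estimate")
        assert abs(rep["median_rel_err"]) < 0.10
        assert rep["f_im_hat"].mean() == pytest.approx(0.13, abs=0.02)

    def test_missing_dot_correction_biases_down(self, aeon):
        """Uncorrected dot plateau drags the fitted Da_perp down/negative —
        the radius-underestimation failure mode."""
        t = default_truth(aeon, shape=(3, 3, 1), radii=(1.0,), f=0.47,
                          Da_par=0.8, f_im=0.13, f_extra=0.4, De_par=0.8,
                          De_perp=0.25, snr=195.0, seed=4)
        good = end_to_end_recovery(t, b_min=20.0, dot_correction="truth")
        bad = end_to_end_recovery(t, b_min=20.0, dot_correction="none")
        assert np.median(bad["Da_perp_hat"]) < np.median(good["Da_perp_hat"])
        assert bad["implausible_fraction"] > 0.5

    def test_dispersion_factored_out(self, connectom):
        """Powder averaging removes orientation dispersion: recovered radii
        are indistinguishable across Watson concentrations (KS test). The
        singular coherent limit (kappa = inf) carries a small extra
        spherical-harmonic truncation bias; it stays within the recovery
        tolerance."""
        reps = {}
        for kappa in (2.0, 8.0, np.inf):
            r_hats = []
            for seed in range(4):
                t = default_truth(connectom, shape=(3, 3, 1), radii=(2.5,),
                                  watson_kappa=kappa, snr=52.0, seed=seed)
                r_hats.extend(end_to_end_recovery(t)["r_hat"].ravel())
            reps[kappa] = np.array(r_hats)
        p = stats.ks_2samp(reps[2.0], reps[8.0]).pvalue
        assert p > 0.01
        assert abs(np.nanmedian(reps[np.inf]) - 2.5) / 2.5 < 0.10
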