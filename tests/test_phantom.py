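"""Phantom construction, forward signal models, noise and corruption."""
import numpy as np
import pytest

from ironmap import phantom
from ironmap.core import (
    ImageSeries,
    cine_protocol,
    gradient_echo_protocol,
    look_locker_protocol,
    spin_echo_protocol,
)
from ironmap.geometry import Disk
from ironmap.phantom import (
    PhantomSpec,
    TissueCompartment,
    add_noise,
    inject_motion_corruption,
    make_phantom,
    simulate_cine,
    simulate_look_locker,
    simulate_multiecho,
)


def _disk_comp(label="liver", center=(4.0, 4.0), radius=2.0, t2=10.0, s0=100.0):
    return TissueCompartment(label, s0, 900.0, t2, min(t2, 5.0), 0.0, Disk(center, radius))


class TestMakePhantom:
    def test_piecewise_constant_maps(self):
        spec = PhantomSpec(shape=(64, 64), voxel_size=(0.125, 0.125),
                           compartments=(_disk_comp(t2=10.0),))
        ph = make_phantom(spec)
        inside = ph.labels == 1
        assert inside.any()
        assert np.all(ph.maps["t2"][inside] == 10.0)
        assert np.all(ph.maps["t2"][~inside] == 0.0)

    def test_disjoint_disk_voxel_counts_match_analytic_area(self):
        vs = (0.1, 0.1)
        spec = PhantomSpec(shape=(128, 128), voxel_size=vs, compartments=(
            _disk_comp("liver", (3.0, 3.0), 1.5),
            _disk_comp("spleen", (9.0, 9.0), 2.0),
        ))
        ph = make_phantom(spec)
        for lab, r in ((1, 1.5), (2, 2.0)):
            count = int((ph.labels == lab).sum())
            analytic = np.pi * r**2 / (vs[0] * vs[1])
            boundary = 2 * np.pi * r / vs[0]  # 1-voxel-wide rim
            assert abs(count - analytic) <= boundary

    def test_empty_compartment_list_gives_background(self):
        ph = make_phantom(PhantomSpec(shape=(16, 16), compartments=()))
        assert np.all(ph.labels == 0)

    def test_overlap_rejected_with_pair_named(self):
        spec = PhantomSpec(shape=(64, 64), voxel_size=(0.125, 0.125), compartments=(
            _disk_comp("liver", (4.0, 4.0), 2.0),
            _disk_comp("spleen", (4.5, 4.5), 2.0),
        ))
        with pytest.raises(ValueError, match="liver.*spleen"):
            make_phantom(spec)


class TestTissueCompartment:
    def test_physical_ordering_enforced(self):
        with pytest.raises(ValueError, match="t2star <= t2 <= t1"):
            TissueCompartment("liver", 100.0, 900.0, 5.0, 10.0)

    def test_background_must_be_signal_free(self):
        with pytest.raises(ValueError, match="background"):
            TissueCompartment("background", 10.0, 900.0, 10.0, 5.0)


class TestSimulateMultiecho:
    def test_closed_form_noiseless_values(self, disk_phantom):
        ph = disk_phantom(t2=10.0, s0=100.0)
        proto = spin_echo_protocol()
        series = simulate_multiecho(ph, proto, snr=np.inf)
        mask = ph.mask("liver")
        te = proto.times_array
        expected = 100.0 * np.exp(-te / 10.0)
        assert np.allclose(series.data[mask, :].mean(axis=0), expected, rtol=1e-12)

    def test_te_zero_returns_s0(self, disk_phantom):
        from ironmap.core import AcquisitionProtocol

        ph = disk_phantom(t2=10.0, s0=100.0)
        proto = AcquisitionProtocol("spin_echo_multiTE", (0.0, 5.0, 10.0))
        series = simulate_multiecho(ph, proto, snr=np.inf)
        assert np.allclose(series.data[ph.mask("liver"), 0], 100.0)

    def test_iron_loaded_regime_near_noise_floor(self, disk_phantom):
        # T2* = 0.7 ms at first gradient echo 2.7 ms leaves ~2% signal
        ph = disk_phantom(t2=5.0, t2star=0.7, s0=100.0)
        from ironmap.core import AcquisitionProtocol

        proto = AcquisitionProtocol("gradient_echo_multiTE", (2.7, 3.7, 4.7, 5.7))
        series = simulate_multiecho(ph, proto, snr=np.inf)
        first = series.data[ph.mask("liver"), 0].mean()
        assert first == pytest.approx(100.0 * np.exp(-2.7 / 0.7), rel=1e-9)
        assert first == pytest.approx(2.11, abs=0.01)


class TestAddNoise:
    def test_background_mean_is_rician_floor(self, disk_phantom):
        ph = disk_phantom(shape=(128, 128), radius=1.0)
        zeros = ImageSeries(np.zeros((128, 128, 2)), [1.0, 2.0], "TE")
        noisy = add_noise(zeros, snr=1.0, seed=7, reference=1.0)  # sigma = 1
        n = noisy.data.size
        expect = np.sqrt(np.pi / 2)
        se = np.sqrt(2 - np.pi / 2) / np.sqrt(n)
        assert abs(noisy.data.mean() - expect) < 3 * se

    def test_background_variance_matches_rician(self):
        zeros = ImageSeries(np.zeros((128, 128, 4)), [1.0, 2, 3, 4], "TE")
        noisy = add_noise(zeros, snr=1.0, seed=11, reference=1.0)
        assert noisy.data.var() == pytest.approx(2 - np.pi / 2, rel=0.05)

    def test_infinite_snr_is_identity(self, disk_phantom):
        ph = disk_phantom()
        series = simulate_multiecho(ph, spin_echo_protocol(), snr=np.inf)
        out = add_noise(series, np.inf, seed=1)
        assert np.array_equal(out.data, series.data)

    def test_seed_reproducible(self, disk_phantom):
        ph = disk_phantom()
        series = simulate_multiecho(ph, spin_echo_protocol(), snr=np.inf)
        a = add_noise(series, 30.0, seed=42)
        b = add_noise(series, 30.0, seed=42)
        assert np.array_equal(a.data, b.data)

    def test_nonpositive_snr_rejected(self, disk_phantom):
        ph = disk_phantom()
        series = simulate_multiecho(ph, spin_echo_protocol(), snr=np.inf)
        with pytest.raises(ValueError):
            add_noise(series, 0.0)


class TestLookLocker:
    def test_null_point_without_saturation(self, disk_phantom):
        # vanishing readout angle: T1* -> T1, null of |S| at T1 ln 2
        t1 = 800.0
        ph = disk_phantom(t1=t1, heart_rate=600.0)
        proto = look_locker_protocol(600.0, n_ti=30, ti0=10.0)
        series = simulate_look_locker(ph, proto, flip_angle=1e-4, snr=np.inf, signed=True)
        curve = series.data[ph.mask("liver"), :].mean(axis=0)
        # signed curve crosses zero at t1*ln2; interpolate the crossing
        null = np.interp(0.0, curve, series.times)
        assert null == pytest.approx(t1 * np.log(2), rel=0.01)
        # and at TI = 0 the signed signal would be -S0 (extrapolate the model)
        assert curve[0] < 0

    def test_asymptote_recovers_equilibrium(self, disk_phantom):
        ph = disk_phantom(t1=500.0, heart_rate=600.0)
        from ironmap.core import AcquisitionProtocol

        rr = 100.0
        proto = AcquisitionProtocol("look_locker", tuple(10.0 + rr * np.arange(60)))
        series = simulate_look_locker(ph, proto, flip_angle=5.0, snr=np.inf, signed=True)
        curve = series.data[ph.mask("liver"), :].mean(axis=0)
        t1s = phantom.saturated_t1(500.0, 5.0, rr)
        a = 100.0 * t1s / 500.0
        assert curve[-1] == pytest.approx(a, rel=1e-4)

    def test_b_over_a_at_least_two(self, disk_phantom):
        # saturation only increases B/A above the perfect-inversion value 2
        t1s = phantom.saturated_t1(900.0, 5.0, 100.0)
        assert t1s < 900.0
        b_over_a = 1 + 900.0 / t1s
        assert b_over_a >= 2.0

    def test_rr_mismatch_rejected(self, disk_phantom):
        ph = disk_phantom(heart_rate=400.0)  # RR = 150 ms
        proto = look_locker_protocol(600.0)  # TIs spaced 100 ms
        with pytest.raises(ValueError, match="inconsistent"):
            simulate_look_locker(ph, proto)


class TestSimulateCine:
    def test_analytic_ef_from_truth_volumes(self):
        ph = phantom.build_lv_phantom()
        res = simulate_cine(ph, cine_protocol(600.0), edv=50.0, esv=15.0, seed=0)
        vols = res.volumes
        ef = 100.0 * (vols[res.ed_index] - vols[res.es_index]) / vols[res.ed_index]
        assert ef == pytest.approx(70.0, abs=1e-9)

    def test_esv_not_below_edv_rejected(self):
        ph = phantom.build_lv_phantom()
        with pytest.raises(ValueError):
            simulate_cine(ph, cine_protocol(600.0), edv=20.0, esv=20.0)

    def test_voxelized_diastolic_volume_close_to_analytic(self):
        ph = phantom.build_lv_phantom()
        res = simulate_cine(ph, cine_protocol(600.0), edv=50.0, esv=15.0, seed=0)
        area = 0.117 * 0.117
        vox = res.truth_masks[:, :, res.ed_index].sum() * area * res.slice_thickness * res.n_slices
        assert vox == pytest.approx(50.0, rel=0.03)


class TestMotionCorruption:
    def _series(self, disk_phantom):
        ph = disk_phantom(shape=(64, 64))
        return ph, simulate_multiecho(ph, gradient_echo_protocol(), snr=np.inf)

    def test_empty_indices_unchanged(self, disk_phantom):
        _, series = self._series(disk_phantom)
        out, truth = inject_motion_corruption(series, [], 0.3, seed=0)
        assert np.array_equal(out.data, series.data)
        assert not truth.any()

    def test_small_severity_nearly_identity(self, disk_phantom):
        _, series = self._series(disk_phantom)
        out, _ = inject_motion_corruption(series, [2], 1.0 / 64.0, seed=0)
        rel = np.abs(out.data[:, :, 2] - series.data[:, :, 2]).sum() / series.data[:, :, 2].sum()
        assert rel < 0.2  # one perturbed line out of 64

    def test_background_energy_increases(self, disk_phantom):
        ph, series = self._series(disk_phantom)
        out, _ = inject_motion_corruption(series, [0, 5], 0.3, seed=3)
        bg = ph.labels == 0
        for i in (0, 5):
            assert (out.data[bg, i] ** 2).mean() > (series.data[bg, i] ** 2).mean()
        # untouched frames are bit-identical
        assert np.array_equal(out.data[:, :, 1], series.data[:, :, 1])

    def test_severity_bounds(self, disk_phantom):
        _, series = self._series(disk_phantom)
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                inject_motion_corruption(series, [0], bad)


class TestCohort:
    def test_zero_sd_reproduces_group_mean_exactly(self):
        spec = phantom.CohortSpec(groups=(phantom.GroupSpec(
            name="g", n=4,
            organ_params={"myocardium": {"t2": (18.0, 0.0), "t2star": (11.5, 0.0),
                                         "t1": (928.0, 0.0)}},
            spleen_ratio=(4.0, 0.0), body_mass=(25.0, 0.0), ef=(65.0, 0.0),
            co=(15.6, 0.0)),), seed=5)
        _, truth = phantom.simulate_cohort(spec)
        assert np.all(truth["myocardium_t2"] == 18.0)

    def test_large_sample_mean_matches_spec(self):
        spec = phantom.default_cohort_spec(n_per_group=200, seed=9)
        _, truth = phantom.simulate_cohort(spec)
        sub = truth[truth["group"] == "humanized_control"]
        # truncation at 2 sd keeps the mean; allow 3 SE of the truncated draw
        se = 0.8 / np.sqrt(len(sub))
        assert abs(sub["myocardium_t2"].mean() - 18.0) < 3 * se + 0.02

    def test_same_seed_same_cohort(self):
        spec = phantom.default_cohort_spec(n_per_group=3, seed=21)
        _, t1 = phantom.simulate_cohort(spec)
        _, t2 = phantom.simulate_cohort(spec)
        assert t1.equals(t2)

    def test_physical_ordering_in_draws(self):
        spec = phantom.default_cohort_spec(n_per_group=50, seed=2)
        _, truth = phantom.simulate_cohort(spec)
        for organ in ("myocardium", "liver", "spleen"):
            assert np.all(truth[f"{organ}_t2star"] <= truth[f"{organ}_t2"] + 1e-12)
            assert np.all(truth[f"{organ}_t2"] <= truth[f"{organ}_t1"] + 1e-12)
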