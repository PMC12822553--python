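"""Fisher information, CRLB scaling, AFM error propagation, photon budget."""

import math

import numpy as np
import pytest

from rimap.optics import EmitterState, LayeredSample, OpticalSystem
from rimap.precision import (AFMUncertainty, UnattainablePrecisionError,
                             delta_n_afm, delta_n_smlm, fisher_information_n,
                             fisher_information_param, required_photons,
                             total_delta_n, crlb_sweep)


@pytest.fixture(scope="module")
def system():
    return OpticalSystem(oversampling=2, pupil_samples=64)


@pytest.fixture(scope="module")
def sample():
    return LayeredSample(n_layer=1.43, thickness=100.0)


@pytest.fixture(scope="module")
def emitter():
    return EmitterState(axial_position=100.0, signal_photons=1e4,
                        background_per_pixel=100.0)


def test_no_layer_carries_no_information(system, emitter):
    flat = LayeredSample(n_layer=1.43, thickness=0.0)
    assert fisher_information_n(system, flat, emitter) == 0.0
    assert delta_n_smlm(system, flat, emitter) == math.inf


def test_finite_difference_step_is_converged(system, sample, emitter):
    """Richardson check: halving the step changes FI by < 0.5%."""
    fi_h = fisher_information_n(system, sample, emitter, step=1e-4)
    fi_h2 = fisher_information_n(system, sample, emitter, step=5e-5)
    assert fi_h > 0
    assert abs(fi_h - fi_h2) / fi_h < 5e-3


def test_crlb_halves_when_photons_quadruple(system, sample):
    """Poisson information is linear in flux at fixed SBR."""
    e1 = EmitterState(axial_position=100.0, signal_photons=1e4,
                      background_per_pixel=100.0)
    e4 = EmitterState(axial_position=100.0, signal_photons=4e4,
                      background_per_pixel=400.0)
    d1 = delta_n_smlm(system, sample, e1)
    d4 = delta_n_smlm(system, sample, e4)
    assert d4 == pytest.approx(d1 / 2.0, rel=0.02)


def test_crlb_scale_equivariance(system, sample):
    """delta_n(N) = delta_n(1e5) * sqrt(1e5 / N)."""
    def at(n_photons):
        e = EmitterState(axial_position=100.0, signal_photons=n_photons,
                         background_per_pixel=n_photons / 100.0)
        return delta_n_smlm(system, sample, e)

    ref = at(1e5)
    for n_photons in (2e4, 5e5):
        assert at(n_photons) == pytest.approx(
            ref * math.sqrt(1e5 / n_photons), rel=0.02)


def test_total_budget_combines_in_quadrature():
    budget = total_delta_n(3e-3, 4e-3)
    assert budget.delta_n_total == pytest.approx(5e-3, rel=1e-12)
    assert total_delta_n(7e-3, 0.0).delta_n_total == pytest.approx(7e-3)
    with pytest.raises(ValueError):
        total_delta_n(-1e-3, 1e-3)


class TestAFMError:
    def test_zero_height_error_gives_zero(self, system, sample):
        assert delta_n_afm(system, sample, AFMUncertainty(0.0)) == 0.0

    def test_one_sided_errors_nearly_symmetric(self, system, sample):
        """|n - n_minus| and |n - n_plus| differ only negligibly."""
        from rimap.precision import _replace_sample, N_FIT_BOUNDS
        from scipy.optimize import minimize_scalar
        from rimap.optics import MoleculeImageModel

        dz = 1.0
        shifts = []
        for h_pert in (sample.thickness - dz, sample.thickness + dz):
            target = MoleculeImageModel(
                system, _replace_sample(sample, thickness=h_pert)).image(
                EmitterState(axial_position=h_pert, signal_photons=1.0))

            def mismatch(n_fit):
                img = MoleculeImageModel(
                    system, _replace_sample(sample, n_layer=n_fit)).image(
                    EmitterState(axial_position=sample.thickness,
                                 signal_photons=1.0))
                return float(((target - img) ** 2).sum())

            res = minimize_scalar(mismatch, bounds=N_FIT_BOUNDS,
                                  method="bounded",
                                  options={"xatol": 1e-6})
            shifts.append(abs(sample.n_layer - res.x))
        assert abs(shifts[0] - shifts[1]) < 0.05 * max(shifts)

    def test_argmin_matches_brute_force_scan(self, system, sample):
        """The bounded minimizer agrees with a dense grid scan."""
        from rimap.precision import _replace_sample
        from rimap.optics import MoleculeImageModel

        dz = 2.0
        h = sample.thickness
        target = MoleculeImageModel(
            system, _replace_sample(sample, thickness=h + dz)).image(
            EmitterState(axial_position=h + dz, signal_photons=1.0))

        def mismatch(n_fit):
            img = MoleculeImageModel(
                system, _replace_sample(sample, n_layer=n_fit)).image(
                EmitterState(axial_position=h, signal_photons=1.0))
            return float(((target - img) ** 2).sum())

        coarse = np.arange(1.40, 1.47, 1e-3)
        vals = [mismatch(n) for n in coarse]
        n0 = coarse[int(np.argmin(vals))]
        fine = np.arange(n0 - 2e-3, n0 + 2e-3, 1e-5)
        n_scan = fine[int(np.argmin([mismatch(n) for n in fine]))]

        est = delta_n_afm(system, sample, AFMUncertainty(dz))
        # the scan gives the one-sided +dz shift; the estimate averages
        # both sides, which differ by < 5 %
        assert abs(sample.n_layer - n_scan) == pytest.approx(est, rel=0.06)

    def test_linear_in_height_error_for_small_dz(self, system, sample):
        d1 = delta_n_afm(system, sample, AFMUncertainty(1.0))
        d2 = delta_n_afm(system, sample, AFMUncertainty(2.0))
        assert d2 == pytest.approx(2.0 * d1, rel=0.1)


class TestRequiredPhotons:
    def test_matches_quarter_rule_far_from_afm_floor(self, system, sample):
        afm = AFMUncertainty(0.2)
        n1 = required_photons(2e-2, system, sample, 100.0, afm)
        n2 = required_photons(1e-2, system, sample, 100.0, afm)
        assert n2 == pytest.approx(4 * n1, rel=0.05)

    def test_round_trip_reaches_target(self, system, sample):
        afm = AFMUncertainty(1.0)
        target = 1e-2
        n_req = required_photons(target, system, sample, 100.0, afm)
        e = EmitterState(axial_position=sample.thickness,
                         signal_photons=float(n_req),
                         background_per_pixel=n_req / 100.0)
        total = total_delta_n(delta_n_smlm(system, sample, e),
                              delta_n_afm(system, sample, afm)).delta_n_total
        assert total == pytest.approx(target, rel=0.01)

    def test_unattainable_target_names_the_floor(self, system, sample):
        afm = AFMUncertainty(5.0)
        floor = delta_n_afm(system, sample, afm)
        with pytest.raises(UnattainablePrecisionError) as err:
            required_photons(floor / 2.0, system, sample, 100.0, afm)
        assert err.value.afm_floor == pytest.approx(floor)
        assert "AFM" in str(err.value)


def test_precision_improves_with_height_and_sbr(system):
    """Coarse check of the trend surfaces (full grid in acceptance).

    The height trend holds while the dye stays well below the focal
    plane (H up to about half the defocus); precision degrades again as
    the emitter approaches focus, so the grid stays in that regime.
    """
    df = crlb_sweep(system, heights_nm=[50.0, 120.0, 200.0],
                    sbr_values=[10.0, 1000.0], photons=1e5)
    for sbr in (10.0, 1000.0):
        sub = df[df.sbr == sbr].sort_values("H_nm")
        assert np.all(np.diff(sub.delta_n_smlm) < 0)
    for h in (50.0, 120.0, 200.0):
        sub = df[df.H_nm == h].sort_values("sbr")
        assert np.all(np.diff(sub.delta_n_smlm) < 0)


def test_precision_tracks_relative_height_precision(system):
    """delta_n is approximately proportional to dH_SMLM / H (rank check)."""
    import scipy.stats

    ratios, dns = [], []
    for h in (60.0, 120.0, 240.0):
        for sbr in (20.0, 200.0):
            sample = LayeredSample(n_layer=1.43, thickness=h)
            e = EmitterState(axial_position=h, signal_photons=1e5,
                             background_per_pixel=1e5 / sbr)
            dn = delta_n_smlm(system, sample, e)
            fi_z = fisher_information_param(system, sample, e, "z")
            ratios.append(1.0 / math.sqrt(fi_z) / h)
            dns.append(dn)
    rho = scipy.stats.spearmanr(ratios, dns).statistic
    assert rho > 0.95
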