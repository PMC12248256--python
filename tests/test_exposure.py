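"""Exposure aggregation and dose tests."""

import numpy as np
import pytest

from pape.exposure import (StandardInputs, aggregate_sz, compute_pape,
                           compute_pape_series, session_exposure,
                           standard_dose)
from pape.preprocess import SegmentedChannel
from pape.ventilation import VentilationSeries

LABELS = tuple("ABCDEFG")


def fine_grid_quadrature(values, times, n_fine=20_001):
    """Independent oracle: dense trapezoid of the piecewise-linear
    interpolant, with the original nodes included in the fine grid."""
    tf = np.union1d(np.linspace(times[0], times[-1], n_fine), times)
    return np.trapezoid(np.interp(tf, times, values), tf)


def make_channels(values_by_segment, spm=3):
    """Wrap one pollutant's node arrays (replicated over all pollutants)
    and a matching constant-is-possible ventilation grid."""
    channels = {}
    for pol in ("pm1", "pm2_5", "pm10", "co2", "tvoc"):
        channels[pol] = SegmentedChannel(pol, static_segments={
            k: np.asarray(v, float) for k, v in values_by_segment.items()},
            samples_per_minute=spm)
    return channels


def make_vm(vm_by_segment, spm=3):
    return VentilationSeries("P01", segments={k: np.asarray(v, float)
                                              for k, v in vm_by_segment.items()},
                             samples_per_minute=spm)


class TestAggregateSz:
    def test_constant_integrand(self):
        assert aggregate_sz([10.0] * 6, np.arange(6.0)) == pytest.approx(50.0)

    def test_single_trapezoid(self):
        assert aggregate_sz([0.0, 10.0], [0.0, 2.0]) == pytest.approx(10.0)

    def test_matches_fine_grid_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            t = np.sort(rng.uniform(0, 5, 15))
            t[0], t[-1] = 0.0, 5.0
            z = rng.uniform(0, 60, 15)
            assert abs(aggregate_sz(z, t) - fine_grid_quadrature(z, t)) < 1e-9

    def test_gap_constraint(self):
        with pytest.raises(ValueError, match="10 min"):
            aggregate_sz([1.0, 2.0, 3.0], [0.0, 5.0, 16.0])

    def test_length_and_monotonicity_errors(self):
        with pytest.raises(ValueError):
            aggregate_sz([1.0], [0.0])
        with pytest.raises(ValueError, match="increasing"):
            aggregate_sz([1.0, 2.0, 3.0], [0.0, 2.0, 1.0])

    def test_additivity_over_adjacent_windows(self):
        rng = np.random.default_rng(6)
        t = np.sort(rng.uniform(0, 30, 31))
        z = rng.uniform(0, 50, 31)
        whole = aggregate_sz(z, t)
        split = aggregate_sz(z[:16], t[:16]) + aggregate_sz(z[15:], t[15:])
        assert whole == pytest.approx(split, rel=1e-12)

    def test_scale_equivariance(self):
        t = np.linspace(0, 5, 15)
        z = np.random.default_rng(1).uniform(0, 40, 15)
        assert aggregate_sz(3.5 * z, t) == pytest.approx(3.5 * aggregate_sz(z, t))


class TestComputePape:
    def test_zero_exposure(self):
        assert compute_pape(0.0, 15.14) == 0.0

    def test_printed_standard_row(self):
        # male tabulated ventilation over 35 min at 19 ug/m3
        sz = 19.0 * 35.0
        assert round(compute_pape(sz, 15.14), 2) == 10.07

    def test_time_varying_product_integral(self):
        rng = np.random.default_rng(12)
        t = np.linspace(0, 5, 15)
        z = rng.uniform(5, 50, 15)
        vm = rng.uniform(8, 30, 15)
        expected = fine_grid_quadrature(z * vm / 1000.0, t)
        assert compute_pape_series(z, vm, t) == pytest.approx(expected, abs=1e-9)

    def test_constant_vm_degenerates(self):
        t = np.linspace(0, 5, 15)
        z = np.random.default_rng(13).uniform(5, 50, 15)
        assert compute_pape_series(z, 12.0, t) == pytest.approx(
            compute_pape(aggregate_sz(z, t), 12.0), rel=1e-12)


class TestStandardDose:
    @pytest.mark.parametrize("vm,c,expected", [
        (13.26, 17.0, 7.89),   # woman, low fixed-station day
        (15.14, 19.0, 10.07),  # man
        (15.14, 40.0, 21.20),  # man, high fixed-station day
    ])
    def test_printed_rows(self, vm, c, expected):
        si = StandardInputs(c_std={"pm2_5": c}, vm_std_lpm=vm)
        assert round(standard_dose(si, "pm2_5"), 2) == expected

    def test_zero_concentration(self):
        si = StandardInputs(c_std={"pm2_5": 0.0}, vm_std_lpm=15.14)
        assert standard_dose(si) == 0.0

    def test_missing_pollutant(self):
        si = StandardInputs(c_std={"pm2_5": 19.0}, vm_std_lpm=15.14)
        with pytest.raises(KeyError):
            standard_dose(si, "pm10")


class TestSessionExposure:
    def test_constant_inputs_reduce_to_closed_form(self):
        c, vm_val = 25.0, 18.0
        channels = make_channels({k: [c] * 15 for k in LABELS})
        vm = make_vm({k: [vm_val] * 15 for k in LABELS})
        table = session_exposure(channels, vm)
        assert table.total("pm2_5") == pytest.approx(
            c * vm_val / 1000.0 * 35.0, rel=1e-15)

    def test_zero_segment_drops_total(self):
        arrays = {k: [10.0] * 15 for k in LABELS}
        arrays["D"] = [0.0] * 15
        channels = make_channels(arrays)
        vm = make_vm({k: [15.0] * 15 for k in LABELS})
        table = session_exposure(channels, vm)
        d_rows = table.rows.query("segment == 'D' and pollutant == 'pm2_5'")
        assert d_rows["pape"].iloc[0] == 0.0
        assert table.total("pm2_5") == pytest.approx(10.0 * 15.0 / 1000.0 * 30.0)

    def test_composition_oracle(self):
        """Per-segment dose equals hand-composed minute means -> sz -> pape."""
        rng = np.random.default_rng(44)
        arrays = {k: rng.uniform(5, 50, 15) for k in LABELS}
        vms = {k: rng.uniform(10, 25, 15) for k in LABELS}
        channels = make_channels(arrays)
        table = session_exposure(channels, make_vm(vms))
        for k in LABELS:
            z_m = arrays[k].reshape(5, 3).mean(axis=1)
            vm_m = vms[k].reshape(5, 3).mean(axis=1)
            row = table.rows.query(f"segment == '{k}' and pollutant == 'pm2_5'")
            assert row["sz"].iloc[0] == pytest.approx(z_m.sum(), rel=1e-12)
            assert row["pape"].iloc[0] == pytest.approx(
                np.sum(z_m * vm_m) / 1000.0, rel=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(9)
        arrays = {k: rng.uniform(5, 50, 15) for k in LABELS}
        vms = {k: rng.uniform(10, 25, 15) for k in LABELS}
        t1 = session_exposure(make_channels(arrays), make_vm(vms))
        t2 = session_exposure(make_channels({k: 2.5 * v for k, v in arrays.items()}),
                              make_vm(vms))
        assert t2.total("pm2_5") == pytest.approx(2.5 * t1.total("pm2_5"), rel=1e-12)

    def test_nodes_mode_uses_trapezoid(self):
        rng = np.random.default_rng(10)
        arrays = {k: rng.uniform(5, 50, 15) for k in LABELS}
        channels = make_channels(arrays)
        vm = make_vm({k: [15.0] * 15 for k in LABELS})
        table = session_exposure(channels, vm, env_factor="nodes")
        t = np.linspace(0, 14 / 3.0, 15)
        row = table.rows.query("segment == 'A' and pollutant == 'pm2_5'")
        assert row["sz"].iloc[0] == pytest.approx(aggregate_sz(arrays["A"], t))

    def test_missing_segment_rejected(self):
        channels = make_channels({k: [10.0] * 15 for k in LABELS})
        vm = make_vm({k: [15.0] * 15 for k in LABELS if k != "D"})
        with pytest.raises(KeyError, match="'D'"):
            session_exposure(channels, vm)
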