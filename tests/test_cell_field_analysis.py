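"""Flux, residence-time, volume-fraction and CFL estimators."""
import numpy as np
import pandas as pd
import pytest

import stenoflow as sf
from stenoflow.cell_field_analysis import BinnedFieldMap
from stenoflow.errors import (
    ConfigurationError,
    TrajectoryError,
    ValidationError,
    WindowError,
)

H, L, W = 130e-6, 572e-6, 50e-6
DOMAIN = (L, H, W)


def make_series(frames, **kw):
    return sf.CellSnapshotSeries(frame=pd.concat(frames, ignore_index=True), domain=DOMAIN, **kw)


def single_cell_series(n_snap, dt, x=10e-6, y=65e-6, kind="PLT", speed=0.0):
    t = np.arange(n_snap) * dt
    return make_series(
        [
            pd.DataFrame(
                {"t": tt, "id": [0], "type": [kind], "x": [(x + speed * tt) % L], "y": [y], "z": [25e-6]}
            )
            for tt in t
        ]
    )


class TestSeries:
    def test_rejects_nonuniform_interval(self):
        frames = [
            pd.DataFrame({"t": tt, "id": [0], "type": ["PLT"], "x": [1e-5], "y": [65e-6], "z": [1e-5]})
            for tt in (0.0, 0.005, 0.02)
        ]
        with pytest.raises(ValidationError, match="interval"):
            make_series(frames)

    def test_rejects_out_of_domain(self):
        frames = [
            pd.DataFrame({"t": 0.0, "id": [0], "type": ["PLT"], "x": [2 * L], "y": [65e-6], "z": [1e-5]})
        ]
        with pytest.raises(ValidationError, match="outside"):
            make_series(frames)

    def test_csv_and_hdf5_roundtrip(self, tmp_path):
        ser = single_cell_series(4, 5e-3)
        ser.to_csv(str(tmp_path / "c.csv"))
        back = sf.CellSnapshotSeries.from_csv(str(tmp_path / "c.csv"), domain=DOMAIN)
        pd.testing.assert_frame_equal(back.frame, ser.frame)
        ser.to_hdf5(str(tmp_path / "c.h5"))
        back = sf.CellSnapshotSeries.from_hdf5(str(tmp_path / "c.h5"))
        assert back.domain == pytest.approx(DOMAIN)
        assert len(back.frame) == len(ser.frame)


class TestFluxMap:
    def test_no_cells_of_type_gives_zero_map(self):
        ser = single_cell_series(4, 5e-3, kind="RBC")
        fm = sf.flux_map(ser, "PLT")
        assert not fm.values.any()

    def test_stationary_platelet_literal_formula(self):
        """60 snapshots over 0.30 s in one bin -> 60/0.30 = 200 per second."""
        ser = single_cell_series(60, 5e-3)
        fm = sf.flux_map(ser, "PLT", bins=2e-6, window=(0.0, 0.30))
        assert fm.values.max() == pytest.approx(200.0)
        assert (fm.values > 0).sum() == 1

    def test_poisson_positions_recover_density(self):
        """Monte-Carlo oracle: uniform random positions, per-bin flux ~ Poisson."""
        rng = np.random.default_rng(42)
        n, n_snap, dt = 4000, 30, 5e-3
        frames = [
            pd.DataFrame(
                {
                    "t": k * dt,
                    "id": np.arange(n),
                    "type": "PLT",
                    "x": rng.random(n) * L,
                    "y": rng.random(n) * H,
                    "z": rng.random(n) * W,
                }
            )
            for k in range(n_snap)
        ]
        ser = make_series(frames)
        bins = (np.linspace(0, L, 12), np.linspace(0, H, 8))
        fm = sf.flux_map(ser, "PLT", bins=bins, window=(0.0, (n_snap - 1) * dt))
        T = (n_snap - 1) * dt
        lam = n / (11 * 7)  # mean count per bin per snapshot
        expected = lam * n_snap / T
        sigma = np.sqrt(lam * n_snap) / T
        frac_in = np.mean(np.abs(fm.values - expected) <= 3 * sigma)
        assert frac_in > 0.95

    def test_conservation_sum_times_window(self):
        """Sum over bins x window duration = total presence count, exactly."""
        rng = np.random.default_rng(7)
        n, n_snap, dt = 500, 10, 5e-3
        frames = [
            pd.DataFrame(
                {
                    "t": k * dt,
                    "id": np.arange(n),
                    "type": "PLT",
                    "x": rng.random(n) * L,
                    "y": rng.random(n) * H,
                    "z": rng.random(n) * W,
                }
            )
            for k in range(n_snap)
        ]
        ser = make_series(frames)
        fm = sf.flux_map(ser, "PLT", bins=2e-6)
        T = fm.window[1] - fm.window[0]
        assert fm.values.sum() * T == pytest.approx(n * n_snap, rel=1e-12)

    def test_empty_window_rejected(self):
        ser = single_cell_series(4, 5e-3)
        with pytest.raises(WindowError):
            sf.flux_map(ser, "PLT", window=(1.0, 2.0))


class TestResidence:
    def test_constant_speed_diameter_over_velocity(self):
        """v = 0.01 m/s -> residence = 2 um / v = 200 us."""
        ser = single_cell_series(20, 5e-3, speed=0.01)
        rm = sf.residence_time_map(ser, bins=2e-6)
        vals = rm.values[np.isfinite(rm.values)]
        assert vals == pytest.approx(2e-4, rel=1e-9)
        # only the final (unresolvable) visit is absent, none censored mid-window
        assert rm.censored.sum() <= 1

    def test_stationary_platelet_censored_at_window(self):
        ser = single_cell_series(2, 1e-2)
        rm = sf.residence_time_map(ser, bins=2e-6)
        vals = rm.values[np.isfinite(rm.values)]
        assert vals == pytest.approx(1e-2)  # the full remaining window
        assert rm.censored.sum() == 1

    def test_poiseuille_advection_matches_d_over_u(self):
        """Analytic-profile oracle: bin residence = d/|u(y)| within 5%."""
        rng = np.random.default_rng(0)
        n = 2000
        q, wd = 2.4e-9 * 50 / 480, 50e-6
        y0 = rng.uniform(10e-6, H - 10e-6, n)
        u = 6 * q / (wd * H) * (y0 / H) * (1 - y0 / H)
        x0 = rng.random(n) * L
        frames = [
            pd.DataFrame(
                {"t": tt, "id": np.arange(n), "type": "PLT", "x": (x0 + u * tt) % L, "y": y0, "z": 25e-6}
            )
            for tt in np.arange(0, 0.05, 5e-3)
        ]
        ser = make_series(frames)
        rm = sf.residence_time_map(
            ser, bins=(np.array([0.0, L]), np.arange(0.0, H + 1e-9, 2e-6))
        )
        yc = rm.y_centers
        expected = 2e-6 / (6 * q / (wd * H) * (yc / H) * (1 - yc / H))
        sel = (yc > 10e-6) & (yc < H - 10e-6) & np.isfinite(rm.values[0])
        rel = np.abs(rm.values[0, sel] - expected[sel]) / expected[sel]
        assert rel.max() < 0.05

    def test_periodic_crossing_unwrapped(self):
        """A platelet looping through the x boundary keeps its true speed."""
        dt, v = 5e-3, 0.02
        x0 = L - 20e-6
        frames = [
            pd.DataFrame(
                {"t": k * dt, "id": [0], "type": ["PLT"], "x": [(x0 + v * k * dt) % L], "y": [65e-6], "z": [1e-5]}
            )
            for k in range(12)
        ]
        rm = sf.residence_time_map(make_series(frames), bins=10e-6)
        vals = rm.values[np.isfinite(rm.values)]
        assert vals == pytest.approx(2e-6 / v, rel=1e-9)

    def test_duplicate_id_rejected(self):
        frames = [
            pd.DataFrame(
                {"t": t, "id": [0, 0], "type": ["PLT", "PLT"], "x": [1e-5, 2e-5], "y": [65e-6] * 2, "z": [1e-5] * 2}
            )
            for t in (0.0, 5e-3)
        ]
        with pytest.raises(TrajectoryError):
            sf.residence_time_map(make_series(frames))

    def test_unlinkable_ids_rejected(self):
        frames = [
            pd.DataFrame({"t": 0.0, "id": [0], "type": ["PLT"], "x": [1e-5], "y": [65e-6], "z": [1e-5]}),
            pd.DataFrame({"t": 5e-3, "id": [1], "type": ["PLT"], "x": [1e-5], "y": [65e-6], "z": [1e-5]}),
        ]
        with pytest.raises(TrajectoryError):
            sf.residence_time_map(make_series(frames))


class TestVolumeFraction:
    def test_no_rbcs_zero_everywhere(self):
        ser = single_cell_series(4, 5e-3, kind="PLT")
        phi = sf.rbc_volume_fraction(ser)
        assert not phi.values.any()

    def test_uniform_density_closed_form(self):
        rng = np.random.default_rng(3)
        n, n_snap = 20000, 10
        frames = [
            pd.DataFrame(
                {
                    "t": k * 5e-3,
                    "id": np.arange(n),
                    "type": "RBC",
                    "x": rng.random(n) * L,
                    "y": rng.random(n) * H,
                    "z": rng.random(n) * W,
                }
            )
            for k in range(n_snap)
        ]
        ser = make_series(frames)
        phi = sf.rbc_volume_fraction(ser, bins=(np.linspace(0, L, 6), np.linspace(0, H, 6)))
        expected = n * ser.cell_volumes["RBC"] / (L * H * W)
        assert phi.values.mean() == pytest.approx(expected, rel=0.02)

    def test_half_domain_occupancy(self):
        rng = np.random.default_rng(4)
        n = 5000
        frames = [
            pd.DataFrame(
                {
                    "t": k * 5e-3,
                    "id": np.arange(n),
                    "type": "RBC",
                    "x": rng.random(n) * L,
                    "y": rng.random(n) * H / 2,  # all in the lower half
                    "z": rng.random(n) * W,
                }
            )
            for k in range(3)
        ]
        phi = sf.rbc_volume_fraction(make_series(frames), bins=10e-6)
        # bins strictly above the occupied half (skip the straddling bin)
        upper = phi.y_centers > H / 2 + 10e-6
        assert not phi.values[:, upper].any()

    def test_missing_volume_rejected(self):
        ser = single_cell_series(4, 5e-3, kind="RBC")
        ser.cell_volumes = {}
        with pytest.raises(ConfigurationError):
            sf.rbc_volume_fraction(ser)


def step_phi_map(edge=5e-6, bin_w=1e-6, phi0=0.33):
    """Constructed fixture: phi = 0 below `edge`, phi0 beyond, on both walls."""
    x_edges = np.array([0.0, L])
    y_edges = np.arange(0.0, H + 1e-9, bin_w)
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    vals = np.where((yc > edge) & (yc < H - edge), phi0, 0.0)[None, :]
    return BinnedFieldMap(x_edges=x_edges, y_edges=y_edges, values=vals, kind="volume_fraction", window=(0, 1))


class TestCFL:
    def test_step_profile_recovers_edge(self):
        phi = step_phi_map(edge=5e-6, bin_w=1e-6)
        for wall in ("glass", "pdms"):
            prof = sf.cfl_thickness(phi, wall)
            assert abs(prof.delta[0] - 5e-6) <= 1e-6  # within one bin width
            assert not prof.flagged[0]

    def test_absolute_mode_uses_unit_reference(self):
        phi = step_phi_map(edge=5e-6, bin_w=1e-6, phi0=0.33)
        rel = sf.cfl_thickness(phi, "glass", threshold_mode="relative")
        ab = sf.cfl_thickness(phi, "glass", threshold_mode="absolute")
        # absolute threshold 0.01 > relative 0.0033: crossing moves outward
        assert ab.delta[0] >= rel.delta[0]

    def test_all_zero_column_capped_and_flagged(self):
        phi = step_phi_map(edge=H, bin_w=2e-6)
        prof = sf.cfl_thickness(phi, "glass")
        assert prof.delta[0] == pytest.approx(H / 2)
        assert prof.flagged[0]

    def test_uniform_column_zero_thickness(self):
        phi = step_phi_map(edge=0.0, bin_w=2e-6)
        prof = sf.cfl_thickness(phi, "glass")
        assert prof.delta[0] <= 2e-6

    def test_requires_volume_fraction_map(self):
        fm = step_phi_map()
        fm.kind = "flux"
        with pytest.raises(ValidationError):
            sf.cfl_thickness(fm, "glass")
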