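"""Occupancy and energy summaries of trajectory-derived tables."""

import numpy as np
import pandas as pd
import pytest

from gagtk import synthetic
from gagtk.md_occupancy import (
    EventSeries,
    HBondCriteria,
    binding_energy_summary,
    classify_occupancy,
    energies_from_csv,
    events_from_csv,
    hbond_occupancy,
    serd_summary,
    site_occupancy_aggregate,
    water_bridge_occupancy,
)


class TestHbondOccupancy:
    def test_always_bonded_is_persistent(self):
        table = hbond_occupancy([EventSeries("R64", (1,) * 50)])
        assert table.loc["R64", "occupancy"] == 1.0
        assert table.loc["R64", "class"] == "persistent"

    def test_direct_count(self):
        frames = tuple(1 if i < 37 else 0 for i in range(100))
        table = hbond_occupancy([EventSeries("R58", frames)])
        assert table.loc["R58", "occupancy"] == pytest.approx(0.37)
        assert table.loc["R58", "class"] == "transient"

    @pytest.mark.parametrize(
        "occ, cls",
        [(0.62, "persistent"), (0.5, "transient"), (0.2, "transient"),
         (0.19, "negligible"), (0.51, "persistent")],
    )
    def test_class_thresholds(self, occ, cls):
        assert classify_occupancy(occ) == cls

    def test_multiplicity_does_not_inflate_occupancy(self):
        """A frame with three bonds counts once, matching the >=1-bond rule."""
        table = hbond_occupancy([EventSeries("R67", (3, 0, 2, 0))])
        assert table.loc["R67", "occupancy"] == pytest.approx(0.5)

    def test_equal_run_weighting_and_convex_hull(self):
        runs = [
            EventSeries("R64", (1,) * 100, run_id=0),  # occupancy 1.0
            EventSeries("R64", (1, 0, 0, 0) * 5, run_id=1),  # occupancy 0.25
        ]
        table = hbond_occupancy(runs)
        # equal weight per run despite 5x length difference
        assert table.loc["R64", "occupancy"] == pytest.approx(0.625)
        assert 0.25 <= table.loc["R64", "occupancy"] <= 1.0
        assert table.loc["R64", "n_runs"] == 2

    def test_bernoulli_convergence(self):
        p = 0.37
        n = 10_000
        series = synthetic.gen_hbond_events(p, n_frames=n, seed=99)
        est = hbond_occupancy(series).loc["R64", "occupancy"]
        assert abs(est - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            EventSeries("R64", ())
        with pytest.raises(ValueError):
            hbond_occupancy([])

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            HBondCriteria(donor_acceptor_cutoff=-1)
        with pytest.raises(ValueError):
            HBondCriteria(angle_cutoff=120)


class TestWaterBridge:
    def test_no_waters_all_zero(self):
        table = water_bridge_occupancy([[], [], []], residues=["R64", "R85"])
        assert (table["occupancy"] == 0.0).all()

    def test_direct_count(self):
        frames = []
        for i in range(50):
            if i < 25:
                frames.append([("w1", "R85", True, True)])
            else:
                frames.append([])
        table = water_bridge_occupancy(frames)
        assert table.loc["R85", "occupancy"] == pytest.approx(0.5)

    def test_conjunction_required(self):
        frames = [[("w1", "R64", True, False)] for _ in range(20)]
        table = water_bridge_occupancy(frames)
        assert table.loc["R64", "occupancy"] == 0.0

    def test_conjunction_bound(self, rng):
        """Bridge occupancy never exceeds either marginal contact occupancy."""
        frames = []
        for _ in range(200):
            to_res = bool(rng.random() < 0.6)
            to_lig = bool(rng.random() < 0.5)
            frames.append([("w1", "R67", to_res, to_lig)])
        bridge = water_bridge_occupancy(frames).loc["R67", "occupancy"]
        occ_res = np.mean([f[0][2] for f in frames])
        occ_lig = np.mean([f[0][3] for f in frames])
        assert bridge <= min(occ_res, occ_lig) + 1e-12


class TestSerd:
    def test_constant_series_top_anchor(self):
        table = serd_summary({"R67": [-10.0] * 10, "K60": [-2.0] * 10})
        assert table.loc["R67", "mean"] == pytest.approx(-10.0)
        assert table.loc["R67", "sd"] == 0.0
        assert table.loc["R67", "rank"] == 1
        assert bool(table.loc["R67", "anchor"]) is True

    def test_zero_energy_not_anchor(self):
        table = serd_summary({"A1": [0.0, 0.0], "R67": [-1.0, -1.0]})
        assert bool(table.loc["A1", "anchor"]) is False

    def test_ranking_arithmetic(self):
        table = serd_summary({"A": [-4.0, -6.0], "B": [-1.0, -1.0]})
        assert table.index.get_loc("A") < table.index.get_loc("B")

    def test_rank_invariant_to_frame_order(self, rng):
        series = {"A": list(rng.normal(-5, 1, 50)), "B": list(rng.normal(-2, 1, 50))}
        shuffled = {
            k: list(np.array(v)[rng.permutation(len(v))]) for k, v in series.items()
        }
        a = serd_summary(series)
        b = serd_summary(shuffled)
        assert list(a.index) == list(b.index)
        assert a["mean"].to_numpy() == pytest.approx(b["mean"].to_numpy())

    def test_multi_run_equal_weighting(self):
        table = serd_summary({"R85": [[-10.0] * 4, [-6.0] * 8]})
        assert table.loc["R85", "mean"] == pytest.approx(-8.0)


class TestBindingEnergy:
    def test_constant_runs(self):
        s = binding_energy_summary([-85.0, -85.0, -85.0])
        assert s["mean"] == -85.0 and s["sd"] == 0.0

    def test_sample_sd_formula(self):
        s = binding_energy_summary([-80.0, -90.0])
        assert s["mean"] == pytest.approx(-85.0)
        assert s["sd"] == pytest.approx(np.sqrt(50.0))  # 7.071

    def test_permutation_invariance(self):
        runs = [-85.0, -117.0, -90.0, -100.0, -95.0]
        assert binding_energy_summary(runs) == binding_energy_summary(runs[::-1])

    def test_single_run_flagged(self):
        s = binding_energy_summary([-85.0])
        assert s["sd_defined"] is False and np.isnan(s["sd"])


class TestAggregatesAndIO:
    def test_site_aggregate_both_conventions(self):
        occ = hbond_occupancy(
            [EventSeries("R64", (1, 1, 0, 0)), EventSeries("R67", (1, 1, 1, 0))]
        )
        agg = site_occupancy_aggregate(occ, ["R64", "R67"])
        assert agg["sum"] == pytest.approx(1.25)
        assert agg["mean"] == pytest.approx(0.625)

    def test_event_and_energy_csv_roundtrip(self, tmp_path):
        series = synthetic.gen_hbond_events(
            {"R64": 0.7, "R85": 0.3}, n_frames=40, n_runs=2, seed=5
        )
        rows = [
            {"run_id": s.run_id, "frame": i, "residue": s.residue, "value": v}
            for s in series
            for i, v in enumerate(s.frames)
        ]
        path = tmp_path / "events.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        back = events_from_csv(path)
        assert hbond_occupancy(back).equals(hbond_occupancy(series))

        energies = synthetic.gen_residue_energies(
            {"R67": -10.0, "K60": -2.0}, sd=1.0, n_frames=30, n_runs=2, seed=6
        )
        erows = [
            {"run_id": run_id, "frame": i, "residue": res, "value": v}
            for res, runs in energies.items()
            for run_id, run in enumerate(runs)
            for i, v in enumerate(run)
        ]
        epath = tmp_path / "energies.csv"
        pd.DataFrame(erows).to_csv(epath, index=False)
        back_e = energies_from_csv(epath)
        assert serd_summary(back_e)["mean"].to_numpy() == pytest.approx(
            serd_summary(energies)["mean"].to_numpy()
        )
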