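"""Size calibration, peak calling, species assignment and yield tables."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import nickplex as nx
from nickplex import trace_analysis as ta
from nickplex.simulate import TrueYieldProfile, species_true_sizes


@pytest.fixture(scope="module")
def gt_quiet_trace(panel, model, quiet_spec):
    prof = nx.make_yield_profile("perfect_fidelity", panel, intensity=1.0)["GT"]
    return nx.simulate_trace(panel.pools["GT"], prof, model, quiet_spec, panel)


class TestCalibration:
    def test_anchors_restored_exactly(self, gt_quiet_trace, quiet_spec):
        ct = ta.calibrate_sizes(gt_quiet_trace, quiet_spec.ladder_sizes)
        mapped = ct.size_of_scan(ct.ladder.scan_positions)
        assert np.allclose(mapped, quiet_spec.ladder_sizes, atol=0)

    def test_map_strictly_monotone(self, gt_quiet_trace, quiet_spec):
        ct = ta.calibrate_sizes(gt_quiet_trace, quiet_spec.ladder_sizes)
        scans = np.linspace(ct.ladder.scan_positions[0] - 100,
                            ct.ladder.scan_positions[-1] + 100, 500)
        assert np.all(np.diff(ct.size_of_scan(scans)) > 0)

    def test_linear_midpoint_between_anchors(self, gt_quiet_trace, quiet_spec):
        ct = ta.calibrate_sizes(gt_quiet_trace, quiet_spec.ladder_sizes)
        pos = dict(zip(ct.ladder.sizes, ct.ladder.scan_positions))
        mid = 0.5 * (pos[50.0] + pos[62.0])
        assert ct.size_of_scan(mid) == pytest.approx(56.0, abs=1e-9)

    def test_missing_ladder_peak_raises(self, gt_quiet_trace, quiet_spec):
        with pytest.raises(ta.CalibrationError, match="ladder"):
            ta.calibrate_sizes(gt_quiet_trace, list(quiet_spec.ladder_sizes) + [150])


class TestPeakDetection:
    def test_fully_reacted_pool_calls_four_peaks(self, gt_quiet_trace, quiet_spec):
        ct = ta.calibrate_sizes(gt_quiet_trace, quiet_spec.ladder_sizes)
        peaks = ta.detect_peaks(ct)
        assert len(peaks) == 4
        assert [p.apparent_size for p in peaks] == sorted(
            p.apparent_size for p in peaks
        )

    def test_species_below_height_floor_not_called(self, panel, model, quiet_spec):
        # product fraction chosen to put its apex height near 95 (< 150)
        prof = TrueYieldProfile("GT", {("C", "A"): 0.02})
        tr = nx.simulate_trace(panel.pools["GT"], prof, model, quiet_spec, panel)
        ct = ta.calibrate_sizes(tr, quiet_spec.ladder_sizes)
        sizes = [round(p.apparent_size) for p in ta.detect_peaks(ct, min_height=150)]
        product_apparent = round(nx.apparent_size(model, 50))
        assert product_apparent not in sizes
        assert len(sizes) == 4  # the four unreacted probes remain

    def test_pure_noise_trace_yields_no_peaks(self, panel, model):
        spec = nx.TraceSpec(noise_sd=20.0, seed=5)
        prof = TrueYieldProfile("GT", {})
        tr = nx.simulate_trace(panel.pools["GT"], prof, model, spec, panel)
        tr = dataclasses.replace(tr, reporter=tr.reporter * 0
                                 + np.random.default_rng(0).normal(0, 20, len(tr.scan)))
        ct = ta.calibrate_sizes(tr, spec.ladder_sizes)
        assert ta.detect_peaks(ct) == []


class TestSpeciesLibrary:
    def test_inventory_and_coelution_groups(self, panel, model):
        lib = ta.build_species_library(panel, "GT", model)
        assert len(lib.entries) == 24  # 4 probes + 4 AppN + 16 products
        assert set(lib.groups) == {frozenset({"AppA", "pG"}), frozenset({"AppC", "pT"})}

    def test_expected_gaps_exceed_twice_tolerance(self, panel, model):
        lib = ta.build_species_library(panel, "GT", model, tolerance=0.75)
        grouped = {n for g in lib.groups for n in g}
        sizes = sorted(e.expected_size for e in lib.entries if e.name not in grouped)
        gaps = np.diff(sizes)
        assert np.all(gaps >= 2 * 0.75)

    def test_reference_table_taken_verbatim(self, panel, model):
        table = {e.name: e.expected_size + 0.1
                 for e in ta.build_species_library(panel, "GT", model).entries}
        lib = ta.build_species_library(panel, "GT", table)
        assert lib.entry("C/pA").expected_size == pytest.approx(table["C/pA"])

    def test_reference_missing_species_raises(self, panel):
        with pytest.raises(KeyError, match="App"):
            ta.build_species_library(panel, "GT", {"pA": 26.0})


@pytest.fixture(scope="module")
def tth_assignment(panel, model):
    prof = nx.make_yield_profile("tth_like", panel)["GT"]
    spec = nx.TraceSpec(seed=21)
    tr = nx.simulate_trace(panel.pools["GT"], prof, model, spec, panel)
    ct = ta.calibrate_sizes(tr, spec.ladder_sizes)
    peaks = ta.detect_peaks(ct)
    lib = ta.build_species_library(panel, "GT", model)
    return ta.assign_peaks(peaks, lib)


class TestAssignment:
    def test_main_products_identified(self, tth_assignment):
        for species in ("C/pA", "C/pT", "T/pA"):
            assert species in tth_assignment.assigned

    def test_coeluting_position_assigned_to_group(self, tth_assignment):
        assert "AppA+pG" in tth_assignment.assigned
        assert "AppC+pT" in tth_assignment.assigned
        assert "pG" not in tth_assignment.assigned

    def test_each_peak_claimed_once(self, tth_assignment):
        scans = [p.apex_scan for p in tth_assignment.assigned.values()]
        assert len(scans) == len(set(scans))

    def test_far_peak_left_unassigned(self, panel, model, gt_quiet_trace, quiet_spec):
        ct = ta.calibrate_sizes(gt_quiet_trace, quiet_spec.ladder_sizes)
        peaks = ta.detect_peaks(ct)
        rogue = ta.Peak(apex_scan=0.0, apparent_size=99.0, height=500.0, area=1000.0,
                        right=10)
        lib = ta.build_species_library(panel, "GT", model)
        asn = ta.assign_peaks(list(peaks) + [rogue], lib)
        assert any(p.apparent_size == 99.0 for p in asn.unassigned)


class TestQuantitation:
    def test_yield_ceiling_quarter(self, panel, model, gt_quiet_trace, quiet_spec):
        ct = ta.calibrate_sizes(gt_quiet_trace, quiet_spec.ladder_sizes)
        lib = ta.build_species_library(panel, "GT", model)
        table = ta.quantify_yields(ta.assign_peaks(ta.detect_peaks(ct), lib))
        assert table.fraction("C/pA") == pytest.approx(0.25, abs=0.005)
        assert table.normalized_yield("C", "A") == pytest.approx(1.0, abs=0.02)

    def test_fractions_sum_to_one(self, panel, model):
        prof = nx.make_yield_profile("tth_like", panel)["GT"]
        spec = nx.TraceSpec(seed=2)
        tr = nx.simulate_trace(panel.pools["GT"], prof, model, spec, panel)
        ct = ta.calibrate_sizes(tr, spec.ladder_sizes)
        lib = ta.build_species_library(panel, "GT", model)
        table = ta.quantify_yields(ta.assign_peaks(ta.detect_peaks(ct), lib))
        assert table.table.fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_known_fraction_recovered_zero_noise(self, panel, model, quiet_spec):
        # product at 0.40 of its probe = 0.10 of total reporter fluorescence
        prof = TrueYieldProfile("GT", {("C", "A"): 0.40})
        tr = nx.simulate_trace(panel.pools["GT"], prof, model, quiet_spec, panel)
        ct = ta.calibrate_sizes(tr, quiet_spec.ladder_sizes)
        lib = ta.build_species_library(panel, "GT", model)
        table = ta.quantify_yields(ta.assign_peaks(ta.detect_peaks(ct), lib))
        assert table.fraction("C/pA") == pytest.approx(0.10, abs=0.01)

    def test_unreacted_pool_all_products_zero(self, panel, model, quiet_spec):
        prof = TrueYieldProfile("GT", {})
        tr = nx.simulate_trace(panel.pools["GT"], prof, model, quiet_spec, panel)
        ct = ta.calibrate_sizes(tr, quiet_spec.ladder_sizes)
        lib = ta.build_species_library(panel, "GT", model)
        table = ta.quantify_yields(ta.assign_peaks(ta.detect_peaks(ct), lib))
        products = table.table[table.table.kind == "product"]
        assert (products.fraction == 0).all()
        assert products["flags"].str.contains("below_floor").all()

    def test_zero_total_area_raises(self, panel, model):
        lib = ta.build_species_library(panel, "GT", model)
        empty = ta.PeakAssignment("GT", {}, [], lib)
        with pytest.raises(ValueError, match="zero"):
            ta.quantify_yields(empty)

    def test_fractions_invariant_under_rescaling(self, panel, model, quiet_spec):
        # all species far above the call floor, so the called set is stable
        prof = nx.make_yield_profile("perfect_fidelity", panel, intensity=1.0)["GT"]
        tr = nx.simulate_trace(panel.pools["GT"], prof, model, quiet_spec, panel)
        scaled = dataclasses.replace(tr, reporter=tr.reporter * 3.7)
        lib = ta.build_species_library(panel, "GT", model)
        tables = []
        for t in (tr, scaled):
            ct = ta.calibrate_sizes(t, quiet_spec.ladder_sizes)
            tables.append(
                ta.quantify_yields(ta.assign_peaks(ta.detect_peaks(ct), lib))
            )
        a, b = (t.table.set_index("species").fraction for t in tables)
        assert np.allclose(a, b.reindex(a.index), atol=1e-6)


class TestPanelAnalysis:
    def test_perfect_panel_single_product_per_pool(self, panel, model, quiet_spec):
        profiles = nx.make_yield_profile("perfect_fidelity", panel, intensity=1.0)
        traces = nx.simulate_panel(panel, profiles, model, quiet_spec)
        result = ta.analyze_panel(traces, panel, model)
        assert len(result.tables) == 16
        for label, table in result.tables.items():
            products = table.table[(table.table.kind == "product")
                                   & (table.table.fraction > 0)]
            assert len(products) == 1

    def test_failed_calibration_flags_pool_keeps_others(self, panel, model, quiet_spec):
        profiles = nx.make_yield_profile("perfect_fidelity", panel, intensity=1.0)
        traces = nx.simulate_panel(panel, profiles, model, quiet_spec)
        broken = dataclasses.replace(traces[0], standard=np.zeros_like(traces[0].standard))
        result = ta.analyze_panel([broken] + traces[1:], panel, model)
        assert result.failed_pools() == [traces[0].pool]
        assert len(result.tables) == 15

    def test_replicates_averaged_with_sd(self, panel, model):
        profiles = nx.make_yield_profile("tth_like", panel)
        reps = []
        for seed in (1, 2, 3):
            spec = nx.TraceSpec(seed=seed)
            reps.append(
                nx.simulate_trace(panel.pools["GT"], profiles["GT"], model, spec, panel)
            )
        result = ta.analyze_panel(reps, panel, model)
        table = result.tables["GT"].table
        row = table[table.species == "C/pA"]
        assert result.diagnostics["GT"]["n_replicates"] == 3
        assert np.isfinite(row.sd.iloc[0]) and row.sd.iloc[0] < 0.02


class TestVendorPeakTables:
    def test_precalled_table_round_trip(self, panel, model):
        df = pd.DataFrame(
            {
                "apparent_size": [nx.apparent_size(model, s) for s in (30, 32, 34, 36, 50)],
                "height": [5000.0] * 5,
                "area": [100.0, 100.0, 100.0, 100.0, 100.0],
            }
        )
        peaks = ta.peaks_from_table(df)
        lib = ta.build_species_library(panel, "GT", model)
        table = ta.quantify_yields(ta.assign_peaks(peaks, lib))
        assert table.fraction("A/pA") == pytest.approx(0.2)
        assert table.fraction("pA") == pytest.approx(0.2)
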