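"""Tests for plate-level screen analytics."""

import numpy as np
import pytest

from meltshift.errors import AnalysisError, ValidationError
from meltshift.melt_core import ThResult, analyze_plate
from meltshift.plate_analysis import (classify_wells, delta_th, dose_response,
                                      export_results, import_results,
                                      ph_profile, summarize_plate, waterfall)
from meltshift.screens import Component, Condition, ScreenDefinition
from meltshift.synthgen import synth_plate


def ok(well, th):
    return ThResult(well, th, None, 11, 100.0, "OK")


def ns(well):
    return ThResult(well, None, None, None, None, "NS")


def screen_with_refs(wells, refs):
    conds = {}
    for w in wells:
        role = "reference" if w in refs else "sample"
        comps = () if role == "reference" else (Component("NaCl", 0.1, "M"),)
        conds[w] = Condition(w, components=comps, role=role)
    return ScreenDefinition("test", conds, tuple(refs))


class TestDeltaTh:
    def test_mean_of_blanks_arithmetic(self):
        results = {"A1": ok("A1", 70.0), "A2": ok("A2", 70.5),
                   "A3": ok("A3", 70.1), "B1": ok("B1", 74.2)}
        screen = screen_with_refs(results, ["A1", "A2", "A3"])
        deltas = delta_th(results, screen)
        assert deltas["B1"] == pytest.approx(4.0, abs=1e-12)

    def test_reference_wells_average_to_zero(self):
        results = {"A1": ok("A1", 69.8), "A2": ok("A2", 70.2), "B1": ok("B1", 71.0)}
        screen = screen_with_refs(results, ["A1", "A2"])
        deltas = delta_th(results, screen)
        assert np.mean([deltas["A1"], deltas["A2"]]) == pytest.approx(0.0, abs=1e-12)

    def test_ns_well_gets_absent_delta(self):
        results = {"A1": ok("A1", 70.0), "B1": ns("B1")}
        screen = screen_with_refs(results, ["A1"])
        assert delta_th(results, screen)["B1"] is None

    def test_no_usable_reference_raises(self):
        results = {"A1": ns("A1"), "B1": ok("B1", 70.0)}
        screen = screen_with_refs(results, ["A1"])
        with pytest.raises(AnalysisError):
            delta_th(results, screen)


class TestClassifyWells:
    def test_sign_and_flag_rules(self):
        results = {"A1": ok("A1", 70.0), "B1": ok("B1", 76.0),
                   "B2": ok("B2", 67.0), "B3": ok("B3", 70.2),
                   "B4": ThResult("B4", 71.0, 76.0, 11, 10.0, "TWO_STEP"),
                   "B5": ns("B5")}
        screen = screen_with_refs(results, ["A1"])
        deltas = delta_th(results, screen)
        cats = classify_wells(results, deltas)
        assert cats["B1"][0] == "INCREASE"
        assert cats["B2"][0] == "DECREASE"
        assert cats["B3"][0] == "NEUTRAL"
        assert cats["B4"][0] == "TWO_STEP"  # flag wins over any delta
        assert cats["B5"][0] == "NS"

    def test_every_well_gets_exactly_one_category(self):
        results = {f"A{i}": ok(f"A{i}", 60.0 + i) for i in range(1, 13)}
        screen = screen_with_refs(results, ["A1"])
        cats = classify_wells(results, delta_th(results, screen))
        assert set(cats) == set(results)

    def test_sign_agreement_on_synthetic_plate(self):
        plate, screen_rows, truth = synth_plate("dilution_series", seed=3,
                                                noise_fraction=0.01)
        results = analyze_plate(plate)
        true_tm = {r["well_id"]: r["tm"] for r in truth}
        ref_truth = np.mean([true_tm[f"H{i}"] for i in range(1, 13)])
        wells = [w for w in results if abs(true_tm[w] - ref_truth) > 1.0]
        refs = [f"H{i}" for i in range(1, 13)]
        screen = screen_with_refs(results, refs)
        cats = classify_wells(results, delta_th(results, screen))
        agree = sum(
            1 for w in wells
            if cats[w][0] == ("INCREASE" if true_tm[w] > ref_truth else "DECREASE"))
        assert agree / len(wells) >= 0.95


class TestPhProfile:
    def test_grouping_and_zero_dpka_identity(self):
        conds = {}
        results = {}
        for i, buf in enumerate(["buffer A", "buffer B", "buffer C"]):
            for j, ph in enumerate([5.0, 7.0, 9.0]):
                w = f"{chr(65 + i)}{j + 1}"
                conds[w] = Condition(w, (Component(buf, 0.2, "M"),),
                                     ph25=ph, dpka_per_degc=0.0)
                results[w] = ok(w, 60.0 + i + j)
        screen = ScreenDefinition("t", conds)
        prof = ph_profile(results, screen)
        assert set(prof) == {"buffer A", "buffer B", "buffer C"}
        for series in prof.values():
            assert [p for p, _ in series] == [5.0, 7.0, 9.0]  # ph == ph25, sorted

    def test_recovers_true_tm_of_ph_surface(self):
        plate, screen_rows, truth = synth_plate("ph_gradient", seed=2,
                                                noise_fraction=0.0)
        results = analyze_plate(plate)
        true_tm = {r["well_id"]: r["tm"] for r in truth}
        conds = {
            r["well"]: Condition(r["well"],
                                 (Component("universal buffer", 0.1, "M"),),
                                 ph25=float(r["ph25"]), dpka_per_degc=0.0)
            for r in screen_rows
        }
        screen = ScreenDefinition("t", conds)
        prof = ph_profile(results, screen)
        (label, series), = prof.items()
        assert len(series) == 96
        by_well = {w: results[w].th_primary for w in results}
        for w, tm in true_tm.items():
            assert by_well[w] == pytest.approx(tm, abs=0.5)

    def test_wells_without_ph_skipped(self):
        conds = {"A1": Condition("A1", (Component("NaCl", 1.0, "M"),)),
                 "A2": Condition("A2", (Component("buffer A", 0.2, "M"),),
                                 ph25=7.0, dpka_per_degc=0.0)}
        results = {"A1": ok("A1", 60.0), "A2": ok("A2", 61.0)}
        prof = ph_profile(results, ScreenDefinition("t", conds))
        assert list(prof) == ["buffer A"]


class TestDoseResponse:
    def make_dilution(self):
        conds = {}
        results = {}
        for i in range(12):
            w = f"A{i + 1}"
            conc_mm = 10.0 / 2 ** i
            conds[w] = Condition(w, (Component("CoCl2", conc_mm, "mM"),))
            results[w] = ok(w, 60.0 + i * 0.1)
        return results, ScreenDefinition("t", conds)

    def test_two_fold_series_lowest_concentrations(self):
        results, screen = self.make_dilution()
        series = dose_response(results, screen, "CoCl2")
        concs = [c for c, _ in series]
        assert concs[0] == pytest.approx(4.8828125)   # ~5 uM
        assert concs[1] == pytest.approx(9.765625)    # ~10 uM
        assert concs == sorted(concs)

    def test_missing_species(self):
        results, screen = self.make_dilution()
        with pytest.raises(ValidationError):
            dose_response(results, screen, "MgCl2")

    def test_saturating_shift_is_monotone(self):
        plate, screen_rows, _ = synth_plate("dilution_series", seed=4,
                                            noise_fraction=0.0)
        results = analyze_plate(plate)
        conds = {}
        for r in screen_rows:
            if r["component"]:
                conds[r["well"]] = Condition(
                    r["well"], (Component(r["component"],
                                          float(r["concentration"]), r["unit"]),))
            else:
                conds[r["well"]] = Condition(r["well"], role="reference")
        screen = ScreenDefinition("t", conds)
        series = dose_response(results, screen, "additive1")
        ths = [th for _, th in series]
        assert all(b >= a - 0.3 for a, b in zip(ths, ths[1:]))  # noise margin


class TestWaterfall:
    def test_labels_reference_and_shifted(self):
        plate, screen_rows, truth = synth_plate("dilution_series", seed=5,
                                                noise_fraction=0.0)
        results = analyze_plate(plate)
        conds = {}
        for r in screen_rows:
            if r["component"]:
                conds[r["well"]] = Condition(
                    r["well"], (Component(r["component"],
                                          float(r["concentration"]), r["unit"]),))
            else:
                conds[r["well"]] = Condition(r["well"], role="reference")
        screen = ScreenDefinition("t", conds,
                                  tuple(f"H{i}" for i in range(1, 13)))
        entries = waterfall(plate, results, screen, "additive1")
        assert [e["concentration_um"] for e in entries] == \
            sorted(e["concentration_um"] for e in entries)
        # high concentrations shift Tm by ~+8 degC, the lowest by <0.2 degC
        assert entries[-1]["label"] == "shifted"
        assert entries[0]["label"] == "no_shift"

    def test_all_ns_plate_warns_and_returns_empty(self):
        results = {"A1": ns("A1"), "A2": ns("A2")}
        screen = screen_with_refs(results, ["A1"])
        with pytest.warns(UserWarning):
            assert waterfall({}, results, screen, "NaCl") == []


class TestExportImport:
    def test_round_trip_and_ns_fields(self, tmp_path):
        results = {"A1": ok("A1", 70.0), "A2": ns("A2"),
                   "A3": ThResult("A3", 55.0, 71.0, 9, 50.0, "TWO_STEP")}
        screen = screen_with_refs(results, ["A1"])
        summaries = summarize_plate(results, screen)
        out = tmp_path / "res.csv"
        export_results(summaries, out)
        again = import_results(out)
        assert len(again) == 3
        by_well = {s.well_id: s for s in again}
        assert by_well["A2"].th_primary is None
        assert by_well["A2"].category == "NS"
        assert by_well["A3"].flag == "TWO_STEP"
        assert by_well["A1"].delta_th == pytest.approx(0.0)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 4  # header + 3 wells
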