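"""Unit and property tests for the calcium-imaging excitability classifier."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nociscreen import calcium_screen as cal
from tests.conftest import make_trace


# ---------------------------------------------------------------------------
# protocol validation and round-trip
# ---------------------------------------------------------------------------

class TestStimulusProtocol:
    def test_rejects_nonpositive_pulse_duration(self):
        with pytest.raises(cal.ProtocolError):
            cal.StimulusProtocol((15.0, 315.0, 615.0), 0.0, 2)

    def test_rejects_non_increasing_onsets(self):
        with pytest.raises(cal.ProtocolError):
            cal.StimulusProtocol((15.0, 15.0, 615.0), 15.0, 2)

    def test_rejects_drug_trial_without_two_baselines(self):
        with pytest.raises(cal.ProtocolError):
            cal.StimulusProtocol((15.0, 315.0, 615.0), 15.0, 1)

    def test_rejects_overlapping_response_windows(self):
        with pytest.raises(cal.ProtocolError):
            cal.StimulusProtocol(
                (15.0, 35.0, 615.0), 15.0, 2, response_window_s=30.0
            )

    def test_default_response_window_is_pulse_plus_15(self):
        p = cal.StimulusProtocol((15.0, 315.0, 615.0), 15.0, 2)
        assert p.response_window_s == 30.0

    def test_round_trip_through_text_file_is_lossless(self, tmp_path, short_protocol):
        path = tmp_path / "protocol.txt"
        cal.write_protocol(short_protocol, path)
        assert cal.read_protocol(path) == short_protocol


# ---------------------------------------------------------------------------
# ΔF/F and per-trial excitability
# ---------------------------------------------------------------------------

class TestComputeDff:
    def test_constant_trace_gives_zero_dff(self, short_protocol):
        t = np.arange(0.0, 170.0)
        trace = cal.CellTrace("c", t, np.full_like(t, 50.0))
        dff = cal.compute_dff(trace, short_protocol)
        assert np.allclose(dff["dff"], 0.0)
        assert set(dff["trial_index"]) == {0, 1, 2}

    def test_doubling_fluorescence_gives_unit_dff(self, make_flat_trace, short_protocol):
        trace = make_flat_trace("c", [1.0, 1.0, 1.0])
        dff = cal.compute_dff(trace, short_protocol)
        e = cal.trial_excitability(dff, short_protocol)
        assert [rec.e for rec in e] == pytest.approx([1.0, 1.0, 1.0])

    def test_gain_invariance(self, make_flat_trace, short_protocol):
        a = make_flat_trace("c", [0.8, 1.0, 0.4])
        b = make_flat_trace("c", [0.8, 1.0, 0.4], gain=37.5)
        da = cal.compute_dff(a, short_protocol)
        db = cal.compute_dff(b, short_protocol)
        assert np.allclose(da["dff"], db["dff"])

    def test_nonpositive_baseline_raises_degenerate_error(self, short_protocol):
        t = np.arange(0.0, 170.0)
        trace = cal.CellTrace("c", t, np.zeros_like(t))
        with pytest.raises(cal.DegenerateBaselineError):
            cal.compute_dff(trace, short_protocol)

    def test_trace_not_spanning_windows_raises(self, short_protocol):
        t = np.arange(0.0, 100.0)  # ends before the third response window
        trace = cal.CellTrace("c", t, np.full_like(t, 50.0))
        with pytest.raises(ValueError):
            cal.compute_dff(trace, short_protocol)

    def test_max_is_taken_without_clipping(self, short_protocol):
        # a trace dipping below baseline in a window yields a negative max
        t = np.arange(0.0, 170.0)
        f = np.full_like(t, 100.0)
        for onset in short_protocol.pulse_onsets_s:
            f[(t >= onset) & (t < onset + 30.0)] = 90.0  # −10% everywhere
        dff = cal.compute_dff(cal.CellTrace("c", t, f), short_protocol)
        e = cal.trial_excitability(dff, short_protocol)
        assert all(rec.e == pytest.approx(-0.1) for rec in e)


# ---------------------------------------------------------------------------
# the classification rules: arithmetic oracles
# ---------------------------------------------------------------------------

class TestQcBaseline:
    @pytest.mark.parametrize(
        "e0, e1, expected",
        [
            (1.00, 1.10, True),   # 0.10/1.05 ≈ 0.0952 < 0.15
            (1.00, 1.20, False),  # 0.20/1.10 ≈ 0.182
            (1.0, 1.0, True),     # zero difference
            (0.01, 0.01, True),   # any equal positive value passes
            (0.0, 0.0, False),    # degenerate mean fails, never raises
            (-1.0, 1.0, False),
            (math.nan, 1.0, False),
        ],
    )
    def test_qc_rule(self, e0, e1, expected):
        assert cal.qc_baseline(e0, e1) is expected

    def test_first_trial_denominator_option(self):
        # |1.0 − 1.14| / 1.0 = 0.14 < 0.15 passes with the 'first' convention
        assert cal.qc_baseline(1.0, 1.14, denominator="first")
        assert not cal.qc_baseline(1.0, 1.16, denominator="first")


class TestClassifyCell:
    @pytest.mark.parametrize(
        "e0, e1, e_drug, label",
        [
            (1.0, 1.0, 0.80, "inhibited"),
            (1.0, 1.0, 0.85, "unchanged"),  # strict boundary
            (1.0, 1.0, 1.15, "unchanged"),  # strict boundary
            (1.0, 1.0, 1.16, "enhanced"),
            (1.0, 1.1, 1.30, "enhanced"),   # baseline 1.05, r ≈ 1.238
            (1.0, 1.0, -0.5, "inhibited"),
        ],
    )
    def test_fifteen_percent_rule(self, e0, e1, e_drug, label):
        got, r = cal.classify_cell(e0, e1, e_drug)
        assert got == label
        assert r == pytest.approx(e_drug / ((e0 + e1) / 2))

    def test_nonpositive_baseline_is_excluded(self):
        label, r = cal.classify_cell(0.0, 0.0, 1.0)
        assert label == "excluded" and math.isnan(r)

    @given(r=st.floats(min_value=0.0, max_value=3.0, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_label_is_step_function_of_relative_excitability(self, r):
        label, rel = cal.classify_cell(1.0, 1.0, r)
        assert rel == pytest.approx(r)
        if r < 0.85:
            assert label == "inhibited"
        elif r > 1.15:
            assert label == "enhanced"
        else:
            assert label == "unchanged"

    @given(
        e_hi=st.floats(min_value=0.01, max_value=3.0),
        e_lo=st.floats(min_value=0.0, max_value=3.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_drug_excitability(self, e_hi, e_lo):
        """Decreasing e_drug never moves a cell from inhibited toward enhanced."""
        order = {"inhibited": 0, "unchanged": 1, "enhanced": 2}
        lo, hi = sorted((e_lo, e_hi))
        assert (
            order[cal.classify_cell(1.0, 1.0, lo)[0]]
            <= order[cal.classify_cell(1.0, 1.0, hi)[0]]
        )


class TestStratify:
    @pytest.mark.parametrize(
        "d, stratum",
        [
            (24.9, "small"),
            (25.0, "medium"),
            (35.0, "medium"),
            (35.1, "large"),
            (None, "unknown"),
            (math.nan, "unknown"),
        ],
    )
    def test_boundaries(self, d, stratum):
        assert cal.stratify_by_diameter(d) == stratum

    def test_nonpositive_diameter_raises(self):
        with pytest.raises(cal.InvalidMeasurementError):
            cal.stratify_by_diameter(-1.0)


# ---------------------------------------------------------------------------
# population summaries and washout
# ---------------------------------------------------------------------------

def _cls(label, stratum="medium", r=1.0):
    return cal.CellClassification(
        cell_id="x",
        qc_pass=label != "excluded",
        label=label,
        relative_excitability=r if label != "excluded" else math.nan,
        stratum=stratum,
    )


class TestSummarize:
    def test_counting_example(self):
        cells = (
            [_cls("inhibited")] * 4
            + [_cls("enhanced")]
            + [_cls("unchanged")] * 3
            + [_cls("excluded")] * 2
        )
        s = cal.summarize_population(cells)
        assert (s.n_total, s.n_excluded) == (10, 2)
        assert s.fraction_inhibited == pytest.approx(4 / 8)
        assert s.fraction_enhanced == pytest.approx(1 / 8)

    def test_all_excluded_flags_undefined_fractions(self):
        s = cal.summarize_population([_cls("excluded")] * 3)
        assert not s.fractions_defined
        assert math.isnan(s.fraction_inhibited)

    def test_counts_conserve_total(self):
        rng = np.random.default_rng(0)
        cells = [
            _cls(rng.choice(["inhibited", "enhanced", "unchanged", "excluded"]))
            for _ in range(200)
        ]
        s = cal.summarize_population(cells)
        assert (
            s.n_inhibited + s.n_enhanced + s.n_unchanged + s.n_excluded
            == s.n_total
        )

    def test_unknown_stratum_counts_in_overall_but_not_strata(self):
        cells = [_cls("inhibited", stratum="unknown"), _cls("unchanged")]
        s = cal.summarize_population(cells)
        assert s.n_total == 2
        assert "unknown" not in s.per_stratum
        assert s.per_stratum["medium"].n_total == 1

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            cal.summarize_population([])


class TestWashout:
    def test_full_recovery_gives_ratio_one(self, short_protocol):
        assert cal.washout_check([1.0, 1.0, 0.5], short_protocol) is None  # no post trials
        p5 = cal.StimulusProtocol(
            (15.0, 75.0, 135.0, 195.0, 255.0), 15.0, 2, response_window_s=30.0
        )
        assert cal.washout_check([1.0, 1.0, 0.5, 1.0, 1.0], p5) == pytest.approx(1.0)

    def test_persistent_effect_tracks_multiplier(self, short_protocol):
        p5 = cal.StimulusProtocol(
            (15.0, 75.0, 135.0, 195.0, 255.0), 15.0, 2, response_window_s=30.0
        )
        ratio = cal.washout_check([1.0, 1.0, 0.5, 0.5, 0.5], p5)
        assert ratio == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# end-to-end per-cell pipeline
# ---------------------------------------------------------------------------

class TestClassifyTrace:
    def test_gain_invariance_of_full_classification(self, short_protocol):
        for gain in (0.5, 1.0, 200.0):
            trace = make_trace("c", short_protocol, [1.0, 1.05, 0.6], gain=gain)
            c = cal.classify_trace(trace, short_protocol)
            assert c.label == "inhibited"
            assert c.relative_excitability == pytest.approx(0.6 / 1.025)

    def test_qc_failure_excludes_with_reason(self, short_protocol):
        trace = make_trace("c", short_protocol, [1.0, 1.3, 1.0])
        c = cal.classify_trace(trace, short_protocol)
        assert c.label == "excluded" and not c.qc_pass
        assert c.exclusion_reason == "baseline_qc"

    def test_degenerate_baseline_excludes_with_reason(self, short_protocol):
        t = np.arange(0.0, 170.0)
        trace = cal.CellTrace("c", t, np.zeros_like(t))
        c = cal.classify_trace(trace, short_protocol)
        assert c.exclusion_reason == "degenerate_baseline"

    def test_missing_diameter_still_classified(self, short_protocol):
        trace = make_trace("c", short_protocol, [1.0, 1.0, 1.0], diameter_um=None)
        c = cal.classify_trace(trace, short_protocol)
        assert c.label == "unchanged" and c.stratum == "unknown"

    def test_traces_round_trip_through_csv(self, tmp_path, short_protocol):
        traces = [
            make_trace("a", short_protocol, [1.0, 1.0, 0.5], diameter_um=20.0),
            make_trace("b", short_protocol, [1.0, 1.0, 1.0], diameter_um=None),
        ]
        path = tmp_path / "traces.csv"
        cal.write_traces(traces, path)
        back = cal.read_traces(path)
        assert [tr.cell_id for tr in back] == ["a", "b"]
        assert np.allclose(back[0].F, traces[0].F)
        assert back[1].diameter_um is None


# ---------------------------------------------------------------------------
# oracle equivalence on hand-built traces
# ---------------------------------------------------------------------------

def brute_force_label(trace, protocol):
    """Independent re-derivation of the label with plain Python loops."""
    samples = list(zip(trace.time_s.tolist(), trace.F.tolist()))
    e = []
    for onset in protocol.pulse_onsets_s:
        base = [f for (t, f) in samples if onset - protocol.f0_window_s <= t < onset]
        f0 = sum(base) / len(base)
        if f0 <= 0:
            return "excluded"
        window = [
            f for (t, f) in samples
            if onset <= t < onset + protocol.response_window_s
        ]
        e.append(max((f - f0) / f0 for f in window))
    mean01 = (e[0] + e[1]) / 2
    if mean01 <= 0 or abs(e[0] - e[1]) / mean01 >= 0.15:
        return "excluded"
    r = e[protocol.drug_trial_index] / mean01
    if r < 0.85:
        return "inhibited"
    if r > 1.15:
        return "enhanced"
    return "unchanged"


def test_pipeline_matches_brute_force_oracle(short_protocol):
    """Full-pipeline labels equal an independent brute-force computation on
    a panel of hand-built traces spanning every label and edge case."""
    peaks_panel = [
        [1.0, 1.0, 0.5],     # clear inhibition
        [1.0, 1.0, 0.84],    # just inhibited
        [1.0, 1.0, 0.85],    # boundary → unchanged
        [1.0, 1.0, 1.0],     # no effect
        [1.0, 1.0, 1.15],    # boundary → unchanged
        [1.0, 1.0, 1.16],    # just enhanced
        [1.0, 1.0, 2.0],     # strong enhancement
        [1.0, 1.1, 1.3],     # uneven baseline, enhanced
        [1.0, 1.3, 1.0],     # QC failure
        [2.0, 2.0, 1.0],     # inhibition at high baseline
        [0.5, 0.5, 0.5],     # low but consistent
        [1.0, 1.0, -0.2],    # suppressed below baseline
    ]
    rng = np.random.default_rng(12)
    for k, peaks in enumerate(peaks_panel):
        gain = float(rng.uniform(0.5, 5.0))
        trace = make_trace(f"cell{k}", short_protocol, peaks, gain=gain)
        expected = brute_force_label(trace, short_protocol)
        got = cal.classify_trace(trace, short_protocol).label
        assert got == expected, f"panel {k}: {got} != {expected}"
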