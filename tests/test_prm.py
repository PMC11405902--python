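"""PRM scoring: RT alignment, XICs, integration, NSA, detection gates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prmkit.chem import LabeledPeptide, precursor_mz
from prmkit.io import TargetRecord
from prmkit.prm import (
    PeakIntegration,
    PrtcAnchorSet,
    ReferenceSpectrum,
    Xic,
    align_reference_rt,
    call_detection,
    extract_xics,
    integrate_peak,
    nsa_score,
    quantify_fragments,
    score_target,
)
from prmkit.sim import (
    NoiseModel,
    make_prm_target,
    random_peptide,
    reference_from_pattern,
    simulate_prm_run,
)
from prmkit.spectra import CentroidSpectrum, Run


class TestRtAlignment:
    def test_linear_interpolation_between_anchors(self):
        anchors = PrtcAnchorSet([10.0, 20.0], [12.0, 24.0])
        assert align_reference_rt(15.0, anchors) == pytest.approx(18.0)

    def test_exact_at_anchor_knots(self):
        anchors = PrtcAnchorSet([10.0, 20.0, 35.0], [12.0, 24.0, 37.5])
        for ref, sample in [(10.0, 12.0), (20.0, 24.0), (35.0, 37.5)]:
            assert align_reference_rt(ref, anchors) == pytest.approx(sample, abs=1e-12)

    def test_extrapolation_continues_last_segment_slope(self):
        anchors = PrtcAnchorSet([10.0, 20.0], [12.0, 24.0])
        assert align_reference_rt(25.0, anchors) == pytest.approx(30.0)
        assert align_reference_rt(5.0, anchors) == pytest.approx(6.0)

    def test_fewer_than_two_anchors_rejected(self):
        with pytest.raises(ValueError):
            PrtcAnchorSet([10.0], [12.0])

    def test_non_monotone_anchors_rejected_with_offenders(self):
        with pytest.raises(ValueError, match="sample"):
            PrtcAnchorSet([10.0, 20.0, 30.0], [12.0, 24.0, 20.0], names=["a", "b", "c"])

    def test_alignment_composed_with_inverse_is_identity(self, rng):
        ref = np.sort(rng.uniform(5, 60, size=6))
        sample = ref * 1.1 + 2.0
        anchors = PrtcAnchorSet(ref, sample)
        for rt in rng.uniform(0, 70, size=20):
            roundtrip = align_reference_rt(
                align_reference_rt(rt, anchors), anchors.inverse()
            )
            assert roundtrip == pytest.approx(rt, abs=1e-9)


class TestNsa:
    def test_identical_vectors_score_one(self):
        assert nsa_score([3.0, 2.0, 1.0], [3.0, 2.0, 1.0]) == pytest.approx(1.0)

    def test_orthogonal_vectors_score_zero(self):
        assert nsa_score([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)

    def test_45_degree_angle_scores_half(self):
        assert nsa_score([1.0, 1.0], [1.0, 0.0]) == pytest.approx(0.5)

    def test_zero_vector_is_undefined(self):
        assert math.isnan(nsa_score([0.0, 0.0], [1.0, 2.0]))

    def test_negative_intensities_rejected(self):
        with pytest.raises(ValueError):
            nsa_score([1.0, -1.0], [1.0, 1.0])

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(0.0, 1e6), min_size=2, max_size=12),
        st.lists(st.floats(0.0, 1e6), min_size=2, max_size=12),
        st.floats(1e-3, 1e3),
    )
    def test_symmetric_scale_invariant_bounded(self, a, b, scale):
        n = min(len(a), len(b))
        a, b = np.array(a[:n]), np.array(b[:n])
        s = nsa_score(a, b)
        if math.isnan(s):
            return
        assert 0.0 <= s <= 1.0
        assert nsa_score(b, a) == pytest.approx(s, abs=1e-12)
        # arccos is ill-conditioned near parallel vectors; 1e-6 covers the
        # amplified rounding of the rescaled dot product
        assert nsa_score(a * scale, b) == pytest.approx(s, abs=1e-6)


def _xic(trace, annotation="y5+", dt_s=1.0, mz=500.0):
    times = np.arange(len(trace)) * dt_s / 60.0 + 10.0
    return Xic(annotation, mz, times, np.asarray(trace, dtype=float), 7.0, (9.0, 11.0))


class TestIntegration:
    def test_triangular_peak_area_and_apex(self):
        integ = integrate_peak([_xic([0, 50, 100, 50, 0])])
        assert integ.apex_rt_min == pytest.approx(10.0 + 2 / 60.0)
        assert integ.areas["y5+"] == pytest.approx(200.0)  # intensity*s, trapezoid

    def test_coeluting_transitions_share_boundaries(self):
        a = _xic([0, 50, 100, 50, 0], "y5+")
        b = _xic([0, 10, 20, 10, 0], "y6+")
        integ = integrate_peak([a, b])
        assert integ.areas["y6+"] == pytest.approx(40.0)
        assert integ.detected["y5+"] and integ.detected["y6+"]

    def test_two_scan_transition_not_detected(self):
        a = _xic([0, 50, 100, 50, 0], "y5+")
        b = _xic([0, 20, 30, 0, 0], "y6+")
        integ = integrate_peak([a, b])
        assert not integ.detected["y6+"]
        assert integ.detected["y5+"]

    def test_all_zero_traces_give_no_peak(self):
        integ = integrate_peak([_xic([0, 0, 0, 0])])
        assert integ.empty
        assert quantify_fragments(integ) == 0.0

    def test_boundaries_stop_at_valley_between_two_peaks(self):
        integ = integrate_peak([_xic([0, 80, 10, 100, 200, 100, 0])])
        lo, hi = integ.boundaries_min
        assert lo >= 10.0 + 2 / 60.0  # the valley at scan 2 bounds the apex peak
        assert integ.apex_rt_min == pytest.approx(10.0 + 4 / 60.0)


class TestQuantify:
    def test_sums_detected_transition_areas(self):
        integ = PeakIntegration(
            10.0, (9.9, 10.1),
            {"a": 100.0, "b": 200.0, "c": 300.0},
            {"a": True, "b": True, "c": True},
        )
        assert quantify_fragments(integ) == 600.0

    def test_undetected_transitions_excluded(self):
        integ = PeakIntegration(
            10.0, (9.9, 10.1),
            {"a": 100.0, "b": 200.0, "c": 50.0},
            {"a": True, "b": True, "c": False},
        )
        assert quantify_fragments(integ) == 300.0


def _reference(n=8):
    pep = LabeledPeptide("RIAESLPVV")
    target = TargetRecord(pep, 2, precursor_mz(pep, 2))
    transitions = [(f"y{i}+", 300.0 + 10 * i, 1.0 - 0.1 * i) for i in range(n)]
    return ReferenceSpectrum(target, transitions, reference_rt_min=25.0)


def _integration(areas, detected=None):
    detected = detected if detected is not None else {a: v > 0 for a, v in areas.items()}
    return PeakIntegration(25.2, (25.0, 25.4), areas, detected)


class TestDetectionCall:
    def test_all_gates_pass(self):
        ref = _reference()
        areas = {a: rel * 1000 for a, _, rel in ref.transitions}
        det = call_detection(_integration(areas), ref, aligned_rt_min=25.0)
        assert det.detected and det.nsa > 0.99 and not det.reasons

    def test_nsa_gate_fails_alone(self):
        ref = _reference()
        # scramble the pattern: detected transitions but wrong relative shape
        areas = {a: 1000.0 if i % 2 else 1.0 for i, (a, _, _) in enumerate(ref.transitions)}
        det = call_detection(_integration(areas), ref, aligned_rt_min=25.0)
        assert not det.detected
        assert "nsa_below_threshold" in det.reasons
        assert "too_few_transitions" not in det.reasons

    def test_transition_count_gate_fails_alone(self):
        ref = _reference()
        # perfect pattern but only 4 transitions detected
        areas = {a: rel * 1000 for a, _, rel in ref.transitions[:4]}
        det = call_detection(_integration(areas), ref, aligned_rt_min=25.0)
        assert not det.detected
        assert "too_few_transitions" in det.reasons
        assert det.n_detected == 4

    def test_rt_gate_fails_alone(self):
        ref = _reference()
        areas = {a: rel * 1000 for a, _, rel in ref.transitions}
        det = call_detection(_integration(areas), ref, aligned_rt_min=28.0)
        assert not det.detected
        assert det.reasons == ["rt_mismatch"]

    def test_weak_peak_scored_on_at_least_top_five(self):
        ref = _reference(12)
        areas = {a: rel * 1000 for a, _, rel in ref.transitions[:6]}
        det = call_detection(_integration(areas), ref, aligned_rt_min=25.0)
        assert det.n_scored == 6  # max(5, detected among top 12)

    def test_library_needs_five_transitions(self):
        pep = LabeledPeptide("RIAESLPVV")
        target = TargetRecord(pep, 2, precursor_mz(pep, 2))
        with pytest.raises(ValueError):
            ReferenceSpectrum(target, [("y4+", 400.0, 1.0)], 25.0)


class TestXicExtraction:
    def _run_with_peak(self, mz_values, target, times=None):
        times = times or [24.0, 24.5, 25.0]
        spectra = [
            CentroidSpectrum(
                i, t, 2,
                np.array(sorted(mz_values)), np.full(len(mz_values), 100.0),
                precursor_mz=target.precursor_mz,
                isolation_halfwidth=target.isolation_halfwidth,
            )
            for i, t in enumerate(times)
        ]
        return Run(spectra, acquisition_type="LC-PRM")

    def test_trace_follows_scan_order(self):
        ref = _reference()
        target = ref.target
        run = self._run_with_peak([310.0], target)
        xics = extract_xics(run, target, ref, rt_center_min=24.5, rt_halfwindow_min=1.5)
        y1 = next(x for x in xics if x.annotation == "y1+")
        np.testing.assert_array_equal(y1.intensity, [100.0, 100.0, 100.0])

    def test_boundary_peak_at_plus_7ppm_included(self):
        ref = _reference()
        target = ref.target
        from prmkit.chem import mz_tolerance_window

        mz = mz_tolerance_window(310.0, 7).upper  # exactly +7 ppm
        run = self._run_with_peak([mz], target)
        xics = extract_xics(run, target, ref, rt_center_min=24.5)
        y1 = next(x for x in xics if x.annotation == "y1+")
        assert y1.intensity.sum() == pytest.approx(300.0)

    def test_scans_outside_rt_window_excluded(self):
        ref = _reference()
        target = ref.target
        run = self._run_with_peak([310.0], target, times=[10.0, 24.9, 25.1])
        xics = extract_xics(run, target, ref, rt_center_min=25.0, rt_halfwindow_min=0.5)
        assert xics[0].time_min.size == 2

    def test_no_matching_scans_gives_empty_flagged_result(self):
        ref = _reference()
        target = ref.target
        run = Run([], acquisition_type="LC-PRM")
        xics = extract_xics(run, target, ref, rt_center_min=25.0)
        integ = integrate_peak(xics)
        assert integ.empty


class TestEndToEndSimulated:
    def test_spiked_target_detected_decoy_and_blank_clean(self, rng):
        anchor_rts = [10.0, 20.0, 30.0, 40.0]
        anchor_specs = [
            make_prm_target(random_peptide(rng, (9, 12), (0, 0)), 2, rt, rng)
            for rt in anchor_rts
        ]
        spec = make_prm_target(random_peptide(rng, (8, 11), (1, 1)), 2, 25.0, rng)
        decoy_pep = random_peptide(rng, (8, 11), (1, 1))
        decoy = TargetRecord(decoy_pep, 2, precursor_mz(decoy_pep, 2),
                             isolation_halfwidth=0.5, expected_rt_min=18.0)
        run, anchors, truth = simulate_prm_run(
            [spec], decoys=[decoy], anchor_rts_min=anchor_rts,
            anchor_specs=anchor_specs, rt_shift_min=1.0,
            noise=NoiseModel(cv=0.15), seed=4,
        )
        ref = reference_from_pattern(spec)
        det = score_target(run, spec.target, ref, anchors)
        assert det.detected and det.nsa >= 0.85 and det.n_detected >= 5

        decoy_ref = ReferenceSpectrum(
            decoy, [(f"y{i}+", 350.0 + 7 * i, 1.0 - 0.05 * i) for i in range(8)],
            reference_rt_min=18.0,
        )
        decoy_det = score_target(run, decoy, decoy_ref, anchors)
        assert not decoy_det.detected

        blank, blank_anchors, _ = simulate_prm_run(
            [], decoys=[spec.target], anchor_rts_min=anchor_rts,
            anchor_specs=anchor_specs, noise=NoiseModel(cv=0.15), seed=5,
        )
        blank_det = score_target(blank, spec.target, ref, blank_anchors)
        assert not blank_det.detected

    def test_global_rt_shift_recovered_by_alignment(self, rng):
        anchor_rts = [10.0, 20.0, 30.0, 40.0]
        anchor_specs = [
            make_prm_target(random_peptide(rng, (9, 12), (0, 0)), 2, rt, rng)
            for rt in anchor_rts
        ]
        spec = make_prm_target(random_peptide(rng, (8, 11), (1, 1)), 2, 26.0, rng)
        run, anchors, _ = simulate_prm_run(
            [spec], anchor_rts_min=anchor_rts, anchor_specs=anchor_specs,
            rt_shift_min=2.0, noise=NoiseModel(cv=0.05), seed=6,
        )
        ref = reference_from_pattern(spec)
        det = score_target(run, spec.target, ref, anchors)
        assert det.detected
        assert det.delta_rt_min <= 0.1

    def test_quantity_scales_linearly_with_spike_level(self, rng):
        pep = random_peptide(rng, (9, 11), (1, 1))
        anchor_rts = [10.0, 40.0]
        levels = [0.01, 0.03, 0.1, 0.3, 1.0]
        quantities = []
        base = make_prm_target(pep, 2, 25.0, rng)
        for level in levels:
            spec = make_prm_target(pep, 2, 25.0, rng)
            spec.pattern = base.pattern
            spec.elution.spike_level = level
            run, anchors, _ = simulate_prm_run(
                [spec], anchor_rts_min=anchor_rts,
                anchor_specs=[
                    make_prm_target(random_peptide(rng, (9, 12), (0, 0)), 2, rt, rng)
                    for rt in anchor_rts
                ],
                noise=NoiseModel(cv=0.0), seed=7,
            )
            det = score_target(run, spec.target, reference_from_pattern(spec), anchors)
            quantities.append(det.quantity)
        r = np.corrcoef(levels, quantities)[0, 1]
        assert r**2 >= 0.99
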