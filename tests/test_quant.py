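"""Doublet arithmetic, window building, peak integration, PSM quantitation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import (
    delete_peaks,
    make_doublet,
    noiseless_design,
    perturb_peaks,
    scale_run,
)
from xlinkquant.config import QuantConfig
from xlinkquant.ms_data import XICTrace
from xlinkquant.quant import (
    build_windows,
    integrate_peak,
    isotope_mz,
    isotope_targets,
    partner_mz,
    quantify_psm,
)
from xlinkquant.synth import simulate_run


# --- m/z arithmetic ------------------------------------------------------

@pytest.mark.parametrize(
    ("mz", "charge", "k", "expected"),
    [
        (500.0, 1, 0, 500.0),
        (500.0, 2, 1, 500.5016774189),
        (400.0, 3, 3, 401.0033548378),
    ],
)
def test_isotope_mz(mz, charge, k, expected):
    assert isotope_mz(mz, charge, k) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize(
    ("mz", "charge", "count", "state", "expected"),
    [
        (500.0, 2, 1, "light", 502.0125550),
        (502.0125550, 2, 1, "heavy", 500.0),
        (600.0, 3, 2, "light", 602.6834067),
    ],
)
def test_partner_mz(mz, charge, count, state, expected):
    assert partner_mz(mz, charge, 4.0251100, count, state) == \
        pytest.approx(expected, abs=1e-7)


def test_partner_mz_involution():
    forward = partner_mz(731.25, 4, 4.0251056, 2, "light")
    assert partner_mz(forward, 4, 4.0251056, 2, "heavy") == pytest.approx(731.25)


def test_partner_mz_rejects_corrupt_heavy():
    with pytest.raises(ValueError, match="corrupt"):
        partner_mz(1.0, 1, 4.0251056, 1, "heavy")


def test_isotope_targets_spacing_and_label_offset():
    from xlinkquant.idlist import PSMRecord

    psm = PSMRecord("r", 1, 800.0, 3, 4.0251056, 2, "light", 60.0, "S", "p")
    targets = isotope_targets(psm)
    spacing = np.diff(targets.light_mz)
    np.testing.assert_allclose(spacing, 1.0033548378 / 3, rtol=1e-12)
    offsets = np.subtract(targets.heavy_mz, targets.light_mz)
    np.testing.assert_allclose(offsets, 2 * 4.0251056 / 3, rtol=1e-12)
    assert targets.used_indices == (1, 2, 3)


# --- window rule ---------------------------------------------------------

def test_build_windows_extension_rule():
    # identified light: heavy window extended towards earlier elution
    win = build_windows(1000.0, 60.0, "light", 30.0)
    assert win.light == (940.0, 1060.0)
    assert win.heavy == (910.0, 1060.0)
    # identified heavy: light window extended towards later elution
    win = build_windows(1000.0, 60.0, "heavy", 30.0)
    assert win.heavy == (940.0, 1060.0)
    assert win.light == (940.0, 1090.0)
    # no extension: both windows identical
    win = build_windows(1000.0, 60.0, "light", 0.0)
    assert win.light == win.heavy


# --- peak integration ----------------------------------------------------

def _trace(intensities, rts=None):
    inten = np.asarray(intensities, dtype=float)
    rt = np.arange(len(inten), dtype=float) if rts is None else np.asarray(rts, float)
    return XICTrace(500.0, 6.0, rt, inten)


def test_integrate_peak_hand_cases():
    # all points above 10% of the apex: window-limited, both sides truncated
    peak = integrate_peak(_trace([1, 5, 10, 5, 1]))
    assert peak.apex_rt == 2.0 and peak.apex_intensity == 10.0
    assert peak.area == pytest.approx(21.0)  # 3 + 7.5 + 7.5 + 3
    assert peak.truncated_left and peak.truncated_right
    # boundary points below threshold excluded, no truncation
    peak = integrate_peak(_trace([0, 2, 10, 2, 0]))
    assert (peak.left_rt, peak.right_rt) == (1.0, 3.0)
    assert peak.area == pytest.approx(12.0)  # 6 + 6
    assert not (peak.truncated_left or peak.truncated_right)


def test_integrate_peak_degenerate_and_ties():
    assert integrate_peak(_trace([0, 0, 0])) is None
    assert integrate_peak(XICTrace(500.0, 6.0, np.empty(0), np.empty(0))) is None
    # equal apex intensities: earliest rt wins
    peak = integrate_peak(_trace([0, 10, 0, 10, 0]))
    assert peak.apex_rt == 1.0


def _oracle_integral(rt, inten, boundary_fraction):
    """Independent re-statement: scan outward from the first maximum and
    integrate with the textbook trapezoid sum."""
    apex = int(np.argmax(inten))
    threshold = boundary_fraction * inten[apex]
    left = apex
    while left - 1 >= 0 and inten[left - 1] >= threshold:
        left -= 1
    right = apex
    while right + 1 < len(inten) and inten[right + 1] >= threshold:
        right += 1
    area = 0.0
    for i in range(left, right):
        area += 0.5 * (inten[i] + inten[i + 1]) * (rt[i + 1] - rt[i])
    return area, left == 0, right == len(inten) - 1


@settings(max_examples=150, derandomize=True, deadline=None)
@given(
    data=st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=1, max_size=40),
    fraction=st.floats(min_value=0.01, max_value=0.9),
)
def test_integrate_peak_matches_trapezoid_oracle(data, fraction):
    inten = np.asarray(data)
    rt = np.cumsum(np.ones_like(inten)) * 1.7
    peak = integrate_peak(XICTrace(500.0, 6.0, rt, inten), None, fraction)
    if inten.max() <= 0:
        assert peak is None
        return
    area, trunc_l, trunc_r = _oracle_integral(rt, inten, fraction)
    assert peak.area == pytest.approx(area, rel=1e-12, abs=1e-12)
    assert peak.truncated_left == trunc_l
    assert peak.truncated_right == trunc_r


# --- PSM quantitation ----------------------------------------------------

def _quantify_single(design, config=None):
    run, _, ids = simulate_run(design)
    return quantify_psm(run, ids.records[0], config), run, ids


def test_noiseless_ratio_recovery():
    """A clean 2:1 doublet with identical elution shapes gives exactly 2."""
    quant, _, _ = _quantify_single(noiseless_design([make_doublet(2.0)]))
    assert quant.ratio_hl == pytest.approx(2.0, rel=1e-6)
    assert not quant.flags


def test_shift_invariance_with_extension():
    """Heavy eluting 20 s earlier changes nothing once the window covers it."""
    design = noiseless_design([make_doublet(2.0, heavy_rt_shift=-20.0)])
    quant, _, _ = _quantify_single(design)  # default extension = quant_window
    assert quant.ratio_hl == pytest.approx(2.0, rel=1e-6)


def test_missing_light_partner_flagged():
    design = noiseless_design([make_doublet(2.0)])
    run, _, ids = simulate_run(design)
    psm = ids.records[0]
    targets = isotope_targets(psm)
    crippled = delete_peaks(run, list(targets.light_mz), 20.0)
    quant = quantify_psm(crippled, psm)
    assert quant.heavy_area > 0
    assert quant.light_area == 0.0
    assert "light_missing" in quant.flags
    assert quant.ratio_hl is None


def test_missing_ms2_header_is_per_psm_error():
    design = noiseless_design([make_doublet(2.0)])
    run, _, ids = simulate_run(design)
    run.ms2_headers.clear()
    quant = quantify_psm(run, ids.records[0])
    assert "ms2_missing" in quant.flags
    assert quant.ratio_hl is None


def test_monoisotopic_peaks_are_ignored():
    """Scaling isotope-0 peaks of either partner never changes the ratio."""
    design = noiseless_design([make_doublet(3.0, heavy_rt_shift=-10.0)])
    run, _, ids = simulate_run(design)
    psm = ids.records[0]
    reference = quantify_psm(run, psm).ratio_hl
    targets = isotope_targets(psm)
    for mono in ([targets.light_mz[0]], [targets.heavy_mz[0]],
                 [targets.light_mz[0], targets.heavy_mz[0]]):
        perturbed = perturb_peaks(run, mono, 6.0, 25.0)
        assert quantify_psm(perturbed, psm).ratio_hl == \
            pytest.approx(reference, rel=1e-9)


def test_scale_invariance():
    design = noiseless_design([make_doublet(0.5)])
    run, _, ids = simulate_run(design)
    psm = ids.records[0]
    reference = quantify_psm(run, psm).ratio_hl
    assert quantify_psm(scale_run(run, 137.5), psm).ratio_hl == \
        pytest.approx(reference, rel=1e-12)


def test_label_swap_reciprocity():
    """Exchanging the partners' abundances maps every ratio r to 1/r."""
    rng = np.random.default_rng(11)
    for _ in range(5):
        ratio = float(rng.uniform(0.2, 5.0))
        shift = float(2.0 * rng.integers(-10, 1))
        mass = float(rng.uniform(1600, 4500))
        forward = noiseless_design(
            [make_doublet(ratio, heavy_rt_shift=shift, peptide_mass=mass)])
        swapped = noiseless_design(
            [make_doublet(1.0 / ratio, heavy_rt_shift=shift, peptide_mass=mass)])
        q_fwd, _, _ = _quantify_single(forward)
        q_swp, _, _ = _quantify_single(swapped)
        assert q_swp.ratio_hl == pytest.approx(1.0 / q_fwd.ratio_hl, rel=1e-9)


def test_per_isotope_apex_mode_agrees_on_clean_data():
    design = noiseless_design([make_doublet(2.0)])
    run, _, ids = simulate_run(design)
    psm = ids.records[0]
    summed = quantify_psm(run, psm, QuantConfig(apex_mode="summed"))
    split = quantify_psm(run, psm, QuantConfig(apex_mode="per_isotope"))
    assert split.ratio_hl == pytest.approx(summed.ratio_hl, rel=1e-9)


def test_noisy_median_recovery():
    """With default noise, the median log2 error stays small over 50 doublets."""
    from xlinkquant.quant import quantify_run
    from xlinkquant.synth import default_design

    design = default_design(n_doublets=50, true_ratio_hl=2.0, seed=5)
    run, _, ids = simulate_run(design)
    quants = quantify_run(run, ids)
    logs = [q.log2_ratio_hl for q in quants.values() if q.ratio_hl is not None]
    assert len(logs) >= 45
    assert abs(float(np.median(logs)) - 1.0) < 0.1
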