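"""Doublet quantitation: the core algorithm.

For each identified cross-linked PSM the light and heavy partner of the
isotope-coded doublet are located from the precursor m/z and the label
arithmetic, an integration window is anchored on the elution time of the
identifying MS2 event (and extended on one side to absorb the deuterium
retention-time shift), the extracted ion chromatograms of isotope peaks
1-3 of each partner are integrated around a shared elution apex with a
10%-of-apex boundary rule, and the ratio is defined as heavy area divided
by light area.  The monoisotopic peak (isotope 0) is excluded: at a ~4 Da
label spacing the heavy monoisotopic peak can overlap the tail of the
light isotope cluster, and for peptide-pair masses the monoisotopic peak
is small anyway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ISOTOPE_SPACING, QuantConfig
from .idlist import IDList, PSMRecord
from .ms_data import MSRun, XICTrace, get_xic

#: Isotope peaks that enter the areas (monoisotopic peak 0 is ignored).
USED_ISOTOPE_INDICES = (1, 2, 3)


@dataclass(frozen=True)
class IsotopeTargets:
    """Expected m/z of isotope peaks 0..3 for both doublet partners."""

    light_mz: tuple[float, float, float, float]
    heavy_mz: tuple[float, float, float, float]
    used_indices: tuple[int, ...] = USED_ISOTOPE_INDICES


@dataclass(frozen=True)
class QuantWindow:
    """Retention-time integration window per partner, seconds."""

    light: tuple[float, float]
    heavy: tuple[float, float]


@dataclass(frozen=True)
class ElutionPeak:
    """One integrated chromatographic peak."""

    apex_rt: float
    apex_intensity: float
    left_rt: float
    right_rt: float
    area: float  # intensity * seconds (trapezoid)
    truncated_left: bool = False
    truncated_right: bool = False

    @property
    def truncated(self) -> bool:
        return self.truncated_left or self.truncated_right


@dataclass
class DoubletQuant:
    """Per-PSM quantitation result.

    ``ratio_hl`` is heavy_area / light_area, defined only when both areas
    are positive; otherwise it is ``None`` and a ``*_missing`` flag names
    the absent partner (never 0 or infinity).
    """

    psm_id: str
    light_area: float = 0.0
    heavy_area: float = 0.0
    flags: set[str] = field(default_factory=set)
    light_peak: ElutionPeak | None = None
    heavy_peak: ElutionPeak | None = None

    @property
    def ratio_hl(self) -> float | None:
        if self.light_area > 0 and self.heavy_area > 0:
            return self.heavy_area / self.light_area
        return None

    @property
    def log2_ratio_hl(self) -> float | None:
        ratio = self.ratio_hl
        return None if ratio is None else math.log2(ratio)


def isotope_mz(
    precursor_mz: float, charge: int, k: int, spacing: float = ISOTOPE_SPACING
) -> float:
    """m/z of the k-th isotope peak of an ion at ``precursor_mz``."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if not 0 <= k <= 3:
        raise ValueError("isotope index must be in 0..3")
    return precursor_mz + k * spacing / charge


def partner_mz(
    precursor_mz: float,
    charge: int,
    label_mass: float,
    label_count: int,
    label_state: str,
) -> float:
    """m/z of the other doublet partner.

    A light precursor's partner is heavier by label_count * label_mass /
    charge; a heavy precursor's partner is lighter by the same amount.
    """
    if label_mass <= 0 or label_count < 1:
        raise ValueError("label_mass must be positive and label_count >= 1")
    shift = label_count * label_mass / charge
    if label_state == "light":
        return precursor_mz + shift
    if label_state == "heavy":
        result = precursor_mz - shift
        if result <= 0:
            raise ValueError("heavy precursor lighter than its label shift (corrupt record)")
        return result
    raise ValueError(f"unknown label_state {label_state!r}")


def isotope_targets(psm: PSMRecord, config: QuantConfig | None = None) -> IsotopeTargets:
    """Expected isotope-peak m/z values (0..3) of both doublet partners."""
    config = config or QuantConfig()
    other = partner_mz(
        psm.precursor_mz, psm.charge, psm.label_mass, psm.label_count, psm.label_state
    )
    if psm.label_state == "light":
        light0, heavy0 = psm.precursor_mz, other
    else:
        light0, heavy0 = other, psm.precursor_mz
    spacing = config.isotope_spacing_da
    light = tuple(isotope_mz(light0, psm.charge, k, spacing) for k in range(4))
    heavy = tuple(isotope_mz(heavy0, psm.charge, k, spacing) for k in range(4))
    return IsotopeTargets(light, heavy)  # type: ignore[arg-type]


def build_windows(
    ms2_rt: float, quant_window: float, label_state: str, extension: float
) -> QuantWindow:
    """Integration windows for both partners, anchored on the MS2 time.

    Both partners get the base window [ms2_rt - quant_window, ms2_rt +
    quant_window].  Deuterated peptides tend to elute earlier on reversed
    phase, so when the identified precursor is the light partner the heavy
    window is extended towards earlier times, and when it is the heavy
    partner the light window is extended towards later times.
    """
    if quant_window <= 0:
        raise ValueError("quant_window must be positive")
    if extension < 0:
        raise ValueError("extension must be >= 0")
    base = (ms2_rt - quant_window, ms2_rt + quant_window)
    if label_state == "light":
        return QuantWindow(light=base, heavy=(base[0] - extension, base[1]))
    if label_state == "heavy":
        return QuantWindow(light=(base[0], base[1] + extension), heavy=base)
    raise ValueError(f"unknown label_state {label_state!r}")


def integrate_peak(
    trace: XICTrace,
    window: tuple[float, float] | None = None,
    boundary_fraction: float = 0.10,
) -> ElutionPeak | None:
    """Integrate the elution peak around the most intense point.

    The apex is the highest-intensity point inside the window (earliest rt
    wins ties).  Boundaries extend from the apex in both directions over
    the contiguous run of points with intensity >= boundary_fraction *
    apex_intensity; the first point below that threshold is excluded.  The
    area is the trapezoidal integral between the boundaries.  A boundary
    that reaches the end of the windowed trace without dropping below the
    threshold sets the corresponding ``truncated`` flag.  Returns ``None``
    for an empty trace or an all-zero window.
    """
    if not 0.0 < boundary_fraction < 1.0:
        raise ValueError("boundary_fraction must lie in (0, 1)")
    if trace.is_empty:
        return None
    rt, inten = trace.rt, trace.intensity
    if window is not None:
        lo, hi = window
        mask = (rt >= lo) & (rt <= hi)
        rt, inten = rt[mask], inten[mask]
        if rt.size == 0:
            return None
    apex_idx = int(np.argmax(inten))  # argmax returns the first (earliest) maximum
    apex = float(inten[apex_idx])
    if apex <= 0:
        return None
    threshold = boundary_fraction * apex

    left = apex_idx
    while left > 0 and inten[left - 1] >= threshold:
        left -= 1
    right = apex_idx
    while right < inten.size - 1 and inten[right + 1] >= threshold:
        right += 1

    area = float(np.trapezoid(inten[left : right + 1], rt[left : right + 1]))
    return ElutionPeak(
        apex_rt=float(rt[apex_idx]),
        apex_intensity=apex,
        left_rt=float(rt[left]),
        right_rt=float(rt[right]),
        area=area,
        truncated_left=(left == 0),
        truncated_right=(right == inten.size - 1),
    )


def _summed_trace(traces: list[XICTrace]) -> XICTrace:
    """Pointwise sum of traces sharing one rt grid."""
    base = traces[0]
    total = np.zeros_like(base.intensity)
    for t in traces:
        total += t.intensity
    return XICTrace(base.target_mz, base.tolerance_ppm, base.rt, total)


def _partner_area(
    run: MSRun,
    target_mzs: tuple[float, ...],
    window: tuple[float, float],
    config: QuantConfig,
) -> tuple[float, ElutionPeak | None, bool]:
    """Integrated area of one partner over isotope peaks 1-3.

    Returns (area, representative peak, truncated).  In ``summed`` mode
    the apex is located on the summed isotope-1..3 trace and that trace is
    integrated; in ``per_isotope`` mode each trace is integrated around
    its own apex and the areas are summed.
    """
    traces = [
        get_xic(run, target_mzs[k], config.tolerance_ppm, window[0], window[1],
                combine=config.xic_combine)
        for k in USED_ISOTOPE_INDICES
    ]
    if traces[0].is_empty:
        return 0.0, None, False
    if config.apex_mode == "summed":
        peak = integrate_peak(_summed_trace(traces), None, config.boundary_fraction)
        if peak is None:
            return 0.0, None, False
        return peak.area, peak, peak.truncated
    area = 0.0
    best: ElutionPeak | None = None
    truncated = False
    for trace in traces:
        peak = integrate_peak(trace, None, config.boundary_fraction)
        if peak is None:
            continue
        area += peak.area
        truncated = truncated or peak.truncated
        if best is None or peak.apex_intensity > best.apex_intensity:
            best = peak
    return area, best, truncated


def quantify_psm(run: MSRun, psm: PSMRecord, config: QuantConfig | None = None) -> DoubletQuant:
    """Quantify one PSM's light/heavy doublet in its run."""
    config = config or QuantConfig()
    result = DoubletQuant(psm_id=psm.psm_id)

    header = run.ms2_headers.get(psm.ms2_scan)
    if header is None:
        result.flags.add("ms2_missing")
        return result

    extension = (
        psm.quant_window if config.extension_seconds is None else config.extension_seconds
    )
    windows = build_windows(header.rt, psm.quant_window, psm.label_state, extension)
    targets = isotope_targets(psm, config)

    light_area, light_peak, light_trunc = _partner_area(
        run, targets.light_mz, windows.light, config
    )
    heavy_area, heavy_peak, heavy_trunc = _partner_area(
        run, targets.heavy_mz, windows.heavy, config
    )
    result.light_area = light_area
    result.heavy_area = heavy_area
    result.light_peak = light_peak
    result.heavy_peak = heavy_peak

    if light_area == 0.0:
        result.flags.add("light_missing")
    if heavy_area == 0.0:
        result.flags.add("heavy_missing")
    if light_trunc or heavy_trunc:
        result.flags.add("truncated")
    if config.min_apex_intensity > 0:
        for peak in (light_peak, heavy_peak):
            if peak is not None and peak.apex_intensity < config.min_apex_intensity:
                result.flags.add("low_snr")
    return result


def quantify_run(
    run: MSRun, idlist: IDList, config: QuantConfig | None = None
) -> dict[str, DoubletQuant]:
    """Quantify every PSM of ``idlist`` that belongs to ``run``.

    PSMs naming a different raw file are skipped; per-PSM failures are
    recorded as flags, never raised, so one bad record cannot abort a run.
    """
    config = config or QuantConfig()
    results: dict[str, DoubletQuant] = {}
    for psm in idlist.records:
        if psm.raw_file != run.run_name:
            continue
        results[psm.psm_id] = quantify_psm(run, psm, config)
    return results
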