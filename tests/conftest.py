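"""Shared builders for synthetic runs used across the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from xlinkquant.ms_data import MS1Scan, MS2Header, MSRun
from xlinkquant.synth import SimDesign, SimDoublet


def make_doublet(
    true_ratio_hl: float = 2.0,
    heavy_rt_shift: float = 0.0,
    peptide_mass: float = 2400.0,
    charge: int = 3,
    apex_rt: float = 300.0,
    peak_sigma: float = 6.0,
    abundance: float = 1.0e6,
    label_count: int = 1,
    site_key: str = "SITE_A",
) -> SimDoublet:
    return SimDoublet(
        peptide_mass=peptide_mass,
        charge=charge,
        true_ratio_hl=true_ratio_hl,
        apex_rt=apex_rt,
        peak_sigma=peak_sigma,
        heavy_rt_shift=heavy_rt_shift,
        abundance=abundance,
        label_count=label_count,
        site_key=site_key,
    )


def noiseless_design(doublets, rt_span: float = 600.0, seed: int = 0, **kw) -> SimDesign:
    """A deterministic, noise-free design: exact ground truth."""
    return SimDesign(
        doublets=tuple(doublets),
        rt_span=rt_span,
        scan_interval=2.0,
        noise_floor=0.0,
        chemical_noise_density=0.0,
        mz_jitter_ppm=0.0,
        intensity_cv=0.0,
        seed=seed,
        n_isotope_peaks=4,
        **kw,
    )


def make_simple_run(scans: list[tuple[float, list[tuple[float, float]]]],
                    name: str = "simple") -> MSRun:
    """Build an MSRun from [(rt, [(mz, intensity), ...]), ...]."""
    ms1 = []
    for i, (rt, peaks) in enumerate(scans, start=1):
        mz = np.array([p[0] for p in peaks])
        inten = np.array([p[1] for p in peaks])
        ms1.append(MS1Scan(i, rt, mz, inten))
    return MSRun(name, ms1)


@pytest.fixture
def simple_run() -> MSRun:
    return make_simple_run(
        [
            (10.0, [(500.0, 100.0), (600.0, 10.0)]),
            (20.0, [(500.0, 200.0)]),
            (30.0, [(500.000001, 150.0), (500.0000005, 50.0)]),
            (40.0, []),
        ]
    )


def perturb_peaks(run: MSRun, targets: list[float], tolerance_ppm: float,
                  factor: float) -> MSRun:
    """Scale every peak within tolerance of any target m/z by ``factor``."""
    new_scans = []
    for scan in run.ms1_scans:
        inten = scan.intensity.copy()
        for target in targets:
            delta = target * tolerance_ppm * 1e-6
            mask = np.abs(scan.mz - target) <= delta
            inten[mask] *= factor
        new_scans.append(MS1Scan(scan.scan_number, scan.rt, scan.mz.copy(), inten))
    return MSRun(run.run_name, new_scans, dict(run.ms2_headers))


def scale_run(run: MSRun, factor: float) -> MSRun:
    new_scans = [
        MS1Scan(s.scan_number, s.rt, s.mz.copy(), s.intensity * factor)
        for s in run.ms1_scans
    ]
    return MSRun(run.run_name, new_scans, dict(run.ms2_headers))


def delete_peaks(run: MSRun, targets: list[float], tolerance_ppm: float) -> MSRun:
    """Remove every peak within tolerance of any target m/z."""
    new_scans = []
    for scan in run.ms1_scans:
        keep = np.ones(scan.mz.size, dtype=bool)
        for target in targets:
            delta = target * tolerance_ppm * 1e-6
            keep &= np.abs(scan.mz - target) > delta
        new_scans.append(MS1Scan(scan.scan_number, scan.rt, scan.mz[keep],
                                 scan.intensity[keep]))
    return MSRun(run.run_name, new_scans, dict(run.ms2_headers))
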