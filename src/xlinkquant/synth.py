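"""Synthetic LC-MS1 runs of cross-linked-peptide doublets with known truth.

Emulates the benchmark design the quantitation is meant for: tryptic
cross-linked peptide pairs carrying a d0/d4-coded cross-linker, measured
at heavy:light mixing ratios such as 1:1, 1:2 and 1:4 in triplicate.
Each doublet contributes two isotope clusters (averagine envelopes) with
Gaussian elution profiles; the heavy partner is scaled by the true ratio
and shifted to earlier retention times (the deuterium isotope effect).
Noise comprises multiplicative log-normal intensity scatter, m/z jitter,
and uniform chemical-noise peaks.  Everything is driven by one seed, so
runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import _mzml
from .config import DEFAULT_LABEL_MASS, ISOTOPE_SPACING
from .idlist import IDList, PSMRecord
from .ms_data import MS1Scan, MS2Header, MSRun

PROTON_MASS = 1.00727646677

# Averagine residue: average elemental composition per 111.1254 Da of peptide.
_AVERAGINE_MASS = 111.1254
_AVERAGINE = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}

# Natural isotope abundances per nominal mass offset.
_ELEMENT_ISOTOPES = {
    "C": np.array([0.9893, 0.0107]),
    "H": np.array([0.999885, 0.000115]),
    "N": np.array([0.99636, 0.00364]),
    "O": np.array([0.99757, 0.00038, 0.00205]),
    "S": np.array([0.9499, 0.0075, 0.0425, 0.0001]),
}


def isotope_envelope(neutral_mass: float, n_peaks: int = 4) -> np.ndarray:
    """Relative isotope abundances 0..n_peaks-1 of an averagine peptide.

    The elemental composition is scaled from the averagine residue to the
    requested mass and the elemental isotope distributions are convolved
    (exponentiation by squaring, truncated to ``n_peaks`` terms).  The
    result is normalised to sum to 1.  For peptide-pair masses (above
    roughly 1800 Da) the monoisotopic peak is no longer the most abundant
    one — the reason it is excluded from quantitation.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    if n_peaks < 4:
        raise ValueError("n_peaks must be >= 4")
    scale = neutral_mass / _AVERAGINE_MASS
    dist = np.array([1.0])
    for element, per_residue in _AVERAGINE.items():
        count = int(round(per_residue * scale))
        if count <= 0:
            continue
        base = _ELEMENT_ISOTOPES[element]
        power = np.array([1.0])
        n = count
        while n:
            if n & 1:
                power = np.convolve(power, base)[:n_peaks]
            base = np.convolve(base, base)[:n_peaks]
            n >>= 1
        dist = np.convolve(dist, power)[:n_peaks]
    if dist.size < n_peaks:
        dist = np.pad(dist, (0, n_peaks - dist.size))
    return dist / dist.sum()


@dataclass(frozen=True)
class SimDoublet:
    """Ground truth for one simulated cross-linked peptide doublet."""

    peptide_mass: float  # neutral mass of the cross-linked pair, Da
    charge: int
    true_ratio_hl: float
    apex_rt: float  # light-partner elution apex, seconds
    peak_sigma: float  # Gaussian elution width, seconds
    heavy_rt_shift: float  # heavy apex minus light apex (negative = earlier)
    abundance: float  # light-partner apex intensity before the envelope
    label_count: int = 1
    site_key: str = ""

    def __post_init__(self) -> None:
        if self.true_ratio_hl <= 0:
            raise ValueError("true_ratio_hl must be positive")
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be positive")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")

    @property
    def light_mz(self) -> float:
        return (self.peptide_mass + self.charge * PROTON_MASS) / self.charge

    def heavy_mz(self, label_mass: float) -> float:
        return self.light_mz + self.label_count * label_mass / self.charge


@dataclass(frozen=True)
class SimDesign:
    """Full description of one simulated run; the seed drives all noise."""

    doublets: tuple[SimDoublet, ...]
    rt_span: float = 900.0  # seconds
    scan_interval: float = 2.0  # seconds between MS1 scans
    noise_floor: float = 30.0  # chemical-noise intensity scale
    chemical_noise_density: float = 5.0  # peaks per scan per 100 Th
    mz_jitter_ppm: float = 2.0
    intensity_cv: float = 0.15
    seed: int = 0
    run_name: str = "sim_run"
    label_mass: float = DEFAULT_LABEL_MASS
    quant_window: float = 60.0  # ID-list window half-width, seconds
    mz_range: tuple[float, float] = (300.0, 1800.0)
    n_isotope_peaks: int = 6

    def __post_init__(self) -> None:
        if self.scan_interval <= 0:
            raise ValueError("scan_interval must be positive")


def default_design(
    n_doublets: int = 50,
    true_ratio_hl: float = 1.0,
    seed: int = 0,
    noiseless: bool = False,
    heavy_rt_shift_mean: float = -15.0,
    heavy_rt_shift_sd: float = 5.0,
    run_name: str | None = None,
    **overrides,
) -> SimDesign:
    """Build a run design mimicking one benchmark acquisition.

    ``n_doublets`` doublets share one true heavy:light ratio (the mixing
    ratio of the run).  Peptide-pair masses are drawn uniformly from
    1500-5000 Da at charges 3-5 (1+ and 2+ precursors are excluded from
    acquisition), elution apexes spread over the gradient, and the heavy
    partner elutes ``heavy_rt_shift_mean`` +- sd seconds relative to the
    light one.  ``noiseless=True`` switches off every noise source and
    snaps retention-time shifts to the scan grid (exact ground truth).
    Two PSMs share each cross-link site so that site-level aggregation
    has real work to do.
    """
    rng = np.random.default_rng(seed)
    base = SimDesign(doublets=(), seed=seed,
                     run_name=run_name or f"sim_r{true_ratio_hl:g}_s{seed}")
    if noiseless:
        base = replace(base, noise_floor=0.0, chemical_noise_density=0.0,
                       mz_jitter_ppm=0.0, intensity_cv=0.0, n_isotope_peaks=4)
    base = replace(base, **overrides)

    margin = 80.0
    doublets = []
    for i in range(n_doublets):
        mass = float(rng.uniform(1500.0, 5000.0))
        charge = int(rng.choice([3, 4, 5], p=[0.45, 0.35, 0.20]))
        apex = float(rng.uniform(margin, base.rt_span - margin))
        sigma = float(rng.uniform(5.0, 8.0))
        shift = float(rng.normal(heavy_rt_shift_mean, heavy_rt_shift_sd))
        if noiseless:
            shift = round(shift / base.scan_interval) * base.scan_interval
        abundance = float(rng.lognormal(np.log(1.0e6), 0.5))
        doublets.append(
            SimDoublet(
                peptide_mass=mass,
                charge=charge,
                true_ratio_hl=true_ratio_hl,
                apex_rt=apex,
                peak_sigma=sigma,
                heavy_rt_shift=shift,
                abundance=abundance,
                label_count=1,
                site_key=f"SITE_{i // 2:03d}",
            )
        )
    return replace(base, doublets=tuple(doublets))


def simulate_run(design: SimDesign) -> tuple[MSRun, pd.DataFrame, IDList]:
    """Render a design into an MS run, a truth table, and an ID list.

    MS1 scans lie on the regular retention-time grid.  One MS2 header per
    doublet is placed just after the MS1 scan nearest the light apex,
    carrying the light precursor m/z (so every ID-list row is a
    light-state identification).  The truth table lists psm_id, site_key
    and true_ratio_hl.
    """
    rng = np.random.default_rng(design.seed)
    grid = np.arange(0.0, design.rt_span + 1e-9, design.scan_interval)
    n_scans = grid.size
    mz_acc: list[list[np.ndarray]] = [[] for _ in range(n_scans)]
    int_acc: list[list[np.ndarray]] = [[] for _ in range(n_scans)]

    sigma_ln = (
        float(np.sqrt(np.log1p(design.intensity_cv**2)))
        if design.intensity_cv > 0
        else 0.0
    )

    ms2_events: list[tuple[float, SimDoublet]] = []  # (rt, doublet)

    for d in design.doublets:
        if not 0.0 <= d.apex_rt <= design.rt_span:
            raise ValueError(
                f"doublet apex {d.apex_rt} s outside the run span 0..{design.rt_span} s"
            )
        envelope = isotope_envelope(d.peptide_mass, design.n_isotope_peaks)
        partners = (
            (d.light_mz, 1.0, d.apex_rt),
            (d.heavy_mz(design.label_mass), d.true_ratio_hl, d.apex_rt + d.heavy_rt_shift),
        )
        for mz0, ratio_scale, apex in partners:
            lo = int(np.searchsorted(grid, apex - 5.0 * d.peak_sigma, side="left"))
            hi = int(np.searchsorted(grid, apex + 5.0 * d.peak_sigma, side="right"))
            if hi <= lo:
                continue
            t = grid[lo:hi]
            profile = d.abundance * ratio_scale * np.exp(
                -((t - apex) ** 2) / (2.0 * d.peak_sigma**2)
            )
            for k in range(design.n_isotope_peaks):
                mz_k = mz0 + k * ISOTOPE_SPACING / d.charge
                inten = envelope[k] * profile
                if sigma_ln > 0:
                    inten = inten * np.exp(rng.normal(0.0, sigma_ln, inten.size))
                if design.mz_jitter_ppm > 0:
                    mzs = mz_k * (
                        1.0 + rng.normal(0.0, design.mz_jitter_ppm, inten.size) * 1e-6
                    )
                else:
                    mzs = np.full(inten.size, mz_k)
                for j, scan_idx in enumerate(range(lo, hi)):
                    mz_acc[scan_idx].append(mzs[j : j + 1])
                    int_acc[scan_idx].append(inten[j : j + 1])
        # MS2 event just after the MS1 scan nearest the light apex
        nearest = int(np.argmin(np.abs(grid - d.apex_rt)))
        ms2_events.append((grid[nearest] + 0.4 * design.scan_interval, d))

    if design.chemical_noise_density > 0 and design.noise_floor > 0:
        mz_lo, mz_hi = design.mz_range
        expected = design.chemical_noise_density * (mz_hi - mz_lo) / 100.0
        for scan_idx in range(n_scans):
            n = int(rng.poisson(expected))
            if n == 0:
                continue
            mz_acc[scan_idx].append(rng.uniform(mz_lo, mz_hi, n))
            int_acc[scan_idx].append(design.noise_floor * rng.exponential(1.0, n))

    ms1_scans: list[MS1Scan] = []
    events: list[tuple[float, str, object]] = [
        (float(grid[i]), "ms1", i) for i in range(n_scans)
    ]
    events.extend((rt, "ms2", d) for rt, d in ms2_events)
    events.sort(key=lambda e: (e[0], e[1]))

    ms2_headers: dict[int, MS2Header] = {}
    records: list[PSMRecord] = []
    truth_rows: list[dict] = []
    psm_counter = 0
    for scan_number, (rt, kind, payload) in enumerate(events, start=1):
        if kind == "ms1":
            i = payload
            if mz_acc[i]:
                mz = np.concatenate(mz_acc[i])
                inten = np.concatenate(int_acc[i])
            else:
                mz = np.empty(0)
                inten = np.empty(0)
            ms1_scans.append(MS1Scan(scan_number, rt, mz, inten))
        else:
            d: SimDoublet = payload
            ms2_headers[scan_number] = MS2Header(scan_number, rt, d.light_mz, d.charge)
            psm_id = f"psm{psm_counter:04d}"
            psm_counter += 1
            records.append(
                PSMRecord(
                    raw_file=design.run_name,
                    ms2_scan=scan_number,
                    precursor_mz=d.light_mz,
                    charge=d.charge,
                    label_mass=design.label_mass,
                    label_count=d.label_count,
                    label_state="light",
                    quant_window=design.quant_window,
                    site_key=d.site_key or psm_id,
                    psm_id=psm_id,
                )
            )
            truth_rows.append(
                {
                    "psm_id": psm_id,
                    "site_key": d.site_key or psm_id,
                    "true_ratio_hl": d.true_ratio_hl,
                }
            )

    run = MSRun(design.run_name, ms1_scans, ms2_headers)
    truth = pd.DataFrame(truth_rows, columns=["psm_id", "site_key", "true_ratio_hl"])
    idlist = IDList(records, source_path=f"<simulated:{design.run_name}>")
    return run, truth, idlist


def write_run(run: MSRun, path: str | Path) -> None:
    """Write an MSRun as plain mzML (lossless for rt, m/z, intensity)."""
    spectra: list[_mzml.SpectrumRecord] = []
    for scan in run.ms1_scans:
        spectra.append(
            _mzml.SpectrumRecord(
                scan.scan_number, 1, scan.rt, scan.mz, scan.intensity, None, None, False
            )
        )
    empty = np.empty(0)
    for header in run.ms2_headers.values():
        spectra.append(
            _mzml.SpectrumRecord(
                header.scan_number, 2, header.rt, empty, empty,
                header.precursor_mz, header.charge, False,
            )
        )
    spectra.sort(key=lambda s: (s.rt, s.ms_level))
    _mzml.write_mzml(path, spectra, run.run_name)
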