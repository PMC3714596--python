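"""Data model for an LC-MS run and extracted ion chromatograms.

An :class:`MSRun` holds the centroided MS1 scans of one acquisition in
retention-time order plus the headers of all MS2 events (only the header
is needed: the quantitation anchors its time window on the elution time
recorded for the identifying MS2 scan).  :func:`get_xic` reads out the
extracted ion chromatogram of a narrow m/z window across the MS1 scans.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from . import _mzml


class CentroidPeak(NamedTuple):
    """One centroided peak: m/z in Th, intensity in detector counts."""

    mz: float
    intensity: float


@dataclass
class MS1Scan:
    """One centroided survey scan.

    ``mz`` is strictly ascending; peaks sharing an identical m/z are merged
    at construction time by summing their intensities.
    """

    scan_number: int
    rt: float  # seconds
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=np.float64)
        inten = np.asarray(self.intensity, dtype=np.float64)
        if mz.shape != inten.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if mz.size and np.any(mz <= 0):
            raise ValueError(f"scan {self.scan_number}: non-positive m/z")
        if mz.size and np.any(inten < 0):
            raise ValueError(f"scan {self.scan_number}: negative intensity")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if mz.size > 1:
            dup = np.diff(mz) == 0.0
            if dup.any():
                # merge exact m/z ties by intensity summation
                keep = np.concatenate(([True], ~dup))
                idx = np.cumsum(keep) - 1
                merged = np.zeros(int(keep.sum()))
                np.add.at(merged, idx, inten)
                mz, inten = mz[keep], merged
        self.mz, self.intensity = mz, inten

    @property
    def peaks(self) -> list[CentroidPeak]:
        return [CentroidPeak(m, i) for m, i in zip(self.mz, self.intensity)]


@dataclass(frozen=True)
class MS2Header:
    """Header of a fragmentation event; fragment peaks are not kept."""

    scan_number: int
    rt: float  # seconds
    precursor_mz: float
    charge: int | None


@dataclass
class MSRun:
    """One LC-MS acquisition: rt-ordered MS1 scans plus MS2 headers."""

    run_name: str
    ms1_scans: list[MS1Scan]
    ms2_headers: dict[int, MS2Header] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ms1_scans = sorted(self.ms1_scans, key=lambda s: s.rt)
        rts = [s.rt for s in self.ms1_scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError(f"run {self.run_name}: MS1 retention times not strictly increasing")
        seen: set[int] = set()
        for scan in self.ms1_scans:
            if scan.scan_number in seen:
                raise ValueError(f"run {self.run_name}: duplicate scan number {scan.scan_number}")
            seen.add(scan.scan_number)
        self._rt_index = np.asarray(rts)

    @property
    def rt_values(self) -> np.ndarray:
        return self._rt_index

    def scans_between(self, rt_lo: float, rt_hi: float) -> list[MS1Scan]:
        """MS1 scans with rt in the closed interval [rt_lo, rt_hi]."""
        lo = bisect.bisect_left(self._rt_index, rt_lo)
        hi = bisect.bisect_right(self._rt_index, rt_hi)
        return self.ms1_scans[lo:hi]


@dataclass
class XICTrace:
    """Intensity vs retention time for one target m/z.

    One point per MS1 scan in the requested window; scans without a
    matching peak contribute an explicit zero, never a gap.
    """

    target_mz: float
    tolerance_ppm: float
    rt: np.ndarray
    intensity: np.ndarray

    @property
    def is_empty(self) -> bool:
        return self.rt.size == 0

    def __len__(self) -> int:
        return int(self.rt.size)


def read_run(path: str | Path, run_name: str | None = None) -> MSRun:
    """Read a centroided mzML file into an :class:`MSRun`.

    Retention times are converted to seconds whatever unit the file
    declares.  Profile-mode MS1 spectra are refused: centroiding must
    happen upstream (msconvert-style conversion).  An MS2 spectrum with a
    missing precursor charge is kept (charge ``None``); it only becomes an
    error if a PSM later needs it.
    """
    path = Path(path)
    if run_name is None:
        run_name = path.name
        for suffix in (".mzML", ".mzml", ".MZML"):
            if run_name.endswith(suffix):
                run_name = run_name[: -len(suffix)]
                break
    ms1: list[MS1Scan] = []
    ms2: dict[int, MS2Header] = {}
    for rec in _mzml.iter_spectra(path):
        if rec.ms_level == 1:
            if rec.is_profile:
                raise _mzml.MzMLError(
                    f"{path}: MS1 scan {rec.scan_number} is profile mode; "
                    "centroid the data during conversion"
                )
            ms1.append(MS1Scan(rec.scan_number, rec.rt, rec.mz, rec.intensity))
        elif rec.ms_level == 2:
            if rec.precursor_mz is None:
                continue  # header useless without a precursor; skip
            ms2[rec.scan_number] = MS2Header(
                rec.scan_number, rec.rt, rec.precursor_mz, rec.charge
            )
    return MSRun(run_name, ms1, ms2)


def get_xic(
    run: MSRun,
    target_mz: float,
    tolerance_ppm: float,
    rt_lo: float,
    rt_hi: float,
    combine: str = "sum",
) -> XICTrace:
    """Extract the ion chromatogram of ``target_mz`` over [rt_lo, rt_hi].

    A centroid peak matches when ``|mz - target_mz| / target_mz`` is at
    most ``tolerance_ppm * 1e-6``.  Multiple matches in one scan are summed
    (``combine="sum"``) or reduced to the most intense (``combine="max"``).
    A window containing no MS1 scans yields an empty trace, not an error.
    """
    if rt_lo >= rt_hi:
        raise ValueError("rt_lo must be smaller than rt_hi")
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    if combine not in ("sum", "max"):
        raise ValueError(f"unknown combine mode {combine!r}")
    delta = target_mz * tolerance_ppm * 1e-6
    lo_mz, hi_mz = target_mz - delta, target_mz + delta
    scans = run.scans_between(rt_lo, rt_hi)
    rt = np.empty(len(scans))
    inten = np.zeros(len(scans))
    for i, scan in enumerate(scans):
        rt[i] = scan.rt
        a = np.searchsorted(scan.mz, lo_mz, side="left")
        b = np.searchsorted(scan.mz, hi_mz, side="right")
        if b > a:
            window = scan.intensity[a:b]
            inten[i] = window.sum() if combine == "sum" else window.max()
    return XICTrace(target_mz, tolerance_ppm, rt, inten)
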