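"""Quantitation settings shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

#: Mass difference between 13C and 12C in Da; spacing of isotope peaks in a
#: peptide cluster is this value divided by the charge.
ISOTOPE_SPACING = 1.0033548378

#: Mass added per cross-linker by a d4 label (4 x (2H - 1H)), in Da.
DEFAULT_LABEL_MASS = 4.0251056


@dataclass
class QuantConfig:
    """Tunable parameters of the doublet quantitation.

    Attributes
    ----------
    tolerance_ppm
        Half-width of the m/z extraction window in parts per million.
        Default 6 ppm, matching the MS1 accuracy the identifications were
        searched with.
    isotope_spacing_da
        Spacing of isotope peaks in Da at charge 1 (13C - 12C mass).
    boundary_fraction
        Elution-peak boundaries are extended from the apex until the
        intensity drops below this fraction of the apex intensity (0.10:
        the 10%-of-maximum rule).
    extension_seconds
        How far the window of the partner NOT anchored by the MS2 event is
        extended to absorb the deuterium retention-time shift (heavy
        partner: towards earlier times; light partner: towards later
        times).  ``None`` means "one quantitation-window half-width", i.e.
        the per-PSM quant_window value.
    apex_mode
        ``"summed"``: one apex is located on the summed isotope-1..3 trace
        of each partner and the summed trace is integrated (default;
        prevents the three isotopes locking onto different co-eluting
        species).  ``"per_isotope"``: each isotope trace is integrated
        around its own apex and the three areas are summed.
    xic_combine
        How multiple centroid peaks inside the m/z tolerance of one scan
        are combined: ``"sum"`` (default, robust to centroid splitting) or
        ``"max"`` (most intense peak only).
    min_evidence
        Minimum number of quantified PSMs a cross-link site needs before a
        site-level ratio is reported ("at least two").
    min_apex_intensity
        Apex intensities below this value raise the ``low_snr`` flag
        (0 disables the check).
    """

    tolerance_ppm: float = 6.0
    isotope_spacing_da: float = ISOTOPE_SPACING
    boundary_fraction: float = 0.10
    extension_seconds: float | None = None
    apex_mode: str = "summed"
    xic_combine: str = "sum"
    min_evidence: int = 2
    min_apex_intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance_ppm must be positive")
        if not 0.0 < self.boundary_fraction < 1.0:
            raise ValueError("boundary_fraction must lie in (0, 1)")
        if self.isotope_spacing_da <= 0:
            raise ValueError("isotope_spacing_da must be positive")
        if self.extension_seconds is not None and self.extension_seconds < 0:
            raise ValueError("extension_seconds must be >= 0")
        if self.apex_mode not in ("summed", "per_isotope"):
            raise ValueError(f"unknown apex_mode: {self.apex_mode!r}")
        if self.xic_combine not in ("sum", "max"):
            raise ValueError(f"unknown xic_combine: {self.xic_combine!r}")
        if self.min_evidence < 1:
            raise ValueError("min_evidence must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "QuantConfig":
        """Read a flat ``key = value`` config file ('#' starts a comment)."""
        known = {f.name: f for f in fields(cls)}
        kwargs: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown setting {key!r}")
            if key in ("apex_mode", "xic_combine"):
                kwargs[key] = value
            elif key == "min_evidence":
                kwargs[key] = int(value)
            elif key == "extension_seconds" and value.lower() in ("none", "auto"):
                kwargs[key] = None
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)  # type: ignore[arg-type]
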