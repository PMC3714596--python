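"""Identification-list parsing and result writing.

The ID list is a tab-separated table with one row per identified
cross-linked peptide-spectrum match (PSM).  It drives the quantitation:
each row names the raw file, the MS2 scan that identified the peptide,
the precursor m/z and charge, the label arithmetic (mass added per
cross-linker, number of cross-linkers, and which partner the listed
precursor is), the half-width of the integration window, and the
cross-link site the PSM supports.

Result writing appends the computed columns to the original rows,
leaving the input columns byte-identical and the row order untouched;
unquantifiable rows get empty ratio fields plus a flag, never silent
omission.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

if TYPE_CHECKING:  # pragma: no cover
    from .quant import DoubletQuant

REQUIRED_COLUMNS = (
    "raw_file",
    "ms2_scan",
    "precursor_mz",
    "charge",
    "label_mass",
    "label_count",
    "label_state",
    "quant_window",
    "site_key",
    "psm_id",
)

RESULT_COLUMNS = ("light_area", "heavy_area", "ratio_hl", "log2_ratio_hl", "flags")

_CHARGE_RE = re.compile(r"^\+?(\d+)\+?$")


class IDListError(ValueError):
    """Raised for files that violate the ID-list contract."""


@dataclass(frozen=True)
class PSMRecord:
    """One identified cross-linked PSM with its label metadata."""

    raw_file: str
    ms2_scan: int
    precursor_mz: float
    charge: int
    label_mass: float
    label_count: int
    label_state: str  # "light" or "heavy": which partner the precursor is
    quant_window: float  # half-width of the base integration window, seconds
    site_key: str
    psm_id: str

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise IDListError(f"psm {self.psm_id!r}: precursor_mz must be positive")
        if self.charge < 1:
            raise IDListError(f"psm {self.psm_id!r}: charge must be >= 1")
        if self.label_mass <= 0:
            raise IDListError(f"psm {self.psm_id!r}: label_mass must be positive")
        if self.label_count < 1:
            raise IDListError(f"psm {self.psm_id!r}: label_count must be >= 1")
        if self.label_state not in ("light", "heavy"):
            raise IDListError(f"psm {self.psm_id!r}: label_state must be light or heavy")
        if self.quant_window <= 0:
            raise IDListError(f"psm {self.psm_id!r}: quant_window must be positive")


@dataclass
class IDList:
    """Ordered PSM records plus the verbatim source lines they came from."""

    records: list[PSMRecord]
    source_path: str = ""
    # verbatim text, used to keep original columns byte-identical on output:
    # header line and one raw line per record (empty when built in memory)
    raw_header: str = ""
    raw_lines: list[str] = field(default_factory=list)
    comment_lines: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.psm_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise IDListError(f"duplicate psm_id values: {', '.join(dup)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _parse_charge(text: str) -> int:
    """Accept the charge dialects '2', '2+' and '+2'."""
    m = _CHARGE_RE.match(text.strip())
    if not m:
        raise ValueError(f"unparseable charge {text!r}")
    return int(m.group(1))


def parse_idlist(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> IDList:
    """Parse a tab-delimited ID list.

    The header row is mandatory and must name every required column
    (snake_case by default; ``column_map`` maps required names to foreign
    header names for other dialects).  Lines starting with '#' are
    comments.  Rows with unparseable mandatory fields are rejected with
    row-numbered messages.
    """
    path = Path(path)
    if not path.is_file():
        raise IDListError(f"ID list not found: {path}")
    lines = path.read_text(encoding="utf-8").splitlines()

    header_line: str | None = None
    comments: list[str] = []
    data: list[tuple[int, str]] = []
    for lineno, line in enumerate(lines, 1):
        if line.startswith("#"):
            comments.append(line)
            continue
        if not line.strip():
            continue
        if header_line is None:
            header_line = line
        else:
            data.append((lineno, line))
    if header_line is None:
        raise IDListError(f"{path}: empty ID list (no header row)")

    names = header_line.split("\t")
    mapping = dict(column_map or {})
    col_index: dict[str, int] = {}
    for col in REQUIRED_COLUMNS:
        header_name = mapping.get(col, col)
        if header_name not in names:
            raise IDListError(f"{path}: missing mandatory column {header_name!r}")
        col_index[col] = names.index(header_name)

    records: list[PSMRecord] = []
    raw_lines: list[str] = []
    for lineno, line in data:
        cells = line.split("\t")
        if len(cells) < len(names):
            raise IDListError(f"{path}:{lineno}: expected {len(names)} columns, got {len(cells)}")

        def cell(col: str) -> str:
            return cells[col_index[col]].strip()

        try:
            record = PSMRecord(
                raw_file=cell("raw_file"),
                ms2_scan=int(cell("ms2_scan")),
                precursor_mz=float(cell("precursor_mz")),
                charge=_parse_charge(cell("charge")),
                label_mass=float(cell("label_mass")),
                label_count=int(cell("label_count")),
                label_state=cell("label_state").lower(),
                quant_window=float(cell("quant_window")),
                site_key=cell("site_key"),
                psm_id=cell("psm_id"),
            )
        except (ValueError, IDListError) as exc:
            raise IDListError(f"{path}:{lineno}: {exc}") from exc
        records.append(record)
        raw_lines.append(line)
    if not records:
        raise IDListError(f"{path}: ID list contains a header but no data rows")
    return IDList(records, str(path), header_line, raw_lines, comments)


def _format_record(record: PSMRecord) -> str:
    return "\t".join(
        (
            record.raw_file,
            str(record.ms2_scan),
            repr(record.precursor_mz),
            str(record.charge),
            repr(record.label_mass),
            str(record.label_count),
            record.label_state,
            repr(record.quant_window),
            record.site_key,
            record.psm_id,
        )
    )


def write_idlist(idlist: IDList, path: str | Path) -> None:
    """Write an ID list in the canonical column order (round-trips losslessly)."""
    lines = ["\t".join(REQUIRED_COLUMNS)]
    lines.extend(_format_record(r) for r in idlist.records)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_results(
    idlist: IDList,
    quants: Mapping[str, "DoubletQuant"],
    path: str | Path,
) -> None:
    """Append quantitation columns to the ID-list rows and write the table.

    Original columns are reproduced byte-identically when the list was
    parsed from a file; row order is preserved.  Rows without a
    quantifiable doublet keep empty ratio fields and carry their flags.
    """
    unknown = set(quants) - {r.psm_id for r in idlist.records}
    if unknown:
        raise IDListError(f"quant results for unknown psm_id: {sorted(unknown)}")

    if idlist.raw_header and len(idlist.raw_lines) == len(idlist.records):
        header = idlist.raw_header
        base_lines = idlist.raw_lines
    else:
        header = "\t".join(REQUIRED_COLUMNS)
        base_lines = [_format_record(r) for r in idlist.records]

    out = [header + "\t" + "\t".join(RESULT_COLUMNS)]
    for record, base in zip(idlist.records, base_lines):
        quant = quants.get(record.psm_id)
        if quant is None:
            extra = ["", "", "", "", "not_quantified"]
        else:
            ratio = quant.ratio_hl
            extra = [
                repr(quant.light_area),
                repr(quant.heavy_area),
                "" if ratio is None else repr(ratio),
                "" if ratio is None else repr(math.log2(ratio)),
                ";".join(sorted(quant.flags)),
            ]
        out.append(base + "\t" + "\t".join(extra))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")
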