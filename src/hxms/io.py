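"""Reading and writing the three-section HXMS text format.

The writer is strict: data lines are fixed-width, left-justified and
space-padded to the published field widths, while metadata and PTM remark
lines are tab-delimited (the format describes the two section styles
differently, and we keep that asymmetry).  The reader is liberal: it accepts
both fixed-width and tab-delimited data lines, blank lines, and ``#``
comments, and attaches a validation report rather than failing on content
problems.  ``read_hxms(write_hxms(f)) == f`` for every valid document.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass
from typing import Optional, TextIO, Union

from .model import (
    Envelope,
    HXMSError,
    HXMSFile,
    Metadata,
    PTMEntry,
    TimepointRecord,
    validate,
)

UNBOUNDED = None


class ParseError(HXMSError):
    """Source text does not follow the HXMS line grammar."""

    def __init__(self, line_no: int, message: str) -> None:
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


class FieldOverflowError(HXMSError):
    """A rendered value does not fit its fixed-width field."""


class ValidationError(HXMSError):
    """Serialization refused because the document has ERROR-level violations."""

    def __init__(self, report) -> None:
        super().__init__("document failed validation:\n" + str(report))
        self.report = report


@dataclass(frozen=True)
class FieldLayout:
    name: str
    width: Optional[int]  # None = unbounded (last field on the line)
    example: str


#: Fixed-width layout of a "TP" data line, in column order.
RECORD_LAYOUT = (
    FieldLayout("TITLE", 12, "TP"),
    FieldLayout("INDEX", 8, "0"),
    FieldLayout("MOD", 7, "A"),
    FieldLayout("START", 7, "1"),
    FieldLayout("END", 7, "10"),
    FieldLayout("REP", 5, "0"),
    FieldLayout("PTM_ID", 8, "0000"),
    FieldLayout("TIME(SEC)", 16, "0.000000e+00"),
    FieldLayout("UPTAKE", 9, "0.00"),
    FieldLayout("ENVELOPE", UNBOUNDED, "0.527,0.298,0.116,0.036,0.000,0.023,0.000"),
)

#: Fixed-width layout of a "PTM" dictionary line.
PTM_LAYOUT = (
    FieldLayout("TITLE_PTM", 12, "PTM"),
    FieldLayout("PTM_ID", 8, "0000"),
    FieldLayout("CONTENT", UNBOUNDED, "Phosphoryl STY (18)"),
)

#: Character offset of each bounded record field on a written line.
RECORD_OFFSETS = tuple(
    sum(f.width for f in RECORD_LAYOUT[:i]) for i, f in enumerate(RECORD_LAYOUT)
    if f.width is not None
)

_METADATA_TITLES = (
    ("PROTEIN_SEQUENCE", "protein_sequence"),
    ("PROTEIN_NAME", "protein_name"),
    ("PROTEIN_STATE", "protein_state"),
    ("TEMPERATURE (K)", "temperature_k"),
    ("pH(READ)", "ph_read"),
    ("D2O_SATURATION", "d2o_saturation"),
)
_NUMERIC_METADATA = {"TEMPERATURE (K)", "pH(READ)", "D2O_SATURATION"}


def format_time(t: float) -> str:
    """Render an incubation time: 6-digit scientific notation, or ``inf``."""
    if math.isinf(t):
        return "inf"
    if t < 0:
        raise HXMSError(f"TIME(SEC) must be non-negative, got {t}")
    return f"{t:.6e}"


def parse_time(token: str, line_no: int = 0) -> float:
    """Inverse of :func:`format_time`; raises :class:`ParseError` on junk."""
    if token.strip().lower() == "inf":
        return math.inf
    try:
        t = float(token)
    except ValueError:
        raise ParseError(line_no, f"TIME(SEC) token {token!r} is neither a real "
                                  "in scientific notation nor 'inf'") from None
    if t < 0:
        raise ParseError(line_no, f"TIME(SEC) must be non-negative, got {token!r}")
    return t


def _format_number(value: float) -> str:
    # repr() is the shortest string that round-trips the double exactly,
    # which is what byte-exact metadata round-trips need (293.15 -> "293.15").
    return repr(float(value))


def _pad(value: str, layout: FieldLayout) -> str:
    if layout.width is None:
        return value
    if len(value) > layout.width:
        raise FieldOverflowError(
            f"{layout.name} value {value!r} is {len(value)} characters; "
            f"field width is {layout.width}")
    return value.ljust(layout.width)


def format_envelope(env: Envelope) -> str:
    """Comma-separated peak intensities, three decimal places each."""
    return ",".join(f"{x:.3f}" for x in env)


def _record_line(rec: TimepointRecord) -> str:
    values = (
        "TP",
        str(rec.index),
        rec.mod,
        str(rec.start),
        str(rec.end),
        str(rec.rep),
        rec.ptm_id,
        format_time(rec.time_sec),
        f"{rec.uptake:.2f}",
    )
    line = "".join(_pad(v, lay) for v, lay in zip(values, RECORD_LAYOUT))
    if rec.envelope is not None:
        line += format_envelope(rec.envelope)
    return line


def write_hxms(file: HXMSFile, destination: TextIO) -> None:
    """Serialize ``file`` to a text sink.

    Sections are emitted in order: metadata, timepoint records, PTM
    dictionary.  Refuses to write a document with ERROR-level validation
    problems.
    """
    report = validate(file)
    if not report.ok:
        raise ValidationError(report)

    md = file.metadata
    for title, attr in _METADATA_TITLES:
        value = getattr(md, attr)
        if value is None:
            continue
        text = _format_number(value) if title in _NUMERIC_METADATA else str(value)
        destination.write(f"METADATA\t{title}\t{text}\n")
    for title, body in md.remarks:
        destination.write(f"REMARK\t{title}\t{body}\n")

    for rec in file.records:
        destination.write(_record_line(rec) + "\n")

    for ptm_id in file.ptm_dict:
        entry = file.ptm_dict[ptm_id]
        line = _pad("PTM", PTM_LAYOUT[0]) + _pad(ptm_id, PTM_LAYOUT[1]) + entry.content
        destination.write(line + "\n")


def dumps(file: HXMSFile) -> str:
    """Serialize to a string (see :func:`write_hxms`)."""
    buf = _io.StringIO()
    write_hxms(file, buf)
    return buf.getvalue()


_KNOWN_TITLES = {t: a for t, a in _METADATA_TITLES}


def _parse_metadata_line(line: str, line_no: int, md: Metadata,
                         warnings: list[str]) -> None:
    parts = line.split("\t")
    tag = parts[0]
    if len(parts) < 3:
        raise ParseError(line_no, f"{tag} line needs TAG<TAB>TITLE<TAB>VALUE")
    title, value = parts[1], "\t".join(parts[2:])
    if tag == "REMARK":
        md.remarks.append((title, value))
        return
    if title not in _KNOWN_TITLES:
        warnings.append(f"line {line_no}: unknown metadata title {title!r} ignored")
        return
    if title in _NUMERIC_METADATA:
        try:
            parsed: object = float(value)
        except ValueError:
            raise ParseError(line_no, f"metadata {title} value {value!r} is not a number") from None
    else:
        parsed = value
    setattr(md, _KNOWN_TITLES[title], parsed)


def parse_envelope_text(text: str) -> Envelope:
    """Parse a comma-separated peak list into an :class:`Envelope`."""
    return Envelope(float(tok) for tok in text.split(","))


def _parse_record_line(line: str, line_no: int) -> TimepointRecord:
    if "\t" in line:
        tokens = [t.strip() for t in line.split("\t") if t.strip()]
    else:
        # Fields never contain spaces (the envelope is comma-joined), so a
        # whitespace split recovers them from fixed-width lines too.
        tokens = line.split()
    if len(tokens) not in (9, 10):
        raise ParseError(line_no, f"TP line has {len(tokens)} fields, expected 9 or 10")
    try:
        index, start, end, rep = int(tokens[1]), int(tokens[3]), int(tokens[4]), int(tokens[5])
        uptake = float(tokens[8])
    except ValueError as exc:
        raise ParseError(line_no, f"bad numeric field on TP line: {exc}") from None
    time_sec = parse_time(tokens[7], line_no)
    envelope = None
    if len(tokens) == 10:
        try:
            envelope = parse_envelope_text(tokens[9])
        except ValueError:
            raise ParseError(line_no, f"bad ENVELOPE field {tokens[9]!r}") from None
    return TimepointRecord(index=index, mod=tokens[2], start=start, end=end,
                           rep=rep, ptm_id=tokens[6], time_sec=time_sec,
                           uptake=uptake, envelope=envelope)


def _parse_ptm_line(line: str, line_no: int) -> PTMEntry:
    if "\t" in line:
        parts = [p.strip() for p in line.split("\t")]
        parts = [p for p in parts if p]
        if len(parts) < 3:
            raise ParseError(line_no, "PTM line needs PTM, PTM_ID and CONTENT fields")
        ptm_id, content = parts[1], "\t".join(parts[2:])
    else:
        # Fixed-width: CONTENT may contain spaces, so slice by offsets.
        ptm_id = line[12:20].strip()
        content = line[20:].strip()
        if not ptm_id or not content:
            raise ParseError(line_no, "PTM line needs PTM, PTM_ID and CONTENT fields")
    return PTMEntry(ptm_id=ptm_id, content=content)


_SECTION_ORDER = {"metadata": 0, "records": 1, "ptm": 2}


def read_hxms(source: Union[str, TextIO]) -> HXMSFile:
    """Parse HXMS text (a string or an open text file) into a document.

    Tolerant reader: blank lines and ``#`` comments are skipped; data lines
    may be fixed-width or tab-delimited; out-of-order sections are accepted
    with a warning.  Grammar problems raise :class:`ParseError` with the
    line number; content problems are left to :func:`hxms.model.validate`
    (a report is attached as ``file.parse_warnings`` side notes).
    """
    text = source if isinstance(source, str) else source.read()
    file = HXMSFile()
    warnings: list[str] = []
    highest_section = 0

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        tag = line.split("\t", 1)[0].split(" ", 1)[0]
        if tag in ("METADATA", "REMARK"):
            section = _SECTION_ORDER["metadata"]
            _parse_metadata_line(line, line_no, file.metadata, warnings)
        elif tag == "TP":
            section = _SECTION_ORDER["records"]
            file.records.append(_parse_record_line(line, line_no))
        elif tag == "PTM":
            section = _SECTION_ORDER["ptm"]
            entry = _parse_ptm_line(line, line_no)
            file.ptm_dict[entry.ptm_id] = entry
        else:
            raise ParseError(line_no, f"unknown line tag {tag!r} "
                                      "(expected METADATA, REMARK, TP or PTM)")
        if section < highest_section:
            warnings.append(f"line {line_no}: sections interleaved "
                            f"({tag} after a later section)")
        highest_section = max(highest_section, section)

    file.parse_warnings = warnings
    return file


def load(path) -> HXMSFile:
    """Read an HXMS document from a filesystem path."""
    with open(path, "r", encoding="utf-8") as fh:
        return read_hxms(fh)


def dump(file: HXMSFile, path) -> None:
    """Write an HXMS document to a filesystem path."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        write_hxms(file, fh)
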