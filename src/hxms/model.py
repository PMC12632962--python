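"""Document model and validation for the HXMS format.

An HXMS document has three sections: experimental metadata, a series of
peptide timepoint records, and a dictionary of post-translational
modifications (PTMs).  The types here are plain in-memory containers;
serialization lives in :mod:`hxms.io` and all numerical work in
:mod:`hxms.envelopes`.
"""

from __future__ import annotations

import math
import re
import string
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

#: One-letter codes accepted in PROTEIN_SEQUENCE (the 20 standard residues
#: plus X for an unknown residue).
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY" + "X")

#: PTM identifier reserved for "no modification".
NO_PTM = "0000"

_PTM_ID_RE = re.compile(r"^\d{4}$")

#: Metadata titles exactly as they appear in the file, in section order.
REQUIRED_METADATA = ("PROTEIN_SEQUENCE", "TEMPERATURE (K)", "pH(READ)", "D2O_SATURATION")
OPTIONAL_METADATA = ("PROTEIN_NAME", "PROTEIN_STATE")


class HXMSError(Exception):
    """Base class for all errors raised by this package."""


class SpanError(HXMSError):
    """A peptide span is inconsistent with the protein sequence."""


class Severity(Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Violation:
    """One validation finding: a severity, a locator and a message.

    ``locator`` names where the problem sits ("metadata", "record 3",
    "ptm 0007", "file").
    """

    severity: Severity
    locator: str
    message: str

    def __str__(self) -> str:
        return f"{self.severity.value:7s} {self.locator}: {self.message}"


class ValidationReport(list):
    """Ordered list of :class:`Violation`, metadata first then by record."""

    @property
    def errors(self) -> list[Violation]:
        return [v for v in self if v.severity is Severity.ERROR]

    @property
    def warnings(self) -> list[Violation]:
        return [v for v in self if v.severity is Severity.WARNING]

    @property
    def ok(self) -> bool:
        """True when no ERROR-level violation is present."""
        return not self.errors

    def __str__(self) -> str:
        if not self:
            return "0 errors, 0 warnings"
        lines = [str(v) for v in self]
        lines.append(f"{len(self.errors)} errors, {len(self.warnings)} warnings")
        return "\n".join(lines)


@dataclass(frozen=True)
class Envelope:
    """Normalized isotopic mass envelope.

    ``intensities`` holds the relative intensity of consecutive isotope
    peaks, starting at the lowest reported peak, with an implicit 1 Da
    spacing.  A well-formed envelope is non-negative and sums to 1 within
    1e-3.
    """

    intensities: tuple[float, ...]

    def __init__(self, intensities) -> None:
        object.__setattr__(self, "intensities", tuple(float(x) for x in intensities))

    def __len__(self) -> int:
        return len(self.intensities)

    def __iter__(self):
        return iter(self.intensities)

    @property
    def total(self) -> float:
        return sum(self.intensities)


@dataclass
class Metadata:
    """Experimental conditions of an HX/MS run.

    Required fields may be ``None`` on a partially built document; they must
    all be present (and legal) before the file can be serialized.
    ``remarks`` are free-form ``(title, body)`` pairs.
    """

    protein_sequence: Optional[str] = None
    temperature_k: Optional[float] = None
    ph_read: Optional[float] = None
    d2o_saturation: Optional[float] = None
    protein_name: Optional[str] = None
    protein_state: Optional[str] = None
    remarks: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class TimepointRecord:
    """One "TP" line: a single peptide timepoint measurement.

    ``time_sec`` is the D2O incubation time in seconds; ``math.inf`` marks a
    fully deuterated control.  ``uptake`` is the deuterium uptake in Daltons
    relative to the 0 s timepoint of the same peptide/replicate.  ``mod``
    labels the sub-population of a multimodal distribution ("A" for a
    unimodal peptide).  ``envelope`` is present only in full-spectrum files.
    """

    index: int
    start: int
    end: int
    time_sec: float
    uptake: float
    mod: str = "A"
    rep: int = 0
    ptm_id: str = NO_PTM
    envelope: Optional[Envelope] = None

    @property
    def fully_deuterated(self) -> bool:
        return math.isinf(self.time_sec)


@dataclass(frozen=True)
class PTMEntry:
    """Dictionary entry describing one or more PTMs on a peptide.

    ``content`` is free text, ideally "LigandName (absolute position)"; a
    peptide carrying several PTMs lists them comma-separated.
    """

    ptm_id: str
    content: str


@dataclass
class HXMSFile:
    """A complete HXMS document: metadata, timepoint records, PTM dictionary.

    Either every record carries an envelope (full-spectrum file) or none
    does (centroid file); mixed documents do not validate.
    """

    metadata: Metadata = field(default_factory=Metadata)
    records: list[TimepointRecord] = field(default_factory=list)
    ptm_dict: dict[str, PTMEntry] = field(default_factory=dict)
    #: Non-fatal reader diagnostics; not part of document identity.
    parse_warnings: list[str] = field(default_factory=list, compare=False, repr=False)

    @property
    def full_spectrum(self) -> bool:
        """True if any record carries an envelope."""
        return any(r.envelope is not None for r in self.records)


def _check_metadata(md: Metadata, report: ValidationReport) -> None:
    present = {
        "PROTEIN_SEQUENCE": md.protein_sequence,
        "TEMPERATURE (K)": md.temperature_k,
        "pH(READ)": md.ph_read,
        "D2O_SATURATION": md.d2o_saturation,
    }
    for title in REQUIRED_METADATA:
        if present[title] is None:
            report.append(Violation(Severity.ERROR, "metadata",
                                    f"required metadata missing: {title}"))
    seq = md.protein_sequence
    if seq is not None:
        if not seq:
            report.append(Violation(Severity.ERROR, "metadata",
                                    "PROTEIN_SEQUENCE is empty"))
        else:
            bad = sorted({c for c in seq if c not in AMINO_ACIDS})
            if bad:
                report.append(Violation(
                    Severity.ERROR, "metadata",
                    f"PROTEIN_SEQUENCE contains invalid residue codes: {''.join(bad)}"))
    if md.temperature_k is not None and not md.temperature_k > 0:
        report.append(Violation(Severity.ERROR, "metadata",
                                f"TEMPERATURE (K) must be positive, got {md.temperature_k}"))
    if md.d2o_saturation is not None and not (0 < md.d2o_saturation <= 1):
        report.append(Violation(Severity.ERROR, "metadata",
                                f"D2O_SATURATION must lie in (0, 1], got {md.d2o_saturation}"))


# Envelope sum deviations below WARN pass silently; between WARN and ERROR the
# envelope is suspicious but legal; beyond ERROR the invariant is broken.
_ENVELOPE_SUM_WARN = 1e-3
_ENVELOPE_SUM_ERROR = 1e-2


def _check_record(rec: TimepointRecord, pos: int, seq_len: Optional[int],
                  ptm_dict: dict[str, PTMEntry], report: ValidationReport) -> None:
    loc = f"record {pos}"
    if rec.index != pos:
        report.append(Violation(Severity.ERROR, loc,
                                f"INDEX must increase by 1 from 0; expected {pos}, got {rec.index}"))
    if not (len(rec.mod) == 1 and rec.mod in string.ascii_uppercase):
        report.append(Violation(Severity.ERROR, loc,
                                f"MOD must be a single letter A-Z, got {rec.mod!r}"))
    if rec.rep < 0:
        report.append(Violation(Severity.ERROR, loc, f"REP must be >= 0, got {rec.rep}"))
    if not _PTM_ID_RE.match(rec.ptm_id):
        report.append(Violation(Severity.ERROR, loc,
                                f"PTM_ID must be exactly four digits, got {rec.ptm_id!r}"))
    elif rec.ptm_id != NO_PTM and rec.ptm_id not in ptm_dict:
        report.append(Violation(Severity.ERROR, loc,
                                f"PTM_ID {rec.ptm_id} has no entry in the PTM dictionary"))
    if rec.start < 1 or rec.end < rec.start:
        report.append(Violation(Severity.ERROR, loc,
                                f"invalid span START={rec.start}, END={rec.end}"))
    elif seq_len is not None and rec.end > seq_len:
        report.append(Violation(Severity.ERROR, loc,
                                f"END={rec.end} exceeds protein length {seq_len}"))
    if not (rec.time_sec >= 0 or math.isinf(rec.time_sec)):
        report.append(Violation(Severity.ERROR, loc,
                                f"TIME(SEC) must be non-negative or inf, got {rec.time_sec}"))
    env = rec.envelope
    if env is not None:
        if len(env) < 1:
            report.append(Violation(Severity.ERROR, loc, "ENVELOPE has no peaks"))
        elif any(x < 0 for x in env):
            report.append(Violation(Severity.ERROR, loc, "ENVELOPE has negative intensities"))
        else:
            dev = abs(env.total - 1.0)
            if dev > _ENVELOPE_SUM_ERROR:
                report.append(Violation(Severity.ERROR, loc,
                                        f"ENVELOPE sum deviates from 1 by {dev:.4g}"))
            elif dev > _ENVELOPE_SUM_WARN:
                report.append(Violation(Severity.WARNING, loc,
                                        f"ENVELOPE sum deviates from 1 by {dev:.4g}"))


def validate(file: HXMSFile) -> ValidationReport:
    """Check every document invariant; report, never raise.

    The report is deterministic: metadata findings first, then records in
    file order, then file-level and PTM-dictionary findings.
    """
    report = ValidationReport()
    _check_metadata(file.metadata, report)
    seq_len = len(file.metadata.protein_sequence) if file.metadata.protein_sequence else None

    for pos, rec in enumerate(file.records):
        _check_record(rec, pos, seq_len, file.ptm_dict, report)

    with_env = sum(1 for r in file.records if r.envelope is not None)
    if 0 < with_env < len(file.records):
        report.append(Violation(
            Severity.ERROR, "file",
            f"mixed file: {with_env} of {len(file.records)} records carry an envelope "
            "(all or none must)"))

    seen: dict[tuple, int] = {}
    for pos, rec in enumerate(file.records):
        key = (rec.start, rec.end, rec.mod, rec.rep, rec.ptm_id, rec.time_sec)
        if key in seen:
            report.append(Violation(
                Severity.WARNING, f"record {pos}",
                f"duplicate measurement of {key} (first at record {seen[key]})"))
        else:
            seen[key] = pos

    for ptm_id, entry in file.ptm_dict.items():
        loc = f"ptm {ptm_id}"
        if ptm_id == NO_PTM:
            report.append(Violation(Severity.ERROR, loc,
                                    "PTM_ID 0000 is reserved for 'no PTM' and may not be defined"))
        elif not _PTM_ID_RE.match(ptm_id):
            report.append(Violation(Severity.ERROR, loc,
                                    f"PTM_ID must be exactly four digits, got {ptm_id!r}"))
        if entry.ptm_id != ptm_id:
            report.append(Violation(Severity.ERROR, loc,
                                    f"dictionary key {ptm_id} disagrees with entry id {entry.ptm_id}"))
    return report


def peptide_sequence(file: HXMSFile, record: TimepointRecord) -> str:
    """Return the peptide covered by ``record``, 1-based inclusive span.

    Raises :class:`SpanError` (naming the record index) when the span does
    not fit the protein sequence.
    """
    seq = file.metadata.protein_sequence
    if seq is None:
        raise SpanError(f"record {record.index}: file has no PROTEIN_SEQUENCE")
    if record.start < 1 or record.end < record.start or record.end > len(seq):
        raise SpanError(
            f"record {record.index}: span {record.start}..{record.end} "
            f"invalid for sequence of length {len(seq)}")
    return seq[record.start - 1:record.end]
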