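"""Converters from common HX/MS export dialects to HXMS documents.

Five tabular dialects are supported: DynamX-style, HDExaminer-style,
HDX Workbench-style, BioPharma Finder-style, and this package's own custom
CSV.  Vendors change export headers between versions, so each dialect is
described by a declarative column map (:data:`DIALECTS`) rather than
hard-coded parsing logic; the maps are this package's documented
conventions, versioned with it.

Capability differences between the programs drive the conversion rules:
DynamX and BioPharma Finder report deuterium uptake directly and their
values are taken as-is; HDX Workbench and HDExaminer report centroids (and
optionally full spectra), so uptake is recomputed against the 0 s
timepoint, averaging replicate zero-centroids when a replicate lacks its
own 0 s sample.  PTMs ride along from DynamX, Workbench and custom inputs;
HDExaminer and BioPharma Finder exports do not carry them.  Full-spectrum
output is only possible for dialects that export spectra.
"""

from __future__ import annotations

import csv
import io as _io
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd

from . import envelopes
from .model import (
    NO_PTM,
    Envelope,
    HXMSError,
    HXMSFile,
    Metadata,
    PTMEntry,
    TimepointRecord,
)


class SchemaError(HXMSError):
    """Input table does not match the dialect's column schema."""


class CellError(HXMSError):
    """A table cell could not be parsed; names its row/column coordinates."""


class CapabilityError(HXMSError):
    """Requested output needs data the dialect does not carry."""


class EmptySelectionError(HXMSError):
    """No rows survived parsing/state filtering."""


@dataclass(frozen=True)
class DialectSpec:
    """Declarative description of one export dialect.

    ``columns`` maps normalized field names (start, end, sequence, state,
    time, rep, run, mod, uptake, centroid, envelope, modification) to the
    dialect's header names; missing keys mean the dialect has no such
    column.  ``required`` lists headers that must be present.  ``time_unit``
    is "s" or "min"; ``fd_labels`` are time tokens meaning fully deuterated.
    """

    name: str
    carries_uptake: bool
    carries_ptms: bool
    carries_spectra: bool
    time_unit: str
    columns: dict[str, str]
    required: tuple[str, ...]
    fd_labels: frozenset[str]


DIALECTS: dict[str, DialectSpec] = {
    "dynamx": DialectSpec(
        name="dynamx",
        carries_uptake=True, carries_ptms=True, carries_spectra=False,
        time_unit="min",
        columns={"start": "Start", "end": "End", "sequence": "Sequence",
                 "state": "State", "time": "Exposure", "run": "File",
                 "uptake": "Uptake", "modification": "Modification"},
        required=("Start", "End", "Sequence", "State", "Exposure", "Uptake"),
        fd_labels=frozenset({"max", "inf", "fd"}),
    ),
    "biopharma": DialectSpec(
        name="biopharma",
        carries_uptake=True, carries_ptms=False, carries_spectra=False,
        time_unit="s",
        columns={"start": "Start", "end": "End", "sequence": "Sequence",
                 "state": "State", "time": "Labeling Time (s)",
                 "rep": "Replicate", "uptake": "D Uptake"},
        required=("Start", "End", "Sequence", "State", "Labeling Time (s)", "D Uptake"),
        fd_labels=frozenset({"full-d", "inf"}),
    ),
    "workbench": DialectSpec(
        name="workbench",
        carries_uptake=False, carries_ptms=True, carries_spectra=True,
        time_unit="s",
        columns={"start": "start", "end": "end", "sequence": "peptide",
                 "state": "protein_state", "time": "time_sec",
                 "rep": "replicate", "mod": "population",
                 "centroid": "centroid", "envelope": "envelope",
                 "modification": "modification"},
        required=("start", "end", "peptide", "protein_state", "time_sec", "centroid"),
        fd_labels=frozenset({"inf"}),
    ),
    "hdexaminer": DialectSpec(
        name="hdexaminer",
        carries_uptake=False, carries_ptms=False, carries_spectra=True,
        time_unit="s",
        columns={"start": "Start", "end": "End", "sequence": "Sequence",
                 "state": "Protein State", "time": "Deut Time",
                 "rep": "Experiment", "mod": "Population",
                 "centroid": "Centroid", "envelope": "Envelope"},
        required=("Start", "End", "Sequence", "Protein State", "Deut Time", "Centroid"),
        fd_labels=frozenset({"fd", "inf"}),
    ),
    "custom": DialectSpec(
        name="custom",
        carries_uptake=True, carries_ptms=True, carries_spectra=True,
        time_unit="s",
        columns={"start": "START", "end": "END", "sequence": "SEQUENCE",
                 "state": "STATE", "time": "TIME(SEC)", "rep": "REP",
                 "mod": "MOD", "uptake": "UPTAKE", "envelope": "ENVELOPE",
                 "modification": "PTM_CONTENT"},
        required=("START", "END", "SEQUENCE", "TIME(SEC)", "UPTAKE"),
        fd_labels=frozenset({"inf"}),
    ),
}


@dataclass
class NormalizedRow:
    """One measurement in dialect-independent form."""

    start: int
    end: int
    sequence: str
    state: str
    time_sec: float
    rep: int = 0
    mod: str = "A"
    uptake: Optional[float] = None
    centroid: Optional[float] = None
    envelope: Optional[list[float]] = None
    modification: Optional[str] = None


@dataclass
class ConversionRequest:
    """Everything needed to convert one export file.

    The exports themselves never contain temperature/pH/D2O saturation, so
    ``metadata`` is user-supplied (the custom CSV embeds it).  ``output_mode``
    is "centroid" or "full_spectrum"; full-spectrum output requires a
    spectra-carrying dialect.
    """

    dialect: DialectSpec
    input: str
    metadata: Metadata
    state_filter: Optional[str] = None
    output_mode: str = "centroid"


def _read_table(text: str) -> pd.DataFrame:
    text = text.lstrip("﻿")
    header = text.splitlines()[0] if text.splitlines() else ""
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(_io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    return df


def _cell_float(value: str, row: int, col: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise CellError(f"row {row}, column {col!r}: cannot parse {value!r} as a number") from None


def _cell_int(value: str, row: int, col: str) -> int:
    try:
        return int(float(value))
    except ValueError:
        raise CellError(f"row {row}, column {col!r}: cannot parse {value!r} as an integer") from None


def _parse_row_time(token: str, spec: DialectSpec, row: int, col: str) -> float:
    low = token.strip().lower()
    if low in spec.fd_labels:
        return math.inf
    # tolerate a trailing unit suffix such as "60s" or "0.5min"
    for suffix in ("min", "sec", "s"):
        if low.endswith(suffix) and low != suffix:
            stem = low[: -len(suffix)]
            try:
                value = float(stem)
            except ValueError:
                continue
            return value * 60.0 if suffix == "min" else value
    value = _cell_float(token, row, col)
    if spec.time_unit == "min":
        value *= 60.0
    return value


def parse_dialect(name: str, input: str,
                  warnings: Optional[list[str]] = None) -> list[NormalizedRow]:
    """Parse tabular export text into normalized rows.

    Times are returned in seconds (dialects reporting minutes are converted);
    fully-deuterated labels map to ``inf``.  Raises :class:`SchemaError` on a
    header mismatch and :class:`CellError` on an unparseable cell.
    """
    if name not in DIALECTS:
        raise SchemaError(f"unknown dialect {name!r}; expected one of {sorted(DIALECTS)}")
    spec = DIALECTS[name]
    warnings = warnings if warnings is not None else []
    df = _read_table(input)
    missing = [c for c in spec.required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{name} input is missing required columns {missing}; "
            f"expected header with {list(spec.required)}")
    if len(df) == 0:
        raise EmptySelectionError(f"{name} input has a header but no data rows")

    cols = spec.columns
    has = {key: col in df.columns for key, col in cols.items()}

    run_to_rep: dict[str, int] = {}
    rows: list[NormalizedRow] = []
    for i, rec in enumerate(df.to_dict("records")):
        def cell(key: str) -> str:
            return str(rec.get(cols[key], "")).strip() if key in cols else ""

        row = NormalizedRow(
            start=_cell_int(cell("start"), i, cols["start"]),
            end=_cell_int(cell("end"), i, cols["end"]),
            sequence=cell("sequence"),
            state=cell("state") if has.get("state") else "",
            time_sec=_parse_row_time(cell("time"), spec, i, cols["time"]),
        )
        if has.get("mod") and cell("mod"):
            row.mod = cell("mod").upper()
        if has.get("rep") and cell("rep"):
            row.rep = _cell_int(cell("rep"), i, cols["rep"])
        elif has.get("run") and cell("run"):
            label = cell("run")
            row.rep = run_to_rep.setdefault(label, len(run_to_rep))
        if has.get("uptake") and cell("uptake"):
            row.uptake = _cell_float(cell("uptake"), i, cols["uptake"])
        if has.get("centroid") and cell("centroid"):
            row.centroid = _cell_float(cell("centroid"), i, cols["centroid"])
        if has.get("envelope") and cell("envelope"):
            try:
                row.envelope = [float(t) for t in cell("envelope").split(",")]
            except ValueError:
                raise CellError(f"row {i}, column {cols['envelope']!r}: "
                                f"bad envelope {cell('envelope')!r}") from None
        if has.get("modification") and cell("modification"):
            row.modification = cell("modification")
        rows.append(row)

    if not (has.get("rep") or has.get("run")):
        groups: dict[tuple, int] = {}
        for row in rows:
            key = (row.start, row.end, row.state, row.mod, row.time_sec)
            row.rep = groups.get(key, 0)
            groups[key] = row.rep + 1
        if any(r.rep > 0 for r in rows):
            warnings.append(
                f"{name}: no replicate/run column; replicates numbered in input order")
    return rows


def _row_centroid(row: NormalizedRow) -> float:
    if row.envelope is not None:
        return envelopes.centroid(envelopes.normalize_envelope(row.envelope))
    if row.centroid is not None:
        return row.centroid
    raise CapabilityError(
        f"peptide {row.start}-{row.end} at t={row.time_sec}: "
        "no centroid or envelope to recompute uptake from")


def _recompute_uptakes(rows: list[NormalizedRow]) -> dict[int, float]:
    """Uptake per row id for centroid-reporting dialects.

    Groups rows into per-replicate centroid series keyed by
    (start, end, mod, rep, modification); replicates missing a 0 s point are
    referenced to the mean zero-centroid of their siblings.  A sub-population
    (mod != "A") with no 0 s point in any replicate falls back to the "A"
    population's zero reference, since 0 s samples are typically unimodal.
    """
    series: dict[tuple, envelopes.CentroidSeries] = {}
    row_at: dict[tuple[tuple, float], int] = {}
    for rid, row in enumerate(rows):
        key = (row.start, row.end, row.mod, row.rep, row.modification or "")
        s = series.setdefault(key, envelopes.CentroidSeries(key=key))
        s.points.append((row.time_sec, _row_centroid(row)))
        row_at[(key, row.time_sec)] = rid

    # zero references per peptide+mod, averaged over replicates when needed
    by_pep_mod: dict[tuple, list[envelopes.CentroidSeries]] = {}
    for key, s in series.items():
        start, end, mod, _rep, content = key
        by_pep_mod.setdefault((start, end, mod, content), []).append(s)

    zero_ref: dict[tuple, dict[int, float]] = {}
    for pep_key, group in by_pep_mod.items():
        try:
            zero_ref[pep_key] = envelopes.zero_reference(group)
        except envelopes.MissingZeroError:
            start, end, mod, content = pep_key
            if mod == "A":
                raise
            a_key = (start, end, "A", content)
            if a_key not in by_pep_mod:
                raise
            a_ref = zero_ref.get(a_key)
            if a_ref is None:
                a_ref = envelopes.zero_reference(by_pep_mod[a_key])
                zero_ref[a_key] = a_ref
            mean_a = sum(a_ref.values()) / len(a_ref)
            zero_ref[pep_key] = {s.rep: a_ref.get(s.rep, mean_a) for s in group}

    uptakes: dict[int, float] = {}
    for key, s in series.items():
        start, end, mod, rep, content = key
        s.sort()
        ref = zero_ref[(start, end, mod, content)][rep]
        for t, u in envelopes.compute_uptake(s, zero_reference=ref):
            uptakes[row_at[(key, t)]] = u
    return uptakes


def _states_of(rows: list[NormalizedRow]) -> list[str]:
    seen: list[str] = []
    for row in rows:
        if row.state not in seen:
            seen.append(row.state)
    return seen


def convert(req: ConversionRequest) -> HXMSFile:
    """Convert one export file to a single-state HXMS document.

    Records are sorted by (start, end, time, rep, mod) and numbered 0, 1,
    2, ... file-wide.  Distinct modification descriptions get PTM ids
    "0001", "0002", ... in first-appearance order; unmodified records keep
    "0000".  Fully-deuterated rows carry time ``inf``.  The result passes
    validation with no errors.
    """
    spec = req.dialect
    if req.output_mode not in ("centroid", "full_spectrum"):
        raise HXMSError(f"unknown output_mode {req.output_mode!r}")
    if req.output_mode == "full_spectrum" and not spec.carries_spectra:
        raise CapabilityError(
            f"dialect {spec.name!r} does not export spectra; "
            "full-spectrum output is impossible")

    warnings: list[str] = []
    rows = parse_dialect(spec.name, req.input, warnings)

    states = _states_of(rows)
    if req.state_filter is not None:
        rows = [r for r in rows if r.state == req.state_filter]
        if not rows:
            raise EmptySelectionError(
                f"state filter {req.state_filter!r} matches no rows "
                f"(states present: {states})")
        state = req.state_filter
    elif len(states) > 1:
        raise HXMSError(
            f"input contains several protein states {states}; pass a "
            "state_filter or use convert_all_states()")
    else:
        state = states[0]

    if req.output_mode == "full_spectrum" and not all(r.envelope for r in rows):
        raise CapabilityError(
            "full-spectrum output requested but some rows carry no envelope")

    if not spec.carries_uptake:
        uptake_of = _recompute_uptakes(rows)
        for i, row in enumerate(rows):
            row.uptake = uptake_of[i]
    else:
        for i, row in enumerate(rows):
            if row.uptake is None:
                raise CellError(f"row {i}: dialect {spec.name} reports uptake "
                                "directly but the cell is empty")

    rows.sort(key=lambda r: (r.start, r.end, r.time_sec, r.rep, r.mod))

    ptm_ids: dict[str, str] = {}
    ptm_dict: dict[str, PTMEntry] = {}
    metadata = replace(req.metadata, remarks=list(req.metadata.remarks))
    if metadata.protein_state is None and state:
        metadata.protein_state = state

    records: list[TimepointRecord] = []
    seq = metadata.protein_sequence or ""
    for index, row in enumerate(rows):
        ptm_id = NO_PTM
        if row.modification:
            if row.modification not in ptm_ids:
                ptm_id = f"{len(ptm_ids) + 1:04d}"
                ptm_ids[row.modification] = ptm_id
                ptm_dict[ptm_id] = PTMEntry(ptm_id=ptm_id, content=row.modification)
            ptm_id = ptm_ids[row.modification]
        envelope = None
        if req.output_mode == "full_spectrum":
            envelope = envelopes.normalize_envelope(row.envelope)
        if row.sequence and seq and seq[row.start - 1:row.end] != row.sequence:
            warnings.append(
                f"record {index}: SEQUENCE {row.sequence!r} disagrees with "
                f"protein_sequence[{row.start}..{row.end}]")
        records.append(TimepointRecord(
            index=index, start=row.start, end=row.end, mod=row.mod,
            rep=row.rep, ptm_id=ptm_id, time_sec=row.time_sec,
            uptake=row.uptake, envelope=envelope))

    file = HXMSFile(metadata=metadata, records=records, ptm_dict=ptm_dict)
    file.parse_warnings = warnings
    return file


def convert_all_states(req: ConversionRequest) -> dict[str, HXMSFile]:
    """One HXMS document per protein state found in the input."""
    rows = parse_dialect(req.dialect.name, req.input)
    out: dict[str, HXMSFile] = {}
    for state in _states_of(rows):
        out[state] = convert(replace(req, state_filter=state))
    return out


_CUSTOM_METADATA_KEYS = {
    "PROTEIN_SEQUENCE": ("protein_sequence", str),
    "PROTEIN_NAME": ("protein_name", str),
    "PROTEIN_STATE": ("protein_state", str),
    "TEMPERATURE (K)": ("temperature_k", float),
    "TEMPERATURE_K": ("temperature_k", float),
    "pH(READ)": ("ph_read", float),
    "PH_READ": ("ph_read", float),
    "D2O_SATURATION": ("d2o_saturation", float),
}
_CUSTOM_REQUIRED = ("PROTEIN_SEQUENCE", "TEMPERATURE (K)", "pH(READ)", "D2O_SATURATION")


def read_custom_csv(input: str) -> ConversionRequest:
    """Parse the self-contained custom CSV into a ready conversion request.

    The file opens with a metadata block of ``KEY,VALUE`` rows (plus optional
    ``REMARK,title,body`` rows) and continues with a data block whose header
    row carries the custom-dialect columns (START, END, TIME(SEC), ...).
    No separate metadata is needed.
    """
    data_columns = set(DIALECTS["custom"].required)
    lines = input.lstrip("﻿").splitlines()
    metadata = Metadata()
    data_start: Optional[int] = None
    for i, parsed in enumerate(csv.reader(lines)):
        if not parsed or not parsed[0].strip():
            continue
        key = parsed[0].strip()
        if data_columns <= {c.strip() for c in parsed}:
            data_start = i
            break
        if key == "REMARK":
            title = parsed[1].strip() if len(parsed) > 1 else ""
            body = ",".join(parsed[2:]).strip() if len(parsed) > 2 else ""
            metadata.remarks.append((title, body))
            continue
        if key in _CUSTOM_METADATA_KEYS:
            attr, cast = _CUSTOM_METADATA_KEYS[key]
            value = parsed[1].strip() if len(parsed) > 1 else ""
            try:
                setattr(metadata, attr, cast(value))
            except ValueError:
                raise SchemaError(f"metadata row {key!r}: bad value {value!r}") from None
        else:
            raise SchemaError(f"unknown metadata key {key!r} before the data header")
    if data_start is None:
        raise SchemaError("custom CSV has no data header (expected a 'START,...' row)")
    missing = [k for k in _CUSTOM_REQUIRED
               if getattr(metadata, _CUSTOM_METADATA_KEYS[k][0]) is None]
    if missing:
        raise SchemaError(f"custom CSV metadata block is missing required keys {missing}; "
                          f"the required set is {list(_CUSTOM_REQUIRED)}")
    data_text = "\n".join(lines[data_start:])
    return ConversionRequest(dialect=DIALECTS["custom"], input=data_text,
                             metadata=metadata,
                             state_filter=None, output_mode="centroid")
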