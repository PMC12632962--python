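"""Synthetic HX/MS experiments and dialect export files for testing and demos.

The generator emulates the data shapes the HXMS format supports —
replicates, bimodal sub-populations, PTMs, fully deuterated controls,
centroid-only and full-spectrum exports — without any real instrument data.

The exchange model is deliberately simple so that every quantity has a
closed form: a peptide with ``n`` exchangeable sites at deuteration
fraction ``p`` produces a Binomial(n, p) mass envelope, convolved with a
fixed natural-abundance-like base envelope; its centroid is the base
centroid plus ``n·p`` exactly, which makes an analytic oracle for the
centroid and uptake math.  Deuteration follows a single-exponential
per-peptide rate, ``p(t) = sat·(1 − exp(−k·t))``, with the fully
deuterated control at ``p = sat``.  Realistic per-residue intrinsic rates,
back-exchange and charge-state effects are intentionally out of scope.

Ground-truth uptakes in the emitted fixtures are computed by a plain-loop
implementation inside this module, independent of :mod:`hxms.envelopes`,
so converter output can be checked against an oracle that shares no code
with the path under test.
"""

from __future__ import annotations

import csv
import io as _io
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .converters import DIALECTS, DialectSpec
from .model import Envelope, HXMSError, HXMSFile, Metadata, PTMEntry, TimepointRecord

#: Natural-abundance-like base envelope convolved into every simulated peptide.
BASE_ENVELOPE = (0.60, 0.27, 0.10, 0.03)

#: Rate multiplier of the fast ("B") sub-population of a bimodal peptide.
FAST_MODE_FACTOR = 20.0


def binomial_pmf(n: int, p: float) -> list[float]:
    """Binomial(n, p) mass function over k = 0..n, by exact combinatorics."""
    if not 0 <= p <= 1:
        raise HXMSError(f"p_exchanged must lie in [0, 1], got {p}")
    return [math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(n + 1)]


def simulate_envelope(n_sites: int, p_exchanged: float, noise_sd: float,
                      rng: np.random.Generator) -> Envelope:
    """Binomial isotope envelope with truncated Gaussian intensity noise.

    Intensities are proportional to the Binomial(n_sites, p_exchanged) mass
    function plus N(0, noise_sd) noise truncated at zero, renormalized to
    unit sum.  With ``noise_sd=0`` the expected centroid is exactly
    ``n_sites · p_exchanged``.
    """
    pmf = np.asarray(binomial_pmf(n_sites, p_exchanged))
    if noise_sd > 0:
        pmf = np.clip(pmf + rng.normal(0.0, noise_sd, size=pmf.size), 0.0, None)
    total = pmf.sum()
    if total == 0:  # pragma: no cover - needs pathological noise
        pmf[0] = 1.0
        total = 1.0
    return Envelope(pmf / total)


def _convolve(a, b) -> list[float]:
    out = [0.0] * (len(a) + len(b) - 1)
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            out[i + j] += x * y
    return out


def _plain_centroid(values) -> float:
    # independent oracle: no calls into hxms.envelopes
    num = 0.0
    den = 0.0
    for i, v in enumerate(values):
        num += i * v
        den += v
    return num / den


@dataclass
class SyntheticExperiment:
    """Parameters of one synthetic HX/MS experiment.

    ``rate_scales`` gives the per-peptide exchange rate constant k in 1/s;
    deuteration is ``d2o_saturation·(1 − exp(−k·t))``.  ``bimodal_fraction``
    marks peptides whose finite nonzero timepoints split into a slow "A"
    and a fast "B" sub-population (the fraction is the fast population's
    share, recorded for the export's population column).  ``ptms`` assigns a
    modification description to peptide spans.  ``missing_zero`` lists
    (start, end, rep) combinations whose 0 s row is withheld from the
    export, exercising the replicate-averaged zero-reference rule.
    """

    protein_sequence: str = "GSHMKTVEVNGADASDDN"
    protein_name: str = "synthetic HX/MS test protein"
    protein_state: str = "APO"
    temperature_k: float = 293.15
    ph_read: float = 6.0
    d2o_saturation: float = 0.91
    peptides: tuple[tuple[int, int], ...] = ((1, 10), (5, 14), (9, 18))
    timepoints_sec: tuple[float, ...] = (0.0, 15.0, 60.0, 600.0, math.inf)
    n_replicates: int = 2
    rate_scales: tuple[float, ...] = (0.005, 0.02, 0.08)
    bimodal_fraction: dict[tuple[int, int], float] = field(default_factory=dict)
    ptms: dict[tuple[int, int], str] = field(default_factory=dict)
    missing_zero: frozenset[tuple[int, int, int]] = frozenset()
    noise_sd: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.protein_sequence)
        for start, end in self.peptides:
            if not (1 <= start <= end <= n):
                raise HXMSError(f"peptide span {start}..{end} invalid for "
                                f"sequence of length {n}")
        if len(self.rate_scales) != len(self.peptides):
            raise HXMSError("need one rate scale per peptide")
        if not (0 in self.timepoints_sec or 0.0 in self.timepoints_sec):
            raise HXMSError("timepoints must include 0 s")
        for frac in self.bimodal_fraction.values():
            if not 0 <= frac <= 1:
                raise HXMSError("bimodal fractions must lie in [0, 1]")

    def n_sites(self, start: int, end: int) -> int:
        """Exchangeable amides: residues minus the N-terminal two, min 1."""
        return max(end - start + 1 - 2, 1)

    def metadata(self) -> Metadata:
        return Metadata(
            protein_sequence=self.protein_sequence,
            protein_name=self.protein_name,
            protein_state=self.protein_state,
            temperature_k=self.temperature_k,
            ph_read=self.ph_read,
            d2o_saturation=self.d2o_saturation,
        )


def default_experiment(seed: int = 0) -> SyntheticExperiment:
    """Standard test experiment: one bimodal peptide, one PTM peptide."""
    return SyntheticExperiment(
        bimodal_fraction={(5, 14): 0.4},
        ptms={(9, 18): "Phosphoryl STY (18)"},
        rng_seed=seed,
    )


def missing_zero_experiment(seed: int = 0) -> SyntheticExperiment:
    """Experiment where replicate 1 of the first peptide lacks its 0 s row."""
    return SyntheticExperiment(
        n_replicates=3,
        missing_zero=frozenset({(1, 10, 1)}),
        rng_seed=seed,
    )


@dataclass
class _SimRow:
    start: int
    end: int
    sequence: str
    mod: str
    rep: int
    time_sec: float
    envelope: tuple[float, ...]  # rounded to written precision
    centroid: float              # plain-loop centroid of the rounded envelope
    modification: Optional[str]
    in_export: bool              # False for withheld 0 s rows


def _deuteration(exp: SyntheticExperiment, k: float, t: float) -> float:
    if math.isinf(t):
        return exp.d2o_saturation
    return exp.d2o_saturation * (1.0 - math.exp(-k * t))


def _simulate_rows(exp: SyntheticExperiment, bimodal: bool) -> list[_SimRow]:
    """All measurements of the experiment, envelopes pre-rounded to 6 dp.

    ``bimodal`` controls whether fast sub-populations appear as separate
    "B" rows (dialects without a population column collapse to mode "A").
    """
    rng = np.random.default_rng(exp.rng_seed)
    rows: list[_SimRow] = []
    for (span, k) in zip(exp.peptides, exp.rate_scales):
        start, end = span
        seq = exp.protein_sequence[start - 1:end]
        n = exp.n_sites(start, end)
        modification = exp.ptms.get(span)
        for rep in range(exp.n_replicates):
            for t in exp.timepoints_sec:
                modes = [("A", k)]
                if (bimodal and span in exp.bimodal_fraction
                        and t > 0 and not math.isinf(t)):
                    modes.append(("B", k * FAST_MODE_FACTOR))
                for mod, k_mode in modes:
                    p = _deuteration(exp, k_mode, t)
                    binom = simulate_envelope(n, p, exp.noise_sd, rng)
                    raw = _convolve(BASE_ENVELOPE, list(binom))
                    rounded = tuple(round(v, 6) for v in raw)
                    rows.append(_SimRow(
                        start=start, end=end, sequence=seq, mod=mod, rep=rep,
                        time_sec=t, envelope=rounded,
                        centroid=_plain_centroid(rounded),
                        modification=modification,
                        in_export=not (t == 0 and (start, end, rep) in exp.missing_zero),
                    ))
    return rows


def _truth_uptakes(rows: list[_SimRow]) -> dict[int, float]:
    """Plain-loop uptake oracle over the exported rows.

    Mirrors the published rule: each replicate is referenced to its own 0 s
    centroid; a replicate without one gets the mean of the other replicates'
    zero-centroids; a "B" sub-population borrows the "A" zero reference.
    """
    exported = [(i, r) for i, r in enumerate(rows) if r.in_export]
    zeros: dict[tuple, float] = {}
    for _i, r in exported:
        if r.time_sec == 0:
            zeros[(r.start, r.end, r.mod, r.rep)] = r.centroid

    def zero_for(r: _SimRow, mod: str) -> Optional[float]:
        key = (r.start, r.end, mod, r.rep)
        if key in zeros:
            return zeros[key]
        sibling = [c for (s, e, m, _rep), c in zeros.items()
                   if (s, e, m) == (r.start, r.end, mod)]
        if sibling:
            total = 0.0
            for c in sibling:
                total += c
            return total / len(sibling)
        return None

    uptakes: dict[int, float] = {}
    for i, r in exported:
        if r.time_sec == 0:
            uptakes[i] = 0.0
            continue
        zero = zero_for(r, r.mod)
        if zero is None:
            zero = zero_for(r, "A")
        if zero is None:
            raise HXMSError(f"synthetic truth: peptide {r.start}-{r.end} has no zero")
        uptakes[i] = r.centroid - zero
    return uptakes


def _fmt_time(spec: DialectSpec, t: float) -> str:
    if math.isinf(t):
        return {"dynamx": "MAX", "biopharma": "Full-D",
                "hdexaminer": "FD"}.get(spec.name, "inf")
    if spec.name == "dynamx":
        return repr(t / 60.0)
    if spec.name == "hdexaminer":
        return f"{t:g}s"
    return repr(t)


def _env_cell(envelope) -> str:
    return ",".join(f"{v:.6f}" for v in envelope)


def emit_dialect_file(exp: SyntheticExperiment, dialect: str,
                      output_mode: Optional[str] = None) -> tuple[str, HXMSFile]:
    """Render the experiment as one dialect's export CSV plus its truth.

    Returns ``(csv_text, truth)`` where ``truth`` is the HXMS document that
    a correct conversion of ``csv_text`` must produce (uptakes computed by
    the plain-loop oracle above, never by :mod:`hxms.envelopes`).
    ``output_mode`` defaults to full_spectrum for spectra-carrying dialects
    and centroid otherwise.
    """
    if dialect not in DIALECTS:
        raise HXMSError(f"unknown dialect {dialect!r}")
    spec = DIALECTS[dialect]
    if output_mode is None:
        output_mode = "full_spectrum" if spec.carries_spectra else "centroid"
    if output_mode == "full_spectrum" and not spec.carries_spectra:
        raise HXMSError(f"dialect {dialect!r} cannot carry spectra")

    has_mod_column = "mod" in spec.columns
    rows = _simulate_rows(exp, bimodal=has_mod_column)
    uptakes = _truth_uptakes(rows)
    exported = [(i, r) for i, r in enumerate(rows) if r.in_export]

    csv_text = _render_csv(spec, exp, exported, uptakes)
    truth = _build_truth(spec, exp, exported, uptakes, output_mode)
    return csv_text, truth


def _render_csv(spec: DialectSpec, exp: SyntheticExperiment,
                exported: list[tuple[int, _SimRow]],
                uptakes: dict[int, float]) -> str:
    cols = spec.columns
    header: list[str] = []
    for key in ("sequence", "start", "end", "state", "mod", "rep", "run",
                "time", "centroid", "uptake", "envelope", "modification"):
        if key in cols:
            header.append(cols[key])
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(header)
    for i, r in exported:
        cells: list[str] = []
        for key in ("sequence", "start", "end", "state", "mod", "rep", "run",
                    "time", "centroid", "uptake", "envelope", "modification"):
            if key not in cols:
                continue
            if key == "sequence":
                cells.append(r.sequence)
            elif key == "start":
                cells.append(str(r.start))
            elif key == "end":
                cells.append(str(r.end))
            elif key == "state":
                cells.append(exp.protein_state)
            elif key == "mod":
                cells.append(r.mod)
            elif key == "rep":
                cells.append(str(r.rep))
            elif key == "run":
                cells.append(f"run_{r.rep}.raw")
            elif key == "time":
                cells.append(_fmt_time(spec, r.time_sec))
            elif key == "centroid":
                cells.append(f"{r.centroid:.6f}")
            elif key == "uptake":
                cells.append(f"{uptakes[i]:.6f}")
            elif key == "envelope":
                cells.append(_env_cell(r.envelope))
            elif key == "modification":
                cells.append(r.modification or "")
        writer.writerow(cells)
    return buf.getvalue()


def _build_truth(spec: DialectSpec, exp: SyntheticExperiment,
                 exported: list[tuple[int, _SimRow]],
                 uptakes: dict[int, float], output_mode: str) -> HXMSFile:
    order = sorted(exported,
                   key=lambda ir: (ir[1].start, ir[1].end, ir[1].time_sec,
                                   ir[1].rep, ir[1].mod))
    ptm_ids: dict[str, str] = {}
    ptm_dict: dict[str, PTMEntry] = {}
    records: list[TimepointRecord] = []
    for index, (i, r) in enumerate(order):
        ptm_id = "0000"
        if spec.carries_ptms and r.modification:
            if r.modification not in ptm_ids:
                new_id = f"{len(ptm_ids) + 1:04d}"
                ptm_ids[r.modification] = new_id
                ptm_dict[new_id] = PTMEntry(ptm_id=new_id, content=r.modification)
            ptm_id = ptm_ids[r.modification]
        uptake = uptakes[i]
        if spec.carries_uptake:
            # the dialect file prints uptake at 6 dp; truth matches the file
            uptake = float(f"{uptake:.6f}")
        envelope = None
        if output_mode == "full_spectrum":
            total = 0.0
            for v in r.envelope:
                total += v
            envelope = Envelope(v / total for v in r.envelope)
        records.append(TimepointRecord(
            index=index, start=r.start, end=r.end, mod=r.mod, rep=r.rep,
            ptm_id=ptm_id, time_sec=r.time_sec, uptake=uptake,
            envelope=envelope))
    return HXMSFile(metadata=exp.metadata(), records=records, ptm_dict=ptm_dict)


def emit_custom_csv(exp: SyntheticExperiment,
                    output_mode: str = "full_spectrum") -> tuple[str, HXMSFile]:
    """Self-contained custom CSV: metadata block followed by the data block."""
    data, truth = emit_dialect_file(exp, "custom", output_mode)
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["PROTEIN_SEQUENCE", exp.protein_sequence])
    writer.writerow(["PROTEIN_NAME", exp.protein_name])
    writer.writerow(["PROTEIN_STATE", exp.protein_state])
    writer.writerow(["TEMPERATURE (K)", repr(exp.temperature_k)])
    writer.writerow(["pH(READ)", repr(exp.ph_read)])
    writer.writerow(["D2O_SATURATION", repr(exp.d2o_saturation)])
    return buf.getvalue() + data, truth


def write_demo(directory, seed: int = 0) -> dict[str, str]:
    """Write one export CSV per dialect plus its truth HXMS file.

    Returns a map of dialect name to the written CSV path.  Used by the
    test corpus and the CLI demo command.
    """
    import os

    from .io import dump

    os.makedirs(directory, exist_ok=True)
    paths: dict[str, str] = {}
    for dialect in DIALECTS:
        exp = default_experiment(seed)
        csv_text, truth = emit_dialect_file(exp, dialect)
        csv_path = os.path.join(directory, f"{dialect}_export.csv")
        with open(csv_path, "w", encoding="utf-8", newline="") as fh:
            fh.write(csv_text)
        dump(truth, os.path.join(directory, f"{dialect}_truth.hxms"))
        paths[dialect] = csv_path
    return paths
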