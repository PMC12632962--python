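"""Shared fixtures: minimal documents, a random-file generator whose values
are exact at serialization precision, and a converted-fixture corpus."""

from __future__ import annotations

import math
import random

import pytest

from hxms import converters, synthetic
from hxms.model import Envelope, HXMSFile, Metadata, PTMEntry, TimepointRecord

AMINO = "ACDEFGHIKLMNPQRSTVWY"


def make_metadata(**overrides) -> Metadata:
    md = Metadata(
        protein_sequence="GSHMKTVEVNGADASDDN",
        temperature_k=293.15,
        ph_read=6.0,
        d2o_saturation=0.91,
    )
    for key, value in overrides.items():
        setattr(md, key, value)
    return md


def make_minimal_file(**metadata_overrides) -> HXMSFile:
    """One centroid record, all defaults."""
    return HXMSFile(
        metadata=make_metadata(**metadata_overrides),
        records=[TimepointRecord(index=0, start=1, end=10, time_sec=0.0, uptake=0.0)],
    )


def exact_envelope(rng: random.Random, n_peaks: int) -> Envelope:
    """Envelope whose intensities are exact 3-decimal values summing to 1."""
    cuts = sorted(rng.sample(range(1, 1000), n_peaks - 1)) if n_peaks > 1 else []
    counts = [b - a for a, b in zip([0] + cuts, cuts + [1000])]
    return Envelope(c / 1000 for c in counts)


def make_random_file(seed: int) -> HXMSFile:
    """Random valid document, every value exact at serialization precision.

    Uptakes are 2-decimal values, envelope peaks 3-decimal, times either from
    a printable set or round-tripped through 6-digit scientific notation, so
    read(write(f)) == f must hold exactly.
    """
    rng = random.Random(seed)
    seq = "".join(rng.choice(AMINO) for _ in range(rng.randint(10, 30)))
    md = Metadata(
        protein_sequence=seq,
        temperature_k=rng.uniform(273.0, 330.0),
        ph_read=rng.uniform(5.0, 9.0),
        d2o_saturation=rng.uniform(0.5, 1.0),
        protein_name=rng.choice([None, "test protein"]),
        protein_state=rng.choice([None, "APO", "BOUND"]),
    )
    if rng.random() < 0.3:
        md.remarks.append(("NOTE", "free text remark, with commas, and spaces"))

    ptm_dict = {}
    if rng.random() < 0.4:
        ptm_dict["0001"] = PTMEntry("0001", "Phosphoryl STY (18)")

    full_spectrum = rng.random() < 0.5
    records = []
    for index in range(rng.randint(1, 8)):
        start = rng.randint(1, len(seq) - 1)
        end = rng.randint(start, len(seq))
        t = rng.choice([0.0, 15.0, 60.0, 600.0, math.inf,
                        float(f"{rng.uniform(0, 1e5):.6e}")])
        envelope = exact_envelope(rng, rng.randint(1, 8)) if full_spectrum else None
        records.append(TimepointRecord(
            index=index, start=start, end=end,
            mod=rng.choice("AAB"), rep=rng.randint(0, 2),
            ptm_id="0001" if (ptm_dict and rng.random() < 0.3) else "0000",
            time_sec=t,
            uptake=float(f"{rng.uniform(-0.5, 8.0):.2f}"),
            envelope=envelope))
    return HXMSFile(metadata=md, records=records, ptm_dict=ptm_dict)


def convert_fixture(dialect: str, exp=None, output_mode=None):
    """(converted file, truth file) for one synthetic dialect export."""
    exp = exp or synthetic.default_experiment(7)
    spec = converters.DIALECTS[dialect]
    csv_text, truth = synthetic.emit_dialect_file(exp, dialect, output_mode)
    mode = output_mode or ("full_spectrum" if spec.carries_spectra else "centroid")
    req = converters.ConversionRequest(
        dialect=spec, input=csv_text, metadata=exp.metadata(), output_mode=mode)
    return converters.convert(req), truth


@pytest.fixture(scope="session")
def corpus() -> list[HXMSFile]:
    """Converted documents from every dialect plus the missing-zero scenario."""
    files = [convert_fixture(d)[0] for d in converters.DIALECTS]
    files.append(convert_fixture(
        "workbench", exp=synthetic.missing_zero_experiment(11))[0])
    return files


def assert_same_document(got: HXMSFile, want: HXMSFile, tol: float = 1e-9) -> None:
    """Field-by-field comparison with a numeric tolerance on uptake/envelope."""
    assert len(got.records) == len(want.records)
    for a, b in zip(got.records, want.records):
        assert (a.index, a.start, a.end, a.mod, a.rep, a.ptm_id) == \
               (b.index, b.start, b.end, b.mod, b.rep, b.ptm_id)
        assert a.time_sec == b.time_sec
        assert a.uptake == pytest.approx(b.uptake, abs=tol)
        assert (a.envelope is None) == (b.envelope is None)
        if a.envelope is not None:
            assert list(a.envelope) == pytest.approx(list(b.envelope), abs=tol)
    assert got.ptm_dict == want.ptm_dict
    assert got.metadata == want.metadata
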