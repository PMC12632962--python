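"""Envelope normalization, centroids, and deuterium uptake.

Peak positions are treated as exact 1 Da steps indexed 0, 1, 2, ... from the
lowest reported peak; charge-state deconvolution is assumed to have been
done upstream.  Uptake at time t is centroid(t) minus the centroid of the
0 s timepoint of the same peptide and replicate; a replicate that has no
0 s sample is referenced to the mean zero-centroid of the replicates that
do (the HDX Workbench convention).  Rounding (to two decimals) happens only
at serialization, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import Envelope, HXMSError

#: Series key: (start, end, mod, rep, ptm_id).
SeriesKey = tuple[int, int, str, int, str]


class MissingZeroError(HXMSError):
    """No 0 s timepoint (and no substitute reference) is available."""


@dataclass
class CentroidSeries:
    """Centroid time course of one peptide/mode/replicate/PTM combination."""

    key: SeriesKey
    points: list[tuple[float, float]] = field(default_factory=list)  # (time_sec, centroid)

    @property
    def rep(self) -> int:
        return self.key[3]

    def sort(self) -> None:
        self.points.sort(key=lambda p: p[0])

    def zero_centroid(self) -> float | None:
        """Centroid of the 0 s point, or None if the series has no zero."""
        for t, c in self.points:
            if t == 0:
                return c
        return None


def normalize_envelope(raw) -> Envelope:
    """Scale non-negative intensities to unit sum."""
    values = [float(x) for x in raw]
    if not values:
        raise HXMSError("cannot normalize an empty envelope")
    if any(x < 0 for x in values):
        raise HXMSError("cannot normalize an envelope with negative intensities")
    total = sum(values)
    if total == 0:
        raise HXMSError("cannot normalize an all-zero envelope")
    return Envelope(x / total for x in values)


def centroid(e: Envelope) -> float:
    """Intensity-weighted first moment, in Da from the first reported peak."""
    return sum(i * p for i, p in enumerate(e))


def compute_uptake(series: CentroidSeries,
                   zero_reference: float | None = None) -> list[tuple[float, float]]:
    """Uptake per timepoint: centroid(t) − centroid(0).

    The zero centroid comes from the series' own 0 s point when present,
    else from ``zero_reference``.  The 0 s point itself reports exactly 0.
    """
    zero = series.zero_centroid()
    if zero is None:
        zero = zero_reference
    if zero is None:
        raise MissingZeroError(
            f"series {series.key} has no 0 s timepoint and no zero reference")
    return [(t, 0.0 if t == 0 else c - zero) for t, c in series.points]


def zero_reference(peptide_series: list[CentroidSeries]) -> dict[int, float]:
    """Zero-centroid per replicate for one peptide (same start/end/mod/ptm).

    Replicates with their own 0 s point use it; replicates without one get
    the arithmetic mean of the zero-centroids of the replicates that have
    one.  Raises :class:`MissingZeroError` when no replicate has a zero.
    """
    own = {s.rep: s.zero_centroid() for s in peptide_series}
    observed = [z for z in own.values() if z is not None]
    if not observed:
        keys = sorted({s.key[:3] + (s.key[4],) for s in peptide_series})
        raise MissingZeroError(f"no replicate of peptide {keys[0]} has a 0 s timepoint")
    fallback = sum(observed) / len(observed)
    return {rep: (z if z is not None else fallback) for rep, z in own.items()}
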