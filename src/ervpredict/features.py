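"""Encode raw insertion factors as the normalized 4-vector the network consumes.

Boolean factors: orientation (1 = sense) and family (1 = ETn/MusD).
Length factors are log10-scaled and capped: intron size at 100 kb, ERV-exon
distance at 50 kb (half the maximum intron size), so both lie in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ervpredict.io_tables import ErvInsertion

INTRON_CAP_BP = 100_000
DISTANCE_CAP_BP = 50_000


@dataclass(frozen=True)
class FeatureVector:
    """Normalized network inputs: all components in [0, 1]."""

    x_orientation: float
    x_family: float
    x_intron: float
    x_distance: float
    target: Optional[float] = None

    def as_array(self) -> np.ndarray:
        return np.array([self.x_orientation, self.x_family, self.x_intron, self.x_distance], dtype=float)


def normalize_length(length_bp, cap_bp: int):
    """Map a length in bp to [0, 1] via log10(length)/log10(cap).

    Lengths above the cap saturate at 1; lengths <= 1 bp map to 0 (a 0 bp
    distance is clamped to 1 bp before the log, since log10(0) is undefined).
    Accepts scalars or arrays.
    """
    if cap_bp <= 1:
        raise ValueError(f"cap_bp must exceed 1, got {cap_bp}")
    arr = np.asarray(length_bp, dtype=float)
    if np.any(arr < 0):
        raise ValueError("length_bp must be non-negative")
    out = np.log10(np.clip(arr, 1.0, float(cap_bp))) / math.log10(cap_bp)
    return float(out) if np.isscalar(length_bp) or arr.ndim == 0 else out


def denormalize_length(u, cap_bp: int):
    """Inverse of :func:`normalize_length` on (1, cap]: 10**(u * log10(cap))."""
    if cap_bp <= 1:
        raise ValueError(f"cap_bp must exceed 1, got {cap_bp}")
    arr = np.asarray(u, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("u must lie in [0, 1]")
    out = np.power(10.0, arr * math.log10(cap_bp))
    return float(out) if np.isscalar(u) or arr.ndim == 0 else out


_TARGET = {"positive": 1.0, "negative": 0.0}


def encode_insertion(rec: ErvInsertion) -> FeatureVector:
    """Encode one record; the target is present only for labeled records."""
    for fld in ("family", "orientation", "intron_size_bp", "exon_distance_bp"):
        if getattr(rec, fld, None) is None:
            raise ValueError(f"record {rec.id!r}: missing factor {fld!r}")
    return FeatureVector(
        x_orientation=1.0 if rec.orientation == "sense" else 0.0,
        x_family=1.0 if rec.family == "ETnMusD" else 0.0,
        x_intron=normalize_length(rec.intron_size_bp, INTRON_CAP_BP),
        x_distance=normalize_length(rec.exon_distance_bp, DISTANCE_CAP_BP),
        target=_TARGET.get(rec.label) if rec.label else None,
    )


def encode_table(records: Sequence[ErvInsertion]):
    """Encode a sequence of records into (X, t) arrays.

    X has shape (n, 4) with columns orientation, family, intron, distance;
    t has shape (n,) and holds NaN where a record is unlabeled.
    """
    vecs = [encode_insertion(r) for r in records]
    X = np.array([v.as_array() for v in vecs], dtype=float)
    t = np.array([v.target if v.target is not None else np.nan for v in vecs], dtype=float)
    return X, t
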