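"""Pairwise sequence distances (p-distance, JC69) with pairwise deletion.

Sites where either row carries a gap, a ``?`` or any IUPAC ambiguity code are
excluded pair by pair.  JC69 returns ``math.inf`` as a saturation sentinel
when the observed proportion of differences reaches the model ceiling of 3/4.
"""

from __future__ import annotations

import math
from typing import Sequence, Union

import numpy as np

from .model import SequenceRecord

__all__ = ["encode", "pairwise_distance", "distance_matrix", "SaturationError"]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
MISSING = 255


class SaturationError(ValueError):
    """All pairs saturated / no comparable sites."""


def encode(residues: str) -> np.ndarray:
    """Encode a row as uint8: A,C,G,T -> 0..3; everything else -> missing."""
    arr = np.full(len(residues), MISSING, dtype=np.uint8)
    for i, ch in enumerate(residues.upper()):
        code = _CODE.get(ch)
        if code is not None:
            arr[i] = code
    return arr


def _as_array(row: Union[str, np.ndarray]) -> np.ndarray:
    if isinstance(row, str):
        return encode(row)
    return row


def _p_distance(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    usable = (a != MISSING) & (b != MISSING)
    n = int(usable.sum())
    if n == 0:
        raise SaturationError("zero comparable sites between rows")
    diff = int((a[usable] != b[usable]).sum())
    return diff / n, n


def jc69(p: float) -> float:
    """JC69 distance; +inf sentinel when p >= 3/4 (outside the model domain)."""
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def pairwise_distance(
    row_a: Union[str, np.ndarray],
    row_b: Union[str, np.ndarray],
    model: str = "JC69",
) -> float:
    """Distance between two equal-length aligned rows under ``model``.

    model: ``p`` (raw proportion of differences) or ``JC69`` (default).
    """
    a, b = _as_array(row_a), _as_array(row_b)
    if len(a) != len(b):
        raise ValueError("rows have unequal aligned lengths")
    p, _ = _p_distance(a, b)
    if model in ("p", "p-distance"):
        return p
    if model == "JC69":
        return jc69(p)
    raise ValueError(f"unknown distance model {model!r}")


def distance_matrix(
    rows: dict[str, Union[str, np.ndarray]],
    model: str = "JC69",
) -> tuple[list[str], np.ndarray]:
    """All-pairs distance matrix over labelled rows (sorted label order).

    Raises :class:`SaturationError` naming the first pair with zero comparable
    sites.
    """
    labels = sorted(rows)
    arrays = [_as_array(rows[l]) for l in labels]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = pairwise_distance(arrays[i], arrays[j], model=model)
            except SaturationError as exc:
                raise SaturationError(
                    f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
                ) from exc
    return labels, d
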