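"""Amino-acid composition profiling and Kullback-Leibler comparison.

A proteome's composition is a 20-residue frequency vector (ambiguity codes
are excluded from numerator and denominator, keeping the vector on the
simplex).  Two comparisons are supported:

* **fractional-difference profiles** against a reference composition of
  fully disordered proteins: delta_i = (C_X,i - C_ref,i) / C_ref,i, plotted
  in order of increasing disorder propensity.  Residues with zero reference
  frequency are flagged undefined rather than silently zeroed.
* **symmetrized Kullback-Leibler divergence** between compositions,
  0.5 * (KL(p||q) + KL(q||p)) with natural logarithms, with the published
  similarity bands: < 0.01 similar, 0.01-0.05 gray zone, > 0.05 unlikely to
  be similar, > 0.1 non-similar.

Zeros are regularized with a pseudocount of 0.5 per residue count before
frequencies are formed, since KL is undefined on empty support.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ProteinRecord
from .scales import AA_INDEX, FDD_COMPOSITION, STANDARD_AA, propensity_order

DEFAULT_PSEUDOCOUNT = 0.5

SIMILARITY_BANDS = ("similar", "gray", "unlikely_similar", "non_similar")


@dataclass
class CompositionVector:
    """Residue counts over the 20 standard amino acids (order ACDE...WY)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (20,):
            raise ValueError("counts must have one entry per standard residue")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("counts must be non-negative and finite")
        self.counts = counts

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty composition")
        return self.counts / self.total

    def frequency(self, residue: str) -> float:
        return float(self.frequencies[AA_INDEX[residue]])

    @classmethod
    def from_counts(cls, counts: Mapping[str, float]) -> "CompositionVector":
        arr = np.zeros(20)
        for aa, c in counts.items():
            arr[AA_INDEX[aa]] = c
        return cls(arr)

    @classmethod
    def from_frequencies(
        cls, frequencies: Mapping[str, float] | Sequence[float], total: float = 1.0
    ) -> "CompositionVector":
        """Build from frequencies, optionally scaled to an effective total."""
        if isinstance(frequencies, Mapping):
            arr = np.zeros(20)
            for aa, f in frequencies.items():
                arr[AA_INDEX[aa]] = f
        else:
            arr = np.asarray(frequencies, dtype=float)
        return cls(arr * total)


@dataclass
class CompositionProfile:
    """Fractional differences against a reference, in propensity order."""

    residues: tuple[str, ...]
    deltas: np.ndarray
    undefined_mask: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.residues,
                "delta": self.deltas,
                "undefined": self.undefined_mask,
            }
        )


@dataclass
class KLMatrix:
    """Symmetric matrix of pairwise KL divergences with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if values.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if np.any(values < 0):
            raise ValueError("divergences must be non-negative")
        if not np.allclose(values, values.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0):
            raise ValueError("diagonal must be zero")
        self.values = values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def bands(self) -> pd.DataFrame:
        band = np.empty(self.values.shape, dtype=object)
        for i in range(self.values.shape[0]):
            for j in range(self.values.shape[1]):
                band[i, j] = similarity_class(self.values[i, j])
        return pd.DataFrame(band, index=self.labels, columns=self.labels)


# Reference composition of fully disordered sequence sets (synthetic
# stand-in constants; see scales.FDD_COMPOSITION).
FDD_REFERENCE = CompositionVector.from_frequencies(FDD_COMPOSITION, total=10_000)


def composition(seqs: Iterable[ProteinRecord]) -> CompositionVector:
    """Pooled residue composition of a set of sequences.

    Ambiguity codes are excluded from both numerator and denominator;
    sequences with no standard residues at all raise "empty composition".
    """
    counter: Counter = Counter()
    for rec in seqs:
        counter.update(rec.sequence)
    arr = np.zeros(20)
    for aa, idx in AA_INDEX.items():
        arr[idx] = counter.get(aa, 0)
    if arr.sum() == 0:
        raise ValueError("empty composition")
    return CompositionVector(arr)


def fractional_difference(
    cx: CompositionVector,
    cref: CompositionVector = FDD_REFERENCE,
    residue_order: Sequence[str] | None = None,
) -> CompositionProfile:
    """(C_X - C_ref) / C_ref per residue, ordered by disorder propensity."""
    order = tuple(residue_order) if residue_order is not None else propensity_order()
    fx = cx.frequencies
    fr = cref.frequencies
    deltas = np.empty(len(order))
    undefined = np.zeros(len(order), dtype=bool)
    for k, aa in enumerate(order):
        i = AA_INDEX[aa]
        if fr[i] > 0:
            deltas[k] = (fx[i] - fr[i]) / fr[i]
        else:
            deltas[k] = np.nan
            undefined[k] = True
    return CompositionProfile(order, deltas, undefined)


def symmetric_kl(p: Sequence[float], q: Sequence[float]) -> float:
    """0.5 * (KL(p||q) + KL(q||p)) with natural logs, on strictly positive
    distributions of any common length."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must share support")
    if np.any(p <= 0) or np.any(q <= 0):
        raise ValueError("unsupported composition")
    p = p / p.sum()
    q = q / q.sum()
    return float(0.5 * (np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p))))


def _regularized_frequencies(
    cv: CompositionVector, pseudocount: float
) -> np.ndarray:
    counts = cv.counts
    if np.any(counts == 0):
        counts = counts + pseudocount
    if np.any(counts <= 0):
        raise ValueError("unsupported composition")
    return counts / counts.sum()


def kl_divergence(
    p: CompositionVector,
    q: CompositionVector,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Symmetrized KL divergence between two compositions.

    Vectors containing zero counts are regularized by adding ``pseudocount``
    to every count of that vector before forming frequencies.
    """
    return symmetric_kl(
        _regularized_frequencies(p, pseudocount),
        _regularized_frequencies(q, pseudocount),
    )


def similarity_class(d: float) -> str:
    """Published similarity band of a divergence value."""
    if not np.isfinite(d) or d < 0:
        raise ValueError("invalid divergence")
    if d < 0.01:
        return "similar"
    if d <= 0.05:
        return "gray"
    if d <= 0.1:
        return "unlikely_similar"
    return "non_similar"


def kl_matrix(
    compositions: Mapping[str, CompositionVector],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> KLMatrix:
    """Pairwise symmetrized KL divergences among labelled compositions."""
    labels = tuple(compositions)
    if len(labels) < 2:
        raise ValueError("need at least two datasets")
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = kl_divergence(
                compositions[labels[i]], compositions[labels[j]], pseudocount
            )
            values[i, j] = values[j, i] = d
    return KLMatrix(labels, values)
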