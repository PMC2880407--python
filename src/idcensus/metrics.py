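"""Proteome-level disorder-content measures.

Three measures summarize how much intrinsic disorder a proteome carries:

* ``idaa`` — fraction of disordered residues, pooled over all residues of
  the proteome (a protein-averaged variant is available as an option);
* ``idp30`` (:func:`fraction_long_idr`) — fraction of proteins containing
  at least one disordered run of more than ``min_run`` consecutive residues
  (strictly greater; at the default 30 a 31-residue run qualifies, a
  30-residue run does not);
* ``widp`` (:func:`fraction_wholly_disordered`) — fraction of proteins
  classified wholly disordered by a whole-protein classifier, here by the
  sign of the CDF distance (negative = disordered side).

A residue is called disordered when its score is greater than or equal to
the threshold; equality goes to disordered so thresholds behave as infima.
Segment coordinates are 1-based inclusive internally and exported as
standard 0-based half-open BED.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring import DisorderProfile


@dataclass(frozen=True)
class DisorderSegment:
    """A maximal run of disordered residues (1-based inclusive)."""

    protein_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("invalid segment coordinates")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DisorderMeasures:
    """The three proteome-level disorder measures for one species."""

    species_id: str
    idaa: float
    idp30: float
    widp: float

    def __post_init__(self) -> None:
        for name in ("idaa", "idp30", "widp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")


@dataclass(frozen=True)
class DomainDisorderStats:
    """Per-domain disorder statistics (percent disordered, region count)."""

    domain_id: str
    percent_disordered: float
    n_regions: int
    region_lengths: tuple[int, ...]


def binarize(profile: DisorderProfile, threshold: float = 0.5) -> np.ndarray:
    """Per-residue order/disorder calls; score >= threshold is disordered."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return profile.scores >= threshold


def extract_segments(labels: Sequence[bool], protein_id: str) -> list[DisorderSegment]:
    """Every maximal run of disordered labels, in order, unfiltered."""
    arr = np.asarray(labels, dtype=bool)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("empty label vector")
    padded = np.concatenate(([False], arr, [False])).astype(np.int8)
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1) + 1  # 1-based
    ends = np.flatnonzero(diff == -1)
    return [DisorderSegment(protein_id, int(s), int(e)) for s, e in zip(starts, ends)]


def _as_profiles(profiles) -> list[DisorderProfile]:
    if isinstance(profiles, Mapping):
        profiles = profiles.values()
    out = list(profiles)
    if not out:
        raise ValueError("no profiles")
    return out


def idaa(
    profiles: Iterable[DisorderProfile] | Mapping[str, DisorderProfile],
    threshold: float = 0.5,
    pooled: bool = True,
) -> float:
    """Fraction of disordered residues in a proteome.

    Pooled over residues by default (total disordered residues over total
    residues); ``pooled=False`` averages per-protein fractions instead.
    """
    profs = _as_profiles(profiles)
    fractions = []
    disordered = total = 0
    for prof in profs:
        calls = binarize(prof, threshold)
        disordered += int(calls.sum())
        total += calls.size
        fractions.append(calls.mean())
    if pooled:
        return disordered / total
    return float(np.mean(fractions))


def fraction_long_idr(
    profiles: Iterable[DisorderProfile] | Mapping[str, DisorderProfile],
    threshold: float = 0.5,
    min_run: int = 30,
) -> float:
    """Fraction of proteins with a disordered run strictly longer than min_run."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    profs = _as_profiles(profiles)
    qualifying = 0
    for prof in profs:
        segments = extract_segments(binarize(prof, threshold), prof.protein_id)
        if any(seg.length > min_run for seg in segments):
            qualifying += 1
    return qualifying / len(profs)


def fraction_wholly_disordered(cdf_distances: Iterable[float]) -> float:
    """Fraction of proteins on the disordered side of the CDF boundary.

    A distance of exactly zero counts as ordered (the >= tie goes to the
    ordered side), so only strictly negative distances enter the numerator.
    """
    distances = np.asarray(list(cdf_distances), dtype=float)
    if distances.size == 0:
        raise ValueError("no classifications")
    return float((distances < 0).mean())


def domain_disorder_stats(
    profile: DisorderProfile, threshold: float = 0.5
) -> DomainDisorderStats:
    """Percent disordered (one decimal) and disordered-region census of a domain."""
    calls = binarize(profile, threshold)
    segments = extract_segments(calls, profile.protein_id) if calls.any() else []
    percent = round(100.0 * calls.mean(), 1)
    return DomainDisorderStats(
        profile.protein_id,
        percent,
        len(segments),
        tuple(seg.length for seg in segments),
    )


def measures_table(measures: Iterable[DisorderMeasures]) -> pd.DataFrame:
    """Tabulate per-species measures (columns species_id, idaa, idp30, widp)."""
    return pd.DataFrame(
        [
            {
                "species_id": m.species_id,
                "idaa": m.idaa,
                "idp30": m.idp30,
                "widp": m.widp,
            }
            for m in measures
        ]
    )


def segments_to_bed(
    segments: Iterable[DisorderSegment],
    path,
    scores_by_id: Mapping[str, DisorderProfile] | None = None,
) -> None:
    """Export segments as BED (0-based half-open).

    Column 4 is the protein id; column 5 carries the mean residue score of
    the segment when profiles are supplied, otherwise 0.
    """
    with open(path, "w") as fh:
        for seg in segments:
            score = 0.0
            if scores_by_id is not None and seg.protein_id in scores_by_id:
                prof = scores_by_id[seg.protein_id]
                score = float(prof.scores[seg.start - 1 : seg.end].mean())
            fh.write(
                f"{seg.protein_id}\t{seg.start - 1}\t{seg.end}\t"
                f"{seg.protein_id}\t{score:.4f}\n"
            )
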