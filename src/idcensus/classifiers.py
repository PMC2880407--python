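"""Whole-protein binary order/disorder classifiers.

Two complementary classifiers assign a single order/disorder call to an
entire protein:

* **CDF analysis** — the cumulative distribution of a protein's per-residue
  disorder scores is compared against a boundary calibrated between groups
  of fully ordered and fully disordered proteins.  Structured proteins have
  mostly low scores, so their CDF saturates early and runs above the
  boundary; the signed mean gap over the calibrated ("active") cutpoints is
  the CDF distance, positive meaning ordered.
* **charge-hydropathy (CH) plot** — each protein maps to a point
  (normalized mean Kyte-Doolittle hydropathy, absolute mean net charge); a
  straight line (default ``<R> = 2.785 <H> - 1.151``) separates extended
  disordered from compact proteins.  The signed vertical distance from the
  line is the CH distance, positive meaning disordered.

Combining both signs yields the CH-CDF quadrant classification:
(CDF-, CH-) molten-globule-like, (CDF-, CH+) extended disordered,
(CDF+, CH-) ordered, (CDF+, CH+) disordered by CH but ordered by CDF.
Zero distances fall on the CDF-ordered / CH-disordered sides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .io import ProteinRecord
from .scales import KYTE_DOOLITTLE, RESIDUE_CHARGE, STANDARD_AA
from .scoring import DisorderProfile

#: Default CDF cutpoint grid: k/20 for k = 1..20.
DEFAULT_CDF_GRID = np.arange(1, 21) / 20.0

#: Published CH boundary coefficients (Uversky et al., 2000).
DEFAULT_CH_SLOPE = 2.785
DEFAULT_CH_INTERCEPT = -1.151

QUADRANTS = (
    "ordered",
    "extended_disordered",
    "molten_globule_like",
    "ch_disordered_cdf_ordered",
)

# Byte-indexed lookup tables so CH coordinates vectorize over raw sequences.
_KD_TABLE = np.zeros(256)
_CHARGE_TABLE = np.zeros(256)
_STANDARD_MASK = np.zeros(256, dtype=bool)
for _aa in STANDARD_AA:
    _KD_TABLE[ord(_aa)] = KYTE_DOOLITTLE[_aa]
    _CHARGE_TABLE[ord(_aa)] = RESIDUE_CHARGE.get(_aa, 0.0)
    _STANDARD_MASK[ord(_aa)] = True


@dataclass
class CDFCurve:
    """Cumulative fraction of residues at or below each score cutpoint."""

    thresholds: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.thresholds.shape != self.values.shape:
            raise ValueError("thresholds/values shape mismatch")
        if np.any(np.diff(self.values) < 0):
            raise ValueError("CDF values must be non-decreasing")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("CDF values must lie in [0, 1]")


@dataclass
class CDFBoundary:
    """Calibrated midline between ordered and disordered mean CDF curves."""

    thresholds: np.ndarray
    boundary_values: np.ndarray
    active_bins: np.ndarray
    training_accuracy: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.boundary_values = np.asarray(self.boundary_values, dtype=float)
        self.active_bins = np.asarray(self.active_bins, dtype=bool)
        if not (
            self.thresholds.shape
            == self.boundary_values.shape
            == self.active_bins.shape
        ):
            raise ValueError("boundary arrays must share one grid")
        if self.boundary_values.min() < 0 or self.boundary_values.max() > 1:
            raise ValueError("boundary values must lie in [0, 1]")


@dataclass(frozen=True)
class CHPoint:
    """Charge-hydropathy coordinates of one protein, both in [0, 1]."""

    mean_hydropathy: float
    mean_net_charge: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_hydropathy <= 1.0 and 0.0 <= self.mean_net_charge <= 1.0):
            raise ValueError("CH coordinates must lie in [0, 1]")


@dataclass(frozen=True)
class WholeProteinCall:
    """Joint CDF/CH classification of one protein."""

    protein_id: str
    mean_hydropathy: float
    mean_net_charge: float
    cdf_distance: float
    ch_distance: float
    quadrant: str


def _validate_grid(thresholds: np.ndarray) -> np.ndarray:
    th = np.asarray(thresholds, dtype=float)
    if th.size < 1 or np.any(np.diff(th) <= 0) or th.min() <= 0 or th.max() > 1:
        raise ValueError("thresholds must be strictly increasing within (0, 1]")
    return th


def cdf_curve(
    profile: DisorderProfile, thresholds: np.ndarray | None = None
) -> CDFCurve:
    """Empirical CDF of a profile's scores on the cutpoint grid."""
    th = DEFAULT_CDF_GRID if thresholds is None else _validate_grid(thresholds)
    scores = profile.scores
    if scores.size == 0:
        raise ValueError("no residues")
    sorted_scores = np.sort(scores)
    values = np.searchsorted(sorted_scores, th, side="right") / scores.size
    return CDFCurve(th.copy(), values)


def calibrate_cdf_boundary(
    ordered_curves: Iterable[CDFCurve],
    disordered_curves: Iterable[CDFCurve],
    separation_tol: float = 0.02,
) -> CDFBoundary:
    """Fit the boundary as the midline of the two class-mean CDF curves.

    Cutpoints where the class means differ by more than ``separation_tol``
    become the active bins over which distances are averaged; if no
    cutpoint separates the classes the calibration fails ("classes
    inseparable").  The classification accuracy on the training curves is
    recorded on the boundary.
    """
    oc = list(ordered_curves)
    dc = list(disordered_curves)
    if not oc or not dc:
        raise ValueError("need both classes")
    grid = oc[0].thresholds
    for curve in oc + dc:
        if curve.thresholds.shape != grid.shape or not np.allclose(
            curve.thresholds, grid
        ):
            raise ValueError("incompatible grids")
    mean_ordered = np.mean([c.values for c in oc], axis=0)
    mean_disordered = np.mean([c.values for c in dc], axis=0)
    active = np.abs(mean_ordered - mean_disordered) > separation_tol
    if not active.any():
        raise ValueError("classes inseparable")
    boundary = CDFBoundary(
        grid.copy(),
        (mean_ordered + mean_disordered) / 2.0,
        active,
        provenance={
            "n_ordered": len(oc),
            "n_disordered": len(dc),
            "separation_tol": separation_tol,
        },
    )
    correct = sum(cdf_distance(c, boundary) >= 0 for c in oc)
    correct += sum(cdf_distance(c, boundary) < 0 for c in dc)
    boundary.training_accuracy = correct / (len(oc) + len(dc))
    return boundary


def cdf_distance(curve: CDFCurve, boundary: CDFBoundary) -> float:
    """Signed mean gap over active bins; positive means ordered."""
    if curve.thresholds.shape != boundary.thresholds.shape or not np.allclose(
        curve.thresholds, boundary.thresholds
    ):
        raise ValueError("incompatible grids")
    gap = curve.values[boundary.active_bins] - boundary.boundary_values[boundary.active_bins]
    return float(gap.mean())


def ch_point(record: ProteinRecord) -> CHPoint:
    """Charge-hydropathy coordinates of a protein.

    ``<H>`` is the mean Kyte-Doolittle value over standard residues,
    rescaled by (KD + 4.5) / 9 into [0, 1]; ``<R>`` is the absolute mean net
    charge |K + R - D - E| / n over standard residues (histidine neutral,
    terminal charges ignored).  Ambiguity codes are excluded from both
    denominators.
    """
    codes = np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8)
    mask = _STANDARD_MASK[codes]
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no scorable residues")
    kd_mean = _KD_TABLE[codes[mask]].mean()
    net_charge = _CHARGE_TABLE[codes[mask]].sum()
    return CHPoint((kd_mean + 4.5) / 9.0, abs(net_charge) / n)


def ch_distance(
    point: CHPoint,
    slope: float = DEFAULT_CH_SLOPE,
    intercept: float = DEFAULT_CH_INTERCEPT,
) -> float:
    """Signed vertical distance from the CH boundary; positive = disordered."""
    return point.mean_net_charge - (slope * point.mean_hydropathy + intercept)


def classify_ch_cdf(cdf_d: float, ch_d: float) -> str:
    """CH-CDF quadrant of a (CDF distance, CH distance) pair.

    Negative CDF distance means disordered by CDF; non-negative CH distance
    means disordered by the CH plot (zero distances take the CDF-ordered
    and CH-disordered sides).
    """
    if cdf_d < 0:
        return "molten_globule_like" if ch_d < 0 else "extended_disordered"
    return "ordered" if ch_d < 0 else "ch_disordered_cdf_ordered"


def classify_proteins(
    records: Iterable[ProteinRecord],
    profiles: Mapping[str, DisorderProfile],
    boundary: CDFBoundary,
    slope: float = DEFAULT_CH_SLOPE,
    intercept: float = DEFAULT_CH_INTERCEPT,
) -> list[WholeProteinCall]:
    """Joint CDF/CH calls for every record with a matching profile."""
    calls = []
    for rec in records:
        prof = profiles[rec.id]
        point = ch_point(rec)
        cdf_d = cdf_distance(cdf_curve(prof, boundary.thresholds), boundary)
        ch_d = ch_distance(point, slope, intercept)
        calls.append(
            WholeProteinCall(
                rec.id,
                point.mean_hydropathy,
                point.mean_net_charge,
                cdf_d,
                ch_d,
                classify_ch_cdf(cdf_d, ch_d),
            )
        )
    return calls


def chcdf_summary(calls: Iterable[WholeProteinCall]) -> dict:
    """Per-quadrant counts plus mean and RMSD of each distance.

    RMSD is computed about the mean (the error-bar convention of averaged
    CH-CDF plots).
    """
    call_list = list(calls)
    if not call_list:
        raise ValueError("no calls")
    cdf_d = np.array([c.cdf_distance for c in call_list])
    ch_d = np.array([c.ch_distance for c in call_list])
    counts = {q: 0 for q in QUADRANTS}
    for c in call_list:
        counts[c.quadrant] += 1
    return {
        "n": len(call_list),
        "counts": counts,
        "cdf_mean": float(cdf_d.mean()),
        "cdf_rmsd": float(np.sqrt(((cdf_d - cdf_d.mean()) ** 2).mean())),
        "ch_mean": float(ch_d.mean()),
        "ch_rmsd": float(np.sqrt(((ch_d - ch_d.mean()) ** 2).mean())),
    }


def calls_table(calls: Iterable[WholeProteinCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": c.protein_id,
                "mean_hydropathy": c.mean_hydropathy,
                "mean_net_charge": c.mean_net_charge,
                "ch_distance": c.ch_distance,
                "cdf_distance": c.cdf_distance,
                "quadrant": c.quadrant,
            }
            for c in calls
        ]
    )


def save_boundary(boundary: CDFBoundary, path) -> None:
    """Persist a calibrated boundary as a small JSON document."""
    doc = {
        "thresholds": boundary.thresholds.tolist(),
        "boundary_values": boundary.boundary_values.tolist(),
        "active_bins": boundary.active_bins.astype(int).tolist(),
        "training_accuracy": boundary.training_accuracy,
        "provenance": boundary.provenance,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_boundary(path) -> CDFBoundary:
    with open(path) as fh:
        doc = json.load(fh)
    return CDFBoundary(
        np.asarray(doc["thresholds"], dtype=float),
        np.asarray(doc["boundary_values"], dtype=float),
        np.asarray(doc["active_bins"], dtype=bool),
        doc.get("training_accuracy"),
        doc.get("provenance", {}),
    )


class CDFClassifier(BaseEstimator, ClassifierMixin):
    """CDF-boundary whole-protein classifier (sklearn-style).

    ``fit(X, y)`` takes disorder profiles and string labels
    ("ordered"/"disordered") and calibrates the boundary;
    ``decision_function`` returns signed CDF distances (positive = ordered)
    and ``predict`` thresholds them at zero with the >= tie going to
    ordered.
    """

    def __init__(self, thresholds=None, separation_tol: float = 0.02):
        self.thresholds = thresholds
        self.separation_tol = separation_tol

    def fit(self, X, y):
        y = np.asarray(y, dtype=object)
        grid = DEFAULT_CDF_GRID if self.thresholds is None else _validate_grid(
            np.asarray(self.thresholds, dtype=float)
        )
        curves = [cdf_curve(p, grid) for p in X]
        ordered = [c for c, lab in zip(curves, y) if lab == "ordered"]
        disordered = [c for c, lab in zip(curves, y) if lab == "disordered"]
        self.boundary_ = calibrate_cdf_boundary(
            ordered, disordered, self.separation_tol
        )
        self.classes_ = np.array(["disordered", "ordered"], dtype=object)
        self.training_accuracy_ = self.boundary_.training_accuracy
        return self

    def decision_function(self, X) -> np.ndarray:
        boundary = self.boundary_
        return np.array(
            [cdf_distance(cdf_curve(p, boundary.thresholds), boundary) for p in X]
        )

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        return np.where(d >= 0, "ordered", "disordered").astype(object)


class CHClassifier(BaseEstimator, ClassifierMixin):
    """Charge-hydropathy whole-protein classifier (sklearn-style).

    The boundary line is fixed by its ``slope`` and ``intercept``
    parameters, so ``fit`` only validates; ``decision_function`` returns
    signed CH distances (positive = disordered).
    """

    def __init__(
        self,
        slope: float = DEFAULT_CH_SLOPE,
        intercept: float = DEFAULT_CH_INTERCEPT,
    ):
        self.slope = slope
        self.intercept = intercept

    def fit(self, X=None, y=None):
        self.classes_ = np.array(["disordered", "ordered"], dtype=object)
        self.is_fitted_ = True
        return self

    def decision_function(self, X) -> np.ndarray:
        return np.array(
            [ch_distance(ch_point(rec), self.slope, self.intercept) for rec in X]
        )

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        return np.where(d >= 0, "disordered", "ordered").astype(object)
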