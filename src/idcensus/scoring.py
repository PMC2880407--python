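"""Per-residue disorder scoring.

The census needs a per-residue disorder score in [0, 1] for every protein.
Two routes are provided:

* a bundled propensity-scale predictor: the TOP-IDP value of each residue is
  averaged over a sliding window (truncated at the chain ends) and min-max
  rescaled to [0, 1] using the scale's extreme values.  This is a
  transparent, weight-free stand-in for trained per-residue predictors such
  as the PONDR family; its absolute scores are not comparable to theirs, but
  the 0.5 decision convention and all downstream machinery are identical.
* an importer for externally computed score tables (TSV with columns
  ``protein_id  position  residue  score``), cross-checked against the FASTA
  sequences, so genuine PONDR/IUPred outputs can drive the same pipeline.

The binary decision threshold defaults to 0.5 (scores >= threshold are
called disordered) and can be re-calibrated on labelled data by maximizing
balanced per-residue accuracy on a 0.01-step grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ProteinRecord, Proteome
from .scales import STANDARD_AA, TOP_IDP


@dataclass(frozen=True)
class PropensityScale:
    """A named map from the 20 standard residues to disorder propensities."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(STANDARD_AA) - set(self.values)
        if missing:
            raise ValueError(f"scale '{self.name}' missing residues: {sorted(missing)}")
        if self.vmax <= self.vmin:
            raise ValueError(f"scale '{self.name}' is degenerate (max <= min)")

    @property
    def vmin(self) -> float:
        return min(self.values[aa] for aa in STANDARD_AA)

    @property
    def vmax(self) -> float:
        return max(self.values[aa] for aa in STANDARD_AA)

    @property
    def vmean(self) -> float:
        return sum(self.values[aa] for aa in STANDARD_AA) / len(STANDARD_AA)


TOPIDP_SCALE = PropensityScale("topidp", TOP_IDP)

#: Registry used when scales are referred to by name (CLI, estimators).
SCALES: dict[str, PropensityScale] = {"topidp": TOPIDP_SCALE}


@dataclass
class DisorderProfile:
    """Per-residue disorder scores in [0, 1] aligned to one sequence."""

    protein_id: str
    scores: np.ndarray
    predictor_tag: str = ""

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 1 or scores.size == 0:
            raise ValueError("scores must be a non-empty 1-d array")
        if not np.all(np.isfinite(scores)):
            raise ValueError("non-finite score")
        if scores.min() < -1e-9 or scores.max() > 1 + 1e-9:
            raise ValueError("score out of range")
        self.scores = np.clip(scores, 0.0, 1.0)

    def __len__(self) -> int:
        return self.scores.size


def score_sequence(
    record: ProteinRecord,
    scale: PropensityScale = TOPIDP_SCALE,
    window: int = 21,
) -> DisorderProfile:
    """Score one sequence with the sliding-window propensity predictor.

    The raw propensity of each position (ambiguity codes receive the scale
    mean) is averaged over a centred window truncated at the chain ends and
    min-max rescaled with the scale's extreme values, so a homopolymer of
    the most disorder-prone residue scores 1.0 everywhere and one of the
    least disorder-prone residue scores 0.0.  Sequences shorter than the
    window receive the whole-chain mean at every position.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd")
    vals = scale.values
    mean_val = scale.vmean
    raw = np.array([vals.get(aa, mean_val) for aa in record.sequence], dtype=float)
    n = raw.size
    if n < window:
        smoothed = np.full(n, raw.mean())
    else:
        half = window // 2
        csum = np.concatenate(([0.0], np.cumsum(raw)))
        idx = np.arange(n)
        lo = np.maximum(0, idx - half)
        hi = np.minimum(n, idx + half + 1)
        smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    scores = (smoothed - scale.vmin) / (scale.vmax - scale.vmin)
    return DisorderProfile(
        record.id,
        np.clip(scores, 0.0, 1.0),
        predictor_tag=f"propensity:{scale.name}:w{window}",
    )


def score_proteome(
    proteome: Proteome,
    scale: PropensityScale = TOPIDP_SCALE,
    window: int = 21,
) -> dict[str, DisorderProfile]:
    """Score every record of a proteome; profiles keyed by protein id."""
    return {rec.id: score_sequence(rec, scale, window) for rec in proteome}


_SCORE_COLUMNS = ("protein_id", "position", "residue", "score")


def load_scores(path, proteome: Proteome) -> dict[str, DisorderProfile]:
    """Import externally computed per-residue scores from a TSV table.

    Each protein must be covered by exactly the positions 1..length, the
    residue column must agree with the FASTA sequence, and every score must
    lie in [0, 1].
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(_SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"score file missing columns: {sorted(missing)}")
    profiles: dict[str, DisorderProfile] = {}
    for pid, group in df.groupby("protein_id", sort=False):
        pid = str(pid)
        if pid not in proteome:
            raise ValueError(f"unknown protein '{pid}' in score file")
        rec = proteome[pid]
        group = group.sort_values("position")
        positions = group["position"].to_numpy()
        if not np.array_equal(positions, np.arange(1, rec.length + 1)):
            raise ValueError(f"incomplete profile for '{pid}'")
        scores = group["score"].to_numpy(dtype=float)
        if np.any(scores < 0) or np.any(scores > 1):
            raise ValueError(f"score out of range for '{pid}'")
        residues = group["residue"].astype(str).to_numpy()
        seq = np.array(list(rec.sequence))
        mism = np.flatnonzero(residues != seq)
        if mism.size:
            raise ValueError(
                f"sequence/score mismatch for '{pid}' at position {mism[0] + 1}"
            )
        profiles[pid] = DisorderProfile(pid, scores, predictor_tag="imported")
    return profiles


def write_scores(
    profiles: Mapping[str, DisorderProfile], proteome: Proteome, path
) -> None:
    """Write profiles in the tabular score-file format read by load_scores."""
    frames = []
    for pid, prof in profiles.items():
        rec = proteome[pid]
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": pid,
                    "position": np.arange(1, rec.length + 1),
                    "residue": list(rec.sequence),
                    "score": prof.scores,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def calibrate_threshold(
    labeled: Iterable[tuple[DisorderProfile, np.ndarray]],
) -> float:
    """Pick the decision threshold maximizing balanced per-residue accuracy.

    The search runs over the fixed grid 0.00, 0.01, ..., 1.00; ties are
    broken by the midpoint of the optimal grid interval, rounded back to
    the grid (half-to-even).  With no labelled data the conventional 0.5 is
    returned; single-class input raises ("cannot calibrate").
    """
    pairs = list(labeled)
    if not pairs:
        return 0.5
    scores = np.concatenate([np.asarray(p.scores, dtype=float) for p, _ in pairs])
    labels = np.concatenate([np.asarray(lab, dtype=bool) for _, lab in pairs])
    if labels.all() or not labels.any():
        raise ValueError("cannot calibrate")
    thresholds = np.arange(101) / 100.0
    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    tpr = (pos.size - np.searchsorted(pos, thresholds, side="left")) / pos.size
    tnr = np.searchsorted(neg, thresholds, side="left") / neg.size
    balanced = 0.5 * (tpr + tnr)
    best = np.flatnonzero(balanced >= balanced.max() - 1e-12)
    midpoint = (best[0] + best[-1]) / 2.0
    return float(np.round(midpoint) / 100.0)


class DisorderScorer(BaseEstimator, TransformerMixin):
    """Sliding-window propensity disorder predictor (sklearn-style).

    Parameters
    ----------
    scale : str or PropensityScale, default "topidp"
        Residue propensity scale, by registry name or as an object.
    window : int, default 21
        Odd smoothing-window width in residues.
    threshold : float, default 0.5
        Binary decision threshold used by ``predict`` when no labelled data
        are supplied to ``fit``.

    ``fit(X, y)`` with ``y`` a list of per-residue boolean label vectors
    calibrates ``threshold_`` by balanced accuracy; without ``y`` the
    configured threshold is adopted.  ``transform`` returns
    :class:`DisorderProfile` objects; ``predict`` returns boolean
    disorder-call vectors.
    """

    def __init__(self, scale="topidp", window: int = 21, threshold: float = 0.5):
        self.scale = scale
        self.window = window
        self.threshold = threshold

    def _resolve_scale(self) -> PropensityScale:
        if isinstance(self.scale, PropensityScale):
            return self.scale
        return SCALES[self.scale]

    def fit(self, X, y=None):
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd")
        self.scale_ = self._resolve_scale()
        if y is None:
            self.threshold_ = float(self.threshold)
        else:
            profiles = self.transform(X)
            self.threshold_ = calibrate_threshold(zip(profiles, y))
        return self

    def transform(self, X) -> list[DisorderProfile]:
        scale = getattr(self, "scale_", None) or self._resolve_scale()
        return [score_sequence(rec, scale, self.window) for rec in X]

    def predict(self, X) -> list[np.ndarray]:
        threshold = getattr(self, "threshold_", float(self.threshold))
        return [prof.scores >= threshold for prof in self.transform(X)]
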