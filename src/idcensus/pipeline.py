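"""End-to-end drivers tying scoring, classification and metrics together.

These helpers run the full census on simulated panels: calibrate the
per-residue decision threshold on a labelled mixed proteome, train the CDF
boundary on fully ordered vs fully disordered synthetic proteins, then
compute the three disorder measures for every species.  They are what the
acceptance checks and the worked examples drive.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .classifiers import CDFBoundary, calibrate_cdf_boundary, cdf_curve, cdf_distance
from .io import Proteome
from .metrics import DisorderMeasures, fraction_long_idr, fraction_wholly_disordered, idaa
from .scoring import (
    DisorderProfile,
    PropensityScale,
    TOPIDP_SCALE,
    calibrate_threshold,
    score_proteome,
)
from .simulate import (
    SpeciesSim,
    generate_proteome,
    make_archetype,
)

DEFAULT_WINDOW = 21


def _rng_from(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(tag,)))


def calibrate_panel_threshold(
    seed: int,
    n_proteins: int = 80,
    window: int = DEFAULT_WINDOW,
    scale: PropensityScale = TOPIDP_SCALE,
) -> float:
    """Calibrate the binary threshold on a labelled mixed calibration proteome.

    A mesophile-like archetype (disorder target 0.20) provides residues of
    both states in a realistic block structure.
    """
    arch = make_archetype("calibration_mixed", 0.20)
    proteome, truths, _ = generate_proteome(
        arch, n_proteins, rng=_rng_from(seed, 11), species_id="calibration"
    )
    profiles = score_proteome(proteome, scale, window)
    labeled = [(profiles[t.protein_id], t.labels) for t in truths]
    return calibrate_threshold(labeled)


def _reference_proteomes(
    seed: int, n_proteins: int, tag_ordered: int, tag_disordered: int
) -> tuple[Proteome, Proteome]:
    ordered, _, _ = generate_proteome(
        make_archetype("fully_ordered", 0.0),
        n_proteins,
        rng=_rng_from(seed, tag_ordered),
        species_id="fully_ordered",
    )
    disordered, _, _ = generate_proteome(
        make_archetype("fully_disordered", 1.0),
        n_proteins,
        rng=_rng_from(seed, tag_disordered),
        species_id="fully_disordered",
    )
    return ordered, disordered


def train_cdf_boundary(
    seed: int,
    n_proteins: int = 150,
    window: int = DEFAULT_WINDOW,
    scale: PropensityScale = TOPIDP_SCALE,
) -> CDFBoundary:
    """Calibrate the CDF boundary on synthetic fully ordered vs fully
    disordered training proteomes."""
    ordered, disordered = _reference_proteomes(seed, n_proteins, 21, 22)
    ordered_curves = [cdf_curve(p) for p in score_proteome(ordered, scale, window).values()]
    disordered_curves = [
        cdf_curve(p) for p in score_proteome(disordered, scale, window).values()
    ]
    return calibrate_cdf_boundary(ordered_curves, disordered_curves)


def boundary_holdout_accuracy(
    boundary: CDFBoundary,
    seed: int,
    n_per_class: int = 100,
    window: int = DEFAULT_WINDOW,
    scale: PropensityScale = TOPIDP_SCALE,
) -> float:
    """Classification accuracy of a boundary on a fresh held-out set."""
    ordered, disordered = _reference_proteomes(seed, n_per_class, 31, 32)
    correct = 0
    for p in score_proteome(ordered, scale, window).values():
        correct += cdf_distance(cdf_curve(p, boundary.thresholds), boundary) >= 0
    for p in score_proteome(disordered, scale, window).values():
        correct += cdf_distance(cdf_curve(p, boundary.thresholds), boundary) < 0
    return correct / (2 * n_per_class)


def species_measures(
    proteome: Proteome,
    boundary: CDFBoundary,
    threshold: float,
    window: int = DEFAULT_WINDOW,
    min_run: int = 30,
    scale: PropensityScale = TOPIDP_SCALE,
) -> DisorderMeasures:
    """The three disorder measures of one proteome under the full pipeline."""
    profiles = score_proteome(proteome, scale, window)
    distances = [
        cdf_distance(cdf_curve(p, boundary.thresholds), boundary)
        for p in profiles.values()
    ]
    return DisorderMeasures(
        proteome.species_id,
        idaa(profiles, threshold),
        fraction_long_idr(profiles, threshold, min_run),
        fraction_wholly_disordered(distances),
    )


def analyze_panel(
    panel: Iterable[SpeciesSim],
    threshold: float | None = None,
    boundary: CDFBoundary | None = None,
    seed: int = 0,
    window: int = DEFAULT_WINDOW,
    min_run: int = 30,
) -> pd.DataFrame:
    """Run the full census over a simulated panel.

    Returns one row per species with the generator targets, the true
    disorder fraction and the three estimated measures.  Threshold and
    boundary are calibrated from ``seed`` when not supplied.
    """
    panel = list(panel)
    if threshold is None:
        threshold = calibrate_panel_threshold(seed, window=window)
    if boundary is None:
        boundary = train_cdf_boundary(seed, window=window)
    rows = []
    for sim in panel:
        m = species_measures(sim.proteome, boundary, threshold, window, min_run)
        rows.append(
            {
                "species_id": sim.species_id,
                "archetype": sim.archetype.name,
                "target_disorder_fraction": sim.archetype.target_disorder_fraction,
                "true_disorder_fraction": sim.true_disorder_fraction,
                "idaa": m.idaa,
                "idp30": m.idp30,
                "widp": m.widp,
            }
        )
    return pd.DataFrame(rows)
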