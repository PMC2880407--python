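"""Habitat correlation and phylogenetic overlay of disorder content.

Relates the three proteome-level disorder measures to habitat factors
(optimal pH, optimal growth temperature, salinity), quantifies how well the
measures track each other across species, and paints a species tree by
disorder content.

Correlations report both Pearson's r and Spearman's rho on
pairwise-complete species; categorical salinity is rank-coded
low < normal < high.  Outliers are flagged by externally studentized
residuals from the least-squares fit (|t| > 2), a reproducible replacement
for marking points by eye on a scatter plot.

Tree leaves are colored by the percentage of disordered residues with the
bins: > 30 red, > 21 orange, > 17 yellow, > 14 light blue, otherwise dark
blue (bin edges left-open, the bottom bin closed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .metrics import DisorderMeasures, measures_table

SALINITY_RANK = {"low": 0.0, "normal": 1.0, "high": 2.0}

#: Habitat-factor aliases -> habitat-table column names.
FACTOR_COLUMNS = {
    "ph": "optimal_ph",
    "temperature": "optimal_temperature_c",
    "salinity": "salinity",
}

MEASURE_NAMES = ("idaa", "idp30", "widp")

COLOR_BINS = ("red", "orange", "yellow", "light_blue", "dark_blue")


@dataclass(frozen=True)
class HabitatRecord:
    """Environmental characteristics of one species' habitat."""

    species_id: str
    optimal_ph: float | None = None
    optimal_temperature: float | None = None
    salinity: str | float | None = None
    lifestyle_flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if (
            self.optimal_ph is None
            and self.optimal_temperature is None
            and self.salinity is None
        ):
            raise ValueError("habitat record needs at least one factor")
        if self.optimal_ph is not None and not 0.0 <= self.optimal_ph <= 14.0:
            raise ValueError("optimal pH outside [0, 14]")


@dataclass(frozen=True)
class FactorCorrelation:
    """Correlation of one disorder measure with one factor across species."""

    factor: str
    measure: str
    n: int
    pearson_r: float
    spearman_rho: float
    slope: float
    intercept: float
    outlier_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("insufficient species")


@dataclass
class AnnotatedTree:
    """A phylogenetic tree with per-leaf disorder content and color bin."""

    tree: dendropy.Tree
    table: pd.DataFrame

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_annotations=False, unquoted_underscores=True
        )

    def write(self, newick_path, tsv_path=None) -> None:
        Path(newick_path).write_text(self.as_newick())
        if tsv_path is not None:
            self.table.to_csv(tsv_path, sep="\t", index=False)


def habitats_table(records: Iterable[HabitatRecord]) -> pd.DataFrame:
    """Tabulate habitat records (TSV-ready column layout)."""
    return pd.DataFrame(
        [
            {
                "species_id": r.species_id,
                "optimal_ph": r.optimal_ph,
                "optimal_temperature_c": r.optimal_temperature,
                "salinity": r.salinity,
                "flags": ";".join(sorted(r.lifestyle_flags)),
            }
            for r in records
        ]
    )


def read_habitats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "species_id" not in df.columns:
        raise ValueError("habitat table needs a species_id column")
    return df


def write_habitats(records: Iterable[HabitatRecord] | pd.DataFrame, path) -> None:
    df = records if isinstance(records, pd.DataFrame) else habitats_table(records)
    df.to_csv(path, sep="\t", index=False)


def _as_measures_frame(measures) -> pd.DataFrame:
    if isinstance(measures, pd.DataFrame):
        return measures
    return measures_table(measures)


def _as_habitats_frame(habitats) -> pd.DataFrame:
    if isinstance(habitats, pd.DataFrame):
        return habitats
    return habitats_table(habitats)


def _correlate(
    x: np.ndarray,
    y: np.ndarray,
    ids: np.ndarray,
    factor: str,
    measure: str,
    outlier_z: float = 2.0,
) -> FactorCorrelation:
    if x.size < 3:
        raise ValueError("insufficient species")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    pearson_r = float(stats.pearsonr(x, y).statistic)
    spearman_rho = float(stats.spearmanr(x, y).statistic)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    # deleted (externally studentized) residuals; degenerate at very small n
    with np.errstate(divide="ignore", invalid="ignore"):
        studentized = fit.get_influence().resid_studentized_external
    flagged = np.isfinite(studentized) & (np.abs(studentized) > outlier_z)
    outliers = tuple(str(i) for i in ids[flagged])
    return FactorCorrelation(
        factor,
        measure,
        int(x.size),
        pearson_r,
        spearman_rho,
        float(fit.params[1]),
        float(fit.params[0]),
        outliers,
    )


def disorder_vs_environment(
    measures,
    habitats,
    factor: str,
    measure: str = "idaa",
    outlier_z: float = 2.0,
) -> FactorCorrelation:
    """Correlate one disorder measure with one habitat factor across species.

    Species missing either value are dropped pairwise (no imputation).
    ``factor`` may be a short alias ("ph", "temperature", "salinity") or a
    habitat-table column name.
    """
    mdf = _as_measures_frame(measures)
    hdf = _as_habitats_frame(habitats)
    column = FACTOR_COLUMNS.get(factor, factor)
    if column not in hdf.columns:
        raise ValueError(f"unknown habitat factor '{factor}'")
    if measure not in mdf.columns:
        raise ValueError(f"unknown measure '{measure}'")
    merged = mdf.merge(hdf, on="species_id")
    raw = merged[column]
    if column == "salinity" and raw.dtype == object:
        unknown = set(raw.dropna()) - set(SALINITY_RANK)
        if unknown:
            raise ValueError(f"unknown salinity labels: {sorted(unknown)}")
        raw = raw.map(SALINITY_RANK)
    x = pd.to_numeric(raw, errors="coerce")
    y = pd.to_numeric(merged[measure], errors="coerce")
    keep = x.notna() & y.notna()
    return _correlate(
        x[keep].to_numpy(float),
        y[keep].to_numpy(float),
        merged.loc[keep, "species_id"].to_numpy(),
        factor,
        measure,
        outlier_z,
    )


def measure_correlation(measures) -> dict[tuple[str, str], FactorCorrelation]:
    """Pairwise correlations among the three disorder measures."""
    mdf = _as_measures_frame(measures)
    if len(mdf) < 3:
        raise ValueError("insufficient species")
    out = {}
    ids = mdf["species_id"].to_numpy()
    for m1, m2 in itertools.combinations(MEASURE_NAMES, 2):
        out[(m1, m2)] = _correlate(
            mdf[m1].to_numpy(float), mdf[m2].to_numpy(float), ids, m1, m2
        )
    return out


def color_bin(idaa_percent: float) -> str:
    """Disorder-content color bin of a percentage in [0, 100]."""
    p = float(idaa_percent)
    if not np.isfinite(p) or p < 0 or p > 100:
        raise ValueError("idaa percent outside [0, 100]")
    if p > 30:
        return "red"
    if p > 21:
        return "orange"
    if p > 17:
        return "yellow"
    if p > 14:
        return "light_blue"
    return "dark_blue"


def annotate_tree(
    newick,
    idaa_percent_by_species: Mapping[str, float],
    strict: bool = False,
) -> AnnotatedTree:
    """Color the leaves of a Newick tree by disorder content.

    ``newick`` may be a Newick string or a path to a Newick file.  Leaves
    absent from the map are left uncolored unless ``strict`` is on, in which
    case they raise ("unannotated leaf").  The topology is never modified.
    """
    text = str(newick)
    if "(" not in text:
        path = Path(text)
        if not path.exists():
            raise ValueError(f"parse error: no such file or tree text: {text!r}")
        text = path.read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ValueError(f"parse error: {exc}") from None
    rows = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon is not None else ""
        if label in idaa_percent_by_species:
            value = float(idaa_percent_by_species[label])
            color = color_bin(value)
            leaf.annotations.add_new("idaa_percent", value)
            leaf.annotations.add_new("color", color)
            rows.append({"leaf": label, "idaa_percent": value, "color": color})
        elif strict:
            raise ValueError(f"unannotated leaf: {label}")
        else:
            rows.append({"leaf": label, "idaa_percent": np.nan, "color": None})
    return AnnotatedTree(tree, pd.DataFrame(rows))
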