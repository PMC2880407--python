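"""Synthetic proteomes with known disorder architecture.

Every protein is generated from a two-state (ordered/disordered) Markov
chain: geometric block lengths with configurable means, stationary
disordered fraction pi_d = mean_d / (mean_d + mean_o), and state-specific
residue emission compositions (the ordered state enriched x2 in
I, L, V, W, F, Y, C, N; the disordered state enriched x2 in
E, K, R, G, Q, S, P, A, both renormalized from uniform).  The true
per-residue state labels are recorded as ground truth, which is what makes
every downstream stage testable without any downloads.

Protein lengths follow a log-normal (default median 180 residues, shape
0.60, hard floor 20) chosen so that the modal 50-residue bin falls in
100-200 and fewer than 2% of proteins are shorter than 50 residues.

The default species panel contrasts three habitat archetypes:
thermophile-like (pi_d = 0.14, 85-100 degC), mesophile-like (pi_d = 0.20,
25-37 degC) and halophile-like (pi_d = 0.34, high salinity), with a small
per-species jitter (+/- 0.02) on pi_d.  All randomness flows from one
master seed through per-species spawned streams, so panels are
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ecoevo import HabitatRecord, habitats_table, write_habitats
from .io import ProteinRecord, Proteome, write_fasta
from .metrics import DisorderSegment, extract_segments, segments_to_bed
from .scales import DISORDER_PROMOTING, ORDER_PROMOTING, STANDARD_AA

_AA_ARRAY = np.array(list(STANDARD_AA))


def biased_composition(promoted: Iterable[str], factor: float = 2.0) -> np.ndarray:
    """Uniform composition re-weighted by ``factor`` on a residue set."""
    weights = np.ones(20)
    for aa in promoted:
        weights[STANDARD_AA.index(aa)] = factor
    return weights / weights.sum()


ORDERED_EMISSION = biased_composition(ORDER_PROMOTING)
DISORDERED_EMISSION = biased_composition(DISORDER_PROMOTING)


@dataclass(frozen=True)
class LengthModel:
    """Log-normal protein-length model with a hard lower floor."""

    median: float = 180.0
    shape: float = 0.60
    floor: int = 20

    def __post_init__(self) -> None:
        if self.median <= 0 or self.shape <= 0 or self.floor < 1:
            raise ValueError("invalid length model")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        draws = rng.lognormal(np.log(self.median), self.shape, size=n)
        return np.maximum(self.floor, np.rint(draws).astype(int))


DEFAULT_LENGTH_MODEL = LengthModel()


@dataclass(frozen=True)
class ArchetypeConfig:
    """A habitat archetype: disorder target, block structure, compositions.

    ``target_disorder_fraction`` must equal the stationary fraction implied
    by the block means, mean_d / (mean_d + mean_o), within 1e-6; use
    :func:`make_archetype` to derive a consistent ordered-block mean.
    """

    name: str
    target_disorder_fraction: float
    mean_disordered_block: float = 40.0
    mean_ordered_block: float | None = None
    ordered_composition: tuple[float, ...] = tuple(ORDERED_EMISSION)
    disordered_composition: tuple[float, ...] = tuple(DISORDERED_EMISSION)
    habitat: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        pi = self.target_disorder_fraction
        if not 0.0 <= pi <= 1.0:
            raise ValueError("target_disorder_fraction outside [0, 1]")
        if self.mean_disordered_block < 1:
            raise ValueError("block means must be >= 1")
        for comp in (self.ordered_composition, self.disordered_composition):
            arr = np.asarray(comp, dtype=float)
            if arr.shape != (20,) or np.any(arr < 0) or abs(arr.sum() - 1) > 1e-9:
                raise ValueError("emission compositions must be 20-simplex points")
        if 0.0 < pi < 1.0:
            if self.mean_ordered_block is None or self.mean_ordered_block < 1:
                raise ValueError("block means must be >= 1")
            implied = self.mean_disordered_block / (
                self.mean_disordered_block + self.mean_ordered_block
            )
            if abs(implied - pi) > 1e-6:
                raise ValueError("inconsistent archetype")

    @property
    def ordered_emission(self) -> np.ndarray:
        return np.asarray(self.ordered_composition, dtype=float)

    @property
    def disordered_emission(self) -> np.ndarray:
        return np.asarray(self.disordered_composition, dtype=float)


def make_archetype(
    name: str,
    disorder_fraction: float,
    mean_disordered_block: float = 40.0,
    habitat: Mapping | None = None,
    ordered_composition: Sequence[float] | None = None,
    disordered_composition: Sequence[float] | None = None,
) -> ArchetypeConfig:
    """Build a consistent archetype, deriving the ordered-block mean."""
    if 0.0 < disorder_fraction < 1.0:
        mean_ordered = mean_disordered_block * (1 - disorder_fraction) / disorder_fraction
    else:
        mean_ordered = mean_disordered_block
    return ArchetypeConfig(
        name,
        disorder_fraction,
        mean_disordered_block,
        mean_ordered,
        tuple(ordered_composition) if ordered_composition is not None else tuple(ORDERED_EMISSION),
        tuple(disordered_composition) if disordered_composition is not None else tuple(DISORDERED_EMISSION),
        dict(habitat) if habitat else {},
    )


@dataclass
class GroundTruth:
    """True per-residue state labels of one synthetic protein."""

    protein_id: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-d vector")

    @property
    def segments(self) -> list[DisorderSegment]:
        if not self.labels.any():
            return []
        return extract_segments(self.labels, self.protein_id)


@dataclass
class SpeciesSim:
    """One simulated species: proteome, truth, habitat, realized archetype."""

    species_id: str
    archetype: ArchetypeConfig
    proteome: Proteome
    truths: list[GroundTruth]
    habitat: HabitatRecord

    @property
    def true_disorder_fraction(self) -> float:
        return true_disorder_fraction(self.truths)


def true_disorder_fraction(truths: Iterable[GroundTruth]) -> float:
    """Pooled fraction of residues whose true state is disordered."""
    disordered = total = 0
    for t in truths:
        disordered += int(t.labels.sum())
        total += t.labels.size
    if total == 0:
        raise ValueError("no truth labels")
    return disordered / total


def generate_protein(
    archetype: ArchetypeConfig,
    length: int,
    rng: np.random.Generator,
    protein_id: str = "P00001",
) -> tuple[ProteinRecord, GroundTruth]:
    """Sample one protein and its true state labels from an archetype."""
    if length < 1:
        raise ValueError("length must be >= 1")
    pi = archetype.target_disorder_fraction
    labels = np.empty(length, dtype=bool)
    if pi <= 0.0:
        labels[:] = False
    elif pi >= 1.0:
        labels[:] = True
    else:
        state = bool(rng.random() < pi)
        pos = 0
        while pos < length:
            mean = (
                archetype.mean_disordered_block
                if state
                else archetype.mean_ordered_block
            )
            run = min(int(rng.geometric(1.0 / mean)), length - pos)
            labels[pos : pos + run] = state
            pos += run
            state = not state
    chars = np.empty(length, dtype="<U1")
    n_dis = int(labels.sum())
    if n_dis:
        chars[labels] = rng.choice(
            _AA_ARRAY, size=n_dis, p=archetype.disordered_emission
        )
    if n_dis < length:
        chars[~labels] = rng.choice(
            _AA_ARRAY, size=length - n_dis, p=archetype.ordered_emission
        )
    record = ProteinRecord(protein_id, "".join(chars))
    return record, GroundTruth(protein_id, labels)


def _realize_habitat(
    template: Mapping, rng: np.random.Generator, species_id: str
) -> HabitatRecord:
    def draw(value):
        if isinstance(value, tuple):
            return float(rng.uniform(*value))
        return value

    return HabitatRecord(
        species_id=species_id,
        optimal_ph=draw(template.get("optimal_ph", 7.0)),
        optimal_temperature=draw(template.get("optimal_temperature")),
        salinity=template.get("salinity", "normal"),
        lifestyle_flags=frozenset(template.get("lifestyle_flags", ())),
    )


def generate_proteome(
    archetype: ArchetypeConfig,
    n_proteins: int,
    length_model: LengthModel | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    species_id: str | None = None,
) -> tuple[Proteome, list[GroundTruth], HabitatRecord]:
    """Sample a whole proteome plus its ground truth and habitat record."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    length_model = length_model or DEFAULT_LENGTH_MODEL
    species_id = species_id or archetype.name
    lengths = length_model.sample(rng, n_proteins)
    records, truths = [], []
    for i, length in enumerate(lengths, start=1):
        rec, truth = generate_protein(
            archetype, int(length), rng, protein_id=f"{species_id}|{i:05d}"
        )
        records.append(rec)
        truths.append(truth)
    habitat = _realize_habitat(archetype.habitat, rng, species_id)
    return Proteome(species_id, records), truths, habitat


def default_archetypes() -> list[ArchetypeConfig]:
    """The three-archetype contrast panel shipped as the default study design."""
    return [
        make_archetype(
            "thermophile_like",
            0.14,
            habitat={
                "optimal_temperature": (85.0, 100.0),
                "optimal_ph": (6.0, 7.5),
                "salinity": "normal",
            },
        ),
        make_archetype(
            "mesophile_like",
            0.20,
            habitat={
                "optimal_temperature": (25.0, 37.0),
                "optimal_ph": (6.5, 7.5),
                "salinity": "normal",
            },
        ),
        make_archetype(
            "halophile_like",
            0.34,
            habitat={
                "optimal_temperature": (35.0, 45.0),
                "optimal_ph": (7.0, 7.8),
                "salinity": "high",
                "lifestyle_flags": ("halophile",),
            },
        ),
    ]


def generate_species_panel(
    archetypes: Sequence[ArchetypeConfig] | None = None,
    n_species_per_archetype: int = 3,
    n_proteins: int = 500,
    length_model: LengthModel | None = None,
    seed: int = 0,
    jitter: float = 0.02,
) -> list[SpeciesSim]:
    """Simulate a multi-species panel spanning the archetype contrasts.

    Per-species disorder targets are jittered uniformly by +/- ``jitter``
    around the archetype value; each species draws from its own stream
    spawned deterministically from the master seed.
    """
    if archetypes is None:
        archetypes = default_archetypes()
    archetypes = list(archetypes)
    if not archetypes:
        raise ValueError("no archetypes")
    streams = np.random.SeedSequence(seed).spawn(
        len(archetypes) * n_species_per_archetype
    )
    panel: list[SpeciesSim] = []
    k = 0
    for arch in archetypes:
        for j in range(n_species_per_archetype):
            rng = np.random.default_rng(streams[k])
            k += 1
            pi = float(
                np.clip(
                    arch.target_disorder_fraction + rng.uniform(-jitter, jitter),
                    0.0,
                    1.0,
                )
            )
            species_arch = make_archetype(
                arch.name,
                pi,
                arch.mean_disordered_block,
                habitat=arch.habitat,
                ordered_composition=arch.ordered_composition,
                disordered_composition=arch.disordered_composition,
            )
            species_id = f"{arch.name}_{j + 1:02d}"
            proteome, truths, habitat = generate_proteome(
                species_arch,
                n_proteins,
                length_model,
                rng=rng,
                species_id=species_id,
            )
            panel.append(SpeciesSim(species_id, species_arch, proteome, truths, habitat))
    return panel


def generate_correlation_panel(
    seed: int = 0,
    n_species: int = 12,
    n_proteins: int = 150,
    temperature_range: tuple[float, float] = (25.0, 100.0),
    disorder_at_cold: float = 0.30,
    disorder_at_hot: float = 0.10,
    n_outliers: int = 2,
    outlier_disorder: float = 0.34,
    length_model: LengthModel | None = None,
) -> list[SpeciesSim]:
    """A temperature-gradient panel with injected high-disorder halophiles.

    The gradient species have disorder targets decreasing linearly in
    habitat temperature; the outlier species sit in the warm half of the
    range, where the trend predicts low disorder, but carry halophile-level
    disorder targets - emulating the high-salinity, hot-habitat exceptions
    that break the temperature trend.
    """
    t_lo, t_hi = temperature_range
    temps = np.linspace(t_lo, t_hi, n_species)
    pis = np.interp(temps, [t_lo, t_hi], [disorder_at_cold, disorder_at_hot])
    outlier_temps = np.linspace(
        t_lo + 0.55 * (t_hi - t_lo), t_lo + 0.8 * (t_hi - t_lo), n_outliers
    )
    streams = np.random.SeedSequence(seed).spawn(n_species + n_outliers)
    panel: list[SpeciesSim] = []
    for i in range(n_species):
        arch = make_archetype(
            f"gradient_{i + 1:02d}",
            float(pis[i]),
            habitat={
                "optimal_temperature": float(temps[i]),
                "optimal_ph": 7.0,
                "salinity": "normal",
            },
        )
        rng = np.random.default_rng(streams[i])
        proteome, truths, habitat = generate_proteome(
            arch, n_proteins, length_model, rng=rng, species_id=arch.name
        )
        panel.append(SpeciesSim(arch.name, arch, proteome, truths, habitat))
    for i in range(n_outliers):
        arch = make_archetype(
            f"halophile_outlier_{i + 1}",
            float(outlier_disorder),
            habitat={
                "optimal_temperature": float(outlier_temps[i]),
                "optimal_ph": 7.2,
                "salinity": "high",
                "lifestyle_flags": ("halophile",),
            },
        )
        rng = np.random.default_rng(streams[n_species + i])
        proteome, truths, habitat = generate_proteome(
            arch, n_proteins, length_model, rng=rng, species_id=arch.name
        )
        panel.append(SpeciesSim(arch.name, arch, proteome, truths, habitat))
    return panel


def export_panel(panel: Iterable[SpeciesSim], outdir, seed: int | None = None) -> None:
    """Write a panel to disk: FASTA + truth BED per species, habitat TSV,
    and a key-value manifest recording all generator parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = list(panel)
    for sim in panel:
        write_fasta(sim.proteome, outdir / f"{sim.species_id}.fasta")
        segments = [seg for t in sim.truths for seg in t.segments]
        segments_to_bed(segments, outdir / f"{sim.species_id}.truth.bed")
    write_habitats([sim.habitat for sim in panel], outdir / "habitats.tsv")
    with open(outdir / "manifest.txt", "w") as fh:
        if seed is not None:
            fh.write(f"master_seed={seed}\n")
        for sim in panel:
            arch = sim.archetype
            fh.write(
                f"species={sim.species_id}\tarchetype={arch.name}\t"
                f"target_disorder_fraction={arch.target_disorder_fraction:.6f}\t"
                f"mean_disordered_block={arch.mean_disordered_block}\t"
                f"mean_ordered_block={arch.mean_ordered_block}\t"
                f"n_proteins={len(sim.proteome)}\n"
            )
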