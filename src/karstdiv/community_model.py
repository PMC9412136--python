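"""Data model and I/O for nested vegetation surveys.

A survey campaign visits plots at five restoration stages (HE herbaceous,
HS herb-shrub transition, SH shrub, TS tree-shrub transition, TR tree).
Each plot is sampled with nested layer subplots (tree / shrub / herb) of
different areas, so individual counts must be normalized by the sampled
area of the layer they came from before plots can be compared.

The module reads tidy CSV tables, validates them, and aggregates nested
surveys into a plot x species density matrix (individuals per m^2) plus
the raw integer counts needed by the finite-sample Simpson index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STAGES = ("HE", "HS", "SH", "TS", "TR")
LAYERS = ("tree", "shrub", "herb")
TRAIT_COLUMNS = ("PLH", "LT", "CHL", "LDMC", "LA", "SLA")

#: standard per-subplot areas (m^2) of the nested design: four subplots
#: per layer, 10x10 m tree, 4x4 m shrub, 1x1 m herb.
SUBPLOT_AREA_M2 = {"tree": 100.0, "shrub": 16.0, "herb": 1.0}

DEFAULT_ABUNDANCE_SCHEMA = {
    "plot": "plot",
    "stage": "stage",
    "layer": "layer",
    "area_m2": "area_m2",
    "species": "species",
    "count": "count",
}


class ValidationError(ValueError):
    """Raised when an input table or survey violates the data contract."""


@dataclass(frozen=True)
class Subplot:
    """One layer subplot: sampled area and species counts."""

    layer: str
    area_m2: float
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if not self.area_m2 > 0:
            raise ValidationError(f"subplot area must be > 0 m^2, got {self.area_m2}")
        for sp, n in self.counts.items():
            if not sp or not str(sp).strip():
                raise ValidationError("species name must be nonempty")
            if int(n) != n or n < 0:
                raise ValidationError(f"count for {sp!r} must be a nonnegative integer, got {n}")


@dataclass(frozen=True)
class PlotSurvey:
    """All subplots surveyed in one plot, with its restoration stage."""

    plot_id: str
    stage: str
    subplots: list[Subplot] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for sub in self.subplots:
            for sp in sub.counts:
                seen.setdefault(sp, None)
        return list(seen)


@dataclass
class AbundanceMatrix:
    """Plot x species densities (per m^2) with raw pooled counts.

    ``density[i, j]`` is the per-m^2 density of species j in plot i,
    computed per layer (counts summed over that layer's subplots divided
    by the layer's summed sampled area) and summed across layers when a
    species occurs in more than one layer. ``raw_counts`` holds the
    pooled integer counts (N_i per plot; N = row sum).
    """

    plot_ids: list[str]
    stages: list[str]
    species: list[str]
    density: np.ndarray
    raw_counts: np.ndarray

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        self.raw_counts = np.asarray(self.raw_counts)
        if self.density.shape != (len(self.plot_ids), len(self.species)):
            raise ValidationError("density shape does not match plot/species axes")
        if self.raw_counts.shape != self.density.shape:
            raise ValidationError("raw_counts shape does not match density")
        if (self.density < 0).any() or (self.raw_counts < 0).any():
            raise ValidationError("densities and counts must be nonnegative")
        if (self.density.sum(axis=1) <= 0).any():
            bad = [self.plot_ids[i] for i in np.where(self.density.sum(axis=1) <= 0)[0]]
            raise ValidationError(f"plots with no individuals: {bad}")

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    def relative_density(self) -> np.ndarray:
        """Per-plot relative densities p_i (each row sums to 1)."""
        tot = self.density.sum(axis=1, keepdims=True)
        return self.density / tot

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.density, index=self.plot_ids, columns=self.species)
        df.insert(0, "stage", self.stages)
        return df


@dataclass
class TraitTable:
    """Species x trait matrix for the six quantitative traits.

    Columns (fixed order): PLH plant height (m), LT leaf thickness (mm),
    CHL chlorophyll content (SPAD), LDMC leaf dry matter content
    (g/g = dry/fresh weight, hence in (0, 1]), LA leaf area (cm^2),
    SLA specific leaf area (cm^2/g = LA/DW).
    """

    species: list[str]
    traits: np.ndarray
    provenance: str = "raw"  # raw | range-standardized

    def __post_init__(self) -> None:
        self.traits = np.asarray(self.traits, dtype=float)
        if self.traits.shape != (len(self.species), len(TRAIT_COLUMNS)):
            raise ValidationError(
                f"trait matrix must be {len(self.species)} x {len(TRAIT_COLUMNS)}"
            )
        if len(set(self.species)) != len(self.species):
            dupes = sorted({s for s in self.species if self.species.count(s) > 1})
            raise ValidationError(f"duplicate species in trait table: {dupes}")
        if np.isnan(self.traits).any():
            raise ValidationError("trait table contains missing values (no imputation is done)")
        if self.provenance == "raw":
            if (self.traits <= 0).any():
                raise ValidationError("all raw trait values must be > 0")
            ldmc = self.traits[:, TRAIT_COLUMNS.index("LDMC")]
            if (ldmc > 1).any():
                bad = [self.species[i] for i in np.where(ldmc > 1)[0]]
                raise ValidationError(
                    f"LDMC > 1 for {bad}: dry weight cannot exceed fresh weight"
                )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.traits, columns=list(TRAIT_COLUMNS))
        df.insert(0, "species", self.species)
        return df

    def subset(self, species: list[str]) -> "TraitTable":
        idx = {s: i for i, s in enumerate(self.species)}
        missing = [s for s in species if s not in idx]
        if missing:
            raise ValidationError(f"species missing from trait table: {missing}")
        rows = [idx[s] for s in species]
        return replace(self, species=list(species), traits=self.traits[rows])


def _canonical_rows(surveys: list[PlotSurvey]) -> pd.DataFrame:
    """Tidy (plot, stage, layer, area_m2, species, count) rows, one per
    (plot, layer, species), counts summed and layer areas pooled."""
    rows = []
    for sv in surveys:
        layer_area: dict[str, float] = {}
        layer_counts: dict[str, dict[str, int]] = {}
        for sub in sv.subplots:
            layer_area[sub.layer] = layer_area.get(sub.layer, 0.0) + sub.area_m2
            cnt = layer_counts.setdefault(sub.layer, {})
            for sp, n in sub.counts.items():
                cnt[sp] = cnt.get(sp, 0) + int(n)
        for layer in LAYERS:
            if layer not in layer_counts:
                continue
            for sp in sorted(layer_counts[layer]):
                rows.append(
                    {
                        "plot": sv.plot_id,
                        "stage": sv.stage,
                        "layer": layer,
                        "area_m2": layer_area[layer],
                        "species": sp,
                        "count": layer_counts[layer][sp],
                    }
                )
    return pd.DataFrame(rows, columns=["plot", "stage", "layer", "area_m2", "species", "count"])


def read_abundance_table(path, schema: dict[str, str] | None = None) -> list[PlotSurvey]:
    """Read a tidy abundance CSV into one :class:`PlotSurvey` per plot.

    The CSV must carry the columns plot, stage, layer, area_m2, species,
    count (renameable through ``schema``, a map from standard name to the
    CSV's column name). ``area_m2`` is the total sampled area of that
    layer in that plot and must agree across rows of the same
    (plot, layer). Duplicate (plot, layer, species) rows are summed.
    """
    colmap = dict(DEFAULT_ABUNDANCE_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ValidationError(f"abundance table is missing columns: {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})

    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.stage not in STAGES:
            raise ValidationError(f"row {i}: unknown stage {row.stage!r}")
        if row.layer not in LAYERS:
            raise ValidationError(f"row {i}: unknown layer {row.layer!r}")
        if not row.area_m2 > 0:
            raise ValidationError(f"row {i}: area_m2 must be > 0, got {row.area_m2}")
        if row.count < 0 or int(row.count) != row.count:
            raise ValidationError(f"row {i}: count must be a nonnegative integer, got {row.count}")
        if not str(row.species).strip():
            raise ValidationError(f"row {i}: empty species name")

    df["species"] = df["species"].astype(str).str.strip()
    surveys = []
    for plot_id, g in df.groupby("plot", sort=True):
        stages = g["stage"].unique()
        if len(stages) > 1:
            raise ValidationError(f"plot {plot_id!r} has conflicting stages {list(stages)}")
        subplots = []
        for layer, gl in g.groupby("layer"):
            areas = gl["area_m2"].unique()
            if len(areas) > 1:
                raise ValidationError(
                    f"plot {plot_id!r} layer {layer!r}: inconsistent areas {list(areas)}"
                )
            counts = gl.groupby("species")["count"].sum().astype(int).to_dict()
            subplots.append(Subplot(layer=layer, area_m2=float(areas[0]), counts=counts))
        subplots.sort(key=lambda s: LAYERS.index(s.layer))
        surveys.append(PlotSurvey(plot_id=str(plot_id), stage=stages[0], subplots=subplots))
    return surveys


def write_abundance_table(surveys: list[PlotSurvey], path) -> None:
    """Write surveys back to the canonical tidy CSV (layer-pooled rows)."""
    _canonical_rows(surveys).to_csv(path, index=False)


def read_trait_table(path) -> TraitTable:
    """Read a species x trait CSV (columns: species + the six traits)."""
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValidationError("trait table must have a 'species' column")
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"trait table is missing trait columns: {missing}")
    species = df["species"].astype(str).str.strip().tolist()
    traits = df[list(TRAIT_COLUMNS)].to_numpy(dtype=float)
    return TraitTable(species=species, traits=traits, provenance="raw")


def write_trait_table(table: TraitTable, path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def aggregate_to_matrix(surveys: list[PlotSurvey]) -> AbundanceMatrix:
    """Pool nested subplots into a plot x species density matrix.

    For each plot and layer, counts are summed over the layer's subplots
    and divided by the layer's total sampled area; a species recorded in
    two layers of one plot gets the sum of its layer densities. Raw
    counts are pooled across all layers. The species axis is the sorted
    union over all plots.
    """
    if not surveys:
        raise ValidationError("need at least one survey")
    species = sorted({sp for sv in surveys for sp in sv.species})
    if not species:
        raise ValidationError("no species recorded in any survey")
    sp_index = {s: j for j, s in enumerate(species)}

    density = np.zeros((len(surveys), len(species)))
    raw = np.zeros((len(surveys), len(species)), dtype=int)
    for i, sv in enumerate(surveys):
        layer_area: dict[str, float] = {}
        layer_counts: dict[str, dict[str, int]] = {}
        for sub in sv.subplots:
            layer_area[sub.layer] = layer_area.get(sub.layer, 0.0) + sub.area_m2
            cnt = layer_counts.setdefault(sub.layer, {})
            for sp, n in sub.counts.items():
                cnt[sp] = cnt.get(sp, 0) + int(n)
        for layer, counts in layer_counts.items():
            area = layer_area[layer]
            for sp, n in counts.items():
                density[i, sp_index[sp]] += n / area
                raw[i, sp_index[sp]] += n

    return AbundanceMatrix(
        plot_ids=[sv.plot_id for sv in surveys],
        stages=[sv.stage for sv in surveys],
        species=species,
        density=density,
        raw_counts=raw,
    )
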