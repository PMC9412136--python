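"""Synthetic vegetation studies with a planted diversity-stability trend.

Generates complete studies (5 restoration stages x 3 replicate plots,
nested tree/shrub/herb subplots, 6 quantitative traits) whose planted
structure mirrors a natural-recovery gradient:

* species richness increases along succession;
* community evenness increases: the share of the planted dominant
  species (strongest in the herbaceous stage, absent in the tree stage)
  and the lognormal spread of the abundance tail both shrink — which
  raises the Simpson index and the inverse-CV stability together
  (stability is never planted directly, it emerges from the evenness
  schedule);
* trait convergence kappa follows a U shape: strong convergence early
  (stress filtering), maximal trait spread at the tree-shrub transition,
  renewed convergence in the tree stage — producing a hump-shaped
  functional diversity peaking mid-succession while functional
  redundancy rises monotonically.

Species abundances are drawn on a *common per-m^2 density scale* across
layers and converted to integer counts in proportion to each layer's
sampled area, so that per-layer density normalization downstream
recovers comparable densities (see docs/methods.md for what this does
and does not emulate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .community_model import (
    LAYERS,
    STAGES,
    SUBPLOT_AREA_M2,
    TRAIT_COLUMNS,
    PlotSurvey,
    Subplot,
    TraitTable,
    ValidationError,
)

#: trait ranges used for generation: (low, high) in the trait's units —
#: PLH m, LT mm, CHL SPAD, LDMC g/g, LA cm^2, SLA cm^2/g.
DEFAULT_TRAIT_RANGES: dict[str, tuple[float, float]] = {
    "PLH": (0.05, 25.0),
    "LT": (0.05, 2.0),
    "CHL": (15.0, 65.0),
    "LDMC": (0.08, 0.65),
    "LA": (0.5, 220.0),
    "SLA": (40.0, 520.0),
}

N_SUBPLOTS_PER_LAYER = 4


@dataclass(frozen=True)
class StageSpec:
    """Planted parameters of one restoration stage."""

    label: str
    richness: int  # species pool size S
    sigma: float  # lognormal abundance spread (evenness; lower = more even)
    kappa: float  # trait convergence in [0, 1]; high = similar traits
    layer_mix: dict[str, float] = field(default_factory=lambda: {"herb": 1.0})
    n_individuals: int = 800  # total individuals N per plot
    dominance: float = 0.0  # extra density share of the stage's dominant species

    def __post_init__(self) -> None:
        if self.label not in STAGES:
            raise ValidationError(f"unknown stage label {self.label!r}")
        if self.richness < 1:
            raise ValidationError("richness must be >= 1")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValidationError("kappa must lie in [0, 1]")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if not 0.0 <= self.dominance < 1.0:
            raise ValidationError("dominance must lie in [0, 1)")
        if self.n_individuals < self.richness:
            raise ValidationError("need at least one individual per species (N >= S)")
        bad = [l for l in self.layer_mix if l not in LAYERS]
        if bad:
            raise ValidationError(f"unknown layers in layer_mix: {bad}")
        total = sum(self.layer_mix.values())
        if not np.isclose(total, 1.0):
            raise ValidationError(f"layer_mix fractions must sum to 1, got {total}")


@dataclass(frozen=True)
class StudySpec:
    """A full study: ordered stage specs, replicates, trait ranges, seed."""

    stages: tuple[StageSpec, ...]
    replicates: int = 3
    trait_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_RANGES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValidationError("need >= 2 replicates per stage for ANOVA")
        missing = [t for t in TRAIT_COLUMNS if t not in self.trait_ranges]
        if missing:
            raise ValidationError(f"trait_ranges missing traits: {missing}")


def default_study_spec(seed: int = 0, replicates: int = 3) -> StudySpec:
    """The default five-stage study emulating a karst recovery gradient.

    Richness rises 8 -> 40 while the planted dominant-species share
    falls 0.77 -> 0 and the lognormal tail spread sigma shrinks, so
    communities grow more even along succession (driving Simpson
    diversity and stability up); trait convergence kappa dips toward
    the tree-shrub transition (driving the functional-diversity hump);
    layer composition moves from herb-only to a full three-layer canopy.
    """
    table = [
        #       S   sigma kappa  layer mix                                    N  dominance
        ("HE",   8, 0.60, 0.60, {"herb": 1.0},                               500, 0.77),
        ("HS",  14, 0.50, 0.70, {"herb": 0.60, "shrub": 0.40},               700, 0.48),
        ("SH",  18, 0.40, 0.34, {"herb": 0.35, "shrub": 0.65},               900, 0.34),
        ("TS",  28, 0.30, 0.31, {"herb": 0.25, "shrub": 0.35, "tree": 0.40}, 1200, 0.16),
        ("TR",  40, 0.45, 0.42, {"herb": 0.20, "shrub": 0.30, "tree": 0.50}, 1500, 0.00),
    ]
    return StudySpec(
        stages=tuple(
            StageSpec(
                label=l, richness=s, sigma=sg, kappa=k,
                layer_mix=mix, n_individuals=n, dominance=d,
            )
            for l, s, sg, k, mix, n, d in table
        ),
        replicates=replicates,
        seed=seed,
    )


def _stage_pool(spec: StageSpec) -> tuple[list[str], dict[str, str]]:
    """Deterministic species names and layer assignment for a stage.

    Layer counts are the largest-remainder rounding of the layer_mix
    fractions; every layer with positive mix gets at least one species.
    """
    names = [f"{spec.label}_sp{i:02d}" for i in range(1, spec.richness + 1)]
    layers = [l for l in LAYERS if spec.layer_mix.get(l, 0.0) > 0]
    fracs = np.array([spec.layer_mix[l] for l in layers])
    counts = np.floor(fracs * spec.richness).astype(int)
    counts = np.maximum(counts, 1)
    while counts.sum() > spec.richness:
        counts[np.argmax(counts)] -= 1
    rema = fracs * spec.richness - counts
    while counts.sum() < spec.richness:
        counts[np.argmax(rema)] += 1
        rema[np.argmax(rema)] = -1
    assignment: dict[str, str] = {}
    k = 0
    for layer, c in zip(layers, counts):
        for _ in range(c):
            assignment[names[k]] = layer
            k += 1
    return names, assignment


def generate_stage_plots(
    spec: StageSpec, replicates: int, seed: int
) -> list[PlotSurvey]:
    """Replicate plots for one stage, deterministic given the seed.

    Per replicate, species relative densities are drawn lognormal(0,
    sigma) on a common per-m^2 scale; expected counts weight each
    species by the sampled area of its layer; N individuals are then
    allocated multinomially to species and, within a species, to the
    four subplots of its layer.
    """
    names, layer_of = _stage_pool(spec)
    stage_idx = STAGES.index(spec.label)
    areas = np.array([SUBPLOT_AREA_M2[layer_of[s]] * N_SUBPLOTS_PER_LAYER for s in names])
    plots = []
    for rep in range(replicates):
        rng = np.random.default_rng([seed, stage_idx, rep])
        q = rng.lognormal(mean=0.0, sigma=spec.sigma, size=len(names))
        rel = (1.0 - spec.dominance) * q / q.sum()
        rel[0] += spec.dominance  # planted dominant species of the stage
        w = rel * areas
        counts = rng.multinomial(spec.n_individuals, w / w.sum())
        sub_counts: dict[tuple[str, int], dict[str, int]] = {}
        for sp, n in zip(names, counts):
            if n == 0:
                continue
            split = rng.multinomial(n, np.full(N_SUBPLOTS_PER_LAYER, 1 / N_SUBPLOTS_PER_LAYER))
            for j, nj in enumerate(split):
                if nj > 0:
                    sub_counts.setdefault((layer_of[sp], j), {})[sp] = int(nj)
        subplots = [
            Subplot(layer=layer, area_m2=SUBPLOT_AREA_M2[layer], counts=cnt)
            for (layer, _j), cnt in sorted(sub_counts.items(), key=lambda kv: (LAYERS.index(kv[0][0]), kv[0][1]))
        ]
        plots.append(
            PlotSurvey(plot_id=f"{spec.label}-{rep + 1}", stage=spec.label, subplots=subplots)
        )
    return plots


def generate_traits(study: StudySpec, seed: int | None = None) -> TraitTable:
    """Trait table for every species in the study's stage pools.

    Species are split between two trait clusters sitting near the low
    and high ends of each trait range; the stage's convergence kappa
    pulls species toward the stage centroid:

        x = kappa * centroid + (1 - kappa) * cluster draw.

    High kappa collapses the community onto its centroid (low pairwise
    distance, low FD); kappa near 0 leaves a strongly bimodal spread
    (high FD). The plant-height centroid increases along succession so
    later stages are taller. All values are clipped into their ranges,
    which keeps traits positive and LDMC <= 1.
    """
    if seed is None:
        seed = study.seed
    species: list[str] = []
    traits: list[np.ndarray] = []
    for stage_idx, spec in enumerate(study.stages):
        names, _ = _stage_pool(spec)
        rng = np.random.default_rng([seed, 1000 + stage_idx])
        lo = np.array([study.trait_ranges[t][0] for t in TRAIT_COLUMNS])
        hi = np.array([study.trait_ranges[t][1] for t in TRAIT_COLUMNS])
        span = hi - lo
        centroid = lo + (0.30 + 0.40 * rng.random(len(TRAIT_COLUMNS))) * span
        # taller canopies later in succession
        plh = TRAIT_COLUMNS.index("PLH")
        centroid[plh] = lo[plh] + (0.08 + 0.18 * stage_idx) * span[plh]
        for i, name in enumerate(names):
            cluster = i % 2
            if cluster == 0:
                draw = lo + (0.02 + 0.10 * rng.random(len(TRAIT_COLUMNS))) * span
            else:
                draw = hi - (0.02 + 0.10 * rng.random(len(TRAIT_COLUMNS))) * span
            x = spec.kappa * centroid + (1 - spec.kappa) * draw
            x = np.clip(x, lo + 1e-6, hi)
            species.append(name)
            traits.append(x)
    return TraitTable(species=species, traits=np.array(traits), provenance="raw")


def generate_study(spec: StudySpec) -> tuple[list[PlotSurvey], TraitTable, dict]:
    """Full synthetic study plus a truth record of the planted trends."""
    surveys: list[PlotSurvey] = []
    for st in spec.stages:
        surveys.extend(generate_stage_plots(st, spec.replicates, spec.seed))
    traits = generate_traits(spec)
    truth = {
        "seed": spec.seed,
        "replicates": spec.replicates,
        "stages": [
            {
                "label": st.label,
                "richness": st.richness,
                "sigma": st.sigma,
                "kappa": st.kappa,
                "n_individuals": st.n_individuals,
                "layer_mix": dict(st.layer_mix),
            }
            for st in spec.stages
        ],
        "planted_trends": {
            "SD": "strictly increasing along succession",
            "FD": "hump-shaped, maximal at TS",
            "FR": "strictly increasing along succession",
            "STB": "increasing (emerges from the evenness schedule)",
        },
    }
    return surveys, traits, truth


#: canonical anchor coordinates of a diversity-saturation geometry:
#: crossings a and b of the FD (y1) and FR (y2) curves, and their
#: values c (FR) and d (FD) at maximal species diversity SD = 1.
SATURATION_ANCHORS = {
    "a": (0.35, 0.18),
    "b": (0.77, 0.38),
    "c": (1.0, 0.66),
    "d": (1.0, 0.34),
}


def planted_saturation_curves(
    anchors: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Quadratic truth curves for saturation-recovery experiments.

    Returns ascending-power coefficients of y1 (hump-shaped functional
    diversity) and y2 (rising functional redundancy) as the unique
    quadratics through the anchor points: both pass through the
    crossings ``a`` and ``b``; y1 additionally through ``d`` and y2
    through ``c``. Sampling these curves (optionally with noise) and
    pushing the points through fit -> solve -> integrate tests whether
    the pipeline recovers the planted geometry.
    """
    from numpy.polynomial import polynomial as P

    pts = dict(SATURATION_ANCHORS)
    if anchors:
        pts.update(anchors)
    a, b, c, d = pts["a"], pts["b"], pts["c"], pts["d"]
    y1 = P.polyfit([a[0], b[0], d[0]], [a[1], b[1], d[1]], 2)
    y2 = P.polyfit([a[0], b[0], c[0]], [a[1], b[1], c[1]], 2)
    return y1, y2


def sample_saturation_points(
    n: int = 15,
    noise: float = 0.0,
    seed: int = 0,
    sd_range: tuple[float, float] = (0.3, 0.95),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample (SD, FD, FR) points from the planted saturation curves.

    SD values are evenly spaced over ``sd_range`` (the realistic span
    of observed Simpson diversity); independent Gaussian noise of
    standard deviation ``noise`` is added to FD and FR.
    """
    from numpy.polynomial import polynomial as P

    y1, y2 = planted_saturation_curves()
    rng = np.random.default_rng(seed)
    sd = np.linspace(sd_range[0], sd_range[1], n)
    fd = P.polyval(sd, y1) + rng.normal(0.0, noise, n)
    fr = P.polyval(sd, y2) + rng.normal(0.0, noise, n)
    return sd, fd, fr


def write_study(spec: StudySpec, outdir) -> dict[str, str]:
    """Write abundance.csv, traits.csv, truth.json into ``outdir``.

    The CSVs use exactly the schemas the readers in
    :mod:`karstdiv.community_model` expect, so a synthetic study is a
    drop-in replacement for field tables.
    """
    from pathlib import Path

    from .community_model import write_abundance_table, write_trait_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    surveys, traits, truth = generate_study(spec)
    paths = {
        "abundance": str(outdir / "abundance.csv"),
        "traits": str(outdir / "traits.csv"),
        "truth": str(outdir / "truth.json"),
    }
    write_abundance_table(surveys, paths["abundance"])
    write_trait_table(traits, paths["traits"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return paths
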