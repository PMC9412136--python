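"""Per-plot diversity and stability statistics.

The decomposition used throughout the package splits species diversity
into a functional part and a redundant part:

* SD — finite-sample (unbiased) Simpson index,
  ``1 - sum_i N_i (N_i - 1) / (N (N - 1))``, computed from raw counts;
* FD — Rao's quadratic entropy, ``sum_ij d_ij p_i p_j``, the expected
  trait dissimilarity of two randomly drawn individuals, computed from
  relative densities and a [0, 1]-bounded trait distance matrix;
* FR = SD - FD — functional redundancy, the share of species diversity
  carried by functionally similar species;
* STB — inverse coefficient of variation mu/sigma of the per-species
  densities present in the plot (sample standard deviation, n - 1).

SD deliberately uses the finite-sample count estimator while FD uses
relative densities: the decomposition is kept exactly as conventionally
printed rather than harmonized to a single estimator. With d_ij <= 1
this still guarantees FR >= 0, because Rao's Q is at most the
Gini-Simpson index 1 - sum p_i^2, which in turn is at most the
finite-sample SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community_model import AbundanceMatrix, ValidationError
from .trait_distance import DistanceMatrix

#: STB value reported when the density spread is zero (sigma = 0) or the
#: plot holds a single species: infinitely stable by the inverse-CV rule.
INFINITE_STABILITY = math.inf


@dataclass(frozen=True)
class DiversityRecord:
    plot_id: str
    stage: str
    SD: float
    FD: float
    FR: float
    STB: float
    S_obs: int


def simpson_sd(counts) -> float:
    """Finite-sample Simpson diversity from integer abundances.

    Probability that two individuals drawn without replacement belong to
    different species. Undefined for N < 2.
    """
    c = np.asarray(counts)
    if (c < 0).any() or not np.allclose(c, np.round(c)):
        raise ValidationError("counts must be nonnegative integers")
    c = np.round(c).astype(np.int64)
    n = int(c.sum())
    if n < 2:
        raise ValidationError(f"Simpson index needs N >= 2 individuals, got N = {n}")
    return 1.0 - float((c * (c - 1)).sum()) / (n * (n - 1))


def rao_fd(p, d: DistanceMatrix | np.ndarray) -> float:
    """Rao's quadratic entropy: sum_i sum_j d_ij p_i p_j.

    ``p`` are relative densities summing to 1; ``d`` a species-aligned
    dissimilarity matrix (zero diagonal, so i = j terms vanish).
    """
    p = np.asarray(p, dtype=float)
    dm = d.d if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    if dm.shape != (p.size, p.size):
        raise ValidationError(
            f"distance matrix {dm.shape} does not match {p.size} relative densities"
        )
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"relative densities must sum to 1, got {p.sum()!r}")
    return float(p @ dm @ p)


def functional_redundancy(sd: float, fd: float) -> float:
    """FR = SD - FD (de Bello decomposition)."""
    if not (math.isfinite(sd) and math.isfinite(fd)):
        raise ValidationError("SD and FD must be finite")
    return sd - fd


def stability_icv(densities) -> float:
    """Community stability as the inverse coefficient of variation.

    mu / sigma over the species *present* (density > 0); sigma is the
    sample standard deviation (n - 1 denominator). Zero spread (all
    present species equally dense, or a single species) returns the
    infinite-stability sentinel rather than raising.
    """
    x = np.asarray(densities, dtype=float)
    if (x < 0).any():
        raise ValidationError("densities must be nonnegative")
    x = x[x > 0]
    if x.size == 0:
        raise ValidationError("no species present: stability undefined")
    if x.size < 2:
        return INFINITE_STABILITY
    sigma = float(np.std(x, ddof=1))
    if sigma == 0.0:
        return INFINITE_STABILITY
    return float(np.mean(x)) / sigma


def community_profile(m: AbundanceMatrix, d: DistanceMatrix) -> pd.DataFrame:
    """Per-plot SD, FD, FR, STB and richness as a tidy table.

    The distance matrix must cover every species in the abundance
    matrix; it is aligned by name. Errors in per-plot computation are
    re-raised with the plot id attached.
    """
    dm = d.subset(m.species)
    rows = []
    for i, plot_id in enumerate(m.plot_ids):
        try:
            counts = m.raw_counts[i]
            dens = m.density[i]
            present = dens > 0
            sd = simpson_sd(counts)
            p = dens[present] / dens[present].sum()
            fd = rao_fd(p, dm.d[np.ix_(present, present)])
            rows.append(
                DiversityRecord(
                    plot_id=plot_id,
                    stage=m.stages[i],
                    SD=sd,
                    FD=fd,
                    FR=functional_redundancy(sd, fd),
                    STB=stability_icv(dens),
                    S_obs=int(present.sum()),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"plot {plot_id!r}: {err}") from err
    return pd.DataFrame([r.__dict__ for r in rows])


def stage_summary(profile: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean and standard error per stage for each metric.

    Stages are ordered along the successional sequence. Plots with the
    infinite-stability sentinel are excluded from the STB mean.
    """
    from .community_model import STAGES

    metrics = ["SD", "FD", "FR", "STB"]
    out = []
    for stage in STAGES:
        g = profile[profile["stage"] == stage]
        if g.empty:
            continue
        row: dict[str, float | str] = {"stage": stage, "n_plots": len(g)}
        for mcol in metrics:
            vals = g[mcol].to_numpy(dtype=float)
            if mcol == "STB":
                vals = vals[np.isfinite(vals)]
            row[f"{mcol}_mean"] = float(np.mean(vals)) if vals.size else math.nan
            row[f"{mcol}_se"] = (
                float(np.std(vals, ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else math.nan
            )
        out.append(row)
    return pd.DataFrame(out)
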