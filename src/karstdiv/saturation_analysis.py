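"""Saturation-point analysis of functional diversity.

Fits polynomial curves of functional diversity (y1) and functional
redundancy (y2) against species diversity (SD), solves for their
intersections, and integrates the area between them:

* ``a`` — first crossing: below it FR rises faster than FD;
* ``b`` — second crossing, the *saturation point* of functional
  diversity: beyond it FR overtakes FD again;
* ``c`` = (1, y2(1)), ``d`` = (1, y1(1)) — curve values at the maximal
  species diversity SD = 1 (usually an extrapolation, and flagged);
* ``S1`` — area between the curves on [a, b] (FD above FR): the net
  gain in functional diversity before saturation;
* ``S2`` — area between the curves on [b, 1] (FR above FD): the net
  gain in functional redundancy after saturation.

Areas are computed exactly from the antiderivative of the difference
polynomial; a shoelace (polygon) routine on the discretized boundary is
provided as an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as P

from .community_model import ValidationError


class CurvesCoincideError(ValidationError):
    """The two fitted polynomials are identical: no isolated crossings."""


@dataclass
class CurveFit:
    """Least-squares polynomial y(SD) with its fit diagnostics."""

    role: str  # "y1" (FD) or "y2" (FR)
    coef: np.ndarray  # ascending powers
    degree: int
    r_squared: float
    domain: tuple[float, float]  # [SD_min, SD_max] of the fitted data

    def __call__(self, x):
        return P.polyval(np.asarray(x, dtype=float), self.coef)

    def is_extrapolation(self, x: float) -> bool:
        return x < self.domain[0] - 1e-12 or x > self.domain[1] + 1e-12

    def to_dict(self) -> dict:
        return {
            "role": self.role,
            "coefficients": [float(c) for c in self.coef],
            "degree": self.degree,
            "r_squared": self.r_squared,
            "domain": [float(self.domain[0]), float(self.domain[1])],
        }


def fit_curve(x, y, degree: int = 2, role: str = "y1") -> CurveFit:
    """Least-squares polynomial fit of y against species diversity x.

    Needs at least ``degree + 2`` points so that R^2 is informative.
    R^2 is defined as 1 when both residual and total sums of squares
    vanish (constant data fitted exactly).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree < 1:
        raise ValidationError("degree must be >= 1")
    if x.size != y.size or x.size < degree + 2:
        raise ValidationError(
            f"need at least degree + 2 = {degree + 2} points, got {x.size}"
        )
    coef = P.polyfit(x, y, degree)
    resid = y - P.polyval(x, coef)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-20 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return CurveFit(
        role=role,
        coef=coef,
        degree=degree,
        r_squared=r2,
        domain=(float(x.min()), float(x.max())),
    )


def _diff_coef(f1: CurveFit, f2: CurveFit) -> np.ndarray:
    n = max(len(f1.coef), len(f2.coef))
    c1 = np.zeros(n)
    c2 = np.zeros(n)
    c1[: len(f1.coef)] = f1.coef
    c2[: len(f2.coef)] = f2.coef
    return c1 - c2


def find_intersections(
    f1: CurveFit,
    f2: CurveFit,
    domain: tuple[float, float] = (0.0, 1.0),
    imag_tol: float = 1e-9,
    dedupe_tol: float = 1e-6,
) -> list[tuple[float, float]]:
    """Real roots of f1 - f2 inside the domain, ascending in SD.

    Roots with imaginary part below ``imag_tol`` count as real; roots
    closer than ``dedupe_tol`` (e.g. a tangency's double root) are
    reported once.
    """
    diff = _diff_coef(f1, f2)
    scale = max(np.abs(np.concatenate([f1.coef, f2.coef])).max(), 1.0)
    if np.abs(diff).max() <= 1e-12 * scale:
        raise CurvesCoincideError("curves coincide: intersections are not isolated")
    trimmed = np.trim_zeros(diff, "b")
    if trimmed.size <= 1:  # constant nonzero difference
        return []
    roots = P.polyroots(trimmed)
    lo, hi = domain
    xs = sorted(
        float(r.real)
        for r in roots
        if abs(r.imag) <= imag_tol and lo - 1e-9 <= r.real <= hi + 1e-9
    )
    out: list[float] = []
    for x in xs:
        x = min(max(x, lo), hi)
        if not out or x - out[-1] > dedupe_tol:
            out.append(x)
    return [(x, float(f1(x))) for x in out]


def endpoint_values(f1: CurveFit, f2: CurveFit, at: float = 1.0) -> dict:
    """Points c = (at, y2(at)) and d = (at, y1(at)) at maximal diversity."""
    return {
        "c": (at, float(f2(at))),
        "d": (at, float(f1(at))),
        "extrapolated": f1.is_extrapolation(at) or f2.is_extrapolation(at),
    }


def net_area(f1: CurveFit, f2: CurveFit, x0: float, x1: float) -> float:
    """Exact area between the curves on [x0, x1] (one curve above).

    Integrates the antiderivative of the difference polynomial; if the
    curves cross strictly inside the interval the integrand changes
    sign and the caller must split at the crossings first.
    """
    if not x0 < x1:
        raise ValidationError(f"need x0 < x1, got [{x0}, {x1}]")
    diff = _diff_coef(f1, f2)
    trimmed = np.trim_zeros(diff, "b")
    if trimmed.size > 1:
        eps = 1e-9 * (x1 - x0)
        roots = P.polyroots(trimmed)
        interior = sorted(
            float(r.real)
            for r in roots
            if abs(r.imag) <= 1e-9 and x0 + eps < r.real < x1 - eps
        )
        for r in interior:
            h = min(r - x0, x1 - r) / 2
            left = float(P.polyval(r - h, diff))
            right = float(P.polyval(r + h, diff))
            if left * right < 0:
                raise ValidationError(
                    f"curves cross at SD = {r:.6g} inside ({x0}, {x1}): "
                    "split the interval at the crossings"
                )
    anti = P.polyint(diff)
    return abs(float(P.polyval(x1, anti) - P.polyval(x0, anti)))


def polygon_area(vertices) -> float:
    """Absolute shoelace area of a closed polygon given ordered vertices."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
        raise ValidationError("polygon needs at least 3 (x, y) vertices")
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


@dataclass
class SaturationResult:
    """Crossings, endpoints and areas of the fitted FD / FR curves."""

    f1: CurveFit
    f2: CurveFit
    a: tuple[float, float] | None = None
    b: tuple[float, float] | None = None
    c: tuple[float, float] | None = None
    d: tuple[float, float] | None = None
    S1: float | None = None
    S2: float | None = None
    regimes: list[dict] = field(default_factory=list)
    extrapolated_endpoints: bool = False
    diagnosis: str = "ok"

    @property
    def saturated(self) -> bool:
        return self.diagnosis == "ok"

    def to_dict(self) -> dict:
        return {
            "diagnosis": self.diagnosis,
            "a": list(self.a) if self.a else None,
            "b": list(self.b) if self.b else None,
            "c": list(self.c) if self.c else None,
            "d": list(self.d) if self.d else None,
            "S1": self.S1,
            "S2": self.S2,
            "regimes": self.regimes,
            "extrapolated_endpoints": self.extrapolated_endpoints,
            "fits": {"y1": self.f1.to_dict(), "y2": self.f2.to_dict()},
        }


def saturation_summary(
    f1: CurveFit, f2: CurveFit, sd_max: float = 1.0
) -> SaturationResult:
    """Full saturation analysis of the fitted FD (f1) and FR (f2) curves.

    Expects exactly two crossings in [0, sd_max]; otherwise the result
    carries a no-saturation diagnosis instead of points and areas.
    """
    try:
        crossings = find_intersections(f1, f2, domain=(0.0, sd_max))
    except CurvesCoincideError:
        return SaturationResult(f1=f1, f2=f2, diagnosis="curves coincide")
    if len(crossings) != 2:
        return SaturationResult(
            f1=f1,
            f2=f2,
            diagnosis=f"no saturation point: {len(crossings)} crossing(s) in [0, {sd_max}]",
        )
    a, b = crossings
    ends = endpoint_values(f1, f2, at=sd_max)
    s1 = net_area(f1, f2, a[0], b[0]) if b[0] - a[0] > 1e-12 else 0.0
    s2 = net_area(f1, f2, b[0], sd_max) if sd_max - b[0] > 1e-12 else 0.0
    regimes = [
        {"interval": [0.0, a[0]], "label": "FR rising faster"},
        {"interval": [a[0], b[0]], "label": "FD rising faster"},
        {"interval": [b[0], sd_max], "label": "FR rising faster"},
    ]
    return SaturationResult(
        f1=f1,
        f2=f2,
        a=a,
        b=b,
        c=ends["c"],
        d=ends["d"],
        S1=s1,
        S2=s2,
        regimes=regimes,
        extrapolated_endpoints=bool(ends["extrapolated"]),
    )
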