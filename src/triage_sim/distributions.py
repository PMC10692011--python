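"""Triangular death-probability distributions and odds-ratio calibration.

Patients entering the simulated ICU are assigned a probability of death
drawn from a triangular distribution ``Δ(minimum; maximum; mode)`` on the
unit interval.  The baseline distribution (patients without impairments or
pre-existing conditions) is ``Δ(0.04; 0.41; 0.045)`` with expected value
0.165.  Distributions for comorbid patient groups are calibrated so that
their expected death probability equals the published odds/hazard ratio
("relative risk of death") times the baseline expectation, while their
support still overlaps the baseline support: a comorbid patient may be
better off than a healthy one, only the odds are worse.

The module provides the density, closed-form CDF/inverse-CDF sampling,
moments, an exact overlap coefficient for two triangle densities, and the
calibration routine that derives a comorbidity distribution from a
relative risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "TriangularParams",
    "ComorbidityProfile",
    "ParameterError",
    "CalibrationError",
    "triangular_mean",
    "triangular_pdf",
    "triangular_cdf",
    "triangular_ppf",
    "sample_triangular",
    "overlap_coefficient",
    "derive_comorbidity_params",
    "load_profiles",
    "BASELINE",
]


class ParameterError(ValueError):
    """Triangular parameters violate 0 <= minimum <= mode <= maximum <= 1."""


class CalibrationError(ValueError):
    """No valid triangular distribution satisfies the requested mean constraint."""


@dataclass(frozen=True)
class TriangularParams:
    """Parameters of a triangular distribution on death probabilities.

    Field order follows the conventional display ``Δ(minimum; maximum; mode)``:
    the mode (most likely value) is listed third even though its magnitude
    lies between minimum and maximum.
    """

    minimum: float
    maximum: float
    mode: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.minimum <= self.mode <= self.maximum <= 1.0):
            raise ParameterError(
                f"invalid triangular parameters: need 0 <= minimum <= mode <= "
                f"maximum <= 1, got Δ({self.minimum}; {self.maximum}; {self.mode})"
            )

    @property
    def mean(self) -> float:
        return triangular_mean(self)

    @property
    def support(self) -> tuple[float, float]:
        return (self.minimum, self.maximum)

    def as_tuple(self) -> tuple[float, float, float]:
        """Return ``(minimum, maximum, mode)`` in display order."""
        return (self.minimum, self.maximum, self.mode)


@dataclass(frozen=True)
class ComorbidityProfile:
    """A named impairment or pre-existing condition.

    ``relative_risk`` is the published odds or hazard ratio used as a
    multiplicative factor on the baseline expected death probability;
    ``ci_low``/``ci_high`` are stored as metadata only (the point estimate
    drives the simulation).  ``prevalence_weight`` is a nonnegative weight
    used for comorbidity assignment within the profile's category.
    """

    name: str
    category: str  # "impairment" or "pre-existing"
    relative_risk: float
    params: TriangularParams
    ci_low: float | None = None
    ci_high: float | None = None
    prevalence_weight: float = 1.0
    strategy: str = "scale"

    def __post_init__(self) -> None:
        if self.category not in ("impairment", "pre-existing"):
            raise ValueError(f"unknown category {self.category!r}")
        if self.prevalence_weight < 0:
            raise ValueError("prevalence_weight must be nonnegative")


#: Baseline distribution of the death probability for patients without
#: impairments or pre-existing conditions (normalized registry data).
BASELINE = TriangularParams(0.04, 0.41, 0.045)


def triangular_mean(params: TriangularParams) -> float:
    """Expected value ``(minimum + maximum + mode) / 3``."""
    return (params.minimum + params.maximum + params.mode) / 3.0


def triangular_pdf(params: TriangularParams, x) -> np.ndarray | float:
    """Piecewise-linear triangle density; zero outside the support.

    The peak height is ``2 / (maximum - minimum)`` at the mode.  For a
    degenerate (point-mass) parameter set the density is 0 everywhere
    except the atom, where it is undefined; 0 is returned.
    """
    a, b, c = params.minimum, params.maximum, params.mode
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    if b > a:
        if c > a:
            rising = (x >= a) & (x <= c)
            # np.where evaluates the branch everywhere; outside the (possibly
            # sliver-thin) rising region the discarded quotient can overflow
            with np.errstate(over="ignore"):
                out = np.where(rising, 2.0 * (x - a) / ((b - a) * (c - a)), out)
        if b > c:
            # include x == c so a left-edge mode (c == a) gets the peak value;
            # at an interior mode both branches agree at x == c
            falling = (x >= c) & (x <= b)
            out = np.where(falling, 2.0 * (b - x) / ((b - a) * (b - c)), out)
        else:  # mode == maximum: density peaks at the right edge
            out = np.where(x == b, 2.0 / (b - a), out)
    return out if out.ndim else float(out)


def triangular_cdf(params: TriangularParams, x) -> np.ndarray | float:
    """Closed-form distribution function of the triangle."""
    a, b, c = params.minimum, params.maximum, params.mode
    x = np.asarray(x, dtype=float)
    if b == a:
        out = np.where(x >= a, 1.0, 0.0)
        return out if out.ndim else float(out)
    out = np.zeros_like(x)
    if c > a:
        left = (x > a) & (x <= c)
        out = np.where(left, (x - a) ** 2 / ((b - a) * (c - a)), out)
    if b > c:
        right = (x > c) & (x < b)
        out = np.where(right, 1.0 - (b - x) ** 2 / ((b - a) * (b - c)), out)
    out = np.where(x >= b, 1.0, out)
    return out if out.ndim else float(out)


def triangular_ppf(params: TriangularParams, u) -> np.ndarray | float:
    """Inverse CDF (quantile function); maps uniforms on [0, 1] to draws."""
    a, b, c = params.minimum, params.maximum, params.mode
    u = np.asarray(u, dtype=float)
    if b == a:
        out = np.full_like(u, a)
        return out if out.ndim else float(out)
    fc = (c - a) / (b - a)
    left = a + np.sqrt(u * (b - a) * (c - a))
    right = b - np.sqrt((1.0 - u) * (b - a) * (b - c))
    out = np.where(u < fc, left, right)
    return out if out.ndim else float(out)


def sample_triangular(
    params: TriangularParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. death probabilities by inverse-CDF transform.

    All draws lie within the support; reproducible given the generator state.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.asarray(triangular_ppf(params, rng.random(n)))


def _segments(params: TriangularParams) -> list[float]:
    return [params.minimum, params.mode, params.maximum]


def overlap_coefficient(p1: TriangularParams, p2: TriangularParams) -> float:
    """Overlap of two triangle densities: ``∫ min(f1, f2) dx`` over [0, 1].

    Computed by exact piecewise-linear segment arithmetic: break the axis at
    the six parameter points and at the crossing points of the two densities,
    then integrate the pointwise minimum with the trapezoidal rule, which is
    exact for linear pieces.  Equals 1 iff the parameter sets are identical,
    0 for disjoint supports.
    """
    if p1 == p2:
        return 1.0
    base = sorted(set(_segments(p1) + _segments(p2)))
    points: list[float] = []
    for lo, hi in zip(base[:-1], base[1:]):
        points.append(lo)
        # both densities are linear on (lo, hi); locate a sign change of f1-f2,
        # evaluating just inside the interval to dodge kinks at the endpoints
        eps = (hi - lo) * 1e-9
        d_lo = triangular_pdf(p1, lo + eps) - triangular_pdf(p2, lo + eps)
        d_hi = triangular_pdf(p1, hi - eps) - triangular_pdf(p2, hi - eps)
        if d_lo * d_hi < 0:
            # linear interpolation gives the exact crossing of two lines
            x_cross = lo + (hi - lo) * d_lo / (d_lo - d_hi)
            if lo < x_cross < hi:
                points.append(x_cross)
    points.append(base[-1])
    points = sorted(points)
    total = 0.0
    for lo, hi in zip(points[:-1], points[1:]):
        if hi <= lo:
            continue
        eps = (hi - lo) * 1e-9
        f_lo = min(triangular_pdf(p1, lo + eps), triangular_pdf(p2, lo + eps))
        f_hi = min(triangular_pdf(p1, hi - eps), triangular_pdf(p2, hi - eps))
        total += 0.5 * (f_lo + f_hi) * (hi - lo)
    return min(total, 1.0)


#: Published parameter set for the hypertension group; its mean 0.3498 is the
#: baseline mean scaled by the hazard ratio 2.12 (rounded in print to 0.35).
PRINTED_HYPERTENSION = TriangularParams(0.19, 0.63, 0.23)


def derive_comorbidity_params(
    baseline: TriangularParams,
    relative_risk: float,
    strategy: str = "scale",
) -> TriangularParams:
    """Calibrate a comorbidity distribution to a relative risk of death.

    The derived distribution satisfies
    ``mean(result) = relative_risk * mean(baseline)`` with support inside
    [0, 1] that overlaps the baseline support.

    Strategies
    ----------
    ``"scale"`` (default)
        Scale the whole triple by the relative risk.  If the scaled maximum
        exceeds 1, re-solve: pin the maximum at 1, keep the scaled minimum
        where feasible (raising it only as far as the mean constraint
        forces, which also keeps it below the baseline maximum so the
        supports overlap), and let the mode absorb the remainder of the
        mean constraint.
    ``"printed-hypertension"``
        Return the published hypertension triple ``Δ(0.19; 0.63; 0.23)``
        verbatim (its mean 0.3498 rounds to the printed 0.35).

    Raises
    ------
    CalibrationError
        If the target mean is not attainable by a distribution on [0, 1].
    """
    if strategy in ("printed", "printed-hypertension"):
        return PRINTED_HYPERTENSION
    if strategy != "scale":
        raise ValueError(f"unknown derivation strategy {strategy!r}")
    if relative_risk <= 0:
        raise CalibrationError("relative risk must be positive")
    m = relative_risk * triangular_mean(baseline)
    if m >= 1.0:
        raise CalibrationError(
            f"target mean {m:.4f} = {relative_risk} x {triangular_mean(baseline):.4f} "
            "is not a probability"
        )
    a = relative_risk * baseline.minimum
    c = relative_risk * baseline.mode
    b = 3.0 * m - a - c  # == relative_risk * baseline.maximum
    if b <= 1.0:
        result = TriangularParams(a, b, c)
    else:
        b = 1.0
        # mean constraint: a + c = 3m - 1; c <= 1 forces a >= 3m - 2
        a = max(a, 3.0 * m - 2.0)
        c = 3.0 * m - 1.0 - a
        if c < a:  # mean so low that the scaled minimum overshoots
            a = c = (3.0 * m - 1.0) / 2.0
        try:
            result = TriangularParams(a, b, c)
        except ParameterError as exc:  # pragma: no cover - defensive
            raise CalibrationError(str(exc)) from exc
    if result.minimum >= baseline.maximum:
        raise CalibrationError(
            "derived support does not overlap the baseline support"
        )
    return result


def _profile_from_dict(entry: dict, baseline: TriangularParams) -> ComorbidityProfile:
    strategy = entry.get("strategy", "scale")
    if "params" in entry:
        p = entry["params"]
        params = TriangularParams(p["minimum"], p["maximum"], p["mode"])
    else:
        params = derive_comorbidity_params(baseline, entry["relative_risk"], strategy)
    ci = entry.get("ci") or (None, None)
    return ComorbidityProfile(
        name=entry["name"],
        category=entry["category"],
        relative_risk=entry["relative_risk"],
        params=params,
        ci_low=ci[0],
        ci_high=ci[1],
        prevalence_weight=entry.get("prevalence_weight", 1.0),
        strategy=strategy,
    )


def load_profiles(path=None) -> tuple[TriangularParams, list[ComorbidityProfile]]:
    """Load the baseline distribution and comorbidity profiles from YAML.

    With no argument, loads the packaged default profile file with the five
    literature-based comorbidities (trisomy 21, amyotrophic lateral
    sclerosis, cardiovascular disease, hypertension, type-2 diabetes).
    """
    if path is None:
        text = (
            resources.files("triage_sim").joinpath("data/profiles.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    base = doc["baseline"]
    baseline = TriangularParams(base["minimum"], base["maximum"], base["mode"])
    profiles = [_profile_from_dict(e, baseline) for e in doc["profiles"]]
    return baseline, profiles
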