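"""Slug-test conductivity estimation and Darcian throughflow for the weathering crust.

The near-surface "weathering crust" of ablating glacier ice behaves as a shallow
unconfined aquifer.  Hydraulic conductivity ``K`` is measured with bail-recharge
(slug) tests in shallow auger holes: the hole is evacuated, and the exponential
recovery of the water level ``h(t) = h0 * exp(-t / T0)`` yields the basic time
lag ``T0``.  With the Hvorslev shape factor for an unlined cylindrical intake,

    K = r^2 * ln(L / R) / (2 * L * T0)

where ``r`` is the casing radius, ``R`` the effective intake radius and ``L``
the intake (wetted) length.  ``K`` then feeds the Darcian throughflow velocity
``v_t = K * dh / phi`` and the specific discharge ``q = v_t * phi * d`` through
a saturated crust of thickness ``d`` and effective porosity ``phi``.

Units: ``K`` and ``v_t`` are reported in m per day at every interface; seconds
are used only inside the slug-test fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

SECONDS_PER_DAY = 86_400.0

__all__ = [
    "SECONDS_PER_DAY",
    "AugerHole",
    "RechargeCurve",
    "CrustProperties",
    "KEstimate",
    "KSummary",
    "NoRechargeError",
    "estimate_K",
    "darcian_velocity",
    "specific_discharge",
    "summarize_K",
    "hvorslev_shape_factor",
    "basic_time_lag",
]


class NoRechargeError(ValueError):
    """Raised when a recharge record shows no head recovery (zero/positive fitted slope)."""


def _require_positive(name: str, value: float) -> None:
    if not (value > 0):
        raise ValueError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class AugerHole:
    """Geometry of a shallow auger hole used for a bail-recharge test.

    Defaults describe a 50 mm diameter ice auger hole: casing radius ``r`` =
    25 mm, an unlined hole so the effective intake radius ``R`` equals ``r``,
    and an intake length ``L`` of 0.20 m.  ``h0`` is the initial head
    displacement produced by bailing.
    """

    r: float = 0.025
    R: float | None = None
    L: float = 0.20
    h0: float = 0.30

    def __post_init__(self) -> None:
        _require_positive("r", self.r)
        _require_positive("L", self.L)
        _require_positive("h0", self.h0)
        if self.R is None:
            object.__setattr__(self, "R", self.r)
        _require_positive("R", self.R)
        if not (self.L > self.R):
            raise ValueError(f"L must exceed R, got L={self.L!r}, R={self.R!r}")


def hvorslev_shape_factor(hole: AugerHole) -> float:
    """ln(L/R) / (2 L), the geometric factor of the basic-time-lag formula (1/m)."""
    return math.log(hole.L / hole.R) / (2.0 * hole.L)


def basic_time_lag(K_m_per_d: float, hole: AugerHole) -> float:
    """Basic time lag T0 (seconds) implied by a conductivity in m/d."""
    _require_positive("K", K_m_per_d)
    k_mps = K_m_per_d / SECONDS_PER_DAY
    return hole.r**2 * hvorslev_shape_factor(hole) / k_mps


@dataclass
class RechargeCurve:
    """A bail-recharge water-level record: times (s), head displacement (m), geometry."""

    t: np.ndarray
    h: np.ndarray
    hole: AugerHole = field(default_factory=AugerHole)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if self.t.shape != self.h.shape or self.t.ndim != 1:
            raise ValueError("t and h must be 1-D arrays of equal length")
        if len(self.t) < 5:
            raise ValueError(f"need at least 5 samples, got {len(self.t)}")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.h < 0):
            raise ValueError("head displacements must be non-negative")


@dataclass(frozen=True)
class CrustProperties:
    """Hydraulic state of the saturated weathering crust.

    Defaults are the study-site values: mean conductivity 0.28 m/d, local
    surface slope 0.022 m/m, effective porosity 22% and saturated thickness
    0.29 m.
    """

    K: float = 0.28
    slope: float = 0.022
    porosity: float = 0.22
    thickness: float = 0.29

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError(f"K must be non-negative, got {self.K!r}")
        _require_positive("slope", self.slope)
        _require_positive("thickness", self.thickness)
        if not (0 < self.porosity <= 1):
            raise ValueError(f"porosity must lie in (0, 1], got {self.porosity!r}")


@dataclass(frozen=True)
class KEstimate:
    """Result of a slug-test fit.

    ``K`` (m/d) is NaN when the record is incomplete (head never recovered to
    <= exp(-1) of its initial displacement), mirroring the exclusion of
    partially recharged holes from conductivity statistics.
    """

    K: float
    T0: float
    fit_r2: float
    n_points: int
    complete: bool


# fraction of h0 the head must fall below for the record to count as complete
# (one basic time lag observed)
COMPLETE_RECOVERY_FRACTION = math.exp(-1.0)


def estimate_K(
    curve: RechargeCurve,
    *,
    skip_initial: int = 2,
    min_rel_head: float = 0.1,
) -> KEstimate:
    """Fit ln(h/h0) against t and convert the basic time lag to conductivity.

    Parameters
    ----------
    curve:
        Validated recharge record.
    skip_initial:
        Leading samples excluded from the fit (bail turbulence), default 2.
    min_rel_head:
        Tail cutoff: samples with ``h < min_rel_head * h0`` are excluded so the
        log-linear fit is not dominated by sensor noise near full recovery.

    Returns
    -------
    KEstimate with ``K`` in m/d, ``T0`` in s, the coefficient of determination
    of the log-linear fit, the number of points used, and a completeness flag.
    ``K`` is withheld (NaN) for incomplete records.
    """
    h0 = curve.h[0]
    if not (h0 > 0):
        raise ValueError("initial head displacement must be positive")

    complete = bool(np.min(curve.h) <= COMPLETE_RECOVERY_FRACTION * h0)

    idx = np.arange(len(curve.t)) >= skip_initial
    mask = idx & (curve.h > 0) & (curve.h >= min_rel_head * h0)
    t = curve.t[mask]
    y = np.log(curve.h[mask] / h0)
    if len(t) < 3:
        raise ValueError("too few usable points for a log-linear fit")

    slope, intercept = np.polyfit(t, y, 1)
    if slope >= 0:
        raise NoRechargeError("no recharge: head does not decay over the record")

    resid = y - (slope * t + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)

    T0 = -1.0 / slope
    k_mps = curve.hole.r**2 * hvorslev_shape_factor(curve.hole) / T0
    K = k_mps * SECONDS_PER_DAY if complete else float("nan")
    return KEstimate(K=K, T0=float(T0), fit_r2=float(r2), n_points=int(mask.sum()), complete=complete)


def darcian_velocity(props: CrustProperties) -> float:
    """Throughflow (pore-water) velocity v_t = K * slope / porosity, in m/d."""
    return props.K * props.slope / props.porosity


def specific_discharge(v_t: float, props: CrustProperties) -> float:
    """Meltwater volume crossing a 1 m-wide strip of saturated crust, m^3/d per m.

    Equals ``v_t * porosity * thickness`` (equivalently ``K * slope * thickness``).
    """
    if v_t < 0:
        raise ValueError(f"v_t must be non-negative, got {v_t!r}")
    return v_t * props.porosity * props.thickness


@dataclass(frozen=True)
class KSummary:
    mean: float
    sd: float | None
    n: int
    min: float
    max: float


def summarize_K(estimates: Sequence[KEstimate]) -> KSummary:
    """Arithmetic mean/sd/range of conductivity over *complete* estimates only."""
    values = np.array([e.K for e in estimates if e.complete], dtype=float)
    if len(values) == 0:
        raise ValueError("no complete recharge estimates to summarize")
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else None
    return KSummary(
        mean=float(values.mean()),
        sd=sd,
        n=len(values),
        min=float(values.min()),
        max=float(values.max()),
    )
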