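"""Cell-to-carbon conversion, per-area microbial loads and doubling-time accumulation.

Cell counts are converted to carbon via four schemes, all widely used in
aquatic microbiology:

* ``constant_low`` / ``constant_high`` -- fixed mass per cell (bacteria 11 or
  20 fg C, algae 153 or 260 fg C), independent of cell size;
* ``allometric`` -- M = c * V**a with (c=162, a=0.91) for bacteria and
  (c=109, a=0.991) for algae, where V is the biovolume in um^3;
* ``biovolume_ratio`` -- fixed carbon density, 560 fg C/um^3 for bacteria and
  110 fg C/um^3 for algal plasma volume.

Biovolumes come from simple geometric idealisations: cells below 1 um are
spheres, larger bacteria are rods (hemispherical-ended cylinders with a
configurable length:width ratio), and algae are 10 um diameter cylinders.
Each size class is represented by its bin midpoint; the open-ended >15 um
algal class is pinned to a nominal 27.5 um length (typical of the filamentous
glacier alga *Ancylonema nordenskioeldii*).

Per-area loads integrate an interstitial abundance (cells/mL) over the
saturated crust: ``load = abundance * 1e6 mL/m^3 * thickness * porosity``.
Growth under exponential doubling contributes a first-day abundance increase
of ``C0 * (2**(1/T_d) - 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .census import SizeClassScheme
from .hydraulics import CrustProperties

# module-level unit constants, exercised by a unit-audit test
KG_PER_FG = 1.0e-18
ML_PER_M3 = 1.0e6
M2_PER_KM2 = 1.0e6

METHODS = ("constant_low", "constant_high", "allometric", "biovolume_ratio")
Method = Literal["constant_low", "constant_high", "allometric", "biovolume_ratio"]

__all__ = [
    "KG_PER_FG",
    "ML_PER_M3",
    "M2_PER_KM2",
    "METHODS",
    "CellGeometry",
    "BiomassConstants",
    "GrowthModel",
    "biovolume",
    "carbon_per_cell",
    "class_geometries",
    "class_taxa",
    "class_carbon",
    "mean_cell_carbon",
    "load_per_area",
    "carbon_areal",
    "growth_increment",
    "accumulation_flux",
]


@dataclass(frozen=True)
class CellGeometry:
    """Idealised cell shape for biovolume estimation.

    ``length`` is the class-representative cell length (um).  Rods are
    hemispherical-ended cylinders of total length ``length`` and width
    ``length / aspect_ratio``; cylinders (algae) have a fixed ``diameter``.
    """

    shape: Literal["sphere", "rod", "cylinder"]
    length: float
    aspect_ratio: float = 2.0
    diameter: float = 10.0

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "rod", "cylinder"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if not (self.length > 0):
            raise ValueError("length must be positive")
        if self.shape == "rod" and self.aspect_ratio < 1:
            raise ValueError("rod aspect_ratio must be >= 1")
        if self.shape == "cylinder" and not (self.diameter > 0):
            raise ValueError("cylinder diameter must be positive")


def biovolume(geom: CellGeometry) -> float:
    """Cell volume in um^3 for the idealised geometry.

    sphere: pi L^3 / 6; rod: cylinder of length (L - w) plus a sphere of
    diameter w = L / aspect_ratio (the two hemispherical caps); cylinder:
    pi (d/2)^2 L.
    """
    L = geom.length
    if geom.shape == "sphere":
        return math.pi * L**3 / 6.0
    if geom.shape == "rod":
        w = L / geom.aspect_ratio
        return math.pi * w**2 / 4.0 * (L - w) + math.pi * w**3 / 6.0
    return math.pi * (geom.diameter / 2.0) ** 2 * L


@dataclass(frozen=True)
class BiomassConstants:
    """Conversion constants for the four carbon schemes (all fg C based)."""

    bacteria_constant_low: float = 11.0
    algae_constant_low: float = 153.0
    bacteria_constant_high: float = 20.0
    algae_constant_high: float = 260.0
    bacteria_allometric_c: float = 162.0
    bacteria_allometric_a: float = 0.91
    algae_allometric_c: float = 109.0
    algae_allometric_a: float = 0.991
    bacteria_ratio: float = 560.0  # fg C per um^3
    algae_ratio: float = 110.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not (value > 0):
                raise ValueError(f"{name} must be positive, got {value!r}")


def carbon_per_cell(
    V: float,
    taxon: Literal["bacteria", "algae"],
    method: Method,
    constants: BiomassConstants = BiomassConstants(),
) -> float:
    """Carbon content of one cell in fg C.

    Constant-mass methods ignore the biovolume ``V``; allometric returns
    ``c * V**a``; biovolume_ratio returns ``ratio * V``.
    """
    if taxon not in ("bacteria", "algae"):
        raise ValueError(f"unknown taxon {taxon!r}")
    if method == "constant_low":
        return constants.bacteria_constant_low if taxon == "bacteria" else constants.algae_constant_low
    if method == "constant_high":
        return constants.bacteria_constant_high if taxon == "bacteria" else constants.algae_constant_high
    if not (V > 0):
        raise ValueError("volume-based methods need V > 0")
    if method == "allometric":
        if taxon == "bacteria":
            return constants.bacteria_allometric_c * V**constants.bacteria_allometric_a
        return constants.algae_allometric_c * V**constants.algae_allometric_a
    if method == "biovolume_ratio":
        ratio = constants.bacteria_ratio if taxon == "bacteria" else constants.algae_ratio
        return ratio * V
    raise ValueError(f"unknown method {method!r}")


def class_geometries(
    scheme: SizeClassScheme = SizeClassScheme(),
    rod_aspect_ratio: float = 2.0,
    algal_diameter: float = 10.0,
    large_algae_length: float = 27.5,
) -> list[CellGeometry]:
    """One representative geometry per size class.

    The first (sub-micron) class is a sphere, remaining bacterial classes are
    rods, classes at/above the bacteria/algae split are cylinders of
    ``algal_diameter``.  Lengths are bin midpoints except the open-ended last
    class, pinned to ``large_algae_length``.
    """
    geoms: list[CellGeometry] = []
    for i, (lo, hi) in enumerate(scheme.class_edges()):
        length = large_algae_length if hi is None else 0.5 * (lo + hi)
        if lo >= scheme.bacteria_algae_split:
            geoms.append(CellGeometry("cylinder", length, diameter=algal_diameter))
        elif i == 0:
            geoms.append(CellGeometry("sphere", length))
        else:
            geoms.append(CellGeometry("rod", length, aspect_ratio=rod_aspect_ratio))
    return geoms


def class_taxa(scheme: SizeClassScheme = SizeClassScheme()) -> list[str]:
    """'bacteria' or 'algae' per class, split at the scheme's 10 um threshold."""
    return ["bacteria" if b else "algae" for b in scheme.is_bacteria()]


def class_carbon(
    method: Method,
    scheme: SizeClassScheme = SizeClassScheme(),
    constants: BiomassConstants = BiomassConstants(),
    **geometry_kwargs,
) -> np.ndarray:
    """fg C per cell for every size class under one conversion method."""
    geoms = class_geometries(scheme, **geometry_kwargs)
    taxa = class_taxa(scheme)
    return np.array(
        [carbon_per_cell(biovolume(g), tax, method, constants) for g, tax in zip(geoms, taxa)]
    )


def _check_simplex(proportions: Sequence[float]) -> np.ndarray:
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0) or not math.isclose(float(p.sum()), 1.0, abs_tol=1e-6):
        raise ValueError("class proportions must be a simplex vector")
    return p


def mean_cell_carbon(
    proportions: Sequence[float],
    method: Method,
    scheme: SizeClassScheme = SizeClassScheme(),
    constants: BiomassConstants = BiomassConstants(),
    include_large_algae: bool = False,
    **geometry_kwargs,
) -> float:
    """Mix-weighted mean carbon per counted cell, fg C.

    Without ``include_large_algae`` the open >15 um class contributes zero
    mass (its cells stay in the count denominator, matching a "cells <= 15 um"
    carbon figure over the same census).
    """
    p = _check_simplex(proportions)
    M = class_carbon(method, scheme, constants, **geometry_kwargs)
    if len(p) != len(M):
        raise ValueError("proportions length must match the number of size classes")
    if not include_large_algae:
        M = np.where(scheme.is_large_algae(), 0.0, M)
    return float(np.sum(p * M))


def load_per_area(abundance: float, props: CrustProperties) -> float:
    """Cells per m^2 of crust: abundance (cells/mL) integrated over the
    saturated pore volume (thickness * porosity)."""
    if abundance < 0:
        raise ValueError("abundance must be non-negative")
    return abundance * ML_PER_M3 * props.thickness * props.porosity


def carbon_areal(
    load: float,
    proportions: Sequence[float],
    method: Method,
    scheme: SizeClassScheme = SizeClassScheme(),
    constants: BiomassConstants = BiomassConstants(),
    include_large_algae: bool = False,
    **geometry_kwargs,
) -> float:
    """Carbon load in kg C per km^2 from a cell load in cells per m^2."""
    if load < 0:
        raise ValueError("load must be non-negative")
    mean_fg = mean_cell_carbon(
        proportions, method, scheme, constants, include_large_algae, **geometry_kwargs
    )
    return load * M2_PER_KM2 * mean_fg * KG_PER_FG


@dataclass(frozen=True)
class GrowthModel:
    """Exponential growth from an antecedent abundance ``C0`` (cells/mL) with
    doubling time ``doubling_time`` (days); presets of interest are 1, 4, 11 d."""

    C0: float = 2.3e3
    doubling_time: float = 4.0

    def __post_init__(self) -> None:
        if not (self.C0 > 0):
            raise ValueError("C0 must be positive")
        if not (self.doubling_time > 0):
            raise ValueError("doubling_time must be positive")


def growth_increment(model: GrowthModel) -> float:
    """First-day abundance increase under exponential doubling:
    ``C0 * (2**(1/T_d) - 1)`` in cells/mL/day."""
    return model.C0 * (2.0 ** (1.0 / model.doubling_time) - 1.0)


def accumulation_flux(
    increment: float,
    props: CrustProperties,
    proportions: Sequence[float],
    method: Method,
    scheme: SizeClassScheme = SizeClassScheme(),
    constants: BiomassConstants = BiomassConstants(),
    include_large_algae: bool = False,
    **geometry_kwargs,
) -> float:
    """In-situ carbon accumulation, kg C per km^2 per day, from an abundance
    increment (cells/mL/day) distributed over the configured size mix."""
    if increment < 0:
        raise ValueError("increment must be non-negative")
    return carbon_areal(
        load_per_area(increment, props),
        proportions,
        method,
        scheme,
        constants,
        include_large_algae,
        **geometry_kwargs,
    )
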