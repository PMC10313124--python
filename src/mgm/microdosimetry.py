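"""Microdosimetric geometry and conversions.

Lineal energy ``y`` is the energy imparted to a site in a single event divided
by the site's mean chord length; for a convex body the mean isotropic chord is
given by Cauchy's formula, which for a sphere equals two-thirds of the
diameter.  Specific energy ``z`` divides by the site mass instead.  The
frequency means ``yF`` (keV/um) and ``zF`` (Gy) are therefore related through
the site geometry alone::

    zF = yF * l_bar * k / m

with ``l_bar`` the mean chord length (um), ``m`` the site mass (kg) and ``k``
the keV-to-joule factor.  This module provides the spherical-site geometry,
that conversion, and the weighted beam averages <yF>, <yF^2> and the dose-mean
lineal energy ``yD = <yF^2>/<yF>`` used to collapse mixed beams onto the
model's single independent variable.

Units are fixed package-wide: keV/um for lineal energy, Gy for specific
energy and dose, um for lengths, kg/m^3 for density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

KEV_TO_J = 1.602176634e-16  # exact, from the 2019 SI definition of the eV

WATER_DENSITY_KG_M3 = 1000.0

#: Validity range of the model's yF-parameterized functions, keV/um.
YF_VALID_RANGE = (2.0, 200.0)


def mean_chord_length(diameter_um: float) -> float:
    """Mean isotropic chord length of a sphere: (2/3) * diameter (Cauchy)."""
    if diameter_um <= 0:
        raise ValueError(f"diameter must be positive, got {diameter_um}")
    return (2.0 / 3.0) * diameter_um


@dataclass(frozen=True)
class MicrodosimetricSite:
    """Spherical site of liquid water (density configurable).

    Derived quantities:

    ``mean_chord_um``
        (2/3) * diameter — Cauchy's formula for a sphere.
    ``mass_kg``
        density * (pi/6) * diameter^3 with the diameter in metres.
    """

    diameter_um: float
    density_kg_m3: float = WATER_DENSITY_KG_M3

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError(f"diameter must be positive, got {self.diameter_um}")
        if self.density_kg_m3 <= 0:
            raise ValueError(f"density must be positive, got {self.density_kg_m3}")

    @property
    def mean_chord_um(self) -> float:
        return mean_chord_length(self.diameter_um)

    @property
    def mass_kg(self) -> float:
        d_m = self.diameter_um * 1e-6
        return self.density_kg_m3 * (np.pi / 6.0) * d_m**3


def yF_to_zF(yF_keV_um: float, site: MicrodosimetricSite) -> float:
    """Convert frequency-mean lineal energy (keV/um) to frequency-mean
    specific energy (Gy) for a spherical site.

    zF = yF * l_bar * k / m, where the mean event energy is yF times the mean
    chord length.  Scales as 1/d^2 with the site diameter.
    """
    if yF_keV_um <= 0:
        raise ValueError(f"yF must be positive, got {yF_keV_um}")
    return yF_keV_um * site.mean_chord_um * KEV_TO_J / site.mass_kg


def zF_to_yF(zF_Gy: float, site: MicrodosimetricSite) -> float:
    """Inverse of :func:`yF_to_zF`; composes with it to identity."""
    if zF_Gy <= 0:
        raise ValueError(f"zF must be positive, got {zF_Gy}")
    return zF_Gy * site.mass_kg / (site.mean_chord_um * KEV_TO_J)


@dataclass
class BeamSpectrum:
    """Weighted (weight, yF) components of a mixed beam.

    Weights are normalized to sum to one on construction.  Each component is
    characterized solely by its yF under the track-segment (short-track)
    condition; full single-event spectra f(y) are outside this model's input.
    """

    components: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("spectrum needs at least one (weight, yF) component")
        total = sum(w for w, _ in self.components)
        if total <= 0:
            raise ValueError("component weights must have a positive sum")
        for w, y in self.components:
            if w < 0:
                raise ValueError(f"negative weight {w}")
            if y <= 0:
                raise ValueError(f"yF must be positive, got {y}")
        self.components = [(w / total, y) for w, y in self.components]

    @classmethod
    def single(cls, yF: float) -> "BeamSpectrum":
        return cls([(1.0, yF)])

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for w, _ in self.components])

    @property
    def yF_values(self) -> np.ndarray:
        return np.array([y for _, y in self.components])


def beam_averages(spectrum: BeamSpectrum) -> tuple[float, float, float]:
    """Weighted moments of a beam: (<yF>, <yF^2>, yD = <yF^2>/<yF>).

    yD >= <yF> always (Cauchy–Schwarz), with equality only for a
    single-component beam.
    """
    w = spectrum.weights
    y = spectrum.yF_values
    yF_mean = float(np.dot(w, y))
    yF2_mean = float(np.dot(w, y**2))
    return yF_mean, yF2_mean, yF2_mean / yF_mean


def load_beam(path: str | Path) -> BeamSpectrum:
    """Read a beam description from a two-column CSV (weight, yF) or a YAML
    file with a ``components`` list of [weight, yF] pairs."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            data = yaml.safe_load(fh)
        comps = [(float(w), float(y)) for w, y in data["components"]]
    else:
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
        comps = [(float(w), float(y)) for w, y in arr]
    return BeamSpectrum(comps)


def save_beam(spectrum: BeamSpectrum, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"units": {"yF": "keV/um"},
                 "components": [[w, y] for w, y in spectrum.components]},
                fh,
            )
    else:
        np.savetxt(path, np.array(spectrum.components), delimiter=",",
                   header="weight,yF_keV_um")
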