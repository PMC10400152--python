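"""Core domain types and preprocessing for leaf reflectance libraries.

A leaf spectrum is reflectance (as a fraction in [0, 1]) on a wavelength
grid; the canonical raw grid is 350-2500 nm at 1 nm resolution (2151
points), the grid produced by benchtop VIS-NIR-SWIR spectroradiometers
with a leaf contact probe. Samples bundle a spectrum with species/year/
environment metadata and a nine-trait vector (macronutrients in % dry
matter, leaf water content in %, chlorophyll in umol m-2 and leaf mass
per area in g m-2); any trait may be missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TRAITS",
    "TRAIT_UNITS",
    "PERCENT_TRAITS",
    "WavelengthGrid",
    "Spectrum",
    "TraitVector",
    "Sample",
    "SpectralLibrary",
    "GravimetricRecord",
    "average_replicate_scans",
    "window_average",
    "derive_lwc",
    "derive_lma",
]

#: Canonical trait order used throughout the package.
TRAITS: tuple[str, ...] = ("N", "P", "K", "Mg", "Ca", "S", "LWC", "CHL", "LMA")

TRAIT_UNITS: dict[str, str] = {
    "N": "% dry matter",
    "P": "% dry matter",
    "K": "% dry matter",
    "Mg": "% dry matter",
    "Ca": "% dry matter",
    "S": "% dry matter",
    "LWC": "%",
    "CHL": "umol m-2",
    "LMA": "g m-2",
}

#: Traits bounded to [0, 100] (percentages); the rest are nonnegative.
PERCENT_TRAITS: frozenset[str] = frozenset({"N", "P", "K", "Mg", "Ca", "S", "LWC"})


class GridMismatchError(ValueError):
    """Two spectra or libraries are on different wavelength grids."""


@dataclass(frozen=True)
class WavelengthGrid:
    """An ordered set of wavelengths (nm).

    Regular grids remember their step so window averaging can validate
    window sizes; coarsened grids hold explicit band centers.
    """

    wavelengths: np.ndarray
    step: float | None = None  # nm, set for regular grids

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    @classmethod
    def regular(cls, start: float, stop: float, step: float) -> "WavelengthGrid":
        if stop <= start:
            raise ValueError(f"stop ({stop}) must exceed start ({start})")
        if step <= 0:
            raise ValueError(f"step must be positive, got {step}")
        n = int(math.floor((stop - start) / step)) + 1
        return cls(start + step * np.arange(n), step=step)

    @classmethod
    def canonical(cls) -> "WavelengthGrid":
        """The 350-2500 nm, 1 nm grid (2151 points)."""
        return cls.regular(350.0, 2500.0, 1.0)

    @property
    def n_points(self) -> int:
        return int(self.wavelengths.size)

    def __len__(self) -> int:
        return self.n_points

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.wavelengths.shape == other.wavelengths.shape and np.array_equal(
            self.wavelengths, other.wavelengths
        )

    def __hash__(self) -> int:
        return hash((self.wavelengths.size, float(self.wavelengths[0]), float(self.wavelengths[-1])))


@dataclass(frozen=True)
class Spectrum:
    """Reflectance fractions on a wavelength grid (one scan or scan-average)."""

    grid: WavelengthGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.n_points,):
            raise ValueError(
                f"expected {self.grid.n_points} reflectance values, got {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("reflectance values must be finite")
        if v.min() < 0.0 or v.max() > 1.0:
            hint = ""
            if v.max() > 1.5:
                hint = " (values look like percent; reflectance must be a fraction in [0, 1])"
            raise ValueError(
                f"reflectance out of range [0, 1]: min={v.min():.4g}, max={v.max():.4g}{hint}"
            )
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class TraitVector:
    """The nine leaf traits; NaN marks a missing measurement."""

    values: np.ndarray  # aligned with TRAITS

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(TRAITS),):
            raise ValueError(f"expected {len(TRAITS)} trait values, got shape {v.shape}")
        for i, name in enumerate(TRAITS):
            x = v[i]
            if np.isnan(x):
                continue
            if name in PERCENT_TRAITS and not (0.0 <= x <= 100.0):
                raise ValueError(f"{name}={x} outside [0, 100] {TRAIT_UNITS[name]}")
            if name not in PERCENT_TRAITS and x < 0.0:
                raise ValueError(f"{name}={x} must be nonnegative ({TRAIT_UNITS[name]})")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "TraitVector":
        unknown = set(d) - set(TRAITS)
        if unknown:
            raise ValueError(f"unknown trait(s): {sorted(unknown)}")
        return cls(np.array([d.get(t, np.nan) for t in TRAITS], dtype=float))

    def __getitem__(self, trait: str) -> float:
        return float(self.values[TRAITS.index(trait)])

    def is_missing(self, trait: str) -> bool:
        return bool(np.isnan(self.values[TRAITS.index(trait)]))

    def as_dict(self) -> dict[str, float]:
        return {t: float(v) for t, v in zip(TRAITS, self.values)}


@dataclass(frozen=True)
class Sample:
    id: str
    species: str
    dataset: str
    year: int
    environment: str
    spectrum: Spectrum
    traits: TraitVector


@dataclass
class SpectralLibrary:
    """An ordered collection of samples on one grid; the calibration currency."""

    samples: list[Sample] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate sample id: {dup!r}")
        grids = {s.spectrum.grid for s in self.samples}
        if len(grids) > 1:
            raise GridMismatchError("samples are on heterogeneous wavelength grids")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, i: int) -> Sample:
        return self.samples[i]

    @property
    def grid(self) -> WavelengthGrid:
        if not self.samples:
            raise ValueError("empty library has no grid")
        return self.samples[0].spectrum.grid

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.samples]

    def spectra_matrix(self) -> np.ndarray:
        """(n_samples, n_wavelengths) reflectance matrix."""
        return np.vstack([s.spectrum.values for s in self.samples])

    def trait_values(self, trait: str) -> np.ndarray:
        i = TRAITS.index(trait)
        return np.array([s.traits.values[i] for s in self.samples])

    def with_trait(self, trait: str) -> "SpectralLibrary":
        """Sub-library of samples with the trait measured; spectra untouched."""
        keep = [s for s in self.samples if not s.traits.is_missing(trait)]
        return SpectralLibrary(keep, provenance=self.provenance)

    def subset_ids(self, ids) -> "SpectralLibrary":
        wanted = set(ids)
        missing = wanted - set(self.ids)
        if missing:
            raise KeyError(f"ids not in library: {sorted(missing)[:5]}")
        return SpectralLibrary(
            [s for s in self.samples if s.id in wanted], provenance=self.provenance
        )

    def map_spectra(self, fn) -> "SpectralLibrary":
        """Apply a Spectrum -> Spectrum transform to every sample."""
        return SpectralLibrary(
            [replace(s, spectrum=fn(s.spectrum)) for s in self.samples],
            provenance=self.provenance,
        )


@dataclass(frozen=True)
class GravimetricRecord:
    """Fresh weight, dry weight (g) and leaf area (cm^2) for one leaf."""

    fw_g: float
    dw_g: float
    la_cm2: float

    def __post_init__(self) -> None:
        if self.dw_g <= 0:
            raise ValueError(f"dry weight must be positive, got {self.dw_g}")
        if self.fw_g < self.dw_g:
            raise ValueError(
                f"fresh weight ({self.fw_g} g) below dry weight ({self.dw_g} g): "
                "likely a data-entry fault"
            )
        if self.la_cm2 <= 0:
            raise ValueError(f"leaf area must be positive, got {self.la_cm2}")


def average_replicate_scans(scans: list[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate scans of one leaf.

    Replicate scans (nine per leaf in the library protocol: three each at
    tip, middle and base) are averaged to damp within-leaf heterogeneity.
    """
    if not scans:
        raise ValueError("need at least one scan to average")
    grid = scans[0].grid
    for s in scans[1:]:
        if s.grid != grid:
            raise GridMismatchError("replicate scans are on different grids")
    return Spectrum(grid, np.mean([s.values for s in scans], axis=0))


def window_average(spec: Spectrum, window_nm: float) -> Spectrum:
    """Coarsen a spectrum by averaging contiguous non-overlapping windows.

    Windows start at the grid start; a trailing partial window is averaged
    over the points it contains (the canonical 2151-point grid with a 10 nm
    window yields 215 full bands plus one trailing point = 216 bands). The
    output grid records the mean wavelength of each window.
    """
    grid = spec.grid
    if grid.step is None:
        raise ValueError("window averaging requires a regular input grid")
    if window_nm < grid.step:
        raise ValueError(f"window ({window_nm} nm) smaller than grid step ({grid.step} nm)")
    ratio = window_nm / grid.step
    n_per = int(round(ratio))
    if abs(ratio - n_per) > 1e-9:
        raise ValueError(
            f"window ({window_nm} nm) must be a multiple of the grid step ({grid.step} nm)"
        )
    n = grid.n_points
    edges = range(0, n, n_per)
    centers = np.array([grid.wavelengths[i : i + n_per].mean() for i in edges])
    values = np.array([spec.values[i : i + n_per].mean() for i in edges])
    step = window_nm if n % n_per == 0 else None
    return Spectrum(WavelengthGrid(centers, step=step), values)


def derive_lwc(rec: GravimetricRecord) -> float:
    """Leaf water content, %: (FW - DW) / FW * 100."""
    return (rec.fw_g - rec.dw_g) / rec.fw_g * 100.0


def derive_lma(rec: GravimetricRecord) -> float:
    """Leaf mass per area, g m-2: DW / LA with LA converted from cm^2 to m^2."""
    return rec.dw_g / (rec.la_cm2 * 1e-4)
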