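"""Synthetic leaf spectral libraries with controllable domain shift.

The generator emulates the statistical structure a library-transfer
analysis relies on, without claiming radiative-transfer realism:

* species-specific smooth reflectance archetypes (VIS floor, green bump,
  red edge, NIR plateau, SWIR water features);
* trait-linked Gaussian absorption features, so reflectance depends
  (linearly, before clipping) on the trait vector — chlorophyll in the
  blue/red, proteins/N in the 1500-1750 nm region, water at 1450/1940 nm,
  leaf mass per area as broad NIR scattering;
* trait values drawn from a truncated multivariate normal with a
  species-specific mean/SD and a fixed correlation structure (notably the
  strong N-chlorophyll association);
* domain shift between the library and external species, realised both as
  an additive smooth baseline offset and as a perturbation of the band
  sensitivities, scaled by a single ``shift_magnitude`` knob;
* per-sample Gaussian scan noise.

Everything is bit-for-bit reproducible from the configuration seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .spectra import (
    PERCENT_TRAITS,
    TRAITS,
    Sample,
    SpectralLibrary,
    Spectrum,
    TraitVector,
    WavelengthGrid,
)

__all__ = [
    "ConfigurationError",
    "FeatureBand",
    "SpeciesArchetype",
    "TraitDistribution",
    "SpeciesConfig",
    "SimulationConfig",
    "sample_traits",
    "render_spectrum",
    "generate_study",
    "default_archetype",
    "default_trait_distribution",
    "demo_config",
    "full_study_config",
    "linear_study_config",
    "FULL_STUDY_LIBRARY_DESIGN",
    "FULL_STUDY_EXTERNAL_DESIGN",
]


class ConfigurationError(ValueError):
    """A simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# archetypes

@dataclass(frozen=True)
class FeatureBand:
    """One Gaussian absorption feature tied to a trait.

    ``sensitivity`` is reflectance units removed per trait unit at the band
    center; ``width_nm`` is the Gaussian sigma.
    """

    center_nm: float
    width_nm: float
    trait: str
    sensitivity: float

    def __post_init__(self) -> None:
        if not (350.0 <= self.center_nm <= 2500.0):
            raise ConfigurationError(f"band center {self.center_nm} nm outside [350, 2500]")
        if self.width_nm <= 0:
            raise ConfigurationError(f"band width must be positive, got {self.width_nm}")
        if self.trait not in TRAITS:
            raise ConfigurationError(f"band references unknown trait {self.trait!r}")


@dataclass(frozen=True)
class SpeciesArchetype:
    """Species-level spectral shape: baseline, trait bands, and shift offset."""

    name: str
    baseline: np.ndarray
    feature_bands: tuple[FeatureBand, ...]
    shift: np.ndarray  # additive smooth offset encoding domain shift

    def __post_init__(self) -> None:
        base = np.asarray(self.baseline, dtype=float)
        if base.min() < 0.02 or base.max() > 0.95:
            raise ConfigurationError(
                f"{self.name}: baseline outside [0.02, 0.95] "
                f"(min={base.min():.3f}, max={base.max():.3f})"
            )
        shift = np.asarray(self.shift, dtype=float)
        if shift.shape != base.shape:
            raise ConfigurationError(f"{self.name}: shift and baseline shapes differ")
        object.__setattr__(self, "baseline", base)
        object.__setattr__(self, "shift", shift)


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# per-species smooth-shape parameters: (VIS floor, green-bump, NIR plateau)
_SHAPE = {
    "maize": (0.16, 0.080, 0.42),
    "sorghum": (0.155, 0.075, 0.44),
    "soybean": (0.165, 0.090, 0.48),
    "camelina": (0.18, 0.100, 0.52),
}

# trait-linked absorption bands: (center nm, sigma nm, sensitivity per unit)
_BANDS: tuple[tuple[float, float, str, float], ...] = (
    (430.0, 28.0, "CHL", 1.6e-4),   # chlorophyll, blue absorption
    (660.0, 32.0, "CHL", 2.0e-4),   # chlorophyll, red absorption
    (1510.0, 45.0, "N", 0.020),     # protein/amide
    (1680.0, 55.0, "N", 0.015),
    (2180.0, 60.0, "N", 0.012),
    (1450.0, 45.0, "LWC", 1.2e-3),  # water
    (1940.0, 55.0, "LWC", 1.5e-3),
    (1190.0, 40.0, "LWC", 0.5e-3),
    (900.0, 150.0, "LMA", -8.0e-4),  # thicker leaf -> brighter NIR
    (2300.0, 80.0, "LMA", 5.0e-4),   # dry matter
    (2150.0, 40.0, "P", 0.080),
    (1730.0, 50.0, "K", 0.025),
    (530.0, 40.0, "Mg", 0.100),      # chlorophyll-linked green region
    (2340.0, 50.0, "Ca", 0.040),
    (2050.0, 40.0, "S", 0.120),
)


def _name_rng(name: str, salt: str) -> np.random.Generator:
    """Deterministic per-name generator for fixed shift shapes."""
    return np.random.default_rng(zlib.crc32(f"{name}/{salt}".encode()) % 2**31)


def default_archetype(
    species: str,
    grid: WavelengthGrid,
    shift_magnitude: float = 0.0,
) -> SpeciesArchetype:
    """Build the default archetype for a species.

    ``shift_magnitude > 0`` adds the species' fixed smooth offset curve and
    perturbs band sensitivities — use it for external species to create a
    library-vs-external domain shift; library species use magnitude 0.
    """
    wl = grid.wavelengths
    vis, green, plateau = _SHAPE.get(species.lower(), (0.16, 0.08, 0.45))
    base = (
        vis
        + green * _gauss(wl, 550.0, 35.0)
        + plateau * _sigmoid((wl - 710.0) / 18.0)
        - 0.12 * _gauss(wl, 1450.0, 55.0)
        - 0.20 * _gauss(wl, 1940.0, 85.0)
        - 0.05 * _gauss(wl, 1190.0, 45.0)
        - 0.15 * _sigmoid((wl - 2000.0) / 180.0)
    )
    rng = _name_rng(species.lower(), "shift")
    if shift_magnitude != 0.0:
        a, b, c = rng.uniform(-1.0, 1.0, size=3)
        shift = shift_magnitude * (
            0.050 * a * _sigmoid((wl - 900.0) / 250.0)
            + 0.040 * b * _gauss(wl, 1200.0, 300.0)
            + 0.030 * c * _gauss(wl, 1800.0, 400.0)
        )
        deltas = rng.uniform(-0.5, 0.5, size=len(_BANDS))
    else:
        rng.uniform(-1.0, 1.0, size=3)  # keep the stream aligned
        shift = np.zeros_like(wl)
        deltas = np.zeros(len(_BANDS))
    bands = tuple(
        FeatureBand(c_, w_, t_, s_ * (1.0 + shift_magnitude * d_))
        for (c_, w_, t_, s_), d_ in zip(_BANDS, deltas)
    )
    return SpeciesArchetype(name=species, baseline=base, feature_bands=bands, shift=shift)


# ---------------------------------------------------------------------------
# trait distributions

@dataclass(frozen=True)
class TraitDistribution:
    """Truncated multivariate normal over the nine traits."""

    mean: np.ndarray
    sd: np.ndarray
    corr: np.ndarray
    lower: np.ndarray = field(default=None)  # type: ignore[assignment]
    upper: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        m = np.asarray(self.mean, dtype=float)
        s = np.asarray(self.sd, dtype=float)
        c = np.asarray(self.corr, dtype=float)
        k = len(TRAITS)
        if m.shape != (k,) or s.shape != (k,):
            raise ConfigurationError(f"mean and sd must have {k} entries")
        if np.any(s < 0):
            raise ConfigurationError("trait SDs must be nonnegative")
        if c.shape != (k, k) or not np.allclose(c, c.T, atol=1e-10):
            raise ConfigurationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-10):
            raise ConfigurationError("correlation matrix must have unit diagonal")
        eig = np.linalg.eigvalsh(c)
        if eig.min() < -1e-8:
            raise ConfigurationError(
                f"correlation matrix is not positive semidefinite (min eig {eig.min():.3g})"
            )
        lower = self.lower if self.lower is not None else _default_lower()
        upper = self.upper if self.upper is not None else _default_upper()
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        if np.any(lower >= upper):
            raise ConfigurationError("truncation bounds must satisfy lower < upper")
        if np.any(m < lower) or np.any(m > upper):
            raise ConfigurationError("trait means must lie inside the truncation bounds")
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "sd", s)
        object.__setattr__(self, "corr", c)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)


def _default_lower() -> np.ndarray:
    return np.zeros(len(TRAITS))


def _default_upper() -> np.ndarray:
    return np.array([100.0 if t in PERCENT_TRAITS else np.inf for t in TRAITS])


def sample_traits(dist: TraitDistribution, n: int, seed: int) -> np.ndarray:
    """Draw n trait vectors by rejection on the truncation bounds."""
    if n < 1:
        raise ValueError(f"n must be at least 1, got {n}")
    rng = np.random.default_rng(seed)
    # PSD factor of the correlation (eigendecomposition tolerates zero modes)
    vals, vecs = np.linalg.eigh(dist.corr)
    factor = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))
    out = np.empty((n, len(TRAITS)))
    got = 0
    attempts = 0
    while got < n:
        batch = max(n - got, 64)
        z = rng.standard_normal((batch, len(TRAITS)))
        draws = dist.mean + (z @ factor.T) * dist.sd
        ok = np.all((draws >= dist.lower) & (draws <= dist.upper), axis=1)
        take = min(int(ok.sum()), n - got)
        out[got : got + take] = draws[ok][:take]
        got += take
        attempts += 1
        if attempts > 1000 and got == 0:
            raise ConfigurationError(
                "truncation bounds reject essentially all draws; widen bounds or shrink SDs"
            )
    return out


# default library-scale trait moments (units per trait: % dm, %, umol m-2, g m-2)
_BASE_MEAN = {"N": 2.5, "P": 0.25, "K": 1.6, "Mg": 0.25, "Ca": 0.45, "S": 0.18,
              "LWC": 78.0, "CHL": 450.0, "LMA": 55.0}
_BASE_SD = {"N": 0.7, "P": 0.08, "K": 0.50, "Mg": 0.09, "Ca": 0.18, "S": 0.05,
            "LWC": 5.0, "CHL": 110.0, "LMA": 12.0}

# species-level mean multipliers (legumes/eudicots richer in N, thinner leaves...)
_SPECIES_MEAN_MULT = {
    "maize": {},
    "sorghum": {"N": 0.95, "Ca": 1.10, "LMA": 1.05},
    "soybean": {"N": 1.30, "Ca": 1.25, "LMA": 0.80, "K": 1.10},
    "camelina": {"N": 1.20, "Ca": 1.35, "LMA": 0.70, "S": 1.25, "LWC": 1.04},
}


def _default_corr() -> np.ndarray:
    k = len(TRAITS)
    c = np.eye(k)

    def set_(a: str, b: str, r: float) -> None:
        i, j = TRAITS.index(a), TRAITS.index(b)
        c[i, j] = c[j, i] = r

    set_("N", "CHL", 0.80)   # about half of leaf N sits in chlorophyll
    set_("N", "S", 0.55)     # both bound in proteins
    set_("N", "Mg", 0.30)
    set_("Mg", "CHL", 0.35)  # Mg is the chlorophyll central ion
    set_("N", "LMA", -0.25)  # dilution in thicker leaves
    set_("LWC", "LMA", -0.35)
    set_("P", "N", 0.30)
    set_("K", "LWC", 0.25)
    # implied second-order associations, needed for positive semidefiniteness
    set_("S", "CHL", 0.45)
    set_("P", "CHL", 0.25)
    set_("LMA", "CHL", -0.20)
    set_("S", "Mg", 0.20)
    set_("P", "S", 0.20)
    return c


def default_trait_distribution(species: str, role: str = "library") -> TraitDistribution:
    """Per-species trait moments; external sets get shifted means and wider SDs."""
    sp = species.lower()
    mult = _SPECIES_MEAN_MULT.get(sp, {})
    mean = np.array([_BASE_MEAN[t] * mult.get(t, 1.0) for t in TRAITS])
    sd = np.array([_BASE_SD[t] for t in TRAITS])
    if role == "external":
        rng = _name_rng(sp, "traits")
        direction = rng.choice([-1.0, 1.0], size=len(TRAITS))
        mean = mean + 0.4 * sd * direction
        sd = sd * 1.25
    return TraitDistribution(mean=mean, sd=sd, corr=_default_corr())


# ---------------------------------------------------------------------------
# spectrum rendering

def render_spectrum(
    archetype: SpeciesArchetype,
    traits: dict[str, float] | TraitVector,
    noise_sd: float,
    seed: int | np.random.Generator,
    grid: WavelengthGrid,
    structured_noise_sd: float = 0.0,
) -> Spectrum:
    """reflectance = clip(baseline + shift - sum(bands) + noise, 0, 1).

    ``noise_sd`` is white per-point scan noise. ``structured_noise_sd``
    adds smooth per-sample baseline variation (random cubic Legendre
    combination) emulating probe-contact and leaf-surface effects — the
    trait-uncorrelated nuisance variance that makes small calibration
    sets overfit on real spectra.
    """
    if noise_sd < 0 or structured_noise_sd < 0:
        raise ValueError("noise SDs must be nonnegative")
    if isinstance(traits, TraitVector):
        tvals = traits.as_dict()
    else:
        tvals = dict(traits)
    wl = grid.wavelengths
    if archetype.baseline.shape != wl.shape:
        raise ValueError("archetype was built on a different grid")
    absorb = np.zeros_like(wl)
    for band in archetype.feature_bands:
        if band.trait not in tvals or np.isnan(tvals[band.trait]):
            raise KeyError(f"trait {band.trait!r} required by a feature band is missing")
        absorb += band.sensitivity * tvals[band.trait] * _gauss(wl, band.center_nm, band.width_nm)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=wl.shape) if noise_sd > 0 else np.zeros_like(wl)
    if structured_noise_sd > 0:
        # smooth high-rank nuisance: a random cubic trend plus random broad
        # bumps; a large library averages it out, a 20-sample set cannot
        x = (wl - wl.mean()) / ((wl[-1] - wl[0]) / 2.0)
        c0, c1, c2, c3 = rng.normal(0.0, 1.0, size=4)
        smooth = c0 + c1 * x + c2 * (1.5 * x**2 - 0.5) + c3 * (2.5 * x**3 - 1.5 * x)
        centers = rng.uniform(400.0, 2450.0, size=8)
        widths = rng.uniform(40.0, 250.0, size=8)
        amps = rng.normal(0.0, 1.0, size=8)
        for ci, wi, ai in zip(centers, widths, amps):
            smooth = smooth + ai * _gauss(wl, ci, wi)
        noise = noise + structured_noise_sd * smooth
    return Spectrum(grid, np.clip(archetype.baseline + archetype.shift - absorb + noise, 0.0, 1.0))


# ---------------------------------------------------------------------------
# study configuration

@dataclass(frozen=True)
class SpeciesConfig:
    """One dataset of one species within the study."""

    species: str
    n: int
    dist: TraitDistribution | None = None   # default: default_trait_distribution
    missing: tuple[str, ...] = ()           # traits recorded as missing
    year: int = 2019
    environment: str = "field"
    set_name: str | None = None             # external-set key; defaults to species
    archetype: SpeciesArchetype | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"{self.species}: n must be at least 1")
        bad = set(self.missing) - set(TRAITS)
        if bad:
            raise ConfigurationError(f"{self.species}: unknown missing traits {sorted(bad)}")


@dataclass(frozen=True)
class SimulationConfig:
    """Full study: library datasets, external datasets, noise and shift."""

    library: tuple[SpeciesConfig, ...]
    external: tuple[SpeciesConfig, ...]
    noise_sd: float = 0.004
    structured_noise_sd: float = 0.012
    shift_magnitude: float = 1.0
    seed: int = 0
    grid: WavelengthGrid = field(default_factory=WavelengthGrid.canonical)

    def __post_init__(self) -> None:
        if not self.library:
            raise ConfigurationError("at least one library dataset is required")
        if self.noise_sd < 0 or self.structured_noise_sd < 0:
            raise ConfigurationError("noise SDs must be nonnegative")
        names = [sc.set_name or sc.species.lower() for sc in self.external]
        if len(set(names)) != len(names):
            raise ConfigurationError("external set names must be unique")


def _make_samples(
    sc: SpeciesConfig,
    role: str,
    dataset: str,
    id_prefix: str,
    cfg: SimulationConfig,
    seed: int,
) -> list[Sample]:
    dist = sc.dist or default_trait_distribution(sc.species, role)
    shift = cfg.shift_magnitude if role == "external" else 0.0
    arch = sc.archetype or default_archetype(sc.species, cfg.grid, shift_magnitude=shift)
    traits = sample_traits(dist, sc.n, seed)
    rng = np.random.default_rng(seed + 1)
    samples = []
    for i in range(sc.n):
        tdict = dict(zip(TRAITS, traits[i]))
        spec = render_spectrum(arch, tdict, cfg.noise_sd, rng, cfg.grid,
                               structured_noise_sd=cfg.structured_noise_sd)
        recorded = dict(tdict)
        for t in sc.missing:
            recorded[t] = np.nan
        samples.append(
            Sample(
                id=f"{id_prefix}-{i:04d}",
                species=sc.species,
                dataset=dataset,
                year=sc.year,
                environment=sc.environment,
                spectrum=spec,
                traits=TraitVector.from_dict(recorded),
            )
        )
    return samples


def generate_study(
    config: SimulationConfig,
) -> tuple[SpectralLibrary, dict[str, SpectralLibrary]]:
    """Generate the library and the named external sets.

    Masked traits are generated (the leaf has them) but recorded as
    missing, mirroring external datasets lacking some lab measurements.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.generate_state(2 * (len(config.library) + len(config.external))) % (2**31)
    ci = 0
    lib_samples: list[Sample] = []
    for di, sc in enumerate(config.library, start=1):
        lib_samples.extend(
            _make_samples(sc, "library", dataset=f"lib{di}", id_prefix=f"L{di}-{sc.species}",
                          cfg=config, seed=int(children[ci]))
        )
        ci += 2
    library = SpectralLibrary(lib_samples, provenance=f"synthetic study seed={config.seed}")
    externals: dict[str, SpectralLibrary] = {}
    for di, sc in enumerate(config.external, start=1):
        name = sc.set_name or sc.species.lower()
        samples = _make_samples(sc, "external", dataset=f"ext-{name}",
                                id_prefix=f"E-{name}", cfg=config, seed=int(children[ci]))
        ci += 2
        externals[name] = SpectralLibrary(
            samples, provenance=f"synthetic external {name} seed={config.seed}"
        )
    return library, externals


# ---------------------------------------------------------------------------
# stock configurations

#: Library design: (dataset no., species, year, environment, n).
FULL_STUDY_LIBRARY_DESIGN: tuple[tuple[int, str, int, str, int], ...] = (
    (1, "Maize", 2018, "greenhouse", 260),
    (2, "Maize", 2018, "field", 567),
    (3, "Maize", 2019, "field", 497),
    (4, "Maize", 2020, "field", 247),
    (5, "Sorghum", 2018, "greenhouse", 322),
    (6, "Sorghum", 2019, "greenhouse", 299),
    (7, "Sorghum", 2020, "field", 268),
)

#: External design: (dataset no., species, year, environment, n, missing traits).
FULL_STUDY_EXTERNAL_DESIGN: tuple[tuple[int, str, int, str, int, tuple[str, ...]], ...] = (
    (8, "Soybean", 2019, "greenhouse", 126, ()),
    (9, "Camelina", 2020, "greenhouse", 96, ("CHL", "LMA")),
    (10, "Maize", 2018, "field", 163, ()),
    (11, "Sorghum", 2019, "greenhouse", 60, ()),
)


def full_study_config(seed: int = 0, grid: WavelengthGrid | None = None) -> SimulationConfig:
    """Full-size study layout: 2460 library samples and 445 external samples
    split over four external sets (two species absent from the library)."""
    grid = grid or WavelengthGrid.canonical()
    library = tuple(
        SpeciesConfig(species=sp, n=n, year=yr, environment=env)
        for _, sp, yr, env, n in FULL_STUDY_LIBRARY_DESIGN
    )
    external = tuple(
        SpeciesConfig(
            species=sp, n=n, year=yr, environment=env, missing=miss,
            set_name=f"{sp.lower()}_ext" if sp in ("Maize", "Sorghum") else sp.lower(),
        )
        for _, sp, yr, env, n, miss in FULL_STUDY_EXTERNAL_DESIGN
    )
    return SimulationConfig(library=library, external=external, seed=seed, grid=grid)


def demo_config(
    seed: int = 0,
    grid: WavelengthGrid | None = None,
    noise_sd: float = 0.004,
    structured_noise_sd: float = 0.012,
    shift_magnitude: float = 1.0,
    n_library: tuple[int, int] = (120, 120),
    n_external: tuple[int, int] = (126, 96),
) -> SimulationConfig:
    """Desk-scale study: two library species, two external species
    (one lacking CHL/LMA), same structure as the full layout."""
    grid = grid or WavelengthGrid.canonical()
    return SimulationConfig(
        library=(
            SpeciesConfig("Maize", n_library[0], year=2019, environment="field"),
            SpeciesConfig("Sorghum", n_library[1], year=2019, environment="greenhouse"),
        ),
        external=(
            SpeciesConfig("Soybean", n_external[0], year=2019, environment="greenhouse"),
            SpeciesConfig("Camelina", n_external[1], year=2020, environment="greenhouse",
                          missing=("CHL", "LMA")),
        ),
        noise_sd=noise_sd,
        structured_noise_sd=structured_noise_sd,
        shift_magnitude=shift_magnitude,
        seed=seed,
        grid=grid,
    )


def linear_study_config(
    n: int = 200,
    traits: tuple[str, ...] = ("N", "LWC", "CHL"),
    seed: int = 0,
    grid: WavelengthGrid | None = None,
) -> SimulationConfig:
    """Noiseless, uncorrelated, exactly-linear library for recovery checks.

    Only the named traits drive the spectrum, so the centered spectra span
    a subspace of dimension len(traits) — the generative signal dimension.
    """
    grid = grid or WavelengthGrid.canonical()
    arch = default_archetype("Maize", grid, shift_magnitude=0.0)
    bands = tuple(b for b in arch.feature_bands if b.trait in traits)
    arch = SpeciesArchetype(arch.name, arch.baseline, bands, arch.shift)
    dist = TraitDistribution(
        mean=np.array([_BASE_MEAN[t] for t in TRAITS]),
        sd=np.array([_BASE_SD[t] if t in traits else 0.0 for t in TRAITS]),
        corr=np.eye(len(TRAITS)),
    )
    return SimulationConfig(
        library=(SpeciesConfig("Maize", n, dist=dist, archetype=arch),),
        external=(),
        noise_sd=0.0,
        structured_noise_sd=0.0,
        shift_magnitude=0.0,
        seed=seed,
        grid=grid,
    )
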