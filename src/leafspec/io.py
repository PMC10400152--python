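"""Wide-CSV reader/writer for spectral libraries.

Layout: one row per sample with columns
``id, species, dataset, year, environment, N, P, K, Mg, Ca, S, LWC, CHL,
LMA, wl_0350 ... wl_2500`` (raw 1 nm grid) or ``wl_c0355``-style headers
carrying window-center wavelengths after binning. Missing traits are empty
fields ("NA" is accepted on read). Reflectance is a fraction in [0, 1];
files that look like percent (max > 1.5) are rejected with a hint rather
than silently rescaled. Lines starting with '#' are ignored (provenance
headers).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import (
    TRAITS,
    Sample,
    SpectralLibrary,
    Spectrum,
    TraitVector,
    WavelengthGrid,
)

__all__ = ["read_library", "write_library"]

META_COLUMNS = ("id", "species", "dataset", "year", "environment")

_RAW_RE = re.compile(r"^wl_(\d{4})$")
_COARSE_RE = re.compile(r"^wl_c(\d{4}(?:\.\d+)?)$")


def _wavelength_header(wl: float, coarse: bool) -> str:
    prefix = "wl_c" if coarse else "wl_"
    if abs(wl - round(wl)) < 1e-9:
        return f"{prefix}{int(round(wl)):04d}"
    return f"{prefix}{wl:06.1f}"


def _parse_wavelength_headers(cols: list[str]) -> tuple[np.ndarray, bool]:
    raw = [_RAW_RE.match(c) for c in cols]
    coarse = [_COARSE_RE.match(c) for c in cols]
    if all(raw):
        wl = np.array([float(m.group(1)) for m in raw])  # type: ignore[union-attr]
    elif all(coarse):
        wl = np.array([float(m.group(1)) for m in coarse])  # type: ignore[union-attr]
    else:
        bad = next(c for c, r, k in zip(cols, raw, coarse) if not (r or k))
        raise ValueError(f"unrecognised wavelength column header: {bad!r}")
    if not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength column headers are not strictly increasing")
    return wl, not all(raw)


def write_library(lib: SpectralLibrary, path: str | Path, header_comment: str | None = None) -> None:
    """Write a library as wide CSV; floats carry 6 significant digits."""
    grid = lib.grid
    coarse = grid.step != 1.0
    wl_cols = [_wavelength_header(w, coarse) for w in grid.wavelengths]
    rows = []
    for s in lib:
        row: dict[str, object] = {
            "id": s.id,
            "species": s.species,
            "dataset": s.dataset,
            "year": s.year,
            "environment": s.environment,
        }
        row.update(s.traits.as_dict())
        row.update(dict(zip(wl_cols, s.spectrum.values)))
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(META_COLUMNS) + list(TRAITS) + wl_cols)
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.6g", na_rep="")


def read_library(path: str | Path) -> SpectralLibrary:
    """Read a wide-CSV library, validating ids, traits and the grid."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype={"id": str})
    cols = list(df.columns)
    for col in META_COLUMNS + TRAITS:
        if col not in cols:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    expected_meta = set(META_COLUMNS) | set(TRAITS)
    wl_cols = [c for c in cols if c not in expected_meta]
    unknown = [c for c in wl_cols if not (_RAW_RE.match(c) or _COARSE_RE.match(c))]
    if unknown:
        raise ValueError(f"{path.name}: unknown column(s): {unknown[:5]}")
    if not wl_cols:
        raise ValueError(f"{path.name}: no wavelength columns found")
    wl, coarse = _parse_wavelength_headers(wl_cols)

    dup = df["id"][df["id"].duplicated()]
    if not dup.empty:
        first = dup.iloc[0]
        line = int(dup.index[0]) + 2  # header + 1-based
        raise ValueError(f"{path.name}:{line}: duplicate sample id {first!r}")

    refl = df[wl_cols].to_numpy(dtype=float)
    if np.nanmax(refl) > 1.5:
        raise ValueError(
            f"{path.name}: reflectance values exceed 1.5 — file looks like percent; "
            "convert to fractional reflectance in [0, 1]"
        )
    if coarse:
        diffs = np.diff(wl)
        step = float(diffs[0]) if diffs.size and np.allclose(diffs, diffs[0]) else None
    else:
        step = 1.0
    grid = WavelengthGrid(wl, step=step)

    samples = []
    for i, row in df.iterrows():
        traits = TraitVector(
            np.array([pd.to_numeric(row[t], errors="coerce") for t in TRAITS], dtype=float)
        )
        try:
            spectrum = Spectrum(grid, refl[i])
        except ValueError as e:
            raise ValueError(f"{path.name}:{int(i) + 2}: {e}") from e
        samples.append(
            Sample(
                id=str(row["id"]),
                species=str(row["species"]),
                dataset=str(row["dataset"]),
                year=int(row["year"]),
                environment=str(row["environment"]),
                spectrum=spectrum,
                traits=traits,
            )
        )
    return SpectralLibrary(samples, provenance=str(path))
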