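"""Reflectance spectra: reading, validation, averaging and colorimetric summaries.

A spectrum is a reflectance curve R(lambda) over the UV-VIS instrument range
300-700 nm.  All downstream computation happens on the canonical 1-nm integer
grid (401 points).  Colorimetric variables follow the standard segment
conventions: total brightness B1 (sum of reflectance), mean brightness B2,
peak-wavelength hue H1, and segment chroma S1 -- the fraction of total
brightness contributed by a named wavelength band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Canonical wavelength grid: integer nanometres, 300..700 inclusive.
CANONICAL_GRID = np.arange(300, 701, dtype=float)

#: The six plumage patches measured per specimen.
PATCHES = ("crown", "mantle", "throat", "breastband1", "breastband2", "belly")

SEXES = ("male", "female")

#: Reflectance floor applied before any log-based computation downstream.
REFLECTANCE_FLOOR = 1e-5

#: Segment-chroma bands, nm, endpoints inclusive.  Bands deliberately overlap
#: (violet contains most of UV; yellow straddles green and red).
S1_BANDS: Mapping[str, tuple[int, int]] = {
    "U": (300, 400),
    "V": (300, 415),
    "B": (400, 510),
    "G": (510, 605),
    "Y": (550, 625),
    "R": (605, 700),
}


class SpectraError(ValueError):
    """Raised for malformed or inconsistent spectral input."""


@dataclass(frozen=True)
class Spectrum:
    """One reflectance measurement (or an average of replicates).

    Parameters
    ----------
    wavelengths : ndarray
        Strictly increasing grid in nm, within [300, 700].
    reflectance : ndarray
        Reflectance fraction per wavelength; finite, same length as the grid.
    species, sex, patch, specimen : str
        Metadata.  ``specimen`` may carry an averaged-count tag.
    n_specimens : int
        Number of replicate measurements averaged into this spectrum.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    species: str = ""
    sex: str = ""
    patch: str = ""
    specimen: str = ""
    n_specimens: int = 1

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        rf = np.asarray(self.reflectance, dtype=float)
        if wl.ndim != 1 or rf.ndim != 1 or wl.size != rf.size or wl.size == 0:
            raise SpectraError("wavelengths and reflectance must be equal-length 1-D arrays")
        if not np.all(np.diff(wl) > 0):
            raise SpectraError("wavelengths must be strictly increasing")
        if wl[0] < 300 - 1e-9 or wl[-1] > 700 + 1e-9:
            raise SpectraError("wavelengths must lie within [300, 700] nm")
        if not np.all(np.isfinite(rf)):
            raise SpectraError("reflectance must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", rf)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.species, self.sex, self.patch)


@dataclass(frozen=True)
class ColorMetrics:
    """Colorimetric summary of one spectrum on the canonical grid."""

    B1: float  #: total brightness, sum of reflectance over the grid
    B2: float  #: mean brightness, B1 / number of grid points
    H1: float  #: hue: wavelength of maximum reflectance (nm; ties -> lowest)
    S1: dict[str, float] = field(default_factory=dict)  #: band -> chroma fraction


@dataclass
class PatchSpectraSet:
    """Grouped spectra keyed by (species, sex, patch).

    Before :func:`average_specimens` a key maps to a list of replicate
    spectra; afterwards each key holds a single averaged spectrum.
    """

    spectra: dict[tuple[str, str, str], list[Spectrum]]

    @property
    def species(self) -> list[str]:
        return sorted({k[0] for k in self.spectra})

    def keys_for(self, sex: str, patch: str) -> list[tuple[str, str, str]]:
        return sorted(k for k in self.spectra if k[1] == sex and k[2] == patch)

    def averaged(self) -> "PatchSpectraSet":
        """Collapse specimen replicates to one mean spectrum per key."""
        return PatchSpectraSet(
            {k: [average_specimens(v)] for k, v in self.spectra.items()}
        )

    def get(self, species: str, sex: str, patch: str) -> Spectrum:
        specs = self.spectra[(species, sex, patch)]
        if len(specs) != 1:
            raise SpectraError(
                f"{(species, sex, patch)} holds {len(specs)} replicates; average first"
            )
        return specs[0]


def _parse_column(name: str) -> tuple[str, str, str, str]:
    parts = name.split("|")
    if len(parts) != 4:
        raise SpectraError(
            f"column {name!r} is not of the form species|sex|patch|specimen"
        )
    species, sex, patch, specimen = (p.strip() for p in parts)
    if sex not in SEXES:
        raise SpectraError(f"unknown sex {sex!r} in column {name!r}")
    if patch not in PATCHES:
        raise SpectraError(f"unknown patch {patch!r} in column {name!r}")
    return species, sex, patch, specimen


def read_spectra(path: str | Path) -> PatchSpectraSet:
    """Read a tabular spectra file into a :class:`PatchSpectraSet`.

    The file is CSV or TSV with a first column ``wl`` (nm) and one column per
    measurement named ``species|sex|patch|specimen``.  Values may be
    reflectance fractions or percentages; percent input is auto-detected
    (any value > 1.5) and divided by 100.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise SpectraError(f"{path} is empty") from exc
    if df.shape[1] < 2 or df.columns[0] != "wl":
        raise SpectraError(f"{path} must start with a 'wl' column plus measurements")
    wl = df["wl"].to_numpy(dtype=float)
    if not np.all(np.diff(wl) > 0):
        raise SpectraError("wavelength column must be strictly increasing")

    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.nanmax(values) > 1.5:  # percent scale
        values = values / 100.0

    grouped: dict[tuple[str, str, str], list[Spectrum]] = {}
    for j, col in enumerate(df.columns[1:]):
        species, sex, patch, specimen = _parse_column(col)
        spec = Spectrum(wl, values[:, j], species, sex, patch, specimen)
        grouped.setdefault((species, sex, patch), []).append(spec)
    if not grouped:
        raise SpectraError(f"{path} contains no measurement columns")
    return PatchSpectraSet(grouped)


def write_spectra(spectra_set: PatchSpectraSet, path: str | Path) -> None:
    """Write a :class:`PatchSpectraSet` in the tabular format of :func:`read_spectra`."""
    cols: dict[str, np.ndarray] = {}
    wl = None
    for key in sorted(spectra_set.spectra):
        for spec in spectra_set.spectra[key]:
            if wl is None:
                wl = spec.wavelengths
            elif not np.array_equal(wl, spec.wavelengths):
                raise SpectraError("all spectra must share one grid to be written")
            name = "|".join([spec.species, spec.sex, spec.patch, spec.specimen or "s1"])
            cols[name] = spec.reflectance
    if wl is None:
        raise SpectraError("empty spectra set")
    pd.DataFrame({"wl": wl, **cols}).to_csv(path, index=False)


def average_specimens(spectra: Iterable[Spectrum]) -> Spectrum:
    """Arithmetic per-wavelength mean of replicate spectra on one grid.

    All inputs must share the wavelength grid and (species, sex, patch) key.
    """
    spectra = list(spectra)
    if not spectra:
        raise SpectraError("cannot average an empty list of spectra")
    first = spectra[0]
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, first.wavelengths):
            raise SpectraError("specimen spectra are on mismatched wavelength grids")
        if s.key != first.key:
            raise SpectraError(f"cannot average across keys {s.key} and {first.key}")
    mean = np.mean([s.reflectance for s in spectra], axis=0)
    n = sum(s.n_specimens for s in spectra)
    return replace(first, reflectance=mean, specimen=f"mean_of_{n}", n_specimens=n)


def regrid(spectrum: Spectrum, grid: np.ndarray | None = None) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (default canonical 1-nm).

    Values are clipped to the positivity floor so downstream log quantum-catch
    ratios stay defined.  The target grid must lie within the measured range.
    """
    grid = CANONICAL_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid[0] < spectrum.wavelengths[0] - 1e-9 or grid[-1] > spectrum.wavelengths[-1] + 1e-9:
        raise SpectraError(
            f"target grid [{grid[0]}, {grid[-1]}] outside measured range "
            f"[{spectrum.wavelengths[0]}, {spectrum.wavelengths[-1]}]"
        )
    values = np.interp(grid, spectrum.wavelengths, spectrum.reflectance)
    values = np.clip(values, REFLECTANCE_FLOOR, None)
    return replace(spectrum, wavelengths=grid, reflectance=values)


def colorimetrics(spectrum: Spectrum) -> ColorMetrics:
    """Brightness, hue and segment chroma of a canonical-grid spectrum.

    B1 is the grid sum of reflectance, B2 the grid mean, H1 the wavelength of
    maximal reflectance (lowest wavelength on ties), and S1[band] the inclusive
    band sum divided by B1.
    """
    wl, rf = spectrum.wavelengths, spectrum.reflectance
    if wl.size != CANONICAL_GRID.size or not np.array_equal(wl, CANONICAL_GRID):
        raise SpectraError("colorimetrics requires the canonical 1-nm 300-700 grid")
    b1 = float(rf.sum())
    if b1 == 0.0:
        raise SpectraError("all-zero spectrum: chroma undefined (B1 = 0)")
    h1 = float(wl[int(np.argmax(rf))])  # argmax takes the first (lowest-wl) max
    s1 = {
        band: float(rf[(wl >= lo) & (wl <= hi)].sum() / b1)
        for band, (lo, hi) in S1_BANDS.items()
    }
    return ColorMetrics(B1=b1, B2=b1 / wl.size, H1=h1, S1=s1)
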