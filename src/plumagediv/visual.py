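"""Avian visual modelling: cone stimuli and receptor-noise colour distances.

Reflectance spectra are converted to quantum catches of the four single-cone
classes of a UV-sensitive (UVS) avian visual system under an idealized flat
illuminant, and pairs of stimuli are compared with the receptor-noise limited
discrimination model.  Distances are in just-noticeable-difference (JND)
units: a distance below 1 is not discriminable by the modelled viewer.

The model is chromatic only: log quantum-catch ratios (Fechner signals) feed
an opponent distance weighted by per-channel noise e_i = w * sqrt(eta_ref /
eta_i), where w is the Weber fraction of the most abundant cone class and
eta_i the relative cone densities.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .spectra import CANONICAL_GRID, PATCHES, PatchSpectraSet, Spectrum

logger = logging.getLogger(__name__)

#: Default peak sensitivities (nm) of an average UVS avian system, u/s/m/l.
DEFAULT_LAMBDA_MAX = (372.0, 456.0, 544.0, 609.0)
#: Default relative cone densities u:s:m:l.
DEFAULT_DENSITIES = (1.0, 2.0, 2.0, 4.0)
#: Default Weber fraction, referenced to the most abundant (longest) cone.
DEFAULT_WEBER = 0.1


def cone_sensitivity(lambda_max: float, grid: np.ndarray | None = None) -> np.ndarray:
    """Visual-pigment absorbance template evaluated on a wavelength grid.

    Uses the Govardovskii A1 template: an alpha band

        S_a(x) = 1 / (exp(A(a - x)) + exp(B(b - x)) + exp(C(c - x)) + D)

    with x = lambda_max / lambda, A=69.7, B=28, C=-14.9, D=0.674, b=0.922,
    c=1.104 and a = 0.8795 + 0.0459 exp(-(lambda_max - 300)^2 / 11940),
    plus the UV beta band

        S_b(lambda) = A_b exp(-((lambda - mu_b) / b_b)^2)

    with A_b = 0.26, mu_b = 189 + 0.315 lambda_max and
    b_b = -40.5 + 0.195 lambda_max.  The sum is re-normalized to unit peak.
    """
    grid = CANONICAL_GRID if grid is None else np.asarray(grid, dtype=float)
    if not (grid[0] <= lambda_max <= grid[-1]):
        raise ValueError(f"lambda_max {lambda_max} nm outside grid [{grid[0]}, {grid[-1]}]")
    x = lambda_max / grid
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    mu_b = 189.0 + 0.315 * lambda_max
    b_b = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((grid - mu_b) / b_b) ** 2))
    curve = alpha + beta
    return curve / curve.max()


@dataclass(frozen=True)
class ConeSet:
    """Receptor complement of the modelled viewer.

    ``densities`` are relative cone abundances; channel noise is
    ``weber * sqrt(eta_ref / eta_i)`` with ``eta_ref`` the largest density, so
    the most abundant class carries the stated Weber fraction exactly.
    """

    lambda_max: tuple[float, ...] = DEFAULT_LAMBDA_MAX
    densities: tuple[float, ...] = DEFAULT_DENSITIES
    weber: float = DEFAULT_WEBER
    labels: tuple[str, ...] = ("u", "s", "m", "l")
    grid: np.ndarray = field(default_factory=lambda: CANONICAL_GRID.copy())

    def __post_init__(self) -> None:
        if len(self.lambda_max) != len(self.densities):
            raise ValueError("lambda_max and densities must have equal length")
        if len(self.labels) != len(self.lambda_max):
            object.__setattr__(self, "labels", tuple(f"c{i}" for i in range(self.n_cones)))
        if any(d <= 0 for d in self.densities) or self.weber <= 0:
            raise ValueError("densities and Weber fraction must be positive")

    @property
    def n_cones(self) -> int:
        return len(self.lambda_max)

    @property
    def sensitivities(self) -> np.ndarray:
        """(n_cones, n_wavelengths) peak-normalized sensitivity curves."""
        return np.vstack([cone_sensitivity(lm, self.grid) for lm in self.lambda_max])

    @property
    def noise(self) -> np.ndarray:
        """Per-channel noise e_i = w * sqrt(eta_ref / eta_i)."""
        eta = np.asarray(self.densities, dtype=float)
        return self.weber * np.sqrt(eta.max() / eta)


@dataclass(frozen=True)
class QuantumCatch:
    """Raw (un-normalized) cone stimuli q_i for one spectrum."""

    q: np.ndarray
    cones: ConeSet
    species: str = ""
    sex: str = ""
    patch: str = ""

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if not np.all(np.isfinite(q)) or np.any(q <= 0):
            raise ValueError("quantum catches must be positive and finite")
        object.__setattr__(self, "q", q)


def flat_illuminant(grid: np.ndarray | None = None) -> np.ndarray:
    """Idealized illuminant: unit irradiance at every wavelength."""
    grid = CANONICAL_GRID if grid is None else np.asarray(grid, dtype=float)
    return np.ones_like(grid)


def quantum_catch(
    spectrum: Spectrum,
    cones: ConeSet,
    illuminant: np.ndarray | None = None,
) -> QuantumCatch:
    """Integrate R(lambda) * I(lambda) * S_i(lambda) over the grid per cone.

    Grid sums are used (uniform 1-nm grid); the spectrum must already be on
    the cone set's grid with the positivity floor applied.
    """
    if spectrum.wavelengths.size != cones.grid.size or not np.array_equal(
        spectrum.wavelengths, cones.grid
    ):
        raise ValueError("spectrum must be on the cone set's wavelength grid")
    illum = flat_illuminant(cones.grid) if illuminant is None else np.asarray(illuminant, float)
    q = cones.sensitivities @ (spectrum.reflectance * illum)
    return QuantumCatch(q, cones, spectrum.species, spectrum.sex, spectrum.patch)


def _rn_distance(delta_f: np.ndarray, e: np.ndarray) -> float:
    """Receptor-noise chromatic distance from Fechner signal differences.

    For n receptor channels with noises e_i,

        dS^2 = sum_{i<j} w_ij (df_j - df_i)^2  /  sum_k v_k,

    where w_ij is the squared product of the noises of all channels other
    than i and j, and v_k the squared product of all noises but k.  For n=2
    this reduces to |df_1 - df_2| / sqrt(e_1^2 + e_2^2); for n=4 it is the
    standard tetrachromatic formula.
    """
    n = e.size
    e2 = e**2
    prod_all = np.prod(e2)
    num = 0.0
    for i, j in itertools.combinations(range(n), 2):
        w_ij = prod_all / (e2[i] * e2[j])  # (prod of others)^2
        num += w_ij * (delta_f[j] - delta_f[i]) ** 2
    den = np.sum(prod_all / e2)
    return float(np.sqrt(num / den))


def jnd(a: QuantumCatch, b: QuantumCatch) -> float:
    """Receptor-noise limited colour distance between two stimuli, in JND.

    Signals are log quantum-catch ratios Delta f_i = ln(q_i^a / q_i^b); a
    common multiplicative factor on both spectra therefore cancels.
    """
    if a.cones is not b.cones and (
        a.cones.lambda_max != b.cones.lambda_max
        or a.cones.densities != b.cones.densities
        or a.cones.weber != b.cones.weber
    ):
        raise ValueError("quantum catches come from different cone sets")
    delta_f = np.log(a.q) - np.log(b.q)
    return _rn_distance(delta_f, a.cones.noise)


@dataclass
class ColorDistanceMatrix:
    """Symmetric matrix of pairwise JND colour distances for one patch."""

    patch: str
    species: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.species)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match the species list")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("colour-distance matrix must be symmetric with zero diagonal")
        if np.any(v < 0):
            raise ValueError("colour distances must be non-negative")
        self.values = v

    def pair(self, sp1: str, sp2: str) -> float:
        i, j = self.species.index(sp1), self.species.index(sp2)
        return float(self.values[i, j])


def patch_distance_matrix(
    spectra_set: PatchSpectraSet,
    patch: str,
    sex: str,
    cones: ConeSet | None = None,
) -> ColorDistanceMatrix:
    """All-pairs JND matrix for one patch and sex.

    Species missing the patch are excluded with a warning.  Spectra are
    regridded to the canonical grid (with the positivity floor) before the
    catches are computed; the pairwise distances are evaluated vectorized
    from the log-catch matrix.
    """
    from .spectra import regrid

    cones = cones or ConeSet()
    keys = spectra_set.keys_for(sex, patch)
    present = [k[0] for k in keys]
    missing = sorted(set(spectra_set.species) - set(present))
    if missing:
        logger.warning("patch %s/%s missing for species %s; excluded", patch, sex, missing)
    log_q = np.vstack(
        [
            np.log(quantum_catch(regrid(spectra_set.get(sp, sex, patch), cones.grid), cones).q)
            for sp in present
        ]
    )
    e2 = cones.noise**2
    prod_all = np.prod(e2)
    den = np.sum(prod_all / e2)
    n = len(present)
    d2 = np.zeros((n, n))
    for i, j in itertools.combinations(range(cones.n_cones), 2):
        w_ij = prod_all / (e2[i] * e2[j])
        diff = (log_q[:, None, j] - log_q[None, :, j]) - (
            log_q[:, None, i] - log_q[None, :, i]
        )
        d2 += w_ij * diff**2
    values = np.sqrt(d2 / den)
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0  # enforce exact symmetry
    return ColorDistanceMatrix(patch, present, values)


def whole_body_average(matrices: list[ColorDistanceMatrix]) -> ColorDistanceMatrix:
    """Element-wise mean of per-patch distance matrices -> whole-body matrix."""
    if not matrices:
        raise ValueError("no matrices to average")
    species = matrices[0].species
    for m in matrices[1:]:
        if m.species != species:
            raise ValueError("distance matrices have mismatched species lists")
    mean = np.mean([m.values for m in matrices], axis=0)
    return ColorDistanceMatrix("average", list(species), mean)


def all_patch_matrices(
    spectra_set: PatchSpectraSet,
    sex: str,
    cones: ConeSet | None = None,
    patches: tuple[str, ...] = PATCHES,
) -> dict[str, ColorDistanceMatrix]:
    """Per-patch JND matrices plus the whole-body ``"average"`` matrix."""
    mats = {p: patch_distance_matrix(spectra_set, p, sex, cones) for p in patches}
    common = sorted(set.intersection(*(set(m.species) for m in mats.values())))
    aligned = []
    for p, m in mats.items():
        idx = [m.species.index(s) for s in common]
        aligned.append(ColorDistanceMatrix(p, common, m.values[np.ix_(idx, idx)]))
        mats[p] = aligned[-1]
    mats["average"] = whole_body_average(aligned)
    return mats
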