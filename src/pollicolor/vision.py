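"""Insect visual models: quantum catches, chromaticity spaces and contrasts.

Two viewer families are supported.  A trichromatic nocturnal hawkmoth (UV /
blue / green receptors) is modelled with relative quantum catches placed in a
Maxwell color triangle, receptor-noise-limited (RNL) chromatic distances in
just-noticeable-difference (JND) units and a long-wavelength achromatic
contrast.  Tetrachromatic flies (blowfly / hoverfly) are modelled with the
categorical opponency space: two pale-pair and two yellow-pair receptors
define opponent signals whose signs place a stimulus into one of four
perceptual categories, with Euclidean distance in the opponency plane as the
graded conspicuousness measure.

All catches are adapted to a background (von Kries transformation), so the
background itself always maps to the achromatic point.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import VisionError
from .spectra import ReflectanceSpectrum

__all__ = [
    "Illuminant",
    "ReceptorSet",
    "ColorLocus",
    "NoiseModel",
    "receptor_template",
    "load_illuminant",
    "load_receptor_set",
    "quantum_catch",
    "maxwell_locus",
    "fly_locus",
    "fly_distance",
    "rnl_chromatic_distance",
    "achromatic_contrast",
    "energy_to_photon_flux",
]

FLY_CATEGORIES = {
    (1, 1): "fly-UV",
    (-1, 1): "fly-blue",
    (-1, -1): "fly-yellow",
    (1, -1): "fly-purple",
}
BOUNDARY_TOL = 1e-9


@dataclass(frozen=True)
class Illuminant:
    """Relative photon-flux irradiance on a wavelength grid."""

    wavelengths: np.ndarray
    irradiance: np.ndarray
    name: str = "custom"

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        irr = np.asarray(self.irradiance, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "irradiance", irr)
        if np.any(irr <= 0):
            raise VisionError("illuminant irradiance must be positive everywhere")

    def on_grid(self, grid: np.ndarray) -> np.ndarray:
        return np.interp(grid, self.wavelengths, self.irradiance)


def energy_to_photon_flux(wavelengths: np.ndarray, energy: np.ndarray) -> np.ndarray:
    """Convert an energy-unit irradiance spectrum to relative photon flux.

    Photon counts scale as energy x wavelength; output is renormalized to a
    maximum of 1.  Off by default in all loaders (bundled tables are already
    quantal).
    """
    flux = np.asarray(energy, dtype=float) * np.asarray(wavelengths, dtype=float)
    return flux / flux.max()


def load_illuminant(source: str = "D65") -> Illuminant:
    """Load a named bundled illuminant (``D65``/``sunset``) or a CSV path."""
    name = source
    if source in {"D65", "d65", "sunset"}:
        fname = "d65.csv" if source.lower() == "d65" else "sunset.csv"
        with resources.files("pollicolor.data").joinpath(fname).open() as fh:
            df = pd.read_csv(fh)
        name = "D65" if fname == "d65.csv" else "sunset"
    else:
        df = pd.read_csv(source)
    return Illuminant(df["wl"].to_numpy(), df["irradiance"].to_numpy(), name=name)


def receptor_template(lambda_max: float, grid: np.ndarray) -> np.ndarray:
    """A1 visual-pigment alpha-band nomogram, peak-normalized to 1.

    Uses the standard template parameterized only by ``lambda_max``:
    ``S(lambda) = 1 / (exp(A(a - x)) + exp(B(b - x)) + exp(C(c - x)) + D)``
    with ``x = lambda_max / lambda``.
    """
    grid = np.asarray(grid, dtype=float)
    if not (grid[0] <= lambda_max <= grid[-1]):
        raise VisionError(
            f"lambda_max={lambda_max} outside grid coverage [{grid[0]}, {grid[-1]}]"
        )
    if not 300.0 <= lambda_max <= 700.0:
        raise VisionError(f"lambda_max must be within [300, 700], got {lambda_max}")
    x = lambda_max / grid
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    b, c = 0.922, 1.104
    s = 1.0 / (np.exp(A * (a - x)) + np.exp(B * (b - x)) + np.exp(C * (c - x)) + D)
    return s / s.max()


@dataclass(frozen=True)
class ReceptorSet:
    """Named photoreceptor sensitivities with relative densities for one viewer."""

    viewer: str
    names: tuple[str, ...]
    lambda_max: tuple[float, ...]
    sensitivities: np.ndarray  # shape (n_receptors, n_wavelengths)
    densities: tuple[float, ...]
    grid: np.ndarray

    def __post_init__(self):
        sens = np.asarray(self.sensitivities, dtype=float)
        object.__setattr__(self, "sensitivities", sens)
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        if np.any(sens < 0):
            raise VisionError("sensitivities must be non-negative")
        if not np.allclose(sens.max(axis=1), 1.0):
            raise VisionError("each sensitivity curve must peak at 1")
        if any(d <= 0 for d in self.densities):
            raise VisionError("densities must be positive")

    @property
    def n_receptors(self) -> int:
        return len(self.names)


def load_receptor_set(
    viewer: str,
    grid: np.ndarray | None = None,
    config: dict | None = None,
    curves: np.ndarray | None = None,
) -> ReceptorSet:
    """Build a :class:`ReceptorSet` for ``viewer`` on ``grid``.

    By default curves come from :func:`receptor_template` with the bundled
    ``lambda_max`` values; pass ``curves`` (receptor x wavelength array) to
    supply measured sensitivities instead.
    """
    if grid is None:
        grid = np.arange(300.0, 701.0)
    if config is None:
        with resources.files("pollicolor.data").joinpath("receptors.yaml").open() as fh:
            config = yaml.safe_load(fh)
    if viewer not in config:
        raise VisionError(f"unknown viewer {viewer!r}; known: {sorted(config)}")
    spec = config[viewer]
    lmax = tuple(float(v) for v in spec["lambda_max"])
    if curves is None:
        curves = np.vstack([receptor_template(lm, grid) for lm in lmax])
    else:
        curves = np.asarray(curves, dtype=float)
        curves = curves / curves.max(axis=1, keepdims=True)
    return ReceptorSet(
        viewer=viewer,
        names=tuple(spec["names"]),
        lambda_max=lmax,
        sensitivities=curves,
        densities=tuple(float(d) for d in spec["densities"]),
        grid=np.asarray(grid, dtype=float),
    )


@dataclass(frozen=True)
class ColorLocus:
    """Per-viewer perceptual coordinates of one stimulus."""

    viewer: str
    receptor_names: tuple[str, ...]
    Q: np.ndarray  # raw catches
    q: np.ndarray  # von Kries adapted catches
    r: np.ndarray  # relative catches, sum to 1
    species: str = ""
    individual: str = ""
    morph: str | None = None

    def __post_init__(self):
        for name in ("Q", "q", "r"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.r < -1e-12):
            raise VisionError("relative catches must be non-negative")
        if abs(self.r.sum() - 1.0) > 1e-9:
            raise VisionError("relative catches must sum to 1")

    @property
    def label(self) -> str:
        m = "" if self.morph is None else f":{self.morph}"
        return f"{self.species}{m}|{self.individual}"


@dataclass(frozen=True)
class NoiseModel:
    """Neural receptor noise from a Weber fraction and receptor densities.

    ``e_i = weber * sqrt(eta_max / eta_i)`` so the most abundant receptor
    class has noise exactly equal to the Weber fraction.
    """

    weber: float = 0.1
    densities: tuple[float, ...] = (0.1, 0.23, 0.67)
    mode: str = "neural"

    @property
    def e(self) -> np.ndarray:
        eta = np.asarray(self.densities, dtype=float)
        return self.weber * np.sqrt(eta.max() / eta)


def quantum_catch(
    spec: ReflectanceSpectrum,
    recs: ReceptorSet,
    illum: Illuminant,
    background: ReflectanceSpectrum,
) -> ColorLocus:
    """Integrate catches ``Q_i = trapz R * S_i * I`` and von Kries adapt to background.

    Reflectance (percent) is converted to a proportion internally.  The
    background is typically the mean leaf spectrum.
    """
    grid = spec.wavelengths
    if background.wavelengths.shape != grid.shape or not np.allclose(
        background.wavelengths, grid
    ):
        raise VisionError("stimulus and background must share one wavelength grid")
    if recs.grid.shape != grid.shape or not np.allclose(recs.grid, grid):
        raise VisionError("receptor sensitivities not on the stimulus grid")
    irr = illum.on_grid(grid)
    refl = spec.reflectance / 100.0
    bkg = background.reflectance / 100.0
    Q = np.trapezoid(refl[None, :] * recs.sensitivities * irr[None, :], grid, axis=1)
    Qb = np.trapezoid(bkg[None, :] * recs.sensitivities * irr[None, :], grid, axis=1)
    if np.any(Qb <= 0):
        raise VisionError("background quantum catch is zero in at least one receptor")
    q = Q / Qb
    total = q.sum()
    if total <= 0:
        raise VisionError("stimulus produced zero total catch")
    return ColorLocus(
        viewer=recs.viewer,
        receptor_names=recs.names,
        Q=Q,
        q=q,
        r=q / total,
        species=spec.species,
        individual=spec.individual,
        morph=spec.morph,
    )


def maxwell_locus(locus: ColorLocus) -> np.ndarray:
    """Maxwell-triangle coordinates of a trichromat locus.

    ``x = (r_G - r_UV)/sqrt(2)``; ``y = sqrt(2/3) * (r_B - (r_G + r_UV)/2)``.
    The center (0, 0) is equal excitation; vertices are pure-receptor colors
    at distance sqrt(2/3) from the center.
    """
    if len(locus.receptor_names) != 3:
        raise VisionError("Maxwell triangle requires a trichromat locus")
    r_uv, r_b, r_g = locus.r
    x = (r_g - r_uv) / np.sqrt(2.0)
    y = np.sqrt(2.0) / np.sqrt(3.0) * (r_b - (r_g + r_uv) / 2.0)
    return np.array([x, y])


def fly_locus(locus: ColorLocus, tie_tol: float = BOUNDARY_TOL) -> tuple[str, np.ndarray]:
    """Categorical fly color: opponency coordinates and quadrant category.

    ``u = (q_R7p - q_R8p)/(q_R7p + q_R8p)``, ``v`` likewise for the yellow
    pair.  The sign pair maps to fly-UV (p+, y+), fly-blue (p-, y+),
    fly-yellow (p-, y-) or fly-purple (p+, y-); within ``tie_tol`` of an axis
    the category is ``"boundary"``.
    """
    if len(locus.receptor_names) != 4:
        raise VisionError("categorical fly model requires a tetrachromat locus")
    q = locus.q
    dp, dy = q[0] + q[1], q[2] + q[3]
    if dp <= 0 or dy <= 0:
        raise VisionError("non-positive opponency denominator")
    u = (q[0] - q[1]) / dp
    v = (q[2] - q[3]) / dy
    if abs(u) < tie_tol or abs(v) < tie_tol:
        cat = "boundary"
    else:
        cat = FLY_CATEGORIES[(int(np.sign(u)), int(np.sign(v)))]
    return cat, np.array([u, v])


def fly_distance(a: ColorLocus, b: ColorLocus) -> float:
    """Euclidean distance between two fly loci in the (u, v) opponency plane."""
    if a.viewer != b.viewer:
        raise VisionError(f"mixed viewers: {a.viewer} vs {b.viewer}")
    _, uv_a = fly_locus(a)
    _, uv_b = fly_locus(b)
    return float(np.linalg.norm(uv_a - uv_b))


def _check_trichromat_pair(a: ColorLocus, b: ColorLocus) -> None:
    if a.viewer != b.viewer:
        raise VisionError(f"mixed viewers: {a.viewer} vs {b.viewer}")
    if len(a.receptor_names) != 3:
        raise VisionError("RNL distance implemented for trichromat loci")
    if np.any(a.q <= 0) or np.any(b.q <= 0):
        raise VisionError("adapted catches must be positive for log contrasts")


def rnl_contrast_from_df(df: np.ndarray, e: np.ndarray) -> float:
    """Trichromatic RNL distance from per-receptor log-contrasts ``df``."""
    e1, e2, e3 = e
    f1, f2, f3 = df
    num = (
        e1**2 * (f3 - f2) ** 2
        + e2**2 * (f3 - f1) ** 2
        + e3**2 * (f2 - f1) ** 2
    )
    den = (e1 * e2) ** 2 + (e1 * e3) ** 2 + (e2 * e3) ** 2
    return float(np.sqrt(num / den))


def rnl_chromatic_distance(a: ColorLocus, b: ColorLocus, noise: NoiseModel) -> float:
    """Receptor-noise-limited chromatic distance between two loci, in JND.

    ``df_i = ln(q_i^a / q_i^b)``; 1 JND is the theoretical discrimination
    threshold.  Uniform scaling of all catches (a purely achromatic shift)
    gives 0.
    """
    _check_trichromat_pair(a, b)
    df = np.log(a.q / b.q)
    return rnl_contrast_from_df(df, noise.e)


def achromatic_contrast(
    a: ColorLocus,
    background: ColorLocus,
    noise: NoiseModel,
    form: str = "michelson",
) -> dict:
    """Long-wavelength-receptor contrast of a stimulus against the background.

    ``michelson`` (default): ``|qL_a - qL_b| / (qL_a + qL_b)``;
    ``log_jnd``: ``|ln(qL_a / qL_b)| / e_L``.  The long-wave receptor is the
    last receptor of the trichromat set.
    """
    if len(a.receptor_names) != 3 or len(background.receptor_names) != 3:
        raise VisionError("achromatic contrast implemented for trichromat loci")
    qa, qb = a.q[-1], background.q[-1]
    if qa <= 0 or qb <= 0:
        raise VisionError("non-positive long-wave catch")
    if form == "michelson":
        value = abs(qa - qb) / (qa + qb)
    elif form == "log_jnd":
        value = abs(np.log(qa / qb)) / noise.e[-1]
    else:
        raise VisionError(f"unknown achromatic form {form!r}")
    return {"form": form, "value": float(value)}
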