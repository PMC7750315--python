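"""Reading, validation and preprocessing of corolla/leaf reflectance spectra.

The processing chain mirrors a standard spectral workflow: spectra are
ingested onto a common 1-nm grid, trimmed to the insect-vision window
(300-700 nm), smoothed by local polynomial regression, averaged within
individuals / species (keeping color morphs separate), and finally
mean-centered and binned into equal wavelength intervals for ordination.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SpectrumError

__all__ = [
    "ReflectanceSpectrum",
    "SpectrumCollection",
    "read_spectra",
    "trim",
    "smooth",
    "aggregate",
    "center_and_bin",
    "bin_matrix",
]

INSECT_RANGE = (300.0, 700.0)


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """A single reflectance measurement on a strictly increasing nm grid.

    Reflectance is expressed as percent of a white standard.  Small negative
    values from instrument noise are tolerated on raw input; processing steps
    clip fitted values to be non-negative.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    species: str
    individual: str
    tissue: str = "corolla"
    morph: str | None = None
    n_averaged: int = 1

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        refl = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", refl)
        if wl.ndim != 1 or refl.shape != wl.shape:
            raise SpectrumError("wavelengths and reflectance must be 1-D and equal length")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise SpectrumError("non-monotone wavelengths")
        if not np.all(np.isfinite(refl)):
            raise SpectrumError("non-finite reflectance values")

    @property
    def key(self) -> tuple:
        return (self.species, self.morph, self.individual, self.tissue)

    def with_values(self, reflectance: np.ndarray, **kw) -> "ReflectanceSpectrum":
        return replace(self, reflectance=np.asarray(reflectance, dtype=float), **kw)


@dataclass
class SpectrumCollection:
    """A list of spectra sharing one wavelength grid."""

    spectra: list[ReflectanceSpectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.spectra:
            grid = self.spectra[0].wavelengths
            for s in self.spectra[1:]:
                if s.wavelengths.shape != grid.shape or not np.allclose(
                    s.wavelengths, grid
                ):
                    raise SpectrumError("spectra do not share a common wavelength grid")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def wavelengths(self) -> np.ndarray:
        if not self.spectra:
            raise SpectrumError("empty collection has no grid")
        return self.spectra[0].wavelengths

    def subset(self, tissue: str | None = None, species: str | None = None) -> "SpectrumCollection":
        out = [
            s
            for s in self.spectra
            if (tissue is None or s.tissue == tissue)
            and (species is None or s.species == species)
        ]
        return SpectrumCollection(out)

    def map(self, fn) -> "SpectrumCollection":
        return SpectrumCollection([fn(s) for s in self.spectra])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: wl, reflectance, species, individual, tissue, morph."""
        rows = []
        for s in self.spectra:
            rows.append(
                pd.DataFrame(
                    {
                        "wl": s.wavelengths,
                        "reflectance": s.reflectance,
                        "species": s.species,
                        "individual": s.individual,
                        "tissue": s.tissue,
                        "morph": "" if s.morph is None else s.morph,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def _resample(wl: np.ndarray, refl: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.interp(grid, wl, refl)


def read_spectra(
    path,
    layout: str = "long",
    sidecar: dict | str | Path | None = None,
    grid_step: float = 1.0,
) -> SpectrumCollection:
    """Read spectra from a CSV/TSV file onto a common ``grid_step``-nm grid.

    Parameters
    ----------
    path:
        Text table.  ``long`` layout needs columns
        ``wl, reflectance, species, individual, tissue[, morph]``; ``wide``
        layout has a first column ``wl`` and one column per sample.
    layout:
        ``"long"`` or ``"wide"``.
    sidecar:
        For wide files: a mapping (or YAML file) from column name to a dict
        with ``species``/``individual``/``tissue``/``morph`` metadata.  When
        absent, the column name is used as both species and individual label.
    """
    path = Path(path)
    if not path.exists():
        raise SpectrumError(f"spectra file not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if layout not in {"long", "wide"}:
        raise SpectrumError(f"unknown layout {layout!r}")

    if isinstance(sidecar, (str, Path)):
        with open(sidecar) as fh:
            sidecar = yaml.safe_load(fh)

    raw: list[ReflectanceSpectrum] = []
    if layout == "wide":
        if df.columns[0].lower() != "wl":
            raise SpectrumError("wide layout requires first column 'wl'")
        wl = df.iloc[:, 0].to_numpy(dtype=float)
        if not np.all(np.diff(wl) > 0):
            raise SpectrumError("non-monotone wavelengths")
        for col in df.columns[1:]:
            meta = (sidecar or {}).get(col, {})
            raw.append(
                ReflectanceSpectrum(
                    wavelengths=wl,
                    reflectance=df[col].to_numpy(dtype=float),
                    species=str(meta.get("species", col)),
                    individual=str(meta.get("individual", col)),
                    tissue=str(meta.get("tissue", "corolla")),
                    morph=meta.get("morph"),
                )
            )
    else:
        required = {"wl", "reflectance", "species", "individual", "tissue"}
        missing = required - set(df.columns)
        if missing:
            raise SpectrumError(f"missing metadata columns: {sorted(missing)}")
        has_morph = "morph" in df.columns
        keys = ["species", "individual", "tissue"] + (["morph"] if has_morph else [])
        for key_vals, sub in df.groupby(keys, sort=True, dropna=False):
            sub = sub.sort_values("wl")
            wl = sub["wl"].to_numpy(dtype=float)
            if not np.all(np.diff(wl) > 0):
                raise SpectrumError("non-monotone wavelengths")
            kv = dict(zip(keys, key_vals))
            morph = kv.get("morph")
            if morph is not None and (pd.isna(morph) or morph == ""):
                morph = None
            raw.append(
                ReflectanceSpectrum(
                    wavelengths=wl,
                    reflectance=sub["reflectance"].to_numpy(dtype=float),
                    species=str(kv["species"]),
                    individual=str(kv["individual"]),
                    tissue=str(kv["tissue"]),
                    morph=None if morph is None else str(morph),
                )
            )

    if not raw:
        raise SpectrumError("no spectra found in file")

    # common grid = intersection of input ranges, at grid_step nm
    lo = max(s.wavelengths[0] for s in raw)
    hi = min(s.wavelengths[-1] for s in raw)
    if hi <= lo:
        raise SpectrumError("spectra wavelength ranges do not overlap")
    grid = np.arange(np.ceil(lo), np.floor(hi) + 0.5 * grid_step, grid_step)
    return SpectrumCollection(
        [s.with_values(_resample(s.wavelengths, s.reflectance, grid), wavelengths=grid) for s in raw]
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def trim(spec: ReflectanceSpectrum, lo: float = 300.0, hi: float = 700.0) -> ReflectanceSpectrum:
    """Restrict a spectrum to the window [lo, hi] nm (default insect range)."""
    if lo >= hi:
        raise SpectrumError(f"invalid trim window: lo={lo} >= hi={hi}")
    wl = spec.wavelengths
    if lo < wl[0] - 1e-9 or hi > wl[-1] + 1e-9:
        raise SpectrumError(
            f"trim window [{lo}, {hi}] outside measured range [{wl[0]}, {wl[-1]}]"
        )
    mask = (wl >= lo - 1e-9) & (wl <= hi + 1e-9)
    return replace(spec, wavelengths=wl[mask], reflectance=spec.reflectance[mask])


def _loess(x: np.ndarray, y: np.ndarray, span: float, degree: int = 2) -> np.ndarray:
    """Local polynomial regression with tricube weights, evaluated at x."""
    n = x.size
    k = max(int(np.ceil(span * n)), degree + 2)
    k = min(k, n)
    out = np.empty(n)
    order = np.arange(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = order[np.argpartition(d, k - 1)[:k]]
        di = d[idx]
        dmax = di.max()
        if dmax <= 0:
            out[i] = y[idx].mean()
            continue
        w = np.clip(1.0 - (di / dmax) ** 3, 0.0, None) ** 3
        # give the furthest-in-window point a tiny weight so the design stays full rank
        w = np.maximum(w, 1e-9)
        t = x[idx] - x[i]
        design = np.vander(t, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[idx] * sw, rcond=None)
        out[i] = coef[0]
    return out


def smooth(spec: ReflectanceSpectrum, span: float = 0.25, degree: int = 2) -> ReflectanceSpectrum:
    """LOESS-smooth a spectrum; negative fitted values are clipped to 0.

    ``span`` is the fraction of grid points in each local window (default
    0.25, the minimum that removes instrument noise without distorting
    spectral shape).
    """
    if not 0 < span <= 1:
        raise SpectrumError(f"span must be in (0, 1], got {span}")
    if spec.wavelengths.size < 10:
        raise SpectrumError("too few points to smooth (need >= 10)")
    fitted = _loess(spec.wavelengths, spec.reflectance, span, degree)
    return spec.with_values(np.clip(fitted, 0.0, None))


_LEVEL_KEYS = {
    "individual": lambda s: (s.species, s.morph, s.individual, s.tissue),
    "species": lambda s: (s.species, s.tissue),
    "species+morph": lambda s: (s.species, s.morph, s.tissue),
}


def aggregate(coll: SpectrumCollection, level: str = "individual") -> SpectrumCollection:
    """Pointwise arithmetic mean of spectra within each group at ``level``.

    Levels: ``individual`` (average replicates), ``species`` (average
    everything per species/tissue) and ``species+morph`` (keep color morphs
    separate).  Group sizes are recorded on the output spectra.
    """
    if level not in _LEVEL_KEYS:
        raise SpectrumError(f"unknown aggregation level {level!r}")
    if len(coll) == 0:
        raise SpectrumError("cannot aggregate an empty collection")
    keyfn = _LEVEL_KEYS[level]
    groups: dict[tuple, list[ReflectanceSpectrum]] = {}
    for s in coll:
        groups.setdefault(keyfn(s), []).append(s)
    out = []
    for key, members in sorted(groups.items(), key=lambda kv: tuple(map(str, kv[0]))):
        vals = np.mean([m.reflectance for m in members], axis=0)
        proto = members[0]
        n_tot = sum(m.n_averaged for m in members)
        if level == "species":
            spec = replace(proto, reflectance=vals, individual="mean", morph=None, n_averaged=n_tot)
        elif level == "species+morph":
            spec = replace(proto, reflectance=vals, individual="mean", n_averaged=n_tot)
        else:
            spec = replace(proto, reflectance=vals, n_averaged=n_tot)
        out.append(spec)
    return SpectrumCollection(out)


def center_and_bin(
    spec: ReflectanceSpectrum, n_bins: int = 10, lo: float = 300.0, hi: float = 700.0
) -> np.ndarray:
    """Mean-center a spectrum then average it within equal-width bins.

    The grid must span exactly [lo, hi].  Bins are right-open except the last,
    which includes ``hi``.  With the defaults this yields the 10 x 40-nm
    binning used for spectral-shape ordination.
    """
    wl = spec.wavelengths
    if abs(wl[0] - lo) > 1e-9 or abs(wl[-1] - hi) > 1e-9:
        raise SpectrumError(
            f"grid spans [{wl[0]}, {wl[-1]}], expected exactly [{lo}, {hi}]"
        )
    centered = spec.reflectance - spec.reflectance.mean()
    edges = np.linspace(lo, hi, n_bins + 1)
    out = np.empty(n_bins)
    for b in range(n_bins):
        if b < n_bins - 1:
            mask = (wl >= edges[b]) & (wl < edges[b + 1])
        else:
            mask = (wl >= edges[b]) & (wl <= edges[b + 1])
        if not mask.any():
            raise SpectrumError(f"empty wavelength bin [{edges[b]}, {edges[b+1]}]")
        out[b] = centered[mask].mean()
    return out


def bin_matrix(
    coll: SpectrumCollection, n_bins: int = 10, lo: float = 300.0, hi: float = 700.0
) -> pd.DataFrame:
    """Stack :func:`center_and_bin` over a collection into a sample x bin table."""
    edges = np.linspace(lo, hi, n_bins + 1)
    cols = [f"bin_{edges[b]:.0f}_{edges[b+1]:.0f}" for b in range(n_bins)]
    rows, index = [], []
    for s in coll:
        rows.append(center_and_bin(s, n_bins=n_bins, lo=lo, hi=hi))
        morph = "" if s.morph is None else f":{s.morph}"
        index.append(f"{s.species}{morph}|{s.individual}")
    return pd.DataFrame(rows, index=index, columns=cols)
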