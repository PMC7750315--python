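"""Synthetic inputs with the statistical structure the analysis assumes.

Generates Yule trees rescaled to a fixed height, parametric reflectance
templates (UV-absorbing white plateaus, dark low-reflectance, chlorophyll-like
green), Brownian-motion continuous traits, and ordered categories produced by
thresholding a Brownian liability.  Every generator is a pure function of its
parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import TreeError
from .spectra import ReflectanceSpectrum, SpectrumCollection
from .trees import PhyloTree

__all__ = [
    "SpectrumTemplate",
    "WHITE",
    "DARK",
    "GREEN",
    "FRECKLED",
    "simulate_tree",
    "simulate_spectra",
    "simulate_bm_trait",
    "simulate_threshold_trait",
    "default_scenario",
    "Scenario",
]

GRID = np.arange(300.0, 701.0)


@dataclass(frozen=True)
class SpectrumTemplate:
    """Parametric reflectance shape for one floral/leaf color mode."""

    mode: str                      # sphingophilous-white | sapro-dark | green | freckled-pale
    plateau: tuple[float, float] = (50.0, 80.0)  # per-individual uniform draw, % reflectance
    uv_level: float = 5.0          # baseline below the cutoff, %
    cutoff: float = 420.0          # logistic rise midpoint, nm
    cutoff_width: float = 10.0     # logistic steepness, nm
    peak_center: float = 550.0     # Gaussian peak (green modes), nm
    peak_width: float = 45.0       # Gaussian sd, nm
    noise_sd: float = 1.0          # additive Gaussian noise, % reflectance


WHITE = SpectrumTemplate("sphingophilous-white", plateau=(50.0, 80.0), uv_level=5.0)
DARK = SpectrumTemplate("sapro-dark", plateau=(12.0, 20.0), uv_level=8.0, noise_sd=0.8)
GREEN = SpectrumTemplate("green", plateau=(18.0, 30.0), uv_level=5.0, noise_sd=0.8)
FRECKLED = SpectrumTemplate("freckled-pale", plateau=(25.0, 38.0), uv_level=7.0, noise_sd=1.2)


def simulate_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int = 0, height: float | None = 8.0
) -> PhyloTree:
    """Pure-birth (Yule) tree, optionally rescaled to a fixed root height.

    The default height of 8 time units mirrors a late-Miocene crown age of
    roughly 8 My.  Pass ``height=None`` to keep the raw Yule depth.
    """
    if n_tips < 2:
        raise TreeError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    # grow a lineage list; each entry is (node_id, birth_time)
    nodes: list[dict] = [{"parent": -1, "t": 0.0}]  # root
    active = [0]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k)) if k > 0 else 0.0
        split = active.pop(int(rng.integers(0, k)))
        for _ in range(2):
            nodes.append({"parent": split, "t": t})
            active.append(len(nodes) - 1)
    t_final = t + rng.exponential(1.0 / (birth_rate * n_tips))

    tips = active
    internal = [i for i in range(len(nodes)) if i not in tips]
    # order internal nodes so children precede parents is irrelevant; we only
    # need index remapping with tips first
    remap = {}
    for new, old in enumerate(tips):
        remap[old] = new
    for off, old in enumerate(internal):
        remap[old] = n_tips + off
    m = len(nodes)
    parent = np.full(m, -1, dtype=int)
    blen = np.zeros(m)
    children: list[list[int]] = [[] for _ in range(m)]
    for old, nd in enumerate(nodes):
        new = remap[old]
        if nd["parent"] >= 0:
            p = remap[nd["parent"]]
            parent[new] = p
            children[p].append(new)
            end = t_final if old in tips else min(
                n2["t"] for n2 in nodes if n2["parent"] == old
            )
            blen[new] = end - nd["t"]
    labels = [f"sp{i+1:02d}" for i in range(n_tips)]
    tree = PhyloTree(tip_labels=labels, parent=parent, blen=blen, children=children)
    if height is not None:
        tree = tree.rescale(height)
    return tree


def _template_curve(template: SpectrumTemplate, plateau: float) -> np.ndarray:
    lam = GRID
    if template.mode == "sphingophilous-white":
        rise = 1.0 / (1.0 + np.exp(-(lam - template.cutoff) / template.cutoff_width))
        base = template.uv_level + (plateau - template.uv_level) * rise
    elif template.mode == "sapro-dark":
        # maroon/black carrion-mimic shape: modest UV bump, blue-green
        # absorption, rise toward red; max stays around the plateau level
        blue_floor = 0.4 * template.uv_level
        uv_bump = (template.uv_level - blue_floor) * np.exp(
            -0.5 * ((lam - 330.0) / 55.0) ** 2
        )
        red_rise = (plateau - blue_floor) / (1.0 + np.exp(-(lam - 600.0) / 30.0))
        base = blue_floor + uv_bump + red_rise
    elif template.mode in {"green", "freckled-pale"}:
        peak = np.exp(-0.5 * ((lam - template.peak_center) / template.peak_width) ** 2)
        base = template.uv_level + (plateau - template.uv_level) * peak
    else:
        raise ValueError(f"unknown template mode {template.mode!r}")
    return base


def simulate_spectra(
    template: SpectrumTemplate,
    n_individuals: int,
    seed: int = 0,
    species: str = "sim",
    tissue: str = "corolla",
    morph: str | None = None,
    replicates: int = 1,
) -> SpectrumCollection:
    """Draw per-individual spectra from a template with seeded noise.

    White mode: logistic rise near the UV cutoff from a low UV baseline to a
    plateau drawn per individual from the template's plateau range.  Dark
    mode: same shape at low reflectance (max about 20%).  Green modes:
    chlorophyll-like Gaussian peak.  All values clipped to [0, 100]%.
    """
    rng = np.random.default_rng(seed)
    out = []
    for ind in range(n_individuals):
        plateau = rng.uniform(*template.plateau)
        base = _template_curve(template, plateau)
        for rep in range(replicates):
            noisy = base + rng.normal(0.0, template.noise_sd, GRID.size) if template.noise_sd > 0 else base.copy()
            out.append(
                ReflectanceSpectrum(
                    wavelengths=GRID.copy(),
                    reflectance=np.clip(noisy, 0.0, 100.0),
                    species=species,
                    individual=f"{species}_i{ind+1:02d}" + (f"_r{rep+1}" if replicates > 1 else ""),
                    tissue=tissue,
                    morph=morph,
                )
            )
    return SpectrumCollection(out)


def simulate_bm_trait(
    tree: PhyloTree, sigma2: float = 1.0, root: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Brownian trait over all nodes (tips first); increments ~ N(0, sigma2*t)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    rng = np.random.default_rng(seed)
    vals = np.zeros(tree.n_nodes)
    vals[tree.root] = root
    for node in tree.preorder:
        p = tree.parent[node]
        if p >= 0:
            vals[node] = vals[p] + rng.normal(0.0, np.sqrt(sigma2 * tree.blen[node]))
    return vals


def simulate_threshold_trait(
    tree: PhyloTree, thresholds, seed: int = 0, root: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Ordered categories from thresholding a BM liability (sigma2 = 1).

    Returns (categories over all nodes, 1-based; true liabilities).  A
    liability exactly at a threshold is assigned to the upper category.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size and np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    liab = simulate_bm_trait(tree, sigma2=1.0, root=root, seed=seed)
    cats = np.searchsorted(thresholds, liab, side="right") + 1
    return cats, liab


# ---------------------------------------------------------------------------
# default end-to-end scenario
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """A fully simulated study: tree, spectra, pollination modes and zones."""

    tree: PhyloTree
    corollas: SpectrumCollection
    leaves: SpectrumCollection
    modes: dict[str, str]       # species -> pollination mode
    zones: dict[str, int]       # species -> ordered environmental zone
    seed: int = 0

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": list(self.modes),
                "mode": [self.modes[s] for s in self.modes],
                "zone": [self.zones[s] for s in self.modes],
            }
        )


def _clade_tips(tree: PhyloTree) -> tuple[list[int], list[int]]:
    """Tips descending from each child of the root (largest two clades)."""
    root = tree.root
    kids = tree.children[root]
    sets = []
    for kid in kids:
        acc, stack = [], [kid]
        while stack:
            nd = stack.pop()
            if nd < tree.n_tips:
                acc.append(nd)
            stack.extend(tree.children[nd])
        sets.append(acc)
    sets.sort(key=len, reverse=True)
    return sets[0], sets[1] if len(sets) > 1 else []


def default_scenario(seed: int = 0, n_species: int = 11, height: float = 8.0) -> Scenario:
    """Two-clade study mimicking the empirical scale: 11 species, 4-11
    individuals each, tree height 8; one clade white/hawkmoth-pollinated in
    zone 1, the other dark/fly-pollinated in zone 3, with a generalist
    (freckled-pale, zone 2) nested in the dark clade."""
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_species, birth_rate=1.0, seed=seed, height=height)
    clade_a, clade_b = _clade_tips(tree)

    modes: dict[str, str] = {}
    zones: dict[str, int] = {}
    corollas: list[ReflectanceSpectrum] = []
    leaves: list[ReflectanceSpectrum] = []
    # make the *smaller* clade sphingophilous, as in a 3-vs-8 split
    white_clade = clade_b if len(clade_b) <= len(clade_a) else clade_a
    dark_clade = clade_a if white_clade is clade_b else clade_b
    generalist = dark_clade[-1] if len(dark_clade) > 2 else None

    for tip in range(tree.n_tips):
        sp = tree.tip_labels[tip]
        n_ind = int(rng.integers(4, 12))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if tip in white_clade:
            template, mode, zone = WHITE, "hawkmoth", 1
        elif tip == generalist:
            template, mode, zone = FRECKLED, "generalist", 2
        else:
            template, mode, zone = DARK, "fly", 3
        modes[sp] = mode
        zones[sp] = zone
        corollas.extend(
            simulate_spectra(template, n_ind, seed=sub_seed, species=sp).spectra
        )
        leaf_seed = int(rng.integers(0, 2**31 - 1))
        leaves.extend(
            simulate_spectra(
                GREEN, 2, seed=leaf_seed, species=sp, tissue="leaf"
            ).spectra
        )
    return Scenario(
        tree=tree,
        corollas=SpectrumCollection(corollas),
        leaves=SpectrumCollection(leaves),
        modes=modes,
        zones=zones,
        seed=seed,
    )
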