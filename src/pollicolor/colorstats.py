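"""Discriminability statistics on groups of color loci.

Bootstrapped centroid-to-centroid color distances with percentile confidence
intervals, and a permutation significance test in which the observed mean
between-group distance is compared against a null distribution obtained by
reshuffling group labels over samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StatsError
from .vision import ColorLocus, NoiseModel, fly_locus, rnl_contrast_from_df

__all__ = [
    "GroupedLoci",
    "DistanceSummary",
    "boot_group_distance",
    "permutation_test",
    "summaries_to_frame",
]


@dataclass
class GroupedLoci:
    """Color loci with group labels at one or more grouping levels."""

    loci: list[ColorLocus]
    labels: dict[str, list[str]]  # level -> one label per locus

    def __post_init__(self):
        for level, labs in self.labels.items():
            if len(labs) != len(self.loci):
                raise StatsError(f"label list for {level!r} does not match loci count")

    def groups(self, level: str) -> dict[str, list[int]]:
        if level not in self.labels:
            raise StatsError(f"unknown grouping level {level!r}")
        out: dict[str, list[int]] = {}
        for i, lab in enumerate(self.labels[level]):
            out.setdefault(lab, []).append(i)
        return out


@dataclass
class DistanceSummary:
    """Bootstrap/permutation summary for one pair of groups."""

    pair: tuple[str, str]
    metric: str
    mean: float
    ci: tuple[float, float]
    n_boot: int
    p_value: float | None = None
    n_perm: int = 0
    seed: int = 0

    @property
    def significant(self) -> bool | None:
        return None if self.p_value is None else self.p_value < 0.05


def _native_coords(loci: list[ColorLocus], metric: str) -> np.ndarray:
    """Coordinates in the metric's native space.

    RNL: log adapted catches (so centroid differences are delta-f vectors and
    the centroid distance is itself a JND).  Fly: (u, v) opponency plane.
    """
    if metric == "rnl":
        q = np.vstack([lc.q for lc in loci])
        if np.any(q <= 0):
            raise StatsError("non-positive adapted catch in RNL metric")
        return np.log(q)
    if metric == "fly_euclid":
        return np.vstack([fly_locus(lc)[1] for lc in loci])
    raise StatsError(f"unknown metric {metric!r}")


def _centroid_distance(fa: np.ndarray, fb: np.ndarray, metric: str, noise: NoiseModel | None) -> float:
    ca, cb = fa.mean(axis=0), fb.mean(axis=0)
    if metric == "rnl":
        assert noise is not None
        return rnl_contrast_from_df(ca - cb, noise.e)
    return float(np.linalg.norm(ca - cb))


def boot_group_distance(
    g: GroupedLoci,
    pair: tuple[str, str],
    level: str,
    metric: str = "rnl",
    n_boot: int = 1000,
    seed: int = 0,
    noise: NoiseModel | None = None,
    ci_level: float = 95.0,
) -> DistanceSummary:
    """Bootstrap the centroid-to-centroid distance between two groups.

    Each replicate resamples loci with replacement within each group,
    recomputes group centroids in the metric's native space, and records the
    centroid distance; reported are the replicate mean and percentile CI.
    """
    if metric == "rnl" and noise is None:
        noise = NoiseModel()
    groups = g.groups(level)
    for name in pair:
        if name not in groups:
            raise StatsError(f"group {name!r} not present at level {level!r}")
        if len(groups[name]) < 2:
            raise StatsError(f"group {name!r} has fewer than 2 samples")
    ia, ib = groups[pair[0]], groups[pair[1]]
    coords = _native_coords(g.loci, metric)
    fa, fb = coords[ia], coords[ib]
    rng = np.random.default_rng(seed)
    dist = np.empty(n_boot)
    for b in range(n_boot):
        ra = fa[rng.integers(0, len(ia), len(ia))]
        rb = fb[rng.integers(0, len(ib), len(ib))]
        dist[b] = _centroid_distance(ra, rb, metric, noise)
    half = (100.0 - ci_level) / 2.0
    lo, hi = np.percentile(dist, [half, 100.0 - half])
    return DistanceSummary(
        pair=pair, metric=metric, mean=float(dist.mean()), ci=(float(lo), float(hi)),
        n_boot=n_boot, seed=seed,
    )


def _pairwise_matrix(coords: np.ndarray, metric: str, noise: NoiseModel | None) -> np.ndarray:
    n = coords.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "rnl":
                d = rnl_contrast_from_df(coords[i] - coords[j], noise.e)
            else:
                d = float(np.linalg.norm(coords[i] - coords[j]))
            D[i, j] = D[j, i] = d
    return D


def permutation_test(
    g: GroupedLoci,
    level: str,
    metric: str = "rnl",
    n_perm: int = 1000,
    seed: int = 0,
    noise: NoiseModel | None = None,
) -> dict[tuple[str, str], DistanceSummary]:
    """Pairwise permutation tests of between-group mean color distance.

    For each group pair the statistic is the observed mean of all
    between-group pairwise distances; the null distribution reshuffles the
    pooled labels of that pair.  ``p = (1 + #{pseudo >= obs}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise StatsError("n_perm must be at least 100")
    if metric == "rnl" and noise is None:
        noise = NoiseModel()
    groups = g.groups(level)
    names = sorted(groups)
    if len(names) < 2:
        raise StatsError("permutation test needs at least 2 groups")
    coords = _native_coords(g.loci, metric)
    D = _pairwise_matrix(coords, metric, noise)
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, str], DistanceSummary] = {}
    for a_i in range(len(names)):
        for b_i in range(a_i + 1, len(names)):
            na, nb = names[a_i], names[b_i]
            ia = np.array(sorted(groups[na]))
            ib = np.array(sorted(groups[nb]))
            pool = np.concatenate([ia, ib])
            ka = ia.size
            obs = float(D[np.ix_(ia, ib)].mean())
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(pool)
                pa, pb = perm[:ka], perm[ka:]
                if D[np.ix_(pa, pb)].mean() >= obs - 1e-12:
                    count += 1
            p = (1 + count) / (n_perm + 1)
            out[(na, nb)] = DistanceSummary(
                pair=(na, nb), metric=metric, mean=obs, ci=(np.nan, np.nan),
                n_boot=0, p_value=p, n_perm=n_perm, seed=seed,
            )
    return out


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Tidy table of distance summaries (from bootstrap and/or permutation)."""
    if isinstance(summaries, dict):
        summaries = list(summaries.values())
    rows = []
    for s in summaries:
        rows.append(
            {
                "group_a": s.pair[0],
                "group_b": s.pair[1],
                "metric": s.metric,
                "mean": s.mean,
                "ci_lo": s.ci[0],
                "ci_hi": s.ci[1],
                "p_value": s.p_value,
                "n_boot": s.n_boot,
                "n_perm": s.n_perm,
                "seed": s.seed,
            }
        )
    return pd.DataFrame(rows)
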