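"""Environmental-space ordination, occurrence-density grids and niche overlap.

The realized niche of each range is summarized as a kernel-smoothed
occupancy density over the first two PCA axes of the environmental
predictors, corrected for the availability of environmental conditions
(background prevalence). Overlap between two such densities is Schoener's
D, and equivalency / similarity permutation tests ask whether the observed
overlap is lower (equivalency) or higher (similarity) than chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter


# ---------------------------------------------------------------------------
# variable selection and ordination
# ---------------------------------------------------------------------------

def select_uncorrelated_variables(values: pd.DataFrame, threshold: float = 0.50) -> list[str]:
    """Greedy collinearity filter in column order.

    A variable is retained iff its absolute Pearson correlation with every
    already-retained variable is below ``threshold``. Constant columns are
    excluded with a warning (their correlation is undefined).
    """
    if values.shape[1] < 2:
        raise ValueError("need at least two candidate variables")
    kept: list[str] = []
    for name in values.columns:
        x = values[name].to_numpy(dtype=float)
        if np.std(x) == 0:
            warnings.warn(f"variable {name!r} is constant; excluded")
            continue
        ok = True
        for k in kept:
            r = np.corrcoef(x, values[k].to_numpy(dtype=float))[0, 1]
            if abs(r) >= threshold:
                ok = False
                break
        if ok:
            kept.append(name)
    return kept


@dataclass
class EnvSpace:
    """Two-axis PCA of occurrence environments with projected background."""

    axis_scores: np.ndarray          # occurrences x 2
    loadings: np.ndarray             # variables x 2
    variance_explained: np.ndarray   # fraction per retained axis
    background_scores: np.ndarray    # background cells x 2
    variable_names: list[str]
    center: np.ndarray
    scale: np.ndarray


def build_env_space(
    occ_values: pd.DataFrame, background_values: pd.DataFrame
) -> EnvSpace:
    """PCA of standardized occurrence environments; background projected
    with the same centering and scaling."""
    if len(occ_values) < 3:
        raise ValueError("need at least three occurrences")
    names = list(occ_values.columns)
    X = occ_values.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [n for n, s in zip(names, sd) if s == 0]
        raise ValueError(f"constant variables: {bad}")
    Z = (X - mu) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    if np.sum(s > s[0] * 1e-10) < 2:
        raise ValueError("environmental data have rank < 2")
    var = s**2 / np.sum(s**2)
    scores = Z @ Vt[:2].T
    B = (background_values[names].to_numpy(dtype=float) - mu) / sd
    return EnvSpace(
        axis_scores=scores,
        loadings=Vt[:2].T,
        variance_explained=var[:2],
        background_scores=B @ Vt[:2].T,
        variable_names=names,
        center=mu,
        scale=sd,
    )


# ---------------------------------------------------------------------------
# occupancy-density grids
# ---------------------------------------------------------------------------

@dataclass
class NicheGrid:
    """Corrected occupancy density z over a gridded 2-D environmental space.

    ``o`` is the kernel-smoothed occurrence density, ``e`` the background
    prevalence, and ``z`` the occupancy corrected by availability
    (o/e where e > 0, zero elsewhere), normalized to sum to one.
    """

    R: int
    extent: tuple[tuple[float, float], tuple[float, float]]
    o: np.ndarray
    e: np.ndarray
    z: np.ndarray

    def same_grid(self, other: "NicheGrid") -> bool:
        return self.R == other.R and np.allclose(
            np.asarray(self.extent), np.asarray(other.extent)
        )


def _silverman(x: np.ndarray) -> float:
    n = len(x)
    sd = np.std(x)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 1.06 * spread * n ** (-0.2) if spread > 0 else 0.0


def _smooth_density(
    pts: np.ndarray,
    extent,
    R: int,
    bandwidth: tuple[float, float],
) -> np.ndarray:
    (x0, x1), (y0, y1) = extent
    H, _, _ = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=R, range=[[x0, x1], [y0, y1]]
    )
    cell = ((x1 - x0) / R, (y1 - y0) / R)
    sig = (bandwidth[0] / cell[0] if cell[0] > 0 else 0.0,
           bandwidth[1] / cell[1] if cell[1] > 0 else 0.0)
    D = gaussian_filter(H, sigma=sig, mode="constant")
    total = D.sum()
    return D / total if total > 0 else D


def occurrence_density_grid(
    scores: np.ndarray,
    background_scores: np.ndarray,
    R: int = 100,
    bandwidth: str | float | tuple[float, float] = "silverman",
    extent=None,
    corrected: bool = True,
) -> NicheGrid:
    """Occurrence and background densities on an R x R grid of the
    ordination plane, with availability-corrected occupancy z.

    Densities are binned counts smoothed by a Gaussian kernel; the default
    bandwidth is Silverman's rule per axis on the occurrence scores. With
    ``corrected=False``, z is the uncorrected occurrence density o
    (normalized), an option the originating framework also offers.
    """
    scores = np.asarray(scores, dtype=float)
    background_scores = np.asarray(background_scores, dtype=float)
    if R < 10:
        raise ValueError("R must be at least 10")
    if scores.size == 0:
        raise ValueError("no occurrences")
    if extent is None:
        lo = background_scores.min(axis=0)
        hi = background_scores.max(axis=0)
        pad = 0.05 * (hi - lo + 1e-12)
        extent = ((lo[0] - pad[0], hi[0] + pad[0]), (lo[1] - pad[1], hi[1] + pad[1]))
    if bandwidth == "silverman":
        bw = (_silverman(scores[:, 0]), _silverman(scores[:, 1]))
    elif np.isscalar(bandwidth):
        bw = (float(bandwidth), float(bandwidth))
    else:
        bw = (float(bandwidth[0]), float(bandwidth[1]))

    o = _smooth_density(scores, extent, R, bw)
    e = _smooth_density(background_scores, extent, R, bw)
    if corrected:
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(e > 0, o / e, 0.0)
    else:
        z = o.copy()
    total = z.sum()
    if total > 0:
        z = z / total
    return NicheGrid(R=R, extent=extent, o=o, e=e, z=z)


def schoener_d(z1: NicheGrid, z2: NicheGrid) -> float:
    """Schoener's D = 1 - 0.5 * sum |z1 - z2| over grid cells (both
    densities normalized to sum to one). 0 = disjoint, 1 = identical."""
    if not z1.same_grid(z2):
        raise ValueError("niche grids are on different grids")
    a, b = z1.z, z2.z
    sa, sb = a.sum(), b.sum()
    if sa > 0:
        a = a / sa
    if sb > 0:
        b = b / sb
    d = 1.0 - 0.5 * np.abs(a - b).sum()
    return float(min(1.0, max(0.0, d)))


def niche_centroid_shift(scores1: np.ndarray, scores2: np.ndarray) -> np.ndarray:
    """Displacement vector between the two occurrence centroids in
    ordination space (descriptive; no test attached)."""
    return np.asarray(scores2, float).mean(axis=0) - np.asarray(scores1, float).mean(axis=0)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

@dataclass
class OverlapTest:
    observed_D: float
    null_D: np.ndarray
    p_value: float
    n_permutations: int
    kind: str          # "equivalency" | "similarity"
    alternative: str   # direction convention of the one-sided p-value


def _joint_extent(*point_sets):
    pts = np.vstack(point_sets)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    pad = 0.05 * (hi - lo + 1e-12)
    return ((lo[0] - pad[0], hi[0] + pad[0]), (lo[1] - pad[1], hi[1] + pad[1]))


def equivalency_test(
    occ1: np.ndarray,
    occ2: np.ndarray,
    background1: np.ndarray,
    background2: np.ndarray,
    R: int = 100,
    n_perm: int = 1000,
    bandwidth="silverman",
    seed: int | None = None,
    corrected: bool = True,
    extent=None,
) -> OverlapTest:
    """Niche equivalency: pool the occurrences, reassign labels at random
    (sample sizes preserved), and recompute D. Small p means the observed
    overlap is lower than expected for interchangeable niches.

    p = (1 + #{null_D <= observed_D}) / (n_perm + 1).
    """
    occ1, occ2 = np.asarray(occ1, float), np.asarray(occ2, float)
    if len(occ1) == 0 or len(occ2) == 0:
        raise ValueError("both occurrence sets must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if extent is None:
        extent = _joint_extent(occ1, occ2, background1, background2)
    kw = dict(R=R, bandwidth=bandwidth, extent=extent, corrected=corrected)
    g1 = occurrence_density_grid(occ1, background1, **kw)
    g2 = occurrence_density_grid(occ2, background2, **kw)
    obs = schoener_d(g1, g2)

    rng = np.random.default_rng(seed)
    pooled = np.vstack([occ1, occ2])
    n1 = len(occ1)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(pooled))
        a = occurrence_density_grid(pooled[perm[:n1]], background1, **kw)
        b = occurrence_density_grid(pooled[perm[n1:]], background2, **kw)
        null[i] = schoener_d(a, b)
    p = (1.0 + np.sum(null <= obs)) / (n_perm + 1.0)
    return OverlapTest(obs, null, float(p), n_perm, "equivalency",
                       "lower overlap than permuted labels (niches differ)")


def similarity_test(
    occ_ref: np.ndarray,
    occ_shifted: np.ndarray,
    background_shifted: np.ndarray,
    background_ref: np.ndarray | None = None,
    R: int = 100,
    n_perm: int = 1000,
    bandwidth="silverman",
    seed: int | None = None,
    corrected: bool = True,
    min_inside: float = 0.95,
    extent=None,
) -> OverlapTest:
    """Niche similarity with the reference niche held fixed.

    The shifted niche's occurrence cloud is translated so its centroid lands
    on a random background point; translations pushing more than
    ``1 - min_inside`` of the points outside the analysis extent are
    resampled. Small p means the niches are more similar than such random
    relocations. p = (1 + #{null_D >= observed_D}) / (n_perm + 1).
    """
    occ_ref, occ_shifted = np.asarray(occ_ref, float), np.asarray(occ_shifted, float)
    background_shifted = np.asarray(background_shifted, float)
    if background_ref is None:
        background_ref = background_shifted
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if extent is None:
        extent = _joint_extent(occ_ref, occ_shifted, background_ref,
                               background_shifted)
    kw = dict(R=R, bandwidth=bandwidth, extent=extent, corrected=corrected)
    g_ref = occurrence_density_grid(occ_ref, background_ref, **kw)
    g_shift = occurrence_density_grid(occ_shifted, background_shifted, **kw)
    obs = schoener_d(g_ref, g_shift)

    rng = np.random.default_rng(seed)
    centroid = occ_shifted.mean(axis=0)
    (x0, x1), (y0, y1) = extent
    null = np.empty(n_perm)
    attempts_cap = 100 * n_perm
    attempts = 0
    for i in range(n_perm):
        while True:
            attempts += 1
            if attempts > attempts_cap:
                raise ValueError("background too small: no admissible shift found")
            target = background_shifted[rng.integers(len(background_shifted))]
            moved = occ_shifted + (target - centroid)
            inside = (
                (moved[:, 0] >= x0) & (moved[:, 0] <= x1)
                & (moved[:, 1] >= y0) & (moved[:, 1] <= y1)
            ).mean()
            if inside >= min_inside:
                break
        g = occurrence_density_grid(moved, background_shifted, **kw)
        null[i] = schoener_d(g_ref, g)
    p = (1.0 + np.sum(null >= obs)) / (n_perm + 1.0)
    return OverlapTest(obs, null, float(p), n_perm, "similarity",
                       "higher overlap than random relocation (niches similar)")
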