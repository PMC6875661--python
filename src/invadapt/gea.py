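"""Genotype-environment association with structure control.

Two complementary detectors run on the same filtered genotype matrix:

* a latent factor mixed model (LFMM): each SNP is regressed on one
  standardized environmental variable while K unobserved factors absorb
  population structure; z-scores from several random restarts are combined
  by their median, recalibrated with a genomic inflation factor (GIF),
  and converted to Storey q-values;
* an ancestry-conditioned partial redundancy analysis (RDA): genotypes and
  predictors are residualized on the ancestry coefficients, the constrained
  axes are extracted, and a robust Mahalanobis distance of each SNP's
  loadings provides the outlier statistic, again GIF-calibrated.

Only SNPs significant in both methods are reported as outliers.

The latent-factor solver here is the deterministic ridge/least-squares
formulation (alternating least squares with random initialization per
repeat) rather than an MCMC sampler; matched K and repeat count reproduce
the statistical behaviour of the sampler-based original.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .synthetic import GenotypeMatrix

CHI2_1_MEDIAN = stats.chi2.median(1)  # 0.4549... ; the "0.456" GIF constant


# ---------------------------------------------------------------------------
# filtering and imputation
# ---------------------------------------------------------------------------

def filter_genotypes(
    raw: GenotypeMatrix, max_missing: float = 0.30, mac: int = 40
) -> tuple[GenotypeMatrix, dict]:
    """Drop SNPs with more than ``max_missing`` missing calls or a minor
    allele count below ``mac`` (both rules are floors: 30% missing and
    MAC exactly 40 are retained)."""
    miss = raw.missing_fraction()
    macs = raw.minor_allele_count()
    keep = (miss <= max_missing) & (macs >= mac)
    report = {
        "n_input": raw.n_snps,
        "n_removed_missing": int((miss > max_missing).sum()),
        "n_removed_mac": int(((macs < mac) & (miss <= max_missing)).sum()),
        "n_kept": int(keep.sum()),
    }
    if report["n_kept"] == 0:
        raise ValueError("no SNP survives filtering")
    return raw.take_snps(np.flatnonzero(keep)), report


def impute_missing(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Replace missing calls by the per-SNP mean genotype.

    Returns (imputed float matrix, boolean missingness mask)."""
    calls = G.calls.astype(float)
    mask = G.calls < 0
    if mask.all(axis=0).any():
        raise ValueError("all-missing SNP present; filter first")
    calls[mask] = np.nan
    col_mean = np.nanmean(calls, axis=0)
    idx = np.where(mask)
    calls[idx] = col_mean[idx[1]]
    return calls, mask


# ---------------------------------------------------------------------------
# latent factor mixed model
# ---------------------------------------------------------------------------

def _als_rank_k(Yc: np.ndarray, K: int, rng, n_iter: int, tol: float) -> np.ndarray:
    """Rank-K factor estimate of a centered matrix by alternating least
    squares from a random start (converges to the leading SVD subspace,
    with repeat-to-repeat jitter from the initialization)."""
    n = Yc.shape[0]
    U = rng.standard_normal((n, K))
    prev = np.inf
    for _ in range(n_iter):
        V, *_ = np.linalg.lstsq(U, Yc, rcond=None)
        U, *_ = np.linalg.lstsq(V.T, Yc.T, rcond=None)
        U = U.T
        sse = float(((Yc - U @ V) ** 2).sum())
        if abs(prev - sse) < tol * max(prev, 1.0):
            break
        prev = sse
    return U


def _als_joint(Yc: np.ndarray, x: np.ndarray, K: int, rng, n_iter: int, tol: float) -> np.ndarray:
    """Rank-K factors of the residual after the environmental effect
    (alternating with the effect estimate). Powerful but leaves the
    structure component along x uncorrected, hence inflated null z."""
    n = Yc.shape[0]
    U = rng.standard_normal((n, K))
    prev = np.inf
    for _ in range(n_iter):
        A = np.column_stack([x, U])
        coef, *_ = np.linalg.lstsq(A, Yc, rcond=None)
        b = coef[0]
        V = coef[1:]
        U, *_ = np.linalg.lstsq(V.T, (Yc - np.outer(x, b)).T, rcond=None)
        U = U.T
        sse = float(((Yc - A @ coef) ** 2).sum())
        if abs(prev - sse) < tol * max(prev, 1.0):
            break
        prev = sse
    return U


def _env_zscores(Yc: np.ndarray, x: np.ndarray, U: np.ndarray) -> np.ndarray:
    """t-statistics of the environmental coefficient in the joint
    regression of every SNP on [1, x, factors]."""
    n = Yc.shape[0]
    D = np.column_stack([np.ones(n), x, U])
    DtD_inv = np.linalg.pinv(D.T @ D)
    beta = DtD_inv @ D.T @ Yc
    resid = Yc - D @ beta
    dof = max(n - D.shape[1], 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.clip(sigma2 * DtD_inv[1, 1], 1e-30, None))
    return beta[1] / se


def lfmm_fit(
    Y: np.ndarray,
    env_variable: np.ndarray,
    K: int = 3,
    n_repeats: int = 5,
    seed: int | None = None,
    n_iter: int = 30,
    tol: float = 1e-8,
    flag_p: float = 1e-3,
) -> np.ndarray:
    """Per-SNP z-scores for one environmental variable under a K-factor
    latent model, one column per repeat.

    Y is the imputed genotype matrix (individuals x SNPs); it is centered
    internally and the environmental variable standardized. Each repeat is
    a two-stage fit from a random initialization:

    1. factors are estimated jointly with the environmental effect
       (alternating least squares on the effect-residual), giving a
       powerful but structure-inflated first-pass statistic that is GIF
       recalibrated to flag candidate SNPs at ``flag_p``;
    2. factors are re-estimated from the genotype matrix with the flagged
       SNPs excluded, so they span population structure rather than the
       environmental response itself, and the final z for every SNP is the
       t-statistic of the environmental coefficient with those factors
       partialled out of the predictor.

    The second stage is what keeps null z-scores calibrated (GIF near 1)
    while strong environmental responses stay out of the factor estimate.
    """
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    if K >= min(n, p):
        raise ValueError("K must be smaller than min(n_individuals, n_snps)")
    x = np.asarray(env_variable, dtype=float)
    sd = x.std()
    x = (x - x.mean()) / (sd if sd > 0 else 1.0)
    Yc = Y - Y.mean(axis=0)

    rng = np.random.default_rng(seed)
    zmat = np.empty((p, n_repeats))
    for rep in range(n_repeats):
        z0 = _env_zscores(Yc, x, _als_joint(Yc, x, K, rng, n_iter, tol))
        lam0 = np.median(z0**2) / CHI2_1_MEDIAN
        p0 = stats.chi2.sf(z0**2 / max(lam0, 1e-12), df=1)
        keep = p0 > flag_p
        if keep.sum() < max(K + 2, p // 10):
            keep = np.ones(p, dtype=bool)
        U = _als_rank_k(Yc[:, keep], K, rng, n_iter, tol)
        zmat[:, rep] = _env_zscores(Yc, x, U)
    return zmat


def combine_z_and_gif(z: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Median-combine z-scores across repeats and recalibrate with the
    genomic inflation factor λ = median(z²) / median(χ²₁).

    Returns (adjusted p per SNP, λ, combined z). Non-finite z are excluded
    from λ and flagged with p = NaN.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] < 1:
        raise ValueError("need at least one repeat")
    zc = np.median(z, axis=1)
    finite = np.isfinite(zc)
    if not finite.any():
        raise ValueError("no finite z-scores")
    lam = float(np.median(zc[finite] ** 2) / CHI2_1_MEDIAN)
    p = np.full(zc.shape, np.nan)
    p[finite] = stats.chi2.sf(zc[finite] ** 2 / lam, df=1)
    return p, lam, zc


# ---------------------------------------------------------------------------
# partial redundancy analysis
# ---------------------------------------------------------------------------

@dataclass
class PartialRDA:
    loadings: np.ndarray            # SNPs x constrained axes
    axis_variance: np.ndarray       # variance fraction per constrained axis
    constrained_fraction: float     # of conditioned genotype variance
    n_axes: int


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ coef


def partial_rda(
    Y: np.ndarray,
    env_matrix: pd.DataFrame,
    condition: np.ndarray,
) -> PartialRDA:
    """Partial RDA of genotypes on environmental predictors, conditioned on
    ancestry coefficients.

    Genotypes (centered, not scaled) and predictors are residualized on the
    conditioning matrix (one ancestry column dropped against the intercept),
    the fitted values of the multivariate regression are decomposed by SVD,
    and each SNP's loadings on the constrained axes are returned.
    """
    Y = np.asarray(Y, dtype=float)
    Y = Y - Y.mean(axis=0)
    E = env_matrix.to_numpy(dtype=float)
    names = list(env_matrix.columns)
    rank = np.linalg.matrix_rank(E - E.mean(axis=0))
    if rank < E.shape[1]:
        dep = []
        for j in range(E.shape[1]):
            sub = E[:, : j + 1] - E[:, : j + 1].mean(axis=0)
            if np.linalg.matrix_rank(sub) < j + 1:
                dep.append(names[j])
        raise ValueError(f"env matrix is rank-deficient; dependent columns: {dep}")
    Q = np.asarray(condition, dtype=float)
    C = np.column_stack([np.ones(len(Y)), Q[:, :-1]])  # drop one ancestry column
    Yr = _residualize(Y, C)
    Er = _residualize(E, C)
    # predictors fully absorbed by the conditioning carry no information;
    # keeping their numerically-zero residuals would project pure noise
    scale = np.linalg.norm(E - E.mean(axis=0), axis=0)
    kept = np.linalg.norm(Er, axis=0) > 1e-8 * np.where(scale > 0, scale, 1.0)
    Er = Er[:, kept]
    if Er.shape[1] == 0:
        return PartialRDA(
            loadings=np.zeros((Y.shape[1], 0)),
            axis_variance=np.zeros(0),
            constrained_fraction=0.0,
            n_axes=0,
        )
    coef, *_ = np.linalg.lstsq(Er, Yr, rcond=None)
    fitted = Er @ coef
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    n_axes = min(E.shape[1], int(np.sum(s > s[0] * 1e-12)) if s.size else 0)
    total = float((Yr**2).sum())
    return PartialRDA(
        loadings=Vt[:n_axes].T,
        axis_variance=(s[:n_axes] ** 2) / total if total > 0 else s[:n_axes] * 0,
        constrained_fraction=float((s[:n_axes] ** 2).sum() / total) if total > 0 else 0.0,
        n_axes=n_axes,
    )


def rda_outlier_pvalues(
    loadings: np.ndarray, n_axes: int | None = None
) -> tuple[np.ndarray, float, np.ndarray]:
    """Outlier p-values from a robust Mahalanobis distance of SNP loadings.

    Axes are centered by their median and scaled by 1.4826 x MAD; the
    squared distance is GIF-calibrated against χ² with ``n_axes`` degrees
    of freedom and converted to q-values.
    """
    L = np.asarray(loadings, dtype=float)
    if n_axes is None:
        n_axes = L.shape[1]
    if n_axes > L.shape[1]:
        raise ValueError("n_axes exceeds the available constrained axes")
    L = L[:, :n_axes]
    if not np.all(np.isfinite(L)):
        raise ValueError("loadings must be finite")
    med = np.median(L, axis=0)
    mad = np.median(np.abs(L - med), axis=0) * 1.4826
    mad = np.where(mad > 0, mad, 1.0)
    d2 = (((L - med) / mad) ** 2).sum(axis=1)
    lam = float(np.median(d2) / stats.chi2.median(n_axes))
    p = stats.chi2.sf(d2 / lam, df=n_axes)
    return p, lam, qvalues(p)


# ---------------------------------------------------------------------------
# FDR control
# ---------------------------------------------------------------------------

def qvalues(p: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with smoother-estimated π₀.

    π₀(λ) = #{p > λ} / (m(1-λ)) over a λ grid is smoothed with a cubic
    spline and read off at the largest λ. q-values are monotone
    non-decreasing in p and never exceed 1.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if pi0 is None:
        grid = np.arange(0.05, 0.96, 0.05)
        pi0_l = np.array([(p > l).mean() / (1 - l) for l in grid])
        if p.max() < grid[0] or np.allclose(pi0_l, 0):
            pi0 = 1.0
        else:
            try:
                sp = UnivariateSpline(grid, pi0_l, k=3)
                pi0 = float(sp(grid[-1]))
            except Exception:
                pi0 = float(pi0_l[-1])
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p)
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0, 1)
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# outlier intersection
# ---------------------------------------------------------------------------

def intersect_outliers(
    lfmm_q: dict[str, np.ndarray] | np.ndarray,
    rda_q: np.ndarray,
    locus_map: np.ndarray,
    snp_ids: list[str] | None = None,
    q_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNPs significant in both detectors, grouped by parent locus.

    ``lfmm_q`` is either one q-value vector or a mapping variable -> vector
    (a SNP is an LFMM hit if significant for any variable). Returns a
    per-SNP table of the intersection and a per-locus summary with each
    method's hit counts and the common count.
    """
    rda_q = np.asarray(rda_q, dtype=float)
    if isinstance(lfmm_q, dict):
        qmat = {k: np.asarray(v, float) for k, v in lfmm_q.items()}
        lfmm_hit = np.zeros(rda_q.size, dtype=bool)
        best_var = np.array([""] * rda_q.size, dtype=object)
        best_q = np.ones(rda_q.size)
        for var, qv in qmat.items():
            hit = qv < q_threshold
            better = qv < best_q
            best_var[better] = var
            best_q = np.minimum(best_q, qv)
            lfmm_hit |= hit
    else:
        best_q = np.asarray(lfmm_q, dtype=float)
        lfmm_hit = best_q < q_threshold
        best_var = np.array([""] * rda_q.size, dtype=object)
    rda_hit = rda_q < q_threshold
    common = lfmm_hit & rda_hit
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(rda_q.size)]
    locus_map = np.asarray(locus_map)
    snp_table = pd.DataFrame(
        {
            "snp": np.asarray(snp_ids, dtype=object)[common],
            "locus": locus_map[common],
            "lfmm_q": best_q[common],
            "lfmm_variable": best_var[common],
            "rda_q": rda_q[common],
        }
    ).reset_index(drop=True)
    locus_table = (
        pd.DataFrame(
            {
                "locus": locus_map,
                "lfmm": lfmm_hit.astype(int),
                "rdadapt": rda_hit.astype(int),
                "common": common.astype(int),
            }
        )
        .groupby("locus", as_index=False)
        .sum()
    )
    locus_table = locus_table[(locus_table[["lfmm", "rdadapt", "common"]].sum(axis=1) > 0)]
    return snp_table, locus_table.reset_index(drop=True)
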