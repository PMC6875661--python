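"""Per-locus pairwise F_ST and generalized dissimilarity modelling (GDM).

Outlier loci from the genotype-environment association step are examined
for spatially explicit shifts in allele frequency: pairwise Weir-Cockerham
F_ST among populations at each locus (multi-SNP loci combined by ratio of
sums) is regressed on monotone I-spline transforms of the environmental
predictors (and straight-line geographic distance) through the saturating
GDM link d = 1 - exp(-eta). The total height of a predictor's fitted
function over the observed gradient is its partial allelic turnover: the
predicted change in F_ST across the gradient.

A reference group of randomly sampled SNPs supplies the null level of
deviance and turnover; candidate loci must (C1) exceed the reference's
explained deviance, (C2) show larger turnover for some environmental
predictor than both the reference and the locus's own geography term, and
(C3) have that predictor account for at least 40% of the locus's %GDM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import nnls
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr, spearmanr

from .synthetic import EnvStack, GenotypeMatrix

log = logging.getLogger(__name__)

GEOGRAPHY = "geography"


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def _wc_pair_components(n1, p1, h1, n2, p2, h2):
    """Weir-Cockerham (1984) variance components a, b, c for two samples.

    n: individuals sampled, p: alt-allele frequency, h: observed
    heterozygote frequency. Vectorized over SNPs.
    """
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
    )
    c = hbar / 2.0
    return a, b, c


def _pop_snp_stats(calls: np.ndarray):
    """Per-SNP genotyped count, alt frequency and heterozygote frequency."""
    obs = calls >= 0
    n = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, calls, 0).sum(axis=0) / np.where(n > 0, 2 * n, np.nan)
        h = np.where(obs, calls == 1, False).sum(axis=0) / np.where(n > 0, n, np.nan)
    return n, p, h


@dataclass
class FstMatrix:
    """Symmetric pairwise F_ST for one locus over its eligible populations.

    ``fst`` holds the Weir-Cockerham estimates (negatives floored at 0);
    ``rescaled`` maps the off-diagonal minimum to 0 and maximum to 1, the
    form the GDM consumes.
    """

    locus: object
    populations: list[str]
    fst: np.ndarray
    rescaled: np.ndarray
    n_per_pop: np.ndarray


def fst_for_snp_set(
    G: GenotypeMatrix, snp_index: np.ndarray, min_n: int = 5, locus: object = None
) -> FstMatrix | None:
    """Multi-SNP pairwise Weir-Cockerham theta (ratio of sums across SNPs).

    Populations whose mean genotyped-individual count across the set's
    SNPs falls below ``min_n`` are excluded; with fewer than two eligible
    populations the locus is skipped (None, with a log entry).
    """
    snp_index = np.asarray(snp_index)
    pops = pd.unique(G.populations)
    stats_by_pop = {}
    eligible = []
    for pop in pops:
        calls = G.calls[G.populations == pop][:, snp_index]
        n, p, h = _pop_snp_stats(calls)
        if n.mean() >= min_n:
            stats_by_pop[pop] = (n, p, h)
            eligible.append(pop)
    if len(eligible) < 2:
        log.info("locus %s skipped: fewer than two populations with n >= %d",
                 locus, min_n)
        return None
    P = len(eligible)
    fst = np.zeros((P, P))
    for i in range(P):
        n1, p1, h1 = stats_by_pop[eligible[i]]
        for j in range(i + 1, P):
            n2, p2, h2 = stats_by_pop[eligible[j]]
            valid = (n1 >= 2) & (n2 >= 2)  # WC components need n > 1
            a, b, c = _wc_pair_components(n1[valid], p1[valid], h1[valid],
                                          n2[valid], p2[valid], h2[valid])
            denom = np.sum(a + b + c)
            theta = np.sum(a) / denom if denom != 0 else 0.0
            fst[i, j] = fst[j, i] = max(theta, 0.0)  # floor negatives at 0
    iu = np.triu_indices(P, k=1)
    vals = fst[iu]
    lo, hi = vals.min(), vals.max()
    rescaled = np.zeros_like(fst)
    if hi > lo:
        rescaled[iu] = (vals - lo) / (hi - lo)
        rescaled += rescaled.T
    n_per_pop = np.array([int(stats_by_pop[p][0].min()) for p in eligible])
    return FstMatrix(locus=locus, populations=list(eligible), fst=fst,
                     rescaled=rescaled, n_per_pop=n_per_pop)


def wc_fst_per_locus(
    G: GenotypeMatrix, loci: list | None = None, min_n: int = 5
) -> dict:
    """Pairwise F_ST matrices per RAD locus (SNPs on one locus combined)."""
    out = {}
    targets = pd.unique(G.locus_ids) if loci is None else loci
    for locus in targets:
        idx = np.flatnonzero(G.locus_ids == locus)
        if idx.size == 0:
            continue
        m = fst_for_snp_set(G, idx, min_n=min_n, locus=locus)
        if m is not None:
            out[locus] = m
    return out


# ---------------------------------------------------------------------------
# monotone I-spline basis
# ---------------------------------------------------------------------------

def ispline_basis(
    x: np.ndarray, n_splines: int = 3, knots: np.ndarray | None = None
) -> np.ndarray:
    """Monotone non-decreasing I-spline basis, each 0 at the gradient
    minimum and 1 at the maximum.

    Basis functions are normalized antiderivatives of degree-1 B-splines on
    ``knots`` (defaults: evenly spaced percentiles of x, so n_splines=3
    gives the 0/50/100th percentiles). Values outside the knot span are
    clamped.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        if np.unique(x).size < n_splines:
            raise ValueError("fewer distinct x values than knots")
        knots = np.quantile(x, np.linspace(0, 1, n_splines))
    knots = np.asarray(knots, dtype=float)
    if np.unique(knots).size != knots.size:
        raise ValueError("fewer distinct x values than knots (tied knots)")
    t = np.r_[knots[0], knots, knots[-1]]
    xc = np.clip(x, knots[0], knots[-1])
    n_basis = len(t) - 2
    B = np.empty((x.size, n_basis))
    for i in range(n_basis):
        coeff = np.zeros(n_basis)
        coeff[i] = 1.0
        F = BSpline(t, coeff, 1, extrapolate=False).antiderivative()
        lo, hi = float(F(knots[0])), float(F(knots[-1]))
        B[:, i] = (np.asarray(F(xc), dtype=float) - lo) / (hi - lo)
    return B


# ---------------------------------------------------------------------------
# GDM fitting
# ---------------------------------------------------------------------------

@dataclass
class GDMModel:
    intercept: float
    coefs: dict                         # predictor -> (n_splines,) >= 0
    knots: dict                         # predictor -> knot vector
    null_deviance: float
    deviance: float
    explained_deviance: float           # delta deviance
    pct_deviance: float                 # %GDM = 100 * delta / null
    predictors: list
    include_geography: bool
    fitted: np.ndarray
    y: np.ndarray
    n_iter: int
    site_env: pd.DataFrame = field(repr=False)
    coords: pd.DataFrame | None = field(default=None, repr=False)
    n_splines: int = 3

    def turnover(self, predictor: str) -> float:
        """Total fitted-function height across the observed gradient: the
        predicted change in (rescaled) F_ST, since each I-spline rises 0->1."""
        if predictor not in self.coefs:
            raise KeyError(f"unknown predictor {predictor!r}")
        return float(np.sum(self.coefs[predictor]))

    def transform(self, predictor: str, x: np.ndarray) -> tuple[np.ndarray, int]:
        """Fitted monotone function of one predictor (clamped to the fitted
        gradient); returns (values, number of clamped inputs)."""
        if predictor not in self.coefs:
            raise KeyError(f"unknown predictor {predictor!r}")
        x = np.asarray(x, dtype=float)
        k = self.knots[predictor]
        n_clamped = int(np.sum((x < k[0]) | (x > k[-1])))
        B = ispline_basis(np.clip(x, k[0], k[-1]), knots=k)
        return B @ self.coefs[predictor], n_clamped


def _gdm_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Binomial-type deviance on the exponential link (0 log 0 = 0)."""
    mu = np.clip(mu, 1e-9, 1 - 1e-9)
    with np.errstate(invalid="ignore", divide="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return float(2.0 * np.sum(t1 + t2))


def _pair_design(site_env, coords, predictors, include_geography, n_splines, knots=None):
    n_sites = len(site_env)
    iu = np.triu_indices(n_sites, k=1)
    blocks, knots_out = [], {}
    for p in predictors:
        vals = site_env[p].to_numpy(dtype=float)
        k = knots[p] if knots else np.quantile(vals, np.linspace(0, 1, n_splines))
        B = ispline_basis(vals, knots=k)
        blocks.append(np.abs(B[iu[0]] - B[iu[1]]))
        knots_out[p] = k
    if include_geography:
        if coords is None:
            raise ValueError("geography requested but no coordinates provided")
        D = cdist(coords.to_numpy(dtype=float), coords.to_numpy(dtype=float))
        dv = D[iu]
        k = knots[GEOGRAPHY] if knots else np.quantile(dv, np.linspace(0, 1, n_splines))
        blocks.append(ispline_basis(dv, knots=k))
        knots_out[GEOGRAPHY] = k
    Z = np.column_stack([np.ones(iu[0].size)] + blocks)
    return Z, iu, knots_out


def fit_gdm(
    dissimilarity: np.ndarray | FstMatrix,
    site_env: pd.DataFrame,
    coords: pd.DataFrame | None = None,
    include_geography: bool = False,
    predictors: list | None = None,
    n_splines: int = 3,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> GDMModel:
    """Fit d_ij = 1 - exp(-eta_ij) with eta = a + sum_p sum_k b_pk
    |I_pk(x_pi) - I_pk(x_pj)|, b >= 0, by iteratively reweighted
    non-negative least squares on the link scale.

    ``dissimilarity`` is a square matrix in [0,1] (or an :class:`FstMatrix`,
    whose rescaled values are used) over the rows of ``site_env``.
    Geography, when included, enters as the I-spline-transformed Euclidean
    distance between ``coords`` rows.
    """
    if isinstance(dissimilarity, FstMatrix):
        site_env = site_env.loc[dissimilarity.populations]
        if coords is not None:
            coords = coords.loc[dissimilarity.populations]
        dissimilarity = dissimilarity.rescaled
    Dm = np.asarray(dissimilarity, dtype=float)
    if Dm.min() < 0 or Dm.max() > 1:
        raise ValueError("dissimilarities must lie in [0,1]")
    if predictors is None:
        predictors = list(site_env.columns)
    Z, iu, knots = _pair_design(site_env, coords, predictors, include_geography, n_splines)
    y = Dm[iu]
    if y.size < 10:
        raise ValueError("need at least 10 population pairs")

    # null (intercept-only) deviance: mean dissimilarity is the optimum
    null_dev = _gdm_deviance(y, np.full_like(y, max(y.mean(), 1e-9)))

    beta = np.zeros(Z.shape[1])
    beta[0] = -np.log(max(1.0 - y.mean(), 1e-9))

    def dev_of(b):
        return _gdm_deviance(y, np.clip(1.0 - np.exp(-(Z @ b)), 1e-9, 1 - 1e-9))

    dev_trace = [dev_of(beta)]
    for it in range(max_iter):
        eta = Z @ beta
        mu = np.clip(1.0 - np.exp(-eta), 1e-9, 1 - 1e-9)
        dmu = 1.0 - mu                              # d mu / d eta = exp(-eta)
        V = mu * (1.0 - mu)
        w = dmu**2 / np.clip(V, 1e-12, None)
        zwork = eta + (y - mu) / np.clip(dmu, 1e-12, None)
        sw = np.sqrt(w)
        beta_new, _ = nnls(Z * sw[:, None], zwork * sw)
        # step-halving keeps the IRLS from 2-cycling on awkward loci
        dev = dev_of(beta_new)
        halvings = 0
        while dev > dev_trace[-1] + 1e-12 and halvings < 30:
            beta_new = 0.5 * (beta_new + beta)
            dev = dev_of(beta_new)
            halvings += 1
        step = np.max(np.abs(beta_new - beta))
        converged = (
            step < tol * (1.0 + np.max(np.abs(beta)))
            or abs(dev_trace[-1] - dev) < tol * (1.0 + dev)
        )
        beta = beta_new
        dev_trace.append(dev)
        if converged:
            break
    else:
        raise RuntimeError(f"GDM did not converge in {max_iter} iterations; "
                           f"deviance trace tail: {dev_trace[-5:]}")

    fitted = 1.0 - np.exp(-(Z @ beta))
    dev = _gdm_deviance(y, fitted)
    delta = max(null_dev - dev, 0.0)
    pct = 100.0 * delta / null_dev if null_dev > 1e-12 else 0.0
    coefs = {}
    pos = 1
    for p in predictors:
        nb = len(knots[p]) if p in knots else n_splines
        coefs[p] = beta[pos : pos + nb]
        pos += nb
    if include_geography:
        coefs[GEOGRAPHY] = beta[pos : pos + len(knots[GEOGRAPHY])]
    return GDMModel(
        intercept=float(beta[0]),
        coefs=coefs,
        knots=knots,
        null_deviance=null_dev,
        deviance=dev,
        explained_deviance=delta,
        pct_deviance=pct,
        predictors=list(predictors),
        include_geography=include_geography,
        fitted=fitted,
        y=y,
        n_iter=len(dev_trace),
        site_env=site_env[predictors].copy(),
        coords=None if coords is None else coords.copy(),
        n_splines=n_splines,
    )


def partial_turnover(model: GDMModel, predictor: str) -> float:
    """Height of the fitted monotone function over the observed gradient
    (the sum of the predictor's I-spline coefficients)."""
    return model.turnover(predictor)


def reference_group_gdm(
    G: GenotypeMatrix,
    site_env: pd.DataFrame,
    coords: pd.DataFrame | None = None,
    n_ref: int = 200,
    min_n: int = 5,
    include_geography: bool = True,
    seed: int | None = None,
    **fit_kw,
) -> GDMModel:
    """GDM for a random reference set of SNPs: the null level of explained
    deviance and turnover used by the candidate classification."""
    if G.n_snps < n_ref:
        raise ValueError("fewer SNPs than n_ref")
    rng = np.random.default_rng(seed)
    idx = rng.choice(G.n_snps, size=n_ref, replace=False)
    m = fst_for_snp_set(G, idx, min_n=min_n, locus="reference")
    if m is None:
        raise ValueError("reference group has fewer than two eligible populations")
    return fit_gdm(m, site_env, coords=coords, include_geography=include_geography, **fit_kw)


# ---------------------------------------------------------------------------
# candidate classification
# ---------------------------------------------------------------------------

def classify_candidates(
    locus_models: dict,
    reference_model: GDMModel,
    threshold: float = 0.40,
) -> pd.DataFrame:
    """Apply the three candidate criteria to per-locus GDMs.

    C1: locus %GDM exceeds the reference group's. C2: the environmental
    predictor with the largest turnover exceeds both the reference's
    turnover for that predictor and the locus's geography turnover (a locus
    whose largest turnover belongs to geography is a false positive). C3:
    refitting with the winning predictor alone retains at least
    ``threshold`` of the full model's %GDM. Candidate iff C1 & C2 & C3.
    """
    env_preds = [p for p in reference_model.predictors if p != GEOGRAPHY]
    rows = []
    for locus, model in locus_models.items():
        turn = {p: model.turnover(p) for p in model.predictors}
        geo = model.turnover(GEOGRAPHY) if GEOGRAPHY in model.coefs else 0.0
        winner = max(env_preds, key=lambda p: turn.get(p, 0.0))
        c1 = model.pct_deviance > reference_model.pct_deviance
        false_positive = geo > turn.get(winner, 0.0)
        ref_turn = reference_model.turnover(winner)
        c2 = (not false_positive) and turn.get(winner, 0.0) > ref_turn and turn.get(winner, 0.0) > geo
        if model.pct_deviance > 0:
            single = fit_gdm(
                _square_from_pairs(model.y, len(model.site_env)),
                model.site_env,
                coords=model.coords,
                include_geography=False,
                predictors=[winner],
                n_splines=model.n_splines,
            )
            share = single.pct_deviance / model.pct_deviance
        else:
            share = 0.0
        c3 = share >= threshold
        if false_positive:
            status = "false_positive"
        elif c1 and c2 and c3:
            status = "candidate"
        else:
            status = "not_candidate"
        row = {
            "locus": locus,
            "n_pops": len(model.site_env),
            "intercept": model.intercept,
            "null_deviance": model.null_deviance,
            "delta_deviance": model.explained_deviance,
            "pct_gdm": model.pct_deviance,
            "ref_pct_gdm": reference_model.pct_deviance,
            "geography_turnover": geo,
            "winner": winner,
            "winner_share": share,
            "C1": c1,
            "C2": c2,
            "C3": c3,
            "status": status,
        }
        for p in env_preds:
            row[f"turnover_{p}"] = turn.get(p, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def _square_from_pairs(y: np.ndarray, n_sites: int) -> np.ndarray:
    M = np.zeros((n_sites, n_sites))
    iu = np.triu_indices(n_sites, k=1)
    M[iu] = y
    return M + M.T


def discover_candidates(
    G: GenotypeMatrix,
    env_variables: list[str] | None = None,
    K: int = 3,
    n_repeats: int = 5,
    q_threshold: float = 0.05,
    n_ref: int = 200,
    min_n: int = 5,
    share_threshold: float = 0.40,
    seed: int | None = None,
) -> pd.DataFrame:
    """The full candidate-discovery chain: GEA screen then GDM classification.

    SNPs must be significant (q < ``q_threshold``) in both the latent-factor
    and the conditioned-RDA detector; their parent loci are then modelled by
    GDM against the reference group and classified by the three criteria.
    Classification is only ever applied to loci surviving the screen, which
    is what keeps the procedure's false-positive rate controlled.
    """
    from . import gea

    if env_variables is None:
        env_variables = list(G.pop_env.columns)
    rng = np.random.default_rng(seed)
    Y, _ = gea.impute_missing(G)
    lq = {}
    for var in env_variables:
        x = G.pop_env[var].loc[G.populations].to_numpy()
        z = gea.lfmm_fit(Y, x, K=K, n_repeats=n_repeats, seed=int(rng.integers(2**31)))
        p, _, _ = gea.combine_z_and_gif(z)
        lq[var] = gea.qvalues(p)
    E = G.pop_env[env_variables].loc[G.populations].reset_index(drop=True)
    rda = gea.partial_rda(Y, E, G.Q)
    _, _, rq = gea.rda_outlier_pvalues(rda.loadings)
    snp_tab, _ = gea.intersect_outliers(lq, rq, G.locus_ids, G.snp_ids, q_threshold)
    if snp_tab.empty:
        return pd.DataFrame(columns=["locus", "status"])
    ref = reference_group_gdm(
        G, G.pop_env[env_variables], G.pop_coords, n_ref=n_ref, min_n=min_n,
        seed=int(rng.integers(2**31)),
    )
    models = {}
    for locus in pd.unique(snp_tab["locus"]):
        idx = np.flatnonzero(G.locus_ids == locus)
        m = fst_for_snp_set(G, idx, min_n=min_n, locus=locus)
        if m is None:
            continue
        try:
            models[locus] = fit_gdm(
                m, G.pop_env[env_variables], coords=G.pop_coords, include_geography=True
            )
        except RuntimeError as exc:
            log.warning("locus %s: GDM failed (%s)", locus, exc)
    if not models:
        return pd.DataFrame(columns=["locus", "status"])
    return classify_candidates(models, ref, threshold=share_threshold)


# ---------------------------------------------------------------------------
# prediction and diagnostics
# ---------------------------------------------------------------------------

def predict_turnover_map(
    model: GDMModel, env: EnvStack, predictor: str
) -> tuple[np.ndarray, int]:
    """Per-cell predicted cumulative change in F_ST from the gradient
    minimum: the fitted I-spline transform of the predictor's raster.

    Cells outside the fitted gradient are clamped; their count is
    returned alongside the map."""
    if predictor not in env.layers:
        raise KeyError(f"predictor {predictor!r} not in env stack")
    vals, n_clamped = model.transform(predictor, env.layers[predictor].ravel())
    return vals.reshape(env.shape), n_clamped


def population_allele_frequencies(G: GenotypeMatrix, snp_index: np.ndarray) -> pd.DataFrame:
    """Observed alternative-allele frequencies per population for a SNP set
    (the overlay plotted on turnover maps)."""
    snp_index = np.atleast_1d(np.asarray(snp_index))
    rows = {}
    for pop in pd.unique(G.populations):
        calls = G.calls[G.populations == pop][:, snp_index]
        obs = calls >= 0
        tot = 2 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(obs, calls, 0).sum(axis=0) / np.where(tot > 0, tot, np.nan)
        rows[pop] = freq
    ids = [G.snp_ids[j] for j in snp_index]
    return pd.DataFrame(rows, index=ids).T


def observed_vs_predicted(model: GDMModel) -> dict:
    """Goodness-of-fit diagnostics: observed vs predicted pairwise
    dissimilarities with correlations and residual quantiles."""
    resid = model.y - model.fitted
    if np.std(model.y) == 0 or np.std(model.fitted) == 0:
        pear = spear = np.nan
    else:
        pear = pearsonr(model.y, model.fitted)[0]
        spear = spearmanr(model.y, model.fitted)[0]
    return {
        "pearson": float(pear) if np.isfinite(pear) else np.nan,
        "spearman": float(spear) if np.isfinite(spear) else np.nan,
        "residual_quantiles": {
            q: float(np.quantile(resid, q)) for q in (0.05, 0.25, 0.5, 0.75, 0.95)
        },
        "observed": model.y,
        "predicted": model.fitted,
    }
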