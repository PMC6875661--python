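"""Landmark-based wing geometric morphometrics.

TPS ingestion, generalized Procrustes alignment (rotation constrained to
det +1 since all wings are from the same side), centroid size, shape PCA,
type II ANOVA / MANOVA group tests, and environment-conditioned partial
redundancy analysis of shape and size with ancestry coefficients as the
conditioning covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.multivariate.manova import MANOVA


# ---------------------------------------------------------------------------
# TPS input / output
# ---------------------------------------------------------------------------

def write_tps(configs: np.ndarray, ids: list[str], path: str) -> None:
    with open(path, "w") as fh:
        for cfg, name in zip(configs, ids):
            fh.write(f"LM={len(cfg)}\n")
            for x, y in cfg:
                fh.write(f"{x:.8f} {y:.8f}\n")
            fh.write(f"ID={name}\n")


def read_tps(path: str, n_landmarks: int = 20) -> tuple[np.ndarray, list[str]]:
    """Parse a TPS file ('LM=' counts, coordinate pairs, 'ID=' records).

    Records whose landmark count differs from ``n_landmarks`` raise an
    error naming the record; malformed coordinate lines are rejected with
    their line number.
    """
    configs, ids = [], []
    current: list[list[float]] | None = None
    expected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                expected = int(line.split("=", 1)[1])
                if expected != n_landmarks:
                    raise ValueError(
                        f"record starting at line {lineno} has LM={expected}, "
                        f"expected {n_landmarks}"
                    )
                current = []
            elif upper.startswith("ID="):
                if current is None or len(current) != expected:
                    raise ValueError(
                        f"record ending at line {lineno} has "
                        f"{0 if current is None else len(current)} landmarks, "
                        f"expected {expected}"
                    )
                configs.append(np.array(current))
                ids.append(line.split("=", 1)[1])
                current = None
            elif upper.startswith(("IMAGE=", "SCALE=")):
                continue
            else:
                if current is None:
                    raise ValueError(f"coordinates outside a record at line {lineno}")
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"malformed coordinate line {lineno}: {line!r}")
                current.append([float(parts[0]), float(parts[1])])
    if current is not None:
        raise ValueError("file ends inside a record (missing ID= line)")
    if not configs:
        raise ValueError("no records found")
    return np.stack(configs), ids


# ---------------------------------------------------------------------------
# centroid size and Procrustes alignment
# ---------------------------------------------------------------------------

def centroid_size(config: np.ndarray) -> float:
    """Square root of the summed squared landmark distances from the
    configuration centroid."""
    cfg = np.asarray(config, dtype=float)
    if cfg.shape[0] < 3:
        raise ValueError("need at least three landmarks")
    centred = cfg - cfg.mean(axis=0)
    cs = float(np.sqrt((centred**2).sum()))
    if cs <= 0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return cs


def _rotate_onto(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Least-squares rotation of X onto Y with det(R) = +1 (no reflection)."""
    U, _, Vt = np.linalg.svd(X.T @ Y)
    d = np.sign(np.linalg.det(U @ Vt))
    S = np.diag([1.0, d])
    return U @ S @ Vt


@dataclass
class ShapeSet:
    """Procrustes-aligned configurations with centroid sizes and factors."""

    aligned: np.ndarray              # (n, L, 2), centred, unit centroid size
    csizes: np.ndarray               # (n,) original centroid sizes
    consensus: np.ndarray            # (L, 2) mean shape
    factors: pd.DataFrame | None = None
    n_iterations: int = 0

    @property
    def log_csizes(self) -> np.ndarray:
        return np.log(self.csizes)

    def flat(self) -> np.ndarray:
        return self.aligned.reshape(len(self.aligned), -1)


def gpa(
    configs: np.ndarray,
    factors: pd.DataFrame | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> ShapeSet:
    """Generalized Procrustes alignment.

    Each configuration is centred and scaled to unit centroid size, then
    iteratively rotated onto the running consensus (itself re-centred and
    re-scaled each round) until the consensus moves by less than ``tol``.
    """
    configs = np.asarray(configs, dtype=float)
    if configs.ndim != 3 or len(configs) < 2:
        raise ValueError("need at least two configurations")
    cs = np.array([centroid_size(c) for c in configs])
    X = (configs - configs.mean(axis=1, keepdims=True)) / cs[:, None, None]

    consensus = X[0].copy()
    n_it = 0
    for n_it in range(1, max_iter + 1):
        for i in range(len(X)):
            X[i] = X[i] @ _rotate_onto(X[i], consensus)
        new = X.mean(axis=0)
        new -= new.mean(axis=0)
        new /= np.sqrt((new**2).sum())
        if np.sqrt(((new - consensus) ** 2).sum()) < tol:
            consensus = new
            break
        consensus = new
    # report the arithmetic mean of the aligned set as the consensus shape
    return ShapeSet(aligned=X, csizes=cs, consensus=X.mean(axis=0),
                    factors=factors, n_iterations=n_it)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Ordinary (partial) Procrustes distance between two configurations
    after centring, unit-size scaling and optimal rotation (det +1)."""
    A = np.asarray(a, float) - np.asarray(a, float).mean(axis=0)
    B = np.asarray(b, float) - np.asarray(b, float).mean(axis=0)
    A /= np.sqrt((A**2).sum())
    B /= np.sqrt((B**2).sum())
    A = A @ _rotate_onto(A, B)
    return float(np.sqrt(((A - B) ** 2).sum()))


# ---------------------------------------------------------------------------
# ordination and group tests
# ---------------------------------------------------------------------------

def shape_pca(shapes: ShapeSet) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the flattened Procrustes coordinates.

    Returns (scores, variance fractions)."""
    Y = shapes.flat()
    if len(Y) < 3:
        raise ValueError("need at least three configurations")
    Yc = Y - Y.mean(axis=0)
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    var = s**2 / np.sum(s**2)
    return Yc @ Vt.T, var


def _reduce_dimensions(Y: np.ndarray, n_groups: int, var_capture: float) -> np.ndarray:
    """Leading PCs capturing ``var_capture`` of variance, capped so the
    within-group covariance stays non-singular."""
    Yc = Y - Y.mean(axis=0)
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    frac = np.cumsum(s**2) / np.sum(s**2)
    k = int(np.searchsorted(frac, var_capture) + 1)
    k = min(k, len(Y) - n_groups - 1, int(np.sum(s > s[0] * 1e-9)))
    if k < 1:
        raise ValueError("too few observations for a multivariate test")
    return Yc @ Vt[:k].T


@dataclass
class MultivariateTest:
    statistic: float        # Pillai's trace
    F: float
    df_num: float
    df_den: float
    p_value: float
    n_dimensions: int


def shape_manova(
    shapes: ShapeSet | np.ndarray,
    factor: np.ndarray,
    var_capture: float = 0.95,
) -> MultivariateTest:
    """Type II MANOVA (Pillai's trace) of Procrustes coordinates on a group
    factor.

    Procrustes coordinates have fewer free dimensions than 2L and often
    more variables than observations, so the test runs on the leading
    principal components capturing ``var_capture`` of the variance; the
    dimension used is reported. For a single factor, type II sums of
    squares coincide with the sequential decomposition.
    """
    Y = shapes.flat() if isinstance(shapes, ShapeSet) else np.asarray(shapes, float)
    factor = np.asarray(factor)
    levels, counts = np.unique(factor, return_counts=True)
    if len(levels) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 observations each")
    Yr = _reduce_dimensions(Y, len(levels), var_capture)
    df = pd.DataFrame(Yr, columns=[f"y{j}" for j in range(Yr.shape[1])])
    df["g"] = factor
    endog = " + ".join(df.columns[:-1])
    mv = MANOVA.from_formula(f"{endog} ~ C(g)", data=df)
    tbl = mv.mv_test().results["C(g)"]["stat"]
    row = tbl.loc["Pillai's trace"]
    return MultivariateTest(
        statistic=float(row["Value"]),
        F=float(row["F Value"]),
        df_num=float(row["Num DF"]),
        df_den=float(row["Den DF"]),
        p_value=float(row["Pr > F"]),
        n_dimensions=Yr.shape[1],
    )


@dataclass
class AnovaResult:
    F: float
    p_value: float
    df: int
    pairwise: pd.DataFrame | None = None


def size_anova(
    log_cs: np.ndarray,
    factor: np.ndarray,
    min_group: int = 5,
    pairwise: bool = True,
) -> AnovaResult:
    """Type II ANOVA of log centroid size on a group factor.

    Pairwise two-sample comparisons are restricted to groups with at least
    ``min_group`` individuals.
    """
    factor = np.asarray(factor)
    levels, counts = np.unique(factor, return_counts=True)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    df = pd.DataFrame({"y": np.asarray(log_cs, float), "g": factor})
    model = ols("y ~ C(g)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    F = float(tab.loc["C(g)", "F"])
    p = float(tab.loc["C(g)", "PR(>F)"])
    dfg = int(tab.loc["C(g)", "df"])
    pw = None
    if pairwise:
        from scipy.stats import ttest_ind

        eligible = [l for l, c in zip(levels, counts) if c >= min_group]
        rows = []
        for i, a in enumerate(eligible):
            for b in eligible[i + 1 :]:
                t, pv = ttest_ind(df.loc[df.g == a, "y"], df.loc[df.g == b, "y"])
                rows.append({"group_a": a, "group_b": b, "t": float(t), "p": float(pv)})
        pw = pd.DataFrame(rows)
    return AnovaResult(F=F, p_value=p, df=dfg, pairwise=pw)


# ---------------------------------------------------------------------------
# environment-conditioned redundancy analysis
# ---------------------------------------------------------------------------

@dataclass
class MorphoRDA:
    constrained_fraction: float
    p_value: float
    per_variable: pd.DataFrame = field(default=None)
    n_permutations: int = 0


def _constrained_fraction(Yr: np.ndarray, Er: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(Er, Yr, rcond=None)
    fitted = Er @ coef
    tot = float((Yr**2).sum())
    return float((fitted**2).sum() / tot) if tot > 0 else 0.0


def morpho_rda(
    response: np.ndarray,
    env: pd.DataFrame,
    condition: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    per_variable: bool = True,
) -> MorphoRDA:
    """Partial RDA of shape (or size) on environmental predictors,
    conditioned on population-averaged ancestry coefficients.

    Response and predictors are residualized on [1, Q minus one column];
    significance comes from permuting the rows of the residualized response
    under the reduced model. One-factor models per variable report the
    variance fraction each predictor constrains on its own.
    """
    Y = np.asarray(response, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if np.isnan(Y).any() or env.isna().any().any():
        raise ValueError("response/env contain missing values; check the "
                         "population join")
    Q = np.asarray(condition, dtype=float)
    C = np.column_stack([np.ones(len(Y)), Q[:, :-1]])
    proj = C @ np.linalg.pinv(C)
    Yr = Y - Y.mean(axis=0) - proj @ (Y - Y.mean(axis=0))
    E = env.to_numpy(dtype=float)
    Er = E - E.mean(axis=0) - proj @ (E - E.mean(axis=0))

    rng = np.random.default_rng(seed)
    perms = [rng.permutation(len(Y)) for _ in range(n_perm)]

    def test(Ecols: np.ndarray) -> tuple[float, float]:
        obs = _constrained_fraction(Yr, Ecols)
        null = np.array([_constrained_fraction(Yr[pi], Ecols) for pi in perms])
        return obs, float((1.0 + np.sum(null >= obs)) / (n_perm + 1.0))

    frac, p = test(Er)
    pv_table = None
    if per_variable:
        rows = []
        for j, name in enumerate(env.columns):
            f1, p1 = test(Er[:, [j]])
            rows.append({"variable": name, "fraction": f1, "p": p1})
        pv_table = pd.DataFrame(rows)
    return MorphoRDA(constrained_fraction=frac, p_value=p,
                     per_variable=pv_table, n_permutations=n_perm)
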