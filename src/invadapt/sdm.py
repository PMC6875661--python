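"""Ensemble distribution modelling and map-agreement niche-change metrics.

The workflow mirrors common ensemble SDM practice: thin occurrences to one
per raster cell, draw repeated pseudo-absence sets from outside a surface
range envelope, calibrate a roster of presence/absence learners on random
70/30 splits scored by TSS and ROC-AUC, combine the members passing a TSS
cutoff into a weighted ensemble, binarize with a TSS-maximizing threshold,
and compare binary maps through stability / expansion / unfilling fractions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler

from .synthetic import EnvStack

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# occurrence thinning and pseudo-absences
# ---------------------------------------------------------------------------

def thin_occurrences(occ: pd.DataFrame, env: EnvStack, seed: int | None = None) -> pd.DataFrame:
    """Keep one occurrence per raster cell, chosen uniformly at random."""
    rng = np.random.default_rng(seed)
    rows = occ["lat"].round().astype(int)
    cols = occ["lon"].round().astype(int)
    cell = rows * env.shape[1] + cols
    keep = (
        pd.Series(np.arange(len(occ)))
        .groupby(cell.to_numpy())
        .apply(lambda idx: idx.iloc[rng.integers(len(idx))])
        .to_numpy()
    )
    return occ.iloc[np.sort(keep)].reset_index(drop=True)


def sre_pseudo_absences(
    env: EnvStack,
    presences: pd.DataFrame,
    n: int = 5000,
    n_sets: int = 5,
    quantile: float = 0.025,
    seed: int | None = None,
) -> list[pd.DataFrame]:
    """Pseudo-absence sets sampled from outside the surface range envelope.

    The envelope is the per-variable [quantile, 1-quantile] interval of the
    presence values; candidate cells fall outside it in at least one
    variable. Each of ``n_sets`` sets holds ``n`` distinct cells.
    """
    if len(presences) < 10:
        raise ValueError("need at least 10 presences to define an envelope")
    names = env.names
    cells = env.table()
    outside = np.zeros(len(cells), dtype=bool)
    for name in names:
        v = presences[name].to_numpy(dtype=float)
        lo, hi = np.quantile(v, [quantile, 1 - quantile])
        outside |= (cells[name].to_numpy() < lo) | (cells[name].to_numpy() > hi)
    pool = np.flatnonzero(outside)
    if pool.size == 0:
        raise ValueError(
            "no cells outside the presence envelope; presences span the "
            "full range of every variable at this quantile"
        )
    if pool.size < n:
        raise ValueError(f"only {pool.size} cells outside envelope, need {n}")
    rng = np.random.default_rng(seed)
    return [
        cells.iloc[rng.choice(pool, size=n, replace=False)].reset_index(drop=True)
        for _ in range(n_sets)
    ]


# ---------------------------------------------------------------------------
# evaluation statistics
# ---------------------------------------------------------------------------

def tss(labels: np.ndarray, scores: np.ndarray, threshold: float) -> float:
    """True skill statistic: sensitivity + specificity - 1 at the threshold."""
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    pred = scores >= threshold
    sens = (pred & labels).sum() / labels.sum()
    spec = (~pred & ~labels).sum() / (~labels).sum()
    return float(sens + spec - 1.0)


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels, scores))


def tss_max_threshold(labels: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """Threshold in (0,1) maximizing TSS, with the TSS it attains."""
    scores = np.asarray(scores, dtype=float)
    cand = np.unique(np.clip(scores, 1e-9, 1 - 1e-9))
    best_t, best = float(cand[0]), -np.inf
    for t in cand:
        v = tss(labels, scores, t)
        if v > best:
            best, best_t = v, float(t)
    return best_t, best


# ---------------------------------------------------------------------------
# learners and calibration
# ---------------------------------------------------------------------------

def default_learners(seed: int | None = None) -> dict:
    """The five model families of the ensemble, behind a shared
    fit/predict_proba contract.

    linear-additive: logistic GLM; smooth-additive: cubic-spline additive
    logistic (GAM-like); boosted-trees: gradient boosting; adaptive-splines:
    L1-pruned piecewise-linear hinge logistic (MARS-like); randomized
    tree-ensemble: random forest.
    """
    rs = None if seed is None else int(seed)
    return {
        "linear-additive": make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000)
        ),
        "smooth-additive": make_pipeline(
            StandardScaler(),
            SplineTransformer(n_knots=5, degree=3),
            LogisticRegression(max_iter=2000),
        ),
        "boosted-trees": GradientBoostingClassifier(
            n_estimators=150, max_depth=3, random_state=rs
        ),
        "adaptive-splines": make_pipeline(
            StandardScaler(),
            SplineTransformer(n_knots=5, degree=1),
            LogisticRegression(solver="liblinear", l1_ratio=1, max_iter=2000),
        ),
        "randomized-tree-ensemble": RandomForestClassifier(
            n_estimators=200, random_state=rs
        ),
    }


@dataclass
class CalibrationResult:
    learner: str
    pa_set: int
    repeat: int
    model: object
    tss: float
    roc_auc: float
    threshold: float
    feature_names: list[str] = field(default_factory=list)


def calibrate_models(
    presences: pd.DataFrame,
    pa_sets: list[pd.DataFrame],
    feature_names: list[str],
    learners: dict | None = None,
    split: float = 0.7,
    n_repeats: int = 3,
    seed: int | None = None,
) -> list[CalibrationResult]:
    """Fit every learner x pseudo-absence set x repeat on a stratified
    random 70% and evaluate TSS / ROC-AUC on the held-out 30%.

    The TSS-maximizing threshold is recorded from the held-out scores.
    Learner failures are logged and skipped; the ensemble proceeds.
    """
    if learners is None:
        learners = default_learners(seed)
    rng = np.random.default_rng(seed)
    Xp = presences[feature_names].to_numpy(dtype=float)
    results: list[CalibrationResult] = []
    for s, pa in enumerate(pa_sets):
        Xa = pa[feature_names].to_numpy(dtype=float)
        X = np.vstack([Xp, Xa])
        y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xa))])
        for rep in range(n_repeats):
            rs = int(rng.integers(2**31))
            Xtr, Xte, ytr, yte = train_test_split(
                X, y, train_size=split, stratify=y, random_state=rs
            )
            for name, proto in learners.items():
                try:
                    model = clone(proto)
                    model.fit(Xtr, ytr)
                    scores = model.predict_proba(Xte)[:, 1]
                    thr, t = tss_max_threshold(yte, scores)
                    results.append(
                        CalibrationResult(
                            learner=name,
                            pa_set=s,
                            repeat=rep,
                            model=model,
                            tss=t,
                            roc_auc=roc_auc(yte, scores),
                            threshold=thr,
                            feature_names=list(feature_names),
                        )
                    )
                except Exception as exc:  # noqa: BLE001 - member failure tolerated
                    log.warning("learner %s failed (pa_set %d, repeat %d): %s",
                                name, s, rep, exc)
    return results


def variable_importance(
    model,
    data: pd.DataFrame,
    variable: str,
    n_perm: int = 10,
    seed: int | None = None,
) -> float:
    """Permutation importance: 1 - mean Pearson correlation between the
    model's predictions and its predictions after permuting the variable."""
    rng = np.random.default_rng(seed)
    X = data.to_numpy(dtype=float)
    j = list(data.columns).index(variable)
    ref = model.predict_proba(X)[:, 1]
    if np.std(ref) == 0:
        warnings.warn("constant predictions; importance defined as 0")
        return 0.0
    rs = []
    for _ in range(n_perm):
        Xp = X.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        pred = model.predict_proba(Xp)[:, 1]
        rs.append(0.0 if np.std(pred) == 0 else pearsonr(ref, pred)[0])
    return float(1.0 - np.mean(rs))


# ---------------------------------------------------------------------------
# ensemble projection and map agreement
# ---------------------------------------------------------------------------

def ensemble_project(
    results: list[CalibrationResult],
    env: EnvStack,
    calibration_data: tuple[np.ndarray, np.ndarray] | None = None,
    tss_min: float = 0.4,
) -> tuple[np.ndarray, np.ndarray, float]:
    """TSS-weighted mean of member probability maps over members passing
    ``tss_min``; the binary map uses the ensemble's TSS-maximizing threshold
    on the calibration data.

    Returns (suitability grid, binary grid, threshold).
    """
    members = [r for r in results if r.tss >= tss_min]
    if not members:
        raise ValueError(f"no calibration result reaches TSS >= {tss_min}")
    feats = members[0].feature_names
    cells = env.table()[feats].to_numpy(dtype=float)
    w = np.array([r.tss for r in members], dtype=float)
    w = w / w.sum()
    suit = np.zeros(len(cells))
    for r, wi in zip(members, w):
        suit += wi * r.model.predict_proba(cells)[:, 1]
    grid = suit.reshape(env.shape)

    if calibration_data is not None:
        Xc, yc = calibration_data
        sc = np.zeros(len(Xc))
        for r, wi in zip(members, w):
            sc += wi * r.model.predict_proba(np.asarray(Xc, float))[:, 1]
        thr, _ = tss_max_threshold(yc, sc)
    else:
        thr = float(np.mean([r.threshold for r in members]))
    return grid, (grid >= thr).astype(int), thr


@dataclass
class NicheChange:
    """Map-agreement fractions between an invaded-range model (A) and a
    source-range model projected onto the same region (B).

    stability = |A∩B|/|A|, expansion = |A\\B|/|A|, unfilling = |B\\A|/|B|;
    stability + expansion = 1 by construction.
    """

    stability: float
    expansion: float
    unfilling: float
    n_invaded: int
    n_source: int
    n_overlap: int


def niche_change_metrics(
    binary_invaded: np.ndarray,
    binary_source: np.ndarray,
    mask: np.ndarray | None = None,
) -> NicheChange:
    A = np.asarray(binary_invaded).astype(bool)
    B = np.asarray(binary_source).astype(bool)
    if A.shape != B.shape:
        raise ValueError("maps are on different grids")
    if mask is not None:
        m = np.asarray(mask).astype(bool)
        A, B = A & m, B & m
    nA, nB = int(A.sum()), int(B.sum())
    if nA == 0 or nB == 0:
        raise ValueError("empty predicted range in one of the maps")
    nAB = int((A & B).sum())
    return NicheChange(
        stability=nAB / nA,
        expansion=(nA - nAB) / nA,
        unfilling=(nB - nAB) / nB,
        n_invaded=nA,
        n_source=nB,
        n_overlap=nAB,
    )


def occurrence_prediction_rate(
    binary_map: np.ndarray, occurrences: pd.DataFrame
) -> tuple[float, int]:
    """Fraction of occurrences falling in predicted-presence cells.

    Occurrences outside the raster are excluded; their count is returned."""
    grid = np.asarray(binary_map).astype(bool)
    rows = occurrences["lat"].round().astype(int).to_numpy()
    cols = occurrences["lon"].round().astype(int).to_numpy()
    inside = (rows >= 0) & (rows < grid.shape[0]) & (cols >= 0) & (cols < grid.shape[1])
    n_excluded = int((~inside).sum())
    if inside.sum() == 0:
        raise ValueError("no occurrence falls on the raster")
    frac = float(grid[rows[inside], cols[inside]].mean())
    return frac, n_excluded
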