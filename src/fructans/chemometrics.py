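"""Chemometrics for HPTLC band tables.

Pareto scaling, PCA, a two-class OPLS-DA (one predictive component after
removal of orthogonal variation, Trygg-Wold style NIPALS), cross-validated
Q2, a label-permutation test, CV-ANOVA on the cross-validated residuals,
S-plot marker selection, and the retention-factor -> degree-of-
polymerization calibration.

The OPLS-DA, permutation and CV-ANOVA machinery is written here; PCA
delegates to scikit-learn behind the :func:`pca` surface.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SKPCA


# ---------------------------------------------------------------------------
# scaling and PCA
# ---------------------------------------------------------------------------

def pareto_scale(table: pd.DataFrame) -> pd.DataFrame:
    """Mean-center each column and divide by the square root of its sample
    standard deviation. Zero-variance columns are dropped with a warning;
    an all-constant table is an error."""
    if len(table) < 2:
        raise ValueError("Pareto scaling needs at least two samples")
    sd = table.std(axis=0, ddof=1)
    dead = sd[sd == 0].index.tolist()
    if len(dead) == len(table.columns):
        raise ValueError("all columns have zero variance")
    if dead:
        warnings.warn(f"dropping zero-variance columns: {dead}", stacklevel=2)
    keep = [c for c in table.columns if c not in dead]
    x = table[keep]
    return (x - x.mean(axis=0)) / np.sqrt(sd[keep])


@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    r2x: np.ndarray
    r2x_cum: np.ndarray


def pca(scaled: pd.DataFrame, n_components: int = 2) -> PcaResult:
    """Principal components of an already-scaled table."""
    x = np.asarray(scaled, dtype=float)
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    model = _SKPCA(n_components=n_components)
    scores = model.fit_transform(x)
    comp = [f"PC{i + 1}" for i in range(n_components)]
    r2x = model.explained_variance_ratio_
    return PcaResult(
        scores=pd.DataFrame(scores, index=scaled.index, columns=comp),
        loadings=pd.DataFrame(model.components_.T, index=scaled.columns, columns=comp),
        r2x=r2x,
        r2x_cum=np.cumsum(r2x),
    )


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

def stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment.

    Samples of each class are shuffled with the seed, interleaved by class
    and dealt round-robin into ``k`` folds, so every fold is as balanced as
    the class sizes allow even when ``k`` exceeds the per-class count
    (k-fold conventions of this software family use k=7 with n=6 per
    class).
    """
    rng = np.random.default_rng(seed)
    order: list[int] = []
    per_class = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        per_class.append(list(idx))
    while any(per_class):
        for lst in per_class:
            if lst:
                order.append(lst.pop())
    folds = np.empty(len(y), dtype=int)
    for pos, sample in enumerate(order):
        folds[sample] = pos % k
    return folds


def _nipals_opls(x: np.ndarray, y: np.ndarray, n_orth: int):
    """Single-y OPLS: strip ``n_orth`` y-orthogonal components, then fit one
    predictive component. Returns the filtered predictive part and the
    orthogonal weights/loadings needed to filter new observations."""
    xr = x.copy()
    w_orth_list, p_orth_list, t_orth_list = [], [], []
    yy = float(y @ y)
    for _ in range(n_orth):
        w = xr.T @ y / yy
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = xr @ w
        p = xr.T @ t / float(t @ t)
        w_o = p - float(w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-10:  # no orthogonal variation left
            break
        w_o /= n_o
        t_o = xr @ w_o
        p_o = xr.T @ t_o / float(t_o @ t_o)
        xr = xr - np.outer(t_o, p_o)
        w_orth_list.append(w_o)
        p_orth_list.append(p_o)
        t_orth_list.append(t_o)
    w = xr.T @ y / yy
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise ValueError("response carries no covariance with the data")
    w /= nw
    t = xr @ w
    p = xr.T @ t / float(t @ t)
    b = float(t @ y) / float(t @ t)
    return {
        "w": w,
        "p": p,
        "b": b,
        "t": t,
        "w_orth": w_orth_list,
        "p_orth": p_orth_list,
        "t_orth": t_orth_list,
    }


def _opls_predict(fitted: dict, x: np.ndarray) -> np.ndarray:
    xr = np.array(x, dtype=float, copy=True)
    for w_o, p_o in zip(fitted["w_orth"], fitted["p_orth"]):
        t_o = xr @ w_o
        xr = xr - np.outer(t_o, p_o)
    return (xr @ fitted["w"]) * fitted["b"]


def _cross_validated_press(
    x: np.ndarray, y: np.ndarray, n_orth: int, folds: np.ndarray
) -> tuple[float, np.ndarray]:
    yhat = np.empty_like(y)
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        y_tr = y[train]
        mu = y_tr.mean()
        fit = _nipals_opls(x[train], y_tr - mu, n_orth)
        yhat[test] = _opls_predict(fit, x[test]) + mu
    press = float(np.sum((y - yhat) ** 2))
    return press, yhat


class OplsDa:
    """Two-class OPLS-DA on an already Pareto-scaled table.

    Parameters
    ----------
    scaled
        samples x variables DataFrame (use :func:`pareto_scale` first).
    labels
        one class label per sample; exactly two classes, each with at
        least three samples.
    n_orth
        number of orthogonal components to strip before the single
        predictive component (default 1).
    positive_class
        label mapped to +1 on the predictive axis (default: the second of
        the sorted class labels).
    """

    def __init__(
        self,
        scaled: pd.DataFrame,
        labels: Sequence,
        n_orth: int = 1,
        positive_class=None,
    ):
        self.x = scaled
        labels = pd.Series(list(labels), index=scaled.index)
        classes = sorted(labels.unique())
        if len(classes) != 2:
            raise ValueError(f"OPLS-DA needs exactly two classes, got {classes}")
        counts = labels.value_counts()
        if counts.min() < 3:
            raise ValueError("each class needs at least three samples")
        if positive_class is None:
            positive_class = classes[1]
        if positive_class not in classes:
            raise ValueError(f"positive_class {positive_class!r} not among {classes}")
        self.labels = labels
        self.positive_class = positive_class
        self.n_orth = int(n_orth)
        self.y = np.where(labels == positive_class, 1.0, -1.0)

    def fit(self, cv_folds: int = 7, seed: int = 0) -> "OplsDaResults":
        x = np.asarray(self.x, dtype=float)
        y = self.y - self.y.mean()
        fitted = _nipals_opls(x, y, self.n_orth)
        # orient the predictive score toward the positive class
        if float(fitted["t"] @ y) < 0:  # pragma: no cover - orientation guard
            for key in ("w", "p", "t"):
                fitted[key] = -fitted[key]
            fitted["b"] = -fitted["b"]
        t = fitted["t"]
        resid = y - t * fitted["b"]
        ssy = float(y @ y)
        r2y = 1.0 - float(resid @ resid) / ssy

        # folds derive from the class labels, not the +/-1 coding, so the
        # cross-validation split is invariant to the positive_class choice
        folds = stratified_folds(np.asarray(self.labels), cv_folds, seed)
        press, yhat = _cross_validated_press(x, self.y, self.n_orth, folds)
        q2 = 1.0 - press / ssy

        # S-plot: covariance / correlation of each scaled variable with the
        # predictive score
        xc = x - x.mean(axis=0)
        tc = t - t.mean()
        n = x.shape[0]
        cov = xc.T @ tc / (n - 1)
        sx = xc.std(axis=0, ddof=1)
        st = tc.std(ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(sx > 0, cov / (sx * st), 0.0)
        s_plot = pd.DataFrame(
            {"covariance": cov, "correlation": corr}, index=self.x.columns
        )
        return OplsDaResults(
            model=self,
            fitted=fitted,
            q2=q2,
            r2y=r2y,
            press=press,
            ssy=ssy,
            folds=folds,
            cv_predictions=yhat,
            s_plot=s_plot,
            cv_folds=cv_folds,
            seed=seed,
        )


@dataclass
class OplsDaResults:
    """Fitted OPLS-DA: scores, validation statistics and S-plot coordinates."""

    model: OplsDa
    fitted: dict
    q2: float
    r2y: float
    press: float
    ssy: float
    folds: np.ndarray
    cv_predictions: np.ndarray
    s_plot: pd.DataFrame
    cv_folds: int
    seed: int
    perm_p: float | None = field(default=None)
    cvanova_p: float | None = field(default=None)

    @property
    def scores(self) -> pd.DataFrame:
        cols = {"t_pred": self.fitted["t"]}
        for i, t_o in enumerate(self.fitted["t_orth"], start=1):
            cols[f"t_orth{i}"] = t_o
        return pd.DataFrame(cols, index=self.model.x.index)

    @property
    def loadings(self) -> pd.DataFrame:
        cols = {"p_pred": self.fitted["p"]}
        for i, p_o in enumerate(self.fitted["p_orth"], start=1):
            cols[f"p_orth{i}"] = p_o
        return pd.DataFrame(cols, index=self.model.x.columns)

    def permutation_test(self, n_perm: int = 100, seed: int = 0) -> float:
        """Label-permutation null for Q2.

        p = (1 + #{Q2_perm >= Q2_obs}) / (n_perm + 1); bit-reproducible for
        a fixed seed. Stores and returns the p value.
        """
        if n_perm < 1:
            raise ValueError("n_perm must be at least 1")
        rng = np.random.default_rng(seed)
        x = np.asarray(self.model.x, dtype=float)
        hits = 0
        self.perm_q2 = []
        for i in range(n_perm):
            y_perm = rng.permutation(self.model.y)
            folds = stratified_folds(y_perm, self.cv_folds, self.seed + i + 1)
            try:
                press, _ = _cross_validated_press(
                    x, y_perm, self.model.n_orth, folds
                )
                q2p = 1.0 - press / self.ssy
            except ValueError:
                q2p = -np.inf
            self.perm_q2.append(q2p)
            if q2p >= self.q2:
                hits += 1
        self.perm_p = (1 + hits) / (n_perm + 1)
        return self.perm_p

    def cv_anova(self) -> float:
        """CV-ANOVA: F-test of the cross-validated predictive residuals
        against the total response variation.

        F = ((SSY - PRESS)/d1) / (PRESS/d2) with d1 = number of model
        components (predictive + orthogonal) and d2 = N - 1 - d1, the
        conventional degrees of freedom for cross-validated residual
        ANOVA of a latent-variable model. Degenerate residuals give p = 1
        with a warning.
        """
        n = len(self.model.y)
        d1 = 1 + len(self.fitted["w_orth"])
        d2 = n - 1 - d1
        if d2 <= 0 or self.press <= 0 or not math.isfinite(self.press):
            warnings.warn("degenerate cross-validated residuals; p = 1", stacklevel=2)
            self.cvanova_p = 1.0
            return 1.0
        f_stat = ((self.ssy - self.press) / d1) / (self.press / d2)
        if f_stat <= 0:
            self.cvanova_p = 1.0
            return 1.0
        self.cvanova_p = float(stats.f.sf(f_stat, d1, d2))
        return self.cvanova_p

    def summary(self) -> str:
        lines = [
            "OPLS-DA (1 predictive + "
            f"{len(self.fitted['w_orth'])} orthogonal component(s))",
            f"classes: {sorted(self.model.labels.unique())}, "
            f"positive = {self.model.positive_class!r}",
            f"R2Y = {self.r2y:.3f}   Q2 = {self.q2:.3f} "
            f"({self.cv_folds}-fold stratified CV, seed {self.seed})",
        ]
        if self.perm_p is not None:
            lines.append(f"permutation p = {self.perm_p:.4f}")
        if self.cvanova_p is not None:
            lines.append(f"CV-ANOVA p = {self.cvanova_p:.4g}")
        return "\n".join(lines)

    def report(self, q2_min: float = 0.40, p_max: float = 0.05) -> dict:
        return {
            "q2": round(self.q2, 4),
            "r2y": round(self.r2y, 4),
            "perm_p": self.perm_p,
            "cvanova_p": self.cvanova_p,
            "valid": bool(
                self.q2 >= q2_min
                and (self.perm_p is None or self.perm_p <= p_max)
                and (self.cvanova_p is None or self.cvanova_p <= p_max)
            ),
        }


def select_discriminant_bands(
    results: OplsDaResults, cov_thresh: float = 0.0, corr_thresh: float = 0.8
) -> pd.DataFrame:
    """S-plot marker selection.

    Variables with |covariance| >= cov_thresh and |correlation| >=
    corr_thresh, signed by class direction: direction ``positive`` marks
    enrichment in the positive class.
    """
    sp = results.s_plot
    mask = (sp["covariance"].abs() >= cov_thresh) & (
        sp["correlation"].abs() >= corr_thresh
    )
    out = sp[mask].copy()
    out["direction"] = np.where(out["covariance"] >= 0, "positive", "negative")
    return out


# ---------------------------------------------------------------------------
# Rf -> DP calibration
# ---------------------------------------------------------------------------

#: (retention factor, degree of polymerization) anchors: fructose, sucrose,
#: neo-kestose and the highest band countable on the plate
RF_DP_ANCHORS = ((0.57, 1), (0.51, 2), (0.40, 3), (0.09, 11))

APPLICATION_POINT = ">11 (application point)"


def rf_to_dp(rf: float):
    """Degree of polymerization from a band's retention factor.

    Monotone-decreasing piecewise-linear interpolation through the plate
    anchors, rounded to the nearest integer; retention above the fructose
    anchor clamps to DP 1. Bands migrating below the last countable anchor
    (rf < 0.09) return ``None`` — they belong to the unresolved
    application-point smear (:data:`APPLICATION_POINT`).
    """
    if not 0 < rf < 1:
        raise ValueError(f"rf must lie strictly in (0, 1), got {rf}")
    rfs = np.array([a[0] for a in RF_DP_ANCHORS])[::-1]  # ascending rf
    dps = np.array([a[1] for a in RF_DP_ANCHORS], dtype=float)[::-1]
    if rf < rfs[0]:
        return None
    return int(math.floor(float(np.interp(rf, rfs, dps)) + 0.5))


def describe_rf(rf: float) -> str:
    dp = rf_to_dp(rf)
    return APPLICATION_POINT if dp is None else f"DP-{dp}"
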