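"""OPLS-DA screening of exogenous markers in a two-group cohort.

The model is orthogonal projections to latent structures discriminant
analysis (OPLS-DA) with one predictive component: class-membership
y (+1 treated, -1 blank) is regressed on intensities after log10
transformation, mean centering and unit-variance (UV) scaling; variation
orthogonal to y is split off into separate components before the
predictive component is extracted.  The decomposition is deterministic
(no random initialisation).

Marker screening follows the common S-plot rule: a feature passes when its
variable importance in projection (VIP) is >= 1.5 and its two-sided Welch
t-test p-value (on log10 intensities) is < 0.05.  VIP is normalised so the
mean of VIP^2 over features is exactly 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_VIP_MIN = 1.5
DEFAULT_P_MAX = 0.05

GROUPS = ("treated", "blank")


def _encode_y(labels: np.ndarray) -> np.ndarray:
    y = np.where(np.asarray(labels) == "treated", 1.0, -1.0)
    return y


def _validate(X: pd.DataFrame, labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("label length must equal sample count")
    unknown = set(labels) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group labels {sorted(unknown)}; use {GROUPS}")
    for grp in GROUPS:
        if (labels == grp).sum() < 2:
            raise ValueError(f"group {grp!r} needs at least 2 samples")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    return np.asarray(X, dtype=float), labels


@dataclass
class OplsModel:
    """A fitted OPLS-DA model (one predictive component)."""

    feature_names: list[str]
    x_mean: np.ndarray
    x_std: np.ndarray
    kept: np.ndarray  # boolean mask of non-constant features
    w: np.ndarray  # predictive weights, unit norm (kept features)
    t: np.ndarray  # predictive scores
    p_load: np.ndarray  # predictive loadings
    t_orth: np.ndarray  # (n_samples, n_orth) orthogonal scores
    p_orth: np.ndarray
    w_orth: np.ndarray
    y: np.ndarray
    b: float  # inner regression coefficient y ~ t
    r2y: float
    log_transform: bool
    pseudocount: float
    X_scaled: np.ndarray = field(repr=False, default=None)


def _preprocess(
    X: np.ndarray, log_transform: bool, pseudocount: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if log_transform:
        X = np.log10(X + pseudocount)
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    # relative floor: identical values can leave ~1e-16 of rounding noise
    kept = std > 1e-8 * np.maximum(1.0, np.abs(mean))
    if not kept.all():
        log.warning("dropping %d constant feature(s) before scaling", (~kept).sum())
    Xs = (X[:, kept] - mean[kept]) / std[kept]
    return Xs, mean, std, kept


def opls_da_fit(
    X: pd.DataFrame,
    labels,
    n_orthogonal: int = 1,
    log_transform: bool = True,
    pseudocount: float = 1.0,
) -> OplsModel:
    """Fit OPLS-DA on a samples x features intensity matrix.

    ``labels`` holds "treated"/"blank" per sample.  Intensities are
    log10(x + pseudocount)-transformed then UV-scaled; constant features
    are dropped with a warning.
    """
    Xm, labels = _validate(X, labels)
    names = list(X.columns)
    Xs, mean, std, kept = _preprocess(Xm, log_transform, pseudocount)
    y = _encode_y(labels)
    yc = y - y.mean()

    w = Xs.T @ yc
    w /= np.linalg.norm(w)

    Xd = Xs.copy()
    t_orth_list, p_orth_list, w_orth_list = [], [], []
    for _ in range(n_orthogonal):
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break  # no orthogonal variation left
        w_o /= norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        t_orth_list.append(t_o)
        p_orth_list.append(p_o)
        w_orth_list.append(w_o)

    t = Xd @ w
    p_load = Xd.T @ t / (t @ t)
    b = (t @ yc) / (t @ t)
    resid = yc - b * t
    r2y = 1.0 - (resid @ resid) / (yc @ yc)

    return OplsModel(
        feature_names=names,
        x_mean=mean,
        x_std=std,
        kept=kept,
        w=w,
        t=t,
        p_load=p_load,
        t_orth=np.column_stack(t_orth_list) if t_orth_list else np.empty((Xs.shape[0], 0)),
        p_orth=np.column_stack(p_orth_list) if p_orth_list else np.empty((Xs.shape[1], 0)),
        w_orth=np.column_stack(w_orth_list) if w_orth_list else np.empty((Xs.shape[1], 0)),
        y=y,
        b=b,
        r2y=r2y,
        log_transform=log_transform,
        pseudocount=pseudocount,
        X_scaled=Xs,
    )


def vip_scores(model: OplsModel) -> pd.Series:
    """VIP over the predictive component; sum of VIP^2 equals feature count.

    With a single predictive component and unit-norm weights this reduces
    to ``sqrt(K) * |w_j|`` over the K retained features; dropped (constant)
    features get VIP 0.
    """
    k = model.w.shape[0]
    vip_kept = np.sqrt(k) * np.abs(model.w)
    vip = np.zeros(len(model.feature_names))
    vip[model.kept] = vip_kept
    return pd.Series(vip, index=model.feature_names, name="VIP")


def feature_pvalues(
    X: pd.DataFrame,
    labels,
    log_transform: bool = True,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Two-sided Welch t-test per feature on log10 intensities."""
    Xm, labels = _validate(X, labels)
    if log_transform:
        Xm = np.log10(Xm + pseudocount)
    a = Xm[np.asarray(labels) == "treated"]
    b = Xm[np.asarray(labels) == "blank"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(a, b, axis=0, equal_var=False).pvalue
    zero_var = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    if zero_var.any():
        log.warning("%d feature(s) with zero variance in both groups: p set to 1",
                    zero_var.sum())
    p = np.where(np.isnan(p) | zero_var, 1.0, p)
    return pd.Series(p, index=X.columns, name="p")


@dataclass(frozen=True)
class ScreenResult:
    feature_id: str
    vip: float
    p: float
    direction: str  # "up" (higher in treated) | "down"
    passes: bool


def screen_markers(
    X: pd.DataFrame,
    labels,
    vip_min: float = DEFAULT_VIP_MIN,
    p_max: float = DEFAULT_P_MAX,
    n_orthogonal: int = 1,
    log_transform: bool = True,
    pseudocount: float = 1.0,
    model: OplsModel | None = None,
) -> list[ScreenResult]:
    """VIP >= vip_min AND p < p_max screen; sorted by VIP descending."""
    if model is None:
        model = opls_da_fit(
            X, labels, n_orthogonal=n_orthogonal,
            log_transform=log_transform, pseudocount=pseudocount,
        )
    vip = vip_scores(model)
    p = feature_pvalues(X, labels, log_transform=log_transform, pseudocount=pseudocount)
    labels = np.asarray(labels)
    Xm = np.asarray(X, dtype=float)
    if log_transform:
        Xm = np.log10(Xm + pseudocount)
    delta = Xm[labels == "treated"].mean(axis=0) - Xm[labels == "blank"].mean(axis=0)
    results = [
        ScreenResult(
            feature_id=name,
            vip=float(vip[name]),
            p=float(p[name]),
            direction="up" if d >= 0 else "down",
            passes=bool(vip[name] >= vip_min and p[name] < p_max),
        )
        for name, d in zip(X.columns, delta)
    ]
    results.sort(key=lambda r: (-r.vip, r.feature_id))
    return results


def splot_coordinates(model: OplsModel) -> pd.DataFrame:
    """S-plot coordinates: x = predictive loading, y = p(corr).

    p(corr) is the Pearson correlation between the predictive score vector
    and each UV-scaled feature; it is bounded by [-1, 1] and its sign gives
    the direction of the group shift.
    """
    t = model.t
    Xs = model.X_scaled
    tc = t - t.mean()
    xc = Xs - Xs.mean(axis=0)
    denom = np.linalg.norm(tc) * np.linalg.norm(xc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pcorr_kept = np.where(denom > 0, xc.T @ tc / denom, 0.0)
    p1 = np.zeros(len(model.feature_names))
    pcorr = np.zeros(len(model.feature_names))
    p1[model.kept] = model.p_load
    pcorr[model.kept] = pcorr_kept
    return pd.DataFrame(
        {"p1": p1, "pcorr": pcorr}, index=model.feature_names
    )


def screen_table(results: list[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.feature_id for r in results],
            "VIP": [r.vip for r in results],
            "p": [r.p for r in results],
            "direction": [r.direction for r in results],
            "passes": [r.passes for r in results],
        }
    )
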