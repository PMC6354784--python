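"""Linear mixed models for the mediation pipeline.

Both mediation models (mediator-on-stimulus and outcome-on-stimulus+mediator)
are Gaussian linear mixed models with per-subject random intercepts and,
by default, random intensity slopes:

    y_ij = x_ij' beta + z_ij' u_i + e_ij,   u_i ~ N(0, G),  e_ij ~ N(0, s2)

The engine profiles out the fixed effects and the residual variance and
optimizes the (RE)ML criterion over the Cholesky factor of G/s2, working
entirely on per-subject sufficient statistics (cross-products). Fits are
therefore O(n) once and microseconds per likelihood evaluation, which is
what makes the permutation experiments (tens of thousands of refits)
feasible. Fixed-effect estimates and their model-based covariance follow
the standard generalized-least-squares identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize

from .trial_data import TrialTable

__all__ = [
    "LmmSpec", "LmmFit", "FitError", "fit_lmm", "moderator_coding",
    "coding_values", "build_design", "SubjectStats", "reml_fit",
]

FIXED_TERMS = ("intercept", "X", "W", "X:W", "M", "M:W")

_CODINGS = {
    "reference": {"touch": 0.0, "pain": 1.0},
    "effect": {"touch": -0.5, "pain": 0.5},
}


class FitError(RuntimeError):
    """Mixed-model fit failed even after dropping the random slope."""


def moderator_coding(modality: str, scheme: str = "reference") -> float:
    """Numeric code of the modality moderator (touch is the reference)."""
    try:
        return _CODINGS[scheme][modality]
    except KeyError:
        raise ValueError(f"unknown modality/scheme: {modality!r}/{scheme!r}") from None


def coding_values(scheme: str = "reference") -> dict[str, float]:
    """Modality -> numeric code map for the given scheme."""
    return dict(_CODINGS[scheme])


@dataclass(frozen=True)
class LmmSpec:
    """Model specification.

    fixed_terms are drawn from {intercept, X, W, X:W, M, M:W}; X is the
    centered intensity, W the coded modality moderator, M the mediator
    z-score column named by ``mediator``.
    """

    outcome: str
    fixed_terms: tuple[str, ...]
    mediator: str | None = None
    random_slope: bool = True
    reml: bool = True

    def __post_init__(self) -> None:
        if "intercept" not in self.fixed_terms:
            raise ValueError("intercept must be included")
        unknown = set(self.fixed_terms) - set(FIXED_TERMS)
        if unknown:
            raise ValueError(f"unknown fixed term(s): {sorted(unknown)}")
        uses_m = any(t.startswith("M") for t in self.fixed_terms)
        if uses_m and self.mediator is None:
            raise ValueError("mediator column required when M terms are present")


@dataclass
class LmmFit:
    """Minimal fit contract the mediation engine consumes."""

    term_names: tuple[str, ...]
    beta: np.ndarray
    vcov_beta: np.ndarray
    sigma2_resid: float
    random_effect_variances: dict
    loglik: float
    converged: bool
    n_obs: int
    n_subjects: int
    reml: bool = True
    theta: np.ndarray | None = None  # optimizer solution, reusable as warm start

    def __post_init__(self) -> None:
        v = np.asarray(self.vcov_beta)
        if v.shape != (len(self.beta), len(self.beta)):
            raise ValueError("vcov_beta dimensions do not match beta")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("vcov_beta is not symmetric")
        if np.any(np.diag(v) < -1e-12):
            raise ValueError("vcov_beta has negative diagonal")

    def coef(self, term: str) -> float:
        return float(self.beta[self.term_names.index(term)])

    def to_dict(self) -> dict:
        return {
            "term_names": list(self.term_names),
            "beta": np.asarray(self.beta).tolist(),
            "vcov_beta": np.asarray(self.vcov_beta).tolist(),
            "sigma2_resid": self.sigma2_resid,
            "random_effect_variances": self.random_effect_variances,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "reml": self.reml,
        }


# ---------------------------------------------------------------------------
# design construction

def build_design(
    df: pd.DataFrame, spec: LmmSpec, coding: str = "reference"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Build (X, Z, y, subject_index, subject_ids) arrays from a table.

    Requires the preprocessing columns (``centered_intensity`` and the
    relevant z-score columns) to be present.
    """
    if "centered_intensity" not in df.columns:
        raise ValueError("table lacks centered_intensity; run center_intensity first")
    n = len(df)
    x = df["centered_intensity"].to_numpy(dtype=float)
    w = df["modality"].map(coding_values(coding)).to_numpy(dtype=float)
    m = df[spec.mediator].to_numpy(dtype=float) if spec.mediator else None
    cols = {
        "intercept": np.ones(n),
        "X": x,
        "W": w,
        "X:W": x * w,
    }
    if m is not None:
        cols["M"] = m
        cols["M:W"] = m * w
    X = np.column_stack([cols[t] for t in spec.fixed_terms])
    Z = np.column_stack([np.ones(n), x]) if spec.random_slope else np.ones((n, 1))
    y = df[spec.outcome].to_numpy(dtype=float)
    codes, uniques = pd.factorize(df["subject_id"], sort=True)
    return X, Z, y, codes, list(uniques)


@dataclass
class SubjectStats:
    """Per-subject cross-products; the engine's sufficient statistics.

    Arrays are stacked over subjects so any subset of subjects can be fit
    by fancy-indexing — this is what the permutation test exploits.
    """

    XtX: np.ndarray  # (S, p, p)
    Xty: np.ndarray  # (S, p)
    yty: np.ndarray  # (S,)
    ZtZ: np.ndarray  # (S, q, q)
    ZtX: np.ndarray  # (S, q, p)
    Zty: np.ndarray  # (S, q)
    n: np.ndarray    # (S,)
    subject_ids: list = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.XtX.shape[2]

    @property
    def q(self) -> int:
        return self.ZtZ.shape[2]

    def subset(self, idx: np.ndarray) -> "SubjectStats":
        ids = [self.subject_ids[i] for i in idx] if self.subject_ids else []
        return SubjectStats(self.XtX[idx], self.Xty[idx], self.yty[idx],
                            self.ZtZ[idx], self.ZtX[idx], self.Zty[idx],
                            self.n[idx], ids)

    def drop_slope(self) -> "SubjectStats":
        return SubjectStats(self.XtX, self.Xty, self.yty,
                            self.ZtZ[:, :1, :1], self.ZtX[:, :1, :], self.Zty[:, :1],
                            self.n, self.subject_ids)


def subject_suffstats(
    X: np.ndarray, Z: np.ndarray, y: np.ndarray, codes: np.ndarray,
    subject_ids: Sequence[str] | None = None,
) -> SubjectStats:
    S = int(codes.max()) + 1
    p, q = X.shape[1], Z.shape[1]
    XtX = np.zeros((S, p, p)); Xty = np.zeros((S, p)); yty = np.zeros(S)
    ZtZ = np.zeros((S, q, q)); ZtX = np.zeros((S, q, p)); Zty = np.zeros((S, q))
    n = np.zeros(S)
    order = np.argsort(codes, kind="stable")
    bounds = np.searchsorted(codes[order], np.arange(S + 1))
    for s in range(S):
        sl = order[bounds[s]:bounds[s + 1]]
        Xs, Zs, ys = X[sl], Z[sl], y[sl]
        XtX[s] = Xs.T @ Xs
        Xty[s] = Xs.T @ ys
        yty[s] = ys @ ys
        ZtZ[s] = Zs.T @ Zs
        ZtX[s] = Zs.T @ Xs
        Zty[s] = Zs.T @ ys
        n[s] = len(sl)
    return SubjectStats(XtX, Xty, yty, ZtZ, ZtX, Zty, n,
                        list(subject_ids) if subject_ids is not None else [])


# ---------------------------------------------------------------------------
# profiled (RE)ML

def _theta_to_L(theta: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    L[np.tril_indices(q)] = theta
    return L


def _stack_inv_logdet(A: np.ndarray):
    """Inverse and summed log-determinant of a stack of small SPD matrices."""
    q = A.shape[-1]
    if q == 1:
        d = A[:, 0, 0]
        if np.any(d <= 0):
            return None, None
        return (1.0 / d)[:, None, None], float(np.log(d).sum())
    if q == 2:
        det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
        if np.any(det <= 0) or np.any(A[:, 0, 0] <= 0):
            return None, None
        inv = np.empty_like(A)
        inv[:, 0, 0] = A[:, 1, 1]
        inv[:, 1, 1] = A[:, 0, 0]
        inv[:, 0, 1] = -A[:, 0, 1]
        inv[:, 1, 0] = -A[:, 1, 0]
        inv /= det[:, None, None]
        return inv, float(np.log(det).sum())
    sign, logdet = np.linalg.slogdet(A)
    if np.any(sign <= 0):
        return None, None
    return np.linalg.inv(A), float(logdet.sum())


@njit(cache=True)
def _woodbury_accumulate(L, ZtZ, ZtX, Zty):
    """Per-subject Woodbury corrections for q in {1, 2} random effects.

    Returns the summed correction terms (subtracted from the raw
    cross-product sums to get the V^{-1}-weighted ones), the summed
    log|I + L'Z'Z L|, and a positivity flag.
    """
    S, q, p = ZtX.shape
    C_xx = np.zeros((p, p))
    C_xy = np.zeros(p)
    c_yy = 0.0
    logdet = 0.0
    Lt = np.ascontiguousarray(L.T)
    V = np.empty((q, p))
    for s in range(S):
        B = Lt @ np.ascontiguousarray(ZtZ[s]) @ L
        U = Lt @ np.ascontiguousarray(ZtX[s])          # (q, p)
        uv = Lt @ np.ascontiguousarray(Zty[s])         # (q,)
        if q == 1:
            a00 = 1.0 + B[0, 0]
            if a00 <= 0.0:
                return C_xx, C_xy, c_yy, logdet, False
            logdet += np.log(a00)
            au0 = uv[0] / a00
            c_yy += uv[0] * au0
            for j in range(p):
                V[0, j] = U[0, j] / a00
            for i in range(p):
                C_xy[i] += U[0, i] * au0
                for j in range(p):
                    C_xx[i, j] += U[0, i] * V[0, j]
        else:
            a00 = 1.0 + B[0, 0]
            a01 = B[0, 1]
            a10 = B[1, 0]
            a11 = 1.0 + B[1, 1]
            det = a00 * a11 - a01 * a10
            if det <= 0.0 or a00 <= 0.0:
                return C_xx, C_xy, c_yy, logdet, False
            logdet += np.log(det)
            i00 = a11 / det
            i01 = -a01 / det
            i11 = a00 / det
            au0 = i00 * uv[0] + i01 * uv[1]
            au1 = i01 * uv[0] + i11 * uv[1]
            c_yy += uv[0] * au0 + uv[1] * au1
            for j in range(p):
                V[0, j] = i00 * U[0, j] + i01 * U[1, j]
                V[1, j] = i01 * U[0, j] + i11 * U[1, j]
            for i in range(p):
                C_xy[i] += U[0, i] * au0 + U[1, i] * au1
                for j in range(p):
                    C_xx[i, j] += U[0, i] * V[0, j] + U[1, i] * V[1, j]
    return C_xx, C_xy, c_yy, logdet, True


def _profile(theta: np.ndarray, st: SubjectStats, reml: bool, sums=None):
    """Profiled -2 log-likelihood (up to constants) and GLS quantities."""
    q = st.q
    L = _theta_to_L(theta, q)
    Lt = L.T
    if sums is None:
        sums = (st.XtX.sum(0), st.Xty.sum(0), float(st.yty.sum()), float(st.n.sum()))
    XtX_sum, Xty_sum, yty_sum, n = sums
    if q <= 2:
        C_xx, C_xy, c_yy, logdetA_sum, ok = _woodbury_accumulate(
            L, st.ZtZ, st.ZtX, st.Zty)
        if not ok:
            return np.inf, None
        XtViX = XtX_sum - C_xx
        XtViy = Xty_sum - C_xy
        ytViy = yty_sum - c_yy
    else:
        # generic stacked path: A_s = I + L' Z'Z L, Woodbury corrections
        A = (Lt @ st.ZtZ) @ L
        A[:, np.arange(q), np.arange(q)] += 1.0
        Ainv, logdetA_sum = _stack_inv_logdet(A)
        if Ainv is None:
            return np.inf, None
        U = Lt @ st.ZtX                       # (S,q,p)
        u = Lt @ st.Zty[:, :, None]           # (S,q,1)
        AU = Ainv @ U
        Au = Ainv @ u
        Ut = U.transpose(0, 2, 1)
        XtViX = XtX_sum - (Ut @ AU).sum(0)
        XtViy = Xty_sum - (Ut @ Au).sum(0)[:, 0]
        ytViy = yty_sum - float((u * Au).sum())
    p = st.p
    try:
        beta = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError:
        return np.inf, None
    rss = ytViy - beta @ XtViy
    rss = max(rss, 1e-300)
    df = n - p if reml else n
    crit = logdetA_sum + df * np.log(rss)
    if reml:
        s2, ld2 = np.linalg.slogdet(XtViX)
        if s2 <= 0:
            return np.inf, None
        crit += ld2
    if not np.isfinite(crit):
        return np.inf, None
    return crit, (beta, XtViX, rss, df, logdetA_sum, L)


def reml_fit(st: SubjectStats, reml: bool = True, term_names: Sequence[str] | None = None,
             x0: np.ndarray | None = None, fast: bool = False,
             _allow_fallback: bool = True) -> LmmFit:
    """Fit the mixed model from per-subject sufficient statistics.

    ``x0`` warm-starts the variance-parameter search and ``fast`` loosens
    the optimizer tolerances; both are used heavily by the permutation
    engine, where thousands of consecutive fits are nearly identical and
    sub-percent precision in the variance components is ample.
    """
    q = st.q
    n_par = q * (q + 1) // 2
    if x0 is None or len(x0) != n_par:
        x0 = np.zeros(n_par)
        x0[np.cumsum(np.arange(1, q + 1)) - 1] = 0.3  # diagonal entries

    sums = (st.XtX.sum(0), st.Xty.sum(0), float(st.yty.sum()), float(st.n.sum()))

    def obj(theta):
        return _profile(theta, st, reml, sums)[0]

    opts = ({"xatol": 1e-2, "fatol": 1e-4, "maxiter": 200} if fast
            else {"xatol": 1e-3, "fatol": 1e-6, "maxiter": 400})
    res = minimize(obj, x0, method="Nelder-Mead", options=opts)
    crit, parts = _profile(res.x, st, reml, sums)
    converged = bool(res.success) and parts is not None
    if not converged:
        if q > 1 and _allow_fallback:
            fit = reml_fit(st.drop_slope(), reml, term_names, fast=fast,
                           _allow_fallback=False)
            fit.converged = False  # random slope was dropped
            return fit
        if parts is None:
            raise FitError("mixed-model optimization failed")

    beta, XtViX, rss, df, logdetA, L = parts
    sigma2 = rss / df
    vcov = sigma2 * np.linalg.inv(XtViX)
    vcov = 0.5 * (vcov + vcov.T)
    G = sigma2 * (L @ L.T)
    re_var = {"intercept": float(G[0, 0])}
    if q > 1:
        re_var["x_slope"] = float(G[1, 1])
        re_var["cov_intercept_slope"] = float(G[0, 1])
    n = st.n.sum()
    p = st.p
    if reml:
        _, ldX = np.linalg.slogdet(XtViX)
        ll = -0.5 * (logdetA + df * np.log(2 * np.pi * sigma2) + rss / sigma2
                     + ldX - p * np.log(sigma2))
    else:
        ll = -0.5 * (logdetA + n * np.log(2 * np.pi * sigma2) + rss / sigma2)
    names = tuple(term_names) if term_names is not None else tuple(f"b{i}" for i in range(p))
    return LmmFit(
        term_names=names, beta=beta, vcov_beta=vcov, sigma2_resid=float(sigma2),
        random_effect_variances=re_var, loglik=float(ll), converged=converged,
        n_obs=int(n), n_subjects=len(st.n), reml=reml, theta=np.asarray(res.x),
    )


def fit_lmm(table: TrialTable | pd.DataFrame, spec: LmmSpec, coding: str = "reference") -> LmmFit:
    """Fit a mediator or outcome mixed model on a preprocessed table.

    On non-convergence with a random intensity slope, refits with a
    random intercept only (``converged`` is then reported False); if that
    also fails, raises :class:`FitError`.
    """
    df = table.df if isinstance(table, TrialTable) else table
    if df["subject_id"].nunique() < 2:
        raise ValueError("need >= 2 subjects")
    X, Z, y, codes, ids = build_design(df, spec, coding)
    st = subject_suffstats(X, Z, y, codes, ids)
    return reml_fit(st, reml=spec.reml, term_names=spec.fixed_terms)
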