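"""General Gaussian path-model (SEM) engine.

Models are described as parameter tables over observed and latent variables
(directed paths, variances/covariances, means/intercepts), compiled into the
reticular-action (RAM) matrices

    Sigma = F (I - A)^{-1} S (I - A)^{-T} F^T,     mu = F (I - A)^{-1} M,

and estimated either from complete-case sample moments (covariance ML) or
by casewise full-information maximum likelihood (FIML) over each case's
observed subvector, which is valid under missing-at-random data.  Equality
constraints are enforced exactly by parameter sharing; multi-group models
sum one objective over disjoint groups with optional cross-group sharing
through labels.

Fit is summarized by the likelihood-ratio chi-square against the saturated
model, the relative chi-square ratio, the incremental and comparative fit
indices (IFI, CFI) against the independence baseline, and the root mean
squared error of approximation (RMSEA) with a noncentral-chi-square
confidence interval.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

__all__ = [
    "PathModelSpec",
    "FitResult",
    "ModelComparison",
    "implied_moments",
    "ml_discrepancy",
    "fiml_loglik",
    "fit_model",
    "fit_multigroup",
    "model_df",
    "fit_indices",
    "rmsea_ci",
    "chi_square_difference",
    "mvn_mle",
]

Kind = Literal["path", "cov", "mean"]

_PENALTY = 1e14


@dataclass(frozen=True)
class Entry:
    """One parameter-table row: a directed path ``a -> b``, an (co)variance
    ``a ~~ b`` (variance when a == b), or a mean/intercept of ``a``.

    ``free`` parameters are estimated; fixed ones take ``value``.  A
    ``label`` ties parameters to a single shared estimate (equality
    constraint), including across groups in multi-group models.  For free
    parameters ``value`` serves as an optional starting hint.
    """

    kind: Kind
    a: str
    b: str | None = None
    free: bool = True
    value: float | None = None
    label: str | None = None

    def pid(self) -> str:
        if self.kind == "path":
            base = f"{self.a}->{self.b}"
        elif self.kind == "cov":
            x, y = sorted((self.a, self.b))
            base = f"{x}~~{y}"
        else:
            base = f"mean:{self.a}"
        return base


class PathModelSpec:
    """A path model over named observed and latent variables."""

    def __init__(
        self,
        observed: Sequence[str],
        latent: Sequence[str] = (),
        group: str | None = None,
    ):
        self.observed = list(observed)
        self.latent = list(latent)
        self.group = group
        self.entries: list[Entry] = []
        dup = set(self.observed) & set(self.latent)
        if dup:
            raise ValueError(f"variables both observed and latent: {sorted(dup)}")

    # -- builder helpers ---------------------------------------------------
    def _check(self, *names: str) -> None:
        known = set(self.observed) | set(self.latent)
        for nm in names:
            if nm not in known:
                raise ValueError(f"unknown variable {nm!r}")

    def path(self, src: str, dst: str, *, free: bool = True, value: float | None = None, label: str | None = None) -> "PathModelSpec":
        self._check(src, dst)
        self.entries.append(Entry("path", src, dst, free, value, label))
        return self

    def cov(self, a: str, b: str | None = None, *, free: bool = True, value: float | None = None, label: str | None = None) -> "PathModelSpec":
        b = a if b is None else b
        self._check(a, b)
        self.entries.append(Entry("cov", a, b, free, value, label))
        return self

    def var(self, a: str, **kw) -> "PathModelSpec":
        return self.cov(a, a, **kw)

    def mean(self, a: str, *, free: bool = True, value: float | None = None, label: str | None = None) -> "PathModelSpec":
        self._check(a)
        self.entries.append(Entry("mean", a, None, free, value, label))
        return self

    # -- introspection -----------------------------------------------------
    @property
    def variables(self) -> list[str]:
        return self.observed + self.latent

    def free_param_ids(self) -> list[str]:
        """Distinct free parameter ids (labels merge within the spec)."""
        seen: list[str] = []
        for e in self.entries:
            if not e.free:
                continue
            pid = e.label if e.label is not None else e.pid()
            if pid not in seen:
                seen.append(pid)
        return seen

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "latent": self.latent,
            "group": self.group,
            "entries": [
                {
                    "kind": e.kind,
                    "a": e.a,
                    "b": e.b,
                    "free": e.free,
                    "value": e.value,
                    "label": e.label,
                }
                for e in self.entries
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PathModelSpec":
        spec = cls(d["observed"], d.get("latent", ()), d.get("group"))
        for e in d["entries"]:
            spec.entries.append(Entry(e["kind"], e["a"], e.get("b"), e.get("free", True), e.get("value"), e.get("label")))
        return spec

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PathModelSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------


class _Compiled:
    """Matrix layout for one group's spec: slot lists per parameter id and
    fixed assignments, over variables ordered observed-first."""

    def __init__(self, spec: PathModelSpec, auto_prefix: str = ""):
        self.spec = spec
        self.names = spec.variables
        self.k = len(self.names)
        self.p = len(spec.observed)
        self.idx = {nm: i for i, nm in enumerate(self.names)}
        # slots[pid] = list of (mat, i, j); mat in {"A", "S", "M"}
        self.slots: dict[str, list[tuple[str, int, int]]] = {}
        self.fixed: list[tuple[str, int, int, float]] = []
        self.start_hint: dict[str, float] = {}
        seen_slots: set[tuple[str, int, int]] = set()
        for e in spec.entries:
            if e.kind == "path":
                slot = ("A", self.idx[e.b], self.idx[e.a])  # A[dst, src]
            elif e.kind == "cov":
                i, j = self.idx[e.a], self.idx[e.b]
                slot = ("S", max(i, j), min(i, j))
            else:
                slot = ("M", self.idx[e.a], 0)
            if slot in seen_slots:
                raise ValueError(f"duplicate parameter slot for {e}")
            seen_slots.add(slot)
            if e.free:
                pid = e.label if e.label is not None else auto_prefix + e.pid()
                self.slots.setdefault(pid, []).append(slot)
                if e.value is not None:
                    self.start_hint[pid] = e.value
            else:
                self.fixed.append((*slot, 0.0 if e.value is None else float(e.value)))

    def matrices(self, values: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        A = np.zeros((self.k, self.k))
        S = np.zeros((self.k, self.k))
        M = np.zeros(self.k)
        def put(mat, i, j, v):
            if mat == "A":
                A[i, j] = v
            elif mat == "S":
                S[i, j] = v
                S[j, i] = v
            else:
                M[i] = v
        for mat, i, j, v in self.fixed:
            put(mat, i, j, v)
        for pid, slots in self.slots.items():
            v = values[pid]
            for mat, i, j in slots:
                put(mat, i, j, v)
        return A, S, M

    def implied(self, values: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray, dict]:
        A, S, M = self.matrices(values)
        I = np.eye(self.k)
        try:
            B = np.linalg.solve(I - A, I)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("singular (I - A): model contains an inconsistent cycle") from exc
        G = B[: self.p, :]
        Sigma = G @ S @ G.T
        mu = G @ M
        aux = {"A": A, "S": S, "M": M, "B": B, "G": G}
        return Sigma, mu, aux


# ---------------------------------------------------------------------------
# public moment / likelihood primitives
# ---------------------------------------------------------------------------


def implied_moments(
    spec: PathModelSpec, values: Mapping[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied covariance matrix and mean vector over the observed
    variables, given a full assignment of the free parameters (by id or
    label)."""
    comp = _Compiled(spec)
    missing = [pid for pid in comp.slots if pid not in values]
    if missing:
        raise ValueError(f"no value for free parameter(s): {missing}")
    Sigma, mu, _ = comp.implied(values)
    return Sigma, mu


def ml_discrepancy(
    S: np.ndarray,
    xbar: np.ndarray,
    Sigma: np.ndarray,
    mu: np.ndarray,
) -> float:
    """Normal-theory ML discrepancy with mean structure:

    ``ln|Sigma| - ln|S| + tr(S Sigma^-1) - p + (xbar-mu)' Sigma^-1 (xbar-mu)``

    Nonnegative; zero iff the implied moments equal the sample moments.
    """
    S = np.asarray(S, float)
    Sigma = np.asarray(Sigma, float)
    p = S.shape[0]
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise np.linalg.LinAlgError("sample covariance not positive definite")
    c, low = cho_factor(Sigma)
    logdet_Sig = 2.0 * np.log(np.diag(c)).sum()
    Sinv_S = cho_solve((c, low), S)
    d = np.atleast_1d(np.asarray(xbar, float) - np.asarray(mu, float))
    quad = float(d @ cho_solve((c, low), d))
    return float(logdet_Sig - logdet_S + np.trace(Sinv_S) - p + quad)


class _Patterns:
    """Casewise data grouped by missingness pattern with per-pattern
    sufficient statistics (count, mean, scatter about the pattern mean)."""

    def __init__(self, X: np.ndarray):
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise ValueError("data must be 2-D (cases x variables)")
        obs_mask = ~np.isnan(X)
        if (~obs_mask.any(axis=1)).any():
            raise ValueError("each case must observe at least one variable")
        self.n, self.p = X.shape
        self.groups: list[tuple[np.ndarray, int, np.ndarray, np.ndarray]] = []
        uniq, inv = np.unique(obs_mask, axis=0, return_inverse=True)
        for g in range(uniq.shape[0]):
            o = np.flatnonzero(uniq[g])
            rows = X[inv == g][:, o]
            n_g = rows.shape[0]
            m = rows.mean(axis=0)
            Z = rows - m
            scatter = Z.T @ Z / n_g
            self.groups.append((o, n_g, m, scatter))


def fiml_loglik(
    spec: PathModelSpec,
    values: Mapping[str, float],
    data: pd.DataFrame | np.ndarray,
) -> float:
    """Casewise Gaussian log-likelihood of possibly-incomplete data under
    the implied moments, marginalized to each case's observed pattern."""
    comp = _Compiled(spec)
    X = _as_matrix(data, spec.observed)
    Sigma, mu, _ = comp.implied(values)
    return _fiml_ll(_Patterns(X), Sigma, mu)


def _fiml_ll(pat: _Patterns, Sigma: np.ndarray, mu: np.ndarray) -> float:
    ll = 0.0
    for o, n_g, m, scatter in pat.groups:
        Sig_o = Sigma[np.ix_(o, o)]
        c, low = cho_factor(Sig_o)
        logdet = 2.0 * np.log(np.diag(c)).sum()
        d = m - mu[o]
        quad = float(d @ cho_solve((c, low), d))
        tr = float(np.trace(cho_solve((c, low), scatter)))
        ll -= 0.5 * n_g * (len(o) * np.log(2 * np.pi) + logdet + tr + quad)
    return ll


def mvn_mle(X: np.ndarray, tol: float = 1e-9, max_iter: int = 2000) -> tuple[np.ndarray, np.ndarray, float]:
    """Saturated multivariate-normal ML estimate (mean, covariance with
    divisor N, log-likelihood) for data with missing entries, via EM.

    Complete data short-circuits to the closed form.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    if not np.isnan(X).any():
        mu = X.mean(axis=0)
        Z = X - mu
        Sigma = Z.T @ Z / n
        ll = _fiml_ll(_Patterns(X), Sigma, mu)
        return mu, Sigma, ll

    pat = _Patterns(X)
    # initial values: available-case means/variances, zero covariances
    mu = np.nanmean(X, axis=0)
    var = np.nanvar(X, axis=0)
    Sigma = np.diag(np.maximum(var, 1e-6))
    ll_old = -np.inf
    for _ in range(max_iter):
        # E-step: accumulate expected sufficient statistics
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        for o, n_g, m, scatter in pat.groups:
            miss = np.setdiff1d(np.arange(p), o)
            Soo = Sigma[np.ix_(o, o)]
            c, low = cho_factor(Soo)
            # conditional expectations per pattern (linear in observed mean)
            if miss.size:
                Smo = Sigma[np.ix_(miss, o)]
                W = Smo @ cho_solve((c, low), np.eye(len(o)))  # regression coefs
                cond_cov = Sigma[np.ix_(miss, miss)] - W @ Smo.T
            # first moments
            Ex = np.zeros(p)
            Ex[o] = m
            if miss.size:
                Ex[miss] = mu[miss] + W @ (m - mu[o])
            s1 += n_g * Ex
            # second moments: E[x x'] = Cov + Ex Ex', built blockwise
            Exx = np.zeros((p, p))
            cov_full = np.zeros((p, p))
            cov_full[np.ix_(o, o)] = scatter
            if miss.size:
                cov_om = scatter @ W.T
                cov_full[np.ix_(o, miss)] = cov_om
                cov_full[np.ix_(miss, o)] = cov_om.T
                cov_full[np.ix_(miss, miss)] = cond_cov + W @ scatter @ W.T
            Exx = cov_full + np.outer(Ex, Ex)
            s2 += n_g * Exx
        mu = s1 / n
        Sigma = s2 / n - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T)
        ll = _fiml_ll(pat, Sigma, mu)
        if ll - ll_old < tol:
            break
        ll_old = ll
    return mu, Sigma, ll


# ---------------------------------------------------------------------------
# fit machinery
# ---------------------------------------------------------------------------


def _as_matrix(data: pd.DataFrame | np.ndarray, observed: Sequence[str]) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        missing = [c for c in observed if c not in data.columns]
        if missing:
            raise ValueError(f"data lacks observed column(s): {missing}")
        return data[list(observed)].to_numpy(dtype=float)
    X = np.asarray(data, dtype=float)
    if X.shape[1] != len(observed):
        raise ValueError("data width does not match the observed variable list")
    return X


class _GroupData:
    def __init__(self, comp: _Compiled, X: np.ndarray, estimator: str, ddof: int):
        self.comp = comp
        self.estimator = estimator
        if estimator == "ml":
            X = X[~np.isnan(X).any(axis=1)]
            if X.shape[0] < comp.p + 1:
                raise ValueError("too few complete cases for covariance ML")
            self.n = X.shape[0]
            self.xbar = X.mean(axis=0)
            Z = X - self.xbar
            self.S = Z.T @ Z / (self.n - ddof)
            sign, self.logdet_S = np.linalg.slogdet(self.S)
            if sign <= 0:
                raise np.linalg.LinAlgError("sample covariance not positive definite")
            self.weight = self.n - ddof
        else:
            self.pat = _Patterns(X)
            self.n = self.pat.n
            self.X = X

    def sample_var(self) -> np.ndarray:
        if self.estimator == "ml":
            return np.diag(self.S).copy()
        return np.nanvar(self.X, axis=0)

    def sample_mean(self) -> np.ndarray:
        if self.estimator == "ml":
            return self.xbar.copy()
        return np.nanmean(self.X, axis=0)


class _Objective:
    """Joint objective over groups with analytic gradient.

    covariance ML:  f = sum_g (N_g - ddof) * F_ML,g   (f at optimum = chi2)
    FIML:           f = -2 * loglik                    (so chi2 arithmetic
                                                        stays linear in f)
    """

    def __init__(self, groups: list[_GroupData], theta_ids: list[str]):
        self.groups = groups
        self.theta_ids = theta_ids
        self.pos = {pid: i for i, pid in enumerate(theta_ids)}
        # per group: slot arrays for fast gradient accumulation
        self._slot_tables = []
        for g in groups:
            rows = []
            for pid, slots in g.comp.slots.items():
                j = self.pos[pid]
                for mat, a, b in slots:
                    rows.append((mat, a, b, j))
            self._slot_tables.append(rows)

    def values_dict(self, theta: np.ndarray) -> dict[str, float]:
        return {pid: float(v) for pid, v in zip(self.theta_ids, theta)}

    def __call__(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        vals = self.values_dict(theta)
        f_total = 0.0
        grad = np.zeros(len(theta))
        for g, rows in zip(self.groups, self._slot_tables):
            comp = g.comp
            try:
                Sigma, mu, aux = comp.implied(vals)
                c, low = cho_factor(Sigma)
            except (np.linalg.LinAlgError, ValueError):
                return _PENALTY, np.zeros(len(theta))
            Sig_inv = cho_solve((c, low), np.eye(comp.p))
            if g.estimator == "ml":
                logdet_Sig = 2.0 * np.log(np.diag(c)).sum()
                d = g.xbar - mu
                Sid = Sig_inv @ d
                F = (
                    logdet_Sig
                    - g.logdet_S
                    + float(np.sum(Sig_inv * g.S))
                    - comp.p
                    + float(d @ Sid)
                )
                f_total += g.weight * F
                Omega = g.weight * (Sig_inv - Sig_inv @ (g.S + np.outer(d, d)) @ Sig_inv)
                omega = g.weight * (-2.0 * Sid)
            else:
                ll = 0.0
                Omega = np.zeros((comp.p, comp.p))
                omega = np.zeros(comp.p)
                for o, n_g, m, scatter in g.pat.groups:
                    Sig_o = Sigma[np.ix_(o, o)]
                    try:
                        co, lo_ = cho_factor(Sig_o)
                    except np.linalg.LinAlgError:
                        return _PENALTY, np.zeros(len(theta))
                    inv_o = cho_solve((co, lo_), np.eye(len(o)))
                    d = m - mu[o]
                    Sid = inv_o @ d
                    logdet = 2.0 * np.log(np.diag(co)).sum()
                    ll -= 0.5 * n_g * (
                        len(o) * np.log(2 * np.pi)
                        + logdet
                        + float(np.sum(inv_o * scatter))
                        + float(d @ Sid)
                    )
                    # d(-2 ll)/dSigma restricted to the pattern block
                    Omega[np.ix_(o, o)] += n_g * (
                        inv_o - inv_o @ (scatter + np.outer(d, d)) @ inv_o
                    )
                    omega[o] += n_g * (-2.0 * Sid)
                f_total += -2.0 * ll
            # chain rule through the RAM structure
            G, B, S, M = aux["G"], aux["B"], aux["S"], aux["M"]
            H = B @ S @ G.T  # k x p
            C1 = G.T @ Omega  # k x p
            BM = B @ M
            D_A = 2.0 * (C1 @ H.T) + np.outer(G.T @ omega, BM)
            D_S = C1 @ G
            D_M = G.T @ omega
            for mat, a_i, b_j, jpos in rows:
                if mat == "A":
                    grad[jpos] += D_A[a_i, b_j]
                elif mat == "S":
                    grad[jpos] += D_S[a_i, b_j] * (1.0 if a_i == b_j else 2.0)
                else:
                    grad[jpos] += D_M[a_i]
        return f_total, grad


def _start_values(groups: list[_GroupData], theta_ids: list[str]) -> np.ndarray:
    theta0 = np.zeros(len(theta_ids))
    hints: dict[str, float] = {}
    for g in groups:
        hints.update(g.comp.start_hint)
    for i, pid in enumerate(theta_ids):
        if pid in hints:
            theta0[i] = hints[pid]
            continue
        # use the first group that owns this parameter for scaling
        owner = next(g for g in groups if pid in g.comp.slots)
        mat, a, b = owner.comp.slots[pid][0]
        var = owner.sample_var()
        mean = owner.sample_mean()
        p = owner.comp.p
        if mat == "S":
            if a == b:
                theta0[i] = 0.5 * var[a] if a < p else 0.5 * float(np.mean(var))
            else:
                theta0[i] = 0.0
        elif mat == "M":
            theta0[i] = mean[a] if a < p else 0.5 * float(np.mean(mean))
        else:  # path
            theta0[i] = 0.1
    return theta0


@dataclass
class ModelComparison:
    """Likelihood-ratio comparison of two nested fits."""

    dchisq: float
    ddf: int
    p: float
    nested_name: str = ""
    fuller_name: str = ""

    def __str__(self) -> str:
        return f"chi2 change = {self.dchisq:.2f}, df = {self.ddf}, p = {self.p:.3g}"


@dataclass
class FitResult:
    """Estimates and global fit of one (possibly multi-group) path model."""

    param_table: pd.DataFrame
    chisq: float
    df: int
    p: float
    ratio: float
    cfi: float
    ifi: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    baseline_chisq: float
    baseline_df: int
    n: int
    loglik: float | None
    estimator: str
    converged: bool
    identified: bool
    n_iter: int
    n_restarts: int
    theta: np.ndarray = field(repr=False, default=None)
    theta_ids: list[str] = field(repr=False, default_factory=list)
    specs: list[PathModelSpec] = field(repr=False, default_factory=list)

    def estimate(self, pid: str) -> float:
        row = self.param_table.loc[self.param_table["id"] == pid]
        if row.empty:
            raise KeyError(pid)
        return float(row["estimate"].iloc[0])

    def se(self, pid: str) -> float:
        row = self.param_table.loc[self.param_table["id"] == pid]
        if row.empty:
            raise KeyError(pid)
        return float(row["se"].iloc[0])

    def pvalue(self, pid: str) -> float:
        row = self.param_table.loc[self.param_table["id"] == pid]
        if row.empty:
            raise KeyError(pid)
        return float(row["p"].iloc[0])

    def to_dict(self) -> dict:
        return {
            "chisq": self.chisq,
            "df": self.df,
            "p": self.p,
            "ratio": self.ratio,
            "cfi": self.cfi,
            "ifi": self.ifi,
            "rmsea": self.rmsea,
            "rmsea_ci": list(self.rmsea_ci),
            "baseline_chisq": self.baseline_chisq,
            "baseline_df": self.baseline_df,
            "n": self.n,
            "loglik": self.loglik,
            "estimator": self.estimator,
            "converged": self.converged,
            "identified": self.identified,
            "params": self.param_table.to_dict(orient="records"),
        }


class Indices(NamedTuple):
    ratio: float
    cfi: float
    ifi: float
    rmsea: float


def fit_indices(
    chisq: float, df: int, baseline_chisq: float, baseline_df: int, n: int
) -> Indices:
    """Relative chi-square ratio, CFI, IFI and RMSEA point estimate.

    CFI = 1 - max(chi2 - df, 0) / max(chi2_b - df_b, chi2 - df, 0);
    IFI = (chi2_b - chi2) / (chi2_b - df);
    RMSEA = sqrt(max(chi2 - df, 0) / (df * (n - 1))).
    """
    if df <= 0:
        raise ValueError("df must be positive")
    ratio = chisq / df
    num = max(chisq - df, 0.0)
    den = max(baseline_chisq - baseline_df, chisq - df, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    ifi = (baseline_chisq - chisq) / (baseline_chisq - df)
    rmsea = float(np.sqrt(max(chisq - df, 0.0) / (df * (n - 1))))
    return Indices(ratio, cfi, ifi, rmsea)


def rmsea_ci(chisq: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """RMSEA confidence interval from the noncentral chi-square: the bounds
    are sqrt(lambda / ((n-1) df)) for the noncentrality values at which the
    observed chi-square sits at the upper/lower tail probabilities
    (1+level)/2 and (1-level)/2; the lower bound is floored at zero."""
    if df <= 0 or n <= 1:
        raise ValueError("need df > 0 and n > 1")
    hi_q, lo_q = (1 + level) / 2, (1 - level) / 2

    def solve(target: float) -> float | None:
        # find lambda with ncx2.cdf(chisq, df, lambda) == target
        if stats.chi2.cdf(chisq, df) <= target:
            return None  # even lambda = 0 puts chisq below the target tail
        lo, hi = 0.0, max(4.0 * chisq, 10.0)
        while stats.ncx2.cdf(chisq, df, hi) > target:
            hi *= 2
            if hi > 1e8:
                return None
        return optimize.brentq(lambda lam: stats.ncx2.cdf(chisq, df, lam) - target, lo, hi, xtol=1e-10)

    lam_lo = solve(hi_q)
    lam_hi = solve(lo_q)
    scale = (n - 1) * df
    lower = 0.0 if lam_lo is None else float(np.sqrt(lam_lo / scale))
    upper = 0.0 if lam_hi is None else float(np.sqrt(lam_hi / scale))
    return lower, upper


def model_df(specs: PathModelSpec | Sequence[PathModelSpec]) -> int:
    """Degrees of freedom: p(p+3)/2 sample moments per group (covariances
    plus means) minus the number of distinct free parameters after equality
    merging within and across groups."""
    if isinstance(specs, PathModelSpec):
        specs = [specs]
    moments = sum(len(s.observed) * (len(s.observed) + 3) // 2 for s in specs)
    distinct: set[str] = set()
    for gi, s in enumerate(specs):
        for e in s.entries:
            if not e.free:
                continue
            pid = e.label if e.label is not None else f"g{gi}:{e.pid()}"
            distinct.add(pid)
    return moments - len(distinct)


def _baseline_stats(groups: list[_GroupData], estimator: str) -> tuple[float, int]:
    """Independence-baseline chi-square and df (free means and variances,
    zero covariances)."""
    chisq_b = 0.0
    df_b = 0
    for g in groups:
        p = g.comp.p
        df_b += p * (p + 3) // 2 - 2 * p
        if estimator == "ml":
            F_b = float(np.log(np.diag(g.S)).sum() - g.logdet_S)
            chisq_b += g.weight * F_b
        else:
            # FIML independence model: per-variable available-case normal ML
            ll_b = 0.0
            X = g.X
            for jcol in range(p):
                x = X[:, jcol]
                x = x[~np.isnan(x)]
                v = x.var()
                ll_b += -0.5 * x.size * (np.log(2 * np.pi) + np.log(v) + 1.0)
            _, _, ll_sat = mvn_mle(X)
            chisq_b += 2.0 * (ll_sat - ll_b)
    return chisq_b, df_b


def _fit(
    specs: list[PathModelSpec],
    datas: list[pd.DataFrame | np.ndarray],
    estimator: str,
    ddof: int,
    max_restarts: int,
    seed: int,
    compute_se: bool,
) -> FitResult:
    estimator = estimator.lower()
    if estimator not in {"ml", "fiml"}:
        raise ValueError("estimator must be 'ml' or 'fiml'")
    comps = [
        _Compiled(s, auto_prefix=f"g{gi}:" if len(specs) > 1 else "")
        for gi, s in enumerate(specs)
    ]
    groups = [
        _GroupData(c, _as_matrix(d, s.observed), estimator, ddof)
        for c, s, d in zip(comps, specs, datas)
    ]
    theta_ids: list[str] = []
    for c in comps:
        for pid in c.slots:
            if pid not in theta_ids:
                theta_ids.append(pid)
    obj = _Objective(groups, theta_ids)
    theta0 = _start_values(groups, theta_ids)

    rng = np.random.default_rng(seed)
    gtol_ok = 1e-3  # a gradient this small moves chi-square by < 1e-6

    def is_ok(r) -> bool:
        return bool(r.fun < _PENALTY / 2 and (r.success or np.max(np.abs(r.jac)) < gtol_ok))

    best = None
    n_restarts = 0
    start = theta0
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(
            obj,
            start,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 5000, "maxfun": 50000, "ftol": 1e-13, "gtol": 1e-7},
        )
        if res.fun < _PENALTY / 2 and not res.success and np.max(np.abs(res.jac)) >= gtol_ok:
            # line-search stall: polish with full-memory BFGS
            polish = optimize.minimize(
                obj, res.x, jac=True, method="BFGS", options={"maxiter": 1000, "gtol": 1e-6}
            )
            if polish.fun <= res.fun:
                polish.nit += res.nit
                res = polish
        if best is None or res.fun < best.fun:
            best = res
        if is_ok(res):
            break
        n_restarts += 1
        start = theta0 * (1 + 0.2 * rng.standard_normal(len(theta0))) + 0.05 * rng.standard_normal(len(theta0))
    res = best
    converged = is_ok(res)
    theta_hat = res.x

    # chi-square
    df = model_df(specs)
    n_total = sum(g.n for g in groups)
    loglik = None
    if estimator == "ml":
        chisq = float(res.fun)
    else:
        ll_model = -0.5 * float(res.fun)
        loglik = ll_model
        ll_sat = 0.0
        for g in groups:
            _, _, ll_s = mvn_mle(g.X)
            ll_sat += ll_s
        chisq = max(2.0 * (ll_sat - ll_model), 0.0)
    p_val = float(stats.chi2.sf(chisq, df)) if df > 0 else float("nan")

    chisq_b, df_b = _baseline_stats(groups, estimator)
    if df > 0:
        idx = fit_indices(chisq, df, chisq_b, df_b, n_total)
        ci = rmsea_ci(chisq, df, n_total)
    else:
        idx = Indices(float("nan"), 1.0, 1.0, 0.0)
        ci = (0.0, 0.0)

    # standard errors from the observed information
    ses = np.full(len(theta_ids), np.nan)
    identified = True
    if compute_se and converged:
        from statsmodels.tools.numdiff import approx_fprime

        H = approx_fprime(theta_hat, lambda t: obj(t)[1], centered=True)
        H = 0.5 * (H + H.T)
        # objective approximates -2 ll in both modes -> cov = 2 H^{-1}
        eigs = np.linalg.eigvalsh(H)
        if eigs.min() < 1e-8 * max(eigs.max(), 1.0):
            identified = False
            logger.warning("information matrix near-singular: model may be underidentified")
            cov = 2.0 * np.linalg.pinv(H)
        else:
            cov = 2.0 * np.linalg.inv(H)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    rows = []
    vals = obj.values_dict(theta_hat)
    for gi, (s, c) in enumerate(zip(specs, comps)):
        for e in s.entries:
            if not e.free:
                continue
            pid = e.label if e.label is not None else (f"g{gi}:" if len(specs) > 1 else "") + e.pid()
            j = theta_ids.index(pid)
            est = vals[pid]
            se = float(ses[j])
            z = est / se if se > 0 else float("nan")
            rows.append(
                {
                    "group": s.group if s.group is not None else "",
                    "id": pid,
                    "kind": e.kind,
                    "lhs": e.a,
                    "rhs": e.b if e.b is not None else "",
                    "label": e.label or "",
                    "estimate": est,
                    "se": se,
                    "z": z,
                    "p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan"),
                }
            )
    table = pd.DataFrame(rows).drop_duplicates(subset=["id"]).reset_index(drop=True)

    logger.info(
        "fit %s: chi2 = %.3f, df = %d, converged = %s, restarts = %d",
        estimator,
        chisq,
        df,
        converged,
        n_restarts,
    )
    return FitResult(
        param_table=table,
        chisq=chisq,
        df=df,
        p=p_val,
        ratio=idx.ratio,
        cfi=idx.cfi,
        ifi=idx.ifi,
        rmsea=idx.rmsea,
        rmsea_ci=ci,
        baseline_chisq=chisq_b,
        baseline_df=df_b,
        n=n_total,
        loglik=loglik,
        estimator=estimator,
        converged=converged,
        identified=identified,
        n_iter=int(res.nit),
        n_restarts=n_restarts,
        theta=theta_hat,
        theta_ids=theta_ids,
        specs=list(specs),
    )


def fit_model(
    spec: PathModelSpec,
    data: pd.DataFrame | np.ndarray,
    estimator: str = "fiml",
    *,
    ddof: int = 1,
    max_restarts: int = 5,
    seed: int = 0,
    compute_se: bool = True,
) -> FitResult:
    """Fit a single-group path model.

    ``estimator='ml'`` minimizes the ML discrepancy of complete-case sample
    moments (chi-square = (N - ddof) * F); ``estimator='fiml'`` maximizes
    the casewise full-information likelihood (chi-square against the
    saturated model).  Standard errors come from the observed information.
    """
    return _fit([spec], [data], estimator, ddof, max_restarts, seed, compute_se)


def fit_multigroup(
    specs: Sequence[PathModelSpec],
    datas: Sequence[pd.DataFrame | np.ndarray],
    estimator: str = "fiml",
    *,
    ddof: int = 1,
    max_restarts: int = 5,
    seed: int = 0,
    compute_se: bool = True,
) -> FitResult:
    """Fit one model simultaneously over disjoint groups.  Parameters with
    the same label are shared across groups; everything else is
    group-specific.  Chi-square and df pool over groups."""
    specs = list(specs)
    datas = list(datas)
    if len(specs) < 2:
        raise ValueError("multi-group fit needs at least 2 groups")
    if len(specs) != len(datas):
        raise ValueError("one dataset per group required")
    for d, s in zip(datas, specs):
        if len(_as_matrix(d, s.observed)) == 0:
            raise ValueError("empty group")
    return _fit(specs, datas, estimator, ddof, max_restarts, seed, compute_se)


def chi_square_difference(
    nested: FitResult, fuller: FitResult, tol: float = 0.05
) -> ModelComparison:
    """Likelihood-ratio test between two nested fits on the same data.
    The nested (more constrained) model must have fewer distinct free
    parameters; its chi-square may not be smaller than the fuller model's
    beyond ``tol`` (that indicates an optimizer failure)."""
    ddf = nested.df - fuller.df
    if ddf <= 0:
        raise ValueError("models are not nested in the required direction (ddf <= 0)")
    dchisq = nested.chisq - fuller.chisq
    if dchisq < -tol:
        raise RuntimeError(
            f"constrained model fits better than the fuller model "
            f"(delta chi2 = {dchisq:.4f}); optimizer failure suspected"
        )
    dchisq = max(dchisq, 0.0)
    p = float(stats.chi2.sf(dchisq, ddf))
    return ModelComparison(dchisq=float(dchisq), ddf=int(ddf), p=p)
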