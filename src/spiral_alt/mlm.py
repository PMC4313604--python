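"""Mixed linear model for momentary outcomes with AR(1) within-subject errors.

The treatment-effect model for a beep-level outcome y (momentary positive
cognition by default) is

    y = b0 + b1*time + b2*condition + b3*time*condition + u_subject + e,

with a random subject intercept (variance sigma_u^2) and residuals that
follow a first-order autoregressive process over the ordered beep sequence
within each subject x period (variance sigma_e^2, lag-1 coefficient rho;
correlation rho^d across a gap of d scheduled beep slots, no correlation
across the pre/post boundary).  ``time`` codes post = 1, ``condition``
codes the treatment arm = 1, so b3 is the difference-in-differences — the
parameter of interest.

The marginal Gaussian likelihood is evaluated exactly in O(n): the Markov
structure of the AR(1) chain whitens the residual covariance in one
vectorized pass, and the random intercept enters through a rank-one
(Woodbury) update per subject.  Fixed effects are profiled out by
generalized least squares.  Wald tests for fixed effects use a normal
reference (justified by the large beep counts); the random-intercept
variance gets a z-test from the observed information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = ["MLMResult", "fit_mlm", "mlm_loglik", "simulate_mlm"]

FIXED_TERMS = ("intercept", "time", "condition", "condition_x_time")


@dataclass
class MLMResult:
    """Estimates from :func:`fit_mlm`.

    ``fixed`` is a table indexed by term with columns estimate, se, t, p.
    Variance components are reported on their natural scale with standard
    errors from the observed information of the profiled likelihood.
    """

    fixed: pd.DataFrame
    sigma_u2: float
    sigma_u2_se: float
    sigma_e2: float
    sigma_e2_se: float
    rho: float
    rho_se: float
    loglik: float
    method: str
    converged: bool
    n_obs: int
    n_subjects: int
    beta_cov: np.ndarray = field(repr=False, default=None)

    @property
    def sigma_u2_z(self) -> float:
        return self.sigma_u2 / self.sigma_u2_se

    @property
    def sigma_u2_p(self) -> float:
        return float(stats.norm.sf(self.sigma_u2_z))  # one-sided: variance > 0

    def to_dict(self) -> dict:
        return {
            "fixed": self.fixed.reset_index().to_dict(orient="records"),
            "random": {
                "intercept_variance": {
                    "estimate": self.sigma_u2,
                    "se": self.sigma_u2_se,
                    "z": self.sigma_u2_z,
                    "p": self.sigma_u2_p,
                },
                "residual_variance": {"estimate": self.sigma_e2, "se": self.sigma_e2_se},
                "ar1": {"estimate": self.rho, "se": self.rho_se},
            },
            "loglik": self.loglik,
            "method": self.method,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
        }


class _Blocks:
    """Stacked per-subject chains with vectorized AR(1) whitening.

    Rows are sorted by (subject, period, position); ``gaps`` holds the
    position difference to the previous row within a chain and +inf at
    chain starts, so the lag-1 correlation ``rho**gap`` is zero exactly
    where a new chain begins.
    """

    def __init__(self, df: pd.DataFrame, outcome_col: str, n_blocks: int = 10):
        df = df.loc[df[outcome_col].notna()].copy()
        if df.empty:
            raise ValueError("no non-missing outcome values")
        time = (df["period"] == "post").astype(float)
        cond = (df["condition"] == "mbct").astype(float)
        pos = (df["day"].astype(int) - 1) * n_blocks + df["block"].astype(int)
        order = np.lexsort((pos.to_numpy(), time.to_numpy(), df["subject"].to_numpy()))

        self.y = df[outcome_col].to_numpy(float)[order]
        t = time.to_numpy()[order]
        c = cond.to_numpy()[order]
        self.X = np.column_stack([np.ones(len(df)), t, c, t * c])
        p_sorted = pos.to_numpy(float)[order]
        subj = df["subject"].to_numpy()[order]

        new_subj = np.r_[True, subj[1:] != subj[:-1]]
        new_chain = new_subj | np.r_[True, t[1:] != t[:-1]]
        self.gaps = np.empty(len(df))
        self.gaps[new_chain] = np.inf
        self.gaps[~new_chain] = (p_sorted - np.r_[np.nan, p_sorted[:-1]])[~new_chain]
        if np.any(self.gaps[~new_chain] <= 0):
            raise ValueError("duplicate beep positions within a subject x period")

        self.subj_starts = np.flatnonzero(new_subj)
        self.n_subjects = self.subj_starts.size
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        self.n_obs = len(df)
        self.p = self.X.shape[1]
        self._yprev = np.r_[0.0, self.y[:-1]]
        self._Xprev = np.vstack([np.zeros(self.p), self.X[:-1]])

    def _r(self, rho: float) -> np.ndarray:
        if rho == 0.0:
            return np.zeros(self.n_obs)
        finite = np.isfinite(self.gaps)
        r = np.zeros(self.n_obs)
        g = self.gaps[finite]
        r[finite] = np.sign(rho) ** (g % 2 * 1) * np.exp(g * np.log(abs(rho)))
        return r

    def whitened(self, rho: float):
        r = self._r(rho)
        scale = np.sqrt(1.0 - r * r)
        yt = (self.y - r * self._yprev) / scale
        Xt = (self.X - r[:, None] * self._Xprev) / scale[:, None]
        ut = (1.0 - r) / scale
        logdet_R = float(np.log(scale * scale).sum())
        return yt, Xt, ut, logdet_R

    def reduce(self, v: np.ndarray) -> np.ndarray:
        return np.add.reduceat(v, self.subj_starts, axis=0)


def _gls_pieces(blocks: _Blocks, sigma_u2: float, sigma_e2: float, rho: float):
    """Accumulate X'V^-1 X, X'V^-1 y, y'V^-1 y and log|V| over subjects."""
    yt, Xt, ut, logdet_R = blocks.whitened(rho)
    a = blocks.reduce(ut * ut)  # u' R^-1 u per subject
    uy = blocks.reduce(ut * yt)
    uX = blocks.reduce(ut[:, None] * Xt)
    inv_denom = (
        1.0 / (1.0 / sigma_u2 + a / sigma_e2) if sigma_u2 > 0 else np.zeros_like(a)
    )
    XtVX = Xt.T @ Xt / sigma_e2 - np.einsum("sp,sq,s->pq", uX, uX, inv_denom) / sigma_e2**2
    XtVy = Xt.T @ yt / sigma_e2 - (uX * (uy * inv_denom)[:, None]).sum(axis=0) / sigma_e2**2
    yty = float(yt @ yt) / sigma_e2 - float(uy * uy @ inv_denom) / sigma_e2**2
    logdet_V = blocks.n_obs * np.log(sigma_e2) + logdet_R
    if sigma_u2 > 0:
        logdet_V += float(np.log1p(sigma_u2 * a / sigma_e2).sum())
    return XtVX, XtVy, yty, logdet_V


def _profile_ll(blocks: _Blocks, sigma_u2: float, sigma_e2: float, rho: float, reml: bool):
    XtVX, XtVy, yty, logdet_V = _gls_pieces(blocks, sigma_u2, sigma_e2, rho)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = yty - 2.0 * float(beta @ XtVy) + float(beta @ XtVX @ beta)
    ll = -0.5 * (blocks.n_obs * np.log(2 * np.pi) + logdet_V + rss)
    if reml:
        _, ld = np.linalg.slogdet(XtVX)
        ll -= 0.5 * ld
    return ll, beta, XtVX


def _outcome_col(data: pd.DataFrame, outcome: str) -> str:
    aliases = {"pc": "thought_pleasant", "pa": "pa_score"}
    col = aliases.get(outcome, outcome)
    if col not in data.columns:
        raise ValueError(f"outcome column {col!r} not in data")
    return col


def mlm_loglik(
    data: pd.DataFrame,
    params,
    outcome: str = "pc",
    n_blocks: int = 10,
) -> float:
    """Exact marginal Gaussian log-likelihood at a full parameter vector
    ``(b0, b1, b2, b3, sigma_u2, sigma_e2, rho)``."""
    beta = np.asarray(params[:4], float)
    sigma_u2, sigma_e2, rho = (float(v) for v in params[4:7])
    if sigma_e2 <= 0 or sigma_u2 < 0 or not (-1 < rho < 1):
        raise ValueError("require sigma_e2 > 0, sigma_u2 >= 0, |rho| < 1")
    blocks = _Blocks(data, _outcome_col(data, outcome), n_blocks=n_blocks)
    XtVX, XtVy, yty, logdet_V = _gls_pieces(blocks, sigma_u2, sigma_e2, rho)
    rss = yty - 2.0 * float(beta @ XtVy) + float(beta @ XtVX @ beta)
    return float(-0.5 * (blocks.n_obs * np.log(2 * np.pi) + logdet_V + rss))


def fit_mlm(
    data: pd.DataFrame,
    outcome: str = "pc",
    method: str = "ML",
    n_blocks: int = 10,
) -> MLMResult:
    """Fit the treatment-effect mixed model by (RE)ML.

    Parameters
    ----------
    data : beep-level table with columns ``subject, condition, period, day,
        block`` and the outcome (``'pc'`` = thought pleasantness, ``'pa'`` =
        beep PA score column ``pa_score``, or any column name).  Missing
        outcomes are dropped casewise.
    method : ``'ML'`` (default; keeps nested fixed-effect likelihood-ratio
        tests valid) or ``'REML'``.

    Returns
    -------
    MLMResult with the four fixed effects (intercept, time, condition,
    condition x time), variance components and their tests.
    """
    reml = method.upper() == "REML"
    blocks = _Blocks(data, _outcome_col(data, outcome), n_blocks=n_blocks)

    def unpack(phi):
        return np.exp(phi[0]), np.exp(phi[1]), np.tanh(phi[2])

    def nll(phi):
        su2, se2, rho = unpack(phi)
        try:
            ll, _, _ = _profile_ll(blocks, su2, se2, rho, reml)
        except np.linalg.LinAlgError:
            return 1e12
        return -ll

    # moment-based start: split the outcome variance
    var0 = max(float(np.var(blocks.y)), 1e-4)
    phi0 = np.array([np.log(0.3 * var0), np.log(0.7 * var0), np.arctanh(0.3)])
    rng = np.random.default_rng(0)
    best = None
    for attempt in range(4):
        res = optimize.minimize(
            nll,
            phi0 if attempt == 0 else phi0 + 0.3 * rng.standard_normal(3),
            method="L-BFGS-B",
            bounds=[(-14, 6), (-14, 6), (-6, 6)],
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
        # gradient scaled by the objective magnitude (a profiled deviance)
        if res.success or np.max(np.abs(res.jac)) < 1e-4 * max(abs(res.fun), 1.0):
            break
    res = best
    converged = bool(res.success or np.max(np.abs(res.jac)) < 1e-4 * max(abs(res.fun), 1.0))
    if not converged:
        logger.warning("mixed-model optimizer did not converge: %s", res.message)
    su2, se2, rho = unpack(res.x)
    ll, beta, XtVX = _profile_ll(blocks, su2, se2, rho, reml)

    beta_cov = np.linalg.inv(XtVX)
    se_beta = np.sqrt(np.diag(beta_cov))
    tvals = beta / se_beta
    pvals = 2 * stats.norm.sf(np.abs(tvals))
    fixed = pd.DataFrame(
        {"estimate": beta, "se": se_beta, "t": tvals, "p": pvals},
        index=pd.Index(FIXED_TERMS, name="term"),
    )

    # observed information of the profiled likelihood on the natural scale
    def nll_nat(v):
        su2_, se2_, rho_ = v
        if se2_ <= 0 or su2_ < 0 or not (-1 < rho_ < 1):
            return 1e12
        return -_profile_ll(blocks, su2_, se2_, rho_, reml)[0]

    from statsmodels.tools.numdiff import approx_hess1

    vhat = np.array([su2, se2, rho])
    try:
        H = approx_hess1(vhat, nll_nat)
        vc_cov = np.linalg.inv(0.5 * (H + H.T))
        vc_se = np.sqrt(np.clip(np.diag(vc_cov), 0, np.inf))
    except np.linalg.LinAlgError:
        vc_se = np.full(3, np.nan)

    return MLMResult(
        fixed=fixed,
        sigma_u2=float(su2),
        sigma_u2_se=float(vc_se[0]),
        sigma_e2=float(se2),
        sigma_e2_se=float(vc_se[1]),
        rho=float(rho),
        rho_se=float(vc_se[2]),
        loglik=float(ll),
        method="REML" if reml else "ML",
        converged=converged,
        n_obs=blocks.n_obs,
        n_subjects=blocks.n_subjects,
        beta_cov=beta_cov,
    )


def simulate_mlm(
    beta=(3.0, 0.0, 0.0, 0.23),
    sigma_u2: float = 0.25,
    sigma_e2: float = 1.0,
    rho: float = 0.4,
    n_control: int = 66,
    n_mbct: int = 64,
    n_days: int = 6,
    n_blocks: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate beep data directly from the mixed model's own process (used
    for calibration under a correctly specified covariance structure).
    Returns a beep table with outcome column ``y``."""
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, float)
    n = n_control + n_mbct
    n_per = n_days * n_blocks
    cond = np.r_[np.zeros(n_control), np.ones(n_mbct)]
    u = rng.normal(0, np.sqrt(sigma_u2), n)

    # stationary AR(1) errors, one chain per subject x period
    e = np.empty((2 * n, n_per))
    e[:, 0] = rng.normal(0, np.sqrt(sigma_e2), 2 * n)
    innov = rng.normal(0, np.sqrt(sigma_e2 * (1 - rho**2)), (2 * n, n_per - 1))
    for i in range(1, n_per):
        e[:, i] = rho * e[:, i - 1] + innov[:, i - 1]

    time = np.repeat([0.0, 1.0], n)  # chains ordered (all pre, all post)
    subj = np.tile(np.arange(n), 2)
    mean = (
        beta[0]
        + beta[1] * time
        + beta[2] * cond[subj]
        + beta[3] * time * cond[subj]
        + u[subj]
    )
    y = mean[:, None] + e

    day = np.repeat(np.arange(1, n_days + 1), n_blocks)
    block = np.tile(np.arange(1, n_blocks + 1), n_days)
    out = pd.DataFrame(
        {
            "subject": np.repeat([f"s{i:04d}" for i in subj], n_per),
            "condition": np.repeat(np.where(cond[subj] > 0, "mbct", "control"), n_per),
            "period": np.repeat(np.where(time > 0, "post", "pre"), n_per),
            "day": np.tile(day, 2 * n),
            "block": np.tile(block, 2 * n),
            "y": y.ravel(),
        }
    )
    return out.sort_values(["subject", "period", "day", "block"]).reset_index(drop=True)
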