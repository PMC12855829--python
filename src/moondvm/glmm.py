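"""Gamma log-link mixed models for depth-binned zooplankton densities.

Two fixed-effect designs are supported, mirroring the two questions the
depth-bin table answers:

* ``daynight`` — density ~ illuminance * size_class (6 fixed effects), run on
  all profiles from daylight into night;
* ``night`` — density ~ illuminance * size_class * temperature
  + illuminance * size_class * chl_a (18 fixed effects), run on the subset of
  profiles after civil twilight.

Both carry random intercepts for sampling date and profile (profiles nested
in dates). The response is bin density (ind/L), modelled as
Gamma(shape k, mean exp(eta)) with eta = X beta + u_date + u_profile.

Estimation is Laplace-approximated maximum likelihood: for candidate
variance/shape parameters, the joint mode over (beta, u) is found by
penalized iteratively reweighted least squares (expected Fisher weights are
constant k under the log link, which keeps each inner step a single linear
solve), and the marginal likelihood is the joint log-density at the mode
minus half the log-determinant of the scaled random-effect curvature.
Uncertainty is quantified by a parametric bootstrap: resimulate responses
from the fitted generative model, refit, and report shortest (HPD) intervals
of the bootstrap distribution; an effect is significant when its interval
excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln

__all__ = [
    "GlmmSpec",
    "GlmmFit",
    "BootstrapCI",
    "NIGHT_TERMS",
    "DAYNIGHT_TERMS",
    "build_design",
    "fit_gamma_glmm",
    "simulate_from_fit",
    "parametric_bootstrap_hpd",
    "hpd_interval",
    "model_report",
]

SIZE_LEVELS = ("small", "medium", "large")

# Fixed-effect terms in the order the result tables print them.
DAYNIGHT_TERMS = (
    "intercept",
    "lx",
    "size_medium",
    "size_large",
    "lx:size_medium",
    "lx:size_large",
)

NIGHT_TERMS = (
    "intercept",
    "size_medium",
    "size_large",
    "lx",
    "temp",
    "chl",
    "lx:size_medium",
    "lx:size_large",
    "temp:size_medium",
    "temp:size_large",
    "lx:temp",
    "chl:size_medium",
    "chl:size_large",
    "lx:chl",
    "lx:temp:size_medium",
    "lx:temp:size_large",
    "lx:chl:size_medium",
    "lx:chl:size_large",
)


@dataclass(frozen=True)
class GlmmSpec:
    """Which model to build and how to scale its continuous covariates.

    The night design z-scores illuminance, temperature and chlorophyll-a by
    default (three-way interaction coefficients are only interpretable on a
    common scale); the day-night design keeps raw lux, whose range carries
    the day/night contrast.
    """

    design: str = "night"
    scale_covariates: bool | None = None
    zero_policy: str = "drop"   # "drop" | "offset"
    response: str = "density"

    def __post_init__(self) -> None:
        if self.design not in ("night", "daynight"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.zero_policy not in ("drop", "offset"):
            raise ValueError(f"unknown zero_policy {self.zero_policy!r}")
        if self.scale_covariates is None:
            object.__setattr__(self, "scale_covariates", self.design == "night")

    @property
    def terms(self) -> tuple[str, ...]:
        return NIGHT_TERMS if self.design == "night" else DAYNIGHT_TERMS


_COVARIATE_COLUMNS = {
    "lx": "illuminance_lx",
    "temp": "temperature_C",
    "chl": "chl_a_ugL",
}


def _scaled_covariates(table: pd.DataFrame, spec: GlmmSpec) -> tuple[dict, dict]:
    needed = ("lx",) if spec.design == "daynight" else ("lx", "temp", "chl")
    cov, scaling = {}, {}
    for name in needed:
        col = _COVARIATE_COLUMNS[name]
        if col not in table.columns:
            raise ValueError(f"bin table is missing covariate column {col!r}")
        x = table[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"non-finite values in covariate column {col!r}")
        if spec.scale_covariates:
            mu, sd = float(x.mean()), float(x.std())
            if sd == 0.0:
                raise ValueError(f"covariate {col!r} is constant; cannot z-score")
            cov[name] = (x - mu) / sd
            scaling[name] = {"mean": mu, "sd": sd}
        else:
            cov[name] = x
            scaling[name] = {"mean": 0.0, "sd": 1.0}
    return cov, scaling


def design_matrix(table: pd.DataFrame, spec: GlmmSpec) -> tuple[np.ndarray, dict]:
    """Fixed-effect design matrix in printed-table column order."""
    if "size_class" not in table.columns:
        raise ValueError("bin table is missing column 'size_class'")
    size = table["size_class"].to_numpy()
    unknown = set(size) - set(SIZE_LEVELS)
    if unknown:
        raise ValueError(f"unknown size_class levels {sorted(unknown)!r}")
    cov, scaling = _scaled_covariates(table, spec)
    med = (size == "medium").astype(float)
    lar = (size == "large").astype(float)
    one = np.ones(len(table))
    cols = {
        "intercept": one,
        "size_medium": med,
        "size_large": lar,
        "lx": cov["lx"],
        "lx:size_medium": cov["lx"] * med,
        "lx:size_large": cov["lx"] * lar,
    }
    if spec.design == "night":
        cols.update(
            {
                "temp": cov["temp"],
                "chl": cov["chl"],
                "temp:size_medium": cov["temp"] * med,
                "temp:size_large": cov["temp"] * lar,
                "lx:temp": cov["lx"] * cov["temp"],
                "chl:size_medium": cov["chl"] * med,
                "chl:size_large": cov["chl"] * lar,
                "lx:chl": cov["lx"] * cov["chl"],
                "lx:temp:size_medium": cov["lx"] * cov["temp"] * med,
                "lx:temp:size_large": cov["lx"] * cov["temp"] * lar,
                "lx:chl:size_medium": cov["lx"] * cov["chl"] * med,
                "lx:chl:size_large": cov["lx"] * cov["chl"] * lar,
            }
        )
    X = np.column_stack([cols[t] for t in spec.terms])
    return X, scaling


@dataclass
class DesignData:
    """Response, fixed design and grouping indices ready for fitting."""

    y: np.ndarray
    X: np.ndarray
    terms: tuple[str, ...]
    date_index: np.ndarray
    profile_index: np.ndarray
    date_levels: np.ndarray
    profile_levels: np.ndarray
    scaling: dict
    n_dropped_zero: int = 0
    spec: GlmmSpec = field(default_factory=GlmmSpec)


def build_design(table: pd.DataFrame, spec: GlmmSpec | None = None) -> DesignData:
    """Assemble (y, X, grouping) from a depth-bin density table.

    Gamma support excludes zero, so zero-density rows are either dropped
    (default) or offset by half the smallest positive density observed
    (``zero_policy="offset"``); the count of affected rows is retained.
    """
    spec = spec or GlmmSpec()
    for col in ("density", "date", "profile_id"):
        if col not in table.columns:
            raise ValueError(f"bin table is missing column {col!r}")
    tbl = table
    y = tbl["density"].to_numpy(dtype=float)
    if np.any(y < 0) or not np.all(np.isfinite(y)):
        raise ValueError("density must be finite and non-negative")
    n_zero = int((y == 0).sum())
    if n_zero:
        if spec.zero_policy == "drop":
            tbl = tbl.loc[y > 0].reset_index(drop=True)
            y = tbl["density"].to_numpy(dtype=float)
        else:
            positive = y[y > 0]
            if positive.size == 0:
                raise ValueError("all densities are zero; nothing to fit")
            y = np.where(y == 0, positive.min() / 2.0, y)
    X, scaling = design_matrix(tbl, spec)
    date_levels, date_idx = np.unique(tbl["date"].to_numpy(), return_inverse=True)
    prof_levels, prof_idx = np.unique(tbl["profile_id"].to_numpy(), return_inverse=True)
    return DesignData(
        y=y,
        X=X,
        terms=spec.terms,
        date_index=date_idx,
        profile_index=prof_idx,
        date_levels=date_levels,
        profile_levels=prof_levels,
        scaling=scaling,
        n_dropped_zero=n_zero,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Laplace-approximated ML fit
# ---------------------------------------------------------------------------

def _gamma_loglik(y: np.ndarray, eta: np.ndarray, shape: float) -> float:
    # Gamma(shape k, mean mu=exp(eta)): k log k - lgamma(k) + (k-1) log y - k eta - k y/mu
    return float(
        len(y) * (shape * np.log(shape) - gammaln(shape))
        + (shape - 1.0) * np.log(y).sum()
        - shape * (eta.sum() + np.sum(y * np.exp(-eta)))
    )


class _Workspace:
    """Precomputed cross-products for one (X, Z) layout.

    With a log link the expected Fisher weight of every observation is the
    constant gamma shape, so the penalized normal-equation matrix is
    k*[X Z]'[X Z] plus the prior precision: [X Z]'[X Z] is computed once and
    reused across all inner and outer iterations.
    """

    def __init__(self, data: DesignData, re_structure: tuple[bool, bool]):
        self.data = data
        self.use_date, self.use_profile = re_structure
        n, p = data.X.shape
        blocks = [data.X]
        self.q_date = len(data.date_levels) if self.use_date else 0
        self.q_prof = len(data.profile_levels) if self.use_profile else 0
        if self.use_date:
            zd = np.zeros((n, self.q_date))
            zd[np.arange(n), data.date_index] = 1.0
            blocks.append(zd)
        if self.use_profile:
            zp = np.zeros((n, self.q_prof))
            zp[np.arange(n), data.profile_index] = 1.0
            blocks.append(zp)
        self.A = np.column_stack(blocks)
        self.G = self.A.T @ self.A
        self.p = p
        self.q = self.q_date + self.q_prof

    def penalty_diag(self, s2_date: float, s2_prof: float) -> np.ndarray:
        d = np.zeros(self.p + self.q)
        if self.use_date:
            d[self.p : self.p + self.q_date] = 1.0 / s2_date
        if self.use_profile:
            d[self.p + self.q_date :] = 1.0 / s2_prof
        return d

    def joint_mode(
        self,
        shape: float,
        s2_date: float,
        s2_prof: float,
        gamma0: np.ndarray | None = None,
        max_iter: int = 60,
        tol: float = 1e-9,
    ) -> tuple[np.ndarray, float, bool]:
        """Penalized IRLS for the joint mode of (beta, u); monotone via step-halving."""
        y = self.data.y
        pen = self.penalty_diag(s2_date, s2_prof)
        gam = np.zeros(self.p + self.q) if gamma0 is None else gamma0.copy()
        if gamma0 is None:
            gam[0] = np.log(y.mean())

        def objective(g: np.ndarray) -> float:
            eta = self.A @ g
            return _gamma_loglik(y, eta, shape) - 0.5 * float(np.sum(pen * g * g))

        obj = objective(gam)
        H = shape * self.G + np.diag(pen)
        converged = False
        for _ in range(max_iter):
            eta = self.A @ gam
            resid = y * np.exp(-eta) - 1.0           # d loglik / d eta / shape
            grad = shape * (self.A.T @ resid) - pen * gam
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            t = 1.0
            for _ in range(30):
                cand = gam + t * step
                cand_obj = objective(cand)
                if cand_obj >= obj - 1e-12:
                    break
                t /= 2.0
            else:
                break
            gained = cand_obj - obj
            gam, obj = cand, cand_obj
            if abs(gained) < tol * (abs(obj) + 1.0):
                converged = True
                break
        return gam, obj, converged

    def laplace_loglik(
        self, shape: float, s2_date: float, s2_prof: float, gamma0=None
    ) -> tuple[float, np.ndarray, bool]:
        gam, joint, ok = self.joint_mode(shape, s2_date, s2_prof, gamma0)
        if self.q == 0:
            return joint, gam, ok
        pen_u = self.penalty_diag(s2_date, s2_prof)[self.p :]
        h_uu = shape * self.G[self.p :, self.p :] + np.diag(pen_u)
        sign, logdet_h = np.linalg.slogdet(h_uu)
        if sign <= 0:
            return -np.inf, gam, False
        logdet_prior = float(np.sum(np.log(pen_u)))  # = -log det D
        # log integral over u: joint + (q/2) log 2pi - 1/2 log det H_uu,
        # with the prior normalizer -(q/2) log 2pi + 1/2 log det D^-1 folded in
        marginal = joint - 0.5 * (logdet_h - logdet_prior)
        return marginal, gam, ok


@dataclass
class GlmmFit:
    """A fitted gamma log-link mixed model."""

    beta: pd.Series
    sigma2_date: float
    sigma2_profile: float
    gamma_shape: float
    loglik: float
    converged: bool
    n_obs: int
    u_date: pd.Series
    u_profile: pd.Series
    scaling: dict
    spec: GlmmSpec
    n_dropped_zero: int
    optimizer_trace: np.ndarray
    data: DesignData | None = None

    def eta(self, data: DesignData | None = None) -> np.ndarray:
        d = data or self.data
        eta = d.X @ self.beta.to_numpy()
        if self.sigma2_date > 0 or len(self.u_date):
            eta = eta + self.u_date.to_numpy()[d.date_index]
        if self.sigma2_profile > 0 or len(self.u_profile):
            eta = eta + self.u_profile.to_numpy()[d.profile_index]
        return eta


def fit_gamma_glmm(
    data: DesignData | None = None,
    *,
    y: np.ndarray | None = None,
    X: np.ndarray | None = None,
    date_index: np.ndarray | None = None,
    profile_index: np.ndarray | None = None,
    terms: tuple[str, ...] | None = None,
    var_date: float | None = None,
    var_profile: float | None = None,
    shape: float | None = None,
    init: tuple[float, float, float] | None = None,
    maxiter: int = 400,
    keep_data: bool = True,
) -> GlmmFit:
    """Fit the gamma GLMM by Laplace-approximated maximum likelihood.

    ``var_date``/``var_profile``/``shape`` may be pinned to fixed values
    (a variance pinned to 0 removes that random term, reducing the model to
    a plain gamma GLM, which is the oracle contract used in testing);
    ``None`` means "estimate".

    Parameters are profiled on the log scale with a Nelder-Mead search over
    the free (shape, variance) coordinates; each evaluation is one penalized
    IRLS solve. ``optimizer_trace`` records the best marginal log-likelihood
    seen so far, a non-decreasing sequence by construction.
    """
    if data is None:
        if y is None or X is None:
            raise ValueError("provide either DesignData or raw y/X arrays")
        n = len(y)
        spec = GlmmSpec(design="night") if X.shape[1] == 18 else GlmmSpec(design="daynight")
        data = DesignData(
            y=np.asarray(y, float),
            X=np.asarray(X, float),
            terms=terms or tuple(f"x{i}" for i in range(X.shape[1])),
            date_index=np.zeros(n, int) if date_index is None else np.asarray(date_index),
            profile_index=np.zeros(n, int) if profile_index is None else np.asarray(profile_index),
            date_levels=np.unique(date_index) if date_index is not None else np.array([0]),
            profile_levels=np.unique(profile_index) if profile_index is not None else np.array([0]),
            scaling={},
            spec=spec,
        )
        if terms is not None:
            data.terms = tuple(terms)
    if np.any(data.y <= 0):
        raise ValueError(
            "response contains non-positive values; apply the zero-density policy "
            "(drop or offset) in build_design before fitting"
        )

    use_date = var_date is None or var_date > 0
    use_prof = var_profile is None or var_profile > 0
    ws = _Workspace(data, (use_date, use_prof))

    # starting values: plain-GLM Pearson moment estimate for the shape
    gam0, _, _ = ws.joint_mode(1.0, 1e6 if use_date else 1.0, 1e6 if use_prof else 1.0)
    mu0 = np.exp(ws.A @ gam0)
    pearson = float(np.sum(((data.y - mu0) / mu0) ** 2))
    dof = max(len(data.y) - ws.p, 1)
    k0 = max(dof / max(pearson, 1e-12), 1e-3)
    if init is not None:
        k0, s2d0, s2p0 = init
    else:
        s2d0, s2p0 = 0.05, 0.05

    free: list[str] = []
    if shape is None:
        free.append("shape")
    if var_date is None and use_date:
        free.append("s2_date")
    if var_profile is None and use_prof:
        free.append("s2_profile")

    start = {"shape": np.log(k0), "s2_date": np.log(s2d0), "s2_profile": np.log(s2p0)}
    fixed = {
        "shape": shape,
        "s2_date": var_date if var_date is not None else None,
        "s2_profile": var_profile if var_profile is not None else None,
    }

    trace: list[float] = []
    warm: dict[str, np.ndarray] = {}

    def unpack(theta: np.ndarray) -> tuple[float, float, float]:
        vals = dict(zip(free, theta))
        k = fixed["shape"] if fixed["shape"] is not None else float(np.exp(vals["shape"]))
        s2d = (
            fixed["s2_date"]
            if fixed["s2_date"] is not None
            else (float(np.exp(vals["s2_date"])) if use_date else 0.0)
        )
        s2p = (
            fixed["s2_profile"]
            if fixed["s2_profile"] is not None
            else (float(np.exp(vals["s2_profile"])) if use_prof else 0.0)
        )
        return k, max(s2d, 1e-10) if use_date else 0.0, max(s2p, 1e-10) if use_prof else 0.0

    def negloglik(theta: np.ndarray) -> float:
        k, s2d, s2p = unpack(theta)
        ll, gam, _ = ws.laplace_loglik(k, s2d, s2p, warm.get("gamma"))
        warm["gamma"] = gam
        if not np.isfinite(ll):
            return 1e12
        trace.append(ll if not trace else max(trace[-1], ll))
        return -ll

    if free:
        theta0 = np.array([start[name] for name in free])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                negloglik,
                theta0,
                method="Nelder-Mead",
                options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-4},
            )
        theta_hat = res.x
        opt_ok = bool(res.success) or len(trace) >= 3
    else:
        theta_hat = np.array([])
        opt_ok = True

    k_hat, s2d_hat, s2p_hat = unpack(theta_hat)
    ll, gam_hat, irls_ok = ws.laplace_loglik(k_hat, s2d_hat, s2p_hat, warm.get("gamma"))
    trace.append(ll if not trace else max(trace[-1], ll))

    beta = pd.Series(gam_hat[: ws.p], index=list(data.terms), name="beta")
    off = ws.p
    u_date = pd.Series(
        gam_hat[off : off + ws.q_date] if use_date else np.zeros(len(data.date_levels)),
        index=list(data.date_levels),
    )
    off += ws.q_date
    u_prof = pd.Series(
        gam_hat[off : off + ws.q_prof] if use_prof else np.zeros(len(data.profile_levels)),
        index=list(data.profile_levels),
    )
    return GlmmFit(
        beta=beta,
        sigma2_date=s2d_hat if use_date else 0.0,
        sigma2_profile=s2p_hat if use_prof else 0.0,
        gamma_shape=k_hat,
        loglik=float(ll),
        converged=bool(opt_ok and irls_ok and np.isfinite(ll)),
        n_obs=len(data.y),
        u_date=u_date,
        u_profile=u_prof,
        scaling=data.scaling,
        spec=data.spec,
        n_dropped_zero=data.n_dropped_zero,
        optimizer_trace=np.asarray(trace),
        data=data if keep_data else None,
    )


# ---------------------------------------------------------------------------
# Parametric bootstrap with HPD intervals
# ---------------------------------------------------------------------------

def simulate_from_fit(fit: GlmmFit, rng: np.random.Generator, data: DesignData | None = None) -> np.ndarray:
    """Draw one response vector from the fitted generative model."""
    d = data or fit.data
    if d is None:
        raise ValueError("fit carries no design data; pass `data` explicitly")
    eta = d.X @ fit.beta.to_numpy()
    if fit.sigma2_date > 0:
        u = rng.normal(0.0, np.sqrt(fit.sigma2_date), len(d.date_levels))
        eta = eta + u[d.date_index]
    if fit.sigma2_profile > 0:
        u = rng.normal(0.0, np.sqrt(fit.sigma2_profile), len(d.profile_levels))
        eta = eta + u[d.profile_index]
    mu = np.exp(eta)
    return rng.gamma(fit.gamma_shape, mu / fit.gamma_shape)


def hpd_interval(draws: np.ndarray, prob: float = 0.95, center: float | None = None) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the draws.

    Sorts the sample and slides a window of ceil(prob*n); ties in width are
    broken toward the window whose midpoint is closest to ``center`` (the
    point estimate) when one is given.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("no draws")
    m = int(np.ceil(prob * n))
    m = min(max(m, 1), n)
    if m == n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    best = np.flatnonzero(widths <= widths.min() + 1e-15)
    if len(best) > 1 and center is not None:
        mids = (x[best + m - 1] + x[best]) / 2.0
        best = [best[int(np.argmin(np.abs(mids - center)))]]
    i = int(best[0])
    return float(x[i]), float(x[i + m - 1])


@dataclass
class BootstrapCI:
    """Per-term HPD intervals from a parametric bootstrap."""

    table: pd.DataFrame          # index: term; columns: estimate, hpd_low, hpd_high, significant
    variance_table: pd.DataFrame  # index: date/profile; columns: estimate, hpd_low, hpd_high
    n_iter: int
    seed: int
    n_failed: int
    draws: pd.DataFrame | None = None


def parametric_bootstrap_hpd(
    fit: GlmmFit,
    n_iter: int = 10_000,
    seed: int = 0,
    prob: float = 0.95,
    max_failure_rate: float = 0.05,
    keep_draws: bool = False,
    refit_maxiter: int = 150,
) -> BootstrapCI:
    """Parametric-bootstrap HPD confidence intervals for a converged fit.

    Simulates ``n_iter`` response vectors from the fitted model (fresh random
    intercepts plus gamma noise), refits each, and summarizes every fixed
    effect and variance component by its shortest 95% interval. An effect is
    flagged significant when its interval excludes zero.
    """
    if not fit.converged:
        raise ValueError("refusing to bootstrap a non-converged fit")
    if fit.data is None:
        raise ValueError("fit carries no design data (fitted with keep_data=False)")
    rng = np.random.default_rng(seed)
    d = fit.data
    init = (fit.gamma_shape, max(fit.sigma2_date, 1e-4), max(fit.sigma2_profile, 1e-4))
    var_date_arg = None if fit.sigma2_date > 0 else 0.0
    var_prof_arg = None if fit.sigma2_profile > 0 else 0.0

    rows, var_rows, failed = [], [], 0
    for _ in range(n_iter):
        y_star = simulate_from_fit(fit, rng)
        sim_data = replace(d, y=y_star)
        try:
            refit = fit_gamma_glmm(
                sim_data,
                var_date=var_date_arg,
                var_profile=var_prof_arg,
                init=init,
                maxiter=refit_maxiter,
                keep_data=False,
            )
        except Exception:
            failed += 1
            continue
        if not refit.converged:
            failed += 1
            continue
        rows.append(refit.beta.to_numpy())
        var_rows.append((refit.sigma2_date, refit.sigma2_profile))
    if n_iter > 0 and failed > max_failure_rate * n_iter:
        raise RuntimeError(
            f"{failed}/{n_iter} bootstrap refits failed to converge "
            f"(> {max_failure_rate:.0%} allowed); the fit is unstable"
        )

    draws = pd.DataFrame(np.asarray(rows), columns=list(fit.beta.index))
    vdraws = pd.DataFrame(np.asarray(var_rows), columns=["date", "profile"])

    records = []
    for term in fit.beta.index:
        est = float(fit.beta[term])
        lo, hi = hpd_interval(draws[term].to_numpy(), prob, center=est)
        records.append(
            {"term": term, "estimate": est, "hpd_low": lo, "hpd_high": hi,
             "significant": not (lo <= 0.0 <= hi)}
        )
    table = pd.DataFrame.from_records(records).set_index("term")

    vrecords = []
    for name, est in (("date", fit.sigma2_date), ("profile", fit.sigma2_profile)):
        lo, hi = hpd_interval(vdraws[name].to_numpy(), prob, center=est)
        vrecords.append({"component": name, "estimate": est, "hpd_low": lo, "hpd_high": hi})
    var_table = pd.DataFrame.from_records(vrecords).set_index("component")

    return BootstrapCI(
        table=table,
        variance_table=var_table,
        n_iter=n_iter,
        seed=seed,
        n_failed=failed,
        draws=pd.concat([draws, vdraws.add_prefix("sigma2_")], axis=1) if keep_draws else None,
    )


def model_report(fit: GlmmFit, ci: BootstrapCI) -> pd.DataFrame:
    """Result table in printed order: fixed effects then variance components."""
    rows = []
    for term in fit.beta.index:
        r = ci.table.loc[term]
        rows.append(
            {
                "row": term,
                "kind": "fixed",
                "estimate": float(fit.beta[term]),
                "hpd_low": float(r["hpd_low"]),
                "hpd_high": float(r["hpd_high"]),
                "significant": bool(r["significant"]),
            }
        )
    for name, est in (("var_date", fit.sigma2_date), ("var_profile", fit.sigma2_profile)):
        r = ci.variance_table.loc[name.removeprefix("var_")]
        rows.append(
            {
                "row": name,
                "kind": "random",
                "estimate": float(est),
                "hpd_low": float(r["hpd_low"]),
                "hpd_high": float(r["hpd_high"]),
                "significant": False,
            }
        )
    out = pd.DataFrame.from_records(rows)
    out.attrs["gamma_shape"] = fit.gamma_shape
    out.attrs["n_obs"] = fit.n_obs
    out.attrs["scaling"] = fit.scaling
    return out
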