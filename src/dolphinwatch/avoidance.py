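"""Binomial mixed models for dolphin-group avoidance responses.

Whether a group avoids approaching vessels (vs reacting neutrally or being
attracted) is modelled as a Bernoulli outcome with a logit link, fixed
effects drawn from {behaviour, vessels, compliance, cohesion, size} and a
random intercept per focal group (groups are resampled across days, so
responses within a group are not independent).

The marginal likelihood integrates the random intercepts out; with a single
scalar intercept per group the integral is approximated by Laplace's method
at the per-group posterior mode, and the resulting log-likelihood is
maximised over (beta, log sigma) with BFGS from a deterministic start (the
ordinary-logistic solution, sigma = 0.1).  Candidate models are ranked by
AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1) and summarised with Akaike weights
w_i = exp(-delta_i/2) / sum exp(-delta_j/2).

Model adequacy is checked with simulation-based scaled residuals: responses
are re-simulated from the fitted model (random intercepts redrawn) and each
observation is placed as a randomised rank within its own simulated
distribution, which is uniform on [0, 1] under a correct model.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .records import COHESION_LEVELS, OBSERVED_STATES, FocalFollow

logger = logging.getLogger(__name__)

#: Candidate fixed-effect terms and the degrees of freedom each one adds.
TERM_DF = {"behaviour": 4, "vessels": 1, "compliance": 1, "cohesion": 2, "size": 1}

#: Canonical term order for model descriptions.
TERM_ORDER = ("behaviour", "vessels", "compliance", "cohesion", "size")

#: Reference levels absorbed into the intercept.
REFERENCE = {"behaviour": "REST", "cohesion": "high", "compliance": "non-compliant"}

_SIGMA_FLOOR = 1e-4  # below this the random-intercept variance is a boundary fit
_LOG_SIGMA_BOUNDS = (math.log(1e-6), math.log(50.0))


@dataclass(frozen=True)
class AvoidanceObservation:
    """One group-response record with covariates for the mixed model."""

    follow_id: str
    avoided: int
    n_vessels: int
    compliant: bool
    group_size: int
    cohesion: str
    behaviour: str

    def __post_init__(self) -> None:
        if self.avoided not in (0, 1):
            raise ValueError("avoided must be 0 or 1")
        if self.cohesion not in COHESION_LEVELS:
            raise ValueError(f"unknown cohesion level {self.cohesion!r}")
        if self.group_size < 1:
            raise ValueError("group_size must be positive")


@dataclass(frozen=True)
class ModelSpec:
    """A candidate fixed-effect structure.

    Every candidate also contains a fixed intercept and a random intercept by
    focal group; the parameter count k is
    1 (intercept) + sum of term dfs + 1 (random-effect variance).
    """

    terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = set(self.terms) - set(TERM_DF)
        if unknown:
            raise ValueError(f"unknown model term(s): {', '.join(sorted(unknown))}")

    @property
    def k(self) -> int:
        return 1 + sum(TERM_DF[t] for t in self.terms) + 1

    @property
    def ordered_terms(self) -> tuple[str, ...]:
        return tuple(t for t in TERM_ORDER if t in self.terms)

    @property
    def description(self) -> str:
        if not self.terms:
            return "intercept only"
        return " + ".join(self.ordered_terms)

    @classmethod
    def from_terms(cls, *terms: str) -> "ModelSpec":
        return cls(frozenset(terms))


def candidate_specs(terms: Sequence[str] = TERM_ORDER) -> list[ModelSpec]:
    """All additive subsets of the given terms (no interactions), including
    the intercept-only model — 32 candidates for the full five-term set."""
    specs = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            specs.append(ModelSpec(frozenset(combo)))
    return specs


def observations_from_follows(follows: Iterable[FocalFollow]) -> pd.DataFrame:
    """Extract avoidance observations from follows.

    A scan contributes one observation when vessels are present and a group
    response was recorded; ``avoided`` codes avoidance (1) vs non-avoidance
    (neutral or attraction, 0).
    """
    rows = []
    for f in follows:
        for s in f.scans:
            if s.n_vessels < 1 or s.response is None:
                continue
            rows.append(
                {
                    "follow_id": s.follow_id,
                    "avoided": int(s.response == "avoidance"),
                    "n_vessels": s.n_vessels,
                    "compliant": int(bool(s.compliant)),
                    "group_size": s.group_size,
                    "cohesion": s.cohesion,
                    "behaviour": s.state,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["follow_id", "avoided", "n_vessels", "compliant",
                 "group_size", "cohesion", "behaviour"],
    )


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _term_columns(term: str) -> list[str]:
    if term == "vessels":
        return ["vessels"]
    if term == "compliance":
        return ["compliance[compliant]"]
    if term == "size":
        return ["size"]
    if term == "cohesion":
        return [f"cohesion[{lv}]" for lv in COHESION_LEVELS if lv != REFERENCE["cohesion"]]
    if term == "behaviour":
        return [f"behaviour[{st}]" for st in OBSERVED_STATES if st != REFERENCE["behaviour"]]
    raise ValueError(term)


def build_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Design matrix for a spec: intercept first, then terms in canonical
    order; categorical terms are dummy-coded against their reference level
    (compliance ref = non-compliant, cohesion ref = high, behaviour ref =
    resting), numeric terms enter untransformed."""
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for term in spec.ordered_terms:
        if term == "vessels":
            cols.append(data["n_vessels"].to_numpy(dtype=float))
        elif term == "compliance":
            cols.append(data["compliant"].astype(int).to_numpy(dtype=float))
        elif term == "size":
            cols.append(data["group_size"].to_numpy(dtype=float))
        elif term == "cohesion":
            lv = data["cohesion"].astype(str)
            bad = set(lv.unique()) - set(COHESION_LEVELS)
            if bad:
                raise ValueError(f"unknown cohesion level(s): {', '.join(sorted(bad))}")
            for level in COHESION_LEVELS:
                if level != REFERENCE["cohesion"]:
                    cols.append((lv == level).to_numpy(dtype=float))
        elif term == "behaviour":
            bv = data["behaviour"].astype(str)
            bad = set(bv.unique()) - set(OBSERVED_STATES)
            if bad:
                raise ValueError(f"unknown behaviour level(s): {', '.join(sorted(bad))}")
            for st in OBSERVED_STATES:
                if st != REFERENCE["behaviour"]:
                    cols.append((bv == st).to_numpy(dtype=float))
        names.extend(_term_columns(term))
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# Laplace-approximated marginal likelihood
# ---------------------------------------------------------------------------

def _group_modes(
    eta_fixed: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_groups: int,
    sigma2: float,
    b0: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton solve for the per-group posterior modes of the random intercepts.

    Returns (modes b, negative curvature H = sum w + 1/sigma2) per group.
    """
    b = np.zeros(n_groups) if b0 is None else b0.copy()
    for _ in range(max_iter):
        eta = eta_fixed + b[groups]
        p = expit(eta)
        grad = np.bincount(groups, weights=y - p, minlength=n_groups) - b / sigma2
        H = np.bincount(groups, weights=p * (1 - p), minlength=n_groups) + 1.0 / sigma2
        step = grad / H
        b += step
        if np.max(np.abs(step)) < tol:
            break
    eta = eta_fixed + b[groups]
    p = expit(eta)
    H = np.bincount(groups, weights=p * (1 - p), minlength=n_groups) + 1.0 / sigma2
    return b, H


def laplace_marginal_loglik(
    beta: np.ndarray,
    log_sigma: float,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_groups: int,
) -> float:
    """Laplace approximation to the marginal log-likelihood.

    For each group g with random intercept b ~ N(0, sigma^2) the contribution
    is  h(b_hat) - 0.5 log(sigma^2 H)  where h is the joint log density of
    (y_g, b) and H = -h''(b_hat).
    """
    sigma = math.exp(log_sigma)
    sigma2 = sigma * sigma
    eta_fixed = X @ beta
    b, H = _group_modes(eta_fixed, y, groups, n_groups, sigma2)
    eta = eta_fixed + b[groups]
    # numerically stable Bernoulli log-likelihood
    ll_obs = np.sum(y * eta - np.logaddexp(0.0, eta))
    ll = ll_obs - np.sum(b * b) / (2.0 * sigma2) - 0.5 * np.sum(np.log(sigma2 * H))
    return float(ll)


@dataclass
class ModelFit:
    """A fitted binomial random-intercept model."""

    spec: ModelSpec
    params: pd.Series
    se: pd.Series | None
    sigma: float
    loglik: float
    n: int
    n_groups: int
    converged: bool
    boundary: bool
    x_columns: list[str]
    optimizer: str
    cov_params: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)
    # training arrays retained for prediction and residual simulation
    _X: np.ndarray | None = None
    _y: np.ndarray | None = None
    _groups: np.ndarray | None = None
    _data_ranges: dict | None = None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ModelFit({self.spec.description!r}, logLik={self.loglik:.2f}, "
            f"sigma={self.sigma:.3f}, n={self.n}, groups={self.n_groups}, "
            f"converged={self.converged})"
        )


class ConvergenceError(RuntimeError):
    """Optimisation failed or produced a degenerate fit."""


def _plain_logistic(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Ordinary logistic solution used as the deterministic start."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            beta = np.asarray(res.params, dtype=float)
            if np.all(np.isfinite(beta)):
                return beta
        except Exception:  # separation, singular design, ...
            pass
    return np.zeros(X.shape[1])


def fit_avoidance_glmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    start_sigma: float = 0.1,
    compute_se: bool = True,
) -> ModelFit:
    """Fit the binomial logit model with a per-group random intercept.

    Parameters
    ----------
    data
        One row per avoidance observation with columns ``follow_id, avoided,
        n_vessels, compliant, group_size, cohesion, behaviour`` (see
        :func:`observations_from_follows`).
    spec
        The fixed-effect structure to fit.
    start_sigma
        Random-intercept SD at the deterministic starting point; fixed
        effects start at the ordinary-logistic solution.
    compute_se
        Standard errors require a numerical Hessian; skip for speed when only
        the log-likelihood is needed (e.g. during model selection).

    The fit is deterministic given data and starting values.  A random-effect
    SD estimated at its lower boundary is flagged (the model then reduces to
    ordinary logistic regression); separation or optimiser failure raises
    :class:`ConvergenceError`.
    """
    data = data.reset_index(drop=True)
    n = len(data)
    if n < 10:
        raise ValueError(f"need >= 10 observations, got {n}")
    group_codes, group_levels = pd.factorize(data["follow_id"], sort=True)
    n_groups = len(group_levels)
    if n_groups < 1:
        raise ValueError("no grouping levels")
    if n_groups < 2:
        warnings.warn(
            "only one focal group: the random-intercept variance is not "
            "identifiable and will sit at the boundary",
            stacklevel=2,
        )
    y = data["avoided"].to_numpy(dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("avoided must be binary")
    X, names = build_design(data, spec)
    for j, name in enumerate(names[1:], start=1):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"term column {name!r} has a single observed level")

    beta0 = _plain_logistic(X, y)
    theta0 = np.concatenate([beta0, [math.log(start_sigma)]])
    p = X.shape[1]

    def nll(theta: np.ndarray) -> float:
        return -laplace_marginal_loglik(theta[:p], theta[p], X, y, group_codes, n_groups)

    bounds = [(None, None)] * p + [_LOG_SIGMA_BOUNDS]
    opt = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    if not np.all(np.isfinite(opt.x)) or not math.isfinite(opt.fun):
        raise ConvergenceError(f"optimiser produced non-finite values: {opt.message}")
    theta = opt.x
    beta_hat, sigma_hat = theta[:p], math.exp(theta[p])
    boundary = sigma_hat <= _SIGMA_FLOOR or theta[p] <= _LOG_SIGMA_BOUNDS[0] + 1e-8
    flags: list[str] = []
    if boundary:
        flags.append("random-intercept variance at boundary (~0): "
                     "fit reduces to ordinary logistic regression")
    converged = bool(opt.success) or boundary
    if not converged:
        raise ConvergenceError(f"GLMM fit did not converge: {opt.message}")
    if np.max(np.abs(beta_hat)) > 30:
        flags.append("extreme coefficient magnitude: possible separation")

    se = None
    cov = None
    if compute_se:
        se_vals, cov = _wald_se(nll, theta, p, boundary)
        if se_vals is None:
            flags.append("Hessian not positive definite: standard errors unavailable")
        else:
            se = pd.Series(se_vals, index=names)
            if not np.all(np.isfinite(se_vals)) or np.max(se_vals) > 1e3:
                flags.append("unstable standard errors: possible separation")

    fit = ModelFit(
        spec=spec,
        params=pd.Series(beta_hat, index=names),
        se=se,
        sigma=float(sigma_hat),
        loglik=float(-opt.fun),
        n=n,
        n_groups=n_groups,
        converged=converged,
        boundary=bool(boundary),
        x_columns=names,
        optimizer="L-BFGS-B on Laplace marginal likelihood",
        cov_params=cov,
        flags=flags,
        _X=X,
        _y=y,
        _groups=group_codes,
        _data_ranges=_covariate_ranges(data),
    )
    return fit


def _wald_se(nll, theta: np.ndarray, p: int, boundary: bool):
    """Standard errors from a central-difference Hessian of the negative
    log-likelihood.  At a boundary fit the log-sigma row is dropped."""
    idx = list(range(p)) if boundary else list(range(len(theta)))
    m = len(idx)
    H = np.zeros((m, m))
    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    f0 = nll(theta)
    for a in range(m):
        for b in range(a, m):
            ia, ib = idx[a], idx[b]
            tpp = theta.copy(); tpp[ia] += h[ia]; tpp[ib] += h[ib]
            tpm = theta.copy(); tpm[ia] += h[ia]; tpm[ib] -= h[ib]
            tmp = theta.copy(); tmp[ia] -= h[ia]; tmp[ib] += h[ib]
            tmm = theta.copy(); tmm[ia] -= h[ia]; tmm[ib] -= h[ib]
            H[a, b] = H[b, a] = (nll(tpp) - nll(tpm) - nll(tmp) + nll(tmm)) / (
                4.0 * h[ia] * h[ib]
            )
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None, None
    d = np.diag(cov)
    if (d <= 0).any():
        return None, None
    se_full = np.sqrt(d[:p])
    cov_beta = cov[:p, :p]
    return se_full, cov_beta


def _covariate_ranges(data: pd.DataFrame) -> dict:
    return {
        "n_vessels": (float(data["n_vessels"].min()), float(data["n_vessels"].max())),
        "group_size": (float(data["group_size"].min()), float(data["group_size"].max())),
        "n_vessels_mean": float(data["n_vessels"].mean()),
        "group_size_mean": float(data["group_size"].mean()),
    }


# ---------------------------------------------------------------------------
# information criteria and model selection
# ---------------------------------------------------------------------------

def aicc(fit: ModelFit) -> float:
    """Small-sample corrected AIC: -2 logLik + 2k + 2k(k+1)/(n-k-1).

    n is the number of response observations (not groups); the correction is
    undefined for n <= k + 1.
    """
    if not fit.converged:
        raise ValueError("AICc requires a converged fit")
    k, n = fit.spec.k, fit.n
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * fit.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(deltas: Sequence[float]) -> np.ndarray:
    """Akaike weights w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2).

    Deltas must be non-negative with at least one zero (the best model).
    """
    d = np.asarray(deltas, dtype=float)
    if (d < 0).any():
        raise ValueError("AICc differences must be non-negative")
    if not np.isclose(d.min(), 0.0):
        raise ValueError("the best model must have a delta of 0")
    w = np.exp(-d / 2.0)
    return w / w.sum()


@dataclass
class SelectionTable:
    """AICc-ranked candidate models with Akaike weights."""

    table: pd.DataFrame  # rank, description, k, aicc, delta_aicc, weight
    fits: dict[str, ModelFit]

    @property
    def best(self) -> ModelFit:
        return self.fits[self.table.iloc[0]["description"]]

    def __len__(self) -> int:
        return len(self.table)


def model_selection(
    data: pd.DataFrame,
    candidates: Sequence[ModelSpec] | None = None,
    compute_se_best: bool = True,
) -> SelectionTable:
    """Fit a candidate set on identical observations and rank by AICc.

    Defaults to all 32 additive subsets of the five terms.  Candidates that
    fail to converge (or whose AICc is undefined) are excluded with a
    warning; ties in AICc are broken by smaller k, then description.  The
    best model is refitted with standard errors when requested.
    """
    if candidates is None:
        candidates = candidate_specs()
    data = data.reset_index(drop=True)
    rows = []
    fits: dict[str, ModelFit] = {}
    for spec in candidates:
        try:
            fit = fit_avoidance_glmm(data, spec, compute_se=False)
            crit = aicc(fit)
        except (ConvergenceError, ValueError) as exc:
            warnings.warn(f"candidate {spec.description!r} excluded: {exc}", stacklevel=2)
            continue
        fits[spec.description] = fit
        rows.append({"description": spec.description, "k": spec.k,
                     "loglik": fit.loglik, "aicc": crit})
    if not rows:
        raise ConvergenceError("every candidate model failed to fit")
    tab = pd.DataFrame(rows).sort_values(
        ["aicc", "k", "description"], kind="mergesort"
    ).reset_index(drop=True)
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].iloc[0]
    tab["weight"] = akaike_weights(tab["delta_aicc"].to_numpy())
    tab.insert(0, "rank", np.arange(1, len(tab) + 1))
    if compute_se_best:
        best_desc = tab.iloc[0]["description"]
        fits[best_desc] = fit_avoidance_glmm(
            data, fits[best_desc].spec, compute_se=True
        )
    return SelectionTable(table=tab[["rank", "description", "k", "loglik",
                                     "aicc", "delta_aicc", "weight"]], fits=fits)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

@dataclass
class Prediction:
    probability: float
    lower: float
    upper: float
    eta: float
    extrapolated: bool = False


def _profile_row(fit: ModelFit, profile: Mapping[str, object]) -> tuple[np.ndarray, bool]:
    """Build one design row from a covariate profile.

    Unspecified categorical terms sit at their reference level; unspecified
    numeric terms at the training-data mean.  Returns (row, extrapolated).
    """
    ranges = fit._data_ranges or {}
    row = np.zeros(len(fit.x_columns))
    row[0] = 1.0
    extrapolated = False
    values = dict(profile)
    for j, name in enumerate(fit.x_columns):
        if name == "intercept":
            continue
        if name == "vessels":
            v = float(values.pop("n_vessels", ranges.get("n_vessels_mean", 0.0)))
            lo, hi = ranges.get("n_vessels", (v, v))
            extrapolated |= not (lo <= v <= hi)
            row[j] = v
        elif name == "size":
            v = float(values.pop("group_size", ranges.get("group_size_mean", 0.0)))
            lo, hi = ranges.get("group_size", (v, v))
            extrapolated |= not (lo <= v <= hi)
            row[j] = v
        elif name == "compliance[compliant]":
            row[j] = float(bool(values.pop("compliant", 0)))
        elif name.startswith("cohesion["):
            level = str(values.get("cohesion", REFERENCE["cohesion"]))
            if level not in COHESION_LEVELS:
                raise ValueError(f"unknown cohesion level {level!r}")
            row[j] = float(name == f"cohesion[{level}]")
        elif name.startswith("behaviour["):
            level = str(values.get("behaviour", REFERENCE["behaviour"]))
            if level not in OBSERVED_STATES:
                raise ValueError(f"unknown behaviour level {level!r}")
            row[j] = float(name == f"behaviour[{level}]")
    values.pop("cohesion", None)
    values.pop("behaviour", None)
    unused = set(values) - {"n_vessels", "group_size", "compliant"}
    if unused:
        raise ValueError(f"profile names covariates not in the model or data: "
                         f"{', '.join(sorted(map(str, unused)))}")
    return row, extrapolated


def predict_avoidance(
    fit: ModelFit,
    profile: Mapping[str, object],
    level: float = 0.95,
) -> Prediction:
    """Population-level avoidance probability for a covariate profile.

    The random intercept is set to 0 (a typical group); the Wald confidence
    band is built on the link scale from the fixed-effect covariance and
    transformed through the inverse logit.  Profiles outside the observed
    covariate range are allowed but warned as extrapolation.
    """
    if not fit.converged:
        raise ValueError("prediction requires a converged fit")
    row, extrapolated = _profile_row(fit, profile)
    if extrapolated:
        warnings.warn("profile lies outside the observed covariate range "
                      "(extrapolation)", stacklevel=2)
    eta = float(row @ fit.params.to_numpy())
    prob = 1.0 / (1.0 + math.exp(-eta))
    if fit.cov_params is None:
        return Prediction(prob, math.nan, math.nan, eta, extrapolated)
    se_eta = float(math.sqrt(max(row @ fit.cov_params @ row, 0.0)))
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = 1.0 / (1.0 + math.exp(-(eta - z * se_eta)))
    hi = 1.0 / (1.0 + math.exp(-(eta + z * se_eta)))
    return Prediction(prob, lo, hi, eta, extrapolated)


def prediction_grid(
    fit: ModelFit,
    covariate: str,
    values: Sequence[object],
    base_profile: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """Predicted avoidance curve over a grid of one covariate."""
    base = dict(base_profile or {})
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for v in values:
            pred = predict_avoidance(fit, {**base, covariate: v})
            rows.append({covariate: v, "probability": pred.probability,
                         "lower": pred.lower, "upper": pred.upper})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simulation-based residual diagnostics
# ---------------------------------------------------------------------------

@dataclass
class ResidualDiagnostics:
    residuals: np.ndarray  # scaled to [0, 1]
    ks_statistic: float
    ks_pvalue: float
    n_sim: int

    @property
    def uniform_ok(self) -> bool:
        return self.ks_pvalue >= 0.05


def simulate_scaled_residuals(
    fit: ModelFit,
    n_sim: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> ResidualDiagnostics:
    """Simulation-based scaled (randomised quantile) residuals.

    ``n_sim`` response vectors are simulated from the fitted model with the
    random intercepts redrawn from N(0, sigma^2); each observed response is
    scaled by its randomised rank within its simulated distribution,
    r_i = (#{sim < obs} + U * (#{sim = obs} + 1)) / (n_sim + 1), which is
    uniform on [0, 1] when the model is correct.  Uniformity is summarised
    with a Kolmogorov-Smirnov test.
    """
    if fit._X is None or fit._y is None or fit._groups is None:
        raise ValueError("fit does not retain its training data")
    if n_sim < 100:
        warnings.warn("n_sim < 100 gives unstable scaled residuals", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X, y, groups = fit._X, fit._y.astype(int), fit._groups
    eta_fixed = X @ fit.params.to_numpy()
    b = rng.normal(0.0, fit.sigma, size=(n_sim, fit.n_groups))
    eta = eta_fixed[None, :] + b[:, groups]
    p = expit(eta)
    sims = (rng.random(p.shape) < p).astype(int)  # (n_sim, n_obs)
    less = (sims < y[None, :]).sum(axis=0)
    equal = (sims == y[None, :]).sum(axis=0)
    u = rng.random(len(y))
    residuals = (less + u * (equal + 1)) / (n_sim + 1)
    ks = stats.kstest(residuals, "uniform")
    return ResidualDiagnostics(
        residuals=residuals,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        n_sim=n_sim,
    )


def residual_predictor_test(
    residuals: np.ndarray,
    covariate: np.ndarray,
) -> tuple[float, float]:
    """Scaled residuals against a predictor: two-sample KS across the median
    split of the covariate.

    The pooled residual distribution stays uniform whenever average response
    rates are matched, even under a badly misspecified mean structure, so an
    omitted covariate is only visible *conditional* on that covariate — the
    analogue of plotting simulation residuals against each predictor.
    Returns (statistic, p-value).
    """
    residuals = np.asarray(residuals, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if residuals.shape != covariate.shape:
        raise ValueError("residuals and covariate must have the same length")
    cut = np.median(covariate)
    lo, hi = residuals[covariate <= cut], residuals[covariate > cut]
    if len(lo) == 0 or len(hi) == 0:
        raise ValueError("covariate has no variation across the median split")
    res = stats.ks_2samp(lo, hi)
    return float(res.statistic), float(res.pvalue)
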