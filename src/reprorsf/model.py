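"""Reproductive-state-varying resource selection model.

Used and available locations are contrasted with a Bernoulli logistic
(use-availability) likelihood in which each selection coefficient may shift
abruptly at parturition and relax back with days since parturition following
a half-normal decay:

    logit p = beta0 + sum_n beta_n(t) * x_n

    beta_n(t) = beta_base_n                                   (no dependent young)
    beta_n(t) = beta_base_n + gamma_n * exp(-Part^2/(2 sigma_n^2))   ("baseline_return")
    beta_n(t) = (beta_base_n + gamma_n) * exp(-Part^2/(2 sigma_n^2)) ("literal_zero")

where ``Part`` is days since parturition, ``gamma_n`` the post-parturition
offset and ``sigma_n`` the half-normal scale (the return "half-life"; twice
sigma is reported as the effective return time). The two decay modes differ
only in their long-time limit: ``baseline_return`` relaxes to the baseline
coefficient, ``literal_zero`` to zero selection; both equal
``beta_base + gamma`` at Part = 0.

Maximum-likelihood fits (sigma on the log scale) feed AICc-based backward
stepwise selection; the Bayesian treatment of the same likelihood lives in
:mod:`reprorsf.bayes`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ModelSpec",
    "ModelData",
    "MLFit",
    "beta_t",
    "linear_predictor",
    "neg_log_likelihood",
    "neg_log_likelihood_matched",
    "fit_ml",
    "aicc",
    "backward_stepwise",
]

DECAY_MODES = ("baseline_return", "literal_zero")


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter the model and which carry the parturition term."""

    covariates: tuple[str, ...]
    time_varying: tuple[str, ...] = ()
    decay_mode: str = "baseline_return"
    intercept: bool = True

    def __post_init__(self):
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "time_varying", tuple(self.time_varying))
        if self.decay_mode not in DECAY_MODES:
            raise ValueError(f"decay_mode must be one of {DECAY_MODES}")
        missing = set(self.time_varying) - set(self.covariates)
        if missing:
            raise ValueError(f"time-varying covariates not in model: {sorted(missing)}")

    @property
    def param_names(self) -> list[str]:
        names = ["beta0"] if self.intercept else []
        names += [f"beta_{c}" for c in self.covariates]
        names += [f"gamma_{c}" for c in self.time_varying]
        names += [f"sigma_{c}" for c in self.time_varying]
        return names

    @property
    def n_params(self) -> int:
        return int(self.intercept) + len(self.covariates) + 2 * len(self.time_varying)

    def to_dict(self) -> dict:
        return {
            "covariates": list(self.covariates),
            "time_varying": list(self.time_varying),
            "decay_mode": self.decay_mode,
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            tuple(d["covariates"]),
            tuple(d.get("time_varying", ())),
            d.get("decay_mode", "baseline_return"),
            d.get("intercept", True),
        )


@dataclass
class ModelData:
    """Pre-extracted design arrays for fast repeated likelihood evaluation."""

    X: np.ndarray            # (n, n_cov) standardized covariates, spec order
    lamb: np.ndarray         # (n,) 0/1 dependent-young indicator
    part: np.ndarray         # (n,) days since parturition (0 where lamb == 0)
    case: np.ndarray         # (n,) 1 = used, 0 = available
    covariates: tuple[str, ...]
    stratum: np.ndarray | None = None  # contiguous ids linking used fix + availables

    @property
    def n(self) -> int:
        return self.case.size

    @classmethod
    def from_table(cls, table: pd.DataFrame, spec: ModelSpec) -> "ModelData":
        missing = [c for c in spec.covariates if c not in table.columns]
        if missing:
            raise ValueError(f"covariates missing from table: {missing}")
        X = table[list(spec.covariates)].to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("non-finite covariate values in table")
        case = table["case"].to_numpy(dtype=float)
        if not np.isin(case, (0.0, 1.0)).all():
            raise ValueError("case column must be 0/1")
        lamb = (
            table["lamb"].to_numpy(dtype=float)
            if "lamb" in table.columns
            else np.zeros(len(table))
        )
        part = (
            np.nan_to_num(table["part"].to_numpy(dtype=float))
            if "part" in table.columns
            else np.zeros(len(table))
        )
        if (part < 0).any():
            raise ValueError("days-since-parturition must be non-negative")
        stratum = None
        if "stratum" in table.columns:
            _, stratum = np.unique(table["stratum"].to_numpy(), return_inverse=True)
        return cls(X, lamb, part, case, spec.covariates, stratum)

    def subset(self, spec: ModelSpec) -> "ModelData":
        idx = [self.covariates.index(c) for c in spec.covariates]
        return ModelData(
            self.X[:, idx], self.lamb, self.part, self.case, spec.covariates, self.stratum
        )


# ---------------------------------------------------------------------------
# process model


def beta_t(beta_base, gamma, sigma, lamb, part_days, decay_mode="baseline_return"):
    """Time-varying selection coefficient; broadcasts over array inputs."""
    lamb = np.asarray(lamb, dtype=float)
    part = np.asarray(part_days, dtype=float)
    if (part < 0).any():
        raise ValueError("part_days must be non-negative")
    sigma = np.asarray(sigma, dtype=float)
    if np.any((np.asarray(lamb) == 1) & (sigma <= 0)):
        raise ValueError("sigma must be positive while provisioning")
    decay = np.exp(-(part**2) / (2.0 * sigma**2))
    if decay_mode == "baseline_return":
        out = beta_base + lamb * gamma * decay
    elif decay_mode == "literal_zero":
        out = (1.0 - lamb) * beta_base + lamb * (beta_base + gamma) * decay
    else:
        raise ValueError(f"unknown decay_mode {decay_mode!r}")
    return out


def _unpack(params: dict, spec: ModelSpec):
    beta0 = float(params.get("beta0", 0.0)) if spec.intercept else 0.0
    beta = np.array([params[f"beta_{c}"] for c in spec.covariates], dtype=float)
    gamma = np.array([params[f"gamma_{c}"] for c in spec.time_varying], dtype=float)
    sigma = np.array([params[f"sigma_{c}"] for c in spec.time_varying], dtype=float)
    return beta0, beta, gamma, sigma


def _eta(data: ModelData, spec: ModelSpec, beta0, beta, gamma, sigma) -> np.ndarray:
    """Linear predictor for every row, vectorised over the table."""
    eta = np.full(data.n, beta0)
    tv = {c: i for i, c in enumerate(spec.time_varying)}
    for j, c in enumerate(spec.covariates):
        x = data.X[:, j]
        if c in tv:
            k = tv[c]
            b = beta_t(beta[j], gamma[k], sigma[k], data.lamb, data.part, spec.decay_mode)
            eta += b * x
        else:
            eta += beta[j] * x
    return eta


def linear_predictor(row, params: dict, spec: ModelSpec) -> float:
    """Logit-scale predictor for one table row (mapping or pandas Series)."""
    beta0, beta, gamma, sigma = _unpack(params, spec)
    for c in spec.covariates:
        if c not in row:
            raise ValueError(f"row is missing covariate {c!r}")
    lamb = float(row.get("lamb", 0.0))
    part = float(row.get("part", 0.0) or 0.0)
    eta = beta0
    tv = {c: i for i, c in enumerate(spec.time_varying)}
    for j, c in enumerate(spec.covariates):
        if c in tv:
            k = tv[c]
            b = float(beta_t(beta[j], gamma[k], sigma[k], lamb, part, spec.decay_mode))
        else:
            b = beta[j]
        eta += b * float(row[c])
    return float(eta)


def neg_log_likelihood(params: dict, table, spec: ModelSpec) -> float:
    """Bernoulli negative log-likelihood, numerically stabilised."""
    data = table if isinstance(table, ModelData) else ModelData.from_table(table, spec)
    beta0, beta, gamma, sigma = _unpack(params, spec)
    return _nll_arrays(data, spec, beta0, beta, gamma, sigma)


def _nll_arrays(data, spec, beta0, beta, gamma, sigma) -> float:
    eta = _eta(data, spec, beta0, beta, gamma, sigma)
    # log(1 + e^eta) - y*eta, via logaddexp for stability at extreme logits
    return float(np.sum(np.logaddexp(0.0, eta) - data.case * eta))


def neg_log_likelihood_matched(params: dict, table, spec: ModelSpec) -> float:
    """Matched (conditional-logit) negative log-likelihood.

    Each stratum — one used fix plus its matched available points — enters
    as a discrete choice: the used row's probability is
    ``exp(eta_used) / sum_i exp(eta_i)`` over the stratum. The intercept
    cancels within strata, and the time-varying normaliser that a pooled
    single-intercept Bernoulli fit cannot absorb is handled exactly, which
    makes this the correctly specified estimator for weighted-candidate
    choice data.
    """
    data = table if isinstance(table, ModelData) else ModelData.from_table(table, spec)
    beta0, beta, gamma, sigma = _unpack(params, spec)
    return _matched_nll_arrays(data, spec, beta0, beta, gamma, sigma)


def _matched_nll_arrays(data, spec, beta0, beta, gamma, sigma) -> float:
    if data.stratum is None:
        raise ValueError("matched likelihood requires a stratum column")
    s = data.stratum
    ns = int(s.max()) + 1
    eta = _eta(data, spec, beta0, beta, gamma, sigma)
    m = np.full(ns, -np.inf)
    np.maximum.at(m, s, eta)
    e = np.exp(eta - m[s])
    denom = np.zeros(ns)
    np.add.at(denom, s, e)
    used = data.case == 1
    lognum = eta[used] - m[s[used]]
    return float(np.sum(np.log(denom[s[used]])) - np.sum(lognum))


# ---------------------------------------------------------------------------
# maximum likelihood


@dataclass
class MLFit:
    spec: ModelSpec
    params: dict[str, float]
    loglik: float
    k: int
    n_obs: int
    aicc: float
    converged: bool
    grad_norm: float = np.nan
    separation_flag: bool = False
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "params": self.params,
            "loglik": self.loglik,
            "k": self.k,
            "n_obs": self.n_obs,
            "aicc": self.aicc,
            "converged": self.converged,
            "grad_norm": self.grad_norm,
            "separation_flag": self.separation_flag,
            "message": self.message,
        }


def _theta_to_params(theta: np.ndarray, spec: ModelSpec) -> dict[str, float]:
    """Optimizer vector -> natural-scale parameter dict (sigma from log)."""
    out: dict[str, float] = {}
    i = 0
    if spec.intercept:
        out["beta0"] = float(theta[0])
        i = 1
    for c in spec.covariates:
        out[f"beta_{c}"] = float(theta[i])
        i += 1
    for c in spec.time_varying:
        out[f"gamma_{c}"] = float(theta[i])
        i += 1
    for c in spec.time_varying:
        out[f"sigma_{c}"] = float(np.exp(theta[i]))
        i += 1
    return out


def fit_ml(
    table,
    spec: ModelSpec,
    init: dict[str, float] | None = None,
    sigma_init: float = 15.0,
    gamma_init: float = 0.2,
    sigma_bounds: tuple[float, float] = (0.5, 300.0),
    maxiter: int = 500,
    separation_beta: float = 15.0,
    likelihood: str = "bernoulli",
) -> MLFit:
    """Maximise the likelihood with L-BFGS-B (sigma optimised on log scale).

    Deterministic given the data and the starting values. Non-convergence
    and perfect-separation symptoms (any |beta| exceeding
    ``separation_beta``) are flagged, not raised. ``likelihood`` selects
    the pooled Bernoulli objective (default) or the matched
    conditional-logit one (requires stratum ids; intercept unidentified).
    """
    if likelihood not in ("bernoulli", "matched"):
        raise ValueError("likelihood must be 'bernoulli' or 'matched'")
    nll_fn = _nll_arrays if likelihood == "bernoulli" else _matched_nll_arrays
    data = table if isinstance(table, ModelData) else ModelData.from_table(table, spec)
    n_tv = len(spec.time_varying)
    p = spec.n_params
    theta0 = np.zeros(p)
    # gamma entries start away from zero so sigma's direction is identified
    off = int(spec.intercept) + len(spec.covariates)
    theta0[off : off + n_tv] = gamma_init
    theta0[off + n_tv :] = np.log(sigma_init)
    if init is not None:
        theta0 = _params_to_theta(init, spec, theta0)

    lo = np.full(p, -np.inf)
    hi = np.full(p, np.inf)
    lo[off + n_tv :] = np.log(sigma_bounds[0])
    hi[off + n_tv :] = np.log(sigma_bounds[1])

    def objective(theta):
        params = _theta_to_params(theta, spec)
        beta0, beta, gamma, sigma = _unpack(params, spec)
        return nll_fn(data, spec, beta0, beta, gamma, sigma)

    res = optimize.minimize(
        objective,
        theta0,
        method="L-BFGS-B",
        bounds=list(zip(lo, hi)),
        options={"maxiter": maxiter},
    )
    params = _theta_to_params(res.x, spec)
    loglik = -float(res.fun)
    k = spec.n_params
    n = data.n
    betas = [v for name, v in params.items() if name.startswith(("beta", "gamma"))]
    sep = bool(np.max(np.abs(betas)) > separation_beta) if betas else False
    return MLFit(
        spec=spec,
        params=params,
        loglik=loglik,
        k=k,
        n_obs=n,
        aicc=aicc(loglik, k, n),
        converged=bool(res.success),
        grad_norm=float(np.linalg.norm(res.jac)),
        separation_flag=sep,
        message=str(res.message),
    )


def _params_to_theta(params: dict, spec: ModelSpec, default: np.ndarray) -> np.ndarray:
    theta = default.copy()
    i = 0
    if spec.intercept:
        if "beta0" in params:
            theta[0] = params["beta0"]
        i = 1
    for c in spec.covariates:
        if f"beta_{c}" in params:
            theta[i] = params[f"beta_{c}"]
        i += 1
    for c in spec.time_varying:
        if f"gamma_{c}" in params:
            theta[i] = params[f"gamma_{c}"]
        i += 1
    for c in spec.time_varying:
        if f"sigma_{c}" in params:
            theta[i] = np.log(params[f"sigma_{c}"])
        i += 1
    return theta


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with the small-sample correction."""
    if n <= k + 1:
        raise ValueError("AICc requires n > k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# backward stepwise selection


def _candidate_moves(spec: ModelSpec) -> list[tuple[str, ModelSpec]]:
    """One-step simplifications, in a fixed (alphabetical) order.

    A time-varying covariate first loses its (gamma, sigma) block; a
    time-constant covariate is a candidate for full removal. The intercept
    is never dropped.
    """
    moves: list[tuple[str, ModelSpec]] = []
    for c in sorted(spec.time_varying):
        moves.append(
            (
                f"drop_tv:{c}",
                replace(spec, time_varying=tuple(t for t in spec.time_varying if t != c)),
            )
        )
    for c in sorted(set(spec.covariates) - set(spec.time_varying)):
        moves.append(
            (
                f"drop:{c}",
                replace(spec, covariates=tuple(t for t in spec.covariates if t != c)),
            )
        )
    return moves


def backward_stepwise(
    table,
    full_spec: ModelSpec,
    delta: float = 2.0,
    rule: str = "uninformative",
    **fit_kwargs,
) -> tuple[ModelSpec, MLFit, pd.DataFrame]:
    """AICc backward elimination of uninformative terms.

    At each step every one-term simplification is refit. Under the default
    ``rule="uninformative"`` (Arnold-style), a term is dispensable when
    keeping it fails to lower AICc by more than ``delta`` relative to the
    model without it; the candidate with the lowest AICc is dropped as long
    as that removal costs less than ``delta`` AICc, and the search stops
    once every removal would worsen AICc by at least ``delta``. Under
    ``rule="strict_improvement"`` a removal must itself *lower* AICc by at
    least ``delta`` (so ``delta=inf`` returns the full model unchanged).

    Returns the selected spec, its fit, and the full trace of candidate
    AICc values. Candidates that fail to converge are skipped with a note.
    """
    if rule not in ("uninformative", "strict_improvement"):
        raise ValueError("rule must be 'uninformative' or 'strict_improvement'")
    data = table if isinstance(table, ModelData) else ModelData.from_table(table, full_spec)
    current = full_spec
    current_fit = fit_ml(data.subset(current), current, **fit_kwargs)
    rows = [
        {"step": 0, "move": "(full)", "aicc": current_fit.aicc, "applied": True, "note": ""}
    ]
    step = 0
    while True:
        step += 1
        best: tuple[str, ModelSpec, MLFit] | None = None
        for move, cand in _candidate_moves(current):
            if not cand.covariates:
                continue
            fit = fit_ml(data.subset(cand), cand, **fit_kwargs)
            note = "" if fit.converged else "non-convergent; skipped"
            rows.append(
                {"step": step, "move": move, "aicc": fit.aicc, "applied": False, "note": note}
            )
            if not fit.converged:
                continue
            if best is None or fit.aicc < best[2].aicc:
                best = (move, cand, fit)
        if best is None:
            break
        if rule == "uninformative":
            accept = best[2].aicc - current_fit.aicc < delta
        else:
            accept = current_fit.aicc - best[2].aicc >= delta
        if not accept:
            break
        move, current, current_fit = best
        for r in rows:
            if r["step"] == step and r["move"] == move:
                r["applied"] = True
    return current, current_fit, pd.DataFrame(rows)
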