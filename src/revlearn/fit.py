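"""Hierarchical model fitting: per-subject MAP under an empirical Gaussian
prior, prior refinement by expectation-maximization, and model comparison by
the integrated Bayesian information criterion (iBIC).

The empirical prior is a diagonal Gaussian over each model's *transformed*
(unconstrained) parameters.  The E-step finds each subject's MAP estimate and
its Laplace curvature; the M-step re-estimates the prior moments from the
MAPs plus their posterior variances.  The iBIC approximates each subject's
marginal likelihood under the fitted prior by Monte-Carlo integration and
penalizes the number of prior hyperparameters (two per parameter) against the
total number of observed choices.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator

from .models import ModelSpec, Params, _nll_batch, _nll_grad
from .task import SessionData

__all__ = [
    "Prior",
    "SubjectFit",
    "GroupFit",
    "map_fit",
    "em_group_fit",
    "ibic",
    "compare_models",
    "HierarchicalModel",
]

VARIANCE_FLOOR = 1e-6


class FitNonConvergenceError(RuntimeError):
    """All MAP restarts failed; carries the best fit found so far."""

    def __init__(self, message: str, best: "SubjectFit | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class Prior:
    """Diagonal Gaussian over a model's transformed parameters."""

    spec: ModelSpec
    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "var", np.asarray(self.var, dtype=float))
        if self.mean.shape != (self.spec.n_params,) or self.var.shape != self.mean.shape:
            raise ValueError("prior dimension does not match the model spec")
        if np.any(self.var <= 0):
            raise ValueError("prior variances must be positive")

    @classmethod
    def default(cls, spec: ModelSpec, mean: float = 0.0, var: float = 6.25) -> "Prior":
        return cls(spec, np.full(spec.n_params, mean), np.full(spec.n_params, var))

    def logpdf(self, x: np.ndarray) -> float:
        z = (x - self.mean) ** 2 / self.var
        return float(-0.5 * np.sum(z + np.log(2.0 * np.pi * self.var)))

    def logpdf_grad(self, x: np.ndarray) -> np.ndarray:
        return -(x - self.mean) / self.var

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.normal(self.mean, np.sqrt(self.var), size=(n, self.spec.n_params))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.spec.param_names,
                "mean": self.mean,
                "variance": self.var,
            }
        )


@dataclass
class SubjectFit:
    subject: str
    wave: int
    spec: ModelSpec
    transformed: np.ndarray
    log_joint: float
    loglik: float
    hessian: np.ndarray
    posterior_var: np.ndarray
    hessian_pd: bool
    converged: bool

    @property
    def params(self) -> Params:
        return Params.from_transformed(self.spec, self.transformed)

    @property
    def natural(self) -> dict[str, float]:
        return self.params.to_natural_dict()


@dataclass
class GroupFit:
    spec: ModelSpec
    prior: Prior
    subject_fits: list[SubjectFit]
    total_choices: int
    n_iter: int = 0
    converged: bool = False
    log_joint_trace: list[float] = field(default_factory=list)
    variance_floor_hits: int = 0
    ibic: float | None = None

    @property
    def n_hyperparams(self) -> int:
        return 2 * self.spec.n_params

    def params_frame(self) -> pd.DataFrame:
        """Tidy per-subject parameter table (natural and transformed)."""
        rows = []
        for f in self.subject_fits:
            for name, tval in zip(self.spec.param_names, f.transformed):
                rows.append(
                    {
                        "subject": f.subject,
                        "wave": f.wave,
                        "parameter": name,
                        "natural_value": f.natural[name],
                        "transformed_value": tval,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fast transformed-space objective (no Params construction per evaluation)


def _x_to_nat5(spec: ModelSpec, x: np.ndarray) -> np.ndarray:
    """Map a transformed vector to canonical naturals
    [alpha_win, alpha_loss, rho_win, rho_loss, beta]."""
    if spec.n_learning_rates == 1:
        aw = al = expit(x[0])
        i = 1
    else:
        aw, al = expit(x[0]), expit(x[1])
        i = 2
    if spec.sensitivity_kind == "choice":
        rw, rl, beta = 1.0, -1.0, math.exp(min(x[i], 30.0))
    elif spec.n_sensitivities == 1:
        rw, rl, beta = x[i], -x[i], 1.0
    else:
        rw, rl, beta = x[i], x[i + 1], 1.0
    return np.array([aw, al, rw, rl, beta])


def _chain_grad(spec: ModelSpec, nat5: np.ndarray, g5: np.ndarray) -> np.ndarray:
    """Convert a gradient w.r.t. canonical naturals into one w.r.t. the
    transformed vector."""
    aw, al, beta = nat5[0], nat5[1], nat5[4]
    grad = np.empty(spec.n_params)
    if spec.n_learning_rates == 1:
        grad[0] = (g5[0] + g5[1]) * aw * (1.0 - aw)
        i = 1
    else:
        grad[0] = g5[0] * aw * (1.0 - aw)
        grad[1] = g5[1] * al * (1.0 - al)
        i = 2
    if spec.sensitivity_kind == "choice":
        grad[i] = g5[4] * beta
    elif spec.n_sensitivities == 1:
        grad[i] = g5[2] - g5[3]
    else:
        grad[i], grad[i + 1] = g5[2], g5[3]
    return grad


def _neg_log_joint_factory(choices, outcomes, spec: ModelSpec, prior: Prior):
    du = 1 if spec.update_rule == "DU" else 0

    def f(x: np.ndarray):
        nat5 = _x_to_nat5(spec, x)
        nll, g5 = _nll_grad(choices, outcomes, nat5, du)
        val = nll - prior.logpdf(x)
        grad = _chain_grad(spec, nat5, g5) - prior.logpdf_grad(x)
        return val, grad

    return f


def _fd_hessian(grad_fn, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.empty((n, n))
    for j in range(n):
        xp, xm = x.copy(), x.copy()
        xp[j] += eps
        xm[j] -= eps
        H[:, j] = (grad_fn(xp)[1] - grad_fn(xm)[1]) / (2.0 * eps)
    return 0.5 * (H + H.T)


def _posterior_var(H: np.ndarray) -> tuple[np.ndarray, bool]:
    """Diagonal of the Laplace posterior covariance (inverse Hessian)."""
    try:
        np.linalg.cholesky(H)
        pd_flag = True
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        pd_flag = False
        cov = np.linalg.pinv(H)
    var = np.abs(np.diag(cov))
    return np.maximum(var, VARIANCE_FLOOR), pd_flag


def map_fit(
    session: SessionData,
    spec: ModelSpec,
    prior: Prior,
    n_restarts: int = 5,
    seed: int | np.random.SeedSequence = 0,
    extra_starts: list[np.ndarray] | None = None,
) -> SubjectFit:
    """Per-subject maximum a posteriori fit in transformed space.

    Restart 0 starts from the prior mean, the others from prior draws; the
    best local optimum wins.  The Hessian of the negative log joint at the
    optimum supplies the Laplace posterior covariance.
    """
    if prior.spec != spec:
        raise ValueError("prior spec does not match the model spec")
    choices, outcomes = session.choices, session.outcomes
    n_resp = int(np.sum(choices >= 0))

    if n_resp == 0:
        # Prior-only posterior: MAP is exactly the prior mean.
        H = np.diag(1.0 / prior.var)
        return SubjectFit(
            subject=session.subject, wave=session.wave, spec=spec,
            transformed=prior.mean.copy(), log_joint=prior.logpdf(prior.mean),
            loglik=0.0, hessian=H, posterior_var=prior.var.copy(),
            hessian_pd=True, converged=True,
        )

    f = _neg_log_joint_factory(choices, outcomes, spec, prior)
    rng = np.random.default_rng(seed)
    starts = [prior.mean.copy()]
    starts += list(prior.sample(rng, max(0, n_restarts - 1)))
    if extra_starts:
        starts = list(extra_starts) + starts
    bounds = []
    for name in spec.param_names:
        if name.startswith("alpha") or name == "beta":
            bounds.append((-16.0, 16.0))
        else:
            bounds.append((-60.0, 60.0))

    best, any_converged = None, False
    for x0 in starts:
        res = minimize(f, np.asarray(x0, dtype=float), jac=True,
                       method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun):
            continue
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitNonConvergenceError(
            f"all {len(starts)} MAP restarts failed for subject {session.subject}"
        )

    H = _fd_hessian(f, best.x)
    post_var, pd_flag = _posterior_var(H)
    # log joint = loglik + log prior, so loglik = -(neg log joint) - log prior
    loglik = (-best.fun) - prior.logpdf(best.x)
    fit = SubjectFit(
        subject=session.subject, wave=session.wave, spec=spec,
        transformed=best.x.copy(), log_joint=float(-best.fun),
        loglik=float(loglik), hessian=H, posterior_var=post_var,
        hessian_pd=pd_flag, converged=any_converged,
    )
    if not any_converged:
        raise FitNonConvergenceError(
            f"no MAP restart reported convergence for subject {session.subject}",
            best=fit,
        )
    return fit


def em_group_fit(
    sessions: list[SessionData],
    spec: ModelSpec,
    tol: float = 1e-3,
    max_iter: int = 200,
    n_restarts: int = 5,
    seed: int | np.random.SeedSequence = 0,
    init_prior: Prior | None = None,
) -> GroupFit:
    """Empirical-prior EM over a cohort of sessions.

    E-step: per-session MAP fits with Laplace posterior variances (full
    multi-start on the first iteration, warm-started from the previous MAP
    afterwards).  M-step: prior mean = mean of MAPs; prior variance = mean of
    (MAP^2 + posterior variance) - mean^2, floored at 1e-6.  Stops when the
    relative change of the total log joint falls below ``tol``.
    """
    if len(sessions) < 2:
        raise ValueError("EM group fit needs at least 2 sessions")
    if spec.is_random:
        raise ValueError("the random baseline has no parameters to fit")
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    base_entropy = [int(v) for v in ss.generate_state(2)]

    def subject_seed(sess: SessionData, iteration: int) -> np.random.SeedSequence:
        # keyed on subject identity, not list position, so the fit is
        # invariant to subject ordering
        key = zlib.crc32(f"{sess.subject}|{sess.wave}".encode())
        return np.random.SeedSequence(base_entropy + [iteration, key])

    prior = init_prior or Prior.default(spec)
    total_choices = int(sum(s.n_responded for s in sessions))
    fits: list[SubjectFit] = []
    trace: list[float] = []
    floor_hits = 0
    converged = False
    it = 0

    for it in range(1, max_iter + 1):
        new_fits = []
        for i, sess in enumerate(sessions):
            extra = [fits[i].transformed] if fits else None
            restarts = n_restarts if it == 1 else 2
            try:
                fit = map_fit(
                    sess, spec, prior, n_restarts=restarts,
                    seed=subject_seed(sess, it),
                    extra_starts=extra,
                )
            except FitNonConvergenceError as exc:
                if exc.best is None:
                    raise
                fit = exc.best
            new_fits.append(fit)
        fits = new_fits
        total_log_joint = float(sum(f.log_joint for f in fits))
        trace.append(total_log_joint)

        m = np.array([f.transformed for f in fits])
        pv = np.array([f.posterior_var for f in fits])
        mu = m.mean(axis=0)
        var = np.mean(m**2 + pv, axis=0) - mu**2
        if np.any(var < VARIANCE_FLOOR):
            floor_hits += int(np.sum(var < VARIANCE_FLOOR))
            warnings.warn(
                f"prior variance hit the floor ({VARIANCE_FLOOR}) for "
                f"{spec.code}; clamped", RuntimeWarning, stacklevel=2,
            )
            var = np.maximum(var, VARIANCE_FLOOR)
        prior = Prior(spec, mu, var)

        if len(trace) >= 2:
            prev, cur = trace[-2], trace[-1]
            if abs(cur - prev) < tol * max(1.0, abs(prev)):
                converged = True
                break

    return GroupFit(
        spec=spec, prior=prior, subject_fits=fits, total_choices=total_choices,
        n_iter=it, converged=converged, log_joint_trace=trace,
        variance_floor_hits=floor_hits,
    )


def _stack_sessions(sessions: list[SessionData]) -> tuple[np.ndarray, np.ndarray]:
    max_len = max(len(s) for s in sessions)
    choices = np.full((len(sessions), max_len), -1, dtype=np.int8)
    outcomes = np.zeros((len(sessions), max_len), dtype=np.int8)
    for i, s in enumerate(sessions):
        c, o = s.choices, s.outcomes
        choices[i, : c.size] = c
        outcomes[i, : o.size] = o
    return choices, outcomes


def ibic(
    group_fit: GroupFit,
    sessions: list[SessionData],
    K: int = 2000,
    seed: int | np.random.SeedSequence = 0,
) -> float:
    """Integrated BIC of a fitted group model.

    -2 * sum_i log[(1/K) sum_k L_i(theta_k)] + n_hyper * log(total choices),
    with theta_k drawn from the fitted prior.  Underflow is handled by
    log-sum-exp.  The zero-parameter random baseline needs no integration.
    """
    spec = group_fit.spec
    total_choices = int(sum(s.n_responded for s in sessions))
    if spec.is_random or spec.n_params == 0:
        value = -2.0 * total_choices * math.log(0.5)
        group_fit.ibic = value
        return value
    if K < 100:
        warnings.warn(
            f"iBIC with K={K} draws is imprecise; use K >= 100",
            RuntimeWarning, stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    draws = group_fit.prior.sample(rng, K)
    nat = np.vstack([_x_to_nat5(spec, x) for x in draws])
    choices2d, outcomes2d = _stack_sessions(sessions)
    du = 1 if spec.update_rule == "DU" else 0
    nll = _nll_batch(choices2d, outcomes2d, nat, du)  # (n_sessions, K)
    log_marginal = logsumexp(-nll, axis=1) - math.log(K)
    value = float(-2.0 * np.sum(log_marginal)
                  + group_fit.n_hyperparams * math.log(total_choices))
    group_fit.ibic = value
    return value


def compare_models(
    sessions: list[SessionData],
    specs: list[ModelSpec],
    grouping: str = "joint",
    K: int = 2000,
    seed: int | np.random.SeedSequence = 0,
    **em_kwargs,
) -> pd.DataFrame:
    """Fit every candidate spec and rank by iBIC (lower is better).

    ``grouping="joint"`` pools all sessions under one empirical prior;
    ``grouping="per_wave"`` fits one prior per acquisition wave and sums the
    per-wave iBICs.  Failed fits are recorded with NaN, not raised.
    """
    if len(specs) < 2:
        raise ValueError("model comparison needs at least 2 candidate specs")
    if grouping not in ("joint", "per_wave"):
        raise ValueError(f"unknown grouping {grouping!r}")
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    groups: dict[str, list[SessionData]]
    if grouping == "joint":
        groups = {"all": list(sessions)}
    else:
        groups = {}
        for s in sessions:
            groups.setdefault(f"wave{s.wave}", []).append(s)

    rows = []
    for spec, spec_ss in zip(specs, ss.spawn(len(specs))):
        total, ok, n_groups_fit = 0.0, True, 0
        err = ""
        for (gname, gsessions), g_ss in zip(groups.items(), spec_ss.spawn(len(groups))):
            try:
                if spec.is_random:
                    gf = GroupFit(
                        spec=spec, prior=None, subject_fits=[],  # type: ignore[arg-type]
                        total_choices=sum(s.n_responded for s in gsessions),
                    )
                else:
                    gf = em_group_fit(gsessions, spec, seed=g_ss, **em_kwargs)
                total += ibic(gf, gsessions, K=K, seed=g_ss)
                n_groups_fit += 1
            except Exception as exc:  # noqa: BLE001 — recorded, not fatal
                ok = False
                err = f"{type(exc).__name__}: {exc}"
                break
        rows.append(
            {
                "model": spec.code,
                "grouping": grouping,
                "n_groups": n_groups_fit,
                "ibic": total if ok else np.nan,
                "error": err,
            }
        )
    table = pd.DataFrame(rows)
    best = table["ibic"].min()
    table["delta_ibic"] = table["ibic"] - best
    return table.sort_values("delta_ibic").reset_index(drop=True)


class HierarchicalModel(BaseEstimator):
    """sklearn-style wrapper around the empirical-prior EM group fit.

    Parameters
    ----------
    spec : str or ModelSpec
        Model variant, e.g. ``"DU-2rho-1alpha"``.
    tol, max_iter, n_restarts : EM / MAP optimizer settings.
    ibic_draws : Monte-Carlo draws for the iBIC integral.
    random_state : seed for restarts and the iBIC integral.

    Fitted attributes: ``prior_``, ``subject_fits_``, ``group_fit_``,
    ``ibic_``, ``n_iter_``, ``converged_``.
    """

    def __init__(
        self,
        spec: str | ModelSpec = "DU-2rho-1alpha",
        tol: float = 1e-3,
        max_iter: int = 200,
        n_restarts: int = 5,
        ibic_draws: int = 2000,
        random_state: int = 0,
    ):
        self.spec = spec
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.ibic_draws = ibic_draws
        self.random_state = random_state

    def _spec(self) -> ModelSpec:
        return (
            self.spec if isinstance(self.spec, ModelSpec)
            else ModelSpec.from_code(self.spec)
        )

    def fit(self, X: list[SessionData], y=None) -> "HierarchicalModel":
        if not isinstance(X, (list, tuple)) or not all(
            isinstance(s, SessionData) for s in X
        ):
            raise TypeError("X must be a list of SessionData")
        ss = np.random.SeedSequence(self.random_state)
        em_ss, ibic_ss = ss.spawn(2)
        gf = em_group_fit(
            list(X), self._spec(), tol=self.tol, max_iter=self.max_iter,
            n_restarts=self.n_restarts, seed=em_ss,
        )
        self.ibic_ = ibic(gf, list(X), K=self.ibic_draws, seed=ibic_ss)
        self.group_fit_ = gf
        self.prior_ = gf.prior
        self.subject_fits_ = gf.subject_fits
        self.n_iter_ = gf.n_iter
        self.converged_ = gf.converged
        return self

    def params_frame(self) -> pd.DataFrame:
        return self.group_fit_.params_frame()
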