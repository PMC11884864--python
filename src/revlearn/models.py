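"""Rescorla-Wagner model family for probabilistic reversal learning.

The family crosses three axes:

* update rule — single-update (SU: only the chosen stimulus's expected value
  moves) vs double-update (DU: the unchosen value simultaneously moves toward
  the sign-flipped outcome, capturing the task's counterfactual structure);
* sensitivity kind — *choice* sensitivity (outcomes coded +/-1, free softmax
  slope beta) vs *reinforcement* sensitivity (free signed outcome value(s)
  rho, beta fixed to 1, so rho bounds the attainable value difference and
  thereby puts a floor on choice stochasticity);
* one or two learning rates (alpha, or alpha_win / alpha_loss).

The winning model in this line of work is DU with two reinforcement
sensitivities and one learning rate ("DU-2rho-1alpha").

Fitting happens in an unconstrained transformed space: alpha is logistic-
transformed, beta log-transformed, rho left as-is.  The likelihood recursion
and its analytic gradient are numba-compiled; a plain-Python replay
(`update_values` / `choice_probability`) provides the readable reference
path used by tests and trial-latent extraction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .task import SessionData, TaskConfig, TaskState, step

__all__ = [
    "ModelSpec",
    "Params",
    "update_values",
    "choice_probability",
    "session_loglik",
    "session_loglik_grad",
    "simulate_subject",
    "trial_latents",
    "candidate_specs",
]

_KIND_CHOICE = 0
_KIND_REINF = 1  # shared magnitude: r = rho * outcome_sign


@dataclass(frozen=True)
class ModelSpec:
    """One member of the model family.

    ``sensitivity_kind`` is "choice", "reinforcement", or "random" (a
    zero-parameter coin-flip baseline used for reference likelihoods).
    """

    update_rule: str = "DU"
    sensitivity_kind: str = "reinforcement"
    n_sensitivities: int = 2
    n_learning_rates: int = 1

    def __post_init__(self) -> None:
        if self.sensitivity_kind == "random":
            return
        if self.update_rule not in ("SU", "DU"):
            raise ValueError(f"unknown update rule {self.update_rule!r}")
        if self.sensitivity_kind not in ("choice", "reinforcement"):
            raise ValueError(f"unknown sensitivity kind {self.sensitivity_kind!r}")
        if self.sensitivity_kind == "choice" and self.n_sensitivities != 1:
            raise ValueError("choice-sensitivity models have a single beta")
        if self.n_sensitivities not in (1, 2) or self.n_learning_rates not in (1, 2):
            raise ValueError("n_sensitivities and n_learning_rates must be 1 or 2")

    # -- parameter bookkeeping -------------------------------------------
    @property
    def param_names(self) -> tuple[str, ...]:
        if self.sensitivity_kind == "random":
            return ()
        names: list[str] = (
            ["alpha"] if self.n_learning_rates == 1 else ["alpha_win", "alpha_loss"]
        )
        if self.sensitivity_kind == "choice":
            names.append("beta")
        elif self.n_sensitivities == 1:
            names.append("rho")
        else:
            names += ["rho_win", "rho_loss"]
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def code(self) -> str:
        if self.sensitivity_kind == "random":
            return "random"
        sens = (
            "beta"
            if self.sensitivity_kind == "choice"
            else f"{self.n_sensitivities}rho"
        )
        return f"{self.update_rule}-{sens}-{self.n_learning_rates}alpha"

    @classmethod
    def from_code(cls, code: str) -> "ModelSpec":
        if code == "random":
            return cls.random()
        try:
            rule, sens, alpha = code.split("-")
            n_alpha = int(alpha.replace("alpha", ""))
            if sens == "beta":
                return cls(rule, "choice", 1, n_alpha)
            return cls(rule, "reinforcement", int(sens.replace("rho", "")), n_alpha)
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"cannot parse model code {code!r}") from exc

    @classmethod
    def random(cls) -> "ModelSpec":
        return cls(update_rule="none", sensitivity_kind="random",
                   n_sensitivities=0, n_learning_rates=0)

    @property
    def is_random(self) -> bool:
        return self.sensitivity_kind == "random"

    def __str__(self) -> str:  # pragma: no cover
        return self.code


def candidate_specs() -> list[ModelSpec]:
    """The combinatorial candidate set for model comparison:
    {SU, DU} x {choice beta, reinforcement 1rho, reinforcement 2rho} x {1, 2 alpha}.
    """
    specs = []
    for rule, sens, n_a in itertools.product(
        ("SU", "DU"), ("beta", "1rho", "2rho"), (1, 2)
    ):
        specs.append(ModelSpec.from_code(f"{rule}-{sens}-{n_a}alpha"))
    return specs


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@dataclass(frozen=True)
class Params:
    """Natural-scale parameter values for a given :class:`ModelSpec`.

    ``alpha_loss`` mirrors ``alpha_win`` for one-learning-rate specs; for
    one-sensitivity specs ``rho_loss = -rho_win``.  ``beta`` is 1 unless the
    spec is choice-sensitivity kind.
    """

    spec: ModelSpec
    alpha_win: float = 0.5
    alpha_loss: float = 0.5
    rho_win: float = 1.0
    rho_loss: float = -1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        for a in (self.alpha_win, self.alpha_loss):
            if not 0.0 < a < 1.0:
                raise ValueError(f"learning rate {a} outside (0, 1)")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @classmethod
    def from_natural(cls, spec: ModelSpec, **kwargs: float) -> "Params":
        """Build from the spec's named parameters (e.g. alpha=, rho_win=)."""
        vals = dict(kwargs)
        out: dict[str, float] = {}
        if "alpha" in vals:
            out["alpha_win"] = out["alpha_loss"] = vals.pop("alpha")
        if "rho" in vals:
            rho = vals.pop("rho")
            out["rho_win"], out["rho_loss"] = rho, -rho
        out.update(vals)
        if spec.n_learning_rates == 2 and "alpha_loss" not in out:
            raise ValueError("two-learning-rate spec needs alpha_win and alpha_loss")
        if spec.sensitivity_kind == "choice":
            out["rho_win"], out["rho_loss"] = 1.0, -1.0
        else:
            out["beta"] = 1.0
        return cls(spec=spec, **out)

    # -- transformed <-> natural -----------------------------------------
    def to_transformed(self) -> np.ndarray:
        vec = []
        for name in self.spec.param_names:
            if name.startswith("alpha"):
                a = self.alpha_win if name in ("alpha", "alpha_win") else self.alpha_loss
                vec.append(math.log(a / (1.0 - a)))
            elif name == "beta":
                vec.append(math.log(self.beta))
            elif name == "rho":
                vec.append(self.rho_win)
            elif name == "rho_win":
                vec.append(self.rho_win)
            else:  # rho_loss
                vec.append(self.rho_loss)
        return np.asarray(vec, dtype=float)

    @classmethod
    def from_transformed(cls, spec: ModelSpec, vec: np.ndarray) -> "Params":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (spec.n_params,):
            raise ValueError(
                f"expected {spec.n_params} transformed values, got shape {vec.shape}"
            )
        kwargs: dict[str, float] = {}
        for name, x in zip(spec.param_names, vec):
            if name.startswith("alpha"):
                kwargs[name] = _logistic(x)
            elif name == "beta":
                kwargs[name] = math.exp(x)
            else:
                kwargs[name] = x
        return cls.from_natural(spec, **kwargs)

    def to_natural_dict(self) -> dict[str, float]:
        out = {}
        for name in self.spec.param_names:
            if name == "alpha":
                out[name] = self.alpha_win
            elif name == "rho":
                out[name] = self.rho_win
            else:
                out[name] = getattr(self, name)
        return out

    def _canonical(self) -> np.ndarray:
        """[alpha_win, alpha_loss, rho_win, rho_loss, beta] for the kernels."""
        return np.array(
            [self.alpha_win, self.alpha_loss, self.rho_win, self.rho_loss, self.beta],
            dtype=np.float64,
        )


# ---------------------------------------------------------------------------
# numba kernels: canonical natural parameters nat = [a_win, a_loss, r_win,
# r_loss, beta]; choices int8 with -1 = missing; outcomes int8 (+1/-1, 0 =
# missing); du flag 0/1.


@njit(cache=True)
def _nll(choices, outcomes, nat, du):
    a_win, a_loss, r_win, r_loss, beta = nat[0], nat[1], nat[2], nat[3], nat[4]
    q = np.zeros(2)
    nll = 0.0
    for t in range(choices.shape[0]):
        c = choices[t]
        if c < 0:
            continue
        u = 1 - c
        z = beta * (q[c] - q[u])
        # -log sigmoid(z), stable
        if z > 0:
            nll += math.log1p(math.exp(-z))
        else:
            nll += -z + math.log1p(math.exp(z))
        if outcomes[t] > 0:
            r, a = r_win, a_win
        else:
            r, a = r_loss, a_loss
        q[c] += a * (r - q[c])
        if du == 1:
            q[u] += a * (-r - q[u])
    return nll


@njit(cache=True)
def _nll_grad(choices, outcomes, nat, du):
    """Negative log-likelihood and gradient w.r.t. the 5 canonical naturals."""
    a_win, a_loss, r_win, r_loss, beta = nat[0], nat[1], nat[2], nat[3], nat[4]
    q = np.zeros(2)
    g = np.zeros((2, 5))  # dq/dnat
    nll = 0.0
    grad = np.zeros(5)
    for t in range(choices.shape[0]):
        c = choices[t]
        if c < 0:
            continue
        u = 1 - c
        dq = q[c] - q[u]
        z = beta * dq
        if z > 0:
            p = 1.0 / (1.0 + math.exp(-z))
            nll += math.log1p(math.exp(-z))
        else:
            e = math.exp(z)
            p = e / (1.0 + e)
            nll += -z + math.log1p(e)
        # d nll / d nat = -(1-p) * dz
        for k in range(5):
            dz = beta * (g[c, k] - g[u, k])
            if k == 4:
                dz += dq
            grad[k] -= (1.0 - p) * dz
        if outcomes[t] > 0:
            r, a, ia, ir = r_win, a_win, 0, 2
        else:
            r, a, ia, ir = r_loss, a_loss, 1, 3
        pe_c = r - q[c]
        pe_u = -r - q[u]
        for k in range(5):
            gc = g[c, k] * (1.0 - a)
            if k == ia:
                gc += pe_c
            if k == ir:
                gc += a
            g[c, k] = gc
        q[c] += a * pe_c
        if du == 1:
            for k in range(5):
                gu = g[u, k] * (1.0 - a)
                if k == ia:
                    gu += pe_u
                if k == ir:
                    gu -= a
                g[u, k] = gu
            q[u] += a * pe_u
    return nll, grad


@njit(cache=True)
def _nll_batch(choices2d, outcomes2d, nat2d, du):
    """Session x parameter-draw matrix of negative log-likelihoods."""
    n, k = choices2d.shape[0], nat2d.shape[0]
    out = np.empty((n, k))
    for i in range(n):
        for j in range(k):
            out[i, j] = _nll(choices2d[i], outcomes2d[i], nat2d[j], du)
    return out


# ---------------------------------------------------------------------------
# readable reference path


def _outcome_sign(outcome) -> int:
    if outcome in (1, "win", True):
        return 1
    if outcome in (-1, "loss", False):
        return -1
    raise ValueError(f"outcome must be win/loss or +/-1, got {outcome!r}")


def update_values(
    Q, choice: int, outcome, params: Params, spec: ModelSpec | None = None
) -> tuple[float, float]:
    """One Rescorla-Wagner update; returns the new (Q0, Q1).

    The chosen value moves toward the (scaled) outcome r by learning rate
    alpha; under double-update the unchosen value simultaneously moves
    toward -r.
    """
    spec = spec or params.spec
    o = _outcome_sign(outcome)
    if spec.sensitivity_kind == "choice":
        r = float(o)
    else:
        r = params.rho_win if o > 0 else params.rho_loss
    a = params.alpha_win if o > 0 else params.alpha_loss
    q = [float(Q[0]), float(Q[1])]
    u = 1 - choice
    q[choice] += a * (r - q[choice])
    if spec.update_rule == "DU":
        q[u] += a * (-r - q[u])
    return (q[0], q[1])


def choice_probability(Q, params: Params, spec: ModelSpec | None = None) -> float:
    """Probability of choosing stimulus 0 given expected values Q."""
    spec = spec or params.spec
    beta = params.beta if spec.sensitivity_kind == "choice" else 1.0
    return _logistic(beta * (float(Q[0]) - float(Q[1])))


def session_loglik(
    session: SessionData, params: Params, spec: ModelSpec | None = None
) -> float:
    """Log-likelihood of the observed choices under the model.

    Missing trials contribute nothing and freeze the value state.
    """
    spec = spec or params.spec
    choices, outcomes = session.choices, session.outcomes
    if spec.is_random:
        return float(np.sum(choices >= 0)) * math.log(0.5)
    if session.n_responded < 1:
        raise ValueError("session has no responded trials")
    ll = -_nll(choices, outcomes, params._canonical(), 1 if spec.update_rule == "DU" else 0)
    if not math.isfinite(ll):
        raise FloatingPointError("non-finite log-likelihood: invalid parameters")
    return float(ll)


def session_loglik_grad(
    choices: np.ndarray, outcomes: np.ndarray, spec: ModelSpec, transformed: np.ndarray
) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and gradient w.r.t. the transformed vector."""
    params = Params.from_transformed(spec, transformed)
    nll, g5 = _nll_grad(
        choices, outcomes, params._canonical(), 1 if spec.update_rule == "DU" else 0
    )
    grad = np.empty(spec.n_params)
    for i, name in enumerate(spec.param_names):
        if name == "alpha":
            a = params.alpha_win
            grad[i] = (g5[0] + g5[1]) * a * (1.0 - a)
        elif name == "alpha_win":
            a = params.alpha_win
            grad[i] = g5[0] * a * (1.0 - a)
        elif name == "alpha_loss":
            a = params.alpha_loss
            grad[i] = g5[1] * a * (1.0 - a)
        elif name == "beta":
            grad[i] = g5[4] * params.beta
        elif name == "rho":
            grad[i] = g5[2] - g5[3]  # rho_loss = -rho
        elif name == "rho_win":
            grad[i] = g5[2]
        else:  # rho_loss
            grad[i] = g5[3]
    return float(nll), grad


def simulate_subject(
    params: Params,
    spec: ModelSpec | None = None,
    config: TaskConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    subject: str = "sim",
    wave: int = 1,
) -> SessionData:
    """Simulate a full session of the agent playing the adaptive task.

    Per trial the generator is consumed in the order: choice draw, feedback
    draw, hazard draw (if the streak qualifies), so sessions are reproducible
    from the seed.
    """
    spec = spec or params.spec
    config = config or TaskConfig()
    state = TaskState.new(config, seed)
    session = SessionData(subject=subject, wave=wave, config=config)
    q = (0.0, 0.0)
    while not state.finished:
        p0 = 0.5 if spec.is_random else choice_probability(q, params, spec)
        choice = 0 if state.rng.random() < p0 else 1
        record = step(state, choice)
        session.trials.append(record)
        if not spec.is_random:
            q = update_values(q, choice, record.feedback_sign, params, spec)
    return session


def trial_latents(
    session: SessionData, params: Params, spec: ModelSpec | None = None
) -> pd.DataFrame:
    """Per-trial model quantities: probability of the made choice, prediction
    errors for the chosen (and, under DU, unchosen) option, and the
    below-chance flag (strictly < 0.5) marking trials the model fails to
    predict.

    Missing trials yield NaN latents and freeze the value state.
    """
    spec = spec or params.spec
    rows = []
    q = (0.0, 0.0)
    for t in session.trials:
        if t.choice is None:
            rows.append(
                dict(trial=t.trial_index + 1, p_choice=np.nan, pe_chosen=np.nan,
                     pe_unchosen=np.nan, below_chance=False)
            )
            continue
        p0 = choice_probability(q, params, spec)
        p_choice = p0 if t.choice == 0 else 1.0 - p0
        o = t.feedback_sign
        if spec.sensitivity_kind == "choice":
            r = float(o)
        else:
            r = params.rho_win if o > 0 else params.rho_loss
        pe_chosen = r - q[t.choice]
        pe_unchosen = (-r - q[1 - t.choice]) if spec.update_rule == "DU" else np.nan
        rows.append(
            dict(
                trial=t.trial_index + 1,
                p_choice=p_choice,
                pe_chosen=pe_chosen,
                pe_unchosen=pe_unchosen,
                below_chance=bool(p_choice < 0.5),
            )
        )
        q = update_values(q, t.choice, o, params, spec)
    return pd.DataFrame(rows)
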