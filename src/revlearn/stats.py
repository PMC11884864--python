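"""Behavioural performance metrics and longitudinal statistics.

Per-session metrics (accuracy, obtained reward, reversal count, stay
probabilities after wins and losses), mixed-effects logistic models of their
development over acquisition waves, cumulative alcohol exposure by
trapezoidal integration of grams/week, and change-score correlations.

The mixed-effects logistic regressions (``stay ~ Session * Valence +
(1 + Session | Subject)`` and ``accuracy ~ Session + (1 + Session |
Subject)``) are estimated by lme4 through Rscript; this module prepares the
trial-level tables, drives the fit, and parses fixed effects, variance
components, and the shrunken per-subject predicted probabilities back into
pandas objects.  If the correlated random structure fails to converge the
model is refitted with uncorrelated, then intercept-only random effects, and
the structure actually used is recorded on the result.
"""

from __future__ import annotations

import json
import math
import subprocess
import tempfile
import textwrap
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .task import SessionData

__all__ = [
    "SessionMetrics",
    "GlmmResult",
    "session_metrics",
    "metrics_frame",
    "stay_trial_table",
    "accuracy_trial_table",
    "fit_stay_glmm",
    "fit_accuracy_glmm",
    "cumulative_auc",
    "change_scores_and_correlations",
    "WEEKS_PER_YEAR",
]

WEEKS_PER_YEAR = 52.1775


@dataclass(frozen=True)
class SessionMetrics:
    subject: str
    wave: int
    accuracy: float
    obtained_reward: float
    n_reversals: int
    p_stay_win: float | None
    p_stay_loss: float | None
    n_responded: int
    undefined: dict = field(default_factory=dict)  # cell -> reason


def session_metrics(session: SessionData) -> SessionMetrics:
    """Accuracy, reward, reversal count and stay probabilities for one session.

    Accuracy is the proportion of responded trials on which the currently
    better stimulus was chosen, regardless of feedback.  Stay probabilities
    condition choice(t) == choice(t-1) on the feedback valence at t-1; the
    first trial and any pair involving a missing trial are excluded.  A stay
    cell with no qualifying pairs is None, with the reason recorded.
    """
    responded = [t for t in session.trials if t.choice is not None]
    if not responded:
        raise ValueError("session has no responded trials")
    accuracy = float(np.mean([t.correct for t in responded]))
    reward = float(sum(t.feedback_value for t in responded))
    n_rev = sum(t.reversal_after for t in session.trials)

    stay = {1: [], -1: []}
    for prev, cur in zip(session.trials[:-1], session.trials[1:]):
        if prev.choice is None or cur.choice is None:
            continue
        stay[prev.feedback_sign].append(cur.choice == prev.choice)

    undefined = {}
    p_sw = float(np.mean(stay[1])) if stay[1] else None
    if p_sw is None:
        undefined["p_stay_win"] = "no responded trial follows a win"
    p_sl = float(np.mean(stay[-1])) if stay[-1] else None
    if p_sl is None:
        undefined["p_stay_loss"] = "no responded trial follows a loss"

    return SessionMetrics(
        subject=session.subject, wave=session.wave, accuracy=accuracy,
        obtained_reward=reward, n_reversals=n_rev,
        p_stay_win=p_sw, p_stay_loss=p_sl,
        n_responded=len(responded), undefined=undefined,
    )


def metrics_frame(sessions: list[SessionData]) -> pd.DataFrame:
    """Tidy per-session metrics for a cohort."""
    rows = []
    for s in sessions:
        m = session_metrics(s)
        rows.append(
            {
                "subject": m.subject, "wave": m.wave, "accuracy": m.accuracy,
                "obtained_reward": m.obtained_reward,
                "n_reversals": m.n_reversals,
                "p_stay_win": m.p_stay_win, "p_stay_loss": m.p_stay_loss,
                "n_responded": m.n_responded,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed-effects logistic regressions (lme4 backend)


@dataclass
class GlmmResult:
    formula: str
    fixed_effects: pd.DataFrame  # term, estimate, se, z, p, odds_ratio
    random_effects: pd.DataFrame  # grp, var1, var2, vcov, sdcor
    subject_estimates: pd.DataFrame  # shrunken predicted probabilities
    random_structure: str  # structure actually used after fallbacks
    converged: bool
    messages: list[str] = field(default_factory=list)


def stay_trial_table(sessions: list[SessionData]) -> pd.DataFrame:
    """Trial-level stay/switch table: one row per consecutive responded pair."""
    rows = []
    for s in sessions:
        for prev, cur in zip(s.trials[:-1], s.trials[1:]):
            if prev.choice is None or cur.choice is None:
                continue
            rows.append(
                {
                    "subject": s.subject,
                    "session": s.wave,
                    "valence": "win" if prev.feedback_sign > 0 else "loss",
                    "stay": int(cur.choice == prev.choice),
                }
            )
    return pd.DataFrame(rows)


def accuracy_trial_table(sessions: list[SessionData]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for t in s.trials:
            if t.choice is None:
                continue
            rows.append(
                {"subject": s.subject, "session": s.wave, "correct": int(t.correct)}
            )
    return pd.DataFrame(rows)


_R_TEMPLATE = textwrap.dedent(
    """
    suppressMessages({{ library(lme4); library(jsonlite) }})
    d <- read.csv("{csv}")
    d$subject <- factor(d$subject)
    {valence_line}
    forms <- c(
      "{dv} ~ {fixed} + (1 + session | subject)",
      "{dv} ~ {fixed} + (1 + session || subject)",
      "{dv} ~ {fixed} + (1 | subject)"
    )
    structures <- c("correlated", "uncorrelated", "intercept_only")
    fit <- NULL; used <- NA; msgs <- character(0); conv <- FALSE
    for (i in seq_along(forms)) {{
      m <- tryCatch(
        glmer(as.formula(forms[i]), data = d, family = binomial,
              control = glmerControl(optimizer = "bobyqa")),
        error = function(e) e, warning = function(w) w
      )
      if (inherits(m, "merMod")) {{
        cm <- m@optinfo$conv$lme4$messages
        if (is.null(cm) && !isSingular(m, tol = 1e-5)) {{
          fit <- m; used <- structures[i]; conv <- TRUE; break
        }}
        if (is.null(fit)) {{ fit <- m; used <- structures[i] }}
        msgs <- c(msgs, paste(structures[i], ":",
                              paste(c(cm, "singular fit"), collapse = "; ")))
      }} else {{
        msgs <- c(msgs, paste(structures[i], ":", conditionMessage(m)))
      }}
    }}
    if (is.null(fit)) {{
      write(toJSON(list(error = msgs)), "{out}")
      quit(status = 0)
    }}
    co <- summary(fit)$coefficients
    fe <- data.frame(term = rownames(co), estimate = co[, 1], se = co[, 2],
                     z = co[, 3], p = co[, 4], row.names = NULL)
    vc <- as.data.frame(VarCorr(fit))
    nd <- unique(d[, c("subject", "session"{valence_col}), drop = FALSE])
    nd$p_hat <- predict(fit, newdata = nd, type = "response")
    write(toJSON(list(fixed = fe, vc = vc, pred = nd, structure = used,
                      converged = conv, messages = msgs), digits = 12,
                 na = "null"), "{out}")
    """
)


def _run_glmm(table: pd.DataFrame, dv: str, fixed: str, with_valence: bool) -> GlmmResult:
    if table["subject"].nunique() < 2:
        raise ValueError("random effects are unidentifiable with a single subject")
    if table["session"].nunique() < 2:
        raise ValueError("the session slope needs at least 2 waves")
    with tempfile.TemporaryDirectory() as tmp:
        csv = Path(tmp) / "trials.csv"
        out = Path(tmp) / "fit.json"
        table.to_csv(csv, index=False)
        script = _R_TEMPLATE.format(
            csv=csv, out=out, dv=dv, fixed=fixed,
            valence_line=(
                'd$valence <- factor(d$valence, levels = c("loss", "win"))'
                if with_valence else ""
            ),
            valence_col=', "valence"' if with_valence else "",
        )
        rfile = Path(tmp) / "fit.R"
        rfile.write_text(script)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(rfile)],
            capture_output=True, text=True, timeout=900,
        )
        if proc.returncode != 0 or not out.exists():
            raise RuntimeError(f"lme4 fit failed:\n{proc.stderr[-2000:]}")
        payload = json.loads(out.read_text())
    if "error" in payload:
        raise RuntimeError("lme4 fit failed: " + "; ".join(payload["error"]))
    fe = pd.DataFrame(payload["fixed"])
    fe["odds_ratio"] = np.exp(fe["estimate"])
    vc = pd.DataFrame(payload["vc"])
    pred = pd.DataFrame(payload["pred"])
    formula = f"{dv} ~ {fixed} + (1 + session | subject)"
    structure = payload["structure"]
    structure = structure[0] if isinstance(structure, list) else structure
    conv = payload["converged"]
    conv = bool(conv[0] if isinstance(conv, list) else conv)
    return GlmmResult(
        formula=formula, fixed_effects=fe, random_effects=vc,
        subject_estimates=pred, random_structure=structure, converged=conv,
        messages=list(payload.get("messages", [])),
    )


def fit_stay_glmm(sessions_or_table) -> GlmmResult:
    """Mixed-effects logistic model of stay behaviour:
    stay ~ Session * Valence with correlated random intercept and session
    slope per subject (one joint model across valences).

    Accepts a list of sessions or a prepared trial table with columns
    subject, session, valence, stay.  Session is a numeric 1/2/3 covariate
    (uncentred); valence reference level is "loss", so the valence odds ratio
    is win vs loss.
    """
    table = (
        sessions_or_table
        if isinstance(sessions_or_table, pd.DataFrame)
        else stay_trial_table(sessions_or_table)
    )
    return _run_glmm(table, "stay", "session * valence", with_valence=True)


def fit_accuracy_glmm(sessions_or_table) -> GlmmResult:
    """Mixed-effects logistic model of accuracy: correct ~ Session with
    correlated random intercept and slope per subject."""
    table = (
        sessions_or_table
        if isinstance(sessions_or_table, pd.DataFrame)
        else accuracy_trial_table(sessions_or_table)
    )
    return _run_glmm(table, "correct", "session", with_valence=False)


# ---------------------------------------------------------------------------
# alcohol exposure


def cumulative_auc(
    wave_times_years,
    grams_per_week,
    weeks_per_year: float = WEEKS_PER_YEAR,
) -> float:
    """Cumulative alcohol consumption in grams: trapezoidal area under the
    grams/week curve over the elapsed weeks between the first and last wave
    (linear interpolation between visits)."""
    t = np.asarray(wave_times_years, dtype=float)
    g = np.asarray(grams_per_week, dtype=float)
    if t.size < 2 or t.size != g.size:
        raise ValueError("need >= 2 waves with matching times and values")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(g))):
        raise ValueError("times and grams/week must be finite")
    if np.any(np.diff(t) <= 0):
        raise ValueError("wave times must be strictly increasing")
    if np.any(g < 0):
        raise ValueError("grams/week must be non-negative")
    return float(np.trapezoid(g, t * weeks_per_year))


def change_scores_and_correlations(
    measures: pd.DataFrame,
    exposure: pd.Series | pd.DataFrame,
    first_wave: int = 1,
    last_wave: int = 3,
) -> pd.DataFrame:
    """Per-measure change scores (last wave minus first) correlated with
    cumulative alcohol consumption.

    ``measures`` is a tidy frame with columns subject, wave, then one column
    per measure; ``exposure`` maps subject -> cumulative grams.  Returns one
    row per measure with n, mean change, Pearson r and p.
    """
    if isinstance(exposure, pd.DataFrame):
        exposure = exposure.set_index("subject").iloc[:, 0]
    value_cols = [c for c in measures.columns if c not in ("subject", "wave")]
    w1 = measures[measures["wave"] == first_wave].set_index("subject")
    w3 = measures[measures["wave"] == last_wave].set_index("subject")
    rows = []
    for col in value_cols:
        delta = (w3[col] - w1[col]).dropna()
        joined = pd.concat([delta.rename("delta"), exposure.rename("cac")],
                           axis=1, join="inner").dropna()
        if len(joined) < 3:
            raise ValueError(
                f"measure {col!r}: fewer than 3 complete wave-{first_wave}/"
                f"wave-{last_wave} pairs"
            )
        r, p = sps.pearsonr(joined["delta"], joined["cac"])
        rows.append(
            {"measure": col, "n": len(joined),
             "mean_change": float(joined["delta"].mean()),
             "pearson_r": float(r), "p_value": float(p)}
        )
    return pd.DataFrame(rows)
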