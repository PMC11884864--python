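"""Model-derived fMRI regressors and reliability metrics.

``build_regressors`` turns a fitted session into trial-wise parametric
modulators for stimulus and feedback events: the model's trial-by-trial
choice probability (confidence), a below-chance flag marking trials the
model predicts at < 50%, and prediction-error traces.  The PE traces fix the
reinforcement sensitivities to +1/-1 (outcomes coded as signs) while keeping
the subject's fitted learning rate, so they isolate learning-rate effects
from sensitivity scaling.  The single-update PE reflects actual feedback for
the chosen option; the "DU-unique" regressor is the double-update PE minus
the single-update PE, isolating the influence of counterfactual updating.

Reliability tools: two-way intraclass correlation (consistency ICC(3,1) by
default, absolute-agreement ICC(2,1) optional) and odd/even split-half
reliability with the Spearman-Brown correction.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .models import Params, trial_latents
from .task import SessionData

__all__ = [
    "build_regressors",
    "icc",
    "split_half",
    "spearman_brown",
    "write_events",
    "write_modulator_files",
    "SplitHalfReport",
]

MODULATOR_COLUMNS = ("choice_prob", "below_chance", "su_pe", "du_unique_pe")


def build_regressors(
    session: SessionData,
    params: Params,
    onsets: np.ndarray | None = None,
    onset_spacing: float = 12.0,
    duration: float = 0.0,
    du_pe: str = "chosen",
) -> pd.DataFrame:
    """Trial-wise regressor table for one session.

    ``params`` is the subject's fitted winning model (supplies the learning
    rate for the +/-1-coded PE traces and the full model for the choice
    probability).  ``du_pe="chosen"`` uses the chosen-option PE under the
    double-update value trace; ``"counterfactual"`` uses the unchosen
    option's counterfactual PE instead.  Onset times are taken from
    ``onsets`` (seconds) or synthesized on a regular grid.

    Missing trials keep their row with null (NaN) modulators.
    """
    if params is None:
        raise ValueError("fitted parameters are required to build regressors")
    if du_pe not in ("chosen", "counterfactual"):
        raise ValueError(f"unknown du_pe reading {du_pe!r}")
    n = len(session.trials)
    if onsets is None:
        onsets = np.arange(n, dtype=float) * onset_spacing
    onsets = np.asarray(onsets, dtype=float)
    if onsets.shape != (n,):
        raise ValueError("onsets length must match the trial count")

    latents = trial_latents(session, params).set_index("trial")
    alpha_win, alpha_loss = params.alpha_win, params.alpha_loss

    q_su = [0.0, 0.0]
    q_du = [0.0, 0.0]
    rows = []
    for t in session.trials:
        row = {
            "onset": onsets[t.trial_index],
            "duration": duration,
            "choice_prob": np.nan,
            "below_chance": np.nan,
            "su_pe": np.nan,
            "du_unique_pe": np.nan,
        }
        if t.choice is not None:
            o = float(t.feedback_sign)
            a = alpha_win if o > 0 else alpha_loss
            c, u = t.choice, 1 - t.choice
            su = o - q_su[c]
            du_chosen = o - q_du[c]
            du_counter = -o - q_du[u]
            du = du_chosen if du_pe == "chosen" else du_counter
            lat = latents.loc[t.trial_index + 1]
            row.update(
                choice_prob=float(lat["p_choice"]),
                below_chance=bool(lat["below_chance"]),
                su_pe=su,
                du_unique_pe=du - su,
            )
            q_su[c] += a * su
            q_du[c] += a * du_chosen
            q_du[u] += a * du_counter
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# intraclass correlation


def icc(values, form: str = "consistency") -> float:
    """Two-way single-measures intraclass correlation of a subjects x
    sessions matrix.

    ``form="consistency"`` is ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE);
    ``form="agreement"`` is ICC(2,1), which additionally charges session
    mean shifts against reliability.  Rows with any missing cell are dropped
    (complete-case); all-missing rows are rejected.
    """
    m = np.asarray(values, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a subjects x sessions matrix with >= 2 sessions")
    if np.any(np.all(np.isnan(m), axis=1)):
        raise ValueError("matrix contains all-missing rows")
    m = m[np.all(np.isfinite(m), axis=1)]
    n, k = m.shape
    if n < 3:
        raise ValueError("need >= 3 complete subjects")
    if form not in ("consistency", "agreement"):
        raise ValueError(f"unknown ICC form {form!r}")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((m - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    if msr <= mse:
        if np.isclose(msr, mse) and np.isclose(mse, 0.0):
            warnings.warn(
                "degenerate variance decomposition (no between-subject "
                "variance); ICC set to 0", RuntimeWarning, stacklevel=2,
            )
            return 0.0
    denom = msr + (k - 1) * mse
    if form == "agreement":
        denom = denom + k * (msc - mse) / n
    if denom <= 0:
        warnings.warn(
            "degenerate variance decomposition; ICC set to 0",
            RuntimeWarning, stacklevel=2,
        )
        return 0.0
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# split-half reliability


def spearman_brown(r_half: float) -> float:
    """Project a half-test correlation to full-test length: 2r / (1 + r)."""
    return 2.0 * r_half / (1.0 + r_half)


@dataclass(frozen=True)
class SplitHalfReport:
    r_half: float | None
    corrected: float | None
    n_used: int
    n_dropped: int
    scheme: str
    flag: str | None = None


def _half_session(session: SessionData, keep_odd: bool) -> SessionData:
    # odd/even by 1-based trial position, preserving task-phase balance
    trials = [
        t for t in session.trials if ((t.trial_index + 1) % 2 == 1) == keep_odd
    ]
    return dataclasses.replace(session, trials=trials)


def split_half(
    sessions: list[SessionData],
    estimator: Callable[[SessionData], float],
    scheme: str = "odd_even",
) -> SplitHalfReport:
    """Split-half reliability of a per-subject scalar measure.

    Each session is split into odd and even trials; ``estimator`` maps a
    half-session to a scalar; the Pearson correlation of the halves across
    subjects is Spearman-Brown corrected.  Subjects on which the estimator
    is undefined (raises or returns None/NaN) are dropped and counted.
    """
    if scheme != "odd_even":
        raise ValueError(f"unknown split scheme {scheme!r}")
    pairs = []
    dropped = 0
    for s in sessions:
        try:
            a = estimator(_half_session(s, keep_odd=True))
            b = estimator(_half_session(s, keep_odd=False))
        except Exception:  # noqa: BLE001 — estimator undefined on a half
            dropped += 1
            continue
        if a is None or b is None or not (np.isfinite(a) and np.isfinite(b)):
            dropped += 1
            continue
        pairs.append((a, b))
    if len(pairs) < 3:
        return SplitHalfReport(None, None, len(pairs), dropped, scheme,
                               flag="fewer than 3 usable subjects")
    arr = np.asarray(pairs)
    if np.std(arr[:, 0]) == 0 or np.std(arr[:, 1]) == 0:
        return SplitHalfReport(None, None, len(pairs), dropped, scheme,
                               flag="constant estimator: correlation undefined")
    r = float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])
    return SplitHalfReport(r, spearman_brown(r), len(pairs), dropped, scheme)


# ---------------------------------------------------------------------------
# event-file export


def write_events(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a BIDS-style events.tsv: onset, duration, then one column per
    modulator, tab-delimited with "n/a" for nulls."""
    cols = ["onset", "duration"] + [c for c in MODULATOR_COLUMNS if c in table]
    out = table[cols].copy()
    if "below_chance" in out:
        out["below_chance"] = out["below_chance"].map(
            lambda v: v if pd.isna(v) else int(v)
        )
    path = Path(path)
    out.to_csv(path, sep="\t", index=False, na_rep="n/a", float_format="%.6f")
    return path


def write_modulator_files(table: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Per-modulator 3-column (onset, duration, value) text files; rows with
    null modulators are omitted."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for col in MODULATOR_COLUMNS:
        if col not in table:
            continue
        sub = table[["onset", "duration", col]].dropna()
        if col == "below_chance":
            sub = sub.assign(below_chance=sub[col].astype(int))
        p = out_dir / f"{col}.txt"
        sub.to_csv(p, sep="\t", index=False, header=False, float_format="%.6f")
        written.append(p)
    return written
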