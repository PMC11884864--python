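"""Validation of the fitting pipeline on simulated ground truth.

Three standard checks:

* parameter recovery — draw subject parameters from a prior, simulate
  sessions, refit with the full EM machinery, correlate refitted with true
  parameters (Pearson on the natural scale, Spearman alongside);
* behavioural recovery — re-simulate each fitted subject at their MAP and
  correlate simulated against observed summary behaviour across subjects;
* model recovery — simulate cohorts from each candidate model and record
  which candidate wins the iBIC comparison (confusion matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fit import GroupFit, Prior, em_group_fit, ibic
from .models import ModelSpec, Params, simulate_subject
from .stats import session_metrics
from .task import SessionData, TaskConfig

__all__ = [
    "RecoveryReport",
    "parameter_recovery",
    "behavioural_recovery",
    "model_recovery",
]

_METRICS = ("accuracy", "p_stay_win", "p_stay_loss", "n_reversals")


@dataclass
class RecoveryReport:
    mode: str
    seed: int | None
    n_reps: int
    parameter_correlations: pd.DataFrame | None = None
    metric_correlations: pd.DataFrame | None = None
    confusion: pd.DataFrame | None = None
    n_failed_fits: int = 0
    flags: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        out = {"mode": self.mode, "seed": self.seed, "n_reps": self.n_reps,
               "n_failed_fits": self.n_failed_fits, "flags": self.flags}
        for name in ("parameter_correlations", "metric_correlations", "confusion"):
            df = getattr(self, name)
            if df is not None:
                out[name] = df.to_dict(orient="records")
        return out


def _natural_matrix(spec: ModelSpec, transformed: np.ndarray) -> np.ndarray:
    rows = [
        [Params.from_transformed(spec, x).to_natural_dict()[n]
         for n in spec.param_names]
        for x in np.atleast_2d(transformed)
    ]
    return np.asarray(rows)


def parameter_recovery(
    spec: ModelSpec,
    prior: Prior,
    n_subjects: int = 143,
    config: TaskConfig | None = None,
    n_reps: int = 1,
    seed: int = 0,
    **em_kwargs,
) -> RecoveryReport:
    """Simulate cohorts from ``prior``, refit with the EM pipeline, and
    correlate true against refitted parameters on the natural scale."""
    config = config or TaskConfig()
    ss = np.random.SeedSequence(seed)
    per_param: dict[str, list[tuple[float, float]]] = {
        n: [] for n in spec.param_names
    }
    n_failed = 0
    for rep_ss in ss.spawn(n_reps):
        draw_ss, fit_ss, *sim_ss = rep_ss.spawn(n_subjects + 2)
        rng = np.random.default_rng(draw_ss)
        truths_t = prior.sample(rng, n_subjects)
        sessions = [
            simulate_subject(
                Params.from_transformed(spec, x), config=config,
                seed=s, subject=f"s{i:03d}",
            )
            for i, (x, s) in enumerate(zip(truths_t, sim_ss))
        ]
        gf = em_group_fit(sessions, spec, seed=fit_ss, **em_kwargs)
        true_nat = _natural_matrix(spec, truths_t)
        fits = np.array([f.transformed for f in gf.subject_fits])
        fit_nat = _natural_matrix(spec, fits)
        ok = np.array([f.converged for f in gf.subject_fits])
        n_failed += int(np.sum(~ok))
        for j, name in enumerate(spec.param_names):
            per_param[name] += list(zip(true_nat[ok, j], fit_nat[ok, j]))

    rows = []
    for name, pairs in per_param.items():
        arr = np.asarray(pairs)
        pr = sps.pearsonr(arr[:, 0], arr[:, 1])
        sr = sps.spearmanr(arr[:, 0], arr[:, 1])
        rows.append(
            {"parameter": name, "n": len(arr),
             "pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
             "spearman_r": float(sr.statistic)}
        )
    return RecoveryReport(
        mode="parameter", seed=seed, n_reps=n_reps,
        parameter_correlations=pd.DataFrame(rows), n_failed_fits=n_failed,
    )


def behavioural_recovery(
    group_fit: GroupFit,
    sessions: list[SessionData],
    config: TaskConfig | None = None,
    n_sims_per_subject: int = 100,
    seed: int = 0,
) -> RecoveryReport:
    """Simulate each fitted subject at their MAP and correlate, across
    subjects, mean simulated vs observed accuracy, stay probabilities and
    reversal count."""
    config = config or (sessions[0].config if sessions else TaskConfig())
    ss = np.random.SeedSequence(seed)
    obs_rows, sim_rows = [], []
    for fit, sess, subj_ss in zip(
        group_fit.subject_fits, sessions, ss.spawn(len(sessions))
    ):
        m = session_metrics(sess)
        obs_rows.append([getattr(m, k) for k in _METRICS])
        params = fit.params
        sims = []
        for sim_ss in subj_ss.spawn(n_sims_per_subject):
            sm = session_metrics(
                simulate_subject(params, config=config, seed=sim_ss)
            )
            sims.append([getattr(sm, k) for k in _METRICS])
        sim_rows.append(np.nanmean(np.asarray(sims, dtype=float), axis=0))
    obs = np.asarray(obs_rows, dtype=float)
    sim = np.asarray(sim_rows, dtype=float)

    rows, flags = [], []
    for j, name in enumerate(_METRICS):
        keep = np.isfinite(obs[:, j]) & np.isfinite(sim[:, j])
        if keep.sum() < 3 or np.std(obs[keep, j]) == 0 or np.std(sim[keep, j]) == 0:
            flags.append(f"{name}: correlation undefined (degenerate variance)")
            rows.append({"metric": name, "n": int(keep.sum()),
                         "pearson_r": np.nan, "pearson_p": np.nan})
            continue
        pr = sps.pearsonr(obs[keep, j], sim[keep, j])
        rows.append({"metric": name, "n": int(keep.sum()),
                     "pearson_r": float(pr.statistic),
                     "pearson_p": float(pr.pvalue)})
    return RecoveryReport(
        mode="behaviour", seed=seed, n_reps=n_sims_per_subject,
        metric_correlations=pd.DataFrame(rows), flags=flags,
    )


def model_recovery(
    specs: list[ModelSpec],
    priors: dict[str, Prior] | None = None,
    n_subjects: int = 100,
    config: TaskConfig | None = None,
    n_reps: int = 10,
    seed: int = 0,
    K: int = 2000,
    **em_kwargs,
) -> RecoveryReport:
    """Confusion matrix of iBIC model selection over simulated cohorts.

    For each generating spec, ``n_reps`` cohorts are simulated from its
    prior; every candidate is fitted and the iBIC winner recorded.  Rows sum
    to ``n_reps``.
    """
    if len(specs) < 2:
        raise ValueError("model recovery needs >= 2 candidate specs")
    config = config or TaskConfig()
    priors = priors or {}
    counts = {g.code: {w.code: 0 for w in specs} for g in specs}
    n_failed = 0
    ss = np.random.SeedSequence(seed)
    for gen_spec, gen_ss in zip(specs, ss.spawn(len(specs))):
        prior = priors.get(gen_spec.code) or Prior.default(gen_spec, var=1.0)
        for rep_ss in gen_ss.spawn(n_reps):
            draw_ss, *rest = rep_ss.spawn(n_subjects + 1 + len(specs))
            sim_ss, fit_ss = rest[:n_subjects], rest[n_subjects:]
            rng = np.random.default_rng(draw_ss)
            truths = prior.sample(rng, n_subjects)
            sessions = [
                simulate_subject(
                    Params.from_transformed(gen_spec, x), config=config,
                    seed=s, subject=f"s{i:03d}",
                )
                for i, (x, s) in enumerate(zip(truths, sim_ss))
            ]
            scores = {}
            for cand, c_ss in zip(specs, fit_ss):
                try:
                    gf = em_group_fit(sessions, cand, seed=c_ss, **em_kwargs)
                    scores[cand.code] = ibic(gf, sessions, K=K, seed=c_ss)
                except Exception:  # noqa: BLE001 — counted, not fatal
                    n_failed += 1
            if scores:
                winner = min(scores, key=scores.get)
                counts[gen_spec.code][winner] += 1
    confusion = pd.DataFrame(counts).T
    confusion.index.name = "generating"
    return RecoveryReport(
        mode="model", seed=seed, n_reps=n_reps,
        confusion=confusion.reset_index(), n_failed_fits=n_failed,
    )
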