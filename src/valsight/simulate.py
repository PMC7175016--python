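"""Simulated cohorts of Q-learning agents performing the selection task.

Subject-level parameters (alpha_gain, alpha_loss, beta) are drawn on the
probit scale from group-level normal distributions, mirroring the
hierarchical generative model the estimation stage assumes. Agents choose
by softmax on current Q values; learning-phase feedback is sampled from
the per-stimulus reinforcement schedule, and transfer-phase trials deliver
no feedback (so value beliefs stay frozen).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import qlearning as ql
from .task import STIMULI, TaskConfig, build_learning_schedule, build_transfer_schedule

PARAM_NAMES = ("alpha_gain", "alpha_loss", "beta")


@dataclass
class AgentParams:
    """Subject-level Q-learning parameters, natural and probit scale."""

    alpha_gain: float
    alpha_loss: float
    beta: float
    z_gain: float = None
    z_loss: float = None
    z_beta: float = None

    def __post_init__(self):
        if not (0.0 <= self.alpha_gain <= 1.0 and 0.0 <= self.alpha_loss <= 1.0):
            raise ValueError("learning rates must lie in [0, 1]")
        if not (0.0 <= self.beta <= 100.0):
            raise ValueError("beta must lie in [0, 100]")

    @classmethod
    def from_z(cls, z_gain, z_loss, z_beta):
        return cls(alpha_gain=ql.probit_link(z_gain),
                   alpha_loss=ql.probit_link(z_loss),
                   beta=ql.probit_link(z_beta, kind="beta"),
                   z_gain=z_gain, z_loss=z_loss, z_beta=z_beta)


@dataclass
class GroupHyperParams:
    """Group-level means and SDs of the probit-scale parameters.

    Defaults describe a moderately heterogeneous adult cohort: median
    learning rates around 0.31 (gain) and 0.18 (loss), median inverse
    temperature around 12, with an SD of 1.1 inside the support of the
    estimation prior on sigma_z.
    """

    mu_z: dict = field(default_factory=lambda: {
        "alpha_gain": -0.5, "alpha_loss": -0.9, "beta": -1.2})
    sigma_z: dict = field(default_factory=lambda: {
        "alpha_gain": 1.1, "alpha_loss": 1.1, "beta": 1.1})

    def __post_init__(self):
        for name in PARAM_NAMES:
            if self.sigma_z[name] < 0:
                raise ValueError(f"sigma_z[{name}] must be >= 0")


def sample_cohort(hyper: GroupHyperParams, n_subjects: int, seed: int) -> list:
    """Draw subject parameters: z ~ N(mu_z, sigma_z), mapped by the probit link."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n_subjects):
        z = {n: rng.normal(hyper.mu_z[n], hyper.sigma_z[n]) for n in PARAM_NAMES}
        cohort.append(AgentParams.from_z(z["alpha_gain"], z["alpha_loss"], z["beta"]))
    return cohort


def simulate_agent(params: AgentParams, schedule: pd.DataFrame,
                   config: TaskConfig, seed: int, q0=None,
                   miss_rate: float = 0.0, model_rt: bool = False):
    """Run one agent through a schedule; returns (records, qtrace).

    Q values update only on learning trials with feedback. ``q0`` may
    override the initial values as a mapping stimulus -> Q (default: 0.5
    everywhere). ``miss_rate`` injects response omissions; ``model_rt``
    adds a log-normal response-time column and locks feedback onsets to it.
    """
    rng = np.random.default_rng(seed)
    records = schedule.copy()
    idx = {s: i for i, s in enumerate(STIMULI)}
    q = np.full(len(STIMULI), ql.Q0)
    if q0 is not None:
        for s, v in q0.items():
            q[idx[s]] = v

    reinforcement = config.stim_reinforcement()
    choices, rewards, rts, fb_onsets = [], [], [], []
    trace_rows = []

    for rec in records.itertuples():
        a, b = rec.pair[0], rec.pair[1]
        row = {f"q_{s}": q[i] for s, i in idx.items()}
        if miss_rate and rng.random() < miss_rate:
            choices.append("MISS")
            rewards.append(np.nan)
            rts.append(np.nan)
            fb_onsets.append(np.nan)
            row.update(q_chosen=np.nan, q_unchosen=np.nan, delta_value=np.nan,
                       rpe_signed=np.nan, rpe_unsigned=np.nan)
            trace_rows.append(row)
            continue

        p_a = ql.choice_prob(q[idx[a]], q[idx[b]], params.beta)
        choice, unchosen = (a, b) if rng.random() < p_a else (b, a)
        choices.append(choice)
        row["q_chosen"] = q[idx[choice]]
        row["q_unchosen"] = q[idx[unchosen]]

        rt = float(rng.lognormal(-0.35, 0.3)) if model_rt else np.nan
        rts.append(rt)

        if rec.phase == "learning":
            row["delta_value"] = q[idx[choice]] - q[idx[unchosen]]
            r = float(rng.random() < reinforcement[choice])
            rewards.append(r)
            rpe = r - q[idx[choice]]
            row["rpe_signed"] = rpe
            row["rpe_unsigned"] = abs(rpe)
            alpha = params.alpha_gain if r == 1.0 else params.alpha_loss
            q[idx[choice]] += alpha * (r - q[idx[choice]])
            if model_rt:
                fb_onsets.append(rec.onset_s + rt + 0.3 + 0.225)
            else:
                fb_onsets.append(rec.feedback_onset_s)
        else:
            rewards.append(np.nan)
            fb_onsets.append(np.nan)
            from .task import optimal_member
            opt = optimal_member(rec.pair)
            sub = a if a != opt else b
            row["delta_value"] = q[idx[opt]] - q[idx[sub]]
            row["rpe_signed"] = np.nan
            row["rpe_unsigned"] = np.nan
        trace_rows.append(row)

    records["choice"] = pd.array(choices, dtype="string")
    records["reward"] = rewards
    records["feedback_onset_s"] = fb_onsets
    if model_rt:
        records["rt_s"] = rts
    qtrace = pd.DataFrame(trace_rows, index=records.index)
    return records, qtrace


def simulate_subject(params: AgentParams, config: TaskConfig, seed: int,
                     subject_id: str = "sub-01", **kwargs):
    """Full session for one subject: learning then transfer, concatenated.

    Transfer simulation continues from the end-of-learning Q values.
    Returns (records, qtrace) spanning both phases.
    """
    rng = np.random.default_rng(seed)
    s1, s2, s3, s4 = rng.integers(0, 2**31 - 1, size=4)
    learn = build_learning_schedule(config, int(s1), subject_id)
    learn_rec, learn_tr = simulate_agent(params, learn, config, int(s2), **kwargs)

    q_end = {s: learn_tr.iloc[-1][f"q_{s}"] for s in STIMULI}
    # apply the final trial's update, which the pre-update trace omits
    last = learn_rec.iloc[-1]
    if pd.notna(last["reward"]) and last["choice"] != "MISS":
        r = float(last["reward"])
        alpha = params.alpha_gain if r == 1.0 else params.alpha_loss
        c = last["choice"]
        q_end[c] = q_end[c] + alpha * (r - q_end[c])

    trans = build_transfer_schedule(config, int(s3), subject_id)
    trans["onset_s"] += learn_rec["onset_s"].iloc[-1] + 30.0
    trans_rec, trans_tr = simulate_agent(params, trans, config, int(s4),
                                         q0=q_end, **kwargs)
    records = pd.concat([learn_rec, trans_rec], ignore_index=True)
    qtrace = pd.concat([learn_tr, trans_tr], ignore_index=True)
    return records, qtrace


def simulate_cohort(hyper: GroupHyperParams, config: TaskConfig,
                    n_subjects: int, seed: int, **kwargs):
    """Simulate a full cohort; returns (records, qtraces, cohort params).

    Records from all subjects are concatenated; per-subject rows carry the
    subject id. The per-subject qtrace rows align with the record rows.
    """
    cohort = sample_cohort(hyper, n_subjects, seed)
    rng = np.random.default_rng(seed + 1)
    all_rec, all_tr = [], []
    for i, params in enumerate(cohort):
        sid = f"sub-{i + 1:02d}"
        rec, tr = simulate_subject(params, config, int(rng.integers(0, 2**31 - 1)),
                                   subject_id=sid, **kwargs)
        all_rec.append(rec)
        all_tr.append(tr)
    records = pd.concat(all_rec, ignore_index=True)
    qtraces = pd.concat(all_tr, ignore_index=True)
    return records, qtraces, cohort
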