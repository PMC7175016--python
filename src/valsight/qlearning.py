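"""Dual-learning-rate Q-learning: update rule, softmax choice, likelihood.

The model maintains an expected value Q in [0, 1] for each of the six
stimuli. After feedback r ∈ {1, 0} the chosen stimulus's value moves toward
r by a step alpha_gain (positive prediction error) or alpha_loss (negative
prediction error):

    Q <- Q + alpha_gain * (r - Q)   if r = 1
    Q <- Q + alpha_loss * (r - Q)   if r = 0

Choice between the two presented stimuli follows a softmax on their Q
values with inverse temperature beta in [0, 100]. Subject-level parameters
live on an unbounded probit scale z, mapped to their natural ranges by
alpha = Phi(z) and beta = 100 * Phi(z).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri

from .task import LEARNING_PAIRS, STIMULI, optimal_member

BETA_SCALE = 100.0
Q0 = 0.5  # midpoint start: the chance expectation of a binary outcome


def q_update(q, r, alpha_gain, alpha_loss):
    """One prediction-error update of a chosen stimulus's value.

    Vectorised over ``q``/``r``. Rewards outside {0, 1} are rejected.
    """
    q = np.asarray(q, dtype=float)
    r = np.asarray(r)
    if not np.isin(r, (0, 1)).all():
        raise ValueError("reward must be 0 or 1")
    r = r.astype(float)
    alpha = np.where(r == 1.0, alpha_gain, alpha_loss)
    out = q + alpha * (r - q)
    return float(out) if out.ndim == 0 else out


def choice_prob(q_a, q_b, beta):
    """Softmax probability of choosing option A over option B.

    Computed as a logistic of beta * (q_a - q_b), which is algebraically
    identical to the two-exponential form but immune to overflow.
    """
    return expit(np.asarray(beta, dtype=float) * (np.asarray(q_a, dtype=float)
                                                  - np.asarray(q_b, dtype=float)))


def probit_link(z, kind="alpha"):
    """Map an unbounded probit-scale value to its natural range.

    alpha = Phi(z) in [0, 1]; beta = 100 * Phi(z) in [0, 100].
    """
    z = np.asarray(z, dtype=float)
    out = ndtr(z) * (BETA_SCALE if kind == "beta" else 1.0)
    return float(out) if out.ndim == 0 else out


def inverse_link(p, kind="alpha"):
    """Exact inverse of :func:`probit_link`; boundary values are rejected."""
    p = np.asarray(p, dtype=float)
    hi = BETA_SCALE if kind == "beta" else 1.0
    if np.any(p <= 0.0) or np.any(p >= hi):
        raise ValueError(f"value must lie strictly inside (0, {hi})")
    out = ndtri(p / hi)
    return float(out) if out.ndim == 0 else out


def _encode_trials(records: pd.DataFrame):
    """Learning-phase records -> integer arrays (chosen, unchosen, reward).

    Misses and rows without feedback are dropped.
    """
    rec = records[records["phase"] == "learning"]
    valid = rec["choice"].notna() & (rec["choice"] != "MISS") & rec["reward"].notna()
    rec = rec[valid]
    idx = {s: i for i, s in enumerate(STIMULI)}
    chosen = rec["choice"].map(idx).to_numpy(dtype=int)
    other = np.array([idx[p[0]] if c != idx[p[0]] else idx[p[1]]
                      for p, c in zip(rec["pair"], chosen)], dtype=int)
    reward = rec["reward"].to_numpy(dtype=float)
    return chosen, other, reward


def negative_log_likelihood(params, records: pd.DataFrame) -> float:
    """-log p(observed learning-phase choices | params), Q propagated forward.

    ``params`` is anything with ``alpha_gain``, ``alpha_loss`` and ``beta``
    attributes. Misses contribute nothing. Raises on an empty record set.
    """
    chosen, other, reward = _encode_trials(records)
    if chosen.size == 0:
        raise ValueError("no valid learning-phase trials to evaluate")
    q = np.full(len(STIMULI), Q0)
    nll = 0.0
    for c, o, r in zip(chosen, other, reward):
        p = choice_prob(q[c], q[o], params.beta)
        nll -= np.log(p)
        alpha = params.alpha_gain if r == 1.0 else params.alpha_loss
        q[c] += alpha * (r - q[c])
    return float(nll)


def ml_fit_subject(records: pd.DataFrame, n_starts: int = 3, seed: int = 0):
    """Per-subject maximum-likelihood fit on the probit scale.

    Multi-start Nelder-Mead over (z_gain, z_loss, z_beta); returns the
    best-fitting parameters as a dict with the achieved NLL.
    """
    from scipy.optimize import minimize

    chosen, other, reward = _encode_trials(records)
    if chosen.size == 0:
        raise ValueError("no valid learning-phase trials to fit")

    def nll_z(zs):
        ag, al = ndtr(zs[0]), ndtr(zs[1])
        beta = BETA_SCALE * ndtr(zs[2])
        q = np.full(len(STIMULI), Q0)
        total = 0.0
        for c, o, r in zip(chosen, other, reward):
            x = beta * (q[c] - q[o])
            total += np.log1p(np.exp(-x)) if x > -30 else -x
            q[c] += (ag if r == 1.0 else al) * (r - q[c])
        return total

    rng = np.random.default_rng(seed)
    best = None
    starts = [np.array([-0.5, -0.5, -1.0])] + [
        rng.normal(-0.5, 0.8, size=3) for _ in range(n_starts - 1)]
    for x0 in starts:
        res = minimize(nll_z, x0, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    z = best.x
    return {"z_gain": z[0], "z_loss": z[1], "z_beta": z[2],
            "alpha_gain": float(ndtr(z[0])), "alpha_loss": float(ndtr(z[1])),
            "beta": float(BETA_SCALE * ndtr(z[2])), "nll": float(best.fun)}


def compute_qtrace(params, records: pd.DataFrame) -> pd.DataFrame:
    """Per-trial value trace for completed records (observed or simulated).

    Each row holds the Q of all six stimuli *before* that trial's update,
    the chosen/unchosen values, the value difference, and the signed and
    unsigned reward prediction errors (learning trials only). During
    transfer no feedback is delivered, so Q stays frozen and ``delta_value``
    is the end-of-learning belief difference Q(optimal) - Q(suboptimal).
    """
    idx = {s: i for i, s in enumerate(STIMULI)}
    q = np.full(len(STIMULI), Q0)
    rows = []
    for rec in records.itertuples():
        choice = rec.choice
        row = {f"q_{s}": q[i] for s, i in idx.items()}
        if choice is None or pd.isna(choice) or choice == "MISS":
            row.update(q_chosen=np.nan, q_unchosen=np.nan, delta_value=np.nan,
                       rpe_signed=np.nan, rpe_unsigned=np.nan)
            rows.append(row)
            continue
        c = idx[choice]
        o = idx[rec.pair[0]] if rec.pair[0] != choice else idx[rec.pair[1]]
        row["q_chosen"] = q[c]
        row["q_unchosen"] = q[o]
        if rec.phase == "learning":
            row["delta_value"] = q[c] - q[o]
            if not pd.isna(rec.reward):
                r = float(rec.reward)
                rpe = r - q[c]
                row["rpe_signed"] = rpe
                row["rpe_unsigned"] = abs(rpe)
                alpha = params.alpha_gain if r == 1.0 else params.alpha_loss
                q[c] += alpha * (r - q[c])
            else:
                row["rpe_signed"] = np.nan
                row["rpe_unsigned"] = np.nan
        else:
            opt = optimal_member(rec.pair)
            sub = rec.pair[0] if rec.pair[0] != opt else rec.pair[1]
            row["delta_value"] = q[idx[opt]] - q[idx[sub]]
            row["rpe_signed"] = np.nan
            row["rpe_unsigned"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, index=records.index)


def end_of_learning_dvalue(q_final, pair: str) -> float:
    """Belief difference Q(optimal) - Q(suboptimal) for a transfer pair.

    Optimality follows the learning-phase reinforcement ranking (A > B,
    ...); for novel pairs the member with the higher scheduled
    reinforcement probability counts as optimal. ``q_final`` maps stimulus
    labels to end-of-learning Q values.
    """
    opt = optimal_member(pair)
    sub = pair[0] if pair[0] != opt else pair[1]
    return float(q_final[opt] - q_final[sub])


def behavior_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-pair learning accuracy (optimal choices / valid trials)."""
    rec = records[(records["phase"] == "learning")
                  & records["choice"].notna() & (records["choice"] != "MISS")].copy()
    rec["optimal"] = [c == optimal_member(p) for c, p in zip(rec["choice"], rec["pair"])]
    out = (rec.groupby(["subject_id", "pair"], sort=True)["optimal"]
           .agg(accuracy="mean", n_valid="count").reset_index())
    return out


def filter_good_learners(summaries: pd.DataFrame,
                         pairs=LEARNING_PAIRS, threshold=0.60) -> list:
    """Subjects with accuracy strictly above threshold on every trained pair.

    Subjects missing a pair entirely (zero valid trials) are excluded with
    a warning.
    """
    import warnings

    good = []
    for sid, grp in summaries.groupby("subject_id", sort=True):
        have = set(grp["pair"])
        if not set(pairs) <= have:
            warnings.warn(f"subject {sid}: no valid trials for "
                          f"{sorted(set(pairs) - have)}; excluded")
            continue
        accs = grp.set_index("pair").loc[list(pairs), "accuracy"]
        if (accs > threshold).all():
            good.append(sid)
    return good
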