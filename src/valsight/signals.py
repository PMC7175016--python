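"""Synthetic ROI BOLD signals and single-trial betas with planted structure.

The generator provides ground truth for the deconvolution and decoding
stages: percent-signal-change time series whose stimulus-locked amplitudes
scale with the chosen/unchosen value beliefs and whose feedback-locked
amplitudes scale with the signed and unsigned reward prediction error,
plus transfer-phase single-trial beta estimates whose separability is
coupled to the choice-outcome label and the trial's value difference.

Default ROI weights plant the qualitative pattern of interest: dorsal
striatum and visual regions carry the chosen-vs-unchosen value contrast,
all striatal and visual regions carry signed-RPE modulation, and the
unsigned-RPE modulation is negative in the accumbens but positive in the
FFA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.stats import gamma as gamma_dist

from .task import optimal_member

ROI_NAMES = ("caudate", "putamen", "accumbens", "OC", "FFA",
             "vmPFC", "DLPFC", "preSMA", "M1")

ROI_GROUPS = {
    "striatal": ("caudate", "putamen", "accumbens"),
    "frontal": ("vmPFC", "M1", "DLPFC", "preSMA"),
    "perceptual": ("FFA", "OC"),
}


def _default_stim_weights():
    # (b0, b_Qchosen, b_Qunchosen) per ROI; value contrast in dorsal
    # striatum and visual regions
    w = {roi: (0.3, 0.0, 0.0) for roi in ROI_NAMES}
    for roi in ("caudate", "putamen", "OC", "FFA"):
        w[roi] = (0.3, 0.5, 0.1)
    w["M1"] = (0.4, 0.0, 0.0)
    return w


def _default_fb_weights():
    # (c0, c_signedRPE, c_unsignedRPE) per ROI
    w = {roi: (0.2, 0.0, 0.0) for roi in ROI_NAMES}
    for roi in ("caudate", "putamen", "OC"):
        w[roi] = (0.2, 0.4, 0.0)
    w["accumbens"] = (0.2, 0.4, -0.2)
    w["FFA"] = (0.2, 0.4, 0.2)
    return w


def _default_beta_weights():
    # label-coupled separability of single-trial betas, concentrated in the
    # regions that rank highest in the decoding analysis
    return {"caudate": 0.5, "putamen": 0.5, "accumbens": 0.25, "OC": 0.3,
            "FFA": 0.35, "vmPFC": 0.25, "DLPFC": 0.15, "preSMA": 0.4,
            "M1": 0.2}


@dataclass
class RoiSignalConfig:
    """Ground-truth coefficients for ROI signal and beta synthesis.

    ``stim_weights[roi] = (b0, b_Qchosen, b_Qunchosen)`` sets the
    stimulus-locked response amplitude ``b0 + b_Qc*Q_chosen +
    b_Qu*Q_unchosen``; ``fb_weights[roi] = (c0, c_signed, c_unsigned)``
    sets the feedback-locked amplitude from the signed/unsigned prediction
    error. Betas are ``beta_weights[roi] * s * (|dValue| if coupled else 1)
    + noise`` with s = +1 for optimal and -1 for suboptimal choices.
    """

    roi_names: tuple = ROI_NAMES
    stim_weights: dict = field(default_factory=_default_stim_weights)
    fb_weights: dict = field(default_factory=_default_fb_weights)
    noise_sd: float = 0.25
    ar1: float = 0.4
    sample_rate_hz: float = 0.5
    beta_weights: dict = field(default_factory=_default_beta_weights)
    beta_couple_dvalue: bool = True
    beta_noise_sd: float = 1.0

    def __post_init__(self):
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        if self.noise_sd < 0 or self.beta_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not abs(self.ar1) < 1:
            raise ValueError("|ar1| must be < 1 for a stationary noise process")


@dataclass
class HRFSpec:
    """Canonical double-gamma haemodynamic response, peak-normalised to 1."""

    peak_s: float = 6.0
    undershoot_s: float = 16.0
    peak_disp: float = 1.0
    under_disp: float = 1.0
    ratio: float = 1.0 / 6.0
    duration_s: float = 32.0

    def evaluate(self, t):
        t = np.asarray(t, dtype=float)
        pos = gamma_dist.pdf(t, self.peak_s / self.peak_disp, scale=self.peak_disp)
        neg = gamma_dist.pdf(t, self.undershoot_s / self.under_disp,
                             scale=self.under_disp)
        h = pos - self.ratio * neg
        h = np.where((t < 0) | (t > self.duration_s), 0.0, h)
        peak = np.max(np.abs(h)) if np.any(h) else 1.0
        return h / peak


def ar1_noise(n, sd, ar1, rng):
    """Stationary AR(1) Gaussian noise with marginal SD ``sd``."""
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - ar1 ** 2)
    e = rng.normal(0.0, innov_sd, size=n)
    x = lfilter([1.0], [1.0, -ar1], e)
    x[0] = rng.normal(0.0, sd)
    return x


def event_amplitudes(records: pd.DataFrame, qtrace: pd.DataFrame,
                     cfg: RoiSignalConfig) -> pd.DataFrame:
    """Ground-truth per-trial response amplitudes for every ROI and event type."""
    rows = []
    for rec, (_, tr) in zip(records.itertuples(), qtrace.iterrows()):
        if pd.isna(rec.choice) or rec.choice == "MISS":
            continue
        for roi in cfg.roi_names:
            b0, bqc, bqu = cfg.stim_weights[roi]
            rows.append({"trial_index": rec.Index, "roi": roi,
                         "event_type": "stimulus", "onset_s": rec.onset_s,
                         "amplitude": b0 + bqc * tr["q_chosen"] + bqu * tr["q_unchosen"]})
        if rec.phase == "learning" and not pd.isna(rec.feedback_onset_s):
            for roi in cfg.roi_names:
                c0, cs, cu = cfg.fb_weights[roi]
                rows.append({"trial_index": rec.Index, "roi": roi,
                             "event_type": "feedback", "onset_s": rec.feedback_onset_s,
                             "amplitude": c0 + cs * tr["rpe_signed"] + cu * tr["rpe_unsigned"]})
    return pd.DataFrame(rows)


def synthesize_roi_timeseries(records: pd.DataFrame, qtrace: pd.DataFrame,
                              cfg: RoiSignalConfig, hrf: HRFSpec = None,
                              seed: int = 0, pad_s: float = 25.0):
    """Per-ROI percent-signal-change series with event-locked responses.

    series = sum over events of amplitude * HRF(t - onset) + AR(1) noise.
    Returns ``(series, truth)`` where ``series`` has a ``time_s`` column
    plus one column per ROI and ``truth`` is the ground-truth amplitude
    table from :func:`event_amplitudes`.
    """
    hrf = hrf or HRFSpec()
    onsets_all = pd.concat([records["onset_s"], records["feedback_onset_s"]])
    if (records["onset_s"] < 0).any():
        raise ValueError("negative event onsets")
    duration = float(np.nanmax(onsets_all)) + pad_s
    dt = 1.0 / cfg.sample_rate_hz
    t = np.arange(0.0, duration, dt)
    if hrf.duration_s <= dt:
        raise ValueError("HRF shorter than one sample: rates misconfigured")

    truth = event_amplitudes(records, qtrace, cfg)
    rng = np.random.default_rng(seed)
    out = {"time_s": t}
    for roi in cfg.roi_names:
        y = np.zeros_like(t)
        for ev in truth[truth["roi"] == roi].itertuples():
            y += ev.amplitude * hrf.evaluate(t - ev.onset_s)
        y += ar1_noise(t.size, cfg.noise_sd, cfg.ar1, rng)
        out[roi] = y
    return pd.DataFrame(out), truth


def synthesize_trial_betas(records: pd.DataFrame, qtrace: pd.DataFrame,
                           cfg: RoiSignalConfig, seed: int = 0) -> pd.DataFrame:
    """Transfer-phase single-trial beta matrix with label-coupled signal.

    One row per non-miss transfer trial: the 9 ROI betas, subject_id,
    trial_sign, the choice-outcome label and the trial's end-of-learning
    value difference. The latent beta is signed by the label and, when
    ``beta_couple_dvalue`` is set, scaled by |dValue| so that easy trials
    (large belief difference) are more separable than hard ones.
    """
    rng = np.random.default_rng(seed)
    mask = ((records["phase"] == "transfer") & records["choice"].notna()
            & (records["choice"] != "MISS"))
    rec = records[mask]
    tr = qtrace.loc[rec.index]
    rows = []
    for r, (_, q) in zip(rec.itertuples(), tr.iterrows()):
        optimal = r.choice == optimal_member(r.pair)
        s = 1.0 if optimal else -1.0
        scale = abs(q["delta_value"]) if cfg.beta_couple_dvalue else 1.0
        row = {"subject_id": r.subject_id, "trial_sign": r.trial_sign,
               "label": "optimal" if optimal else "suboptimal",
               "dvalue": q["delta_value"]}
        for roi in cfg.roi_names:
            row[roi] = (cfg.beta_weights[roi] * s * scale
                        + rng.normal(0.0, cfg.beta_noise_sd))
        rows.append(row)
    cols = (["subject_id", "trial_sign", "label", "dvalue"] + list(cfg.roi_names))
    return pd.DataFrame(rows, columns=cols)
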