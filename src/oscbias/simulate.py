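"""Seeded generative model of the dichotic 2AFC experiment.

The observer accumulates Gaussian evidence whose mean is displaced toward
the stimulated ear by half the sensory separation ``delta``.  Target
presentation transiently potentiates an ear-specific alpha-band gain: for
``gate_depth`` trials after a target in ear *e*, the evidence gain of that
ear is modulated as

    λ_e(t) = 1 + osc_amp · cos(2π · osc_freq · t + φ_e),

with the oscillation phase-locked to noise onset (t = SOA) and the two
ears in antiphase (φ_L = φ_R + 180° by default).  Because the ears are
modulated in counterphase, the hit- and false-alarm-rate modulations
cancel in d′ but sum in the criterion — the generative counterpart of the
sensitivity/criterion dissociation the analysis pipeline is built to
detect.  The decision threshold additionally carries an assimilative
2-back stimulus bias and a weak repulsive 1-back response-alternation
bias, and target intensity is driven by an accelerated
stochastic-approximation staircase holding accuracy near 75%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .trials import Dataset

#: sensory separation giving 75% correct for an unbiased observer: 2·Φ⁻¹(0.75)
DELTA_75 = float(2.0 * norm.ppf(0.75))


@dataclass(frozen=True)
class StaircaseConfig:
    """Accelerated stochastic-approximation staircase (Kesten-style).

    After each trial the level moves against the outcome,
    ``level -= step/(1+shift_count) · (outcome − target_p)``, and the
    effective step shrinks whenever the outcome direction reverses, so the
    level converges on the intensity yielding ``target_p`` correct.
    """

    initial_level: float = 60.0
    initial_step: float = 6.0
    target_p: float = 0.75


@dataclass
class StaircaseState:
    level: float
    step: float
    shift_count: int = 0
    target_p: float = 0.75
    last_outcome: int | None = None


def staircase_next(state: StaircaseState, correct: bool) -> StaircaseState:
    """One accelerated stochastic-approximation update."""
    outcome = 1 if correct else 0
    shifts = state.shift_count
    if state.last_outcome is not None and outcome != state.last_outcome:
        shifts += 1
    level = state.level - (state.step / (1 + shifts)) * (outcome - state.target_p)
    return StaircaseState(
        level=level,
        step=state.step,
        shift_count=shifts,
        target_p=state.target_p,
        last_outcome=outcome,
    )


@dataclass(frozen=True)
class ObserverConfig:
    """Parameters of the synthetic observer and experiment.

    Defaults mirror the experimental design being emulated: 14 subjects,
    2,800 trials each, SOA uniform on 0.2–1.2 s, random ear assignment,
    ~75% accuracy held by the staircase, and a history-gated antiphase
    sensitivity modulation near 9.4 Hz.
    """

    n_subjects: int = 14
    n_trials: int = 2800
    soa_range: tuple[float, float] = (0.2, 1.2)
    iti_range: tuple[float, float] = (1.2, 2.2)
    delta: float = DELTA_75           # used when the staircase is disabled
    osc_freq: float = 9.4             # Hz
    osc_amp: float = 0.4              # relative gain modulation, in [0, 1)
    osc_phase_right: float = 0.0      # degrees at noise onset
    ear_phase_offset: float = 180.0   # degrees; antiphase ears by default
    gate_depth: int = 2               # trials a target potentiates its ear
    gate_decay: float | None = None   # optional per-trial decay factor
    bias_2back: float = 0.1           # assimilative criterion shift
    alt_1back: float = 0.05           # repulsive response-alternation shift
    c0: float = 0.0                   # baseline criterion
    staircase: StaircaseConfig | None = field(default_factory=StaircaseConfig)
    threshold_mean_db: float = 55.0   # population mean of subject thresholds
    threshold_sd_db: float = 3.0
    slope_db: float = 4.0             # psychometric slope: delta = 2(level−θ)/slope
    rt_median_s: float = 0.6
    rt_sigma: float = 0.35
    blocks: int = 40
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.osc_amp < 1.0):
            raise ValueError("osc_amp must lie in [0, 1)")
        if self.gate_depth < 0:
            raise ValueError("gate_depth must be >= 0")
        object.__setattr__(self, "osc_phase_right", float(np.mod(self.osc_phase_right, 360.0)))
        object.__setattr__(self, "ear_phase_offset", float(np.mod(self.ear_phase_offset, 360.0)))


def ear_gain(ear: str, soa: float, cfg: ObserverConfig, gated: bool, trials_since: int | None = None) -> float:
    """Multiplicative sensitivity gain λ_e(soa) of the stimulated ear."""
    if not gated:
        return 1.0
    phi = cfg.osc_phase_right if ear == "R" else cfg.osc_phase_right + cfg.ear_phase_offset
    amp = cfg.osc_amp
    if cfg.gate_decay is not None and trials_since is not None and trials_since > 1:
        amp = amp * cfg.gate_decay ** (trials_since - 1)
    return 1.0 + amp * math.cos(2.0 * math.pi * cfg.osc_freq * soa + math.radians(phi))


def response_p_right(
    stim_ear: str,
    soa: float,
    cfg: ObserverConfig,
    delta: float,
    gated: bool,
    back2_stim: str | None = None,
    back1_resp: str | None = None,
    trials_since: int | None = None,
) -> float:
    """Closed-form P(respond "R") for one trial of the generative model.

    Evidence is X ~ N(s·(delta/2)·λ_e(soa), 1) with s = +1 for a right and
    −1 for a left target; the observer responds "R" iff X exceeds the
    trial's decision threshold c0 − bias_2back·s₂ + alt_1back·r₁.
    """
    s = 1.0 if stim_ear == "R" else -1.0
    lam = ear_gain(stim_ear, soa, cfg, gated, trials_since)
    s2 = 0.0 if back2_stim is None else (1.0 if back2_stim == "R" else -1.0)
    r1 = 0.0 if back1_resp is None else (1.0 if back1_resp == "R" else -1.0)
    c_trial = cfg.c0 - cfg.bias_2back * s2 + cfg.alt_1back * r1
    mean = s * (delta / 2.0) * lam
    p = norm.cdf(mean - c_trial)
    if not (0.0 < p < 1.0):
        raise ValueError("response probability left (0,1); extreme parameters")
    return float(p)


def observer_response(
    stim_ear: str,
    soa: float,
    cfg: ObserverConfig,
    rng: np.random.Generator,
    delta: float | None = None,
    gated: bool = False,
    back2_stim: str | None = None,
    back1_resp: str | None = None,
    trials_since: int | None = None,
) -> str:
    """Sample one response ("L"/"R") from the generative model."""
    delta = cfg.delta if delta is None else delta
    s = 1.0 if stim_ear == "R" else -1.0
    lam = ear_gain(stim_ear, soa, cfg, gated, trials_since)
    s2 = 0.0 if back2_stim is None else (1.0 if back2_stim == "R" else -1.0)
    r1 = 0.0 if back1_resp is None else (1.0 if back1_resp == "R" else -1.0)
    c_trial = cfg.c0 - cfg.bias_2back * s2 + cfg.alt_1back * r1
    x = s * (delta / 2.0) * lam + rng.standard_normal()
    return "R" if x > c_trial else "L"


def simulate_dataset(cfg: ObserverConfig) -> Dataset:
    """Simulate the full experiment; deterministic given ``cfg.seed``.

    Per subject: sequential trials with equiprobable ear, uniform SOA,
    staircase-controlled intensity (one staircase per ear, as in the
    emulated design), responses from the evidence model, and lognormal
    nuisance reaction times.
    """
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    rows = []
    trials_per_block = max(1, cfg.n_trials // cfg.blocks)
    ln_mu = math.log(cfg.rt_median_s)
    for si in range(cfg.n_subjects):
        rng = np.random.default_rng(seeds[si])
        subject = f"S{si + 1:02d}"
        theta = cfg.threshold_mean_db + cfg.threshold_sd_db * rng.standard_normal()
        if cfg.staircase is not None:
            sc = cfg.staircase
            stairs = {
                e: StaircaseState(level=sc.initial_level, step=sc.initial_step, target_p=sc.target_p)
                for e in ("L", "R")
            }
        else:
            stairs = None

        ears = np.where(rng.random(cfg.n_trials) < 0.5, "L", "R")
        soas = rng.uniform(cfg.soa_range[0], cfg.soa_range[1], cfg.n_trials)
        rts = np.exp(ln_mu + cfg.rt_sigma * rng.standard_normal(cfg.n_trials))
        noise = rng.standard_normal(cfg.n_trials)

        last_seen = {"L": None, "R": None}  # trial index of last target per ear
        prev_stim: list[str] = []
        prev_resp: list[str] = []
        for ti in range(cfg.n_trials):
            ear = str(ears[ti])
            soa = float(soas[ti])
            if stairs is not None:
                level = stairs[ear].level
                delta = 2.0 * (level - theta) / cfg.slope_db
            else:
                level = theta + cfg.slope_db * cfg.delta / 2.0
                delta = cfg.delta
            since = None if last_seen[ear] is None else ti - last_seen[ear]
            gated = since is not None and since <= cfg.gate_depth
            s2 = prev_stim[-2] if len(prev_stim) >= 2 else None
            r1 = prev_resp[-1] if len(prev_resp) >= 1 else None

            s = 1.0 if ear == "R" else -1.0
            lam = ear_gain(ear, soa, cfg, gated, since)
            s2v = 0.0 if s2 is None else (1.0 if s2 == "R" else -1.0)
            r1v = 0.0 if r1 is None else (1.0 if r1 == "R" else -1.0)
            c_trial = cfg.c0 - cfg.bias_2back * s2v + cfg.alt_1back * r1v
            x = s * (delta / 2.0) * lam + noise[ti]
            resp = "R" if x > c_trial else "L"
            correct = resp == ear
            if stairs is not None:
                stairs[ear] = staircase_next(stairs[ear], correct)

            rows.append(
                (
                    subject,
                    ti // trials_per_block + 1,
                    ti + 1,
                    soa,
                    ear,
                    resp,
                    float(rts[ti]),
                    float(level),
                )
            )
            last_seen[ear] = ti
            prev_stim.append(ear)
            prev_resp.append(resp)

    df = pd.DataFrame(
        rows,
        columns=["subject", "block", "order", "soa_s", "stim_ear", "resp_ear", "rt_s", "intensity_db"],
    )
    return Dataset(df, meta={"simulation": {"config": cfg, "seed": cfg.seed}})


def accuracy(d: Dataset, burn_in: int = 200) -> float:
    """Mean proportion correct across subjects after a per-subject burn-in."""
    df = d.trials
    accs = []
    for _, grp in df.groupby("subject", sort=False):
        g = grp[grp["order"] > burn_in]
        accs.append(float((g["stim_ear"] == g["resp_ear"]).mean()))
    return float(np.mean(accs))
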