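"""Single-trial harmonic regression per subject and 2D group statistics.

Instead of binning, each subject's trial outcomes y_i (±1 accuracy or ±1
response bias) are regressed on harmonics of the target SOA t_i,

    ŷ = β0 + β1·sin(2πft) + β2·cos(2πft) [+ β3·S(t)],

where the optional stimulus regressor S ∈ {−1, +1} absorbs stimulus
imbalance under non-uniform SOA sampling.  The (β1, β2) pair at each
frequency is a 2D vector whose length and angle are the oscillation
amplitude and phase (cosine convention: phase = atan2(−β1, β2), matching
the aggregate sinusoid fit).  Group inference uses the vector average
across subjects: a max-amplitude permutation test over the frequency
grid, a one-sample 2D t-test on the subject vectors, and a BIC-style
Bayes-factor approximation from the t statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spectrum import PermutationNull
from .trials import Dataset
from .vectors import Vector2D, mean_vector, wrap_deg


@dataclass(frozen=True)
class HarmonicFit:
    freq: float
    beta0: float
    beta1: float
    beta2: float
    beta3: float  # NaN when the stimulus regressor is excluded or collinear
    n_trials: int
    stim_dropped: bool = False

    @property
    def vector(self) -> Vector2D:
        amp = float(np.hypot(self.beta1, self.beta2))
        phase = float(wrap_deg(np.rad2deg(np.arctan2(-self.beta1, self.beta2))))
        return Vector2D(amp, phase)


def _outcome(df: pd.DataFrame, outcome: str) -> np.ndarray:
    if outcome == "accuracy":
        return np.where(df["resp_ear"].to_numpy() == df["stim_ear"].to_numpy(), 1.0, -1.0)
    if outcome == "bias":
        return np.where(df["resp_ear"].to_numpy() == "R", 1.0, -1.0)
    raise ValueError(f"unknown outcome {outcome!r}")


def harmonic_glm_arrays(
    t: np.ndarray, y: np.ndarray, freq: float, S: np.ndarray | None = None
) -> HarmonicFit:
    """OLS of y on {1, sin(2πft), cos(2πft)[, S]}; no link transformation."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if len(t) < 10:
        raise ValueError("need at least 10 trials for a harmonic fit")
    w = 2.0 * np.pi * freq
    cols = [np.ones_like(t), np.sin(w * t), np.cos(w * t)]
    stim_dropped = False
    if S is not None:
        S = np.asarray(S, float)
        if np.ptp(S) == 0:  # all targets in one ear: collinear with intercept
            stim_dropped = True
        else:
            cols.append(S)
    X = np.column_stack(cols)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    b3 = float(beta[3]) if (S is not None and not stim_dropped) else float("nan")
    return HarmonicFit(
        freq=float(freq),
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta2=float(beta[2]),
        beta3=b3,
        n_trials=len(t),
        stim_dropped=stim_dropped,
    )


def harmonic_glm(
    subject_trials: pd.DataFrame,
    freq: float,
    outcome: str = "bias",
    include_stim: bool = True,
) -> HarmonicFit:
    """Harmonic GLM on one subject's valid trials."""
    df = subject_trials
    if "valid" in df.columns:
        df = df[df["valid"]]
    t = df["soa_s"].to_numpy(float)
    y = _outcome(df, outcome)
    S = np.where(df["stim_ear"].to_numpy() == "R", 1.0, -1.0) if include_stim else None
    return harmonic_glm_arrays(t, y, freq, S)


def subject_vectors(
    d: Dataset,
    grid: np.ndarray,
    outcome: str = "bias",
    include_stim: bool = True,
) -> tuple[list, np.ndarray]:
    """(β1, β2) for every subject × frequency.

    Returns the subject roster and an array of shape (n_subjects,
    n_freqs, 2).
    """
    grid = np.asarray(grid, float)
    subjects = d.subjects
    out = np.empty((len(subjects), len(grid), 2))
    for i, subj in enumerate(subjects):
        df = d.trials[d.trials["subject"] == subj]
        for j, f in enumerate(grid):
            fit = harmonic_glm(df, f, outcome=outcome, include_stim=include_stim)
            out[i, j] = (fit.beta1, fit.beta2)
    return subjects, out


def group_spectrum(betas: np.ndarray, grid: np.ndarray) -> pd.DataFrame:
    """Vector-average the per-subject (β1, β2) at each frequency.

    ``betas`` has shape (n_subjects, n_freqs, 2).  Returns a table with the
    group amplitude and phase per frequency plus the mean components.
    """
    betas = np.asarray(betas, float)
    if betas.ndim != 3 or betas.shape[1] != len(grid):
        raise ValueError("betas must be (n_subjects, n_freqs, 2) matching the grid")
    mean_b = betas.mean(axis=0)  # (n_freqs, 2): mean (β1, β2)
    amp = np.hypot(mean_b[:, 0], mean_b[:, 1])
    phase = wrap_deg(np.rad2deg(np.arctan2(-mean_b[:, 0], mean_b[:, 1])))
    return pd.DataFrame(
        {"freq": np.asarray(grid, float), "amp": amp, "phase_deg": phase,
         "mean_beta1": mean_b[:, 0], "mean_beta2": mean_b[:, 1]}
    )


def _glm_null_max_amps(
    t: np.ndarray, y: np.ndarray, S: np.ndarray | None, grid: np.ndarray,
    rng: np.random.Generator, n_perm: int
) -> np.ndarray:
    """Per-permutation (β1, β2) for one subject at every grid frequency.

    Shuffling a subject's SOAs while keeping (y, S) pairs is equivalent to
    permuting (y, S) jointly over the fixed SOAs, so the harmonic design is
    fixed per frequency and the per-permutation solutions reduce to batched
    linear algebra.  Returns an array (n_freqs, n_perm, 2).
    """
    n = len(t)
    perm = np.argsort(rng.random((n_perm, n)), axis=1)  # independent permutations
    Y = y[perm].T  # (n, n_perm)
    out = np.empty((len(grid), n_perm, 2))
    if S is None:
        for j, f in enumerate(grid):
            w = 2.0 * np.pi * f
            F = np.column_stack([np.ones(n), np.sin(w * t), np.cos(w * t)])
            G = F.T @ F
            B = np.linalg.solve(G, F.T @ Y)  # (3, n_perm)
            out[j, :, 0] = B[1]
            out[j, :, 1] = B[2]
    else:
        Smat = S[perm].T  # (n, n_perm)
        sy = float(S @ y)  # invariant under joint permutation
        for j, f in enumerate(grid):
            w = 2.0 * np.pi * f
            F = np.column_stack([np.ones(n), np.sin(w * t), np.cos(w * t)])
            G = F.T @ F  # (3, 3)
            FS = F.T @ Smat  # (3, n_perm)
            FY = F.T @ Y  # (3, n_perm)
            A = np.empty((n_perm, 4, 4))
            A[:, :3, :3] = G
            A[:, :3, 3] = FS.T
            A[:, 3, :3] = FS.T
            A[:, 3, 3] = n
            b = np.empty((n_perm, 4))
            b[:, :3] = FY.T
            b[:, 3] = sy
            B = np.linalg.solve(A, b[:, :, None])[:, :, 0]  # (n_perm, 4)
            out[j, :, 0] = B[:, 1]
            out[j, :, 1] = B[:, 2]
    return out


def permutation_max_vector(
    d: Dataset,
    grid: np.ndarray,
    outcome: str = "bias",
    n_perm: int = 2000,
    seed: int | None = None,
    include_stim: bool = False,
    add_one: bool = True,
) -> PermutationNull:
    """Max-amplitude permutation test of the group vector spectrum.

    Each surrogate shuffles SOAs within every subject, refits the harmonic
    GLM at all grid frequencies, vector-averages across subjects, and
    contributes the maximal group amplitude over the grid to the null.
    ``include_stim`` adds the β3 stimulus regressor (recommended for real
    data; unnecessary under uniform simulated SOA sampling).
    """
    grid = np.asarray(grid, float)
    if len(d.subjects) < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives an unstable null tail", stacklevel=2)
    rng = np.random.default_rng(seed)

    subjects, betas = subject_vectors(d, grid, outcome=outcome, include_stim=include_stim)
    obs = group_spectrum(betas, grid)["amp"].to_numpy()

    acc = np.zeros((len(grid), n_perm, 2))
    for subj in subjects:
        df = d.trials[d.trials["subject"] == subj]
        if "valid" in df.columns:
            df = df[df["valid"]]
        t = df["soa_s"].to_numpy(float)
        y = _outcome(df, outcome)
        S = np.where(df["stim_ear"].to_numpy() == "R", 1.0, -1.0) if include_stim else None
        acc += _glm_null_max_amps(t, y, S, grid, rng, n_perm)
    acc /= len(subjects)
    null = np.hypot(acc[:, :, 0], acc[:, :, 1]).max(axis=0)  # (n_perm,)

    k = (null[None, :] >= obs[:, None]).sum(axis=1)
    corrected_p = (1.0 + k) / (1.0 + n_perm) if add_one else k / n_perm
    return PermutationNull(
        freqs=grid,
        observed=obs,
        null_values=null,
        corrected_p=corrected_p,
        threshold95=float(np.quantile(null, 0.95)),
        stat_name="max-vector",
        n_perm=n_perm,
        seed=seed,
        add_one=add_one,
    )


@dataclass(frozen=True)
class GroupVectorStat:
    """One-sample 2D t-test on per-subject amplitude/phase vectors."""

    mean_vector: Vector2D
    sd_2d: float
    amp_sem: float
    phase_sem_deg: float
    t_stat: float
    df: int
    p: float
    log_bf: float
    n: int
    degenerate: bool = False


def vector_t_test(vectors: np.ndarray, sem_divisor: str = "sqrt") -> GroupVectorStat:
    """2D one-sample t-test of the mean subject vector against the origin.

    The 2D scatter is the RMS deviation from the mean vector,
    SD = √(Σ|v−mv|²/N).  Deviations are projected on the mean direction;
    the amplitude SEM is the RMS parallel projection divided by √(N−1)
    (``sem_divisor="sqrt"``, default) or by N−1 (``"linear"``, the literal
    reading).  t = |mv| / SEM_amp with df = N−1, two-tailed p; the phase
    SEM uses the perpendicular projection via error propagation.
    """
    v = np.asarray(vectors, float)
    n = len(v)
    if n < 3:
        raise ValueError("need at least 3 subject vectors")
    mv = v.mean(axis=0)
    mvec = Vector2D.from_components(mv[0], mv[1])
    dev = v - mv
    sd_2d = float(np.sqrt(np.mean(np.sum(dev**2, axis=1))))
    if mvec.amp == 0:
        u = np.array([1.0, 0.0])
    else:
        u = mv / mvec.amp
    u_perp = np.array([-u[1], u[0]])
    s_par = float(np.sqrt(np.mean((dev @ u) ** 2)))
    s_perp = float(np.sqrt(np.mean((dev @ u_perp) ** 2)))
    div = np.sqrt(n - 1) if sem_divisor == "sqrt" else (n - 1)
    amp_sem = s_par / div
    phase_sem = np.rad2deg(s_perp / div / mvec.amp) if mvec.amp > 0 else float("inf")
    scale = float(np.abs(v).max())
    degenerate = amp_sem <= 1e-12 * max(scale, 1e-30)
    t = float("inf") if degenerate else mvec.amp / amp_sem
    df = n - 1
    p = 0.0 if degenerate else float(2.0 * stats.t.sf(abs(t), df))
    lb = bayes_factor_t(t, n, df)
    return GroupVectorStat(
        mean_vector=mvec,
        sd_2d=sd_2d,
        amp_sem=float(amp_sem),
        phase_sem_deg=float(phase_sem),
        t_stat=t,
        df=df,
        p=p,
        log_bf=lb,
        n=n,
        degenerate=degenerate,
    )


def bayes_factor_t(t_stat: float, n: int, df2: int, base: float = 10.0) -> float:
    """BIC approximation to the one-sample Bayes factor from a t statistic.

    BF₁₀ ≈ (1 + t²/df2)^(n/2) / √n, returned as a logarithm (base 10 by
    default).  Monotone increasing in |t|; at t = 0 it equals −log(√n),
    favouring the null.
    """
    if df2 < 1:
        raise ValueError("df2 must be >= 1")
    if not np.isfinite(t_stat):
        return float("inf")
    log_bf10 = (n / 2.0) * np.log1p(t_stat**2 / df2) - 0.5 * np.log(n)
    return float(log_bf10 / np.log(base))
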