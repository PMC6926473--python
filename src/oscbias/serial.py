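"""Serial dependence: n-back-contingent bias and congruency subsetting.

The average serial effect of the trial n places back is measured by
splitting each subject's trials on the ear of the n-back stimulus (or
response) and computing the SDT criterion in each split, pooled over SOA.
With the sign convention c > 0 = leftward tendency, a positive
(c | n-back L) − (c | n-back R) difference is assimilative.  Congruency
splits group trials by stimulus-history pattern codes (e.g. the totally
congruent set llL ∪ rrR) for the history-gated oscillation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .harmonics import bayes_factor_t
from .sdt import RatePair, sdt_point
from .trials import Dataset, response_pattern

#: pattern sets per congruency scheme; "totally" requires depth-2 labels
SCHEMES = {
    "1back": {"congruent": ("lL", "rR"), "incongruent": ("lR", "rL")},
    "2back_given_1back_incongruent": {"congruent": ("lrL", "rlR"), "incongruent": ("rrL", "llR")},
    "totally": {"congruent": ("llL", "rrR"), "incongruent": ("rrL", "llR")},
}


def _criterion_of(df: pd.DataFrame, denom: float = 2.0) -> tuple[float, float]:
    stim_r = df["stim_ear"].to_numpy() == "R"
    resp_r = df["resp_ear"].to_numpy() == "R"
    n_r = int(stim_r.sum())
    n_l = int((~stim_r).sum())
    if n_r == 0 or n_l == 0:
        raise ValueError("empty target condition")
    pt = sdt_point(
        RatePair(
            hit_right=float(resp_r[stim_r].mean()),
            fa_left=float(resp_r[~stim_r].mean()),
            n_right=n_r,
            n_left=n_l,
        ),
        denom=denom,
    )
    return pt.criterion, pt.dprime


def contingent_bias(
    d: Dataset,
    nback: int = 2,
    contingent_on: str = "stimulus",
    denom: float = 2.0,
) -> pd.DataFrame:
    """Per-subject criterion and d' split by the n-back stimulus/response ear.

    Returns one row per subject with columns ``c_backL``/``c_backR`` (and
    ``d_backL``/``d_backR``); ``c_diff = c_backL − c_backR`` is positive
    for an assimilative stimulus effect.  Subjects with an empty split are
    dropped (logged in the returned frame's attrs).
    """
    if contingent_on not in ("stimulus", "response"):
        raise ValueError(f"unknown contingency {contingent_on!r}")
    col = f"back{nback}_stim" if contingent_on == "stimulus" else f"back{nback}_resp"
    if col not in d.trials.columns:
        raise ValueError(f"history not labeled to depth {nback}")
    rows, dropped = [], []
    for subj in d.subjects:
        df = d.trials[(d.trials["subject"] == subj)]
        if "valid" in df.columns:
            df = df[df["valid"]]
        df = df[df[col].notna()]
        try:
            c_l, d_l = _criterion_of(df[df[col] == "L"], denom)
            c_r, d_r = _criterion_of(df[df[col] == "R"], denom)
        except ValueError:
            dropped.append(subj)
            continue
        rows.append((subj, c_l, c_r, c_l - c_r, d_l, d_r, d_l - d_r))
    out = pd.DataFrame(
        rows,
        columns=["subject", "c_backL", "c_backR", "c_diff", "d_backL", "d_backR", "d_diff"],
    )
    out.attrs["dropped"] = dropped
    out.attrs["nback"] = nback
    out.attrs["contingent_on"] = contingent_on
    return out


@dataclass(frozen=True)
class SerialResult:
    nback: int
    contingent_on: str
    mean_diff: float
    t_stat: float
    df: int
    p_raw: float
    p_corrected: float
    log_bf: float
    n_subjects: int
    degenerate: bool = False


def serial_table(
    d: Dataset,
    max_back: int = 5,
    contingent_on: str = "stimulus",
    correction: str = "bonferroni",
    measure: str = "criterion",
    denom: float = 2.0,
) -> pd.DataFrame:
    """Group serial-dependence table over lags 1..max_back.

    A paired two-tailed t-test across subjects compares the criterion (or
    d') conditioned on n-back = L vs R at each lag.  Bonferroni correction
    multiplies the raw p by the number of lags without capping (matching
    the convention of reporting values such as p = 3.69); BH-FDR is
    available with ``correction="fdr"``.
    """
    if correction not in ("bonferroni", "bonferroni_capped", "fdr"):
        raise ValueError(f"unknown correction {correction!r}")
    col = "c_diff" if measure == "criterion" else "d_diff"
    rows = []
    raw_ps = []
    for k in range(1, max_back + 1):
        tab = contingent_bias(d, nback=k, contingent_on=contingent_on, denom=denom)
        if len(tab) < 3:
            raise ValueError(f"fewer than 3 subjects with defined {k}-back splits")
        diffs = tab[col].to_numpy()
        n = len(diffs)
        degenerate = np.std(diffs, ddof=1) == 0.0
        if degenerate:
            t = float("inf") if diffs.mean() != 0 else 0.0
            p = 0.0 if diffs.mean() != 0 else 1.0
        else:
            t, p = stats.ttest_1samp(diffs, 0.0)
            t, p = float(t), float(p)
        raw_ps.append(p)
        rows.append(
            SerialResult(
                nback=k,
                contingent_on=contingent_on,
                mean_diff=float(diffs.mean()),
                t_stat=t,
                df=n - 1,
                p_raw=p,
                p_corrected=np.nan,
                log_bf=bayes_factor_t(t, n, n - 1),
                n_subjects=n,
                degenerate=bool(degenerate),
            )
        )
    raw = np.asarray(raw_ps)
    if correction == "bonferroni":
        corr = raw * max_back
    elif correction == "bonferroni_capped":
        corr = np.minimum(raw * max_back, 1.0)
    else:  # Benjamini-Hochberg
        order = np.argsort(raw)
        ranked = raw[order] * max_back / (np.arange(max_back) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        corr = np.empty_like(raw)
        corr[order] = np.minimum(ranked, 1.0)
    out = pd.DataFrame([r.__dict__ for r in rows])
    out["p_corrected"] = corr
    out.attrs["correction"] = correction
    out.attrs["measure"] = measure
    return out


def congruency_split(d: Dataset, scheme: str, contingent_on: str = "stimulus") -> dict[str, Dataset]:
    """Split a history-labeled Dataset into named congruency subsets.

    Schemes: ``"1back"`` (lL∪rR vs lR∪rL), ``"2back_given_1back_incongruent"``
    (lrL∪rlR vs rrL∪llR) and ``"totally"`` (llL∪rrR vs rrL∪llR).  With
    ``contingent_on="response"``, patterns are rebuilt from previous
    responses (the current letter stays the stimulus ear).  Subsets
    partition the trials whose patterns are defined at the scheme's depth.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}")
    sets = SCHEMES[scheme]
    depth = len(next(iter(sets.values()))[0]) - 1
    if contingent_on == "stimulus":
        cols = [f"back{k}_stim" for k in range(depth, 0, -1)]
        if any(c not in d.trials.columns for c in cols):
            raise ValueError(f"history not labeled to depth {depth}; run label_history first")
        # rebuild the pattern at the scheme's depth so deeper labeling still works
        pat = d.trials[cols[0]].str.lower()
        for c in cols[1:]:
            pat = pat + d.trials[c].str.lower()
        pat = pat + d.trials["stim_ear"]
    elif contingent_on == "response":
        pat = response_pattern(d, depth=depth)
    else:
        raise ValueError(f"unknown contingency {contingent_on!r}")
    out = {}
    for name, patterns in sets.items():
        mask = pat.isin(patterns)
        out[name] = d.subset(mask, name=f"{scheme}:{name}")
    return out
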