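"""Trial-level data model for dichotic 2AFC tone-detection experiments.

A trial table has one row per 2AFC observation: which ear received the
target tone, which ear the subject reported, the stimulus-onset asynchrony
(SOA) of the target within the 2-s noise burst, the reaction time, and the
staircase-controlled target intensity.  This module provides CSV I/O with
schema remapping, the standard exclusion filters (responses outside the
noise burst, outlying reaction times and intensities), and n-back
stimulus/response history labeling used by every history-contingent
analysis downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column names of the trial CSV schema
CANONICAL_COLUMNS = (
    "subject",
    "block",
    "order",
    "soa_s",
    "stim_ear",
    "resp_ear",
    "rt_s",
    "intensity_db",
)

EARS = ("L", "R")


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class RowError(ValueError):
    """One or more rows could not be parsed; offending line numbers attached."""

    def __init__(self, message: str, lines: Sequence[int]):
        super().__init__(message)
        self.lines = list(lines)


@dataclass
class Dataset:
    """Ordered trial table plus provenance metadata.

    ``trials`` always carries the canonical columns; analysis stages add
    ``valid``/``excl_reason`` (exclusion filtering) and ``back*_stim``,
    ``back*_resp``, ``pattern`` (history labeling).
    """

    trials: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.trials["subject"]))

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def valid_trials(self) -> pd.DataFrame:
        """Trials surviving exclusion (all trials if never filtered)."""
        if "valid" not in self.trials.columns:
            return self.trials
        return self.trials[self.trials["valid"]]

    def subset(self, mask: pd.Series, name: str | None = None) -> "Dataset":
        meta = dict(self.meta)
        if name is not None:
            meta["subset"] = name
        return Dataset(self.trials[mask].copy(), meta)

    def copy(self) -> "Dataset":
        return Dataset(self.trials.copy(), dict(self.meta))


def _normalize_ear(value) -> str:
    s = str(value).strip().upper()
    if s not in EARS:
        raise ValueError(f"not an ear label: {value!r}")
    return s


def read_trials(path: str | Path, schema: Mapping[str, str] | None = None) -> Dataset:
    """Read a trial CSV into a :class:`Dataset`.

    Parameters
    ----------
    path:
        CSV file with a header row.
    schema:
        Optional map from canonical column names (:data:`CANONICAL_COLUMNS`)
        to the names actually used in the file.

    Raises
    ------
    SchemaError
        if a required column is absent.
    RowError
        if ear labels or numeric fields cannot be parsed; the error lists
        the offending line numbers (1-based, header = line 1).
    """
    path = Path(path)
    raw = pd.read_csv(path)
    schema = dict(schema or {})
    rename = {schema.get(c, c): c for c in CANONICAL_COLUMNS}
    missing = [schema.get(c, c) for c in CANONICAL_COLUMNS if schema.get(c, c) not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")
    df = raw.rename(columns=rename)

    bad_lines: list[int] = []
    for col in ("stim_ear", "resp_ear"):
        normed = []
        for i, v in enumerate(df[col]):
            try:
                normed.append(_normalize_ear(v))
            except ValueError:
                bad_lines.append(i + 2)  # +1 header, +1 one-based
                normed.append(None)
        df[col] = normed
    for col in ("soa_s", "rt_s", "intensity_db"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_lines.extend((np.flatnonzero(coerced.isna() & df[col].notna()) + 2).tolist())
        df[col] = coerced
    for col in ("block", "order"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_lines.extend((np.flatnonzero(coerced.isna()) + 2).tolist())
        df[col] = coerced
    if bad_lines:
        lines = sorted(set(bad_lines))
        raise RowError(f"unparsable field(s) at line(s) {lines} of {path}", lines)

    df["block"] = df["block"].astype(int)
    df["order"] = df["order"].astype(int)
    df = df.sort_values(["subject", "order"], kind="stable").reset_index(drop=True)
    return Dataset(df, meta={"source": str(path)})


def write_trials(d: Dataset, path: str | Path) -> Path:
    """Write a Dataset back to the canonical CSV schema (plus any extra columns)."""
    path = Path(path)
    cols = [c for c in CANONICAL_COLUMNS if c in d.trials.columns]
    extra = [c for c in d.trials.columns if c not in cols]
    d.trials[cols + extra].to_csv(path, index=False)
    return path


def filter_trials(
    d: Dataset,
    rt_ci: float = 0.99,
    intensity_ci: float = 0.95,
    noise_duration: float = 2.0,
    min_valid: int = 20,
) -> Dataset:
    """Mark invalid trials without dropping or reordering rows.

    Exclusion rules, applied in order (a trial keeps the first reason that
    fires):

    a. ``premature_or_late`` — response before target onset (``rt <= 0``) or
       after the noise burst ends (``soa + rt > noise_duration``);
    b. ``rt_outlier`` — reaction time outside the subject's central
       ``rt_ci`` percentile interval;
    c. ``intensity_outlier`` — target intensity outside the subject's
       central ``intensity_ci`` interval.

    Percentile (distribution-free) intervals are used for (b) and (c).
    Exclusion counts per rule are recorded in ``meta['exclusions']``.
    """
    if not (0 < rt_ci < 1 and 0 < intensity_ci < 1):
        raise ValueError("coverages must lie in (0, 1)")
    df = d.trials.copy()
    reason = pd.Series(pd.NA, index=df.index, dtype="object")

    rt = df["rt_s"].to_numpy(float)
    soa = df["soa_s"].to_numpy(float)
    rule_a = (rt <= 0) | (soa + rt > noise_duration)
    reason[rule_a] = "premature_or_late"

    for col, cov, tag in (("rt_s", rt_ci, "rt_outlier"), ("intensity_db", intensity_ci, "intensity_outlier")):
        alpha = (1.0 - cov) / 2.0
        for _, idx in df.groupby("subject", sort=False).groups.items():
            x = df.loc[idx, col].to_numpy(float)
            lo, hi = np.nanquantile(x, [alpha, 1.0 - alpha])
            out = (x < lo) | (x > hi)
            mask = out & reason[idx].isna().to_numpy()
            reason[np.asarray(idx)[mask]] = tag

    df["valid"] = reason.isna()
    df["excl_reason"] = reason
    counts = reason.value_counts().to_dict()
    counts["retained"] = int(df["valid"].sum())

    for subj, grp in df.groupby("subject", sort=False):
        n_ok = int(grp["valid"].sum())
        if n_ok < min_valid:
            logger.warning("subject %r has only %d valid trials", subj, n_ok)

    meta = dict(d.meta)
    meta["exclusions"] = counts
    return Dataset(df, meta)


def label_history(d: Dataset, depth: int = 2, on: str = "presented") -> Dataset:
    """Annotate each trial with n-back stimulus/response ears and a pattern code.

    The pattern code concatenates the lowercase history ears, oldest first,
    with the uppercase current stimulus ear: the sequence L, R, L at depth 2
    gives the third trial the pattern ``"lrL"``.  The first ``depth`` trials
    of each subject have undefined history fields (``NA``) and no pattern.

    ``on`` selects the sequence the history is read from: ``"presented"``
    (default) uses the as-presented order including trials later marked
    invalid, since the subject experienced them; ``"retained"`` skips
    excluded trials.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if on not in ("presented", "retained"):
        raise ValueError(f"unknown history basis {on!r}")
    df = d.trials.copy()
    use = df.index if on == "presented" or "valid" not in df else df.index[df["valid"]]
    sub = df.loc[use]
    for k in range(1, depth + 1):
        g = sub.groupby("subject", sort=False)
        df.loc[use, f"back{k}_stim"] = g["stim_ear"].shift(k)
        df.loc[use, f"back{k}_resp"] = g["resp_ear"].shift(k)
    for k in range(1, depth + 1):
        for col in (f"back{k}_stim", f"back{k}_resp"):
            if col not in df:
                df[col] = pd.NA

    # pattern: oldest..newest lowercase history + uppercase current
    parts = [df[f"back{k}_stim"].str.lower() for k in range(depth, 0, -1)]
    pattern = parts[0]
    for p in parts[1:]:
        pattern = pattern + p
    df["pattern"] = (pattern + df["stim_ear"]).where(~pattern.isna())
    meta = dict(d.meta)
    meta["history"] = {"depth": depth, "on": on}
    return Dataset(df, meta)


def response_pattern(d: Dataset, depth: int = 2) -> pd.Series:
    """Pattern codes built from previous *responses* (current letter is still
    the stimulus ear), for response-contingent congruency splits."""
    df = d.trials
    cols = [f"back{k}_resp" for k in range(depth, 0, -1)]
    if any(c not in df.columns for c in cols):
        raise ValueError("history not labeled to requested depth")
    pattern = df[cols[0]].str.lower()
    for c in cols[1:]:
        pattern = pattern + df[c].str.lower()
    return (pattern + df["stim_ear"]).where(~pattern.isna())
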