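"""Reading and writing long-format longitudinal measurement tables.

The on-disk format is a tidy CSV with one row per measurement
(``subject_id,trait_id,time,value``) plus an optional per-subject outcome
table (``subject_id,outcome``).  Irregular, subject-specific visit times
are first-class: times are continuous reals on a declared study domain
and no common grid is assumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ["subject_id", "trait_id", "time", "value"]
OUTCOME_COLUMNS = ["subject_id", "outcome"]


@dataclass
class SparseFunctionalSample:
    """Irregular (time, value) observations for one trait.

    Parameters
    ----------
    subject_ids
        Ordered roster of subject identifiers.
    times, values
        Per-subject arrays; ``times[i]`` is strictly increasing with the
        same length as ``values[i]`` (the per-subject count ``N_i >= 1``).
    domain
        Closed study interval ``[t_min, t_max]`` containing every time.
    """

    subject_ids: list
    times: list
    values: list
    domain: tuple

    def __post_init__(self):
        if not (len(self.subject_ids) == len(self.times) == len(self.values)):
            raise ValueError("subject_ids, times and values must have equal length")
        t0, t1 = self.domain
        for sid, t, x in zip(self.subject_ids, self.times, self.values):
            t = np.asarray(t, dtype=float)
            x = np.asarray(x, dtype=float)
            if t.size == 0:
                raise ValueError(f"subject {sid!r} has no observations")
            if t.size != x.size:
                raise ValueError(f"subject {sid!r}: times/values length mismatch")
            if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x))):
                raise ValueError(f"subject {sid!r}: non-finite time or value")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"subject {sid!r}: times not strictly increasing")
            if t[0] < t0 or t[-1] > t1:
                raise ValueError(
                    f"subject {sid!r}: observation time outside domain [{t0}, {t1}]"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def counts(self) -> np.ndarray:
        """Per-subject observation counts N_i."""
        return np.array([len(t) for t in self.times])

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """All (time, value) pairs pooled across subjects."""
        return (
            np.concatenate([np.asarray(t, float) for t in self.times]),
            np.concatenate([np.asarray(v, float) for v in self.values]),
        )


@dataclass
class MultiTraitSample:
    """Several traits observed on a common, identically ordered roster."""

    traits: dict  # trait_id -> SparseFunctionalSample
    outcome: np.ndarray | None = None
    subject_ids: list = field(default_factory=list)

    def __post_init__(self):
        if not self.traits:
            raise ValueError("at least one trait is required")
        rosters = [tuple(s.subject_ids) for s in self.traits.values()]
        if len(set(rosters)) != 1:
            raise ValueError("trait rosters differ or are ordered differently")
        if not self.subject_ids:
            self.subject_ids = list(rosters[0])
        elif tuple(self.subject_ids) != rosters[0]:
            raise ValueError("subject_ids does not match trait rosters")
        if self.outcome is not None:
            self.outcome = np.asarray(self.outcome, dtype=float)
            if self.outcome.shape != (len(self.subject_ids),):
                raise ValueError("outcome must have one value per subject")
            if not np.all(np.isfinite(self.outcome)):
                raise ValueError("outcome contains non-finite values")

    @property
    def d(self) -> int:
        return len(self.traits)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def trait_ids(self) -> list:
        return list(self.traits)


def read_long_table(path, domain: tuple, required_traits: Sequence[str]) -> MultiTraitSample:
    """Read a tidy measurement CSV into a :class:`MultiTraitSample`.

    Subjects missing any of ``required_traits`` are dropped (the joint
    analysis needs scores on every trait); the number dropped is logged.
    """
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("time", "value"):
        bad = ~np.isfinite(pd.to_numeric(df[col], errors="coerce"))
        if bad.any():
            # +2: header row and 1-based numbering
            lines = (df.index[bad] + 2).tolist()[:10]
            raise ValueError(f"{path}: malformed or non-finite {col!r} at lines {lines}")
    t0, t1 = domain
    outside = (df["time"] < t0) | (df["time"] > t1)
    if outside.any():
        lines = (df.index[outside] + 2).tolist()[:10]
        raise ValueError(
            f"{path}: times outside domain [{t0}, {t1}] at lines {lines}"
        )

    required = list(required_traits) if required_traits else sorted(df["trait_id"].unique())
    observed = df.groupby("subject_id")["trait_id"].agg(set)
    complete = [sid for sid, s in observed.items() if set(required) <= s]
    n_dropped = len(observed) - len(complete)
    if n_dropped:
        logger.info("dropped %d subjects missing at least one required trait", n_dropped)
    if not complete:
        raise ValueError(f"{path}: no subject has all required traits {required}")

    roster = sorted(complete)
    traits = {}
    grouped = df[df["subject_id"].isin(roster)].sort_values(["subject_id", "trait_id", "time"])
    by_key = {k: g for k, g in grouped.groupby(["subject_id", "trait_id"])}
    for trait in required:
        times, values = [], []
        for sid in roster:
            g = by_key[(sid, trait)]
            times.append(g["time"].to_numpy(float))
            values.append(g["value"].to_numpy(float))
        traits[trait] = SparseFunctionalSample(list(roster), times, values, (t0, t1))
    return MultiTraitSample(traits=traits)


def read_outcomes(path, sample: MultiTraitSample) -> MultiTraitSample:
    """Attach per-subject scalar outcomes; subjects without one are dropped."""
    df = pd.read_csv(path)
    missing = [c for c in OUTCOME_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()[:5]
        raise ValueError(f"{path}: duplicate subject_id entries {dups}")
    y = dict(zip(df["subject_id"], pd.to_numeric(df["outcome"], errors="coerce")))
    keep = [i for i, sid in enumerate(sample.subject_ids)
            if sid in y and np.isfinite(y[sid])]
    n_dropped = sample.n_subjects - len(keep)
    if n_dropped:
        logger.info("dropped %d subjects without a finite outcome", n_dropped)
    if not keep:
        raise ValueError(f"{path}: no rostered subject has an outcome")
    sub = subset_subjects(sample, keep)
    sub.outcome = np.array([y[sub.subject_ids[i]] for i in range(len(keep))])
    return MultiTraitSample(traits=sub.traits, outcome=sub.outcome)


def subset_subjects(sample: MultiTraitSample, indices: Sequence[int]) -> MultiTraitSample:
    """Roster-preserving subset by positional indices."""
    indices = list(indices)
    traits = {}
    for tid, s in sample.traits.items():
        traits[tid] = SparseFunctionalSample(
            [s.subject_ids[i] for i in indices],
            [s.times[i] for i in indices],
            [s.values[i] for i in indices],
            s.domain,
        )
    outcome = sample.outcome[indices] if sample.outcome is not None else None
    return MultiTraitSample(traits=traits, outcome=outcome)


def write_long_table(path, sample: MultiTraitSample) -> None:
    rows = []
    for tid, s in sample.traits.items():
        for sid, t, v in zip(s.subject_ids, s.times, s.values):
            for tj, vj in zip(t, v):
                rows.append((sid, tid, tj, vj))
    pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS).to_csv(path, index=False)


def write_outcomes(path, sample: MultiTraitSample) -> None:
    if sample.outcome is None:
        raise ValueError("sample has no outcome to write")
    pd.DataFrame(
        {"subject_id": sample.subject_ids, "outcome": sample.outcome}
    ).to_csv(path, index=False)
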