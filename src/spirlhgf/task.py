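"""Probabilistic reward-learning task designs, trial data containers and quality control.

The SPIRL task (speed-incentivised reward learning) presents two fractals whose
reward probabilities are complementary (they sum to 1 on every trial) and drift
through phases of stability, high volatility (rapid probability switches) and
complete unpredictability (p = 0.5).  Participants predict the rewarded fractal
within a 1.7 s response window; both the binary prediction and its response time
are recorded.

This module owns the task-side data model: the design (per-trial reward
probability and phase label), per-subject trial records, outcome sampling,
adjusted correctness, the pre-registered inclusion rules, and delimited-text I/O.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TaskDesign",
    "TrialRecord",
    "Dataset",
    "QCVerdict",
    "DEFAULT_PHASE_SPEC",
    "generate_design",
    "default_design",
    "sample_outcomes",
    "max_expected_correct",
    "adjusted_correctness",
    "qc_filter",
    "read_trials",
    "write_trials",
    "read_design",
    "write_design",
]

PHASE_LABELS = ("stable", "volatile", "unpredictable")

#: Default 160-trial phase structure: a long stable block, rapid-switch volatile
#: blocks at complementary 0.8/0.2 levels, a 30-trial unpredictable block at 0.5.
DEFAULT_PHASE_SPEC = [
    (40, 0.8, "stable"),
    (10, 0.2, "volatile"),
    (10, 0.8, "volatile"),
    (10, 0.2, "volatile"),
    (10, 0.8, "volatile"),
    (20, 0.2, "stable"),
    (30, 0.5, "unpredictable"),
    (10, 0.8, "volatile"),
    (10, 0.2, "volatile"),
    (10, 0.8, "stable"),
]


@dataclass(frozen=True)
class TaskDesign:
    """Per-trial reward probability trajectory of one task run.

    ``p_reward_a[k]`` is the probability that fractal A is rewarded on trial
    k+1; fractal B's probability is the complement.  ``phase_label`` tags each
    trial as stable / volatile / unpredictable.
    """

    p_reward_a: np.ndarray
    phase_label: np.ndarray
    response_window: float = 1.7

    def __post_init__(self) -> None:
        p = np.asarray(self.p_reward_a, dtype=float)
        lab = np.asarray(self.phase_label, dtype=object)
        if p.ndim != 1 or p.size < 1:
            raise ValueError("design needs at least one trial")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("reward probabilities must lie in [0, 1]")
        if lab.shape != p.shape:
            raise ValueError("phase labels must cover all trials")
        bad = set(lab) - set(PHASE_LABELS)
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")
        object.__setattr__(self, "p_reward_a", p)
        object.__setattr__(self, "phase_label", lab)

    @property
    def n_trials(self) -> int:
        return int(self.p_reward_a.size)


@dataclass
class TrialRecord:
    """One trial of one subject.

    ``u`` encodes which option was rewarded (1 = fractal A).  ``y_bin`` and
    ``y_rt`` are the subject's prediction and response time in seconds; both are
    ``None`` on ignored trials.  ``irregular`` marks anticipatory responses
    (RT < 0.1 s) whose RT is excluded from likelihoods.
    """

    k: int
    u: int
    y_bin: int | None = None
    y_rt: float | None = None
    ignored: bool = False
    irregular: bool = False

    def __post_init__(self) -> None:
        if self.u not in (0, 1):
            raise ValueError("u must be 0 or 1")
        if self.ignored and (self.y_bin is not None or self.y_rt is not None):
            raise ValueError("ignored trials carry no response or RT")
        if self.irregular and not (self.y_rt is not None and self.y_rt < 0.1):
            raise ValueError("irregular flag requires RT < 0.1 s")


@dataclass
class Dataset:
    """All trials of one subject, ordered 1..n without gaps."""

    subject_id: str
    trials: list[TrialRecord]
    design: TaskDesign | None = None

    def __post_init__(self) -> None:
        ks = [t.k for t in self.trials]
        if ks != list(range(1, len(ks) + 1)):
            raise ValueError("trial indices must be 1..n without gaps")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def u(self) -> np.ndarray:
        return np.array([t.u for t in self.trials], dtype=np.int64)

    @property
    def y_bin(self) -> np.ndarray:
        """Binary responses as float with NaN for missing."""
        return np.array(
            [np.nan if t.y_bin is None else float(t.y_bin) for t in self.trials]
        )

    @property
    def y_rt(self) -> np.ndarray:
        """Response times in seconds with NaN for missing."""
        return np.array(
            [np.nan if t.y_rt is None else float(t.y_rt) for t in self.trials]
        )

    @property
    def valid_rt(self) -> np.ndarray:
        """Trials whose RT enters the likelihood (responded, not anticipatory)."""
        return np.array(
            [t.y_rt is not None and not t.ignored and not t.irregular for t in self.trials]
        )

    @property
    def valid_bin(self) -> np.ndarray:
        """Trials whose binary response enters the likelihood."""
        return np.array([t.y_bin is not None and not t.ignored for t in self.trials])

    @property
    def n_bad(self) -> int:
        return sum(t.ignored or t.irregular for t in self.trials)


def generate_design(phase_spec, response_window: float = 1.7) -> TaskDesign:
    """Concatenate phase blocks ``(length, p_reward_A, label)`` into a design."""
    if not phase_spec:
        raise ValueError("phase spec is empty")
    probs, labels = [], []
    for length, p, label in phase_spec:
        length = int(length)
        if length <= 0:
            raise ValueError("block lengths must be positive")
        if not 0.0 <= p <= 1.0:
            raise ValueError("reward probability outside [0, 1]")
        probs.extend([float(p)] * length)
        labels.extend([label] * length)
    return TaskDesign(np.array(probs), np.array(labels, dtype=object), response_window)


def default_design() -> TaskDesign:
    """The built-in 160-trial phase-structured design."""
    return generate_design(DEFAULT_PHASE_SPEC)


def sample_outcomes(design: TaskDesign, seed) -> np.ndarray:
    """Draw the rewarded option per trial, u_k ~ Bernoulli(p_reward_A_k).

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    rng = np.random.default_rng(seed)
    return (rng.random(design.n_trials) < design.p_reward_a).astype(np.int64)


def max_expected_correct(u: np.ndarray, design: TaskDesign) -> int:
    """Trials on which the objectively more probable option was rewarded.

    This is the best prediction count achievable by an agent that knows the
    probability schedule.  On p = 0.5 trials neither option is more probable;
    such trials count their realised outcome (they are trivially achievable by
    an agent with full knowledge of the realised sequence).
    """
    u = np.asarray(u)
    p = design.p_reward_a[: u.size]  # tolerate incomplete runs
    better = np.where(p >= 0.5, 1, 0)
    return int(np.sum((u == better) | (p == 0.5)))


def adjusted_correctness(n_correct: int, max_expected: int) -> float:
    """Percent correct rescaled so the schedule's achievable maximum is 100%.

    Under a probabilistic schedule even an ideal observer is wrong whenever the
    less probable option is rewarded, so raw percent correct understates
    performance; dividing by the achievable maximum (122 of 160 trials for the
    original task sequence) restores a 0-100% scale.  Capped at 100.
    """
    if n_correct < 0 or max_expected < 1:
        raise ValueError("need n_correct >= 0 and max_expected_correct >= 1")
    return min(100.0, 100.0 * n_correct / max_expected)


@dataclass(frozen=True)
class QCVerdict:
    included: bool
    reasons: tuple[str, ...]
    n_bad: int
    adjusted_pct: float


def qc_filter(
    dataset: Dataset,
    max_bad_trials: int = 10,
    min_adjusted_pct: float = 65.0,
    max_expected: int | None = None,
) -> QCVerdict:
    """Apply the pre-registered inclusion rules.

    A subject is excluded if (a) more than ``max_bad_trials`` trials were
    ignored or irregular, (b) adjusted correctness is below
    ``min_adjusted_pct`` percent, or (c) the task is incomplete relative to its
    design.  All violated rules are reported.
    """
    reasons: list[str] = []
    if dataset.design is not None and dataset.n_trials < dataset.design.n_trials:
        reasons.append("incomplete")
    n_bad = dataset.n_bad
    if n_bad > max_bad_trials:
        reasons.append("bad-trials")
    if max_expected is None:
        if dataset.design is None:
            raise ValueError("need a design or an explicit max_expected")
        max_expected = max_expected_correct(dataset.u, dataset.design)
    y = dataset.y_bin
    n_correct = int(np.nansum(y == dataset.u))
    pct = adjusted_correctness(n_correct, max_expected)
    if pct < min_adjusted_pct:
        reasons.append("accuracy")
    return QCVerdict(not reasons, tuple(reasons), n_bad, pct)


# ---------------------------------------------------------------------------
# delimited-text I/O

_COLUMNS = ["subject_id", "trial", "u", "y_bin", "y_rt_s", "ignored", "irregular"]


def write_trials(datasets: list[Dataset], path) -> None:
    """Write subjects to CSV; missing responses become empty fields."""
    rows = []
    for ds in datasets:
        for t in ds.trials:
            rows.append(
                {
                    "subject_id": ds.subject_id,
                    "trial": t.k,
                    "u": t.u,
                    "y_bin": "" if t.y_bin is None else t.y_bin,
                    "y_rt_s": "" if t.y_rt is None else t.y_rt,
                    "ignored": int(t.ignored),
                    "irregular": int(t.irregular),
                }
            )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_trials(path, design: TaskDesign | None = None) -> list[Dataset]:
    """Read subjects from CSV written by :func:`write_trials`.

    Validates the header and trial-index contiguity, and (re)applies the
    anticipatory-response rule: any present RT below 0.1 s is flagged
    irregular on load.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    if list(df.columns) != _COLUMNS:
        raise ValueError(f"expected columns {_COLUMNS}, got {list(df.columns)}")
    datasets = []
    for sid, grp in df.groupby("subject_id", sort=False):
        if grp["trial"].duplicated().any():
            raise ValueError(f"duplicate trial indices for subject {sid}")
        grp = grp.sort_values("trial")
        trials = []
        for _, row in grp.iterrows():
            y_bin = None if pd.isna(row["y_bin"]) else int(row["y_bin"])
            y_rt = None if pd.isna(row["y_rt_s"]) else float(row["y_rt_s"])
            irregular = bool(int(row["irregular"])) or (y_rt is not None and y_rt < 0.1)
            trials.append(
                TrialRecord(
                    k=int(row["trial"]),
                    u=int(row["u"]),
                    y_bin=y_bin,
                    y_rt=y_rt,
                    ignored=bool(int(row["ignored"])),
                    irregular=irregular,
                )
            )
        datasets.append(Dataset(str(sid), trials, design))
    return datasets


def write_design(design: TaskDesign, path) -> None:
    """Serialise a design as YAML/JSON phase blocks (run-length encoded)."""
    blocks = []
    p, lab = design.p_reward_a, design.phase_label
    start = 0
    for i in range(1, design.n_trials + 1):
        if i == design.n_trials or p[i] != p[start] or lab[i] != lab[start]:
            blocks.append(
                {"length": i - start, "p_reward_A": float(p[start]), "label": str(lab[start])}
            )
            start = i
    doc = {"response_window": design.response_window, "blocks": blocks}
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(doc, fh, indent=1)
        else:
            yaml.safe_dump(doc, fh)


def read_design(path) -> TaskDesign:
    path = str(path)
    with open(path) as fh:
        doc = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    spec = [(b["length"], b["p_reward_A"], b["label"]) for b in doc["blocks"]]
    return generate_design(spec, response_window=float(doc.get("response_window", 1.7)))
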