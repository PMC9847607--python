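"""Trial selection and binning for simultaneity-judgment (SJ) data.

An SJ trial pairs an odor and a taste stimulus at a signed stimulus onset
asynchrony (SOA; negative = odor first) and records whether the participant
judged them simultaneous, successive, or gave no response.  Analysis starts
by excluding unusable trials and converting the survivors into per-window
simultaneous-response rates over actual SOA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

RESPONSE_SIMULTANEOUS = "simultaneous"
RESPONSE_SUCCESSIVE = "successive"
RESPONSE_NONE = "none"
RESPONSES = (RESPONSE_SIMULTANEOUS, RESPONSE_SUCCESSIVE, RESPONSE_NONE)

#: The 23 nominal SOA steps of the test design, in ms (negative = odor first).
NOMINAL_SOA_STEPS_MS = tuple(
    sorted(
        [0]
        + [s for mag in (50, 100, 150, 200, 250, 300, 350, 400, 500, 600, 800)
           for s in (-mag, mag)]
    )
)

TRIAL_COLUMNS = [
    "participant_id",
    "condition",
    "session",
    "trial_index",
    "nominal_soa_ms",
    "actual_soa_ms",
    "response",
]


@dataclass(frozen=True)
class TrialRecord:
    """One SJ trial.

    ``nominal_soa_ms`` is the programmed SOA; ``actual_soa_ms`` is the SOA
    realised by the stimulus apparatus.  ``response`` is one of
    ``"simultaneous"``, ``"successive"`` or ``"none"`` (no finger report).
    """

    participant_id: str
    condition: str
    session: int
    nominal_soa_ms: float
    actual_soa_ms: float
    response: str
    trial_index: int = 0

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(
                f"response must be one of {RESPONSES}, got {self.response!r}"
            )


TrialsLike = Union[pd.DataFrame, Iterable[TrialRecord]]


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [
        (r.participant_id, r.condition, r.session, r.trial_index,
         r.nominal_soa_ms, r.actual_soa_ms, r.response)
        for r in records
    ]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def as_trial_frame(trials: TrialsLike) -> pd.DataFrame:
    """Normalise a trial table or a sequence of records to a DataFrame."""
    if isinstance(trials, pd.DataFrame):
        missing = set(TRIAL_COLUMNS) - set(trials.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        bad = set(trials["response"].unique()) - set(RESPONSES)
        if bad:
            raise ValueError(f"unknown response values: {sorted(bad)}")
        return trials
    return records_to_frame(trials)


@dataclass
class SelectionResult:
    """Outcome of the trial-exclusion rules.

    ``adoption_rate`` is the percentage of input trials retained, computed on
    the original trial count.
    """

    retained: pd.DataFrame
    n_total: int
    n_retained: int

    @property
    def adoption_rate(self) -> float:
        return 100.0 * self.n_retained / self.n_total


def select_trials(trials: TrialsLike) -> SelectionResult:
    """Apply the trial-exclusion rules.

    A trial is dropped when the participant gave no response, or when the
    actual SOA fell at or below -1000 ms or above +1000 ms.  The boundary is
    deliberately asymmetric: exactly -1000 ms is excluded while exactly
    +1000 ms is retained.

    Raises
    ------
    ValueError
        If the input contains no trials.
    """
    frame = as_trial_frame(trials)
    if len(frame) == 0:
        raise ValueError("cannot select from an empty trial table")
    keep = (
        (frame["response"] != RESPONSE_NONE)
        & (frame["actual_soa_ms"] > -1000.0)
        & (frame["actual_soa_ms"] <= 1000.0)
    )
    retained = frame.loc[keep].reset_index(drop=True)
    return SelectionResult(retained=retained, n_total=len(frame),
                           n_retained=len(retained))


def default_window_edges() -> np.ndarray:
    """21 contiguous 100-ms windows spanning (-1050, +1050] ms.

    Centers fall on -1000, -900, ..., +1000 ms.  Windows are lower-open /
    upper-closed, mirroring the asymmetric exclusion boundary.
    """
    return np.linspace(-1050.0, 1050.0, 22)


@dataclass
class BinnedRates:
    """Per-window trial counts and simultaneous-response proportions.

    ``rate`` is NaN where a window received no trials; such windows carry no
    information and are excluded from curve fitting rather than imputed.
    """

    window_edges_ms: np.ndarray
    n_trials: np.ndarray
    n_simultaneous: np.ndarray

    def __post_init__(self) -> None:
        self.window_edges_ms = np.asarray(self.window_edges_ms, dtype=float)
        self.n_trials = np.asarray(self.n_trials, dtype=int)
        self.n_simultaneous = np.asarray(self.n_simultaneous, dtype=int)
        if np.any(np.diff(self.window_edges_ms) <= 0):
            raise ValueError("window edges must be strictly increasing")
        if len(self.n_trials) != len(self.window_edges_ms) - 1:
            raise ValueError("need one count per window")

    @property
    def window_centers_ms(self) -> np.ndarray:
        e = self.window_edges_ms
        return (e[:-1] + e[1:]) / 2.0

    @property
    def rate(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_trials > 0,
                            self.n_simultaneous / np.maximum(self.n_trials, 1),
                            np.nan)

    @property
    def occupied(self) -> np.ndarray:
        return self.n_trials > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window_center_ms": self.window_centers_ms,
            "window_low_ms": self.window_edges_ms[:-1],
            "window_high_ms": self.window_edges_ms[1:],
            "n_trials": self.n_trials,
            "n_simultaneous": self.n_simultaneous,
            "rate": self.rate,
        })


def bin_trials(selection: Union[SelectionResult, TrialsLike],
               edges: Sequence[float] | None = None) -> BinnedRates:
    """Bin retained trials by actual SOA and compute simultaneity rates.

    Windows are lower-open / upper-closed: a trial at exactly an edge value
    falls in the window below it.  Every retained trial must land inside the
    edge span.

    Parameters
    ----------
    selection
        A :class:`SelectionResult`, a trial DataFrame, or records.  Trials
        with ``response == "none"`` must already have been removed.
    edges
        Strictly increasing window boundaries; defaults to the 21-window
        design of :func:`default_window_edges`.
    """
    if isinstance(selection, SelectionResult):
        frame = selection.retained
    else:
        frame = as_trial_frame(selection)
    if edges is None:
        edges = default_window_edges()
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("window edges must be strictly increasing")

    soa = frame["actual_soa_ms"].to_numpy(dtype=float)
    # (lo, hi] convention: a value equal to an edge belongs to the lower bin
    idx = np.searchsorted(edges, soa, side="left") - 1
    out = (soa <= edges[0]) | (soa > edges[-1])
    if np.any(out):
        j = int(np.flatnonzero(out)[0])
        row = frame.iloc[j]
        raise ValueError(
            f"trial outside window span: participant {row['participant_id']} "
            f"condition {row['condition']} session {row['session']} "
            f"trial {row['trial_index']} actual SOA {row['actual_soa_ms']} ms"
        )

    n_windows = len(edges) - 1
    n_trials = np.bincount(idx, minlength=n_windows)
    sim = (frame["response"] == RESPONSE_SIMULTANEOUS).to_numpy()
    n_sim = np.bincount(idx[sim], minlength=n_windows)
    return BinnedRates(window_edges_ms=edges, n_trials=n_trials,
                       n_simultaneous=n_sim)
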