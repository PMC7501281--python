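"""Behavioral scoring for the Go/NoGo color discrimination task.

The operant response is mandibulation — opening/closing of the lower jaw —
recorded by a pressure-sensitive piezo-electric sensor under the jaw, with a
second piezo channel as a common-mode reference.  This module turns the raw
two-channel trace into discrete mandibulation events, classifies each trial
into the signal-detection taxonomy (Hit / Miss / CR / FA), and computes the
session-level SDT statistics (hit rate, false-alarm rate, d').
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .preprocess_qc import mad

__all__ = [
    "PiezoTrace",
    "TrialOutcome",
    "SDTSummary",
    "detect_mandibulations",
    "classify_trials",
    "sdt_summary",
    "roc_point",
    "peristimulus_histogram",
]

GO = "splus"
NOGO = "sminus"
MAD_TO_SD = 1.4826  # Gaussian consistency factor


@dataclass(frozen=True)
class PiezoTrace:
    """Two-channel piezo pressure recording.

    time          : sample times, s (monotone increasing)
    signal        : jaw-mounted sensor channel
    reference     : common-mode reference channel
    sampling_rate : Hz
    """

    time: np.ndarray
    signal: np.ndarray
    reference: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        r = np.asarray(self.reference, dtype=float)
        if not (t.size == s.size == r.size):
            raise ValueError("time, signal and reference must have equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)
        object.__setattr__(self, "reference", r)


@dataclass(frozen=True)
class TrialOutcome:
    """Classification of a single trial."""

    trial_id: int
    onset: float
    trial_type: str  # GO or NOGO
    label: str  # hit | miss | cr | fa
    rt: float | None  # s from stimulus onset, defined for hit/fa
    n_mandib: int  # mandibulation count inside the stimulus window


@dataclass(frozen=True)
class SDTSummary:
    hit_rate: float
    fa_rate: float
    d_prime: float
    counts: dict  # keys hit, miss, cr, fa


def detect_mandibulations(
    trace: PiezoTrace,
    z_threshold: float = 3.0,
    refractory: float = 0.1,
    envelope_window: float = 0.15,
) -> np.ndarray:
    """Detect mandibulation event times from the differential piezo signal.

    The differential channel (signal - reference) cancels common-mode
    artifacts.  It is standardized to a robust z score (median / scaled MAD),
    converted to a trailing RMS envelope over ``envelope_window`` seconds,
    and events are placed at upward crossings of ``z_threshold`` by the
    envelope; crossings closer than ``refractory`` seconds are merged.
    """
    if trace.sampling_rate < 50:
        raise ValueError("sampling rate must be at least 50 Hz")
    diff = trace.signal - trace.reference
    scale = mad(diff) * MAD_TO_SD
    if scale == 0:
        return np.empty(0)
    z = (diff - np.median(diff)) / scale
    w = max(int(round(envelope_window * trace.sampling_rate)), 1)
    # trailing RMS so the crossing stays close to burst onset
    power = np.convolve(z * z, np.ones(w) / w)[: z.size]
    env = np.sqrt(power)
    above = env >= z_threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.concatenate([[0], crossings])
    times = trace.time[crossings]
    if times.size == 0:
        return times
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= refractory:
            keep.append(t)
    return np.asarray(keep)


def classify_trials(events: pd.DataFrame, mandib_times) -> list[TrialOutcome]:
    """Classify each stimulus trial by mandibulations in its stimulus window.

    ``events`` rows with trial_type GO/NOGO are trials; a trial with >= 1
    event in [onset, onset + duration) is a hit (GO) or FA (NOGO), otherwise
    a miss (GO) or CR (NOGO).  RT is the first in-window event time minus the
    onset (hits and FAs only).
    """
    mandib = np.sort(np.asarray(mandib_times, dtype=float))
    trials = events[events["trial_type"].isin([GO, NOGO])].sort_values("onset")
    ends = trials["onset"].to_numpy() + trials["duration"].to_numpy()
    if np.any(trials["onset"].to_numpy()[1:] < ends[:-1]):
        raise ValueError("overlapping trials")
    outcomes: list[TrialOutcome] = []
    for i, (_, row) in enumerate(trials.iterrows()):
        onset = float(row["onset"])
        dur = float(row["duration"])
        in_win = mandib[(mandib >= onset) & (mandib < onset + dur)]
        responded = in_win.size > 0
        ttype = row["trial_type"]
        if ttype == GO:
            label = "hit" if responded else "miss"
        else:
            label = "fa" if responded else "cr"
        rt = float(in_win[0] - onset) if responded else None
        outcomes.append(
            TrialOutcome(
                trial_id=i,
                onset=onset,
                trial_type=ttype,
                label=label,
                rt=rt,
                n_mandib=int(in_win.size),
            )
        )
    return outcomes


def sdt_summary(outcomes: list[TrialOutcome], correction: str = "loglinear") -> SDTSummary:
    """Hit rate, FA rate and the SDT sensitivity index d'.

    d' = Phi^-1(hit rate) - Phi^-1(FA rate).  With ``correction='loglinear'``
    0.5 is added to each cell and 1 to each denominator before the inverse
    normal transform, which keeps d' finite at perfect performance; with
    ``correction='none'`` extreme rates yield +/- inf.
    """
    counts = {"hit": 0, "miss": 0, "cr": 0, "fa": 0}
    for o in outcomes:
        counts[o.label] += 1
    n_go = counts["hit"] + counts["miss"]
    n_nogo = counts["cr"] + counts["fa"]
    if n_go == 0 or n_nogo == 0:
        raise ValueError("need at least one S+ and one S- trial")
    hit_rate = counts["hit"] / n_go
    fa_rate = counts["fa"] / n_nogo
    if correction == "loglinear":
        h = (counts["hit"] + 0.5) / (n_go + 1)
        f = (counts["fa"] + 0.5) / (n_nogo + 1)
    elif correction == "none":
        h, f = hit_rate, fa_rate
    else:
        raise ValueError("correction must be 'loglinear' or 'none'")
    with np.errstate(divide="ignore"):
        d_prime = float(ndtri(h) - ndtri(f))
    return SDTSummary(hit_rate=hit_rate, fa_rate=fa_rate, d_prime=d_prime, counts=counts)


def roc_point(summary: SDTSummary) -> tuple[float, float, bool]:
    """(FA rate, hit rate) coordinates in ROC space, plus above-diagonal flag."""
    return (summary.fa_rate, summary.hit_rate, summary.hit_rate > summary.fa_rate)


def peristimulus_histogram(
    outcomes: list[TrialOutcome],
    mandib_times,
    bin: float = 0.2,
    window: tuple[float, float] = (-2.0, 8.0),
) -> dict:
    """Peristimulus histogram of mandibulation events, split by trial type.

    Counts events in bins of width ``bin`` seconds relative to each trial's
    stimulus onset, within ``window`` = (start, end) seconds.  Returns a dict
    with bin edges and one count array per trial type.
    """
    if bin <= 0:
        raise ValueError("bin width must be positive")
    start, end = window
    edges = np.arange(start, end + bin / 2, bin)
    mandib = np.asarray(mandib_times, dtype=float)
    hists = {GO: np.zeros(edges.size - 1, dtype=int), NOGO: np.zeros(edges.size - 1, dtype=int)}
    for o in outcomes:
        rel = mandib - o.onset
        sel = rel[(rel >= start) & (rel < edges[-1])]
        h, _ = np.histogram(sel, bins=edges)
        hists[o.trial_type] += h
    return {"edges": edges, GO: hists[GO], NOGO: hists[NOGO]}
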