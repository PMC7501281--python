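"""Synthetic awake-pigeon fMRI sessions: designs, BOLD, motion, piezo logs.

Every generator is a pure function of its specification and a seed, and the
defaults reproduce the study conditions of the real experiment:

* color discrimination task — TR = 4 s, layout rest / 72-trial session /
  rest / 72-trial session / rest (10-min rests), 2 s stimulus, 0.8 s reward
  delay, 1 s reward, ITI jittered over 12.2-20.2 s, 1170 volumes, 78 min;
* HRF characterization runs — TR = 2 s, 30 trials of 2 s stimulus + 28 s
  darkness, 30 pre- and 10 post-stimulation volumes, 490 volumes;
* BOLD — double-gamma HRF forward model on a small voxel grid with AR(1) +
  white noise and slow sinusoidal drift, calibrated so the in-mask tSNR
  lands in the 110-220 range observed in the pigeon telencephalon;
* motion — smooth sub-voxel traces bounded by the observed maxima
  (0.048 mm translation, 0.045 deg rotation);
* piezo — mandibulation bursts (20 Hz damped oscillation, 150 ms) with
  truncated-normal Go latencies of 0.9 +/- 0.4 s and FA latencies of
  0.7 +/- 0.5 s, plus drinking bursts during reward, on a signal channel
  sharing common-mode noise with a reference channel.

The ITI jitter is a balanced permutation of an evenly spaced grid over
[12.2, 20.2] s (mean exactly 16.2 s), so total run duration — and hence the
volume count — is deterministic, as in the real fixed-length runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import truncnorm

from .behavior import GO, NOGO, PiezoTrace, TrialOutcome
from .glm_task import TASK_CONDITIONS, convolve_to_tr, task_condition_events
from .hrf_core import CANONICAL, HRFParams, hrf_response
from .preprocess_qc import BOLDSeries, MotionTrace

__all__ = [
    "TaskSpec",
    "NoiseSpec",
    "BehaviorSpec",
    "SessionBundle",
    "make_discrimination_design",
    "make_hrf_design",
    "simulate_bold",
    "simulate_motion",
    "simulate_piezo",
    "simulate_session",
    "simulate_hrf_run",
    "default_active_mask",
]

TRIAL_TYPES = (
    (GO, "low"),
    (GO, "high"),
    (NOGO, "low"),
    (NOGO, "high"),
)


@dataclass(frozen=True)
class TaskSpec:
    """Timing of the Go/NoGo color discrimination runs."""

    trials_per_session: int = 72
    n_sessions: int = 2
    stimulus_duration: float = 2.0
    reward_delay: float = 0.8
    reward_duration: float = 1.0
    post_reward_go: float = 4.0  # after reward offset
    post_reward_nogo: float = 5.0  # after NoGo stimulus offset
    iti_range: tuple[float, float] = (12.2, 20.2)
    rest_block_duration: float = 600.0
    TR: float = 4.0

    def __post_init__(self) -> None:
        if self.iti_range[0] >= self.iti_range[1]:
            raise ValueError("iti_range must satisfy min < max")
        for name in ("stimulus_duration", "reward_delay", "reward_duration",
                     "rest_block_duration", "TR"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def trial_footprint(self) -> float:
        """Stimulus + delay + reward time preceding each ITI, s."""
        return self.stimulus_duration + self.reward_delay + self.reward_duration

    @property
    def total_duration(self) -> float:
        iti_mean = 0.5 * (self.iti_range[0] + self.iti_range[1])
        session = self.trials_per_session * (self.trial_footprint + iti_mean)
        return (self.n_sessions + 1) * self.rest_block_duration + self.n_sessions * session

    @property
    def n_volumes(self) -> int:
        return int(round(self.total_duration / self.TR))


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for simulated BOLD: AR(1) + white + sinusoidal drift.

    ``white_sd`` is calibrated so the in-mask median tSNR of a default run,
    computed after 100 s high-pass filtering and spatial smoothing, falls in
    ``target_tsnr_range``.
    """

    baseline_level: float = 1000.0
    white_sd: float = 18.0
    ar1_coefficient: float = 0.3
    drift_amplitude: float = 10.0
    drift_period: float = 120.0
    target_tsnr_range: tuple[float, float] = (110.0, 220.0)

    def __post_init__(self) -> None:
        if self.white_sd <= 0:
            raise ValueError("white_sd must be positive")
        if not (0 <= self.ar1_coefficient < 1):
            raise ValueError("ar1_coefficient must be in [0, 1)")


@dataclass(frozen=True)
class BehaviorSpec:
    """Response statistics of a trained bird."""

    hit_rate: float = 0.9
    fa_rate: float = 0.1
    go_latency_mean: float = 0.9
    go_latency_sd: float = 0.4
    fa_latency_mean: float = 0.7
    fa_latency_sd: float = 0.5
    reward_burst_rate: float = 3.0  # drinking mandibulations during reward, Hz
    spontaneous_rate: float = 0.05  # baseline mandibulations in rest/ITI, Hz
    min_latency: float = 0.05

    def __post_init__(self) -> None:
        for r in (self.hit_rate, self.fa_rate):
            if not (0 <= r <= 1):
                raise ValueError("rates must be in [0, 1]")
        if min(self.go_latency_mean, self.fa_latency_mean) <= 0:
            raise ValueError("latencies must be positive")


@dataclass(frozen=True)
class SessionBundle:
    """One complete simulated run plus its ground truth."""

    events: pd.DataFrame
    bold: BOLDSeries
    motion: MotionTrace
    piezo: PiezoTrace
    truth: dict = field(default_factory=dict)


def _balanced_itis(spec: TaskSpec, rng: np.random.Generator) -> np.ndarray:
    """A random permutation of an evenly spaced ITI grid (mean exactly centered)."""
    lo, hi = spec.iti_range
    grid = np.linspace(lo, hi, spec.trials_per_session)
    return rng.permutation(grid)


def make_discrimination_design(spec: TaskSpec = TaskSpec(), seed: int = 0) -> pd.DataFrame:
    """Generate the trial table for one color discrimination run.

    Rows are stimulus events (onset, duration, trial_type, intensity); the
    four type-by-intensity conditions are exactly balanced and pseudo-random
    within each session.  Run bookkeeping (duration, volume count) is stored
    in ``DataFrame.attrs``.
    """
    if spec.trials_per_session % len(TRIAL_TYPES) != 0:
        raise ValueError(
            f"trials_per_session must be divisible by {len(TRIAL_TYPES)} conditions"
        )
    rng = np.random.default_rng(seed)
    per_cond = spec.trials_per_session // len(TRIAL_TYPES)
    rows = []
    t = spec.rest_block_duration
    for _ in range(spec.n_sessions):
        conds = [tt for tt in TRIAL_TYPES for _ in range(per_cond)]
        order = rng.permutation(len(conds))
        itis = _balanced_itis(spec, rng)
        for k, idx in enumerate(order):
            ttype, intensity = conds[idx]
            rows.append((t, spec.stimulus_duration, ttype, intensity))
            t += spec.trial_footprint + itis[k]
        t += spec.rest_block_duration
    df = pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "intensity"])
    df.attrs["duration_s"] = float(spec.total_duration)
    df.attrs["n_volumes"] = spec.n_volumes
    df.attrs["TR"] = spec.TR
    assert abs(t - spec.total_duration) < 1e-6
    return df


def make_hrf_design(
    n_trials: int = 30,
    stim_duration: float = 2.0,
    rest_after: float = 28.0,
    TR: float = 2.0,
    n_pre_volumes: int = 30,
    n_post_volumes: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate the slow event-related HRF characterization design.

    Red and green 2 s flashes in pseudo-random order (half each), one every
    ``stim_duration + rest_after`` seconds, padded by pre/post rest volumes.
    """
    if min(n_trials, n_pre_volumes, n_post_volumes) <= 0:
        raise ValueError("all counts must be positive")
    if n_trials % 2 != 0:
        raise ValueError("n_trials must be even (half red, half green)")
    rng = np.random.default_rng(seed)
    colors = rng.permutation(["red"] * (n_trials // 2) + ["green"] * (n_trials // 2))
    t0 = n_pre_volumes * TR
    trial_len = stim_duration + rest_after
    rows = [(t0 + i * trial_len, stim_duration, colors[i]) for i in range(n_trials)]
    df = pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])
    n_vol = n_pre_volumes + int(round(n_trials * trial_len / TR)) + n_post_volumes
    df.attrs["duration_s"] = float(n_vol * TR)
    df.attrs["n_volumes"] = n_vol
    df.attrs["TR"] = TR
    return df


def default_active_mask(grid_shape: tuple = (16, 16, 4)) -> np.ndarray:
    """A compact ellipsoidal 'active region' in the grid center."""
    zz = np.zeros(grid_shape, dtype=bool)
    cx, cy, cz = (s / 2 - 0.5 for s in grid_shape)
    x, y, z = np.indices(grid_shape)
    r = ((x - cx) / 3.0) ** 2 + ((y - cy) / 3.0) ** 2 + ((z - cz) / 1.5) ** 2
    zz[r <= 1.0] = True
    return zz


def simulate_bold(
    events: pd.DataFrame,
    active_mask: np.ndarray,
    true_params: HRFParams,
    betas: dict,
    noise: NoiseSpec = NoiseSpec(),
    TR: float | None = None,
    grid_shape: tuple = (16, 16, 4),
    seed: int = 0,
    n_volumes: int | None = None,
    voxel_size: tuple = (0.47, 0.47, 1.0),
) -> BOLDSeries:
    """Forward-model a 4D BOLD run from an event table.

    Active voxels carry, on top of the baseline, one percent-signal-change
    unit per beta: every condition's boxcar is convolved with ``true_params``
    and scaled by one common factor — the peak of a single isolated
    ``ref_duration``-second event — so ``betas[cond]`` is the peak % signal
    change an isolated reference event would evoke, and relative regressor
    scales match an HRF-convolved analysis design exactly.  All voxels get
    independent AR(1)-plus-white noise and a slow sinusoidal drift with
    random phase.
    """
    TR = float(events.attrs.get("TR") if TR is None else TR)
    n_vol = int(events.attrs.get("n_volumes") if n_volumes is None else n_volumes)
    active_mask = np.asarray(active_mask, dtype=bool)
    if active_mask.shape != tuple(grid_shape):
        raise ValueError("active_mask shape must match grid_shape")
    unknown = set(betas) - set(events["trial_type"].unique())
    if unknown:
        raise ValueError(f"betas reference event types absent from the table: {unknown}")
    rng = np.random.default_rng(seed)

    ref_duration = float(events.loc[events["duration"] > 0, "duration"].median())
    ref_peak = hrf_response(true_params, stim_duration=ref_duration, dt=0.01).values.max()
    signal_pct = np.zeros(n_vol)
    for cond, beta in betas.items():
        sel = events[events["trial_type"] == cond]
        reg = convolve_to_tr(
            sel["onset"].to_numpy(), sel["duration"].to_numpy(), true_params, TR, n_vol
        )
        signal_pct = signal_pct + beta * reg / ref_peak

    n_active = int(active_mask.sum())
    data = np.empty(tuple(grid_shape) + (n_vol,))
    base = noise.baseline_level
    data[...] = base
    data[active_mask] = base * (1.0 + signal_pct / 100.0)

    n_vox = int(np.prod(grid_shape))
    white = rng.standard_normal((n_vox, n_vol)) * noise.white_sd
    phi = noise.ar1_coefficient
    if phi > 0:
        ar = np.empty_like(white)
        ar[:, 0] = white[:, 0] / np.sqrt(1 - phi**2)
        for t in range(1, n_vol):
            ar[:, t] = phi * ar[:, t - 1] + white[:, t]
    else:
        ar = white
    tsec = TR * np.arange(n_vol)
    phase = rng.uniform(0, 2 * np.pi, size=n_vox)
    drift = noise.drift_amplitude * np.sin(
        2 * np.pi * tsec[None, :] / noise.drift_period + phase[:, None]
    )
    data += (ar + drift).reshape(tuple(grid_shape) + (n_vol,))

    brain_mask = np.ones(tuple(grid_shape), dtype=bool)
    return BOLDSeries(data=data, TR=TR, voxel_size=voxel_size, mask=brain_mask)


def simulate_motion(
    n_volumes: int,
    max_translation: float = 0.048,
    max_rotation: float = 0.045,
    seed: int = 0,
) -> MotionTrace:
    """Six smooth bounded motion traces (rotations in deg bound, stored rad).

    Each trace is a Gaussian-smoothed random walk rescaled so its absolute
    maximum is a random fraction (60-100%) of the bound, guaranteeing the
    bound is respected in every draw.
    """
    if max_translation < 0 or max_rotation < 0:
        raise ValueError("bounds must be non-negative")
    rng = np.random.default_rng(seed)

    def traces(bound: float) -> np.ndarray:
        out = np.zeros((n_volumes, 3))
        if bound == 0:
            return out
        for j in range(3):
            walk = np.cumsum(rng.standard_normal(n_volumes))
            walk = gaussian_filter1d(walk, sigma=5.0, mode="nearest")
            walk -= walk[0]
            peak = np.abs(walk).max()
            amp = bound * rng.uniform(0.6, 1.0)
            out[:, j] = walk * (amp / peak) if peak > 0 else walk
        return out

    rot_deg = traces(max_rotation)
    trans = traces(max_translation)
    return MotionTrace(rotations=np.deg2rad(rot_deg), translations=trans, rotation_unit="rad")


def _burst(duration: float, sampling_rate: float, freq: float = 20.0, amp: float = 20.0) -> np.ndarray:
    """Damped 20 Hz oscillation — the mandibulation pressure signature."""
    t = np.arange(int(duration * sampling_rate)) / sampling_rate
    return amp * np.sin(2 * np.pi * freq * t) * np.exp(-t / (duration / 3))


def simulate_piezo(
    events: pd.DataFrame,
    spec: BehaviorSpec = BehaviorSpec(),
    sampling_rate: float = 1000.0,
    seed: int = 0,
    *,
    reward_delay: float = 0.8,
    reward_duration: float = 1.0,
) -> tuple[PiezoTrace, dict]:
    """Simulate the two-channel piezo log for a run.

    Each S+ trial yields an in-window mandibulation burst with probability
    ``hit_rate`` at a truncated-normal latency; S- trials likewise with
    ``fa_rate``.  Hit trials are followed by drinking bursts during the
    reward window.  Both channels share common-mode noise; bursts appear on
    the signal channel only.  Returns the trace and a ground-truth dict with
    true event times and per-trial labels.
    """
    if sampling_rate < 50:
        raise ValueError("sampling_rate must be at least 50 Hz")
    rng = np.random.default_rng(seed)
    duration = float(events.attrs.get("duration_s", events["onset"].max() + 60.0))
    n = int(duration * sampling_rate)
    t = np.arange(n) / sampling_rate

    common = gaussian_filter1d(rng.standard_normal(n), sigma=sampling_rate * 0.05) * 3.0
    signal = common + rng.standard_normal(n)
    reference = common + rng.standard_normal(n)

    def latency(mean: float, sd: float, hi: float) -> float:
        a = (spec.min_latency - mean) / sd
        b = (hi - mean) / sd
        return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))

    burst = _burst(0.15, sampling_rate)
    event_times: list[float] = []
    labels: list[str] = []

    def add_burst(t_on: float) -> None:
        i0 = int(round(t_on * sampling_rate))
        seg = burst[: max(0, min(burst.size, n - i0))]
        if seg.size:
            signal[i0 : i0 + seg.size] += seg
            event_times.append(t_on)

    trials = events[events["trial_type"].isin([GO, NOGO])].sort_values("onset")
    for _, row in trials.iterrows():
        onset, dur = float(row["onset"]), float(row["duration"])
        hi = dur - spec.min_latency
        if row["trial_type"] == GO:
            if rng.random() < spec.hit_rate:
                add_burst(onset + latency(spec.go_latency_mean, spec.go_latency_sd, hi))
                labels.append("hit")
                r_on = onset + dur + reward_delay
                n_drink = rng.poisson(spec.reward_burst_rate * reward_duration)
                for u in np.sort(rng.uniform(0, reward_duration, size=n_drink)):
                    add_burst(r_on + u)
            else:
                labels.append("miss")
        else:
            if rng.random() < spec.fa_rate:
                add_burst(onset + latency(spec.fa_latency_mean, spec.fa_latency_sd, hi))
                labels.append("fa")
            else:
                labels.append("cr")

    # spontaneous mandibulations (homogeneous Poisson) outside stimulus
    # windows, so trial labels remain exactly as drawn above
    n_spont = rng.poisson(spec.spontaneous_rate * duration)
    stim_lo = trials["onset"].to_numpy()
    stim_hi = stim_lo + trials["duration"].to_numpy()
    for u in np.sort(rng.uniform(0, duration - 0.2, size=n_spont)):
        if not np.any((u >= stim_lo) & (u < stim_hi)):
            add_burst(float(u))

    trace = PiezoTrace(
        time=t, signal=signal, reference=reference, sampling_rate=sampling_rate
    )
    truth = {"mandib_times": np.sort(np.asarray(event_times)), "trial_labels": labels}
    return trace, truth


DEFAULT_TASK_BETAS = {
    "hit": 1.5,
    "miss": 1.2,
    "cr": 0.4,
    "fa": 0.5,
    "reward": 1.0,
    "post_reward": 0.6,
    "mandibulation": 0.4,
}


def simulate_session(
    task: TaskSpec = TaskSpec(),
    noise: NoiseSpec = NoiseSpec(),
    behavior: BehaviorSpec = BehaviorSpec(),
    hrf: HRFParams | None = None,
    betas: dict | None = None,
    grid_shape: tuple = (16, 16, 4),
    active_mask: np.ndarray | None = None,
    seed: int = 0,
    piezo_sampling_rate: float = 1000.0,
) -> SessionBundle:
    """Generate one complete color discrimination run with ground truth.

    The BOLD forward model is driven by the *behaviorally realized*
    condition events (hit/miss/cr/fa/reward/post-reward/mandibulation), so
    the task GLM applied downstream sees exactly the structure it assumes.
    """
    hrf = CANONICAL["pigeon"] if hrf is None else hrf
    betas = dict(DEFAULT_TASK_BETAS) if betas is None else dict(betas)
    rng = np.random.default_rng(seed)
    s_design, s_piezo, s_bold, s_motion = rng.integers(0, 2**31 - 1, size=4)

    events = make_discrimination_design(task, seed=int(s_design))
    piezo, truth = simulate_piezo(
        events,
        behavior,
        sampling_rate=piezo_sampling_rate,
        seed=int(s_piezo),
        reward_delay=task.reward_delay,
        reward_duration=task.reward_duration,
    )
    outcomes = _truth_outcomes(events, truth)
    cond_events = task_condition_events(
        events,
        outcomes,
        truth["mandib_times"],
        reward_delay=task.reward_delay,
        reward_duration=task.reward_duration,
        post_reward_go=task.post_reward_go,
        post_reward_nogo=task.post_reward_nogo,
    )
    cond_events.attrs.update(events.attrs)
    betas = {k: v for k, v in betas.items() if (cond_events["trial_type"] == k).any()}
    if active_mask is None:
        active_mask = default_active_mask(grid_shape)
    bold = simulate_bold(
        cond_events,
        active_mask,
        hrf,
        betas,
        noise=noise,
        TR=task.TR,
        grid_shape=grid_shape,
        seed=int(s_bold),
        n_volumes=task.n_volumes,
    )
    motion = simulate_motion(task.n_volumes, seed=int(s_motion))
    truth = dict(
        truth,
        active_mask=active_mask,
        betas=betas,
        hrf=hrf,
        condition_events=cond_events,
        outcomes=outcomes,
        seed=seed,
    )
    return SessionBundle(events=events, bold=bold, motion=motion, piezo=piezo, truth=truth)


def _truth_outcomes(events: pd.DataFrame, truth: dict) -> list[TrialOutcome]:
    """Ground-truth TrialOutcomes from the generator's own labels."""
    trials = events[events["trial_type"].isin([GO, NOGO])].sort_values("onset")
    mandib = np.asarray(truth["mandib_times"])
    outcomes = []
    for i, ((_, row), label) in enumerate(zip(trials.iterrows(), truth["trial_labels"])):
        onset, dur = float(row["onset"]), float(row["duration"])
        in_win = mandib[(mandib >= onset) & (mandib < onset + dur)]
        rt = float(in_win[0] - onset) if label in ("hit", "fa") and in_win.size else None
        outcomes.append(
            TrialOutcome(
                trial_id=i,
                onset=onset,
                trial_type=row["trial_type"],
                label=label,
                rt=rt,
                n_mandib=int(in_win.size),
            )
        )
    return outcomes


def simulate_hrf_run(
    hrf: HRFParams | None = None,
    peak_psc: float = 2.0,
    noise: NoiseSpec = NoiseSpec(),
    grid_shape: tuple = (16, 16, 4),
    active_mask: np.ndarray | None = None,
    seed: int = 0,
    design_kwargs: dict | None = None,
) -> SessionBundle:
    """One HRF characterization run: slow event-related red/green flashes.

    Active voxels respond to both colors with a true peak percent signal
    change of ``peak_psc``.  Spatial smoothing and ROI averaging dilute this
    by roughly 40%, so the default of 2.0 puts the *measured* ROI-average
    response near the middle of the observed 0.8-1.5% range.
    """
    hrf = CANONICAL["pigeon"] if hrf is None else hrf
    rng = np.random.default_rng(seed)
    s_design, s_bold, s_motion = rng.integers(0, 2**31 - 1, size=3)
    events = make_hrf_design(seed=int(s_design), **(design_kwargs or {}))
    if active_mask is None:
        active_mask = default_active_mask(grid_shape)
    betas = {"red": peak_psc, "green": peak_psc}
    bold = simulate_bold(
        events, active_mask, hrf, betas, noise=noise, grid_shape=grid_shape, seed=int(s_bold)
    )
    motion = simulate_motion(events.attrs["n_volumes"], seed=int(s_motion))
    truth = {"active_mask": active_mask, "betas": betas, "hrf": hrf, "seed": seed}
    return SessionBundle(events=events, bold=bold, motion=motion, piezo=None, truth=truth)
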