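"""Event-related first-level GLM for the Go/NoGo task and cluster inference.

The first-level model regresses each voxel's BOLD series on seven
HRF-convolved task regressors — Hit, Miss, CR, FA stimulus windows, reward,
post-reward period, and mandibulation onsets during rest/ITI — plus six
demeaned motion nuisance regressors and an intercept.  Voxelwise contrasts
are converted to z statistics and thresholded with cluster-extent inference:
supra-threshold clusters (face connectivity) survive when their size exceeds
the (1 - alpha) quantile of a permutation null of maximal cluster sizes,
built by sign-flipping residual volumes (first level) or subject maps
(group level).  Cluster-extent permutation inference is used instead of
Gaussian-random-field theory because smoothness estimation is unreliable on
small grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .behavior import GO, NOGO, TrialOutcome
from .hrf_core import HRFParams, double_gamma_kernel
from .preprocess_qc import BOLDSeries, MotionTrace

__all__ = [
    "DesignMatrix",
    "GLMFit",
    "Cluster",
    "ContrastResult",
    "TASK_CONDITIONS",
    "CONTRAST_PRESETS",
    "task_condition_events",
    "convolve_to_tr",
    "build_design_matrix",
    "fit_glm",
    "contrast_z",
    "contrast_vector",
    "cluster_threshold",
    "first_level_clusters",
    "group_level",
]

TASK_CONDITIONS = ("hit", "miss", "cr", "fa", "reward", "post_reward", "mandibulation")

# Named directional contrasts over the seven task regressors.
CONTRAST_PRESETS = {
    "go_gt_nogo_plus_mandibulation": {
        "hit": 0.5, "miss": 0.5, "cr": -1 / 3, "fa": -1 / 3, "mandibulation": -1 / 3,
    },
    "nogo_gt_go": {"cr": 0.5, "fa": 0.5, "hit": -0.5, "miss": -0.5},
    "mandibulation_gt_rest": {"mandibulation": 1.0},
    # omnibus stimulus-response contrast; the high-power choice for
    # recovering the task-responsive region as a whole
    "task_gt_rest": {"hit": 0.25, "miss": 0.25, "cr": 0.25, "fa": 0.25},
}

Z_CAP = 40.0  # numerical ceiling for |z|; values at the cap are flagged


@dataclass(frozen=True)
class DesignMatrix:
    matrix: np.ndarray  # (n_volumes, n_regressors)
    names: list[str]
    TR: float
    hrf: HRFParams
    dropped: list[str] = field(default_factory=list)

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


@dataclass(frozen=True)
class GLMFit:
    X: DesignMatrix
    betas: np.ndarray  # (..., n_regressors), spatial shape leading
    sigma2: np.ndarray  # residual variance, spatial shape
    dof: int
    xtx_inv: np.ndarray
    residuals: np.ndarray  # (n_volumes, n_voxels), flattened spatial order
    spatial_shape: tuple


@dataclass(frozen=True)
class Cluster:
    cluster_id: int
    size: int
    peak_z: float
    peak_ijk: tuple
    p_fwe: float
    voxels: np.ndarray  # (size, 3) integer indices


@dataclass(frozen=True)
class ContrastResult:
    contrast: np.ndarray
    effect: np.ndarray | None
    zmap: np.ndarray
    clusters: list[Cluster]
    z_min: float
    alpha: float
    critical_extent: int
    method: str


def task_condition_events(
    events: pd.DataFrame,
    outcomes: list[TrialOutcome],
    mandib_times,
    *,
    reward_delay: float = 0.8,
    reward_duration: float = 1.0,
    post_reward_go: float = 4.0,
    post_reward_nogo: float = 5.0,
) -> pd.DataFrame:
    """Expand stimulus trials + behavioral labels into GLM condition events.

    Hit trials get a reward event (``reward_delay`` after stimulus offset,
    ``reward_duration`` long) followed by a ``post_reward_go``-second
    post-reward window; unrewarded trials (miss, CR, FA) get a
    ``post_reward_nogo``-second post-reward window starting at stimulus
    offset.  Mandibulation onsets are kept as zero-duration impulse events
    only where they fall outside every trial's stimulus-to-post-reward span
    (i.e. during rest and bare ITI).
    """
    trials = events[events["trial_type"].isin([GO, NOGO])].sort_values("onset")
    if len(trials) != len(outcomes):
        raise ValueError("labels must cover every trial")
    rows = []
    spans = []  # per-trial exclusion window for the mandibulation regressor
    for (_, row), out in zip(trials.iterrows(), outcomes):
        onset, dur = float(row["onset"]), float(row["duration"])
        rows.append((onset, dur, out.label))
        if out.label == "hit":
            r_on = onset + dur + reward_delay
            rows.append((r_on, reward_duration, "reward"))
            pr_on = r_on + reward_duration
            rows.append((pr_on, post_reward_go, "post_reward"))
            spans.append((onset, pr_on + post_reward_go))
        else:
            rows.append((onset + dur, post_reward_nogo, "post_reward"))
            spans.append((onset, onset + dur + post_reward_nogo))
    for t in np.sort(np.asarray(mandib_times, dtype=float)):
        if not any(lo <= t < hi for lo, hi in spans):
            rows.append((float(t), 0.0, "mandibulation"))
    out_df = pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])
    return out_df.sort_values("onset", kind="stable").reset_index(drop=True)


def convolve_to_tr(
    onsets,
    durations,
    hrf: HRFParams,
    TR: float,
    n_volumes: int,
    dt: float = 0.1,
) -> np.ndarray:
    """HRF-convolved condition regressor sampled on the TR grid.

    The condition boxcar is built on a fine ``dt`` grid (zero-duration
    events become single-bin impulses), convolved with the double-gamma
    kernel, and decimated at the volume acquisition times t = i * TR.
    """
    n_fine = int(np.ceil(n_volumes * TR / dt)) + 1
    box = np.zeros(n_fine)
    for onset, dur in zip(np.atleast_1d(onsets), np.atleast_1d(durations)):
        i0 = int(round(onset / dt))
        i1 = max(int(round((onset + dur) / dt)), i0 + 1)
        box[i0 : min(i1, n_fine)] = 1.0
    t_kernel = dt * np.arange(int(round(32.0 / dt)) + 1)
    kernel = double_gamma_kernel(t_kernel, hrf)
    fine = np.convolve(box, kernel)[:n_fine] * dt
    idx = np.round(np.arange(n_volumes) * TR / dt).astype(int)
    return fine[np.minimum(idx, n_fine - 1)]


def build_design_matrix(
    events: pd.DataFrame,
    outcomes: list[TrialOutcome],
    mandib_times,
    motion: MotionTrace,
    hrf: HRFParams,
    TR: float,
    n_volumes: int,
    dt: float = 0.1,
) -> DesignMatrix:
    """Assemble the task design: 7 HRF-convolved condition regressors,
    6 demeaned motion nuisance regressors, and an intercept.

    Condition columns with no events are dropped and recorded in
    ``dropped`` (contrasts referencing them will fail loudly).
    """
    if motion.n_volumes != n_volumes:
        raise ValueError("motion trace length must equal the number of volumes")
    cond = task_condition_events(events, outcomes, mandib_times)
    cols, names, dropped = [], [], []
    for name in TASK_CONDITIONS:
        sel = cond[cond["trial_type"] == name]
        if len(sel) == 0:
            dropped.append(name)
            continue
        reg = convolve_to_tr(
            sel["onset"].to_numpy(), sel["duration"].to_numpy(), hrf, TR, n_volumes, dt
        )
        cols.append(reg)
        names.append(name)
    mot = motion.as_matrix()
    mot = mot - mot.mean(axis=0)
    for j, nm in enumerate(["rot_x", "rot_y", "rot_z", "trans_x", "trans_y", "trans_z"]):
        cols.append(mot[:, j])
        names.append(nm)
    cols.append(np.ones(n_volumes))
    names.append("intercept")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return DesignMatrix(matrix=X, names=names, TR=TR, hrf=hrf, dropped=dropped)


def fit_glm(series: BOLDSeries, X: DesignMatrix) -> GLMFit:
    """Ordinary least squares per voxel; dof = volumes - rank(X)."""
    M = X.matrix
    n, p = M.shape
    if series.n_volumes != n:
        raise ValueError("series length must match design rows")
    rank = np.linalg.matrix_rank(M)
    if rank < p:
        # name the offending columns for the error message
        _, r = np.linalg.qr(M)
        bad = [X.names[j] for j in range(p) if abs(r[j, j]) < 1e-10]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    shape = series.data.shape[:3]
    Y = series.data.reshape(-1, n).T  # (n, V)
    xtx_inv = np.linalg.inv(M.T @ M)
    betas = xtx_inv @ (M.T @ Y)  # (p, V)
    resid = Y - M @ betas
    dof = n - rank
    sigma2 = (resid**2).sum(axis=0) / dof
    return GLMFit(
        X=X,
        betas=betas.T.reshape(shape + (p,)),
        sigma2=sigma2.reshape(shape),
        dof=dof,
        xtx_inv=xtx_inv,
        residuals=resid,
        spatial_shape=shape,
    )


def _t_to_z(t: np.ndarray, dof: int) -> np.ndarray:
    """Map t statistics to z scores through matched tail probabilities."""
    t = np.asarray(t, dtype=float)
    z = np.empty_like(t)
    pos = t >= 0
    # symmetric mapping via the survival function for numerical stability
    z[pos] = stats.norm.isf(stats.t.sf(t[pos], dof))
    z[~pos] = -stats.norm.isf(stats.t.sf(-t[~pos], dof))
    return np.clip(np.nan_to_num(z, nan=0.0, posinf=Z_CAP, neginf=-Z_CAP), -Z_CAP, Z_CAP)


def contrast_vector(X: DesignMatrix, contrast: str | dict) -> np.ndarray:
    """Resolve a preset name or {regressor: weight} dict into a full vector."""
    if isinstance(contrast, str):
        try:
            contrast = CONTRAST_PRESETS[contrast]
        except KeyError:
            raise ValueError(
                f"unknown contrast {contrast!r}; presets: {sorted(CONTRAST_PRESETS)}"
            ) from None
    if isinstance(contrast, dict):
        vec = np.zeros(len(X.names))
        for name, w in contrast.items():
            if name not in X.names:
                raise ValueError(f"contrast references missing regressor {name!r}")
            vec[X.names.index(name)] = w
        return vec
    return np.asarray(contrast, dtype=float)


def contrast_z(fit: GLMFit, contrast) -> np.ndarray:
    """Voxelwise z map for a contrast of regression coefficients."""
    c = contrast_vector(fit.X, contrast)
    if c.size != len(fit.X.names):
        raise ValueError("contrast length must equal the regressor count")
    effect = fit.betas @ c
    cvc = float(c @ fit.xtx_inv @ c)
    var = cvc * fit.sigma2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, effect / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    return _t_to_z(t, fit.dof)


def _clusters_from_zmap(zmap: np.ndarray, z_min: float):
    """Label face-connected supra-threshold clusters; returns (labels, sizes)."""
    structure = ndimage.generate_binary_structure(zmap.ndim, 1)
    labels, n = ndimage.label(zmap > z_min, structure=structure)
    if n == 0:
        return labels, np.empty(0, dtype=int)
    sizes = np.bincount(labels.ravel())[1:]
    return labels, sizes


def _max_cluster_size(zmap: np.ndarray, z_min: float) -> int:
    _, sizes = _clusters_from_zmap(zmap, z_min)
    return int(sizes.max()) if sizes.size else 0


def cluster_threshold(
    zmap: np.ndarray,
    z_min: float = 3.1,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
    *,
    null_source=None,
    null_max_sizes=None,
    contrast: np.ndarray | None = None,
    effect: np.ndarray | None = None,
    method: str = "permutation-sign-flip",
) -> ContrastResult:
    """Cluster-extent inference on a z map.

    Supra-threshold clusters (z > z_min, face connectivity) survive when
    their family-wise p value — the fraction of null maximal cluster sizes
    at least as large, with the +1 correction — is <= alpha.  The null is
    supplied either as precomputed ``null_max_sizes`` or generated by
    calling ``null_source(rng)`` ``n_permutations`` times for null z maps.
    """
    if z_min <= 0:
        raise ValueError("z_min must be positive")
    if null_max_sizes is None:
        if null_source is None:
            raise ValueError("either null_source or null_max_sizes is required")
        if n_permutations < 500:
            raise ValueError("need at least 500 permutations for stable tails")
        rng = np.random.default_rng(seed)
        null_max_sizes = np.array(
            [_max_cluster_size(null_source(rng), z_min) for _ in range(n_permutations)]
        )
    null_max_sizes = np.asarray(null_max_sizes)
    n_perm = null_max_sizes.size
    labels, sizes = _clusters_from_zmap(zmap, z_min)
    # smallest extent whose FWE p value is <= alpha
    critical = 0
    if n_perm:
        cand = np.arange(0, (int(null_max_sizes.max()) if n_perm else 0) + 2)
        for s in cand:
            if (1 + (null_max_sizes >= s).sum()) / (n_perm + 1) <= alpha:
                critical = int(s)
                break
        else:
            critical = int(cand[-1])
    clusters = []
    for cid in range(1, sizes.size + 1):
        size = int(sizes[cid - 1])
        p_fwe = (1 + (null_max_sizes >= size).sum()) / (n_perm + 1)
        if p_fwe > alpha:
            continue
        vox = np.argwhere(labels == cid)
        zvals = zmap[labels == cid]
        peak = vox[int(np.argmax(zvals))]
        clusters.append(
            Cluster(
                cluster_id=cid,
                size=size,
                peak_z=float(zvals.max()),
                peak_ijk=tuple(int(v) for v in peak),
                p_fwe=float(p_fwe),
                voxels=vox,
            )
        )
    clusters.sort(key=lambda cl: -cl.size)
    return ContrastResult(
        contrast=np.asarray(contrast) if contrast is not None else np.empty(0),
        effect=effect,
        zmap=zmap,
        clusters=clusters,
        z_min=z_min,
        alpha=alpha,
        critical_extent=critical,
        method=method,
    )


def _first_level_null_source(fit: GLMFit, c: np.ndarray):
    """Null z-map generator: per-volume sign flips of the fitted residuals.

    Sign-flipped residuals are refit against the full design, giving a null
    contrast map with the same spatial/temporal noise structure but no task
    coupling (residuals are exchangeable under symmetric noise).
    """
    M = fit.X.matrix
    n, p = M.shape
    hat = fit.xtx_inv @ M.T  # (p, n)
    xtx = M.T @ M
    R = fit.residuals  # (n, V)
    rss0 = (R**2).sum(axis=0)
    cvc = float(c @ fit.xtx_inv @ c)

    def source(rng: np.random.Generator) -> np.ndarray:
        s = rng.choice([-1.0, 1.0], size=n)
        hat_s = hat * s  # equivalent to hat @ diag(s)
        beta = hat_s @ R  # (p, V)
        expl = np.einsum("pv,pq,qv->v", beta, xtx, beta)
        rss = np.maximum(rss0 - expl, 1e-300)
        sig2 = rss / fit.dof
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (c @ beta) / np.sqrt(cvc * sig2)
        return _t_to_z(t, fit.dof).reshape(fit.spatial_shape)

    return source


def first_level_clusters(
    fit: GLMFit,
    contrast,
    z_min: float = 3.1,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ContrastResult:
    """Contrast z map + cluster-extent permutation inference for one run."""
    c = contrast_vector(fit.X, contrast)
    zmap = contrast_z(fit, c)
    effect = fit.betas @ c
    return cluster_threshold(
        zmap,
        z_min=z_min,
        alpha=alpha,
        n_permutations=n_permutations,
        seed=seed,
        null_source=_first_level_null_source(fit, c),
        contrast=c,
        effect=effect,
        method="first-level residual sign-flip",
    )


def _one_sample_z(maps: np.ndarray) -> np.ndarray:
    """Voxelwise one-sample t across the leading (subject) axis, as z."""
    s = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0) * np.sqrt(s), np.sign(mean) * np.inf)
    return _t_to_z(t, s - 1)


def group_level(
    subject_maps,
    z_min: float = 3.1,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ContrastResult:
    """Summary-statistics group inference on per-subject contrast maps.

    A voxelwise one-sample t test on the subject effect maps gives the group
    z map; the cluster-extent null is built by randomly sign-flipping whole
    subject maps, which is exact under symmetric subject effects.
    """
    maps = np.asarray(subject_maps, dtype=float)
    if maps.shape[0] < 3:
        raise ValueError("group inference needs at least 3 subjects")
    zmap = _one_sample_z(maps)

    def source(rng: np.random.Generator) -> np.ndarray:
        s = rng.choice([-1.0, 1.0], size=maps.shape[0])
        flipped = maps * s.reshape((-1,) + (1,) * (maps.ndim - 1))
        return _one_sample_z(flipped)

    return cluster_threshold(
        zmap,
        z_min=z_min,
        alpha=alpha,
        n_permutations=n_permutations,
        seed=seed,
        null_source=source,
        effect=maps.mean(axis=0),
        method="group subject-map sign-flip",
    )
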