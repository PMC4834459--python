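"""Seeded synthetic cohorts for the PPI -> MLDA pipeline.

Real resting/task fMRI from the clinical study this pipeline targets is not
publicly deposited, so every downstream stage is exercised on simulated data
with a known ground truth.  Two generators are provided:

* :func:`generate_ppi_maps` — draws per-subject smoothed Gaussian random
  fields standing in for first-level PPI t-maps, and implants a sparse,
  clustered mean shift (standardised effect size ``effect_size_d``) at 1% of
  in-mask voxels in the patient group only.
* :func:`generate_timeseries_cohort` — simulates full event-related BOLD
  runs in which voxel signals follow ``y(t) = b1*p(t) + b2*s(t) +
  b3*(s_c*p_c)(t) + noise`` with the psychophysiological interaction
  coefficient ``b3`` present in controls but abolished in patients at the
  truth voxels (a guilt-selective seed disconnection).

Both are fully deterministic given ``SimConfig.rng_seed``.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal
from scipy.ndimage import gaussian_filter

from .volume import VolumeGrid, default_affine, voxel_centers_mm

GAUSS_TRUNCATE = 4.0  # kernel support in units of sigma (scipy convention)

PATIENT, CONTROL = 1, 0


# --------------------------------------------------------------------------
# configuration & event schedules
# --------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Simulation parameters.

    Acquisition defaults mirror a 3-T event-related protocol: TR 2.0 s,
    400 volumes per run, 3 runs, 2.29 x 2.29 x 3 mm voxels, 6 mm FWHM
    smoothing; group sizes default to 25 patients / 21 controls.  The grid
    defaults to a reduced 20 x 24 x 20 field of view so simulated cohorts
    stay desk-scale; a full-size grid is a matter of configuration.
    """

    grid_shape: tuple[int, int, int] = (20, 24, 20)
    voxel_size_mm: tuple[float, float, float] = (2.29, 2.29, 3.0)
    tr_s: float = 2.0
    n_volumes: int = 400
    n_runs: int = 3
    n_patients: int = 25
    n_controls: int = 21
    effect_size_d: float = 1.5
    signal_fraction: float = 0.01
    smooth_fwhm_mm: float = 6.0
    noise_ar1: float = 0.3
    rng_seed: int = 0
    # truth-voxel geometry
    n_truth_clusters: int = 4
    # time-series generative coefficients
    beta_psych: float = 1.0
    beta_physio: float = 0.7
    beta_ppi_control: float = 0.5
    beta_ppi_patient: float = 0.0
    noise_sigma: float = 1.0
    seed_noise_sigma: float = 1.0
    seed_radius_mm: float = 4.0
    seed_center_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if self.seed_center_mm is not None:
            self.seed_center_mm = tuple(float(c) for c in self.seed_center_mm)
        for name in ("tr_s", "n_volumes", "n_runs", "n_patients", "n_controls"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel_size_mm must be positive, got {self.voxel_size_mm}")
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValueError(f"signal_fraction must be in [0, 1], got {self.signal_fraction}")
        if not 0.0 <= self.noise_ar1 < 1.0:
            raise ValueError(f"noise_ar1 must be in [0, 1), got {self.noise_ar1}")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smooth_fwhm_mm must be non-negative")

    def make_grid(self) -> VolumeGrid:
        """Empty 3D grid with the configured shape and a world origin at its center."""
        shape = tuple(self.grid_shape)
        vs = np.asarray(self.voxel_size_mm, dtype=float)
        origin = -(np.asarray(shape) - 1) / 2.0 * vs
        return VolumeGrid(np.zeros(shape), default_affine(vs, origin))

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("grid_shape", "voxel_size_mm", "seed_center_mm"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d


@dataclass
class EventSchedule:
    """Trial onsets/durations/condition labels for one run."""

    onsets_s: np.ndarray
    durations_s: np.ndarray
    conditions: list[str]

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.durations_s = np.asarray(self.durations_s, dtype=float)
        if not (len(self.onsets_s) == len(self.durations_s) == len(self.conditions)):
            raise ValueError("onsets, durations and conditions must have equal length")
        if len(self.onsets_s) and self.onsets_s[0] < 0:
            raise ValueError("onsets must be non-negative")
        if np.any(np.diff(self.onsets_s) <= 0):
            raise ValueError("onsets must be strictly increasing within a run")
        if np.any(self.durations_s <= 0):
            raise ValueError("durations must be positive")

    def __len__(self) -> int:
        return len(self.onsets_s)


def default_event_schedules(
    config: SimConfig,
    rng: np.random.Generator,
    n_per_condition: int | None = None,
    trial_duration_s: float = 5.0,
) -> list[EventSchedule]:
    """Randomised per-run schedules: equal numbers of guilt, indignation and
    baseline trials (30 each per run at the standard 800 s run length, i.e.
    90 per condition over 3 runs), 5 s events, jittered inter-trial gaps
    filling the run.  On shorter runs the trial count is reduced so events
    plus a minimum 2 s gap still fit."""
    run_dur = config.n_volumes * config.tr_s
    if n_per_condition is None:
        fit = int((run_dur - 22.0) / (3.0 * (trial_duration_s + 2.0)))
        n_per_condition = max(1, min(30, fit))
    conds = ["guilt", "indignation", "baseline"] * n_per_condition
    n = len(conds)
    lead_in, tail = 6.0, 16.0
    slack = run_dur - lead_in - tail - n * trial_duration_s
    if slack < 0:
        raise ValueError(
            f"{n} trials of {trial_duration_s}s do not fit a {run_dur}s run"
        )
    schedules = []
    for _ in range(config.n_runs):
        order = list(np.asarray(conds)[rng.permutation(n)])
        raw = rng.uniform(0.5, 1.5, size=n)
        gaps = raw / raw.sum() * slack
        onsets = lead_in + np.concatenate(
            ([0.0], np.cumsum(trial_duration_s + gaps[:-1]))
        )
        schedules.append(
            EventSchedule(onsets, np.full(n, trial_duration_s), order)
        )
    return schedules


# --------------------------------------------------------------------------
# spatial primitives
# --------------------------------------------------------------------------

def fwhm_to_sigma_vox(fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units: FWHM / (2*sqrt(2*ln 2)) / size."""
    vs = np.asarray(voxel_size_mm, dtype=float)
    return fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / vs


def smooth_volume(data: np.ndarray, fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Separable Gaussian smoothing, kernels truncated at 4 sigma, zero-padded
    boundaries (``mode="constant"``)."""
    if fwhm_mm == 0:
        return np.asarray(data, dtype=float).copy()
    sigma = fwhm_to_sigma_vox(fwhm_mm, voxel_size_mm)
    return gaussian_filter(
        np.asarray(data, dtype=float), sigma=sigma, mode="constant",
        truncate=GAUSS_TRUNCATE,
    )


def _kernel_1d(sigma: float) -> np.ndarray:
    """The normalised 1D kernel gaussian_filter applies (radius = int(4*sigma+0.5))."""
    radius = int(GAUSS_TRUNCATE * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w / w.sum()


def smoothing_variance_factor(fwhm_mm: float, voxel_size_mm) -> float:
    """Variance of smoothed unit white noise at an interior voxel.

    For iid N(0,1) input the smoothed value is a weighted sum, so its
    variance is the product over axes of the sum of squared kernel weights.
    Used to re-standardise smoothed noise fields to unit voxelwise variance.
    """
    if fwhm_mm == 0:
        return 1.0
    return float(
        np.prod([(_kernel_1d(s) ** 2).sum() for s in fwhm_to_sigma_vox(fwhm_mm, voxel_size_mm)])
    )


def make_sphere_roi(center_mm, radius_mm: float, grid: VolumeGrid) -> np.ndarray:
    """Binary mask of voxels whose center lies within ``radius_mm`` of ``center_mm``.

    Membership is decided by the world-space distance from each voxel center
    (via the grid affine) to the sphere center.
    """
    center_mm = np.asarray(center_mm, dtype=float)
    ijk = grid.world_to_voxel(center_mm)
    shape = np.asarray(grid.shape3d)
    if np.any(ijk < -0.5) or np.any(ijk > shape - 0.5):
        raise ValueError(
            f"sphere center {tuple(center_mm)} mm maps to voxel {tuple(np.round(ijk, 2))}, "
            f"outside the grid of shape {tuple(shape)}"
        )
    centers = voxel_centers_mm(grid)
    dist = np.linalg.norm(centers - center_mm, axis=-1)
    return dist <= radius_mm + 1e-9


def make_gray_matter_map(grid: VolumeGrid, rng_seed: int = 0) -> VolumeGrid:
    """Smooth synthetic tissue-probability field in [0, 1].

    A heavily smoothed Gaussian random field is min-max rescaled to [0, 1] and,
    if necessary, power-adjusted until more than 25% of voxels exceed the 0.25
    masking threshold, so downstream gray-matter masks are never degenerate.
    """
    rng = np.random.default_rng(rng_seed)
    f = gaussian_filter(rng.standard_normal(grid.shape3d), sigma=2.0, mode="nearest")
    f = (f - f.min()) / (f.max() - f.min())
    while (f > 0.25).mean() <= 0.25:
        f = f ** 0.7
    return grid.with_data(f)


def _place_truth_clusters(
    mask: np.ndarray,
    n_voxels: int,
    n_clusters: int,
    rng: np.random.Generator,
    margin: np.ndarray,
) -> np.ndarray:
    """Sample ``n_voxels`` in-mask voxels as ~``n_clusters`` contiguous blobs.

    Cluster seeds are drawn away from the volume edge (``margin`` voxels per
    axis) so the implanted effect sits where smoothed-noise variance is
    stationary; blobs grow by 6-neighbourhood BFS within the mask.
    """
    shape = mask.shape
    interior = np.zeros(shape, dtype=bool)
    sl = tuple(slice(int(m), s - int(m)) for m, s in zip(margin, shape))
    interior[sl] = True
    candidates = np.argwhere(mask & interior)
    if len(candidates) == 0:
        candidates = np.argwhere(mask)
    n_clusters = min(n_clusters, n_voxels, len(candidates))
    seeds = candidates[rng.choice(len(candidates), size=n_clusters, replace=False)]

    truth = np.zeros(shape, dtype=bool)
    queues = [deque([tuple(s)]) for s in seeds]
    visited = set(map(tuple, seeds))
    count = 0
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while count < n_voxels and any(queues):
        for q in queues:
            if count >= n_voxels or not q:
                continue
            v = q.popleft()
            if truth[v]:
                continue
            truth[v] = True
            count += 1
            for d in offsets:
                nb = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if (
                    all(0 <= nb[a] < shape[a] for a in range(3))
                    and mask[nb] and nb not in visited
                ):
                    visited.add(nb)
                    q.append(nb)
    if count < n_voxels:  # mask smaller than requested blob area: backfill
        rest = np.argwhere(mask & ~truth)
        extra = rest[rng.choice(len(rest), size=n_voxels - count, replace=False)]
        truth[tuple(extra.T)] = True
    return truth


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Per-subject maps (3D) or runs (list of 4D grids), group labels
    (1=patient, 0=control), the implanted truth mask and the analysis mask."""

    maps: list
    labels: np.ndarray
    truth_mask: np.ndarray
    mask: np.ndarray
    seed_roi: np.ndarray | None = None
    events: list[EventSchedule] | None = None
    config: SimConfig | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.maps) != len(self.labels):
            raise ValueError("one label per subject required")
        if not (set(np.unique(self.labels)) <= {PATIENT, CONTROL}):
            raise ValueError("labels must be 0 (control) or 1 (patient)")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("cohort must contain both groups")
        if np.any(self.truth_mask & ~self.mask):
            raise ValueError("truth_mask must be a subset of the analysis mask")

    @property
    def n_subjects(self) -> int:
        return len(self.labels)

    def subject_ids(self) -> list[str]:
        return [f"sub-{i + 1:03d}" for i in range(self.n_subjects)]


def _cohort_labels(config: SimConfig) -> np.ndarray:
    return np.concatenate(
        [np.ones(config.n_patients, int), np.zeros(config.n_controls, int)]
    )


def _truth_mask_for(config: SimConfig, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("analysis mask is empty")
    if config.signal_fraction == 0:
        return np.zeros_like(mask)
    n_signal = config.signal_fraction * n_mask
    if n_signal < 1:
        raise ValueError(
            f"signal_fraction * |mask| = {n_signal:.3f} < 1: no voxel would carry the effect"
        )
    sigma = fwhm_to_sigma_vox(config.smooth_fwhm_mm, config.voxel_size_mm)
    margin = np.minimum(
        (GAUSS_TRUNCATE * sigma + 0.5).astype(int),
        np.asarray(mask.shape) // 2 - 1,
    ).clip(min=0)
    return _place_truth_clusters(
        mask, int(math.ceil(n_signal)), config.n_truth_clusters, rng, margin
    )


def generate_ppi_maps(config: SimConfig, mask: np.ndarray) -> SyntheticCohort:
    """Synthetic per-subject interaction maps with a sparse group difference.

    Each subject's map is a smoothed white-noise field re-standardised to unit
    voxelwise variance (so spatial correlation from smoothing is preserved but
    the marginal scale is known); patients additionally receive a mean shift
    of ``effect_size_d`` at the truth voxels.  The realised voxelwise Cohen's
    d at those voxels therefore matches ``effect_size_d`` up to sampling error.
    """
    rng = np.random.default_rng(config.rng_seed)
    mask = np.asarray(mask, dtype=bool)
    grid = config.make_grid()
    if mask.shape != grid.shape3d:
        raise ValueError(f"mask shape {mask.shape} != grid shape {grid.shape3d}")
    truth = _truth_mask_for(config, mask, rng)
    scale = math.sqrt(smoothing_variance_factor(config.smooth_fwhm_mm, config.voxel_size_mm))
    labels = _cohort_labels(config)
    maps = []
    for lab in labels:
        field3d = smooth_volume(
            rng.standard_normal(grid.shape3d), config.smooth_fwhm_mm, config.voxel_size_mm
        ) / scale
        if lab == PATIENT:
            field3d[truth] += config.effect_size_d
        maps.append(grid.with_data(field3d))
    return SyntheticCohort(maps, labels, truth, mask, config=config)


def _ar1_noise(rng: np.random.Generator, rho: float, shape: tuple) -> np.ndarray:
    """Stationary unit-variance AR(1) series along axis 0."""
    e = rng.standard_normal(shape)
    if rho == 0:
        return e
    x0 = rng.standard_normal(shape[1:]) if len(shape) > 1 else rng.standard_normal()
    innov = e * math.sqrt(1.0 - rho * rho)
    zi = (rho * x0)[np.newaxis] if len(shape) > 1 else np.array([rho * x0])
    out, _ = sp_signal.lfilter([1.0], [1.0, -rho], innov, axis=0, zi=zi)
    return out


def generate_timeseries_cohort(
    config: SimConfig,
    mask: np.ndarray,
    events: Sequence[EventSchedule],
) -> SyntheticCohort:
    """Full event-related 4D runs with an implanted psychophysiological interaction.

    Per run, the seed signal is the HRF-convolved all-trials regressor plus
    AR(1) noise; every in-mask voxel follows ``b1*psych + b2*seed +
    b3*(centered seed x centered psych) + noise`` where ``b3`` is
    ``beta_ppi_control`` at truth voxels in controls, ``beta_ppi_patient``
    (default 0: disconnection) at truth voxels in patients, and 0 elsewhere
    in both groups.  The seed ROI voxels carry the seed signal itself.
    """
    from .ppi import HRFSpec, build_psych_regressor  # local import avoids cycle at import time

    rng = np.random.default_rng(config.rng_seed)
    mask = np.asarray(mask, dtype=bool)
    grid = config.make_grid()
    if mask.shape != grid.shape3d:
        raise ValueError(f"mask shape {mask.shape} != grid shape {grid.shape3d}")
    if not mask.any():
        raise ValueError("analysis mask is empty")
    if len(events) != config.n_runs:
        raise ValueError(f"expected {config.n_runs} event schedules, got {len(events)}")
    run_dur = config.n_volumes * config.tr_s
    for ev in events:
        if np.any(ev.onsets_s + ev.durations_s > run_dur):
            raise ValueError(
                f"events extend past the run ({run_dur} s for n_volumes={config.n_volumes})"
            )

    hrf = HRFSpec()
    center = config.seed_center_mm
    if center is None:
        center = tuple(grid.voxel_to_world((np.asarray(grid.shape3d) - 1) / 2.0))
    seed_roi = make_sphere_roi(center, config.seed_radius_mm, grid)
    truth = _truth_mask_for(config, mask & ~seed_roi, rng)

    psych_runs, task_runs = [], []
    for ev in events:
        psych = build_psych_regressor(
            ev, {"guilt": 1.0, "indignation": -1.0, "baseline": 0.0},
            hrf, config.n_volumes, config.tr_s,
        )
        task = build_psych_regressor(
            ev, {"guilt": 1.0, "indignation": 1.0, "baseline": 0.0},
            hrf, config.n_volumes, config.tr_s,
        )
        psych_runs.append(psych)
        task_runs.append(task)

    labels = _cohort_labels(config)
    flat_mask = mask.reshape(-1)
    flat_seed = seed_roi.reshape(-1)
    flat_truth = truth.reshape(-1)
    n_vox = flat_mask.size
    subjects = []
    for lab in labels:
        b3 = np.zeros(n_vox)
        b3[flat_truth] = config.beta_ppi_patient if lab == PATIENT else config.beta_ppi_control
        runs = []
        for psych, task in zip(psych_runs, task_runs):
            seed_ts = task + config.seed_noise_sigma * _ar1_noise(
                rng, config.noise_ar1, (config.n_volumes,)
            )
            inter = (seed_ts - seed_ts.mean()) * (psych - psych.mean())
            y = config.noise_sigma * _ar1_noise(rng, config.noise_ar1, (config.n_volumes, n_vox))
            y[:, flat_mask] += (
                config.beta_psych * psych[:, None]
                + config.beta_physio * seed_ts[:, None]
            )
            y += b3[None, :] * inter[:, None]
            # seed voxels carry the seed signal itself, plus ordinary
            # measurement noise so their GLM fit is never exactly perfect
            y[:, flat_seed] = seed_ts[:, None] + config.noise_sigma * _ar1_noise(
                rng, config.noise_ar1, (config.n_volumes, int(flat_seed.sum()))
            )
            runs.append(grid.with_data(
                np.moveaxis(y, 0, -1).reshape(grid.shape3d + (config.n_volumes,))
            ))
        subjects.append(runs)
    return SyntheticCohort(
        subjects, labels, truth, mask, seed_roi=seed_roi,
        events=list(events), config=config,
    )
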