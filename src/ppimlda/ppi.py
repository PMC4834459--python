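"""Psychophysiological-interaction GLM: design assembly and voxelwise t-maps.

The PPI model asks, voxel by voxel, whether coupling with a seed region
changes with psychological context.  The design contains the psychological
contrast regressor p(t) (condition boxcars convolved with a double-gamma
HRF), the seed/physiological regressor s(t), and their interaction formed at
the BOLD level as the product of the mean-centered regressors.  Deconvolution
to neural-level signals is deliberately not attempted: it is ill-posed and
adds estimator variance; the BOLD-level product is the documented convention
here.  The interaction-contrast t-map is the subject-level feature image; the
physiological contrast provides the condition-independent control analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

from .volume import VolumeGrid
from .synthetic import EventSchedule

#: condition weights for the guilt-vs-indignation psychological contrast
GUILT_VS_INDIGNATION = {"guilt": 1.0, "indignation": -1.0, "baseline": 0.0}


@dataclass
class HRFSpec:
    """Canonical double-gamma hemodynamic response function.

    ``h(t) = pdf_gamma(t; peak) - ratio * pdf_gamma(t; undershoot)`` with the
    usual defaults: response peak governed by a 6 s delay, undershoot by a
    16 s delay, unit dispersions, peak:undershoot ratio 6:1, 32 s support.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    ratio: float = 1.0 / 6.0
    duration_s: float = 32.0

    def __post_init__(self) -> None:
        if self.duration_s < 16.0:
            raise ValueError("HRF kernel must span at least 16 s")
        if self.kernel(0.1).sum() <= 0:
            raise ValueError("HRF kernel must integrate to a positive constant")

    def kernel(self, dt_s: float) -> np.ndarray:
        """Kernel sampled every ``dt_s`` seconds over [0, duration_s]."""
        t = np.arange(0.0, self.duration_s + dt_s / 2, dt_s)
        peak = gamma_dist.pdf(
            t, self.peak_delay_s / self.peak_dispersion_s, scale=self.peak_dispersion_s
        )
        under = gamma_dist.pdf(
            t,
            self.undershoot_delay_s / self.undershoot_dispersion_s,
            scale=self.undershoot_dispersion_s,
        )
        return peak - self.ratio * under


def extract_seed_timeseries(run: VolumeGrid, roi: np.ndarray) -> np.ndarray:
    """Mean time series over the ROI voxels (one value per volume)."""
    roi = np.asarray(roi, dtype=bool)
    if run.data.ndim != 4:
        raise ValueError("run must be a 4D grid")
    if roi.shape != run.shape3d:
        raise ValueError(f"roi shape {roi.shape} != run grid {run.shape3d}")
    if not roi.any():
        raise ValueError("seed ROI is empty")
    return run.data[roi].mean(axis=0)


def build_psych_regressor(
    events: EventSchedule,
    weights: dict[str, float],
    hrf: HRFSpec,
    n_volumes: int,
    tr_s: float,
    dt_s: float = 0.1,
) -> np.ndarray:
    """Condition-weighted boxcar convolved with the HRF, sampled at volume
    times, mean-centered.

    The boxcar is built on a fine time grid (default 0.1 s) so event onsets
    and durations need not align with the TR.
    """
    missing = sorted(set(events.conditions) - set(weights))
    if missing:
        raise ValueError(f"no contrast weight for condition(s): {missing}")
    run_dur = n_volumes * tr_s
    n_fine = int(round(run_dur / dt_s))
    box = np.zeros(n_fine)
    for onset, dur, cond in zip(events.onsets_s, events.durations_s, events.conditions):
        w = weights[cond]
        if w == 0:
            continue
        i0 = int(round(onset / dt_s))
        i1 = min(int(round((onset + dur) / dt_s)), n_fine)
        box[i0:i1] += w
    reg_fine = np.convolve(box, hrf.kernel(dt_s))[:n_fine] * dt_s
    vol_idx = np.round(np.arange(n_volumes) * tr_s / dt_s).astype(int)
    reg = reg_fine[vol_idx]
    return reg - reg.mean()


@dataclass
class DesignMatrix:
    """Named GLM regressors, ``n_volumes x n_regressors``, full column rank."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values must be n_volumes x len(names)")
        rank = np.linalg.matrix_rank(self.values)
        if rank < len(self.names):
            raise ValueError(
                "design matrix is rank deficient; collinear columns: "
                + ", ".join(_collinear_columns(self.names, self.values))
            )

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def contrast_vector(self, name: str) -> np.ndarray:
        c = np.zeros(len(self.names))
        c[self.names.index(name)] = 1.0
        return c


def _collinear_columns(names: list[str], X: np.ndarray) -> list[str]:
    """Columns implicated in the null space (for rank-deficiency messages)."""
    norms = np.linalg.norm(X, axis=0)
    degenerate = [n for n, v in zip(names, norms) if v < 1e-12]
    if degenerate:
        return degenerate
    _, s, vt = np.linalg.svd(X / norms, full_matrices=False)
    null = vt[s < 1e-10 * s[0]]
    if null.size == 0:
        return names
    implicated = np.any(np.abs(null) > 1e-6, axis=0)
    return [n for n, hit in zip(names, implicated) if hit]


def assemble_ppi_design(
    seed_ts: np.ndarray,
    psych: np.ndarray,
    confounds: dict[str, np.ndarray] | None = None,
    run_lengths: list[int] | None = None,
) -> DesignMatrix:
    """PPI design: psych, physio (seed), their interaction, run intercepts.

    The interaction column is the elementwise product of the mean-centered
    seed series and mean-centered psychological regressor, computed per run;
    one intercept per run absorbs run means when runs are concatenated.
    """
    seed_ts = np.asarray(seed_ts, dtype=float)
    psych = np.asarray(psych, dtype=float)
    if seed_ts.shape != psych.shape:
        raise ValueError("seed_ts and psych must have equal length")
    n = len(seed_ts)
    if run_lengths is None:
        run_lengths = [n]
    if sum(run_lengths) != n:
        raise ValueError(f"run_lengths sum {sum(run_lengths)} != series length {n}")

    interaction = np.empty(n)
    intercepts = np.zeros((n, len(run_lengths)))
    start = 0
    for r, ln in enumerate(run_lengths):
        sl = slice(start, start + ln)
        s_c = seed_ts[sl] - seed_ts[sl].mean()
        p_c = psych[sl] - psych[sl].mean()
        interaction[sl] = s_c * p_c
        intercepts[sl, r] = 1.0
        start += ln

    names = ["psych", "physio", "interaction"]
    cols = [psych, seed_ts, interaction]
    names += [f"intercept_run{r + 1}" for r in range(len(run_lengths))]
    cols += list(intercepts.T)
    for cname, cvals in (confounds or {}).items():
        names.append(cname)
        cols.append(np.asarray(cvals, dtype=float))
    return DesignMatrix(names, np.column_stack(cols))


@dataclass
class PPIMap:
    """Voxelwise contrast t-map for one subject."""

    t_values: VolumeGrid
    dof: int
    contrast_name: str = "interaction"
    #: voxels where the residual variance vanished (t is 0 or signed infinity)
    zero_variance: np.ndarray | None = None


def fit_glm_tmap(
    run: VolumeGrid,
    design: DesignMatrix,
    contrast: np.ndarray,
    contrast_name: str = "interaction",
) -> PPIMap:
    """Ordinary-least-squares GLM at every voxel and the contrast t statistic.

    t = c'b / sqrt(s2 * c'(X'X)^-1 c), s2 = RSS/dof, dof = n - rank(X).
    Voxels with vanishing residual variance are flagged rather than raised:
    t is signed infinity there (0 when the contrast estimate is itself 0).
    """
    if run.data.ndim != 4:
        raise ValueError("run must be a 4D grid")
    X = design.values
    n, p = X.shape
    if run.n_volumes != n:
        raise ValueError(f"run has {run.n_volumes} volumes but design has {n} rows")
    if n <= p:
        raise ValueError(f"need more volumes ({n}) than regressors ({p})")
    c = np.asarray(contrast, dtype=float)
    if c.shape != (p,):
        raise ValueError(f"contrast must have length {p}")

    Y = run.data.reshape(-1, n).T  # volumes x voxels
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - p  # X is full rank by DesignMatrix contract
    rss = np.einsum("ij,ij->j", resid, resid)
    cb = c @ beta
    c_var = float(c @ xtx_inv @ c)

    scale = np.mean(Y * Y, axis=0) + 1e-300
    zero_var = rss <= 1e-12 * n * scale
    sigma2 = rss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cb / np.sqrt(sigma2 * c_var)
    cb_is_zero = np.abs(cb) <= 1e-8 * np.sqrt(c_var * scale)
    t[zero_var & cb_is_zero] = 0.0
    t[zero_var & ~cb_is_zero] = np.sign(cb[zero_var & ~cb_is_zero]) * np.inf

    shape3d = run.shape3d
    return PPIMap(
        t_values=VolumeGrid(t.reshape(shape3d), run.affine.copy()),
        dof=dof,
        contrast_name=contrast_name,
        zero_variance=zero_var.reshape(shape3d),
    )


@dataclass
class FeatureIndex:
    """Fixed voxel ordering behind a feature vector.

    Voxels are ordered by ascending linear index with the x axis varying
    fastest (Fortran-order ravel of the (x, y, z) array), recorded so that
    feature vectors, fold models and weight maps are comparable and can be
    back-projected exactly.
    """

    flat_idx: np.ndarray  # Fortran-order linear indices of the kept voxels
    shape: tuple[int, int, int]
    affine: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.flat_idx)

    def extract(self, grid: VolumeGrid) -> np.ndarray:
        if grid.shape3d != tuple(self.shape):
            raise ValueError(f"grid shape {grid.shape3d} != index shape {tuple(self.shape)}")
        return grid.data.ravel(order="F")[self.flat_idx]

    def to_volume(self, values: np.ndarray, fill: float = 0.0) -> VolumeGrid:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_features,):
            raise ValueError(
                f"expected {self.n_features} values, got {values.shape}"
            )
        flat = np.full(int(np.prod(self.shape)), fill)
        flat[self.flat_idx] = values
        return VolumeGrid(flat.reshape(self.shape, order="F"), np.asarray(self.affine))


def mask_to_features(
    ppi_map: "PPIMap | VolumeGrid",
    gm_map: VolumeGrid,
    threshold: float = 0.25,
) -> tuple[np.ndarray, FeatureIndex]:
    """Gray-matter masking: keep voxels with tissue probability strictly above
    ``threshold`` and return them as an ordered feature vector plus the index
    table for exact back-projection."""
    tmap = ppi_map.t_values if isinstance(ppi_map, PPIMap) else ppi_map
    if gm_map.shape3d != tmap.shape3d:
        raise ValueError(f"gray-matter map shape {gm_map.shape3d} != t-map {tmap.shape3d}")
    keep = gm_map.data > threshold
    if not keep.any():
        raise ValueError(f"no voxel has gray-matter value > {threshold}")
    flat_idx = np.flatnonzero(keep.ravel(order="F"))
    index = FeatureIndex(flat_idx, tmap.shape3d, np.asarray(gm_map.affine))
    return index.extract(tmap), index


def feature_matrix(
    maps: list[PPIMap], gm_map: VolumeGrid, threshold: float = 0.25
) -> tuple[np.ndarray, FeatureIndex]:
    """Stack per-subject masked t-maps into an ``n_subjects x p`` matrix."""
    rows, index = [], None
    for m in maps:
        vec, index = mask_to_features(m, gm_map, threshold)
        rows.append(vec)
    return np.vstack(rows), index
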