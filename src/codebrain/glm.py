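"""Run-wise GLM fitting, fixed-effects pooling, and FDR binarization.

The GLM path mirrors a standard surface-based single-subject analysis:

* design matrices built from event schedules, one boxcar regressor per
  condition (only the 24 s function phase of code trials is modeled)
  convolved with a canonical double-gamma HRF plus its first temporal
  derivative (derivative betas are nuisance, excluded from contrasts);
* ordinary least-squares fits per run with contrast t / p maps;
* inverse-variance (fixed-effects) pooling of run-level contrast estimates
  into a subject-level z map;
* Benjamini-Hochberg FDR thresholding of a p map into a 0/1 activation map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .designgen import TrialSchedule

__all__ = [
    "VertexMap",
    "BinaryActivationMap",
    "DesignMatrix",
    "RunStats",
    "canonical_hrf",
    "build_design",
    "fit_run",
    "combine_fixed_effects",
    "fdr_binarize",
]


@dataclass
class VertexMap:
    """One statistic per vertex for one subject and contrast.

    ``kind`` is one of ``beta | t | z | p``; ``hemispheres`` labels each
    vertex 'L' or 'R'.
    """

    values: np.ndarray
    kind: str
    hemispheres: np.ndarray
    contrast: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.hemispheres = np.asarray(self.hemispheres)
        if self.values.shape != self.hemispheres.shape:
            raise ValueError("values and hemisphere labels must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("VertexMap values must be finite")
        if not set(np.unique(self.hemispheres)) <= {"L", "R"}:
            raise ValueError("hemisphere labels must be 'L' or 'R'")

    def hemi(self, label: str) -> np.ndarray:
        return self.values[self.hemispheres == label]


@dataclass
class BinaryActivationMap:
    """0/1 per vertex: the FDR-thresholded form of a statistic map."""

    values: np.ndarray
    hemispheres: np.ndarray
    contrast: str = ""
    q: float = 0.05

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.hemispheres = np.asarray(self.hemispheres)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary map values must be 0 or 1")
        self.values = self.values.astype(np.uint8)

    def hemi(self, label: str) -> np.ndarray:
        return self.values[self.hemispheres == label]

    def active_count(self, hemisphere: str | None = None) -> int:
        v = self.values if hemisphere is None else self.hemi(hemisphere)
        return int(v.sum())


@dataclass
class DesignMatrix:
    matrix: np.ndarray
    names: list[str]
    tr_s: float
    condition_names: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        c = np.zeros(len(self.names))
        for name, w in weights.items():
            if name not in self.names:
                raise KeyError(f"no regressor named {name!r}")
            c[self.names.index(name)] = w
        return c


@dataclass
class RunStats:
    """Per-vertex contrast estimate for one run."""

    beta: np.ndarray
    variance: np.ndarray  # sampling variance of the contrast estimate
    t: np.ndarray
    p: np.ndarray
    df: int
    coefficients: np.ndarray | None = None  # full (regressors x vertices) betas
    regressor_names: list[str] | None = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(self.variance)


def canonical_hrf(t_grid: np.ndarray, peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                  ratio: float = 1.0 / 6.0, dispersion: float = 1.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1.

    The response is a gamma density peaking at ``peak_delay`` seconds minus
    ``ratio`` times a gamma density peaking at ``undershoot_delay`` seconds,
    rescaled so its maximum on ``t_grid`` is 1.  hrf(0) = 0.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be non-negative and strictly increasing")

    def gamma_pdf(x, shape):
        out = np.zeros_like(x)
        pos = x > 0
        xp = x[pos]
        out[pos] = np.exp((shape - 1) * np.log(xp) - xp - gammaln(shape))
        return out

    # Shape a, scale 1: mode at (a-1)*dispersion.
    h = gamma_pdf(t / dispersion, peak_delay / dispersion + 1) - ratio * gamma_pdf(
        t / dispersion, undershoot_delay / dispersion + 1
    )
    peak = h.max()
    if peak <= 0:
        raise ValueError("t_grid does not cover the response peak")
    return h / peak


def build_design(schedule: TrialSchedule, tr_s: float, n_samples: int,
                 per_function: bool = False, include_derivative: bool = True,
                 extra_regressors: pd.DataFrame | None = None,
                 oversample: int = 20) -> DesignMatrix:
    """Build a design matrix from the 24 s function-phase events of a schedule.

    One boxcar regressor per condition (or per function when
    ``per_function`` is True, as used for MVPA pattern estimation), convolved
    with the canonical HRF, plus its first temporal derivative and an
    intercept.  ``extra_regressors`` (e.g. nuisance covariates) are appended
    as given.
    """
    events = schedule.function_events()
    scan_len = n_samples * tr_s
    if len(events) and (events["onset"] + events["duration"]).max() > scan_len + tr_s:
        raise ValueError("schedule extends beyond the requested scan duration")

    key = "function_id" if per_function else "trial_type"
    groups = {f"{key_val}": ev for key_val, ev in events.groupby(key)} if len(events) else {}

    dt = tr_s / oversample
    fine_n = n_samples * oversample
    fine_t = np.arange(fine_n) * dt
    hrf_t = np.arange(0, 32 + dt, dt)
    hrf = canonical_hrf(hrf_t)
    dhrf = np.gradient(hrf, dt)

    cols, names, cond_names = [], [], []
    for cond in sorted(groups):
        ev = groups[cond]
        box = np.zeros(fine_n)
        for onset, dur in zip(ev["onset"], ev["duration"]):
            i0 = int(round(onset / dt))
            i1 = int(round((onset + dur) / dt))
            if box[i0:i1].any():
                raise ValueError(f"overlapping events for regressor {cond!r}")
            box[i0 : min(i1, fine_n)] = 1.0
        conv = np.convolve(box, hrf)[:fine_n:oversample]
        cols.append(conv)
        names.append(str(cond))
        cond_names.append(str(cond))
        if include_derivative:
            cols.append(np.convolve(box, dhrf)[:fine_n:oversample] * dt)
            names.append(f"{cond}__derivative")

    cols.append(np.ones(n_samples))
    names.append("intercept")
    if extra_regressors is not None:
        for name in extra_regressors.columns:
            cols.append(np.asarray(extra_regressors[name], dtype=float))
            names.append(str(name))

    X = np.column_stack(cols) if cols else np.zeros((n_samples, 0))
    return DesignMatrix(matrix=X, names=names, tr_s=tr_s, condition_names=cond_names)


def fit_run(Y: np.ndarray, X: DesignMatrix | np.ndarray,
            contrast_weights: dict[str, float] | np.ndarray,
            names: list[str] | None = None) -> RunStats:
    """Ordinary least-squares fit of one run with a single contrast.

    ``t = c'b / se(c'b)`` with ``se^2 = sigma^2 c'(X'X)^-1 c`` and two-sided
    p from a t distribution on ``n - rank(X)`` degrees of freedom.  Raises on
    rank-deficient designs, naming the collinear columns.
    """
    if isinstance(X, DesignMatrix):
        names = X.names
        c = X.contrast_vector(contrast_weights) if isinstance(contrast_weights, dict) else np.asarray(contrast_weights, float)
        Xm = X.matrix
    else:
        Xm = np.asarray(X, dtype=float)
        if isinstance(contrast_weights, dict):
            if names is None:
                raise ValueError("names required for dict contrast on a raw matrix")
            c = np.zeros(Xm.shape[1])
            for k, w in contrast_weights.items():
                c[names.index(k)] = w
        else:
            c = np.asarray(contrast_weights, dtype=float)

    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, k = Xm.shape
    if Y.shape[0] != n:
        raise ValueError("Y and X row counts differ")
    rank = np.linalg.matrix_rank(Xm)
    if rank < k:
        bad = _collinear_columns(Xm, names)
        raise np.linalg.LinAlgError(f"design matrix is rank deficient; collinear columns: {bad}")

    XtX_inv = np.linalg.inv(Xm.T @ Xm)
    B = XtX_inv @ Xm.T @ Y  # regressors x vertices
    resid = Y - Xm @ B
    df = n - rank
    sigma2 = (resid**2).sum(axis=0) / df
    cb = c @ B
    cvar = float(c @ XtX_inv @ c)
    var = sigma2 * cvar
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, cb / np.sqrt(var), 0.0)
    if np.allclose(c, 0):
        p = np.ones_like(t)
    else:
        p = 2 * stats.t.sf(np.abs(t), df)
    return RunStats(beta=cb, variance=var, t=t, p=p, df=df, coefficients=B,
                    regressor_names=list(names) if names else None)


def _collinear_columns(Xm: np.ndarray, names: list[str] | None) -> list[str]:
    keep: list[int] = []
    bad: list[int] = []
    for j in range(Xm.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(Xm[:, trial]) == len(trial):
            keep.append(j)
        else:
            bad.append(j)
    if names:
        return [names[j] for j in bad]
    return [str(j) for j in bad]


def combine_fixed_effects(run_stats: list[RunStats], hemispheres: np.ndarray,
                          contrast: str = "") -> tuple[VertexMap, VertexMap]:
    """Inverse-variance pooling of run-level contrast estimates.

    ``b_fe = sum(b_i / v_i) / sum(1 / v_i)`` with variance ``1 / sum(1/v_i)``
    and ``z = b_fe / sqrt(var)``.  Returns the z map and the matching
    two-sided p map.
    """
    if not run_stats:
        raise ValueError("need at least one run")
    betas = np.stack([r.beta for r in run_stats])
    variances = np.stack([r.variance for r in run_stats])
    if np.any(variances <= 0):
        raise ValueError("all run variances must be positive")
    w = 1.0 / variances
    beta_fe = (betas * w).sum(axis=0) / w.sum(axis=0)
    var_fe = 1.0 / w.sum(axis=0)
    z = beta_fe / np.sqrt(var_fe)
    p = 2 * stats.norm.sf(np.abs(z))
    zmap = VertexMap(values=z, kind="z", hemispheres=hemispheres, contrast=contrast)
    pmap = VertexMap(values=p, kind="p", hemispheres=hemispheres, contrast=contrast)
    return zmap, pmap


def fixed_effects_beta(run_stats: list[RunStats]) -> tuple[np.ndarray, np.ndarray]:
    """Pooled contrast estimate and its variance (helper for downstream use)."""
    betas = np.stack([r.beta for r in run_stats])
    variances = np.stack([r.variance for r in run_stats])
    if np.any(variances <= 0):
        raise ValueError("all run variances must be positive")
    w = 1.0 / variances
    return (betas * w).sum(axis=0) / w.sum(axis=0), 1.0 / w.sum(axis=0)


def fdr_binarize(pmap: VertexMap, q: float = 0.05) -> BinaryActivationMap:
    """Benjamini-Hochberg threshold a p map into a 0/1 activation map.

    The BH family is all vertices of the map (both hemispheres jointly); a
    vertex is 1 iff its p-value falls at or below the BH cutoff at level q.
    """
    if pmap.kind != "p":
        raise ValueError("fdr_binarize expects a p map")
    if pmap.values.size == 0:
        raise ValueError("empty map")
    if np.any((pmap.values < 0) | (pmap.values > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, _, _, _ = multipletests(pmap.values, alpha=q, method="fdr_bh")
    return BinaryActivationMap(values=reject.astype(np.uint8),
                               hemispheres=pmap.hemispheres,
                               contrast=pmap.contrast, q=q)


def z_to_pmap(zmap: VertexMap) -> VertexMap:
    """Two-sided normal p map from a z map."""
    if zmap.kind != "z":
        raise ValueError("expects a z map")
    p = 2 * stats.norm.sf(np.abs(zmap.values))
    return VertexMap(values=p, kind="p", hemispheres=zmap.hemispheres, contrast=zmap.contrast)
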