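"""EEG-informed first-level BOLD general linear model.

Design matrices contain the 0-back / 1-back / 2-back sub-blocks as
boxcars and the motor responses and beta bursts as impulses, all
convolved with the canonical double-gamma hemodynamic response function
on a microtime grid finer than the repetition time, then sampled at scan
times. Voxelwise ordinary least squares yields coefficient, t and p maps
for arbitrary contrasts; Benjamini-Hochberg FDR thresholding, minimum
cluster-extent filtering, and spherical-ROI summaries post-process the
maps.

Simplifications relative to a full SPM pipeline, documented as design
choices: no temporal-derivative columns and no autocorrelation
(prewhitening) model — plain OLS — with an optional cosine high-pass
drift basis (off by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DesignMatrix",
    "GLMFit",
    "RoiSummary",
    "canonical_hrf",
    "build_design_matrix",
    "fit_glm",
    "fdr_bh",
    "cluster_filter",
    "roi_extract",
]

HRF_LENGTH = 32.0  # s

# canonical double-gamma parameterization: response/undershoot delays 6 s
# and 16 s, unit dispersions, peak:undershoot amplitude ratio 6
HRF_PEAK_DELAY = 6.0
HRF_UNDER_DELAY = 16.0
HRF_PEAK_DISP = 1.0
HRF_UNDER_DISP = 1.0
HRF_RATIO = 6.0

BOXCAR_CONDITIONS = ("0back", "1back", "2back")


def canonical_hrf(dt: float) -> np.ndarray:
    """Canonical double-gamma HRF sampled on [0, 32] s at resolution dt.

    The kernel is the difference of two gamma densities (positive lobe
    peaking near 5 s, undershoot near 15 s at one sixth the amplitude),
    normalised to unit peak.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = np.arange(0.0, HRF_LENGTH + dt / 2, dt)
    h = sps.gamma.pdf(t, HRF_PEAK_DELAY / HRF_PEAK_DISP, scale=HRF_PEAK_DISP) \
        - sps.gamma.pdf(t, HRF_UNDER_DELAY / HRF_UNDER_DISP, scale=HRF_UNDER_DISP) / HRF_RATIO
    return h / h.max()


@dataclass
class DesignMatrix:
    """Named scans x regressors matrix with its build parameters."""

    values: np.ndarray
    names: list
    tr: float
    microtime_factor: int

    def __post_init__(self):
        if len(self.names) != self.values.shape[1]:
            raise ValueError("names do not match the number of columns")
        if len(set(self.names)) != len(self.names):
            raise ValueError("regressor names must be unique")

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def contrast_vector(self, name: str) -> np.ndarray:
        c = np.zeros(len(self.names))
        c[self.names.index(name)] = 1.0
        return c

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)


def _cosine_drift(n_scans, tr, cutoff):
    """Discrete-cosine high-pass basis (periods longer than cutoff s)."""
    order = int(np.floor(2 * n_scans * tr / cutoff))
    t = np.arange(n_scans)
    cols = [np.sqrt(2.0 / n_scans) * np.cos(np.pi * (t + 0.5) * k / n_scans)
            for k in range(1, order + 1)]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


def build_design_matrix(events: pd.DataFrame, burst_times, n_scans: int,
                        tr: float, microtime_factor: int = 16,
                        drift_cutoff: float = None) -> DesignMatrix:
    """Build the first-level design from events and burst times.

    Sub-block boxcars (value 1 for the duration of each 0-back / 1-back /
    2-back sub-block), response impulses and burst impulses are laid out
    on a microtime grid of ``tr / microtime_factor``, convolved with the
    canonical HRF at that resolution, sampled at scan acquisition times
    ``i * tr``, and augmented with an intercept (and, optionally, a cosine
    drift basis with the given cutoff period in seconds).
    """
    if tr <= 0:
        raise ValueError("tr must be > 0")
    if microtime_factor < 1:
        raise ValueError("microtime_factor must be >= 1")
    t_max = n_scans * tr
    burst_times = np.asarray(burst_times, dtype=float)
    offenders = []
    ev_on = events["onset"].to_numpy(float)
    bad_ev = (ev_on < 0) | (ev_on >= t_max)
    if bad_ev.any():
        offenders += list(ev_on[bad_ev])
    bad_b = (burst_times < 0) | (burst_times >= t_max)
    if bad_b.any():
        offenders += list(burst_times[bad_b])
    if offenders:
        raise ValueError(
            f"event times outside the scan window [0, {t_max}) s: {offenders[:10]}"
        )

    dt = tr / microtime_factor
    n_fine = n_scans * microtime_factor
    hrf = canonical_hrf(dt)
    scan_idx = np.arange(n_scans) * microtime_factor

    def _convolved(fine):
        return np.convolve(fine, hrf)[:n_fine][scan_idx]

    cols, names = [], []
    for cond in BOXCAR_CONDITIONS:
        fine = np.zeros(n_fine)
        for row in events[events["trial_type"] == cond].itertuples():
            i0 = int(np.round(row.onset / dt))
            i1 = int(np.round((row.onset + row.duration) / dt))
            fine[i0:max(i1, i0 + 1)] += 1.0  # additive: column is linear in events
        cols.append(_convolved(fine))
        names.append(cond)

    def _impulses(times):
        fine = np.zeros(n_fine)
        idx = np.clip(np.round(np.asarray(times, float) / dt).astype(int), 0, n_fine - 1)
        np.add.at(fine, idx, 1.0)
        return fine

    resp = events.loc[events["trial_type"] == "response", "onset"].to_numpy(float)
    cols.append(_convolved(_impulses(resp)) if resp.size else np.zeros(n_scans))
    names.append("response")
    cols.append(_convolved(_impulses(burst_times)) if burst_times.size else np.zeros(n_scans))
    names.append("burst")

    if drift_cutoff is not None:
        drift = _cosine_drift(n_scans, tr, drift_cutoff)
        for i in range(drift.shape[1]):
            cols.append(drift[:, i])
            names.append(f"drift_{i + 1}")
    cols.append(np.ones(n_scans))
    names.append("intercept")
    return DesignMatrix(values=np.column_stack(cols), names=names,
                        tr=tr, microtime_factor=microtime_factor)


@dataclass
class GLMFit:
    """Voxelwise OLS fit: betas (voxels x regressors), residual variance,
    degrees of freedom, and per-contrast estimate / t / p arrays."""

    betas: np.ndarray
    sigma2: np.ndarray
    df: int
    names: list
    rank_deficient: bool = False
    _X: np.ndarray = field(default=None, repr=False)
    _XtX_inv: np.ndarray = field(default=None, repr=False)

    def contrast(self, c):
        """Estimate, t and two-sided p of contrast c'beta per voxel."""
        c = np.asarray(c, dtype=float)
        est = self.betas @ c
        var_scale = float(c @ self._XtX_inv @ c)
        se = np.sqrt(self.sigma2 * var_scale)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / se, 0.0)
        p = 2.0 * sps.t.sf(np.abs(t), self.df)
        return est, t, p


def fit_glm(Y: np.ndarray, X) -> GLMFit:
    """Ordinary least squares of each voxel's series on the design.

    ``Y`` is scans x voxels (a 1-D vector is treated as one voxel). With a
    rank-deficient design a warning is emitted and the pseudo-inverse
    path is used (flagged in the result); df = scans - rank(X).
    """
    Xv = X.values if isinstance(X, DesignMatrix) else np.asarray(X, float)
    names = X.names if isinstance(X, DesignMatrix) else \
        [f"x{i}" for i in range(Xv.shape[1])]
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != Xv.shape[0]:
        raise ValueError(
            f"Y has {Y.shape[0]} scans but the design has {Xv.shape[0]}"
        )
    rank = np.linalg.matrix_rank(Xv)
    deficient = rank < Xv.shape[1]
    if deficient:
        warnings.warn(
            f"design matrix is rank deficient (rank {rank} < {Xv.shape[1]}); "
            "using the pseudo-inverse", stacklevel=2,
        )
    df = Y.shape[0] - rank
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    pinv = np.linalg.pinv(Xv)
    B = pinv @ Y                       # regressors x voxels
    resid = Y - Xv @ B
    sigma2 = np.sum(resid**2, axis=0) / df
    return GLMFit(
        betas=B.T, sigma2=sigma2, df=df, names=list(names),
        rank_deficient=deficient, _X=Xv, _XtX_inv=pinv @ pinv.T,
    )


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level q."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def cluster_filter(mask: np.ndarray, k_min: int = 20, connectivity: int = 26):
    """Label connected components of a 3-D binary mask and drop those with
    fewer than ``k_min`` voxels.

    Returns ``(labels, sizes)`` where labels is an int array (0 =
    background, clusters renumbered 1..n by decreasing size) and sizes the
    per-cluster voxel counts. Connectivity is 6, 18 or 26 (default).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    lab, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n == 0:
        return np.zeros_like(lab), np.empty(0, dtype=int)
    counts = np.bincount(lab.ravel())[1:]
    keep = np.nonzero(counts >= k_min)[0] + 1
    keep = keep[np.argsort(-counts[keep - 1], kind="stable")]
    out = np.zeros_like(lab)
    sizes = []
    for new, old in enumerate(keep, start=1):
        out[lab == old] = new
        sizes.append(int(counts[old - 1]))
    return out, np.asarray(sizes, dtype=int)


@dataclass
class RoiSummary:
    center_mm: tuple
    radius_mm: float
    mean: float
    n_voxels: int


def roi_extract(beta_map: np.ndarray, affine: np.ndarray, center_mm,
                radius_mm: float = 10.0) -> RoiSummary:
    """Mean of a 3-D map over a spherical ROI (default radius 1 cm).

    Membership is by voxel-centre distance: a voxel belongs to the sphere
    iff the mm coordinate of its centre (voxel index through the NIfTI
    affine) lies within ``radius_mm`` of ``center_mm``.
    """
    beta_map = np.asarray(beta_map, dtype=float)
    if beta_map.ndim != 3:
        raise ValueError("beta_map must be 3-D")
    if radius_mm <= 0:
        raise ValueError("radius_mm must be > 0")
    from nibabel.affines import apply_affine

    idx = np.indices(beta_map.shape).reshape(3, -1).T
    mm = apply_affine(np.asarray(affine, float), idx)
    d2 = np.sum((mm - np.asarray(center_mm, float)) ** 2, axis=1)
    inside = d2 <= radius_mm**2
    if not inside.any():
        raise ValueError("spherical ROI contains no voxel centres")
    vals = beta_map.reshape(-1)[inside]
    return RoiSummary(
        center_mm=tuple(np.asarray(center_mm, float)),
        radius_mm=float(radius_mm),
        mean=float(vals.mean()),
        n_voxels=int(inside.sum()),
    )
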