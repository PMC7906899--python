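"""Diffusion tensor fitting and derived scalar maps.

Fits a single diffusion tensor per white-matter voxel from the
log-linearized Stejskal-Tanner signal equation

    ln S(g, b) = ln S0 - b * g^T D g

and derives eigenvalues, fractional anisotropy (FA) and the principal
diffusion direction v1 that deterministic tracking follows.  Two
estimators are provided: ordinary least squares (``ols``) and an
iteratively reweighted least squares fit with a Tukey biweight on the
log-signal residuals (``robust``), the conventional redescending
M-estimator for rejecting signal outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DWIAcquisition",
    "TensorField",
    "fit_tensors",
    "fa_from_eigenvalues",
]

B0_THRESHOLD = 50.0  # s/mm^2; volumes below this count as b=0
LOG_SIGNAL_FLOOR = 1e-10  # nonpositive signals are floored before the log

# Tukey biweight tuning (95% Gaussian efficiency) for method="robust"
TUKEY_C = 4.685
ROBUST_MAX_ITER = 20
ROBUST_TOL = 1e-6


@dataclass
class DWIAcquisition:
    """A diffusion-weighted acquisition: 4-D signal plus gradient scheme.

    Attributes
    ----------
    signal : (X, Y, Z, V) float array, arbitrary signal units
    bvals : (V,) b-values in s/mm^2
    bvecs : (V, 3) unit gradient directions (arbitrary for b=0 volumes)
    wm_mask : (X, Y, Z) bool, white-matter voxels (fit/seed domain)
    brain_mask : (X, Y, Z) bool, superset of wm_mask
    voxel_size : isotropic voxel edge length in mm
    """

    signal: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    wm_mask: np.ndarray
    brain_mask: np.ndarray
    voxel_size: float = 1.7

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.wm_mask = np.asarray(self.wm_mask, dtype=bool)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, volume)")
        n_vol = self.signal.shape[3]
        if self.bvals.shape != (n_vol,):
            raise ValueError("bvals length must match the number of volumes")
        if self.bvecs.shape != (n_vol, 3):
            raise ValueError("bvecs must be (n_volumes, 3)")
        if self.wm_mask.shape != self.signal.shape[:3]:
            raise ValueError("wm_mask grid does not match signal grid")
        if self.brain_mask.shape != self.signal.shape[:3]:
            raise ValueError("brain_mask grid does not match signal grid")
        if not (self.bvals < B0_THRESHOLD).any():
            raise ValueError("acquisition needs at least one b=0 volume")
        dwi = self.bvals >= B0_THRESHOLD
        norms = np.linalg.norm(self.bvecs[dwi], axis=1)
        if dwi.any() and not np.allclose(norms, 1.0, atol=1e-3):
            raise ValueError("bvecs must be unit-norm for b>0 volumes")
        if (self.wm_mask & ~self.brain_mask).any():
            raise ValueError("wm_mask must be contained in brain_mask")

    @property
    def b0_volumes(self) -> np.ndarray:
        return self.bvals < B0_THRESHOLD


@dataclass
class TensorField:
    """Per-voxel tensor model: D, eigenvalues, FA and principal direction.

    ``defined`` marks voxels with a valid fit; voxels outside the fitting
    mask or with degenerate signal are undefined (NaN maps) and are treated
    as sub-threshold FA by the tracker.
    """

    tensor: np.ndarray        # (X, Y, Z, 3, 3) mm^2/s
    eigenvalues: np.ndarray   # (X, Y, Z, 3) sorted descending
    fa: np.ndarray            # (X, Y, Z) in [0, 1], NaN where undefined
    v1: np.ndarray            # (X, Y, Z, 3) unit principal eigenvector
    defined: np.ndarray       # (X, Y, Z) bool
    voxel_size: float = 1.7
    flagged_voxels: list = field(default_factory=list)  # degenerate-signal voxels


def fa_from_eigenvalues(eigenvalues) -> float | np.ndarray:
    """Fractional anisotropy from sorted or unsorted eigenvalues.

    FA = sqrt(3/2) * sqrt(sum_i (l_i - lbar)^2) / sqrt(sum_i l_i^2),
    with FA defined as 0 for an all-zero tuple.  Accepts a length-3 vector
    or an (..., 3) array.  Negative eigenvalues are a domain error here;
    clamping is the fitter's job.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("expected 3 eigenvalues on the last axis")
    if (lam < 0).any():
        raise ValueError("eigenvalues must be nonnegative")
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt((np.square(lam - mean)).sum(axis=-1))
    den = np.sqrt(np.square(lam).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den == 0, 0.0, fa)
    out = np.clip(fa, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows map the 6 unique tensor elements to -ln(S/S0)/1:
    ln(S/S0) = -b (gx^2 Dxx + gy^2 Dyy + gz^2 Dzz
                   + 2 gx gy Dxy + 2 gx gz Dxz + 2 gy gz Dyz).
    Coefficient order: (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz).
    """
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    b = bvals
    return -np.column_stack(
        [b * gx**2, b * gy**2, b * gz**2,
         2 * b * gx * gy, 2 * b * gx * gz, 2 * b * gy * gz]
    )


def _coeffs_to_tensor(coef: np.ndarray) -> np.ndarray:
    dxx, dyy, dzz, dxy, dxz, dyz = coef
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


def _tukey_weights(resid: np.ndarray) -> np.ndarray:
    scale = np.median(np.abs(resid - np.median(resid))) / 0.6745
    if scale <= 0:
        # MAD degenerates when most residuals are exactly zero (clean signal
        # plus a few outliers); fall back to the mean absolute deviation.
        scale = np.mean(np.abs(resid)) / 0.7979
    if scale <= 0:
        return np.ones_like(resid)
    u = resid / (TUKEY_C * scale)
    w = np.square(1.0 - np.square(u))
    w[np.abs(u) >= 1.0] = 0.0
    return w


def _fit_voxel_robust(A: np.ndarray, y: np.ndarray, w0: np.ndarray,
                      coef0: np.ndarray) -> np.ndarray:
    coef = coef0
    w_prior = w0
    for _ in range(ROBUST_MAX_ITER):
        resid = y - A @ coef
        w = _tukey_weights(resid) * w_prior
        if w.sum() == 0 or np.count_nonzero(w) < A.shape[1]:
            break
        sw = np.sqrt(w)
        new_coef, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
        if np.max(np.abs(new_coef - coef)) < ROBUST_TOL:
            coef = new_coef
            break
        coef = new_coef
    return coef


def fit_tensors(acq: DWIAcquisition, method: str = "ols",
                fit_mask: np.ndarray | None = None) -> TensorField:
    """Fit a diffusion tensor in every white-matter voxel.

    S0 is estimated as the mean of the b=0 volumes (b < 50 s/mm^2); the
    6-parameter log-linear system is then solved over the b>0 volumes by
    least squares (``ols``) or Tukey-biweight IRLS (``robust``).  Negative
    eigenvalues are clamped to zero before FA.  Voxels with all-zero or
    nonpositive-mean b0 signal are flagged and left undefined.

    ``fit_mask`` overrides the fitting domain (default: ``acq.wm_mask``);
    pass the union of the white-matter mask and the parcellation labels
    when tracking is meant to enter gray-matter end regions.
    """
    if method not in ("ols", "robust"):
        raise ValueError(f"unknown fitting method {method!r}")
    domain = acq.wm_mask if fit_mask is None else np.asarray(fit_mask, dtype=bool)
    if domain.shape != acq.signal.shape[:3]:
        raise ValueError("fit_mask grid does not match signal grid")
    dwi = ~acq.b0_volumes
    n_dwi = int(dwi.sum())
    if n_dwi < 6 or acq.signal.shape[3] < 7:
        raise ValueError("need >= 6 gradient volumes and 1 b0 for a determined fit")
    A = _design_matrix(acq.bvals[dwi], acq.bvecs[dwi])
    if np.linalg.matrix_rank(A) < 6:
        raise ValueError("gradient scheme is rank-deficient: tensor not identifiable")

    shape = acq.signal.shape[:3]
    tensor = np.full(shape + (3, 3), np.nan)
    evals = np.full(shape + (3,), np.nan)
    fa = np.full(shape, np.nan)
    v1 = np.full(shape + (3,), np.nan)
    defined = np.zeros(shape, dtype=bool)
    flagged: list[tuple[int, int, int]] = []

    vox = np.argwhere(domain)
    if vox.size == 0:
        return TensorField(tensor, evals, fa, v1, defined, acq.voxel_size, flagged)

    sig = acq.signal[domain]                     # (n_vox, V)
    s0 = sig[:, acq.b0_volumes].mean(axis=1)          # (n_vox,)
    bad = ~(s0 > 0) | np.all(sig == 0, axis=1)
    floored = np.maximum(sig[:, dwi], LOG_SIGNAL_FLOOR)
    ok = ~bad
    y = np.empty_like(floored)
    y[ok] = np.log(floored[ok] / s0[ok, None])

    # Single shared-design lstsq for every voxel at once (OLS start values)
    coefs = np.full((len(vox), 6), np.nan)
    if ok.any():
        sol, *_ = np.linalg.lstsq(A, y[ok].T, rcond=None)
        coefs[ok] = sol.T

    if method == "robust":
        prior = (sig[:, dwi] > 0).astype(float)  # floored signals are down-weighted out
        for i in np.flatnonzero(ok):
            coefs[i] = _fit_voxel_robust(A, y[i], prior[i], coefs[i])

    for i, (x, yy, z) in enumerate(vox):
        if bad[i]:
            flagged.append((int(x), int(yy), int(z)))
            continue
        D = _coeffs_to_tensor(coefs[i])
        w, V = np.linalg.eigh(D)          # ascending
        w = w[::-1]
        V = V[:, ::-1]
        w_clamped = np.maximum(w, 0.0)
        tensor[x, yy, z] = D
        evals[x, yy, z] = w_clamped
        fa[x, yy, z] = fa_from_eigenvalues(w_clamped)
        v = V[:, 0]
        v1[x, yy, z] = v / np.linalg.norm(v)
        defined[x, yy, z] = True

    return TensorField(tensor, evals, fa, v1, defined, acq.voxel_size, flagged)
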