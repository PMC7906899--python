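"""Quality control: head motion, connectome outlier screening, covariate
transforms.

Mean framewise displacement (FD) summarizes the six rigid-body motion
parameters returned by eddy-current correction: frame-to-frame absolute
differences of the three translations plus the three rotations converted
to arc length on a 50 mm sphere.  Connectome screening flags subjects
whose mean NOS / mean FA over existing connections, or whose prevalence
of existing (equivalently, non-existing) connections, falls outside
Q1 - k*IQR or Q3 + k*IQR fences (k = 2), in a single pass; scans with a
severe fat-suppression artifact rating are excluded outright.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MotionTrace",
    "framewise_displacement",
    "iqr_outliers",
    "qc_connectomes",
    "log_transform_covariates",
    "load_motion_trace",
]

SPHERE_RADIUS_MM = 50.0
VALID_RATINGS = ("no/very mild", "moderate", "severe")
QC_STATISTICS = ("mean_nos_existing", "mean_fa_existing",
                 "prevalence_existing", "prevalence_nonexisting")


@dataclass
class MotionTrace:
    """Per-frame rigid-body motion: translations in mm, rotations in radians."""

    translations: np.ndarray  # (T, 3) mm
    rotations: np.ndarray     # (T, 3) radians

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape != self.rotations.shape or \
                self.translations.shape[1] != 3:
            raise ValueError("translations and rotations must both be (T, 3)")
        if len(self.translations) < 2:
            raise ValueError("framewise displacement needs at least 2 frames")
        if np.abs(self.rotations).max() > np.pi:
            warnings.warn("rotations exceed pi: units may be degrees, not radians",
                          stacklevel=2)


def load_motion_trace(path: str | Path,
                      column_order: str = "rot_first") -> MotionTrace:
    """Read a 6-column whitespace motion-parameter table (one row per
    volume).  ``column_order``: 'rot_first' (3 rotations then 3
    translations, the eddy_correct convention) or 'trans_first'."""
    arr = np.loadtxt(path)
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 6:
        raise ValueError("motion table must have 6 columns")
    if column_order == "rot_first":
        return MotionTrace(translations=arr[:, 3:], rotations=arr[:, :3])
    if column_order == "trans_first":
        return MotionTrace(translations=arr[:, :3], rotations=arr[:, 3:])
    raise ValueError("column_order must be 'rot_first' or 'trans_first'")


def framewise_displacement(m: MotionTrace,
                           sphere_radius: float = SPHERE_RADIUS_MM):
    """Per-frame FD (mm) and its mean.

    FD_t = sum_i |d translation_i| + r * sum_i |d rotation_i|, rotations
    converted to displacement as arc length on a sphere of radius r
    (default 50 mm).  The first frame has FD 0 and is excluded from the
    mean.
    """
    dt = np.abs(np.diff(m.translations, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(m.rotations, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], dt + sphere_radius * dr])
    return fd, float(fd[1:].mean())


def iqr_outliers(values, k: float = 2.0) -> np.ndarray:
    """Tukey-fence outlier flags: value > Q3 + k*IQR or < Q1 - k*IQR.

    Quartiles use linear interpolation at positions p*(n-1).  Fences are
    computed once on the full vector (single-pass rule).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 4:
        raise ValueError("need a 1-D vector of at least 4 values")
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    q1, q3 = np.percentile(v, [25, 75])  # linear interpolation
    iqr = q3 - q1
    return (v > q3 + k * iqr) | (v < q1 - k * iqr)


def connectome_qc_statistics(conn) -> dict:
    """The four per-subject screening statistics.  An existing connection
    is a nonzero NOS edge; prevalence is the fraction of possible pairs
    with one."""
    n = conn.nos.shape[0]
    iu = np.triu_indices(n, k=1)
    nos = conn.nos[iu]
    fa = conn.fa[iu]
    existing = nos > 0
    n_exist = int(existing.sum())
    return {
        "mean_nos_existing": float(nos[existing].mean()) if n_exist else 0.0,
        "mean_fa_existing": float(fa[existing].mean()) if n_exist else 0.0,
        "prevalence_existing": n_exist / len(nos),
        "prevalence_nonexisting": 1.0 - n_exist / len(nos),
    }


def qc_connectomes(connectomes: dict, ratings: dict, k: float = 2.0) -> pd.DataFrame:
    """Per-subject QC report and include/exclude decision.

    ``connectomes`` maps subject id -> Connectome, ``ratings`` maps
    subject id -> artifact rating.  Severely artifacted scans are excluded
    regardless of statistics; the remaining subjects are screened with
    ``iqr_outliers`` (k = 2) on each of the four statistics across
    subjects.  A subject is excluded iff any criterion flags.  With fewer
    than 4 subjects the outlier step is skipped with a warning.
    """
    rows = []
    for sid, conn in connectomes.items():
        rating = ratings.get(sid, "no/very mild")
        if rating not in VALID_RATINGS:
            raise ValueError(f"unknown artifact rating {rating!r} for {sid!r}")
        stats = connectome_qc_statistics(conn)
        rows.append({"subject": sid, "artifact_rating": rating, **stats})
    report = pd.DataFrame(rows)
    report["flag_severe_artifact"] = report["artifact_rating"] == "severe"

    screen = ~report["flag_severe_artifact"]
    for stat in QC_STATISTICS:
        col = f"flag_{stat}"
        report[col] = False
        if screen.sum() >= 4:
            flags = iqr_outliers(report.loc[screen, stat].to_numpy(), k=k)
            report.loc[screen, col] = flags
        else:
            warnings.warn("fewer than 4 screenable subjects: outlier step skipped",
                          stacklevel=2)
    flag_cols = [c for c in report.columns if c.startswith("flag_")]
    report["exclude"] = report[flag_cols].any(axis=1)
    return report


def log_transform_covariates(cohort: pd.DataFrame,
                             fd_col: str = "mean_fd",
                             cesd_col: str = "cesd") -> pd.DataFrame:
    """Add ln(mean FD) and ln(CES-D + 1) columns (skewed covariates are
    log-transformed before modeling; the +1 offset accommodates CES-D
    scores of zero).  Originals are retained."""
    out = cohort.copy()
    if fd_col in out:
        fd = out[fd_col].to_numpy(dtype=float)
        if (fd[~np.isnan(fd)] <= 0).any():
            raise ValueError("mean FD must be positive for the log transform")
        out["ln_mean_fd"] = np.log(fd)
    if cesd_col in out:
        ces = out[cesd_col].to_numpy(dtype=float)
        if (ces[~np.isnan(ces)] < 0).any():
            raise ValueError("CES-D scores must be nonnegative")
        out["ln_cesd"] = np.log(ces + 1.0)
    return out
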