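"""Digital fiber phantoms and simulated cohorts.

Every downstream stage of the pipeline is testable without real data:

* :func:`make_phantom` builds a voxel grid containing a fiber bundle with a
  known per-voxel diffusion tensor, synthesizes the diffusion-weighted
  signal S(g) = S0 * exp(-b g^T D g) for an approximately uniform gradient
  scheme (b = 1000 s/mm^2, 60 directions by default, 1.7 mm isotropic
  voxels), optionally corrupts it with Rician noise, and returns the
  ground truth (bundle voxels, analytic bundle FA, expected streamline
  count between the labeled end regions).

* :func:`make_cohort` simulates a participant table with Hardy-Weinberg
  genotypes at two obesity-related loci, an additive FTO effect on BMI,
  and network metrics carrying a planted (by default negative) BMI effect
  plus covariates - the generative counterpart of the regression models
  applied to it downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .tensor import DWIAcquisition, fa_from_eigenvalues

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "make_phantom",
    "make_cohort",
    "fibonacci_sphere",
    "save_phantom",
    "load_phantom",
]

GEOMETRIES = ("straight_bundle", "curved_bundle", "two_bundles")

# Default single-tensor diffusivities (mm^2/s): prolate white-matter-like
# bundle, isotropic background at the trace-matched mean diffusivity.
BUNDLE_EIGENVALUES = (1.7e-3, 0.3e-3, 0.3e-3)
BACKGROUND_EIGENVALUES = (0.76e-3, 0.76e-3, 0.76e-3)


@dataclass
class PhantomSpec:
    """Configuration of a digital fiber phantom."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    geometry: str = "straight_bundle"
    bundle_cross_section: int = 3          # side of the square cross-section, voxels
    bundle_length: int | None = None       # centerline length in voxels; None = fit grid
    bundle_eigenvalues: tuple[float, float, float] = BUNDLE_EIGENVALUES
    background_eigenvalues: tuple[float, float, float] = BACKGROUND_EIGENVALUES
    b_value: float = 1000.0                # s/mm^2
    n_directions: int = 60
    n_b0: int = 1
    noise_sigma: float = 0.0               # Rician sigma in signal units; 0 = noise-free
    s0: float = 1000.0
    voxel_size: float = 1.7                # mm, isotropic
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}")
        for lam in (self.bundle_eigenvalues, self.background_eigenvalues):
            if any(x < 0 for x in lam) or list(lam) != sorted(lam, reverse=True):
                raise ValueError("eigenvalues must be nonnegative and sorted descending")
        if self.n_directions < 6:
            raise ValueError("need at least 6 gradient directions")
        if self.n_b0 < 1:
            raise ValueError("need at least one b=0 volume")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


@dataclass
class PhantomTruth:
    """Ground truth shipped with a phantom, the oracle for downstream tests."""

    bundle_voxels: list            # [[x, y, z], ...] white-matter bundle voxels
    expected_bundle_fa: float      # closed-form FA of the bundle eigenvalues
    end_region_labels: list        # label ids of the end caps
    expected_nos: int              # seeds whose streamline should touch both caps
    label_pairs: list              # [[a, b], ...] cap pairs joined by a bundle

    # expected_nos is exact for straight geometries (every seed lies on a
    # principal-direction line between the caps); for curved bundles it is
    # an upper bound, since seeds near the tube wall can drift out sideways.


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (spherical Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (1.0 + np.sqrt(5.0))
    theta = golden * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def _tensor_from_tangent(tangent: np.ndarray, eigenvalues) -> np.ndarray:
    """Prolate tensor with the principal axis along ``tangent``."""
    l1, l2, l3 = eigenvalues
    t = tangent / np.linalg.norm(tangent)
    # any orthonormal complement
    a = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e2 = np.cross(t, a)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(t, e2)
    return l1 * np.outer(t, t) + l2 * np.outer(e2, e2) + l3 * np.outer(e3, e3)


def _centerline(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, int]:
    """Dense centerline samples, tangents, and points-per-voxel density.

    The polyline includes a one-voxel straight extension at each end: the
    extensions become the labeled end caps, the interior the bundle.
    """
    nx, ny, nz = spec.grid_shape
    cap = 1.0  # end caps are 1-voxel-thick slabs
    density = 20  # samples per voxel of arc length
    if spec.geometry in ("straight_bundle", "two_bundles"):
        length = spec.bundle_length or (nz - 2 * (int(cap) + 1) - 2)
        if length < 3:
            raise ValueError("grid too small for the bundle plus end caps")
        z0 = (nz - length) / 2.0
        total = length + 2 * cap
        if z0 - cap < 1 or z0 + length + cap > nz - 1:
            raise ValueError("bundle plus end caps does not fit the grid")
        s = np.linspace(-cap, length + cap, int(total * density))
        pts = np.column_stack([np.full_like(s, nx / 2.0),
                               np.full_like(s, ny / 2.0),
                               z0 + s])
        tans = np.tile([0.0, 0.0, 1.0], (len(s), 1))
        return pts, tans, density
    # curved_bundle: quarter arc in the x-z plane
    margin = spec.bundle_cross_section / 2.0 + cap + 1.5
    radius = min(nx, nz) - 2 * margin
    if radius < 4:
        raise ValueError("grid too small for the curved bundle")
    cx, cz = margin, margin
    arc_len = np.pi / 2.0 * radius
    n_arc = int(arc_len * density)
    theta = np.linspace(0.0, np.pi / 2.0, n_arc)
    arc = np.column_stack([cx + radius * np.sin(theta),
                           np.full(n_arc, ny / 2.0),
                           cz + radius * np.cos(theta)])
    tan = np.column_stack([np.cos(theta), np.zeros(n_arc), -np.sin(theta)])
    # straight one-voxel extensions at both ends (the future caps)
    next_a = np.linspace(-cap, 0.0, int(cap * density), endpoint=False)
    ext_a = arc[0] + next_a[:, None] * tan[0]
    tan_a = np.tile(tan[0], (len(next_a), 1))
    next_b = np.linspace(0.0, cap, int(cap * density) + 1)[1:]
    ext_b = arc[-1] + next_b[:, None] * tan[-1]
    tan_b = np.tile(tan[-1], (len(next_b), 1))
    pts = np.vstack([ext_a, arc, ext_b])
    tans = np.vstack([tan_a, tan, tan_b])
    return pts, tans, density


def _tube_voxels(pts: np.ndarray, tans: np.ndarray, radius: float,
                 grid_shape: tuple[int, int, int], cap: float, density: int):
    """Voxels whose center lies within ``radius`` of the polyline, split into
    (start cap, interior bundle, end cap) by arc-length position."""
    lo = np.maximum(np.floor(pts.min(axis=0) - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(pts.max(axis=0) + radius + 1).astype(int),
                    np.array(grid_shape))
    xs, ys, zs = [np.arange(lo[d], hi[d]) for d in range(3)]
    centers = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1) + 0.5
    flat = centers.reshape(-1, 3)
    d2 = ((flat[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    # lateral (perpendicular) distance to the polyline must be within the
    # tube radius; the axial overhang past the sampled ends is rejected so
    # the end caps stay exactly one voxel thick
    diff = flat - pts[nearest]
    axial = np.einsum("ij,ij->i", diff, tans[nearest])
    lat2 = d2[np.arange(len(flat)), nearest] - axial**2
    inside = (lat2 <= radius**2) & (np.abs(axial) <= 1.0 / density)
    n_cap = int(cap * density)
    cap_a, bundle, cap_b, tangent = [], [], [], {}
    for idx in np.flatnonzero(inside):
        vox = tuple(int(c) for c in np.floor(flat[idx]).astype(int))
        k = nearest[idx]
        tangent[vox] = tans[k]
        if k < n_cap:
            cap_a.append(vox)
        elif k >= len(pts) - n_cap:
            cap_b.append(vox)
        else:
            bundle.append(vox)
    return cap_a, bundle, cap_b, tangent


def make_phantom(spec: PhantomSpec):
    """Build (DWIAcquisition, parcellation volume, PhantomTruth).

    The white-matter mask is exactly the bundle voxel set; the end regions
    are 1-voxel-thick caps carrying integer labels (1, 2, ... per bundle)
    and the bundle's anisotropic tensor, so tracking can enter them before
    leaving the tracking mask.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    radius = spec.bundle_cross_section / 2.0

    bundles = []
    if spec.geometry == "two_bundles":
        base_pts, base_tans, density = _centerline(spec)
        gap = spec.bundle_cross_section + 2
        off = np.array([gap / 2.0 + radius, 0.0, 0.0])
        for sign in (-1.0, +1.0):
            bundles.append((base_pts + sign * off, base_tans, density))
    else:
        bundles.append(_centerline(spec))

    wm = np.zeros(shape, dtype=bool)
    parc = np.zeros(shape, dtype=np.int32)
    D_bg = np.diag(spec.background_eigenvalues)
    tensors = np.tile(D_bg, shape + (1, 1)).reshape(shape + (3, 3)).copy()
    bundle_voxels: list[tuple[int, int, int]] = []
    label_pairs: list[list[int]] = []
    next_label = 1
    for pts, tans, density in bundles:
        cap_a, bund, cap_b, tangent = _tube_voxels(pts, tans, radius, shape,
                                                   cap=1.0, density=density)
        if not cap_a or not cap_b or len(bund) < 3:
            raise ValueError("geometry does not fit the grid")
        la, lb = next_label, next_label + 1
        next_label += 2
        label_pairs.append([la, lb])
        for vox in bund:
            wm[vox] = True
            bundle_voxels.append(vox)
            tensors[vox] = _tensor_from_tangent(tangent[vox], spec.bundle_eigenvalues)
        for vox, lab in [(v, la) for v in cap_a] + [(v, lb) for v in cap_b]:
            if wm[vox]:
                continue  # bundle membership wins at the seam
            parc[vox] = lab
            tensors[vox] = _tensor_from_tangent(tangent[vox], spec.bundle_eigenvalues)

    # noise-free signal from the ground-truth tensor field
    dirs = fibonacci_sphere(spec.n_directions)
    bvecs = np.vstack([np.zeros((spec.n_b0, 3)), dirs])
    bvals = np.concatenate([np.zeros(spec.n_b0), np.full(spec.n_directions, spec.b_value)])
    quad = np.einsum("vi,xyzij,vj->xyzv", bvecs, tensors, bvecs)
    signal = spec.s0 * np.exp(-bvals[None, None, None, :] * quad)

    if spec.noise_sigma > 0:  # Rician: magnitude of complex Gaussian
        n1 = rng.normal(0.0, spec.noise_sigma, signal.shape)
        n2 = rng.normal(0.0, spec.noise_sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)

    brain = np.ones(shape, dtype=bool)
    acq = DWIAcquisition(signal=signal, bvals=bvals, bvecs=bvecs,
                         wm_mask=wm, brain_mask=brain, voxel_size=spec.voxel_size)
    truth = PhantomTruth(
        bundle_voxels=[list(v) for v in sorted(bundle_voxels)],
        expected_bundle_fa=float(fa_from_eigenvalues(spec.bundle_eigenvalues)),
        end_region_labels=np.unique(parc[parc > 0]).astype(int).tolist(),
        expected_nos=len(bundle_voxels),
        label_pairs=label_pairs,
    )
    return acq, parc, truth


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

NETWORK_METRICS = ("fa_cs", "fa_cc", "nos_cs", "nos_cc")
REWARD_REGIONS = ("accumbens", "caudate", "putamen", "medialorbitofrontal",
                  "lateralorbitofrontal")

# Planted BMI slopes on the four normalized network metrics and the residual
# SDs that reproduce confidence-interval widths of the scale observed at
# n ~ 350 (half-width ~ 1.96 * sigma / (sd_BMI * sqrt(n))).
DEFAULT_METRIC_BETAS = {"fa_cs": -0.00089, "fa_cc": -0.02,
                        "nos_cs": -0.0025, "nos_cc": 0.31}
DEFAULT_METRIC_SDS = {"fa_cs": 0.025, "fa_cc": 0.68,
                      "nos_cs": 0.053, "nos_cc": 13.5}
DEFAULT_METRIC_INTERCEPTS = {"fa_cs": 1.15, "fa_cc": 2.0,
                             "nos_cs": 1.3, "nos_cc": 10.0}

# Node-wise connectivity-strength slopes (per kg/m^2), one per reward region
# and hemisphere, for each edge type.
DEFAULT_NODE_BETAS = {
    "fa_cs": {
        ("accumbens", "right"): -3.0e-4, ("accumbens", "left"): -2.8e-4,
        ("caudate", "right"): 1.8e-4, ("caudate", "left"): -1.0e-4,
        ("putamen", "right"): -1.7e-4, ("putamen", "left"): -2.5e-4,
        ("medialorbitofrontal", "right"): -6.9e-5,
        ("medialorbitofrontal", "left"): -1.4e-4,
        ("lateralorbitofrontal", "right"): -3.5e-4,
        ("lateralorbitofrontal", "left"): 7.9e-5,
    },
    "nos_cs": {
        ("accumbens", "right"): -5.1e-4, ("accumbens", "left"): -2.8e-4,
        ("caudate", "right"): -6.2e-5, ("caudate", "left"): -4.5e-4,
        ("putamen", "right"): -6.6e-4, ("putamen", "left"): -1.3e-3,
        ("medialorbitofrontal", "right"): -4.2e-4,
        ("medialorbitofrontal", "left"): -4.7e-4,
        ("lateralorbitofrontal", "right"): -3.9e-4,
        ("lateralorbitofrontal", "left"): -3.1e-4,
    },
}
DEFAULT_NODE_SDS = {"fa_cs": 0.01, "nos_cs": 0.03}


@dataclass
class CohortSpec:
    """Generative model of the simulated participant table.

    BMI follows intercept + age/sex effects + an additive risk-allele
    effect at the FTO locus + Gaussian noise; each network metric follows
    intercept + beta_bmi * BMI + covariate effects + Gaussian noise.
    Genotypes are drawn at Hardy-Weinberg proportions.  Covariate
    distributions (age uniform 20-59, head motion, depression score,
    smoking, education, artifact ratings and their missingness) default to
    the demographic profile of a middle-aged population cohort.
    """

    n: int = 347
    maf_fto: float = 0.42
    maf_taq1a: float = 0.15
    fto_bmi_effect: float = 1.0            # kg/m^2 per risk allele
    taq1a_bmi_effect: float = 0.0
    bmi_intercept: float = 23.5
    bmi_age_effect: float = 0.03           # kg/m^2 per year
    bmi_sex_effect: float = 0.5            # male minus female
    noise_sd_bmi: float = 3.4
    beta_bmi_on_metric: dict = field(default_factory=lambda: dict(DEFAULT_METRIC_BETAS))
    noise_sd_metric: dict = field(default_factory=lambda: dict(DEFAULT_METRIC_SDS))
    metric_intercepts: dict = field(default_factory=lambda: dict(DEFAULT_METRIC_INTERCEPTS))
    covariate_effects: dict = field(default_factory=lambda: {"age": -2e-4,
                                                             "ln_mean_fd": -0.01})
    node_betas: dict = field(default_factory=lambda: {k: dict(v) for k, v in
                                                      DEFAULT_NODE_BETAS.items()})
    node_noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NODE_SDS))
    include_nodewise: bool = True
    missing_smoking: float = 10 / 347
    missing_education: float = 2 / 347
    missing_cesd: float = 21 / 347
    prop_moderate_artifact: float = 29 / 347
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.maf_fto, self.maf_taq1a):
            if not 0.0 <= f <= 1.0:
                raise ValueError("allele frequencies must lie in [0, 1]")
        if self.n < 12:  # number of Model-2 parameters + 2
            raise ValueError("cohort too small for the models applied to it")


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate the participant table (one row per participant)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    age = rng.uniform(20.0, 59.0, n)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    fto = rng.binomial(2, spec.maf_fto, n)            # risk-allele count
    taq1a_geno = rng.binomial(2, spec.maf_taq1a, n)
    taq1a = (taq1a_geno >= 1).astype(int)             # >= 1 risk allele

    bmi = (spec.bmi_intercept
           + spec.bmi_age_effect * age
           + spec.bmi_sex_effect * (sex == "male")
           + spec.fto_bmi_effect * fto
           + spec.taq1a_bmi_effect * taq1a
           + rng.normal(0.0, spec.noise_sd_bmi, n))
    bmi = np.clip(bmi, 15.0, None)

    # head motion tracks BMI (the collinearity the sensitivity models adjust for)
    mean_fd = np.clip(0.50 + 0.0045 * bmi + rng.normal(0.0, 0.12, n), 0.2, None)
    cesd = np.round(np.clip(rng.gamma(1.95, 4.87, n), 0.0, 50.0))
    smoking = rng.choice(["never", "previous", "current"], size=n,
                         p=np.array([175, 79, 83]) / 337)
    education = rng.choice([1, 2, 3], size=n, p=np.array([9, 190, 146]) / 345)
    rating = np.where(rng.random(n) < spec.prop_moderate_artifact,
                      "moderate", "no/very mild")

    df = pd.DataFrame({
        "pid": np.arange(n),
        "age": age,
        "sex": sex,
        "bmi": bmi,
        "fto": fto,
        "taq1a": taq1a,
        "mean_fd": mean_fd,
        "cesd": cesd,
        "smoking": smoking,
        "education": education,
        "artifact_rating": rating,
    })

    cov_values = {
        "age": age,
        "sex": (sex == "male").astype(float),
        "ln_mean_fd": np.log(mean_fd),
        "ln_cesd": np.log(cesd + 1.0),
        "education": education.astype(float),
    }
    for metric in NETWORK_METRICS:
        y = np.full(n, spec.metric_intercepts.get(metric, 1.0))
        y = y + spec.beta_bmi_on_metric.get(metric, 0.0) * bmi
        for cov, coef in spec.covariate_effects.items():
            y = y + coef * cov_values[cov]
        y = y + rng.normal(0.0, spec.noise_sd_metric.get(metric, 0.05), n)
        df[metric] = y

    if spec.include_nodewise:
        for edge, betas in spec.node_betas.items():
            sd = spec.node_noise_sd.get(edge, 0.02)
            for (region, hemi), beta in betas.items():
                y = 0.1 + beta * bmi + rng.normal(0.0, sd, n)
                df[f"{edge}_{region}_{hemi}"] = y

    # listwise-missing questionnaire covariates
    for col, rate in [("smoking", spec.missing_smoking),
                      ("education", spec.missing_education),
                      ("cesd", spec.missing_cesd)]:
        miss = rng.random(n) < rate
        df.loc[miss, col] = np.nan

    return df


# ---------------------------------------------------------------------------
# Serialization (NIfTI + FSL-style gradient text + JSON truth + CSV cohort)
# ---------------------------------------------------------------------------

def save_phantom(acq: DWIAcquisition, parc: np.ndarray, truth: PhantomTruth,
                 out_dir: str | Path, spec: PhantomSpec | None = None) -> Path:
    """Write a phantom as NIfTI volumes + bvals/bvecs text + truth JSON."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([acq.voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(acq.signal.astype(np.float32), affine), out / "dwi.nii")
    nib.save(nib.Nifti1Image(acq.wm_mask.astype(np.uint8), affine), out / "wm_mask.nii")
    nib.save(nib.Nifti1Image(acq.brain_mask.astype(np.uint8), affine),
             out / "brain_mask.nii")
    nib.save(nib.Nifti1Image(np.asarray(parc, dtype=np.int32), affine),
             out / "parcellation.nii")
    np.savetxt(out / "bvals", acq.bvals[None, :], fmt="%.1f")
    np.savetxt(out / "bvecs", acq.bvecs.T, fmt="%.8f")   # FSL: 3 rows
    with open(out / "truth.json", "w") as fh:
        json.dump(asdict(truth), fh, indent=1)
    if spec is not None:
        with open(out / "phantom_spec.json", "w") as fh:
            json.dump(asdict(spec), fh, indent=1)
    return out


def load_phantom(in_dir: str | Path):
    """Inverse of :func:`save_phantom`."""
    import nibabel as nib

    d = Path(in_dir)
    img = nib.load(d / "dwi.nii")
    signal = np.asarray(img.dataobj, dtype=float)
    voxel_size = float(img.header.get_zooms()[0])
    wm = np.asarray(nib.load(d / "wm_mask.nii").dataobj) > 0
    brain = np.asarray(nib.load(d / "brain_mask.nii").dataobj) > 0
    parc = np.asarray(nib.load(d / "parcellation.nii").dataobj).astype(np.int32)
    bvals = np.loadtxt(d / "bvals").ravel()
    bvecs = np.loadtxt(d / "bvecs").T
    acq = DWIAcquisition(signal=signal, bvals=bvals, bvecs=bvecs, wm_mask=wm,
                         brain_mask=brain, voxel_size=voxel_size)
    truth = None
    tpath = d / "truth.json"
    if tpath.exists():
        truth = PhantomTruth(**json.loads(tpath.read_text()))
    return acq, parc, truth
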