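"""Deterministic FACT streamline tractography.

Fiber Assignment by Continuous Tracking follows, from a seed at every
white-matter voxel center, the voxel-wise principal diffusion direction in
a straight line until the ray leaves the current voxel, then adopts the
next voxel's direction (sign-aligned with the incoming one).  A direction
of propagation terminates when the next voxel falls below the FA
threshold, leaves the tracking mask, or would require a turn of more than
the angle threshold (strictly greater).  The two half-tracks from each
seed are concatenated; tracks visiting fewer distinct voxels than
``min_length`` are discarded.  The procedure involves no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .tensor import TensorField

__all__ = [
    "TrackingConfig",
    "Streamline",
    "StreamlineSet",
    "track",
    "angle_between",
    "save_streamlines_text",
    "load_streamlines_text",
]

_TIE_TOL = 1e-9


@dataclass
class TrackingConfig:
    """Stopping criteria and seeding policy for FACT tracking.

    fa_threshold and angle_threshold are the classical termination rules
    (propagation stops below FA 0.1 or at a turn of more than 45 degrees);
    min_length suppresses near-point tracks; max_steps is a safety cap
    that cannot trigger on well-posed fields.
    """

    fa_threshold: float = 0.1
    angle_threshold: float = 45.0      # degrees, strict ">" stops
    min_length: int = 3                # distinct voxels
    seed_policy: str = "every_wm_voxel"
    max_steps: int | None = None       # default: 10 * max grid dimension

    def __post_init__(self) -> None:
        if not 0.0 <= self.fa_threshold < 1.0:
            raise ValueError("fa_threshold must lie in [0, 1)")
        if not 0.0 < self.angle_threshold <= 90.0:
            raise ValueError("angle_threshold must lie in (0, 90] degrees")
        if self.min_length < 1:
            raise ValueError("min_length must be positive")
        if self.seed_policy != "every_wm_voxel":
            raise ValueError("only the every_wm_voxel seed policy is supported")


@dataclass
class Streamline:
    points: np.ndarray                  # (P, 3) voxel-space coordinates
    seed: tuple[int, int, int]
    visited: list                       # ordered distinct voxels, (x, y, z) tuples
    termination: tuple[str, str]        # reason at (backward end, forward end)


@dataclass
class StreamlineSet:
    streamlines: list
    n_seeds: int
    units: str = "voxel"
    config: TrackingConfig | None = None

    def __len__(self) -> int:
        return len(self.streamlines)


def angle_between(d_in: np.ndarray, d_new: np.ndarray) -> float:
    """Turning angle in degrees after sign-aligning ``d_new`` with ``d_in``.

    Both inputs must be unit vectors.  The sign of d_new is chosen so that
    its dot product with d_in is nonnegative; the plain arccos of that dot
    product is returned, hence the result lies in [0, 90].
    """
    a = np.asarray(d_in, dtype=float)
    b = np.asarray(d_new, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cannot measure the angle of a zero vector")
    if not (np.isclose(na, 1.0, atol=1e-6) and np.isclose(nb, 1.0, atol=1e-6)):
        raise ValueError("angle_between expects unit vectors")
    dot = float(a @ b)
    if dot < 0:
        dot = -dot
    return float(np.degrees(np.arccos(np.clip(dot, -1.0, 1.0))))


def _ray_voxel_exit(pos: np.ndarray, d: np.ndarray, vox: np.ndarray):
    """Exit point of the ray pos + t*d from the axis-aligned unit voxel
    ``vox`` = [i, i+1) x [j, j+1) x [k, k+1), and the next voxel entered.

    Ties (corner or edge exits) are resolved by advancing half a voxel
    along the ray past the boundary and taking the containing voxel.
    """
    ts = np.full(3, np.inf)
    for ax in range(3):
        if d[ax] > _TIE_TOL:
            ts[ax] = (vox[ax] + 1.0 - pos[ax]) / d[ax]
        elif d[ax] < -_TIE_TOL:
            ts[ax] = (vox[ax] - pos[ax]) / d[ax]
    t = ts.min()
    if not np.isfinite(t):
        raise ValueError("direction vector is numerically zero")
    exit_pos = pos + t * d
    crossing = np.flatnonzero(ts - t <= _TIE_TOL)
    if len(crossing) == 1:
        nxt = vox.copy()
        nxt[crossing[0]] += 1 if d[crossing[0]] > 0 else -1
    else:  # corner/edge tie
        probe = pos + (t + 0.5) * d
        nxt = np.floor(probe).astype(int)
    return exit_pos, nxt


def _half_track(field: TensorField, mask: np.ndarray, cfg: TrackingConfig,
                seed: tuple[int, int, int], sign: float, max_steps: int):
    """Propagate from the seed center along sign * v1 until termination."""
    pos = np.asarray(seed, dtype=float) + 0.5
    d = sign * field.v1[seed]
    vox = np.asarray(seed, dtype=int)
    points = [pos]
    visited = [tuple(seed)]
    shape = mask.shape
    reason = "max_steps"
    for _ in range(max_steps):
        exit_pos, nxt = _ray_voxel_exit(pos, d, vox)
        points.append(exit_pos)
        pos = exit_pos
        if (nxt < 0).any() or (nxt >= np.asarray(shape)).any() or not mask[tuple(nxt)]:
            reason = "left_mask"
            break
        t_nxt = tuple(int(c) for c in nxt)
        if not field.defined[t_nxt] or not field.fa[t_nxt] >= cfg.fa_threshold:
            reason = "low_fa"
            break
        v_new = field.v1[t_nxt].copy()
        if float(v_new @ d) < 0:
            v_new = -v_new
        if angle_between(d, v_new) > cfg.angle_threshold:
            reason = "sharp_turn"
            break
        vox = nxt
        visited.append(t_nxt)
        d = v_new
    return points, visited, reason


def track(field: TensorField, tracking_mask: np.ndarray,
          cfg: TrackingConfig | None = None,
          seed_mask: np.ndarray | None = None) -> StreamlineSet:
    """FACT tracking: one bidirectional streamline per seed voxel.

    Seeds are the voxels of ``seed_mask`` (default: ``tracking_mask``)
    whose tensor is defined and whose FA clears the threshold.  The
    tracking mask is typically the union of the white-matter mask and the
    parcellation labels, so that tracks can enter gray-matter end regions
    before terminating.
    """
    import warnings

    cfg = cfg or TrackingConfig()
    mask = np.asarray(tracking_mask, dtype=bool)
    if mask.shape != field.fa.shape:
        raise ValueError("tracking_mask grid does not match the tensor field")
    seeds_from = mask if seed_mask is None else np.asarray(seed_mask, dtype=bool)
    max_steps = cfg.max_steps or 10 * max(mask.shape)

    seeds = np.argwhere(seeds_from)
    if seeds.size == 0:
        warnings.warn("empty seed mask: no streamlines generated", stacklevel=2)
        return StreamlineSet([], n_seeds=0, config=cfg)

    out: list[Streamline] = []
    for seed in map(tuple, seeds):
        if not field.defined[seed] or not field.fa[seed] >= cfg.fa_threshold:
            continue
        p_fwd, v_fwd, r_fwd = _half_track(field, mask, cfg, seed, +1.0, max_steps)
        p_bwd, v_bwd, r_bwd = _half_track(field, mask, cfg, seed, -1.0, max_steps)
        points = np.vstack([np.asarray(p_bwd[::-1]), np.asarray(p_fwd[1:])])
        visited: list[tuple[int, int, int]] = []
        seen = set()
        for v in v_bwd[::-1] + v_fwd[1:]:
            if v not in seen:
                seen.add(v)
                visited.append(v)
        if len(visited) < cfg.min_length:
            continue
        out.append(Streamline(points=points, seed=seed, visited=visited,
                              termination=(r_bwd, r_fwd)))
    return StreamlineSet(out, n_seeds=len(seeds), config=cfg)


# ---------------------------------------------------------------------------
# Plain-text streamline serialization (one point per line, blank line
# between streamlines) - a language-neutral companion to binary formats.
# ---------------------------------------------------------------------------

def save_streamlines_text(streams: StreamlineSet, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# streamlines in {streams.units} coordinates\n")
        for s in streams.streamlines:
            for p in s.points:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            fh.write("\n")
    return path


def save_streamlines_trk(streams: StreamlineSet, path: str | Path,
                         voxel_size: float = 1.7,
                         shape: tuple[int, int, int] = (32, 32, 32)) -> Path:
    """Write streamlines as a TrackVis .trk file (voxel -> mm scaling)."""
    import nibabel as nib

    affine = np.diag([voxel_size] * 3 + [1.0])
    tractogram = nib.streamlines.Tractogram(
        [s.points * voxel_size for s in streams.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    header = nib.streamlines.trk.TrkFile.create_empty_header()
    header["voxel_sizes"] = (voxel_size,) * 3
    header["dimensions"] = shape
    header["voxel_to_rasmm"] = affine
    nib.streamlines.save(nib.streamlines.trk.TrkFile(tractogram, header), str(path))
    return Path(path)


def load_streamlines_text(path: str | Path) -> list[np.ndarray]:
    """Read the plain-text format back as a list of (P, 3) arrays."""
    chunks: list[list[list[float]]] = [[]]
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line.startswith("#"):
            continue
        if not line:
            if chunks[-1]:
                chunks.append([])
            continue
        chunks[-1].append([float(x) for x in line.split()])
    return [np.asarray(c) for c in chunks if c]
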