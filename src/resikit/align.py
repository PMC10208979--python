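"""Round-to-round channel alignment.

Sequential imaging rounds must be brought into one coordinate frame before
localization clouds can be compared across channels. Alignment proceeds in
two stages, mirroring common SMLM practice: a coarse global translation found
by cross-correlating binned 2D localization histograms, then a rigid
(translation + in-plane rotation) refinement from corresponding fiducial
sites, solved as an orthogonal Procrustes problem without scaling. z is never
rotated: the refinement is strictly in-plane.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.spatial import cKDTree

from .errors import ValidationError
from .io import LocalizationTable


@dataclass
class RigidTransform2D:
    """In-plane rigid transform.

    Applying the transform rotates by ``rotation`` radians about ``pivot``
    and then translates by ``translation`` (nm):
    ``p' = R (p - pivot) + pivot + translation``.

    ``rms`` optionally records the post-fit fiducial residual (nm).
    """

    rotation: float = 0.0  # radians, normalized to (-pi, pi]
    translation: tuple[float, float] = (0.0, 0.0)
    pivot: tuple[float, float] = (0.0, 0.0)
    rms: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        a = math.remainder(self.rotation, 2.0 * math.pi)
        if a <= -math.pi:
            a += 2.0 * math.pi
        self.rotation = a

    @property
    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 2) or (N, 3) point array; z passes through."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        xy = points[:, :2]
        piv = np.asarray(self.pivot)
        out_xy = (xy - piv) @ self.matrix.T + piv + np.asarray(self.translation)
        if points.shape[1] > 2:
            return np.column_stack([out_xy, points[:, 2:]])
        return out_xy

    def inverse(self) -> "RigidTransform2D":
        """Exact inverse: ``t.inverse().apply(t.apply(p)) == p``."""
        piv = np.asarray(self.pivot)
        tr = np.asarray(self.translation)
        # p = R^-1(p' - piv - tr) + piv, rewritten about pivot' = piv + tr
        return RigidTransform2D(
            rotation=-self.rotation,
            translation=tuple(-tr),
            pivot=tuple(piv + tr),
        )


def compose(second: RigidTransform2D, first: RigidTransform2D) -> RigidTransform2D:
    """The transform equivalent to applying ``first`` then ``second``."""
    r2 = second.matrix
    v1 = np.asarray(first.pivot)
    v2 = np.asarray(second.pivot)
    t1 = np.asarray(first.translation)
    t2 = np.asarray(second.translation)
    t_tot = r2 @ (v1 + t1 - v2) + v2 + t2 - v1
    return RigidTransform2D(
        rotation=first.rotation + second.rotation,
        translation=tuple(t_tot),
        pivot=tuple(v1),
        rms=second.rms,
    )


def coarse_translate(
    reference: LocalizationTable,
    moving: LocalizationTable,
    bin_size: float = 5.0,
) -> RigidTransform2D:
    """Estimate the global translation mapping ``moving`` onto ``reference``.

    Both tables are rendered as 2D histograms on a common grid and
    cross-correlated; the correlation peak, refined to sub-bin precision by
    quadratic interpolation along each axis, gives the shift. Rotation is
    zero by contract. A correlation with no significant peak (e.g. disjoint
    fields) yields a warning and zero shift.
    """
    if len(reference) == 0 or len(moving) == 0:
        raise ValidationError("cannot align empty localization tables")
    if bin_size <= 0:
        raise ValidationError("bin_size must be > 0")
    ref = reference.coords()[:, :2]
    mov = moving.coords()[:, :2]
    if np.any(mov.min(axis=0) > ref.max(axis=0)) or np.any(
        mov.max(axis=0) < ref.min(axis=0)
    ):
        warnings.warn(
            "fields do not overlap; no correlation peak expected, returning zero shift"
        )
        return RigidTransform2D()
    lo = np.minimum(ref.min(axis=0), mov.min(axis=0)) - bin_size
    hi = np.maximum(ref.max(axis=0), mov.max(axis=0)) + bin_size
    nbins = np.maximum(np.ceil((hi - lo) / bin_size).astype(int), 1)
    edges = [lo[d] + bin_size * np.arange(nbins[d] + 1) for d in range(2)]
    h_ref, _, _ = np.histogram2d(ref[:, 0], ref[:, 1], bins=edges)
    h_mov, _, _ = np.histogram2d(mov[:, 0], mov[:, 1], bins=edges)

    corr = signal.fftconvolve(h_ref, h_mov[::-1, ::-1], mode="full")
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    spread = corr.std()
    if spread == 0 or (corr[peak] - corr.mean()) / spread < 5.0:
        warnings.warn("no correlation peak above background; returning zero shift")
        return RigidTransform2D()

    shift = []
    for axis in range(2):
        p = peak[axis]
        centre = float(p)
        if 0 < p < corr.shape[axis] - 1:
            sl: list = list(peak)
            sl[axis] = slice(p - 1, p + 2)
            line = corr[tuple(sl)]
            denom = line[0] - 2.0 * line[1] + line[2]
            if denom != 0:
                centre += 0.5 * (line[0] - line[2]) / denom
        # displacement delta such that moving shifted by +delta bins matches
        # the reference; histograms share a grid so n_ref == n_mov
        shift.append((centre - (h_mov.shape[axis] - 1)) * bin_size)
    return RigidTransform2D(rotation=0.0, translation=(shift[0], shift[1]))


def match_fiducials(
    ref_points: np.ndarray,
    mov_points: np.ndarray,
    max_dist: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair fiducials by mutual nearest neighbour within ``max_dist`` nm.

    Ambiguous or unmatched fiducials are dropped with a warning. Returns the
    matched subsets in corresponding order.
    """
    ref = np.atleast_2d(np.asarray(ref_points, dtype=float))[:, :2]
    mov = np.atleast_2d(np.asarray(mov_points, dtype=float))[:, :2]
    if len(ref) == 0 or len(mov) == 0:
        return ref[:0], mov[:0]
    t_ref = cKDTree(ref)
    t_mov = cKDTree(mov)
    d_rm, j_rm = t_mov.query(ref, k=1, distance_upper_bound=max_dist)
    _, j_mr = t_ref.query(mov, k=1, distance_upper_bound=max_dist)
    pairs = [
        (i, j)
        for i, (d, j) in enumerate(zip(d_rm, j_rm))
        if np.isfinite(d) and j < len(mov) and j_mr[j] == i
    ]
    if len(pairs) < min(len(ref), len(mov)):
        warnings.warn(
            f"dropped {min(len(ref), len(mov)) - len(pairs)} ambiguous/unmatched fiducial(s)"
        )
    if not pairs:
        return ref[:0], mov[:0]
    ri, mi = map(np.asarray, zip(*pairs))
    return ref[ri], mov[mi]


def rigid_refine(
    fiducials_ref: np.ndarray,
    fiducials_mov: np.ndarray,
    pivot: tuple[float, float] | None = None,
) -> RigidTransform2D:
    """Least-squares rigid transform mapping moving fiducials onto reference.

    Solves the 2D orthogonal Procrustes problem without scaling via SVD
    (Kabsch). ``pivot`` defaults to the moving-fiducial centroid, which
    decouples the rotation and translation estimates. The RMS residual after
    alignment is stored on the returned transform.
    """
    ref = np.atleast_2d(np.asarray(fiducials_ref, dtype=float))[:, :2]
    mov = np.atleast_2d(np.asarray(fiducials_mov, dtype=float))[:, :2]
    if ref.shape != mov.shape or len(ref) < 2:
        raise ValidationError("need >= 2 corresponding fiducial pairs")
    c_ref = ref.mean(axis=0)
    c_mov = mov.mean(axis=0)
    a = mov - c_mov
    b = ref - c_ref
    sv = np.linalg.svd(a, compute_uv=False)
    if sv[0] == 0 or sv[1] / sv[0] < 1e-9:
        warnings.warn("fiducials are (near-)collinear; rotation poorly conditioned")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T)) or 1.0
    rot = vt.T @ np.diag([1.0, d]) @ u.T
    angle = math.atan2(rot[1, 0], rot[0, 0])
    piv = tuple(c_mov) if pivot is None else tuple(pivot)
    piv_a = np.asarray(piv)
    t_vec = c_ref - (rot @ (c_mov - piv_a) + piv_a)
    out = RigidTransform2D(rotation=angle, translation=tuple(t_vec), pivot=piv)
    resid = out.apply(mov) - ref
    out.rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return out


def apply_transform(table: LocalizationTable, t: RigidTransform2D) -> LocalizationTable:
    """Return a new table with transformed x/y; frame, lp, z, channel are
    untouched and pairwise distances are preserved (rigidity)."""
    locs = table.locs.copy()
    xy = t.apply(locs[["x", "y"]].to_numpy(float))
    locs["x"] = xy[:, 0]
    locs["y"] = xy[:, 1]
    return LocalizationTable(locs, table.meta)


def align_rounds(
    tables: list[LocalizationTable],
    fiducials: list[np.ndarray] | None = None,
    bin_size: float = 5.0,
    max_match_dist: float = 50.0,
) -> tuple[list[LocalizationTable], list[RigidTransform2D]]:
    """Align every round onto the first (reference) round.

    Each moving round is first coarse-translated by histogram
    cross-correlation; when per-round fiducial coordinate lists are given,
    the transform is refined rigidly from mutually matched fiducials.
    Returns the aligned tables and the total per-round transforms (identity
    for the reference round).
    """
    if not tables:
        return [], []
    aligned = [tables[0]]
    transforms = [RigidTransform2D()]
    ref_fid = np.asarray(fiducials[0], dtype=float) if fiducials else None
    for i, tab in enumerate(tables[1:], start=1):
        coarse = coarse_translate(tables[0], tab, bin_size=bin_size)
        total = coarse
        if ref_fid is not None and len(ref_fid) >= 2:
            mov_fid = coarse.apply(np.asarray(fiducials[i], dtype=float)[:, :2])
            mref, mmov = match_fiducials(ref_fid, mov_fid, max_match_dist)
            if len(mref) >= 2:
                fine = rigid_refine(mref, mmov)
                total = compose(fine, coarse)
        aligned.append(apply_transform(tab, total))
        transforms.append(total)
    return aligned, transforms
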