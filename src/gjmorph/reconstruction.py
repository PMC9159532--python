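"""Reconstruction of gap-junction plaques from bead detections.

Detections are grouped into plaques by single-linkage clustering in 3D
physical coordinates, then each plaque slice is reduced to an ordered
structure: a smooth midline through the mixed two-string point cloud, a
side label (A/B, the two apposed membranes) for every bead from the sign
of its perpendicular offset, per-side polylines through the bead centroids
in arc order, and a closed polygon between the two polylines whose area is
the per-plane intercellular surface.

The midline fit orders beads by projection onto the cloud's principal
axis and smooths the ordered points with a centred moving average; because
the two strings interleave along the arc, the average runs between them.
For strongly curved (folded) plaques where principal-axis ordering breaks
down, the ordering falls back to the diameter path of the points' minimum
spanning tree.  When docked bead pairs can be identified, the midline is
refitted through pair midpoints, which keeps it centred across orphan
(single-strand) intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, connected_components, minimum_spanning_tree
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

__all__ = [
    "PlaqueCluster",
    "Midline",
    "PlaneProfile",
    "InnerSpaceSegment",
    "PlaqueReconstruction",
    "cluster_plaques",
    "fit_midline",
    "assign_sides",
    "fit_side_polylines",
    "segment_inner_space",
    "reconstruct_plaque",
    "reconstruct",
    "polyline_length",
]

logger = logging.getLogger(__name__)

MIN_BEADS_PER_PROFILE = 4
AMBIGUOUS_OFFSET_NM = 2.0


@dataclass
class PlaqueCluster:
    """One plaque candidate: detections linked across slices."""

    plaque_id: int
    detections: pd.DataFrame  # detection rows, all slices
    extent_nm: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.detections.x_nm.mean()), float(self.detections.y_nm.mean())


def cluster_plaques(
    detections: pd.DataFrame,
    dz_nm: float = 50.0,
    link_distance_nm: float = 150.0,
    min_beads: int = 6,
) -> list[PlaqueCluster]:
    """Single-linkage connected components under 3D physical distance.

    z is the slice index scaled by the section thickness.  Components with
    fewer than ``min_beads`` members are discarded.  Cluster ids are
    assigned in a stable spatial order (first slice, then centroid y, x).
    """
    if len(detections) == 0:
        return []
    det = detections.reset_index(drop=True)
    coords = np.column_stack(
        [det.x_nm.to_numpy(), det.y_nm.to_numpy(), det["slice"].to_numpy() * dz_nm]
    )
    tree = cKDTree(coords)
    pairs = tree.query_pairs(link_distance_nm, output_type="ndarray")
    n = len(det)
    if len(pairs):
        adj = csr_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        adj = csr_matrix((n, n))
    _, labels = connected_components(adj, directed=False)
    clusters = []
    for lab in np.unique(labels):
        members = det[labels == lab]
        if len(members) < min_beads:
            continue
        clusters.append(members)
    clusters.sort(
        key=lambda m: (int(m["slice"].min()), float(m.y_nm.mean()), float(m.x_nm.mean()))
    )
    out = []
    for i, members in enumerate(clusters):
        out.append(
            PlaqueCluster(
                plaque_id=i,
                detections=members.reset_index(drop=True),
                extent_nm=(
                    float(members.x_nm.min()),
                    float(members.x_nm.max()),
                    float(members.y_nm.min()),
                    float(members.y_nm.max()),
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# midline fitting
# ---------------------------------------------------------------------------

@dataclass
class Midline:
    """Arc-parameterised polyline: vertices ``pts`` at arc positions ``s``."""

    pts: np.ndarray  # (M, 2) nm
    s: np.ndarray  # (M,) nm, strictly increasing from 0

    @property
    def length_nm(self) -> float:
        return float(self.s[-1])

    def flipped(self) -> "Midline":
        return Midline(pts=self.pts[::-1].copy(), s=self.s[-1] - self.s[::-1])


def polyline_length(pts: np.ndarray) -> float:
    pts = np.asarray(pts, float)
    if len(pts) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _principal_axis(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Unit principal axis of a 2D cloud and the eigenvalue ratio l2/l1."""
    centred = points - points.mean(axis=0)
    cov = centred.T @ centred / max(len(points) - 1, 1)
    w, v = np.linalg.eigh(cov)
    axis = v[:, -1]
    ratio = float(w[0] / w[1]) if w[1] > 0 else 0.0
    return axis, ratio


def _mst_path_order(points: np.ndarray) -> np.ndarray:
    """Order points along the diameter path of their Euclidean MST.

    Robust for folded (U- or C-shaped) clouds where projection onto a
    single axis is not monotone along the structure.
    """
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    mst = minimum_spanning_tree(csr_matrix(d)).toarray()
    mst = mst + mst.T
    graph = csr_matrix(mst)

    def farthest(start: int) -> int:
        order, _ = breadth_first_order(graph, start, directed=False)
        return int(order[-1])

    a = farthest(0)
    b = farthest(a)
    # path from a to b via predecessors
    order, preds = breadth_first_order(graph, a, directed=False, return_predecessors=True)
    path = [b]
    while path[-1] != a:
        path.append(int(preds[path[-1]]))
    path = path[::-1]
    # park every off-path point at its nearest path vertex
    path_idx = {p: i for i, p in enumerate(path)}
    rank = np.empty(n)
    sub = np.empty(n)
    for i in range(n):
        if i in path_idx:
            rank[i] = path_idx[i]
            sub[i] = 0.0
        else:
            nearest = int(np.argmin([d[i, p] for p in path]))
            rank[i] = nearest
            sub[i] = d[i, path[nearest]]
    return np.lexsort((sub, rank))


# eigenvalue-ratio trigger for the spanning-tree ordering fallback: folded
# (U- or C-shaped) clouds have a fat second principal component, while
# near-straight undulating plaques stay well below 0.05
_CURVED_EIGRATIO = 0.1


def fit_midline(
    points: np.ndarray,
    smooth_window: int | None = None,
    resample_step_nm: float = 5.0,
    end_extension_nm: float = 150.0,
) -> Midline | None:
    """Fit a smooth arc-parameterised midline through an unordered cloud.

    The smoothed curve is extrapolated tangentially by
    ``end_extension_nm`` at both termini so that beads at the physical
    ends of the structure project perpendicularly instead of clamping to
    the curve's endpoints (a centred moving average shrinks the ends by
    about half the smoothing window).

    Returns None (with a logged warning) for fewer than 4 points, which is
    too few to define a two-string profile.
    """
    points = np.asarray(points, float)
    if len(points) < MIN_BEADS_PER_PROFILE:
        logger.warning(
            "midline fit skipped: %d bead(s) < %d required", len(points),
            MIN_BEADS_PER_PROFILE,
        )
        return None
    axis, eigratio = _principal_axis(points)
    if eigratio > _CURVED_EIGRATIO:
        order = _mst_path_order(points)
    else:
        t = points @ axis
        order = np.argsort(t, kind="stable")
    ordered = points[order]

    n = len(ordered)
    if smooth_window is None:
        smooth_window = int(np.clip(n // 6, 5, 15)) | 1
    sm = (
        pd.DataFrame(ordered)
        .rolling(smooth_window, center=True, min_periods=max(2, smooth_window // 3))
        .mean()
        .to_numpy()
    )
    # collapse near-duplicate consecutive vertices
    keep = np.r_[True, np.linalg.norm(np.diff(sm, axis=0), axis=1) > 1e-9]
    sm = sm[keep]
    if len(sm) < 2:
        logger.warning("midline fit degenerate: smoothed curve collapsed to a point")
        return None
    if end_extension_nm > 0:
        t0 = sm[0] - sm[1]
        t1 = sm[-1] - sm[-2]
        t0 = t0 / np.linalg.norm(t0)
        t1 = t1 / np.linalg.norm(t1)
        sm = np.vstack([sm[0] + end_extension_nm * t0, sm,
                        sm[-1] + end_extension_nm * t1])
    s_raw = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(sm, axis=0), axis=1))]
    total = s_raw[-1]
    m = max(2, int(round(total / resample_step_nm)) + 1)
    s = np.linspace(0.0, total, m)
    pts = np.column_stack(
        [np.interp(s, s_raw, sm[:, 0]), np.interp(s, s_raw, sm[:, 1])]
    )
    return Midline(pts=pts, s=s)


def orient_midline(midline: Midline, direction: np.ndarray) -> Midline:
    """Flip the midline if its end-to-end vector opposes ``direction``."""
    v = midline.pts[-1] - midline.pts[0]
    if float(v @ direction) < 0:
        return midline.flipped()
    return midline


# ---------------------------------------------------------------------------
# side assignment
# ---------------------------------------------------------------------------

def _project_to_polyline(points: np.ndarray, midline: Midline):
    """Arc position and signed offset of each point w.r.t. the midline.

    The sign is the z-component of tangent x (point - foot); positive
    offsets are side A under the package's orientation convention.
    """
    P = midline.pts
    seg = np.diff(P, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    ok = seg_len > 0
    seg_dir = np.zeros_like(seg)
    seg_dir[ok] = seg[ok] / seg_len[ok, None]
    s_arc = np.zeros(len(points))
    offset = np.zeros(len(points))
    for i, p in enumerate(points):
        rel = p - P[:-1]
        t = np.einsum("ij,ij->i", rel, seg_dir)
        t = np.clip(t, 0.0, seg_len)
        foot = P[:-1] + t[:, None] * seg_dir
        d2 = np.einsum("ij,ij->i", p - foot, p - foot)
        j = int(np.argmin(d2))
        s_arc[i] = midline.s[j] + t[j]
        dvec = p - foot[j]
        offset[i] = seg_dir[j, 0] * dvec[1] - seg_dir[j, 1] * dvec[0]
    return s_arc, offset


def assign_sides(
    beads: pd.DataFrame, midline: Midline,
    ambiguous_offset_nm: float = AMBIGUOUS_OFFSET_NM,
) -> pd.DataFrame:
    """Assign each bead to membrane side A or B with its arc position.

    Side is the sign of the perpendicular offset from the midline (A =
    positive normal side).  Beads at near-zero offset are assigned by a
    nearest-neighbour vote among unambiguous beads and flagged.
    """
    pts = beads[["x_nm", "y_nm"]].to_numpy()
    s_arc, offset = _project_to_polyline(pts, midline)
    side = np.where(offset >= 0, "A", "B")
    ambiguous = np.abs(offset) < ambiguous_offset_nm
    if ambiguous.any() and (~ambiguous).any():
        clear_pts = pts[~ambiguous]
        clear_sides = side[~ambiguous]
        tree = cKDTree(clear_pts)
        k = min(3, len(clear_pts))
        _, nn = tree.query(pts[ambiguous], k=k)
        nn = np.atleast_2d(nn)
        if nn.ndim == 1:
            nn = nn[:, None]
        votes = clear_sides[nn]
        side[np.nonzero(ambiguous)[0]] = [
            "A" if (row == "A").sum() * 2 >= len(row) else "B" for row in votes
        ]
    out = beads.copy().reset_index(drop=True)
    out["side"] = side
    out["s_nm"] = s_arc
    out["offset_nm"] = offset
    out["ambiguous"] = ambiguous
    return out


def fit_side_polylines(assigned: pd.DataFrame) -> dict[str, pd.DataFrame | None]:
    """Per-side polylines through bead centroids in arc order.

    A side with fewer than 2 beads contributes no polyline (the slice is
    then not measurable for area but remains hemiplaque evidence).
    """
    out: dict[str, pd.DataFrame | None] = {}
    for side in ("A", "B"):
        sub = assigned[assigned.side == side].sort_values(
            ["s_nm", "x_nm", "y_nm"], kind="stable"
        )
        out[side] = sub[["s_nm", "x_nm", "y_nm"]].reset_index(drop=True) if len(sub) >= 2 else None
    return out


# ---------------------------------------------------------------------------
# plane profile and inner-space segmentation
# ---------------------------------------------------------------------------

@dataclass
class PlaneProfile:
    """Reconstruction of one plaque in one slice."""

    plaque_id: int
    slice: int
    midline: Midline
    sides: dict[str, pd.DataFrame | None]
    assignments: pd.DataFrame

    @property
    def overlap_nm(self) -> tuple[float, float] | None:
        """Common arc interval covered by both side polylines."""
        a, b = self.sides.get("A"), self.sides.get("B")
        if a is None or b is None:
            return None
        lo = max(a.s_nm.min(), b.s_nm.min())
        hi = min(a.s_nm.max(), b.s_nm.max())
        return (float(lo), float(hi)) if hi > lo else None

    def side_point_at(self, side: str, s) -> np.ndarray:
        poly = self.sides[side]
        s = np.atleast_1d(np.asarray(s, float))
        x = np.interp(s, poly.s_nm, poly.x_nm)
        y = np.interp(s, poly.s_nm, poly.y_nm)
        return np.column_stack([x, y])


@dataclass
class InnerSpaceSegment:
    """Closed contour between the two side polylines and its area."""

    plaque_id: int
    slice: int
    polygon: np.ndarray  # (V, 2) closed ring (first point not repeated)
    area_nm2: float
    s_lo_nm: float
    s_hi_nm: float
    repaired: bool = False


def segment_inner_space(profile: PlaneProfile) -> InnerSpaceSegment | None:
    """Polygonise the intercellular space of one plane.

    Both side polylines are trimmed to their common arc interval, the ring
    is closed by straight end caps, and the area is the polygon area
    (shoelace).  A self-intersecting ring is repaired by taking the
    largest simple component and flagged.
    """
    ov = profile.overlap_nm
    if ov is None:
        return None
    s_lo, s_hi = ov
    a = profile.sides["A"]
    b = profile.sides["B"]

    def trimmed(poly: pd.DataFrame) -> np.ndarray:
        inside = poly[(poly.s_nm > s_lo) & (poly.s_nm < s_hi)]
        lo_pt = profile.side_point_at("A" if poly is a else "B", [s_lo])[0]
        hi_pt = profile.side_point_at("A" if poly is a else "B", [s_hi])[0]
        pts = np.vstack([lo_pt, inside[["x_nm", "y_nm"]].to_numpy(), hi_pt])
        return pts

    ring = np.vstack([trimmed(a), trimmed(b)[::-1]])
    poly = Polygon(ring)
    repaired = False
    if not poly.is_valid:
        fixed = poly.buffer(0)
        if fixed.is_empty:
            return None
        if fixed.geom_type == "MultiPolygon":
            fixed = max(fixed.geoms, key=lambda p: p.area)
        poly = fixed
        repaired = True
        logger.warning(
            "plaque %d slice %d: self-intersecting inner-space ring repaired",
            profile.plaque_id, profile.slice,
        )
    return InnerSpaceSegment(
        plaque_id=profile.plaque_id,
        slice=profile.slice,
        polygon=np.asarray(poly.exterior.coords)[:-1],
        area_nm2=float(poly.area),
        s_lo_nm=s_lo,
        s_hi_nm=s_hi,
        repaired=repaired,
    )


# ---------------------------------------------------------------------------
# per-plaque reconstruction
# ---------------------------------------------------------------------------

@dataclass
class PlaqueReconstruction:
    """All per-slice profiles of one plaque."""

    plaque_id: int
    cluster: PlaqueCluster
    profiles: list[PlaneProfile] = field(default_factory=list)

    @property
    def slices(self) -> list[int]:
        return [p.slice for p in self.profiles]


def _mutual_arc_pairs(sa: np.ndarray, sb: np.ndarray, tol: float):
    """Indices of mutually nearest (by arc position) A/B couples within tol."""
    if len(sa) == 0 or len(sb) == 0:
        return np.empty((0, 2), dtype=int)
    nb = np.abs(sa[:, None] - sb[None, :]).argmin(axis=1)
    na = np.abs(sb[:, None] - sa[None, :]).argmin(axis=1)
    pairs = [
        (i, nb[i])
        for i in range(len(sa))
        if na[nb[i]] == i and abs(sa[i] - sb[nb[i]]) <= tol
    ]
    return np.array(pairs, dtype=int).reshape(-1, 2)


def _refine_midline_from_pairs(
    assigned: pd.DataFrame, midline: Midline
) -> Midline:
    """Refit the midline through docked-pair midpoints when available.

    Pair midpoints sit exactly between the membranes, so this pass removes
    the bias a plain moving average acquires over single-strand (orphan)
    intervals.  Falls back to the input midline when too few pairs exist.
    """
    a = assigned[assigned.side == "A"].sort_values("s_nm")
    b = assigned[assigned.side == "B"].sort_values("s_nm")
    if len(a) < 2 or len(b) < 2:
        return midline
    spacing = np.median(np.diff(np.sort(assigned.s_nm.unique())))
    tol = max(3.0 * spacing, 10.0)
    pairs = _mutual_arc_pairs(a.s_nm.to_numpy(), b.s_nm.to_numpy(), tol)
    if len(pairs) < MIN_BEADS_PER_PROFILE:
        return midline
    mid_pts = 0.5 * (
        a.iloc[pairs[:, 0]][["x_nm", "y_nm"]].to_numpy()
        + b.iloc[pairs[:, 1]][["x_nm", "y_nm"]].to_numpy()
    )
    refined = fit_midline(mid_pts, smooth_window=3)
    if refined is None:
        return midline
    return orient_midline(refined, midline.pts[-1] - midline.pts[0])


def reconstruct_plaque(
    cluster: PlaqueCluster,
    refine_from_pairs: bool = True,
) -> PlaqueReconstruction:
    """Build per-slice profiles (midline, sides, polylines) for a cluster.

    Slices with fewer than 4 beads are skipped with a warning.  Midlines
    of all slices are oriented along the cluster's global principal axis so
    side labels are consistent across slices.
    """
    det = cluster.detections
    global_axis, _ = _principal_axis(det[["x_nm", "y_nm"]].to_numpy())
    # fix a deterministic sign for the global axis
    if abs(global_axis[0]) >= abs(global_axis[1]):
        if global_axis[0] < 0:
            global_axis = -global_axis
    elif global_axis[1] < 0:
        global_axis = -global_axis
    recon = PlaqueReconstruction(plaque_id=cluster.plaque_id, cluster=cluster)
    for k in sorted(det["slice"].unique()):
        beads = det[det["slice"] == k].reset_index(drop=True)
        if len(beads) < MIN_BEADS_PER_PROFILE:
            logger.warning(
                "plaque %d slice %d skipped: %d bead(s) < %d",
                cluster.plaque_id, k, len(beads), MIN_BEADS_PER_PROFILE,
            )
            continue
        midline = fit_midline(beads[["x_nm", "y_nm"]].to_numpy())
        if midline is None:
            continue
        midline = orient_midline(midline, global_axis)
        assigned = assign_sides(beads, midline)
        if refine_from_pairs:
            refined = _refine_midline_from_pairs(assigned, midline)
            if refined is not midline:
                midline = orient_midline(refined, global_axis)
                assigned = assign_sides(beads, midline)
        sides = fit_side_polylines(assigned)
        recon.profiles.append(
            PlaneProfile(
                plaque_id=cluster.plaque_id, slice=int(k), midline=midline,
                sides=sides, assignments=assigned,
            )
        )
    return recon


def reconstruct(
    detections: pd.DataFrame,
    dz_nm: float = 50.0,
    link_distance_nm: float = 150.0,
    min_beads: int = 6,
    refine_from_pairs: bool = True,
) -> list[PlaqueReconstruction]:
    """Cluster detections and reconstruct every plaque."""
    clusters = cluster_plaques(
        detections, dz_nm=dz_nm, link_distance_nm=link_distance_nm, min_beads=min_beads
    )
    return [reconstruct_plaque(c, refine_from_pairs=refine_from_pairs) for c in clusters]


def reconstruction_to_dict(recons: list[PlaqueReconstruction]) -> dict:
    """JSON-serialisable representation of a reconstruction."""
    out = {"plaques": []}
    for r in recons:
        entry = {"plaque_id": r.plaque_id, "slices": []}
        for p in r.profiles:
            entry["slices"].append(
                {
                    "slice": p.slice,
                    "midline": p.midline.pts.tolist(),
                    "midline_s": p.midline.s.tolist(),
                    "sides": {
                        s: (df[["s_nm", "x_nm", "y_nm"]].to_numpy().tolist()
                            if df is not None else None)
                        for s, df in p.sides.items()
                    },
                    "beads": p.assignments[
                        ["x_nm", "y_nm", "side", "s_nm", "offset_nm", "ambiguous"]
                    ].to_dict(orient="list"),
                }
            )
        out["plaques"].append(entry)
    return out
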