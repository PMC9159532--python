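"""Per-plane and per-plaque morphometrics and hemiplaque calling.

Metrics mirror the measurements made on gap-junction plaques in volume EM:

* per plane: plaque length (midline arc over the interval covered by both
  bead strings), intercellular area between the strings, and the ratio
  area / length (units reduce to nm -- the mean gap width);
* per plaque: the unweighted mean of per-plane ratios, the maximal width
  between the membranes anywhere in the structure (sampled perpendicular
  to the midline at <= 5 nm arc steps), the total plaque length (sum of
  per-plane lengths);
* hemiplaques: arc intervals where one membrane carries a consecutive run
  of beads without opposing partners.  Beads are paired across sides by
  mutual-nearest arc position (tolerance scaled to the bead spacing);
  runs of >= 3 consecutive unpaired beads spanning >= 100 nm are called as
  hemiplaque segments, the run span extended by half a bead spacing at
  each end.  Both run thresholds are parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reconstruction import (
    PlaneProfile,
    InnerSpaceSegment,
    PlaqueReconstruction,
    segment_inner_space,
)

__all__ = [
    "MorphometricsRecord",
    "BeadPairing",
    "plane_metrics",
    "plaque_summary",
    "pair_beads",
    "call_hemiplaques",
    "measure_plaque",
    "measure",
    "cohort_hemiplaque_stats",
    "records_to_frame",
]

logger = logging.getLogger(__name__)

WIDTH_SAMPLING_STEP_NM = 5.0
DEFAULT_MIN_RUN_BEADS = 3
DEFAULT_MIN_RUN_LENGTH_NM = 100.0
DEFAULT_MAX_PAIR_GAP_NM = 120.0
PAIRING_TOL_SPACING_FACTOR = 0.6


@dataclass
class MorphometricsRecord:
    """All measurements of one plaque."""

    plaque_id: int
    plane_rows: pd.DataFrame  # slice, length_nm, area_nm2, area_per_length_nm
    avg_area_per_length_nm: float
    max_width_nm: float
    total_plaque_length_nm: float
    hemiplaque_segments: pd.DataFrame  # slice, start_nm, length_nm
    total_hemiplaque_length_nm: float
    hemiplaque_fraction_pct: float
    has_hemiplaque: bool
    labels: dict = field(default_factory=dict)

    @property
    def n_planes(self) -> int:
        return len(self.plane_rows)


@dataclass
class BeadPairing:
    """Docked-pair assignment for one plane."""

    slice: int
    pairs: pd.DataFrame  # index_a, index_b, s_a_nm, s_b_nm, distance_nm
    unpaired: pd.DataFrame  # side, index, s_nm


def plane_metrics(
    profile: PlaneProfile, segment: InnerSpaceSegment | None
) -> dict | None:
    """Per-plane row (length, area, area/length); None when unmeasurable."""
    if segment is None:
        logger.warning(
            "plaque %d slice %d: no two-sided overlap, plane skipped",
            profile.plaque_id, profile.slice,
        )
        return None
    length = segment.s_hi_nm - segment.s_lo_nm
    if length <= 0:
        logger.warning(
            "plaque %d slice %d: zero-length overlap, plane skipped",
            profile.plaque_id, profile.slice,
        )
        return None
    return {
        "slice": profile.slice,
        "length_nm": float(length),
        "area_nm2": float(segment.area_nm2),
        "area_per_length_nm": float(segment.area_nm2 / length),
    }


def profile_max_width(
    profile: PlaneProfile, step_nm: float = WIDTH_SAMPLING_STEP_NM
) -> float:
    """Maximum inter-polyline width of one plane, sampled along the arc."""
    ov = profile.overlap_nm
    if ov is None:
        return 0.0
    s_lo, s_hi = ov
    n = max(2, int(np.ceil((s_hi - s_lo) / step_nm)) + 1)
    s = np.linspace(s_lo, s_hi, n)
    pa = profile.side_point_at("A", s)
    pb = profile.side_point_at("B", s)
    return float(np.linalg.norm(pa - pb, axis=1).max())


def plaque_summary(
    rows: list[dict], widths: list[float]
) -> tuple[float, float, float]:
    """Per-plaque aggregation of plane rows.

    Returns (avg area per length = unweighted mean of per-plane ratios,
    max width = maximum over planes, total length = sum of plane lengths).
    """
    if not rows:
        raise ValueError("plaque summary requires at least one valid plane row")
    ratios = [r["area_per_length_nm"] for r in rows]
    total = sum(r["length_nm"] for r in rows)
    return float(np.mean(ratios)), float(max(widths) if widths else 0.0), float(total)


def _median_spacing(s_sorted: np.ndarray) -> float:
    d = np.diff(s_sorted)
    d = d[d > 0]
    return float(np.median(d)) if len(d) else 0.0


def pair_beads(
    profile: PlaneProfile,
    pairing_arc_tol_nm: float | None = None,
    max_gap_nm: float = DEFAULT_MAX_PAIR_GAP_NM,
) -> BeadPairing:
    """Mutual-nearest pairing of beads across the two sides of one plane.

    A and B beads are matched by arc position; a couple is accepted when
    each is the other's nearest opposite-side bead, their arc positions
    differ by at most ``pairing_arc_tol_nm`` (default 0.6 x the median
    bead spacing of the plane) and their Euclidean separation is at most
    ``max_gap_nm``.  All remaining beads are unpaired.
    """
    asg = profile.assignments.reset_index(drop=True)
    a = asg[asg.side == "A"].sort_values("s_nm", kind="stable")
    b = asg[asg.side == "B"].sort_values("s_nm", kind="stable")
    if pairing_arc_tol_nm is None:
        spacing = _median_spacing(np.sort(asg.s_nm.to_numpy()))
        # the all-bead ordering interleaves the two strings, so the pair
        # spacing is ~2x the consecutive-arc spacing
        pairing_arc_tol_nm = PAIRING_TOL_SPACING_FACTOR * 2.0 * spacing
        if pairing_arc_tol_nm <= 0:
            pairing_arc_tol_nm = max_gap_nm
    pairs_rows = []
    used_a: set = set()
    used_b: set = set()
    if len(a) and len(b):
        sa = a.s_nm.to_numpy()
        sb = b.s_nm.to_numpy()
        nb = np.abs(sa[:, None] - sb[None, :]).argmin(axis=1)
        na = np.abs(sb[:, None] - sa[None, :]).argmin(axis=1)
        for i in range(len(sa)):
            j = nb[i]
            if na[j] != i or abs(sa[i] - sb[j]) > pairing_arc_tol_nm:
                continue
            pa = a.iloc[i][["x_nm", "y_nm"]].to_numpy(dtype=float)
            pb = b.iloc[j][["x_nm", "y_nm"]].to_numpy(dtype=float)
            dist = float(np.linalg.norm(pa - pb))
            if dist > max_gap_nm:
                continue
            pairs_rows.append(
                {
                    "index_a": int(a.index[i]),
                    "index_b": int(b.index[j]),
                    "s_a_nm": float(sa[i]),
                    "s_b_nm": float(sb[j]),
                    "distance_nm": dist,
                }
            )
            used_a.add(int(a.index[i]))
            used_b.add(int(b.index[j]))
    unpaired_rows = [
        {"side": row.side, "index": int(idx), "s_nm": float(row.s_nm)}
        for idx, row in asg.iterrows()
        if (row.side == "A" and idx not in used_a)
        or (row.side == "B" and idx not in used_b)
    ]
    return BeadPairing(
        slice=profile.slice,
        pairs=pd.DataFrame(
            pairs_rows, columns=["index_a", "index_b", "s_a_nm", "s_b_nm", "distance_nm"]
        ),
        unpaired=pd.DataFrame(unpaired_rows, columns=["side", "index", "s_nm"]),
    )


def call_hemiplaques(
    pairings: list[BeadPairing],
    profiles: list[PlaneProfile],
    min_run_beads: int = DEFAULT_MIN_RUN_BEADS,
    min_run_length_nm: float = DEFAULT_MIN_RUN_LENGTH_NM,
) -> pd.DataFrame:
    """Call hemiplaque segments from per-plane pairings.

    Within each plane and side, beads in arc order are scanned for maximal
    runs of consecutive unpaired beads; runs with at least
    ``min_run_beads`` members spanning at least ``min_run_length_nm`` are
    emitted as segments whose length is the run span extended by half a
    bead spacing at each end.
    """
    by_slice = {p.slice: p for p in profiles}
    segments = []
    for pairing in pairings:
        profile = by_slice.get(pairing.slice)
        if profile is None:
            continue
        asg = profile.assignments.reset_index(drop=True)
        unpaired_idx = set(pairing.unpaired["index"].tolist())
        for side in ("A", "B"):
            sub = asg[asg.side == side].sort_values("s_nm", kind="stable")
            if len(sub) == 0:
                continue
            spacing = _median_spacing(sub.s_nm.to_numpy())
            run: list[float] = []
            runs: list[list[float]] = []
            for idx, row in sub.iterrows():
                if idx in unpaired_idx:
                    run.append(float(row.s_nm))
                else:
                    if run:
                        runs.append(run)
                    run = []
            if run:
                runs.append(run)
            for r in runs:
                span = r[-1] - r[0]
                if len(r) < min_run_beads or span < min_run_length_nm:
                    continue
                ext = spacing / 2.0
                segments.append(
                    {
                        "slice": pairing.slice,
                        "side": side,
                        "start_nm": r[0] - ext,
                        "length_nm": span + 2 * ext,
                        "n_beads": len(r),
                    }
                )
    return pd.DataFrame(
        segments, columns=["slice", "side", "start_nm", "length_nm", "n_beads"]
    )


def measure_plaque(
    recon: PlaqueReconstruction,
    pairing_arc_tol_nm: float | None = None,
    max_gap_nm: float = DEFAULT_MAX_PAIR_GAP_NM,
    min_run_beads: int = DEFAULT_MIN_RUN_BEADS,
    min_run_length_nm: float = DEFAULT_MIN_RUN_LENGTH_NM,
    labels: dict | None = None,
) -> MorphometricsRecord | None:
    """Full morphometrics of one reconstructed plaque.

    Returns None when no plane could be measured.
    """
    rows: list[dict] = []
    widths: list[float] = []
    pairings: list[BeadPairing] = []
    plane_lengths: dict[int, float] = {}
    for profile in recon.profiles:
        segment = segment_inner_space(profile)
        row = plane_metrics(profile, segment)
        pairings.append(
            pair_beads(profile, pairing_arc_tol_nm=pairing_arc_tol_nm,
                       max_gap_nm=max_gap_nm)
        )
        if row is not None:
            rows.append(row)
            widths.append(profile_max_width(profile))
            plane_lengths[profile.slice] = row["length_nm"]
    if not rows:
        logger.warning("plaque %d: no measurable plane", recon.plaque_id)
        return None
    avg_apl, max_width, total_len = plaque_summary(rows, widths)
    segs = call_hemiplaques(
        pairings, recon.profiles,
        min_run_beads=min_run_beads, min_run_length_nm=min_run_length_nm,
    )
    if len(segs):
        # a slice's hemiplaque total cannot exceed that slice's length
        capped = []
        for k, sub in segs.groupby("slice"):
            cap = plane_lengths.get(int(k))
            tot = sub.length_nm.sum()
            if cap is not None and tot > cap:
                sub = sub.assign(length_nm=sub.length_nm * cap / tot)
            capped.append(sub)
        segs = pd.concat(capped, ignore_index=True)
    total_hemi = float(segs.length_nm.sum()) if len(segs) else 0.0
    total_hemi = min(total_hemi, total_len)
    record = MorphometricsRecord(
        plaque_id=recon.plaque_id,
        plane_rows=pd.DataFrame(rows),
        avg_area_per_length_nm=avg_apl,
        max_width_nm=max_width,
        total_plaque_length_nm=total_len,
        hemiplaque_segments=segs,
        total_hemiplaque_length_nm=total_hemi,
        hemiplaque_fraction_pct=100.0 * total_hemi / total_len if total_len else 0.0,
        has_hemiplaque=total_hemi > 0,
        labels=dict(labels or {}),
    )
    return record


def measure(
    recons: list[PlaqueReconstruction],
    labels: dict | None = None,
    **kwargs,
) -> list[MorphometricsRecord]:
    """Measure every reconstructed plaque; unmeasurable ones are dropped."""
    out = []
    for r in recons:
        rec = measure_plaque(r, labels=labels, **kwargs)
        if rec is not None:
            out.append(rec)
    return out


def records_to_frame(records: list[MorphometricsRecord]) -> pd.DataFrame:
    """Per-plaque summary table (one row per plaque, labels as columns)."""
    rows = []
    for r in records:
        rows.append(
            {
                **r.labels,
                "plaque_id": r.plaque_id,
                "n_planes": r.n_planes,
                "avg_area_per_length_nm": r.avg_area_per_length_nm,
                "max_width_nm": r.max_width_nm,
                "total_plaque_length_nm": r.total_plaque_length_nm,
                "total_hemiplaque_length_nm": r.total_hemiplaque_length_nm,
                "hemiplaque_fraction_pct": r.hemiplaque_fraction_pct,
                "has_hemiplaque": r.has_hemiplaque,
            }
        )
    return pd.DataFrame(rows)


def plane_rows_frame(records: list[MorphometricsRecord]) -> pd.DataFrame:
    """Per-plane table across plaques (mirrors per-section analyses)."""
    frames = []
    for r in records:
        df = r.plane_rows.copy()
        df.insert(0, "plaque_id", r.plaque_id)
        for k, v in r.labels.items():
            df[k] = v
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def cohort_hemiplaque_stats(
    per_plaque: pd.DataFrame,
    group_cols: tuple[str, ...] = ("genotype", "ventricle"),
) -> pd.DataFrame:
    """Group-level hemiplaque statistics.

    Per group: the percentage of plaques with at least one hemiplaque,
    the pooled hemiplaque length, the pooled plaque length and the pooled
    length fraction (100 x sum(hemiplaque length) / sum(plaque length)).
    """
    group_cols = [c for c in group_cols if c in per_plaque.columns]
    if not group_cols:
        raise ValueError("no grouping columns present in the table")
    rows = []
    for key, sub in per_plaque.groupby(list(group_cols), sort=True):
        if len(sub) == 0:
            raise ValueError(f"empty group {key}")
        key = key if isinstance(key, tuple) else (key,)
        total_len = float(sub.total_plaque_length_nm.sum())
        total_hemi = float(sub.total_hemiplaque_length_nm.sum())
        rows.append(
            {
                **dict(zip(group_cols, key)),
                "n_plaques": len(sub),
                "pct_with_hemiplaque": 100.0 * float(sub.has_hemiplaque.mean()),
                "total_hemiplaque_length_nm": total_hemi,
                "total_plaque_length_nm": total_len,
                "pooled_length_fraction_pct": (
                    100.0 * total_hemi / total_len if total_len else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)
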