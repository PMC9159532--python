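"""Default study conditions: two-genotype synthetic cohorts.

Two morphologies are emulated:

* ``control_like`` -- gently undulating plaques with a constant ~20 nm
  inter-string gap and fully docked bead pairs (two parallel, closely
  packed strings of label);
* ``pkp2cko_like`` -- desmosome-deficient morphology: the gap bulges
  locally up to ~100 nm and each plaque carries an orphan run covering
  roughly 20% of its arc, i.e. an interval where one membrane's beads are
  absent (a hemiplaque).

Plaques are laid out four per region of interest (ROI) in separate
horizontal bands of a stack; each ROI carries a ventricle label (LV or
RV, alternating) so group comparisons can be stratified the way the
source experiments were.  All sizes are in nm; the default voxel geometry
is 3.5 nm laterally and 50 nm sections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import (
    Bulge,
    GroundTruth,
    OrphanRun,
    PlaqueSpec,
    generate_stack,
    generate_truth,
)
from .volume import EMStack, VoxelGeometry

__all__ = [
    "CohortCondition",
    "CONTROL_LIKE",
    "PKP2CKO_LIKE",
    "make_plaque_spec",
    "build_roi",
    "build_cohort",
    "tiny_fixture",
    "PLAQUES_PER_ROI",
]

PLAQUES_PER_ROI = 4
ROI_N_SLICES = 7
BAND_HEIGHT_NM = 910.0
ROI_MARGIN_NM = 150.0


@dataclass(frozen=True)
class CohortCondition:
    """Generator settings for one genotype-like group."""

    name: str
    gap_baseline_nm: float = 20.0
    bulge_amplitude_range_nm: tuple[float, float] = (0.0, 0.0)
    bulge_width_range_nm: tuple[float, float] = (150.0, 300.0)
    n_bulges: int = 0
    orphan_prob: float = 0.0
    orphan_arc_fraction: float = 0.20
    plaque_length_range_nm: tuple[float, float] = (1500.0, 2100.0)
    bead_spacing_nm: float = 25.0
    bead_spacing_jitter_nm: float = 3.0
    bead_contrast: float = 120.0
    undulation_sd_nm: float = 35.0


CONTROL_LIKE = CohortCondition(name="control_like")

PKP2CKO_LIKE = CohortCondition(
    name="pkp2cko_like",
    bulge_amplitude_range_nm=(60.0, 80.0),
    n_bulges=1,
    orphan_prob=1.0,
)


def make_plaque_spec(
    condition: CohortCondition,
    origin_xy_nm: tuple[float, float],
    band_halfwidth_nm: float,
    n_slices: int,
    rng: np.random.Generator,
    z_start: int = 0,
) -> PlaqueSpec:
    """Draw one plaque spec under a cohort condition.

    The midline runs mostly along x from ``origin_xy_nm`` with smooth y
    undulation confined to the ROI band.
    """
    length = float(rng.uniform(*condition.plaque_length_range_nm))
    n_ctrl = max(4, int(round(length / 300.0)) + 1)
    xs = origin_xy_nm[0] + np.linspace(0.0, length, n_ctrl)
    ys = origin_xy_nm[1] + np.cumsum(rng.normal(0.0, condition.undulation_sd_nm, n_ctrl))
    ys = np.clip(ys, origin_xy_nm[1] - band_halfwidth_nm, origin_xy_nm[1] + band_halfwidth_nm)
    ctrl = np.column_stack([xs, ys])

    bulges = []
    for _ in range(condition.n_bulges):
        amp = float(rng.uniform(*condition.bulge_amplitude_range_nm))
        if amp > 0:
            bulges.append(
                Bulge(
                    center_nm=float(rng.uniform(0.25 * length, 0.75 * length)),
                    amplitude_nm=amp,
                    width_nm=float(rng.uniform(*condition.bulge_width_range_nm)),
                )
            )
    orphan_runs = []
    if condition.orphan_prob > 0 and rng.uniform() < condition.orphan_prob:
        run_len = condition.orphan_arc_fraction * length
        start = float(rng.uniform(0.1 * length, 0.9 * length - run_len))
        side = "A" if rng.uniform() < 0.5 else "B"
        orphan_runs.append(OrphanRun(side=side, start_nm=start, length_nm=run_len))

    return PlaqueSpec(
        midline_control_points=ctrl,
        n_slices_spanned=int(rng.integers(max(3, n_slices - 2), n_slices + 1)),
        z_start=z_start,
        gap_baseline_nm=condition.gap_baseline_nm,
        bulges=bulges,
        bead_spacing_nm=condition.bead_spacing_nm,
        bead_spacing_jitter_nm=condition.bead_spacing_jitter_nm,
        orphan_runs=orphan_runs,
        bead_contrast=condition.bead_contrast,
    )


def _roi_geometry(condition: CohortCondition, n_plaques: int) -> VoxelGeometry:
    dx = 3.5
    width_nm = condition.plaque_length_range_nm[1] + 2 * (ROI_MARGIN_NM + 200.0)
    height_nm = n_plaques * BAND_HEIGHT_NM
    return VoxelGeometry(
        shape=(ROI_N_SLICES, int(np.ceil(height_nm / dx)), int(np.ceil(width_nm / dx))),
        dx_nm=dx, dy_nm=dx, dz_nm=50.0,
    )


def build_roi(
    condition: CohortCondition,
    seed: int,
    n_plaques: int = PLAQUES_PER_ROI,
    render: bool = True,
    noise_sd: float = 8.0,
) -> tuple[EMStack | None, GroundTruth]:
    """Generate one region of interest: ``n_plaques`` plaques in bands.

    With ``render=False`` only the ground truth (bead coordinates and gap
    profiles) is generated, which is much faster for large simulated
    cohorts.
    """
    geometry = _roi_geometry(condition, n_plaques)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF1E1D)))
    specs = []
    for i in range(n_plaques):
        band_center = (i + 0.5) * BAND_HEIGHT_NM
        origin_x = float(rng.uniform(ROI_MARGIN_NM + 100.0, ROI_MARGIN_NM + 300.0))
        origin_y = band_center + float(rng.normal(0.0, 40.0))
        specs.append(
            make_plaque_spec(
                condition,
                origin_xy_nm=(origin_x, origin_y),
                band_halfwidth_nm=BAND_HEIGHT_NM / 2 - 180.0,
                n_slices=ROI_N_SLICES,
                rng=rng,
            )
        )
    if render:
        stack, truth = generate_stack(specs, geometry, noise_sd=noise_sd, seed=seed)
    else:
        stack, truth = None, generate_truth(specs, geometry, seed=seed)
    truth.labels["condition"] = condition.name
    return stack, truth


def build_cohort(
    condition: CohortCondition,
    n_plaques: int,
    seed: int,
    render: bool = True,
) -> list[tuple[EMStack | None, GroundTruth]]:
    """Generate a cohort of plaques grouped into ROIs of four.

    ROIs alternate ventricle labels LV/RV (recorded in the ground-truth
    labels) so per-ventricle stratification can be exercised.
    """
    n_rois = int(np.ceil(n_plaques / PLAQUES_PER_ROI))
    out = []
    remaining = n_plaques
    for r in range(n_rois):
        n_here = min(PLAQUES_PER_ROI, remaining)
        remaining -= n_here
        stack, truth = build_roi(
            condition, seed=seed * 1000 + r, n_plaques=n_here, render=render
        )
        truth.labels.update(
            {"roi": r, "ventricle": "LV" if r % 2 == 0 else "RV",
             "genotype": condition.name}
        )
        out.append((stack, truth))
    return out


def tiny_fixture(seed: int = 0, render: bool = True):
    """One short plaque in a small 5-slice frame; runs end-to-end in seconds."""
    dx = 3.5
    geometry = VoxelGeometry(shape=(5, 200, 320), dx_nm=dx, dy_nm=dx, dz_nm=50.0)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x71217)))
    spec = make_plaque_spec(
        CohortCondition(name="tiny", plaque_length_range_nm=(750.0, 800.0),
                        undulation_sd_nm=20.0),
        origin_xy_nm=(150.0, 200.0 * dx / 2),
        band_halfwidth_nm=120.0,
        n_slices=5,
        rng=rng,
    )
    if render:
        stack, truth = generate_stack([spec], geometry, noise_sd=8.0, seed=seed)
    else:
        stack, truth = None, generate_truth([spec], geometry, seed=seed)
    truth.labels.update({"condition": "tiny", "genotype": "control_like",
                         "ventricle": "LV", "roi": 0})
    return stack, truth


def truth_per_plaque_frame(truths: list[GroundTruth]) -> pd.DataFrame:
    """Oracle per-plaque table across a cohort of ground truths."""
    from .morphometrics import records_to_frame
    from .synthetic import truth_metrics

    frames = []
    offset = 0
    for t in truths:
        records = truth_metrics(t)
        for rec in records:
            rec.labels = {
                "genotype": t.labels.get("genotype", t.labels.get("condition")),
                "ventricle": t.labels.get("ventricle"),
                "roi": t.labels.get("roi"),
            }
            rec.plaque_id += offset
        offset += len(records)
        frames.append(records_to_frame(records))
    return pd.concat(frames, ignore_index=True)
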