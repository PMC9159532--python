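import itertools

import numpy as np
import pandas as pd
import pytest

from gjmorph.evaluation import evaluate_cohorts
from gjmorph.fixtures import (
    CONTROL_LIKE,
    PKP2CKO_LIKE,
    CohortCondition,
    build_cohort,
    truth_per_plaque_frame,
)
from gjmorph.morphometrics import (
    call_hemiplaques,
    cohort_hemiplaque_stats,
    measure_plaque,
    pair_beads,
    plane_metrics,
    plaque_summary,
    profile_max_width,
)
from gjmorph.reconstruction import reconstruct, segment_inner_space

from test_reconstruction import make_profile


def straight_profile(n=40, gap=20.0, spacing=50.0, orphan=None):
    """Two opposed strings; ``orphan`` removes side-B beads on an s-interval."""
    x = np.arange(n) * spacing
    a = np.column_stack([x, np.full(n, 100.0 + gap / 2)])
    b = np.column_stack([x, np.full(n, 100.0 - gap / 2)])
    if orphan is not None:
        lo, hi = orphan
        keep = (b[:, 0] < lo) | (b[:, 0] > hi)
        b = b[keep]
    # build with equal-length lists then drop: make_profile needs pairs, so
    # construct manually instead
    from gjmorph.reconstruction import (
        Midline,
        PlaneProfile,
        assign_sides,
        fit_side_polylines,
    )

    mid = Midline(
        pts=np.column_stack([x, np.full(n, 100.0)]),
        s=np.r_[0.0, np.cumsum(np.diff(x))],
    )
    beads = pd.DataFrame({
        "slice": 0,
        "x_nm": np.r_[a[:, 0], b[:, 0]],
        "y_nm": np.r_[a[:, 1], b[:, 1]],
    })
    asg = assign_sides(beads, mid)
    return PlaneProfile(0, 0, mid, fit_side_polylines(asg), asg)


class TestPlaneMetrics:
    def test_rectangle_row(self):
        x = np.linspace(0, 1000, 21)
        a = np.column_stack([x, np.full_like(x, 110.0)])
        b = np.column_stack([x, np.full_like(x, 90.0)])
        prof = make_profile(a, b)
        seg = segment_inner_space(prof)
        row = plane_metrics(prof, seg)
        assert row["length_nm"] == pytest.approx(1000.0, rel=1e-6)
        assert row["area_nm2"] == pytest.approx(20_000.0, rel=1e-6)
        assert row["area_per_length_nm"] == pytest.approx(20.0, rel=1e-6)

    def test_trapezoid_area_per_length(self):
        x = np.linspace(0, 1000, 21)
        half = (20.0 + 20.0 * x / 1000.0) / 2
        prof = make_profile(
            np.column_stack([x, 100.0 + half]), np.column_stack([x, 100.0 - half])
        )
        row = plane_metrics(prof, segment_inner_space(prof))
        assert row["area_per_length_nm"] == pytest.approx(30.0, rel=1e-3)

    def test_missing_segment_skipped(self, caplog):
        prof = straight_profile()
        assert plane_metrics(prof, None) is None


class TestPlaqueSummary:
    def test_average_is_unweighted_mean(self):
        rows = [{"area_per_length_nm": r, "length_nm": 1000.0} for r in (20, 30, 40)]
        avg, width, total = plaque_summary(rows, [20.0, 25.0, 22.0])
        assert avg == pytest.approx(30.0)
        assert width == pytest.approx(25.0)
        assert total == pytest.approx(3000.0)

    def test_constant_gap_max_width_equals_gap(self):
        prof = straight_profile(gap=20.0)
        assert profile_max_width(prof) == pytest.approx(20.0, abs=1e-6)

    def test_empty_rows_rejected(self):
        with pytest.raises(ValueError):
            plaque_summary([], [])


def brute_force_mutual_pairs(sa, sb, tol):
    """Oracle: all mutual-nearest pairs by exhaustive search."""
    out = []
    for i, j in itertools.product(range(len(sa)), range(len(sb))):
        if (
            abs(sa[i] - sb[j]) <= tol
            and all(abs(sa[i] - sb[k]) >= abs(sa[i] - sb[j]) for k in range(len(sb)))
            and all(abs(sb[j] - sa[k]) >= abs(sa[i] - sb[j]) for k in range(len(sa)))
        ):
            out.append((i, j))
    return out


class TestPairBeads:
    def test_perfectly_opposed_strings_fully_paired(self):
        prof = straight_profile(n=30, gap=20.0, spacing=50.0)
        pairing = pair_beads(prof)
        assert len(pairing.pairs) == 30
        assert len(pairing.unpaired) == 0

    def test_orphan_interval_leaves_survivors_unpaired(self):
        prof = straight_profile(n=40, gap=20.0, spacing=50.0, orphan=(500.0, 800.0))
        pairing = pair_beads(prof)
        up = pairing.unpaired
        assert (up.side == "A").all()
        in_run = up[(up.s_nm >= 500.0) & (up.s_nm <= 800.0)]
        assert len(in_run) == len(up)
        assert len(up) == 7  # beads at 500, 550, ..., 800

    def test_matches_exhaustive_mutual_nearest(self):
        """4 vs 4 beads with one offset bead: greedy mutual-nearest equals
        the exhaustive-search mutual-nearest matching."""
        from gjmorph.reconstruction import Midline, PlaneProfile, assign_sides, fit_side_polylines

        sa = np.array([0.0, 50.0, 100.0, 150.0])
        sb = np.array([2.0, 48.0, 123.0, 151.0])
        x = np.linspace(-50, 250, 7)
        mid = Midline(pts=np.column_stack([x, np.zeros(7)]), s=x - x[0])
        beads = pd.DataFrame({
            "slice": 0,
            "x_nm": np.r_[sa, sb],
            "y_nm": np.r_[np.full(4, 10.0), np.full(4, -10.0)],
        })
        asg = assign_sides(beads, mid)
        prof = PlaneProfile(0, 0, mid, fit_side_polylines(asg), asg)
        tol = 15.0
        pairing = pair_beads(prof, pairing_arc_tol_nm=tol)
        got = {(r.s_a_nm, r.s_b_nm) for r in pairing.pairs.itertuples()}
        sa_sorted = np.sort(asg[asg.side == "A"].s_nm.to_numpy())
        sb_sorted = np.sort(asg[asg.side == "B"].s_nm.to_numpy())
        expected = {
            (sa_sorted[i], sb_sorted[j])
            for i, j in brute_force_mutual_pairs(sa_sorted, sb_sorted, tol)
        }
        assert got == expected
        assert len(pairing.unpaired) == 2  # 100 vs 123 exceed tolerance

    def test_side_swap_symmetry(self):
        """Swapping A/B labels leaves pairs and hemiplaque calls unchanged."""
        prof = straight_profile(n=40, orphan=(500.0, 800.0))
        flipped = straight_profile(n=40, orphan=(500.0, 800.0))
        flipped.assignments = flipped.assignments.assign(
            side=flipped.assignments.side.map({"A": "B", "B": "A"})
        )
        from gjmorph.reconstruction import fit_side_polylines

        flipped.sides = fit_side_polylines(flipped.assignments)
        p1 = pair_beads(prof)
        p2 = pair_beads(flipped)
        assert len(p1.pairs) == len(p2.pairs)
        h1 = call_hemiplaques([p1], [prof])
        h2 = call_hemiplaques([p2], [flipped])
        assert h1.length_nm.sum() == pytest.approx(h2.length_nm.sum())

    def test_excessive_euclidean_gap_blocks_pairing(self):
        prof = straight_profile(n=20, gap=200.0)
        pairing = pair_beads(prof, max_gap_nm=120.0)
        assert len(pairing.pairs) == 0


class TestCallHemiplaques:
    def test_fully_paired_plaque_has_no_segments(self):
        prof = straight_profile(n=30)
        segs = call_hemiplaques([pair_beads(prof)], [prof])
        assert len(segs) == 0

    def test_single_orphan_run_length(self):
        """300 nm orphan run at 50 nm spacing -> one segment, 300 +/- 50 nm
        (run span extended by half a spacing at each end)."""
        prof = straight_profile(n=40, spacing=50.0, orphan=(500.0, 800.0))
        segs = call_hemiplaques([pair_beads(prof)], [prof])
        assert len(segs) == 1
        assert segs.iloc[0].side == "A"
        assert segs.iloc[0].length_nm == pytest.approx(300.0, abs=50.0)

    def test_short_runs_below_thresholds_ignored(self):
        prof = straight_profile(n=40, spacing=50.0, orphan=(500.0, 560.0))
        segs = call_hemiplaques([pair_beads(prof)], [prof], min_run_beads=3,
                                min_run_length_nm=100.0)
        assert len(segs) == 0


class TestCohortStats:
    def per_plaque(self, rows):
        return pd.DataFrame(rows)

    def test_percentage_with_hemiplaques(self):
        df = self.per_plaque([
            {"genotype": "g", "has_hemiplaque": i < 4,
             "total_hemiplaque_length_nm": 10.0 * (i < 4),
             "total_plaque_length_nm": 100.0}
            for i in range(10)
        ])
        out = cohort_hemiplaque_stats(df, group_cols=("genotype",))
        assert out.iloc[0].pct_with_hemiplaque == pytest.approx(40.0)

    def test_pooled_length_fraction(self):
        """(30/300) + (0/200) pooled -> 100*30/500 = 6%."""
        df = self.per_plaque([
            {"genotype": "g", "has_hemiplaque": True,
             "total_hemiplaque_length_nm": 30.0, "total_plaque_length_nm": 300.0},
            {"genotype": "g", "has_hemiplaque": False,
             "total_hemiplaque_length_nm": 0.0, "total_plaque_length_nm": 200.0},
        ])
        out = cohort_hemiplaque_stats(df, group_cols=("genotype",))
        assert out.iloc[0].pooled_length_fraction_pct == pytest.approx(6.0)

    def test_missing_group_columns_rejected(self):
        with pytest.raises(ValueError):
            cohort_hemiplaque_stats(pd.DataFrame({"x": [1]}), group_cols=("genotype",))


class TestRecordInvariants:
    def test_fraction_bounds_and_length_cap(self, ko_roi):
        stack, _ = ko_roi
        from gjmorph.detection import detect_beads
        from gjmorph.morphometrics import measure

        records = measure(reconstruct(detect_beads(stack)))
        assert records
        for r in records:
            assert 0.0 <= r.hemiplaque_fraction_pct <= 100.0
            assert r.total_hemiplaque_length_nm <= r.total_plaque_length_nm
            np.testing.assert_allclose(
                r.plane_rows.area_per_length_nm,
                r.plane_rows.area_nm2 / r.plane_rows.length_nm,
            )


class TestCohortRecovery:
    def test_orphan_prevalence_recovered_at_half_penetrance(self):
        """A cohort generated with orphan runs in 50% of disease-like
        plaques recovers that percentage within 10 points."""
        cond = CohortCondition(
            name="pkp2cko_like",
            bulge_amplitude_range_nm=(60.0, 80.0),
            n_bulges=1,
            orphan_prob=0.5,
        )
        rois = build_cohort(cond, n_plaques=20, seed=31, render=True)
        truth_pct = 100.0 * np.mean(
            [bool(p.spec.orphan_runs) for _, t in rois for p in t.plaques]
        )
        res = evaluate_cohorts(rois)
        rec_pct = 100.0 * res.paired.rec_has_hemiplaque.mean()
        assert abs(rec_pct - truth_pct) <= 10.0

    def test_metric_recovery_and_group_ordering(self):
        """Default two-genotype cohorts: avg area/length and max width
        recovered within 15% relative error, hemiplaque fraction within 5
        points, and the widened group exceeds control in truth and in the
        recovered metrics (mean over seeds 1-2)."""
        apl_err, w_err, hemi_err = [], [], []
        for seed in (1, 2):
            rois_c = build_cohort(CONTROL_LIKE, n_plaques=20, seed=seed, render=True)
            rois_k = build_cohort(PKP2CKO_LIKE, n_plaques=20, seed=100 + seed, render=True)
            res_c = evaluate_cohorts(rois_c)
            res_k = evaluate_cohorts(rois_k)
            df = pd.concat([res_c.paired, res_k.paired], ignore_index=True)
            apl_err.append(
                (df.rec_avg_area_per_length_nm / df.truth_avg_area_per_length_nm - 1)
                .abs().mean()
            )
            w_err.append(
                (df.rec_max_width_nm / df.truth_max_width_nm - 1).abs().mean()
            )
            hemi_err.append(
                (df.rec_hemiplaque_fraction_pct - df.truth_hemiplaque_fraction_pct)
                .abs().mean()
            )
            for col in ("truth_avg_area_per_length_nm", "rec_avg_area_per_length_nm",
                        "truth_max_width_nm", "rec_max_width_nm"):
                assert res_k.paired[col].mean() > res_c.paired[col].mean()
        assert np.mean(apl_err) <= 0.15
        assert np.mean(w_err) <= 0.15
        assert np.mean(hemi_err) <= 5.0

    def test_truth_cohort_tables_carry_labels(self):
        truths = [t for _, t in build_cohort(CONTROL_LIKE, 8, seed=7, render=False)]
        df = truth_per_plaque_frame(truths)
        assert set(df.ventricle) == {"LV", "RV"}
        assert (df.genotype == "control_like").all()
        assert len(df) == 8
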