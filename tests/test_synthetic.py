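"""Generator contracts: replay exactness, determinism, parameter recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliomaquant.ihc import positivity, separate_stains
from gliomaquant.synthetic import (
    CohortSpec,
    CoreImageSpec,
    PRWParams,
    SpheroidSimSpec,
    gen_cohort,
    gen_core_image,
    gen_spheroid_series,
    gen_tracks,
)
from gliomaquant.tracks import track_stats


def _cohort_spec(counts, **kw):
    return CohortSpec(category_counts=counts, **kw)


class TestCohort:
    def test_replay_reproduces_localization_crosstab(self, localization_malignancy_counts):
        counts = {
            "localization": {
                ("membranous", "malignant"): 23, ("membranous", "benign"): 2,
                ("cytoplasmic", "malignant"): 12, ("cytoplasmic", "benign"): 5,
                ("negative", "malignant"): 25, ("negative", "benign"): 15,
            }
        }
        spec = _cohort_spec(counts, class_variable="tumor_type", seed=1)
        df = gen_cohort(spec)
        assert len(df) == 82
        ct = pd.crosstab(df["localization"], df["tumor_type"])
        ct = ct.reindex(
            index=["membranous", "cytoplasmic", "negative"],
            columns=["malignant", "benign"],
        )
        assert (ct.to_numpy() == localization_malignancy_counts).all()

    def test_all_zero_counts_give_empty_cohort(self):
        spec = _cohort_spec({"sex": {("M", "low"): 0, ("F", "high"): 0}})
        assert len(gen_cohort(spec)) == 0

    def test_negative_count_rejected_naming_cell(self):
        spec = _cohort_spec({"sex": {("M", "low"): -1}})
        with pytest.raises(ValueError, match="sex.*'M'.*'low'"):
            gen_cohort(spec)

    def test_inconsistent_class_totals_rejected(self):
        spec = _cohort_spec(
            {"sex": {("M", "low"): 3, ("F", "low"): 1},
             "location": {("cerebrum", "low"): 5}}
        )
        with pytest.raises(ValueError, match="class totals"):
            gen_cohort(spec)

    def test_sample_mode_frequencies_within_3se(self):
        n = 10000
        spec = _cohort_spec(
            {"sex": {("M", "low"): n // 2, ("M", "high"): n // 2}},
            mode="sample", seed=42,
        )
        df = gen_cohort(spec)
        frac = (df["expression_class"] == "low").mean()
        se = math.sqrt(0.25 / n)
        assert abs(frac - 0.5) <= 3 * se

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 20), st.integers(0, 20)), min_size=2, max_size=4
        ),
        seed=st.integers(0, 2**16),
    )
    def test_replay_is_exact_inverse_of_crosstab(self, counts, seed):
        """cross_tab(gen_cohort(replay, C)) == C for any non-negative C."""
        cats = [f"cat{i}" for i in range(len(counts))]
        cells = {}
        for cat, (lo, hi) in zip(cats, counts):
            cells[(cat, "low")] = lo
            cells[(cat, "high")] = hi
        df = gen_cohort(_cohort_spec({"cov": cells}, seed=seed))
        ct = pd.crosstab(df.get("cov", pd.Series(dtype=str)),
                         df.get("expression_class", pd.Series(dtype=str)))
        for cat, (lo, hi) in zip(cats, counts):
            got_lo = ct.loc[cat, "low"] if cat in ct.index and "low" in ct.columns else 0
            got_hi = ct.loc[cat, "high"] if cat in ct.index and "high" in ct.columns else 0
            assert (got_lo, got_hi) == (lo, hi)

    def test_deterministic_under_fixed_seed(self):
        counts = {"sex": {("M", "low"): 7, ("F", "low"): 3, ("M", "high"): 2}}
        a = gen_cohort(_cohort_spec(counts, seed=5))
        b = gen_cohort(_cohort_spec(counts, seed=5))
        pd.testing.assert_frame_equal(a, b)


class TestCoreImage:
    def test_zero_stained_fraction_zero_positivity(self):
        core = gen_core_image(CoreImageSpec(intensity_level=2, stained_fraction=0.0))
        _, dab = separate_stains(core.rgb)
        assert positivity(dab, core.tissue_mask) == 0.0

    def test_closed_loop_recovery_of_stained_fraction(self):
        core = gen_core_image(
            CoreImageSpec(intensity_level=2, stained_fraction=40.0, noise_sd=0.0, seed=7)
        )
        _, dab = separate_stains(core.rgb)
        assert positivity(dab, core.tissue_mask) == pytest.approx(40.0, abs=2.0)

    def test_fully_stained_core_reaches_top_digital_score(self):
        from gliomaquant.ihc import digital_score

        core = gen_core_image(CoreImageSpec(intensity_level=3, stained_fraction=100.0))
        _, dab = separate_stains(core.rgb)
        assert digital_score(positivity(dab, core.tissue_mask)) == 7

    def test_recovery_error_monotone_in_noise(self):
        errs = []
        for sd in (0.0, 0.1, 0.3):
            err = []
            for seed in range(5):
                core = gen_core_image(
                    CoreImageSpec(intensity_level=2, stained_fraction=40.0,
                                  noise_sd=sd, seed=seed)
                )
                _, dab = separate_stains(core.rgb)
                err.append(abs(positivity(dab, core.tissue_mask) - 40.0))
            errs.append(np.mean(err))
        assert errs[0] <= errs[1] <= errs[2]

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError, match="stained_fraction"):
            CoreImageSpec(intensity_level=1, stained_fraction=101.0)

    def test_bitwise_reproducible(self):
        spec = CoreImageSpec(intensity_level=1, stained_fraction=30.0, noise_sd=0.05, seed=9)
        assert np.array_equal(gen_core_image(spec).rgb, gen_core_image(spec).rgb)


class TestTracks:
    def test_zero_speed_tracks_are_stationary(self):
        tracks = gen_tracks(PRWParams(speed=0.0, persistence_time=10.0,
                                      duration=60.0, n_cells=3))
        for tr in tracks:
            s = track_stats(tr)
            assert s.velocity == 0.0 and s.path_length == 0.0

    def test_infinite_persistence_gives_straight_lines(self):
        tracks = gen_tracks(PRWParams(speed=0.1, persistence_time=math.inf,
                                      duration=120.0, n_cells=5))
        for tr in tracks:
            assert track_stats(tr).directionality == pytest.approx(1.0)

    def test_velocity_recovery(self):
        tracks = gen_tracks(PRWParams(speed=0.2, persistence_time=30.0,
                                      duration=4320.0, n_cells=200, seed=4))
        v = np.mean([track_stats(tr).velocity for tr in tracks])
        assert v == pytest.approx(0.2, rel=0.05)

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            PRWParams(speed=0.1, persistence_time=10.0, dt=0.0)

    def test_msd_scaling_regimes(self):
        """Ensemble MSD grows ~t^2 below the persistence time, ~t above it."""
        p = PRWParams(speed=0.1, persistence_time=50.0, dt=1.0,
                      duration=5000.0, n_cells=300, seed=12)
        tracks = gen_tracks(p)
        x = np.stack([tr.x for tr in tracks])
        y = np.stack([tr.y for tr in tracks])
        msd = ((x - x[:, :1]) ** 2 + (y - y[:, :1]) ** 2).mean(axis=0)
        t = np.arange(msd.size) * p.dt

        def slope(lo, hi):
            sel = (t >= lo) & (t <= hi)
            return np.polyfit(np.log(t[sel]), np.log(msd[sel]), 1)[0]

        assert 1.7 <= slope(1, 10) <= 2.05  # ballistic regime
        assert 0.8 <= slope(1000, 5000) <= 1.2  # diffusive regime

    def test_deterministic_under_fixed_seed(self):
        p = PRWParams(speed=0.1, persistence_time=20.0, duration=100.0, n_cells=4, seed=3)
        a, b = gen_tracks(p), gen_tracks(p)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.x, tb.x) and np.array_equal(ta.y, tb.y)


class TestSpheroidSim:
    def test_zero_rates_zero_mi(self):
        from gliomaquant.spheroid import migration_index

        spec = SpheroidSimSpec(core_radius0=200.0, front_rate=0.0, edge_rate=0.0)
        truth, _ = gen_spheroid_series(spec)
        mi = migration_index(truth)
        assert (mi["mi_front"] == 0).all() and (mi["mi_edge"] == 0).all()

    def test_non_monotone_timepoints_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            SpheroidSimSpec(core_radius0=200.0, front_rate=1.0, edge_rate=2.0,
                            timepoints=(0.0, 48.0, 24.0))

    def test_timepoints_must_start_at_zero(self):
        with pytest.raises(ValueError, match="start at 0"):
            SpheroidSimSpec(core_radius0=200.0, front_rate=1.0, edge_rate=2.0,
                            timepoints=(24.0, 48.0))

    def test_edge_rate_must_dominate_front_rate(self):
        with pytest.raises(ValueError, match="front_rate"):
            SpheroidSimSpec(core_radius0=200.0, front_rate=3.0, edge_rate=1.0)

    def test_masks_deterministic(self):
        spec = SpheroidSimSpec(core_radius0=150.0, front_rate=0.5, edge_rate=1.0, seed=2)
        _, m1 = gen_spheroid_series(spec)
        _, m2 = gen_spheroid_series(spec)
        assert all(np.array_equal(a, b) for a, b in zip(m1, m2))
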