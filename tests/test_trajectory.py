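import io
from dataclasses import replace

import numpy as np
import pytest

from cropsail.errors import ConfigurationError, ParseError, SchemaError
from cropsail.trajectory import (
    CropState,
    TrajectoryConfig,
    read_crop_report,
    read_trajectory_csv,
    simulate_campaign,
    simulate_trajectory,
    write_trajectory_csv,
)


class TestSimulateTrajectory:
    def test_zero_length_season_yields_no_records(self):
        assert simulate_trajectory(TrajectoryConfig(
            season_length=0, peak_das=0, senescence_onset_das=0)) == []

    def test_same_seed_is_bitwise_deterministic(self):
        cfg = TrajectoryConfig(seed=7)
        assert simulate_trajectory(cfg) == simulate_trajectory(cfg)

    def test_lai_peaks_near_configured_peak(self):
        cfg = TrajectoryConfig(peak_lai=6.0, peak_das=100, season_length=160,
                               sampling_interval=14)
        traj = simulate_trajectory(cfg)
        lai = np.array([s.LAI_total for s in traj])
        das = np.array([s.das for s in traj])
        imax = int(np.argmax(lai))
        assert lai[imax] >= 0.9 * 6.0 and lai[imax] <= 1.1 * 6.0
        assert abs(das[imax] - 100) <= 14

    def test_all_state_invariants_hold(self):
        for seed in range(5):
            for s in simulate_trajectory(TrajectoryConfig(seed=seed)):
                s.validate()  # raises on violation

    def test_single_interior_maximum_then_decline(self):
        traj = simulate_trajectory(TrajectoryConfig(seed=3))
        lai = [s.LAI_total for s in traj]
        imax = int(np.argmax(lai))
        assert all(a <= b + 1e-12 for a, b in zip(lai[:imax], lai[1:imax + 1]))
        assert all(a >= b - 1e-12 for a, b in zip(lai[imax:], lai[imax + 1:]))

    def test_dead_fraction_zero_before_onset_then_nondecreasing(self):
        cfg = TrajectoryConfig(seed=5)
        traj = simulate_trajectory(cfg)
        f = [(s.das, s.f_dead) for s in traj]
        for das, fd in f:
            if das < cfg.senescence_onset_das:
                assert fd == 0.0
        after = [fd for das, fd in f if das >= cfg.senescence_onset_das]
        assert all(a <= b + 1e-12 for a, b in zip(after, after[1:]))

    def test_zadok_monotone_toward_maturity(self):
        traj = simulate_trajectory(TrajectoryConfig(seed=9))
        zs = [s.Zs for s in traj]
        assert all(a <= b for a, b in zip(zs, zs[1:]))
        assert zs[-1] > 80

    def test_different_seeds_give_different_output(self):
        pairs = [(i, 1000 + i) for i in range(20)]
        differing = 0
        for a, b in pairs:
            ta = simulate_trajectory(TrajectoryConfig(seed=a))
            tb = simulate_trajectory(TrajectoryConfig(seed=b))
            differing += ta != tb
        assert differing == len(pairs)

    @pytest.mark.parametrize("field,value", [
        ("sampling_interval", 0),
        ("peak_das", 200),
        ("senescence_onset_das", 500),
        ("sla_range", (0.3, 0.1)),
        ("latitude", 123.0),
    ])
    def test_invalid_config_names_offending_field(self, field, value):
        with pytest.raises(ConfigurationError, match=field.split("_")[0]):
            simulate_trajectory(replace(TrajectoryConfig(), **{field: value}))


class TestCampaign:
    def test_pooled_lai_coverage(self):
        trajs = simulate_campaign(TrajectoryConfig(seed=0, peak_lai=6.0), 50)
        lai = np.concatenate([[s.LAI_total for s in t] for t in trajs])
        assert lai.min() <= 0.1 * 6.0
        assert lai.max() >= 0.9 * 6.0

    def test_campaign_deterministic(self):
        a = simulate_campaign(TrajectoryConfig(seed=4), 5)
        b = simulate_campaign(TrajectoryConfig(seed=4), 5)
        assert a == b


REPORT = """das,zadok,lai_total,lai_dead,ldw_g_m2,cnc_g_m2
30,21,1.5,0.0,60,2.2
60,33,3.5,0.1,150,5.0
90,40,5.0,0.4,230,7.5
"""


class TestReadCropReport:
    def test_well_formed_file_in_order(self):
        states = read_crop_report(io.StringIO(REPORT))
        assert len(states) == 3
        assert [s.das for s in states] == [30, 60, 90]
        assert states[1].CNC == 5.0

    def test_invariant_violating_row_rejected_with_warning(self):
        bad = REPORT + "100,50,2.0,3.0,100,3.0\n"  # dead > total
        with pytest.warns(UserWarning, match="row 3"):
            states = read_crop_report(io.StringIO(bad))
        assert len(states) == 3

    def test_header_aliasing_equivalent_to_canonical(self):
        aliased = REPORT.replace("lai_total", "LeafLAI")
        states = read_crop_report(io.StringIO(aliased),
                                  column_map={"LeafLAI": "lai_total"})
        assert states == read_crop_report(io.StringIO(REPORT))

    def test_missing_column_is_schema_error(self):
        with pytest.raises(SchemaError, match="cnc_g_m2"):
            read_crop_report(io.StringIO(REPORT.replace("cnc_g_m2", "other")))

    def test_unparsable_numeric_names_row_and_column(self):
        broken = REPORT.replace("3.5", "oops")
        with pytest.raises(ParseError, match="row 1.*lai_total"):
            read_crop_report(io.StringIO(broken))


def test_trajectory_csv_round_trip(tmp_path):
    trajs = simulate_campaign(TrajectoryConfig(seed=2), 3)
    path = tmp_path / "t.csv"
    write_trajectory_csv(trajs, path)
    back = read_trajectory_csv(path)
    assert len(back) == 3
    for t0, t1 in zip(trajs, back):
        for a, b in zip(t0, t1):
            assert a.das == b.das
            assert a.LAI_total == pytest.approx(b.LAI_total, rel=1e-12)
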