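"""Study orchestration, reporting and internal consistency."""

import filecmp

import numpy as np
import pytest

from liftrisk.risk import clbl_analysis
from liftrisk.study import render_reports
from liftrisk.trajectory import Trajectory


def test_all_blocks_solved(study_result):
    assert set(study_result.blocks) == {
        f"{v}-{c}" for v in ("HO", "HwE") for c in ("LSQ", "CLBL", "PLBL", "HYB")
    }
    for b in study_result.blocks.values():
        assert b.success, f"{b.name}: {b.message}"
        assert b.trajectory is not None


def test_table_rows_match_solved_blocks(study_result):
    table = study_result.table()
    n_solved = sum(1 for b in study_result.blocks.values() if b.trajectory is not None)
    assert len(table) == n_solved


def test_ho_lsq_is_the_normalization_block(study_result):
    table = study_result.table().set_index("block")
    assert table.loc["HO-LSQ", "clbl_ratio"] == pytest.approx(1.0)
    assert table.loc["HO-LSQ", "plbl_ratio"] == pytest.approx(1.0)


def test_metrics_recomputable_from_stored_trajectories(study_result, tmp_path):
    """No hidden state: the tabulated CLBL equals the trapezoid of the
    stored L5/S1 series to 0.5%."""
    for b in study_result.blocks.values():
        if b.trajectory is None:
            continue
        path = tmp_path / f"{b.name}.csv"
        b.trajectory.to_csv(path)
        back = Trajectory.from_csv(path)
        clbl = clbl_analysis(back.time, back.extras["l5s1_moment"])
        assert clbl == pytest.approx(b.clbl, rel=5e-3, abs=0.5)


def test_predictive_ratios_do_not_exceed_tracking(study_result):
    """The block minimizing a metric does not worsen that metric's ratio."""
    t = study_result.table().set_index("block")
    for variant in ("HO", "HwE"):
        assert t.loc[f"{variant}-CLBL", "clbl_ratio"] <= 1.0 + 1e-9
        assert t.loc[f"{variant}-PLBL", "plbl_ratio"] <= 1.0 + 1e-9


def test_lsq_durations_match_reference(study_result, scenario):
    for name in ("HO-LSQ", "HwE-LSQ"):
        b = study_result.blocks[name]
        assert np.allclose(b.durations, scenario.phase_durations)


def test_predictive_durations_within_bounds(study_result, cfg):
    lo, hi = cfg["ocp"]["phase_duration_bounds"]
    for b in study_result.blocks.values():
        if b.cost == "LSQ":
            continue
        assert np.all(b.durations >= lo - 1e-9)
        assert np.all(b.durations <= hi + 1e-9)


def test_reports_are_deterministic(study_result, tmp_path):
    """Rendering the same result twice gives byte-identical CSV files."""
    d1, d2 = tmp_path / "a", tmp_path / "b"
    p1 = render_reports(study_result, d1)
    p2 = render_reports(study_result, d2)
    for key in ("risk_table", "durations", "reference"):
        assert filecmp.cmp(p1[key], p2[key], shallow=False)


def test_render_rejects_empty_result(study_result):
    import copy

    from liftrisk.study import StudyResult

    empty = StudyResult(
        blocks={
            k: copy.copy(b) for k, b in study_result.blocks.items()
        },
        reference=study_result.reference,
        config=study_result.config,
        seed=study_result.seed,
    )
    for b in empty.blocks.values():
        b.trajectory = None
    with pytest.raises(ValueError, match="no solved blocks"):
        render_reports(empty, "/tmp/should_not_exist_liftrisk")


def test_reference_generation_is_deterministic(ho_model, scenario):
    from liftrisk.synthetic import ReferenceMotion

    t1 = ReferenceMotion(ho_model, scenario).sample(hz=25)
    t2 = ReferenceMotion(ho_model, scenario).sample(hz=25)
    assert np.array_equal(t1.q, t2.q)
    assert np.array_equal(t1.tau, t2.tau)
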