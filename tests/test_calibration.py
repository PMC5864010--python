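"""IPC quality gate, additive calibration, and the expression filter."""

import numpy as np
import pytest

from conftest import make_ct_table
from mirserum.calibration import CalibrationError, calibrate, filter_expressed, ipc_qc
from mirserum.containers import ValidationError


def two_plate_table(ipc1=20.0, ipc2=22.0, shift2=0.0):
    values = {
        "UniSp3-A": {"S1": ipc1, "S2": ipc2},
        "hsa-miR-1": {"S1": 30.0, "S2": 30.5 + shift2},
        "hsa-miR-2": {"S1": 25.0, "S2": 26.0 + shift2},
    }
    plates = {f: {"S1": "P1", "S2": "P2"} for f in values}
    roles = {"UniSp3-A": "ipc", "hsa-miR-1": "target", "hsa-miR-2": "target"}
    return make_ct_table(values, roles, plates=plates)


def test_identical_ipc_means_zero_sd_pass():
    table = two_plate_table(20.0, 20.0)
    rep = ipc_qc(table)
    assert rep.ipc_sd == 0.0 and rep.passed


def test_close_but_over_threshold_fails():
    """Plate IPC means 20.00 / 20.10 spread beyond the 0.05-cycle gate."""
    rep = ipc_qc(two_plate_table(20.00, 20.10))
    assert rep.ipc_sd == pytest.approx(np.std([20.0, 20.1], ddof=1))
    assert not rep.passed


def test_ipc_sd_matches_two_pass_oracle():
    rng = np.random.default_rng(4)
    means = rng.uniform(19, 21, size=6)
    values, plates = {}, {}
    values["UniSp3-A"] = {f"S{i}": m for i, m in enumerate(means)}
    plates["UniSp3-A"] = {f"S{i}": f"P{i}" for i in range(6)}
    values["hsa-miR-1"] = {f"S{i}": 30.0 for i in range(6)}
    plates["hsa-miR-1"] = {f"S{i}": f"P{i}" for i in range(6)}
    table = make_ct_table(values, {"UniSp3-A": "ipc", "hsa-miR-1": "target"}, plates=plates)
    rep = ipc_qc(table)
    mean = sum(means) / len(means)
    sd = (sum((m - mean) ** 2 for m in means) / (len(means) - 1)) ** 0.5
    assert rep.ipc_sd == pytest.approx(sd, abs=1e-12)


def test_qc_invariant_to_orderings():
    table = two_plate_table(20.0, 20.2)
    rep1 = ipc_qc(table)
    rev = table.subset(list(reversed(table.features)))
    rep2 = ipc_qc(rev)
    assert rep1.ipc_sd == pytest.approx(rep2.ipc_sd, abs=1e-12)
    assert rep1.passed == rep2.passed


def test_plate_without_ipc_is_hard_error():
    values = {
        "UniSp3-A": {"S1": 20.0, "S2": 20.0},
        "hsa-miR-1": {"S1": 30.0, "S2": 30.0},
    }
    plates = {"UniSp3-A": {"S1": "P1", "S2": "P1"}, "hsa-miR-1": {"S1": "P1", "S2": "P2"}}
    table = make_ct_table(values, {"UniSp3-A": "ipc", "hsa-miR-1": "target"}, plates=plates)
    with pytest.raises(CalibrationError, match="P2"):
        ipc_qc(table)


def test_calibration_symmetry_and_identity():
    """Plates with IPC means 20 and 22 get CFs +1/-1, meeting at 21; a
    single-plate run calibrates to itself."""
    table = two_plate_table(20.0, 22.0)
    rep = ipc_qc(table)
    assert rep.factors == {"P1": 1.0, "P2": -1.0}
    cal = calibrate(table, rep, override=True)
    assert cal.values.at["UniSp3-A", "S1"] == pytest.approx(21.0)
    assert cal.values.at["UniSp3-A", "S2"] == pytest.approx(21.0)

    values = {"UniSp3-A": {"S1": 20.0}, "hsa-miR-1": {"S1": 30.0}}
    plates = {f: {"S1": "P1"} for f in values}
    single = make_ct_table(values, {"UniSp3-A": "ipc", "hsa-miR-1": "target"}, plates=plates)
    rep1 = ipc_qc(single)
    assert rep1.factors["P1"] == 0.0
    cal1 = calibrate(single, rep1)
    assert cal1.values.equals(single.values)


def test_calibration_removes_plate_shift_exactly():
    """Shifting one plate's every Ct by +c and recalibrating restores the
    unshifted target values up to the common re-centering constant c/2
    (calibration equalizes plates at the *global* IPC mean): the residual
    between calibrated-shifted and unshifted values is the same constant in
    every well, and the plate IPC means coincide afterwards."""
    c = 0.8
    base = two_plate_table(20.0, 20.0)
    shifted = two_plate_table(20.0, 20.0 + c, shift2=c)
    cal = calibrate(shifted, ipc_qc(shifted), override=True)
    residuals = {
        (f, s): cal.values.at[f, s] - base.values.at[f, s]
        for f in ("hsa-miR-1", "hsa-miR-2")
        for s in ("S1", "S2")
    }
    assert all(r == pytest.approx(c / 2, abs=1e-12) for r in residuals.values())
    assert cal.values.at["UniSp3-A", "S1"] == pytest.approx(cal.values.at["UniSp3-A", "S2"])


def test_calibration_preserves_within_plate_differences():
    table = two_plate_table(19.5, 22.3)
    cal = calibrate(table, ipc_qc(table), override=True)
    for s in ("S1", "S2"):
        before = table.values.at["hsa-miR-1", s] - table.values.at["hsa-miR-2", s]
        after = cal.values.at["hsa-miR-1", s] - cal.values.at["hsa-miR-2", s]
        assert after == pytest.approx(before, abs=1e-12)


def test_failed_qc_requires_override():
    table = two_plate_table(20.0, 22.0)
    rep = ipc_qc(table)
    assert not rep.passed
    with pytest.raises(CalibrationError, match="override"):
        calibrate(table, rep)


def test_censored_cells_stay_censored_through_calibration():
    values = {
        "UniSp3-A": {"S1": 20.0, "S2": 21.0},
        "hsa-miR-1": {"S1": 40.0, "S2": 30.0},
    }
    plates = {f: {"S1": "P1", "S2": "P2"} for f in values}
    table = make_ct_table(values, {"UniSp3-A": "ipc", "hsa-miR-1": "target"}, plates=plates)
    assert table.n_censored() == 1
    cal = calibrate(table, ipc_qc(table), override=True)
    assert cal.values.at["hsa-miR-1", "S1"] == 40.0
    assert bool(cal.censored.at["hsa-miR-1", "S1"])


def test_filter_removes_ceiling_touching_features():
    values = {
        "hsa-miR-1": {"S1": 30.0, "S2": 40.0},
        "hsa-miR-2": {"S1": 30.0, "S2": 31.0},
        "hsa-miR-103a-3p": {"S1": 22.0, "S2": 22.1},
    }
    roles = {"hsa-miR-1": "target", "hsa-miR-2": "target", "hsa-miR-103a-3p": "reference"}
    table = make_ct_table(values, roles)
    out = filter_expressed(table, panel_policy="all")
    assert "hsa-miR-1" not in out.features
    assert "hsa-miR-2" in out.features
    assert "hsa-miR-103a-3p" in out.features  # controls retained unchanged


def test_filter_panel_policy_and_idempotence(null_experiment):
    _, table, _, _ = null_experiment
    out = filter_expressed(table, panel_policy="panel_I_only")
    targets = [f for f in out.features if out.roles[f] == "target"]
    assert all(out.panels[f] == "I" for f in targets)
    again = filter_expressed(out, panel_policy="panel_I_only")
    assert again.features == out.features


def test_filter_matches_brute_force_scan(null_experiment):
    _, table, _, _ = null_experiment
    out = filter_expressed(table, panel_policy="all")
    survivors = {f for f in out.features if out.roles[f] == "target"}
    expected = {
        f
        for f in table.features
        if table.roles[f] == "target"
        and all(table.values.loc[f] < table.ceiling)
        and not table.censored.loc[f].any()
    }
    assert survivors == expected


def test_filter_empty_survivor_set_is_hard_error():
    values = {"hsa-miR-1": {"S1": 40.0, "S2": 40.0}}
    table = make_ct_table(values, {"hsa-miR-1": "target"})
    with pytest.raises(ValidationError, match="filter"):
        filter_expressed(table, panel_policy="all")
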