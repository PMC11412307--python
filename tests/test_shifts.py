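import numpy as np
import pandas as pd
import pytest

from idpens import (
    ShiftTable,
    compare_ce_se,
    ensemble_average,
    phospho_delta,
    read_shift_table,
    score_against_reference,
)
from idpens.design import EnsembleSpec
from idpens.shifts import AtomScore, EvaluationReport

SPARTA_FIXTURE = """\
REMARK SPARTA+ protein chemical shift prediction
DATA SOURCE synthetic fixture (hand-written for the reader dialect test)
VARS   RESID RESNAME ATOMNAME SS_SHIFT SHIFT RC_SHIFT HM_SHIFT EF_SHIFT SIGMA
FORMAT %4d %4s %4s %9.3f %9.3f %9.3f %9.3f %9.3f %9.3f
   2    A     N     0.123   119.456   118.000     0.100     0.000     2.500
   2    A    HN     0.050     8.350     8.150     0.050     0.000     0.450
   2    A    CA    -0.200    52.300    52.500     0.000     0.000     0.900
   3    G   HA2     0.000     3.900     3.960     0.000     0.000     0.250
   3    G   HA3     0.000     4.100     3.960     0.000     0.000     0.250
"""


def table_of(rows):
    return ShiftTable.from_records(rows)


# ----------------------------------------------------------------- parsing

def test_generic_tsv_round_trip(tmp_path):
    t = table_of([(0, 0, "ALA", "HN", 8.0), (0, 1, "GLY", "CA", 45.2)])
    path = tmp_path / "shifts.tsv"
    t.write_tsv(str(path))
    back = read_shift_table(str(path))
    assert len(back.df) == 2
    assert back.df["shift_ppm"].tolist() == [8.0, 45.2]


def test_duplicate_records_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        table_of([(0, 0, "ALA", "HN", 8.0), (0, 0, "ALA", "HN", 8.1)])


def test_sparta_pred_tab_dialect(tmp_path):
    path = tmp_path / "pred.tab"
    path.write_text(SPARTA_FIXTURE)
    t = read_shift_table(str(path), dialect="sparta_pred_tab", frame=7)
    # residues renumbered to 0-based; HA2/HA3 averaged into one HA record
    assert set(t.df["atom"]) == {"N", "HN", "CA", "HA"}
    assert len(t.df) == 4
    ha = t.df[t.df["atom"] == "HA"]
    assert ha["shift_ppm"].iloc[0] == pytest.approx(4.0)
    assert ha["res_index"].iloc[0] == 2
    assert set(t.df["frame"].dropna()) == {7}
    n_row = t.df[t.df["atom"] == "N"]
    assert n_row["shift_ppm"].iloc[0] == pytest.approx(119.456)
    assert n_row["res_name"].iloc[0] == "ALA"


def test_unknown_atom_codes_skipped_with_warning(tmp_path):
    path = tmp_path / "odd.tsv"
    pd.DataFrame({
        "frame": [0, 0], "res_index": [0, 0], "res_name": ["ALA", "ALA"],
        "atom": ["HN", "HG12"], "shift_ppm": [8.0, 0.9],
    }).to_csv(path, sep="\t", index=False)
    with pytest.warns(UserWarning, match="HG12"):
        t = read_shift_table(str(path))
    assert len(t.df) == 1


# --------------------------------------------------------------- averaging

def test_ensemble_average_uniform_and_weighted():
    per_frame = table_of([(0, 0, "ALA", "HN", 8.0), (1, 0, "ALA", "HN", 8.4)])
    ens = EnsembleSpec(np.array([0, 1]), "CE",
                       weights=np.array([0.75, 0.25]))
    uni = ensemble_average(per_frame, ens)
    assert uni.df["shift_ppm"].iloc[0] == pytest.approx(8.2)
    wtd = ensemble_average(per_frame, ens, use_weights=True)
    assert wtd.df["shift_ppm"].iloc[0] == pytest.approx(8.1)
    assert not wtd.has_frames


def test_ensemble_average_single_frame_identity():
    per_frame = table_of([(3, 0, "ALA", "HN", 8.3), (3, 1, "ALA", "CA", 52.0)])
    ens = EnsembleSpec(np.array([3]), "SE")
    avg = ensemble_average(per_frame, ens)
    assert sorted(avg.df["shift_ppm"]) == [8.3, 52.0]


def test_ensemble_average_missing_frame_and_partial_coverage():
    per_frame = table_of([
        (0, 0, "ALA", "HN", 8.0), (1, 0, "ALA", "HN", 8.4),
        (0, 1, "ALA", "CA", 52.0),  # CA present only in frame 0
    ])
    ens = EnsembleSpec(np.array([0, 1]), "SE")
    with pytest.warns(UserWarning, match="missing in part"):
        avg = ensemble_average(per_frame, ens)
    ca = avg.df[avg.df["atom"] == "CA"]
    assert ca["shift_ppm"].iloc[0] == pytest.approx(52.0)
    with pytest.raises(ValueError, match="missing from shift table"):
        ensemble_average(per_frame, EnsembleSpec(np.array([0, 9]), "SE"))


def test_ensemble_average_linear_and_order_invariant(rng):
    rows_a, rows_b = [], []
    for f in range(4):
        for r in range(3):
            rows_a.append((f, r, "ALA", "HN", float(rng.normal(8, 0.3))))
            rows_b.append((f, r, "ALA", "HN", float(rng.normal(8, 0.3))))
    ta, tb = table_of(rows_a), table_of(rows_b)
    mixed = ShiftTable(pd.DataFrame({
        "frame": ta.df["frame"], "res_index": ta.df["res_index"],
        "res_name": "ALA", "atom": "HN",
        "shift_ppm": 0.3 * ta.df["shift_ppm"] + 0.7 * tb.df["shift_ppm"],
    }))
    ens = EnsembleSpec(np.array([0, 2, 3]), "CE")
    avg_mixed = ensemble_average(mixed, ens).df.sort_values("res_index")
    combo = (0.3 * ensemble_average(ta, ens).df.sort_values("res_index")["shift_ppm"].to_numpy()
             + 0.7 * ensemble_average(tb, ens).df.sort_values("res_index")["shift_ppm"].to_numpy())
    np.testing.assert_allclose(avg_mixed["shift_ppm"].to_numpy(), combo,
                               atol=1e-12)
    shuffled = ShiftTable(ta.df.sample(frac=1.0, random_state=0))
    np.testing.assert_allclose(
        ensemble_average(shuffled, ens).df.sort_values("res_index")["shift_ppm"].to_numpy(),
        ensemble_average(ta, ens).df.sort_values("res_index")["shift_ppm"].to_numpy(),
        atol=1e-12)


# ----------------------------------------------------------------- scoring

def _ref_and_pred(pred_vals, ref_vals, atom="HN"):
    pred = table_of([(None, i, "ALA", atom, v) for i, v in enumerate(pred_vals)])
    ref = table_of([(None, i, "ALA", atom, v) for i, v in enumerate(ref_vals)])
    return pred, ref


def test_score_perfect_agreement():
    pred, ref = _ref_and_pred([8.0, 8.5, 7.9], [8.0, 8.5, 7.9])
    rep = score_against_reference(pred, ref)
    assert rep.r2("HN") == pytest.approx(1.0)
    assert rep.rmse("HN") == pytest.approx(0.0, abs=1e-12)


def test_score_hand_evaluated_pair():
    pred, ref = _ref_and_pred([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
    rep = score_against_reference(pred, ref)
    assert rep.r2("HN") == pytest.approx(27.0 / 28.0, abs=1e-4)  # 0.9643
    assert rep.rmse("HN") == pytest.approx(np.sqrt(1.0 / 3.0), abs=1e-6)


def test_score_degenerate_and_affine_invariance(rng):
    pred, ref = _ref_and_pred([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
    rep = score_against_reference(pred, ref)
    assert not rep.scores["HN"].r2_defined
    assert np.isfinite(rep.rmse("HN"))

    x = rng.normal(8, 0.5, 10)
    y = x + rng.normal(0, 0.1, 10)
    p1, r1 = _ref_and_pred(x, y)
    p2, r2_t = _ref_and_pred(2.0 * x + 3.0, y)
    a = score_against_reference(p1, r1)
    b = score_against_reference(p2, r2_t)
    assert a.r2("HN") == pytest.approx(b.r2("HN"), abs=1e-10)
    assert a.rmse("HN") != pytest.approx(b.rmse("HN"), abs=1e-3)


def test_score_drops_proline_nitrogen():
    pred = table_of([(None, 0, "ALA", "N", 118.0), (None, 1, "PRO", "N", 135.0),
                     (None, 2, "GLY", "N", 108.0), (None, 3, "ALA", "N", 120.0)])
    ref = table_of([(None, 0, "ALA", "N", 118.5), (None, 1, "PRO", "N", 999.0),
                    (None, 2, "GLY", "N", 108.5), (None, 3, "ALA", "N", 119.5)])
    rep = score_against_reference(pred, ref)
    assert rep.scores["N"].n == 3
    rep_all = score_against_reference(pred, ref, drop_proline_N=False)
    assert rep_all.scores["N"].n == 4


# ------------------------------------------------------------ CE-vs-SE

def _report(r2_by_k, atom="HN"):
    return {k: EvaluationReport({atom: AtomScore(v, 1.0, 10)})
            for k, v in r2_by_k.items()}


def test_compare_ce_se_win_rules():
    ce = _report({3: 0.5, 5: 0.6, 8: 0.7})
    se = _report({3: 0.4, 5: 0.65, 8: 0.6})
    assert compare_ce_se(ce, se, metric="r2", atom="HN") == pytest.approx(2 / 3)
    assert compare_ce_se(ce, ce, metric="r2", atom="HN") == 0.0  # ties lose
    better = _report({3: 0.9, 5: 0.9, 8: 0.9})
    assert compare_ce_se(better, se, metric="r2", atom="HN") == 1.0
    with pytest.raises(ValueError):
        compare_ce_se(ce, _report({3: 0.1}), metric="r2", atom="HN")


def test_compare_ce_se_rmse_direction():
    ce = {k: EvaluationReport({"N": AtomScore(0.5, rm, 10)})
          for k, rm in {3: 0.1, 5: 0.3}.items()}
    se = {k: EvaluationReport({"N": AtomScore(0.5, 0.2, 10)}) for k in (3, 5)}
    assert compare_ce_se(ce, se, metric="rmse", atom="N") == pytest.approx(0.5)


# ----------------------------------------------------------------- phospho

def test_phospho_delta_classification():
    control = table_of([(None, i, "ALA", "HN", 8.0) for i in range(6)])
    shifted_rows = []
    for i in range(6):
        delta = {1: 0.2, 3: -0.2, 4: 0.3}.get(i, 0.0)
        name = "SEP" if i == 4 else "ALA"
        shifted_rows.append((None, i, name, "HN", 8.0 + delta))
    shifted = table_of(shifted_rows)
    out = phospho_delta(shifted, control, atom="HN")
    got = dict(zip(out["res_index"], out["classification"]))
    assert got == {0: "unchanged", 1: "deshielded", 2: "unchanged",
                   3: "shielded", 4: "deshielded", 5: "unchanged"}
    np.testing.assert_allclose(
        out.set_index("res_index")["delta_ppm"][[1, 3, 4]],
        [0.2, -0.2, 0.3], atol=1e-12)


def test_phospho_identical_tables_unchanged():
    t = table_of([(None, i, "ALA", "HN", 8.0 + 0.01 * i) for i in range(4)])
    out = phospho_delta(t, t, atom="HN")
    assert (out["classification"] == "unchanged").all()
    np.testing.assert_allclose(out["delta_ppm"], 0.0, atol=1e-15)


def test_phospho_skips_unmatched_residues():
    a = table_of([(None, 0, "ALA", "HN", 8.0), (None, 1, "ALA", "HN", 8.0)])
    b = table_of([(None, 0, "ALA", "HN", 8.0)])
    with pytest.warns(UserWarning, match="skipped"):
        out = phospho_delta(a, b, atom="HN")
    assert out["res_index"].tolist() == [0]


def test_phospho_heavy_atom_threshold_default():
    a = table_of([(None, 0, "ALA", "N", 119.1), (None, 1, "ALA", "N", 119.3)])
    b = table_of([(None, 0, "ALA", "N", 119.0), (None, 1, "ALA", "N", 119.0)])
    out = phospho_delta(a, b, atom="N")  # default threshold 0.2 for 15N
    assert out["classification"].tolist() == ["unchanged", "deshielded"]
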