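import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from arraxis.drug_response import (
    ChannelBlock,
    DrugRecord,
    DrugTableError,
    action_vector,
    dose_sweep,
    hill_block,
    read_drug_table,
    write_drug_table,
)


class TestHillBlock:
    def test_half_maximal_at_ic50(self):
        assert hill_block(100.0, 100.0) == pytest.approx(0.5)

    def test_no_block_at_zero_dose(self):
        assert hill_block(100.0, 0.0) == 1.0

    def test_ajmaline_kr_potency(self):
        # IC50/EFTPC = 2.735 gives the dataset's delta_Kr at 25x dose
        assert hill_block(2.735, 25.0) == pytest.approx(0.0986, rel=5e-3)

    @pytest.mark.parametrize("ic50,conc", [(-1.0, 10.0), (0.0, 10.0), (1.0, -1.0)])
    def test_domain_errors(self, ic50, conc):
        with pytest.raises(ValueError):
            hill_block(ic50, conc)

    @given(
        ic50=st.floats(0.1, 1e3),
        h=st.floats(0.5, 2.0),
        c0=st.floats(0.1, 1e3),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_dose(self, ic50, h, c0):
        # dose doublings across a potency range where delta stays resolvable
        deltas = [hill_block(ic50, c0 * 2.0**k, h) for k in range(5)]
        assert all(a > b for a, b in zip(deltas, deltas[1:]))


class TestActionVector:
    def test_ajmaline_25x(self):
        A = action_vector(ChannelBlock(dose=25.0, delta=(0.654, 0.0986, 1.0, 1.0)))
        assert A == pytest.approx([-0.425, -2.32, 0.0, 0.0], abs=5e-3)

    def test_linezolid_25x(self):
        A = action_vector(ChannelBlock(dose=25.0, delta=(0.067, 0.437, 1.0, 1.0)))
        # delta_CaL is printed to 2 sf (0.067); its half-ulp propagates to
        # +/-0.0075 on alpha_CaL = ln(delta), so -2.703 is consistent with
        # the printed -2.71
        assert A == pytest.approx([-2.71, -0.828, 0.0, 0.0], abs=0.012)

    def test_drug_free_is_zero(self):
        assert np.all(action_vector((1.0, 1.0, 1.0, 1.0)) == 0.0)

    def test_total_block_rejected(self):
        with pytest.raises(ValueError):
            action_vector((0.0, 1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            ChannelBlock(dose=1.0, delta=(0.0, 1.0, 1.0, 1.0))


class TestDoseSweep:
    def test_equal_ic50s_trace_a_straight_ray(self):
        rec = DrugRecord(
            drug_id=1, compound="uniform", clinical_class=3, eftpc=50.0,
            ic50={c: 500.0 for c in ("CaL", "Kr", "NaL", "Ks")},
        )
        sweep = dose_sweep(rec, [1, 5, 25])
        dirs = [A / np.linalg.norm(A) for _, _, A in sweep]
        for d in dirs[1:]:
            assert np.allclose(d, dirs[0], atol=1e-12)

    def test_differing_potencies_curve_the_path(self):
        # Kr far more potent than CaL: the action direction rotates with dose
        # (at low dose |alpha_Kr/alpha_CaL| -> IC50_CaL/IC50_Kr; it tends
        # monotonically to 1 as both channels saturate), so the path in
        # action space is curvilinear rather than a straight ray
        rec = DrugRecord(
            drug_id=1, compound="ajmaline-like", clinical_class=1, eftpc=100.0,
            ic50={"CaL": 5000.0, "Kr": 273.5},
        )
        ratios = [
            abs(A[1]) / abs(A[0])
            for _, _, A in dose_sweep(rec, [0.1, 1, 5, 25, 30])
        ]
        assert all(a > b > 1.0 for a, b in zip(ratios, ratios[1:]))
        assert ratios[0] == pytest.approx(5000.0 / 273.5, rel=0.05)

    def test_zero_dose_zero_action(self):
        rec = DrugRecord(
            drug_id=1, compound="x", clinical_class=2, eftpc=10.0, ic50={"Kr": 5.0}
        )
        _, blk, A = dose_sweep(rec, [0.0])[0]
        assert blk.delta == (1.0, 1.0, 1.0, 1.0)
        assert np.all(A == 0.0)

    def test_unblocked_channels_stay_at_zero_action(self):
        rec = DrugRecord(
            drug_id=1, compound="kr-only", clinical_class=1, eftpc=10.0,
            ic50={"Kr": 20.0},
        )
        for _, _, A in dose_sweep(rec, [1, 10, 100]):
            assert A[0] == 0.0 and A[2] == 0.0 and A[3] == 0.0
            assert A[1] < 0.0


class TestDrugTableIO:
    def _records(self):
        return [
            DrugRecord(
                drug_id=i + 1, compound=f"drug{i}", clinical_class=(i % 4) + 1,
                eftpc=10.0 * (i + 1), ic50={"Kr": 30.0 * (i + 1), "CaL": 90.0 * (i + 1)},
            )
            for i in range(10)
        ]

    def test_round_trip_identity(self, tmp_path):
        path = tmp_path / "drugs.csv"
        df = write_drug_table(self._records(), path, doses=[1, 5, 25])
        back = read_drug_table(path)
        assert len(back) == 10
        for orig, rec in zip(self._records(), back):
            assert rec.compound == orig.compound
            assert rec.clinical_class == orig.clinical_class
            assert rec.eftpc == orig.eftpc
            for dose in (1.0, 5.0, 25.0):
                assert rec.block_at(dose).delta == pytest.approx(
                    orig.block_at(dose).delta, rel=1e-9
                )
        df2 = write_drug_table(back, tmp_path / "again.csv")
        pd.testing.assert_frame_equal(df.reset_index(drop=True), df2.reset_index(drop=True))

    def test_table_row_yields_printed_action_vector(self, tmp_path):
        # one row with the dataset's Ajmaline 25x fractional conductances
        df = pd.DataFrame(
            [{
                "DrugID": 1, "Compound": "Ajmaline", "Class": 1,
                "EFTPC": 70.5, "Cmax": 25.0, "Conc": 25 * 70.5,
                "GKrScale": 0.0986, "GCaLScale": 0.654,
            }]
        )
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        rec = read_drug_table(path)[0]
        A = rec.action_at(25.0)
        assert A == pytest.approx([-0.425, -2.32, 0.0, 0.0], abs=5e-3)

    def test_blank_cells_mean_unblocked(self, tmp_path):
        df = pd.DataFrame(
            [{
                "DrugID": 7, "Compound": "inert", "Class": 4,
                "EFTPC": 5.0, "Cmax": 25.0, "Conc": 125.0,
                "GKrScale": np.nan,
            }]
        )
        path = tmp_path / "inert.csv"
        df.to_csv(path, index=False)
        rec = read_drug_table(path)[0]
        assert rec.block_at(25.0).delta == (1.0, 1.0, 1.0, 1.0)

    def test_raw_ic50_schema(self, tmp_path):
        df = pd.DataFrame(
            [{"Compound": "x", "Class": 2, "EFTPC_nM": 10.0, "IC50_Kr": 10.0}]
        )
        path = tmp_path / "raw.csv"
        df.to_csv(path, index=False)
        rec = read_drug_table(path)[0]
        assert rec.block_at(1.0).delta[1] == pytest.approx(0.5)

    def test_bad_delta_reports_row(self, tmp_path):
        df = pd.DataFrame(
            [{
                "DrugID": 1, "Compound": "bad", "Class": 1, "EFTPC": 1.0,
                "Cmax": 1.0, "Conc": 1.0, "GKrScale": 1.5,
            }]
        )
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(DrugTableError, match="row"):
            read_drug_table(path)

    def test_unknown_schema_rejected(self, tmp_path):
        path = tmp_path / "junk.csv"
        pd.DataFrame([{"a": 1}]).to_csv(path, index=False)
        with pytest.raises(DrugTableError):
            read_drug_table(path)
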