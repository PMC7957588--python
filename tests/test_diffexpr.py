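import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from heatmir.config import PipelineConfig
from heatmir.diffexpr import (
    RESPONSES,
    audic_claverie_pvalue,
    call_dem,
    classify_type,
    ddct,
    dem_table,
    tpm_matrix,
)


def _matrix(rows):
    """rows: mirna_id -> (NF1NT, NF1HT, YF1NT, YF1HT) counts."""
    return pd.DataFrame(
        [
            {
                "mirna_id": mid,
                "count_NF1NT": a,
                "count_NF1HT": b,
                "count_YF1NT": c,
                "count_YF1HT": d,
            }
            for mid, (a, b, c, d) in rows.items()
        ]
    )


class TestTPM:
    def test_formula(self):
        m = _matrix({"x": (50, 0, 10, 10)})
        out = tpm_matrix(m, {"NF1NT": 10**6, "NF1HT": 10**6,
                             "YF1NT": 10**6, "YF1HT": 10**6})
        assert out.loc[0, "tpm_NF1NT"] == pytest.approx(50.0)
        assert out.loc[0, "tpm_NF1HT"] == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            tpm_matrix(_matrix({"x": (1, 1, 1, 1)}), {"NF1NT": 0})

    def test_column_sums_to_one_million_over_all_tags(self, rng):
        counts = rng.integers(0, 500, size=300)
        total = int(counts.sum())
        m = _matrix({f"t{i}": (int(c), 0, 0, 0)
                     for i, c in enumerate(counts)})
        out = tpm_matrix(m, {"NF1NT": total})
        assert out["tpm_NF1NT"].sum() == pytest.approx(1e6, rel=1e-9)


class TestAudicClaverie:
    def _brute(self, x, y, n1, n2):
        q = n2 / (n1 + n2)
        pmf = lambda k: float(sps.nbinom.pmf(k, x + 1, 1 - q))
        lower = sum(pmf(k) for k in range(0, y + 1))
        upper = 1.0 - sum(pmf(k) for k in range(0, y))
        return min(1.0, 2.0 * min(lower, upper))

    @pytest.mark.parametrize(
        "x,y,n1,n2",
        [(0, 5, 10_000, 20_000), (3, 10, 10_000, 20_000),
         (10, 3, 10_000, 20_000), (7, 7, 50_000, 50_000),
         (0, 0, 1_000, 1_000)],
    )
    def test_matches_tail_summation(self, x, y, n1, n2):
        got = float(audic_claverie_pvalue(x, y, n1, n2))
        assert got == pytest.approx(self._brute(x, y, n1, n2), rel=1e-9)

    def test_null_calibration_small(self, rng):
        n = 500
        x = rng.poisson(300, n)
        y = rng.poisson(300, n)
        p = audic_claverie_pvalue(x, y, 10**6, 10**6)
        rate = (p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) < 4 * se


class TestCallDEM:
    TOTALS = {"NF1NT": 10**6, "NF1HT": 10**6,
              "YF1NT": 10**6, "YF1HT": 10**6}

    def _one(self, nt, ht, config=None):
        m = _matrix({"x": (nt, ht, 0, 0)})
        recs = call_dem(
            m, ("NF1HT", "NF1NT"), config or PipelineConfig(), self.TOTALS
        )
        return recs[0]

    def test_fourfold_change_significant(self):
        rec = self._one(1000, 4000)
        assert rec.fold_change == pytest.approx(4.0)
        assert rec.significant and rec.direction == "induced"

    def test_fold_change_exactly_two_is_significant(self):
        rec = self._one(1000, 2000)
        assert rec.fold_change == pytest.approx(2.0)
        assert rec.significant  # threshold is inclusive (>= 2)

    def test_below_threshold_never_significant(self):
        rec = self._one(10_000, 15_000)  # FC 1.5, p astronomically small
        assert rec.p_value < 1e-10
        assert not rec.significant
        assert rec.direction == "unchanged"

    def test_on_off_expression_uses_pseudocount(self):
        rec = self._one(0, 30)
        assert rec.on_off
        assert rec.fold_change == pytest.approx(31.0)
        assert rec.significant and rec.direction == "induced"

    def test_unknown_library_rejected(self):
        with pytest.raises(ValueError):
            call_dem(_matrix({"x": (1, 1, 1, 1)}), ("NF1HT", "nope"))

    @settings(max_examples=60, derandomize=True)
    @given(
        nt=st.integers(min_value=0, max_value=5000),
        ht=st.integers(min_value=0, max_value=5000),
    )
    def test_swapping_contrast_inverts_fc_and_keeps_significance(
        self, nt, ht
    ):
        m = _matrix({"x": (nt, ht, 0, 0)})
        fwd = call_dem(m, ("NF1HT", "NF1NT"), totals=self.TOTALS)[0]
        rev = call_dem(m, ("NF1NT", "NF1HT"), totals=self.TOTALS)[0]
        assert fwd.fold_change == pytest.approx(
            1.0 / rev.fold_change, rel=1e-9
        )
        assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-12)
        assert fwd.significant == rev.significant


class TestPatternTypes:
    def test_grid_is_total_and_unique(self):
        seen = set()
        for rt in RESPONSES:
            for rs in RESPONSES:
                t = classify_type(rt, rs)
                assert t not in seen
                seen.add(t)
        assert seen == set("I II III IV V VI VII VIII IX".split())

    @pytest.mark.parametrize(
        "rt,rs,expected",
        [
            ("induced", "induced", "I"),      # induced in both genotypes
            ("repressed", "repressed", "IV"),  # repressed in both
            ("unchanged", "unchanged", "IX"),  # no response to HT
        ],
    )
    def test_anchor_types(self, rt, rs, expected):
        assert classify_type(rt, rs) == expected

    def test_unknown_response_rejected(self):
        with pytest.raises(ValueError):
            classify_type("induced", "sideways")

    def test_dem_table_types_follow_designed_responses(self):
        m = _matrix(
            {
                "both_up": (100, 1000, 100, 1000),
                "both_down": (1000, 100, 1000, 100),
                "flat": (500, 500, 500, 500),
                "tol_only_up": (100, 1000, 500, 500),
            }
        )
        totals = {lib: 10**6 for lib in
                  ("NF1NT", "NF1HT", "YF1NT", "YF1HT")}
        out = dem_table(m, PipelineConfig(), totals)
        types = dict(zip(out["mirna_id"], out["pattern_type"]))
        assert types == {
            "both_up": "I", "both_down": "IV",
            "flat": "IX", "tol_only_up": "II",
        }


class TestDDCT:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["sample", "gene", "replicate", "ct"]
        )

    def test_zero_ddct_gives_one(self):
        t = self._table([
            ("test", "target", 1, 20.0), ("test", "control", 1, 20.0),
            ("calibrator", "target", 1, 22.0),
            ("calibrator", "control", 1, 22.0),
        ])
        assert ddct(t)["relative_expression"] == pytest.approx(1.0)

    def test_minus_one_ddct_gives_two(self):
        t = self._table([
            ("test", "target", 1, 19.0), ("test", "control", 1, 20.0),
            ("calibrator", "target", 1, 20.0),
            ("calibrator", "control", 1, 20.0),
        ])
        assert ddct(t)["relative_expression"] == pytest.approx(2.0)

    def test_worked_example_gives_four(self):
        # gene 24 / control 20 in test; gene 26 / control 20 in calibrator
        t = self._table([
            ("test", "target", 1, 24.0), ("test", "control", 1, 20.0),
            ("calibrator", "target", 1, 26.0),
            ("calibrator", "control", 1, 20.0),
        ])
        out = ddct(t)
        assert out["ddct"] == pytest.approx(-2.0)
        assert out["relative_expression"] == pytest.approx(4.0)

    def test_replicates_propagate_dispersion(self):
        t = self._table([
            ("test", "target", 1, 24.0), ("test", "target", 2, 25.0),
            ("test", "control", 1, 20.0), ("test", "control", 2, 20.0),
            ("calibrator", "target", 1, 26.0),
            ("calibrator", "control", 1, 20.0),
        ])
        out = ddct(t)
        assert out["sd_ddct"] > 0
        assert out["low"] < out["relative_expression"] < out["high"]

    def test_missing_control_cell_raises(self):
        t = self._table([
            ("test", "target", 1, 24.0),
            ("calibrator", "target", 1, 26.0),
            ("calibrator", "control", 1, 20.0),
        ])
        with pytest.raises(ValueError, match="control"):
            ddct(t)
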