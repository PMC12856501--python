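"""2^-ddCt arithmetic, translational efficiency, tanshinone folds, t tests."""

import math
import random

import numpy as np
import pandas as pd
import pytest

from uorfkit.quant import (
    QuantError,
    benjamini_hochberg,
    ddct,
    tanshinone_summary,
    translational_efficiency,
    two_sample_t,
)
from uorfkit.simulate import simulate_expression_tables


def _ct_table(fold, n_bio=3, n_tech=2, sd=0.0, seed=0):
    rng = random.Random(seed)
    rows = []
    for cond in ("calibrator", "treatment"):
        for b in range(n_bio):
            sample = f"{cond}_{b}"
            tgt = 24.0 - (math.log2(fold) if cond == "treatment" else 0.0)
            for t in range(n_tech):
                rows.append(dict(sample_id=sample, gene="G", role="target",
                                 condition=cond, replicate=t,
                                 ct=tgt + rng.gauss(0, sd)))
                rows.append(dict(sample_id=sample, gene="ref", role="reference_gene",
                                 condition=cond, replicate=t,
                                 ct=19.0 + rng.gauss(0, sd)))
    return pd.DataFrame(rows)


class TestDdct:
    def test_equal_cts_give_rq_one(self):
        res = ddct(_ct_table(fold=1.0))
        by_cond = {r.condition: r for r in res}
        assert by_cond["treatment"].rq == pytest.approx(1.0)
        assert by_cond["calibrator"].rq == 1.0

    def test_ddct_minus_one_gives_rq_two(self):
        res = ddct(_ct_table(fold=2.0))
        rq = {r.condition: r.rq for r in res}
        assert rq["treatment"] == pytest.approx(2.0)

    def test_calibrator_rq_is_exactly_one(self):
        res = ddct(_ct_table(fold=3.7, sd=0.3, seed=5))
        cal = [r for r in res if r.condition == "calibrator"][0]
        assert cal.delta_delta_ct == 0.0
        assert cal.rq == 1.0

    def test_rq_monotone_decreasing_in_ddct(self):
        rqs = []
        for fold in (0.25, 0.5, 1.0, 2.0, 4.0):
            res = ddct(_ct_table(fold=fold))
            rqs.append([r for r in res if r.condition == "treatment"][0])
        ddcts = [r.delta_delta_ct for r in rqs]
        values = [r.rq for r in rqs]
        assert ddcts == sorted(ddcts, reverse=True)
        assert values == sorted(values)

    @pytest.mark.parametrize("fold", [0.5, 1.0, 2.0, 4.0])
    def test_parameter_recovery_under_noise(self, fold):
        """Mean recovered RQ across seeded tables stays within 10% of the
        planted fold at Ct noise sd 0.1."""
        recovered = []
        for seed in range(60):
            res = ddct(_ct_table(fold=fold, sd=0.1, seed=seed, n_bio=3, n_tech=3))
            recovered.append([r for r in res if r.condition == "treatment"][0].rq)
        assert np.mean(recovered) == pytest.approx(fold, rel=0.10)

    def test_missing_cell_is_named_error(self):
        df = _ct_table(fold=1.0)
        df = df[~((df.condition == "treatment") & (df.role == "target"))]
        with pytest.raises(QuantError, match="treatment"):
            ddct(df)

    def test_ct_range_warning(self):
        df = _ct_table(fold=1.0)
        df.loc[0, "ct"] = 55.0
        with pytest.warns(UserWarning, match="10-40"):
            ddct(df)


class TestTranslationalEfficiency:
    def test_identity(self):
        assert translational_efficiency(1.5, 1.5, 1.5, 1.5) == 1.0

    def test_reporter_activity_ratio_with_equal_mrna(self):
        # activity 2.214 (uATGs mutated) vs 1.035 (wild type), mRNA unchanged
        te = translational_efficiency(2.214, 1.035, 1.0, 1.0)
        assert te == pytest.approx(2.139, abs=5e-4)

    def test_transcriptional_change_cancels(self):
        assert translational_efficiency(4.0, 2.0, 4.0, 2.0) == 1.0

    def test_non_positive_rejected(self):
        with pytest.raises(QuantError):
            translational_efficiency(0.0, 1.0, 1.0, 1.0)


def _met_table(tta_by_line):
    fr = {"TanI": 0.2, "TanIIA": 0.4, "CPT": 0.3, "DHT": 0.1}
    rows = [
        dict(line_id=line, analyte=a, mg_per_g_dw=tta * f, replicate=1)
        for line, tta in tta_by_line.items()
        for a, f in fr.items()
    ]
    return pd.DataFrame(rows)


class TestTanshinoneSummary:
    def test_tta_additivity(self):
        df = pd.DataFrame(
            [dict(line_id="CK", analyte=a, mg_per_g_dw=1.0, replicate=1)
             for a in ("TanI", "TanIIA", "CPT", "DHT")]
        )
        (s,) = tanshinone_summary(df)
        assert s.tta == 4.0
        assert s.fold_vs_ck_2dp == 1.0

    def test_printed_fold_changes(self):
        res = tanshinone_summary(
            _met_table({"CK": 2.85, "Del2": 5.11, "Del3": 5.15, "Del1": 3.39})
        )
        folds = {s.line_id: s.fold_vs_ck_2dp for s in res}
        assert folds == {"CK": 1.0, "Del2": 1.79, "Del3": 1.81, "Del1": 1.19}

    def test_missing_analyte_rejected(self):
        df = _met_table({"CK": 2.85}).iloc[:-1]
        with pytest.raises(QuantError, match="DHT"):
            tanshinone_summary(df)

    def test_pct_increase_per_analyte(self):
        res = tanshinone_summary(_met_table({"CK": 2.0, "M": 4.0}))
        m = {s.line_id: s for s in res}["M"]
        assert all(v == 100.0 for v in m.pct_increase.values())


class TestTwoSampleT:
    def test_identical_samples(self):
        t, df, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0 and df == 4

    def test_strong_separation(self):
        t, df, p = two_sample_t([1.0, 2.0, 3.0], [101.0, 102.0, 103.1])
        assert p < 0.001

    def test_zero_variance_equal_means(self):
        t, df, p = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_degenerate_n_rejected(self):
        with pytest.raises(QuantError):
            two_sample_t([1.0], [1.0, 2.0])

    def test_student_matches_welch_for_balanced_equal_variance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 20), rng.normal(0.4, 1, 20)
        ts, dfs, ps = two_sample_t(x, y, equal_variance=True)
        tw, dfw, pw = two_sample_t(x, y, equal_variance=False)
        # equal n: the statistics coincide exactly; df (hence p) differs only
        # through the sample-variance imbalance
        assert ts == pytest.approx(tw, rel=1e-9)
        assert dfw <= dfs
        assert ps == pytest.approx(pw, rel=0.05)

    def test_type_i_error_rate_near_alpha(self):
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            x, y = rng.normal(0, 1, 6), rng.normal(0, 1, 6)
            _, _, p = two_sample_t(x, y)
            rejections += p < 0.05
        assert 0.035 <= rejections / n_rep <= 0.065

    def test_bh_adjustment_monotone(self):
        p = [0.001, 0.01, 0.04, 0.2, 0.9]
        adj = benjamini_hochberg(p)
        assert all(a >= b for a, b in zip(adj, p))
        assert list(adj) == sorted(adj)


class TestSimulatedTables:
    def test_zero_noise_recovers_planted_folds_exactly(self):
        ct_df, met_df = simulate_expression_tables(ct_sd=0.0, analyte_cv=0.0, seed=1)
        res = ddct(ct_df)
        for r in res:
            if r.condition == "treatment":
                from uorfkit.simulate import DEFAULT_GENE_FOLDS

                assert r.rq == pytest.approx(DEFAULT_GENE_FOLDS[r.gene], rel=1e-9)
        folds = {s.line_id: s.fold_vs_ck_2dp for s in tanshinone_summary(met_df)}
        assert folds["Del2"] == 1.79 and folds["Del3"] == 1.81 and folds["Del1"] == 1.19
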