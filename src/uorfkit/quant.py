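"""Relative expression (2^-ddCt), translational efficiency, tanshinone
summaries and two-sample t tests.

The qPCR model: technical replicates are averaged per sample, dCt is the
target-minus-reference-gene Ct within a sample, ddCt subtracts the mean dCt
of the calibrator condition, and the relative quantity is ``2 ** -ddCt``
(so the calibrator's RQ is 1 by construction).  Total tanshinone
accumulation (TTA) is the exact sum of the four quantified analytes
(Tan I, Tan IIA, CPT, DHT) in mg/g dry weight; fold changes are taken
against the unedited control line and reported to two decimals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import round_half_up

ANALYTES = ("TanI", "TanIIA", "CPT", "DHT")

CT_COLUMNS = ["sample_id", "gene", "role", "condition", "replicate", "ct"]
MET_COLUMNS = ["line_id", "analyte", "mg_per_g_dw", "replicate"]


class QuantError(ValueError):
    pass


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    condition: str
    delta_ct: float  # mean per-sample dCt (cycles)
    delta_delta_ct: float  # cycles, 0 for the calibrator
    rq: float  # 2 ** -ddCt
    rq_sd: float  # sd of per-sample RQs
    n: int


@dataclass(frozen=True)
class TanshinoneSummary:
    line_id: str
    tan1: float
    tan2a: float
    cpt: float
    dht: float
    tta: float
    fold_vs_ck: float  # raw ratio
    fold_vs_ck_2dp: float  # report value, half-up to 2 decimals
    pct_increase: dict[str, float]  # per analyte, percent vs control


def ddct(records: pd.DataFrame, calibrator: str = "calibrator") -> list[ExpressionResult]:
    """2^-ddCt relative expression from a tidy Ct table.

    ``records`` columns: sample_id, gene, role (``target``/``reference_gene``),
    condition, replicate, ct.  Every (condition, role) cell needs at least one
    replicate; reference-gene Ct values are matched to targets within the same
    sample.
    """
    df = records.copy()
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise QuantError(f"Ct table missing columns: {sorted(missing)}")
    bad = df[(df.ct < 10) | (df.ct > 40)]
    if not bad.empty:
        warnings.warn(f"{len(bad)} Ct values outside the typical 10-40 range")
    if not np.isfinite(df.ct).all():
        raise QuantError("non-finite Ct value")

    # Average technical replicates per sample.
    per_sample = (
        df.groupby(["condition", "sample_id", "gene", "role"], as_index=False)
        .ct.mean()
    )
    ref = per_sample[per_sample.role == "reference_gene"]
    tgt = per_sample[per_sample.role == "target"]
    if ref.empty:
        raise QuantError("no reference_gene rows")
    ref_ct = ref.groupby(["condition", "sample_id"]).ct.mean()

    results: list[ExpressionResult] = []
    conditions = list(dict.fromkeys(df.condition))
    if calibrator not in conditions:
        raise QuantError(f"calibrator condition {calibrator!r} absent")
    for gene in dict.fromkeys(tgt.gene):
        dct: dict[str, np.ndarray] = {}
        for cond in conditions:
            sub = tgt[(tgt.gene == gene) & (tgt.condition == cond)]
            if sub.empty:
                raise QuantError(f"missing cell: gene={gene!r} condition={cond!r}")
            vals = []
            for _, row in sub.iterrows():
                key = (cond, row.sample_id)
                if key not in ref_ct.index:
                    raise QuantError(
                        f"missing reference_gene Ct for sample {row.sample_id!r} "
                        f"in condition {cond!r}"
                    )
                vals.append(row.ct - ref_ct.loc[key])
            dct[cond] = np.asarray(vals, dtype=float)
        cal_mean = float(dct[calibrator].mean())
        for cond in conditions:
            ddct_val = float(dct[cond].mean()) - cal_mean
            per_sample_rq = 2.0 ** -(dct[cond] - cal_mean)
            results.append(
                ExpressionResult(
                    gene=gene,
                    condition=cond,
                    delta_ct=float(dct[cond].mean()),
                    delta_delta_ct=ddct_val,
                    rq=2.0 ** -ddct_val,
                    rq_sd=float(per_sample_rq.std(ddof=1)) if len(per_sample_rq) > 1 else 0.0,
                    n=len(per_sample_rq),
                )
            )
    return results


def translational_efficiency(
    activity_ratio_treat: float,
    activity_ratio_ctrl: float,
    mrna_ratio_treat: float,
    mrna_ratio_ctrl: float,
) -> float:
    """Relative translational efficiency from dual-luciferase readouts.

    TE of a condition is its LUC/REN activity ratio divided by its LUC/REN
    mRNA ratio; the result is TE_treat / TE_ctrl.
    """
    ratios = (activity_ratio_treat, activity_ratio_ctrl,
              mrna_ratio_treat, mrna_ratio_ctrl)
    if any(r <= 0 for r in ratios):
        raise QuantError("all ratios must be positive")
    return (activity_ratio_treat / mrna_ratio_treat) / (
        activity_ratio_ctrl / mrna_ratio_ctrl
    )


def tanshinone_summary(table: pd.DataFrame, ck_line_id: str = "CK") -> list[TanshinoneSummary]:
    """Per-line TTA, fold vs control, and per-analyte percent increases.

    ``table`` columns: line_id, analyte (TanI/TanIIA/CPT/DHT), mg_per_g_dw,
    replicate (optional).  Replicates are averaged per line and analyte.
    """
    df = table.copy()
    need = {"line_id", "analyte", "mg_per_g_dw"}
    if not need <= set(df.columns):
        raise QuantError(f"metabolite table missing columns: {sorted(need - set(df.columns))}")
    means = df.groupby(["line_id", "analyte"]).mg_per_g_dw.mean()

    lines = list(dict.fromkeys(df.line_id))
    if ck_line_id not in lines:
        raise QuantError(f"control line {ck_line_id!r} absent")

    def analyte_means(line: str) -> dict[str, float]:
        vals = {}
        for a in ANALYTES:
            if (line, a) not in means.index:
                raise QuantError(f"line {line!r} missing analyte {a!r}")
            vals[a] = float(means.loc[(line, a)])
        return vals

    ck = analyte_means(ck_line_id)
    ck_tta = sum(ck.values())
    out: list[TanshinoneSummary] = []
    for line in lines:
        vals = analyte_means(line)
        tta = sum(vals.values())
        fold = tta / ck_tta
        pct = {
            a: round_half_up(100.0 * (vals[a] - ck[a]) / ck[a], 1) for a in ANALYTES
        }
        out.append(
            TanshinoneSummary(
                line_id=line,
                tan1=vals["TanI"],
                tan2a=vals["TanIIA"],
                cpt=vals["CPT"],
                dht=vals["DHT"],
                tta=tta,
                fold_vs_ck=fold,
                fold_vs_ck_2dp=round_half_up(fold, 2),
                pct_increase=pct,
            )
        )
    return out


def two_sample_t(
    x, y, equal_variance: bool = True
) -> tuple[float, float, float]:
    """Two-sided two-sample t test: ``(t, df, p)``.

    Pooled-variance Student's t by default; Welch with
    ``equal_variance=False`` (df by Welch-Satterthwaite).  Two identical
    zero-variance samples give t=0, p=1 rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise QuantError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            df = len(x) + len(y) - 2 if equal_variance else float("nan")
            return 0.0, float(df), 1.0
        raise QuantError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(x, y, equal_var=equal_variance)
    if equal_variance:
        df = len(x) + len(y) - 2
    else:
        nx, ny = len(x), len(y)
        num = (vx / nx + vy / ny) ** 2
        den = (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        df = num / den
    return float(res.statistic), float(df), float(res.pvalue)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (optional; raw p-values are reported by default)."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")
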