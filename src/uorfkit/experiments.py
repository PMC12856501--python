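"""Reusable study-scale experiments built on the library.

These functions regenerate the study's quantitative summaries from scratch:
cohort editing statistics from simulated clone sets, uORF landscape deltas
on the control-leader emulation, tanshinone fold changes from planted
tables, genotyping-recovery and ddCt-recovery experiments, and the t-test
calibration check.  Analysis drivers and the acceptance machinery all call
into here so the numbers are always computed, never transcribed.
"""

from __future__ import annotations

import math
import random

import numpy as np

from .edits import DeltaReport, apply_edits, predict_edit_outcome
from .genotype import (
    CohortSummary,
    ZygosityCall,
    classify_zygosity,
    genotype_clone,
    summarize_cohort,
)
from .quant import ddct, tanshinone_summary, two_sample_t
from .simulate import (
    EditPattern,
    TruthBundle,
    ck_spec,
    plant_leader,
    simulate_clones,
    simulate_edit_pattern,
    simulate_expression_tables,
)

#: The study cohort: 93 explants, 30 transgenic events, zygosity categories
#: among the 30 (25 edited + 5 unedited).
STUDY_COHORT = {"HETEROZYGOUS": 13, "CHIMERIC": 6, "HOMOZYGOUS": 6, "WILD_TYPE": 5}
STUDY_N_EXPLANTS = 93

#: Lesion profiles emulating the four characterized edited lines.
DEL_PATTERNS = {
    # count and type preserved: lesions confined to uORF-free segments
    "Del1": EditPattern("preserve_all_uatg", preserve_types=True),
    # two frameshift deletions (64 and 8 bp) removing two uATGs
    "Del2": EditPattern("disrupt_k_uatg", k=2, lesions=(64, 8)),
    # two uATGs lost and an in-frame uORF converted to an N-terminal extension
    "Del3": EditPattern("convert_to_type3", k=2),
    # count kept, one Type-1 traded for a Type-2 by a frameshift in its body
    "Del4": EditPattern("convert_to_type2"),
}


def study_reference(seed: int, max_seeds: int = 200) -> TruthBundle:
    """First control-leader planting (from ``seed`` upward) on which every
    Del-line profile is realizable; deterministic given ``seed``."""
    from .simulate import InfeasibleSpecError

    for s in range(seed, seed + max_seeds):
        truth = plant_leader(ck_spec(seed=s))
        try:
            for pattern in DEL_PATTERNS.values():
                simulate_edit_pattern(truth, pattern, seed=seed)
        except InfeasibleSpecError:
            continue
        return truth
    raise RuntimeError("no planting admitting all Del-line profiles")


def _line_mixture(truth: TruthBundle, category: str, rng: random.Random):
    """Allele mixture (id, seq, proportion) for one line of a category."""
    ref = truth.context.transcript_seq
    wt = ("WT", ref)

    def allele(k: int, seed: int):
        edits = simulate_edit_pattern(truth, EditPattern("disrupt_k_uatg", k=k), seed=seed)
        return apply_edits(ref, edits, f"edit{seed}")

    s = rng.getrandbits(30)
    if category == "WILD_TYPE":
        return [wt], [1.0]
    if category == "HOMOZYGOUS":
        return [("a", allele(1, s).seq)], [1.0]
    if category == "HETEROZYGOUS":
        return [wt, ("a", allele(1, s).seq)], [0.5, 0.5]
    if category == "CHIMERIC":
        a, b = allele(1, s), allele(2, s + 1)
        return [wt, ("a", a.seq), ("b", b.seq)], [1 / 3, 1 / 3, 1 / 3]
    raise ValueError(category)


def simulated_cohort_summary(
    seed: int,
    cohort: dict[str, int] | None = None,
    n_explants: int = STUDY_N_EXPLANTS,
    n_clones: int = 12,
    error_rate: float = 0.0,
    min_support: int = 2,
) -> CohortSummary:
    """Genotype a full simulated cohort and summarize it.

    Each line gets its own clone set drawn from a category-appropriate
    allele mixture; every clone is aligned, variant-called and the line
    classified, so the summary percentages are products of the entire
    genotyping chain.
    """
    cohort = STUDY_COHORT if cohort is None else cohort
    rng = random.Random(seed)
    truth = plant_leader(ck_spec(seed=rng.getrandbits(30)))
    ref = truth.context.transcript_seq
    calls: list[ZygosityCall] = []
    i = 0
    for category, n_lines in cohort.items():
        for _ in range(n_lines):
            i += 1
            mix, props = _line_mixture(truth, category, rng)
            clones = simulate_clones(mix, props, n_clones, error_rate,
                                     seed=rng.getrandbits(30))
            sigs = [genotype_clone(ref, c.seq) for c in clones]
            calls.append(classify_zygosity(f"line_{i:02d}", sigs, min_support))
    return summarize_cohort(n_explants, sum(cohort.values()), calls)


def disrupt_two_delta(seed: int) -> DeltaReport:
    """Plant the control leader, abolish two of its five Type-1 uATGs with
    no new starts, and return the predicted landscape delta."""
    truth = plant_leader(ck_spec(seed=seed))
    edits = simulate_edit_pattern(truth, EditPattern("disrupt_k_uatg", k=2),
                                  seed=seed + 1)
    _, _, delta = predict_edit_outcome(truth.context, edits)
    return delta


def tta_fold_changes(seed: int) -> dict[str, float]:
    """Planted-total metabolite tables -> per-line TTA fold vs control."""
    _, met = simulate_expression_tables(analyte_cv=0.0, seed=seed)
    return {s.line_id: s.fold_vs_ck_2dp for s in tanshinone_summary(met)}


def genotyping_recovery(
    n_sims: int = 500,
    seed: int = 0,
    n_clones: int = 12,
    error_rate: float = 0.001,
    min_support: int = 2,
) -> float:
    """Fraction of simulated clone sets whose planted zygosity category is
    recovered by the genotyping chain."""
    rng = random.Random(seed)
    truth = plant_leader(ck_spec(seed=rng.getrandbits(30)))
    ref = truth.context.transcript_seq
    categories = ("HOMOZYGOUS", "HETEROZYGOUS", "CHIMERIC", "WILD_TYPE")
    hits = 0
    for i in range(n_sims):
        category = categories[i % len(categories)]
        mix, props = _line_mixture(truth, category, rng)
        clones = simulate_clones(mix, props, n_clones, error_rate,
                                 seed=rng.getrandbits(30))
        sigs = [genotype_clone(ref, c.seq) for c in clones]
        try:
            call = classify_zygosity("sim", sigs, min_support)
        except Exception:
            continue
        hits += call.category == category
    return hits / n_sims


def ddct_recovery(
    folds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0),
    n_seeds: int = 200,
    ct_sd: float = 0.1,
    seed: int = 0,
) -> dict[float, float]:
    """Mean recovered relative quantity per planted fold across seeds."""
    out: dict[float, float] = {}
    for fold in folds:
        recovered = []
        for i in range(n_seeds):
            ct, _ = simulate_expression_tables(
                gene_folds={"G": fold}, ct_sd=ct_sd, analyte_cv=0.0,
                seed=seed * 100003 + int(fold * 1000) * 1009 + i,
            )
            res = ddct(ct)
            recovered.append(
                [r.rq for r in res if r.condition == "treatment" and r.gene == "G"][0]
            )
        out[fold] = float(np.mean(recovered))
    return out


def ttest_type_i_error(n_reps: int = 10_000, n: int = 6, alpha: float = 0.05,
                       seed: int = 0) -> float:
    """Empirical rejection rate of the pooled t test under the null."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, size=(n_reps, n))
    y = rng.normal(0.0, 1.0, size=(n_reps, n))
    rejections = 0
    for i in range(n_reps):
        _, _, p = two_sample_t(x[i], y[i])
        rejections += p < alpha
    return rejections / n_reps
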