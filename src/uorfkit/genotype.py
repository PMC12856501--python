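"""Amplicon genotyping: alignment, variant calling, zygosity, cohort stats.

Clone sequences are aligned globally to the reference amplicon under affine
gap scoring (defaults match +2, mismatch -3, gap open -5, gap extend -1; a
length-L gap scores ``open + L * extend``).  Gapped columns are converted to
DEL/INS/SUB edits, indels are left-aligned within repeat context, and each
clone's normalized edit set forms an allele signature.  Lines are classified
from their signature multiset:

* all clones wild-type -> WILD_TYPE
* one non-empty signature -> HOMOZYGOUS (indistinguishable from hemizygous
  by clone counting; flagged)
* two signatures -> HETEROZYGOUS
* three or more -> CHIMERIC

Signatures supported by fewer than ``min_support`` clones are discarded as
noise (sequencing errors make each affected clone's signature unique).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from Bio import Align

from .edits import Edit, EditKind


class GenotypeError(ValueError):
    pass


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), matching printed percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Scoring:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class AlignmentResult:
    ref_aligned: str
    query_aligned: str
    score: float

    def __post_init__(self) -> None:
        assert len(self.ref_aligned) == len(self.query_aligned)


CATEGORIES = ("HOMOZYGOUS", "HETEROZYGOUS", "CHIMERIC", "WILD_TYPE")


@dataclass(frozen=True)
class ZygosityCall:
    line_id: str
    category: str
    allele_signatures: tuple[tuple[tuple[Edit, ...], int], ...]  # (edits, support)
    n_clones: int
    n_discarded: int
    hemizygous_possible: bool = False  # set for HOMOZYGOUS calls

    @property
    def edited(self) -> bool:
        return self.category in ("HOMOZYGOUS", "HETEROZYGOUS", "CHIMERIC")


@dataclass(frozen=True)
class CohortSummary:
    n_explants: int
    n_transgenic: int
    n_edited: int
    n_homozygous: int
    n_heterozygous: int
    n_chimeric: int
    n_wild_type: int
    transformation_efficiency_pct: float | None
    editing_efficiency_pct: float | None
    homozygous_pct: float | None
    heterozygous_pct: float | None
    chimeric_pct: float | None


def _aligner(scoring: Scoring) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    # Biopython charges open for the first gap base; our convention charges
    # open + extend, so fold one extend into the open score.
    a.open_gap_score = scoring.gap_open + scoring.gap_extend
    a.extend_gap_score = scoring.gap_extend
    return a


def align_pair(reference: str, query: str, scoring: Scoring = Scoring(),
               max_len: int = 20_000) -> AlignmentResult:
    """Optimal global alignment of ``query`` against ``reference``.

    Deterministic: the aligner's first optimal traceback is taken.
    """
    if not reference or not query:
        raise GenotypeError("empty sequence")
    if len(reference) > max_len or len(query) > max_len:
        raise GenotypeError(f"sequence longer than cap of {max_len}")
    best = _aligner(scoring).align(reference, query)[0]
    return AlignmentResult(best[0], best[1], best.score)


def call_variants(aln: AlignmentResult) -> list[Edit]:
    """Convert an alignment into normalized reference-coordinate edits.

    Maximal gap/mismatch runs become DEL/INS/SUB; adjacent substituted bases
    merge into one SUB; indels are left-aligned within repeat context (never
    across a previously emitted edit).
    """
    ref = aln.ref_aligned.replace("-", "")
    edits: list[Edit] = []
    rpos = 0
    i = 0
    n = len(aln.ref_aligned)
    while i < n:
        r, q = aln.ref_aligned[i], aln.query_aligned[i]
        if r == "-":  # insertion run
            j = i
            ins = []
            while j < n and aln.ref_aligned[j] == "-":
                ins.append(aln.query_aligned[j])
                j += 1
            edits.append(Edit(EditKind.INS, rpos, alt_seq="".join(ins)))
            i = j
        elif q == "-":  # deletion run
            j = i
            dlen = 0
            while j < n and aln.query_aligned[j] == "-":
                dlen += 1
                j += 1
            edits.append(Edit(EditKind.DEL, rpos, del_len=dlen))
            rpos += dlen
            i = j
        elif r != q:  # substitution run
            j = i
            alt = []
            while (j < n and aln.ref_aligned[j] != "-" and aln.query_aligned[j] != "-"
                   and aln.ref_aligned[j] != aln.query_aligned[j]):
                alt.append(aln.query_aligned[j])
                j += 1
            edits.append(Edit(EditKind.SUB, rpos, alt_seq="".join(alt)))
            rpos += len(alt)
            i = j
        else:
            rpos += 1
            i += 1

    # Left-align indels within repeat context.
    normalized: list[Edit] = []
    prev_end = 0
    for e in edits:
        if e.kind is EditKind.DEL:
            p, L = e.pos, e.del_len
            while p > prev_end and ref[p - 1] == ref[p + L - 1]:
                p -= 1
            e = Edit(EditKind.DEL, p, del_len=L)
        elif e.kind is EditKind.INS:
            p, alt = e.pos, e.alt_seq
            while p > prev_end and p <= len(ref) and ref[p - 1] == alt[-1]:
                alt = alt[-1] + alt[:-1]
                p -= 1
            e = Edit(EditKind.INS, p, alt_seq=alt)
        normalized.append(e)
        prev_end = max(prev_end, e.span[1] if e.kind is not EditKind.INS else e.pos)
    return normalized


def signature(edits: list[Edit]) -> tuple[Edit, ...]:
    """Canonical allele signature: edits sorted by position then kind."""
    return tuple(sorted(edits, key=lambda e: (e.pos, e.kind.value, e.del_len, e.alt_seq)))


def genotype_clone(reference: str, clone_seq: str, scoring: Scoring = Scoring()) -> tuple[Edit, ...]:
    return signature(call_variants(align_pair(reference, clone_seq, scoring)))


def classify_zygosity(
    line_id: str,
    clone_edit_sets: list[tuple[Edit, ...]],
    min_support: int = 2,
) -> ZygosityCall:
    """Classify a line from its clones' normalized edit signatures."""
    if len(clone_edit_sets) < 2:
        raise GenotypeError("at least 2 clones required")
    counts: dict[tuple[Edit, ...], int] = {}
    for sig in clone_edit_sets:
        counts[sig] = counts.get(sig, 0) + 1
    kept = {s: c for s, c in counts.items() if c >= min_support}
    n_discarded = len(clone_edit_sets) - sum(kept.values())
    if not kept:
        raise GenotypeError(f"insufficient clone support for line {line_id}")

    sigs = set(kept)
    if sigs == {()}:
        category = "WILD_TYPE"
    elif len(sigs) == 1:
        category = "HOMOZYGOUS"
    elif len(sigs) == 2:
        category = "HETEROZYGOUS"
    else:
        category = "CHIMERIC"
    ordered = tuple(sorted(kept.items(), key=lambda kv: (-kv[1], kv[0])))
    return ZygosityCall(line_id, category, ordered, len(clone_edit_sets),
                        n_discarded, hemizygous_possible=(category == "HOMOZYGOUS"))


def summarize_cohort(
    n_explants: int,
    n_transgenic: int,
    calls: list[ZygosityCall],
) -> CohortSummary:
    """Cohort editing statistics with half-up 2-decimal percentage reporting.

    Zero denominators yield None fields rather than exceptions.
    """
    if n_transgenic > n_explants:
        raise GenotypeError("n_transgenic exceeds n_explants")
    if len(calls) > n_transgenic:
        raise GenotypeError("more zygosity calls than transgenic events")
    n_hom = sum(c.category == "HOMOZYGOUS" for c in calls)
    n_het = sum(c.category == "HETEROZYGOUS" for c in calls)
    n_chi = sum(c.category == "CHIMERIC" for c in calls)
    n_wt = sum(c.category == "WILD_TYPE" for c in calls)
    n_edited = n_hom + n_het + n_chi

    def pct(num: int, den: int) -> float | None:
        return round_half_up(100.0 * num / den, 2) if den > 0 else None

    return CohortSummary(
        n_explants=n_explants,
        n_transgenic=n_transgenic,
        n_edited=n_edited,
        n_homozygous=n_hom,
        n_heterozygous=n_het,
        n_chimeric=n_chi,
        n_wild_type=n_wt,
        transformation_efficiency_pct=pct(n_transgenic, n_explants),
        editing_efficiency_pct=pct(n_edited, n_transgenic),
        homozygous_pct=pct(n_hom, n_transgenic),
        heterozygous_pct=pct(n_het, n_transgenic),
        chimeric_pct=pct(n_chi, n_transgenic),
    )
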