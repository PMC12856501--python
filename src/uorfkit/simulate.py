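"""Synthetic inputs for the whole pipeline.

The deposited study sequence is not machine-readable, so every input is
generated here under the published summary statistics:

* ``plant_leader`` builds a 5' leader containing planted uORFs of specified
  types and lengths (default emulation: a 192-nt leader carrying five
  overlapping Type-1 uORFs of 57, 15, 30, 54 and 84 nt with no stray ATGs),
  plus a short valid CDS.  Truth is *always* recomputed by an independent
  brute-force scan of the final sequence, never assumed from the spec.
* ``simulate_edit_pattern`` produces CRISPR-like lesion sets realizing named
  outcome profiles (preserve all uATGs, disrupt k uATGs, convert a uORF to a
  Type-3 N-terminal extension or a Type-2 overlap, bare lesion sizes), each
  verified through the edit-outcome predictor before being returned.
* ``simulate_clones`` draws Sanger-like clone sequences from an allele
  mixture with independent per-base substitution noise.
* ``simulate_expression_tables`` emits qPCR Ct and metabolite tables with
  planted fold changes (defaults reproduce the study's printed totals:
  control TTA 2.85 mg/g DW, edited lines 3.39/5.11/5.15 mg/g DW).  The
  per-analyte split of the control TTA is synthetic — only the totals are
  constrained — and is documented as such.

All generators are deterministic per seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace

import pandas as pd

from .annotate import (
    LeaderContext,
    ScanConfig,
    UOrf,
    UOrfAnnotation,
    UOrfType,
)
from .edits import Edit, EditKind, EditError, predict_edit_outcome

STOPS = ("TAA", "TAG", "TGA")
BASES = "ACGT"


class InfeasibleSpecError(ValueError):
    """A planting or edit profile that cannot be realized."""


# ---------------------------------------------------------------------------
# Planting specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedUOrf:
    utype: UOrfType
    length_nt: int | None = None  # derived from position for TYPE3
    uatg_pos: int | None = None


@dataclass(frozen=True)
class PlantSpec:
    leader_len: int
    planted: tuple[PlantedUOrf, ...]
    forbid_stray_atg: bool = True
    max_attempts: int = 500
    seed: int | None = None
    cds_len: int = 60  # filler CDS, long enough for Type-2/3 stops
    transcript_id: str = "synthetic"


#: Emulation of the study's control leader: 192 nt, five Type-1 uORFs whose
#: printed lengths total 240 nt, forcing overlap.
CK_LENGTHS = (57, 15, 30, 54, 84)


def ck_spec(seed: int | None = None, **kwargs) -> PlantSpec:
    planted = tuple(PlantedUOrf(UOrfType.TYPE1, n) for n in CK_LENGTHS)
    return PlantSpec(leader_len=192, planted=planted, seed=seed,
                     transcript_id="CK", **kwargs)


@dataclass(frozen=True)
class TruthBundle:
    context: LeaderContext
    truth_annotation: UOrfAnnotation  # recomputed by the brute-force oracle
    planted_map: tuple[UOrf, ...]  # spec entry -> realized uORF


@dataclass(frozen=True)
class Clone:
    clone_id: str
    seq: str
    allele_id: str  # truth label


# ---------------------------------------------------------------------------
# Brute-force scanning oracle (independent of annotate.scan_uorf)
# ---------------------------------------------------------------------------


def oracle_scan(transcript: str, matg: int) -> list[dict]:
    """Exhaustively scan the leader for uORFs by direct substring checks."""
    found = []
    for p in range(min(matg, len(transcript) - 2)):
        if transcript[p] == "A" and transcript[p + 1] == "T" and transcript[p + 2] == "G":
            q = p + 3
            stop = None
            while q + 3 <= len(transcript):
                if transcript[q : q + 3] in STOPS:
                    stop = q
                    break
                q += 3
            in_frame = (p % 3) == (matg % 3)
            if stop is None:
                found.append(dict(uatg=p, stop_start=None, stop_end=None,
                                  length=None, utype=UOrfType.INCOMPLETE,
                                  in_frame=in_frame))
                continue
            end = stop + 3
            if end <= matg:
                t = UOrfType.TYPE1
            elif in_frame:
                t = UOrfType.TYPE3
            else:
                t = UOrfType.TYPE2
            found.append(dict(uatg=p, stop_start=stop, stop_end=end,
                              length=end - p, utype=t, in_frame=in_frame))
    return found


def oracle_annotation(ctx: LeaderContext, include_incomplete: bool = False) -> UOrfAnnotation:
    """UOrfAnnotation assembled from the brute-force oracle."""
    counts = {t: 0 for t in UOrfType}
    uorfs = []
    for rec in oracle_scan(ctx.transcript_seq, ctx.matg_pos):
        counts[rec["utype"]] += 1
        if rec["utype"] is UOrfType.INCOMPLETE and not include_incomplete:
            continue
        uorfs.append(
            UOrf(rec["uatg"], rec["stop_start"], rec["stop_end"], rec["length"],
                 rec["utype"], rec["uatg"] % 3, rec["in_frame"])
        )
    total = counts[UOrfType.TYPE1] + counts[UOrfType.TYPE2] + counts[UOrfType.TYPE3]
    return UOrfAnnotation(ctx, tuple(uorfs), counts, total)


# ---------------------------------------------------------------------------
# Leader planting
# ---------------------------------------------------------------------------


def _static_checks(spec: PlantSpec) -> None:
    matg = spec.leader_len
    total = matg + spec.cds_len
    if spec.cds_len < 6 or spec.cds_len % 3 != 0:
        raise InfeasibleSpecError("cds_len must be a multiple of 3 and >= 6")
    for i, p in enumerate(spec.planted):
        tag = f"planted uORF #{i} ({p.utype.value})"
        if p.utype is UOrfType.TYPE3:
            if p.uatg_pos is None and p.length_nt is None:
                raise InfeasibleSpecError(f"{tag}: needs uatg_pos or length_nt")
            continue
        if p.length_nt is None:
            raise InfeasibleSpecError(f"{tag}: length_nt required")
        if p.length_nt % 3 != 0:
            raise InfeasibleSpecError(f"{tag}: length {p.length_nt} not a multiple of 3")
        if p.length_nt < 6:
            raise InfeasibleSpecError(f"{tag}: length below minimal start+stop (6)")
        if p.utype is UOrfType.TYPE1 and p.length_nt > matg:
            raise InfeasibleSpecError(f"{tag}: length {p.length_nt} exceeds leader")
        if p.utype is UOrfType.TYPE2 and p.length_nt > total - 3:
            raise InfeasibleSpecError(f"{tag}: length {p.length_nt} exceeds transcript")
        if p.uatg_pos is not None and not (0 <= p.uatg_pos < matg):
            raise InfeasibleSpecError(f"{tag}: uatg_pos outside leader")


def _choose_positions(spec: PlantSpec, rng: random.Random) -> list[tuple[int, int, UOrfType]] | None:
    """Pick (uatg, stop_start, utype) per entry or None if the draw fails."""
    matg = spec.leader_len
    total = matg + spec.cds_len
    chosen: list[tuple[int, int, UOrfType]] = []
    used: set[int] = set()
    for i, p in enumerate(spec.planted):
        if p.utype is UOrfType.TYPE1:
            lo, hi = 0, matg - p.length_nt
        elif p.utype is UOrfType.TYPE2:
            # stop must land inside the mORF but before its final stop codon
            lo = max(0, matg - p.length_nt + 4)
            hi = min(matg - 3, total - 3 - p.length_nt)
        else:  # TYPE3
            if p.uatg_pos is not None:
                lo = hi = p.uatg_pos
            else:
                pos = total - p.length_nt
                lo = hi = pos
        if p.uatg_pos is not None:
            lo = hi = p.uatg_pos
        if lo > hi or lo < 0:
            return None
        for _ in range(20):
            u = rng.randint(lo, hi)
            if p.utype is UOrfType.TYPE2 and u % 3 == matg % 3:
                continue
            if p.utype is UOrfType.TYPE3 and u % 3 != matg % 3:
                return None
            if u not in used:
                break
        else:
            return None
        used.add(u)
        if p.utype is UOrfType.TYPE3:
            stop = total - 3
        else:
            stop = u + (p.length_nt or 0) - 3
        chosen.append((u, stop, p.utype))
    return chosen


def plant_leader(spec: PlantSpec) -> TruthBundle:
    """Rejection/backtracking sampler realizing a :class:`PlantSpec`.

    Each uATG and (for complete types) its stop codon are written into a
    transcript template; remaining bases are filled left-to-right from
    letters that neither create an unplanned ATG (sense strand, leader plus
    a 30-nt CDS prefix window, when ``forbid_stray_atg``) nor a premature
    stop in any planted frame or in the CDS frame.  Every candidate is then
    validated against the brute-force oracle; failures are resampled up to
    ``max_attempts`` before an :class:`InfeasibleSpecError` is raised.
    """
    _static_checks(spec)
    master = random.Random(spec.seed)
    matg = spec.leader_len
    total = matg + spec.cds_len

    for _ in range(spec.max_attempts):
        rng = random.Random(master.getrandbits(31))
        chosen = _choose_positions(spec, rng)
        if chosen is None:
            continue
        cells: list[str | None] = [None] * total

        def write(pos: int, s: str) -> bool:
            for k, ch in enumerate(s):
                cur = cells[pos + k]
                if cur is not None and cur != ch:
                    return False
            for k, ch in enumerate(s):
                cells[pos + k] = ch
            return True

        ok = write(matg, "ATG") and write(total - 3, "TAA")
        planted_starts = {u for u, _, _ in chosen}
        for u, stop, utype in chosen:
            ok = ok and write(u, "ATG")
            if not ok:
                break
            if utype is not UOrfType.TYPE3:
                for codon in rng.sample(STOPS, 3):
                    saved = cells[stop : stop + 3]
                    if write(stop, codon):
                        break
                    cells[stop : stop + 3] = saved
                else:
                    ok = False
                    break
        if not ok:
            continue

        # Codon positions that must never read as a stop: every in-frame
        # codon strictly before each planted stop, and the CDS interior.
        guarded: set[int] = set()
        for u, stop, _ in chosen:
            guarded.update(range(u + 3, stop, 3))
        guarded.update(range(matg + 3, total - 3, 3))

        allowed_atg = planted_starts | {matg}
        stray_limit = min(matg + 30, total - 2) if spec.forbid_stray_atg else 0

        def window_ok(w: int) -> bool:
            if w < 0 or w >= stray_limit or w in allowed_atg:
                return True
            tri = cells[w : w + 3]
            return None in tri or "".join(tri) != "ATG"  # type: ignore[arg-type]

        def codon_ok(q: int) -> bool:
            tri = cells[q : q + 3]
            return None in tri or "".join(tri) not in STOPS  # type: ignore[arg-type]

        ok = all(window_ok(w) for w in range(stray_limit)) and all(
            codon_ok(q) for q in guarded
        )
        if not ok:
            continue

        for i in range(total):
            if cells[i] is not None:
                continue
            for letter in rng.sample(BASES, 4):
                cells[i] = letter
                if all(window_ok(w) for w in (i - 2, i - 1, i)) and all(
                    codon_ok(q) for q in (i - 2, i - 1, i) if q in guarded
                ):
                    break
                cells[i] = None
            if cells[i] is None:
                ok = False
                break
        if not ok:
            continue

        transcript = "".join(cells)  # type: ignore[arg-type]
        leader, cds = transcript[:matg], transcript[matg:]

        # Enforced truth: validate against the oracle, never assume.
        recs = {r["uatg"]: r for r in oracle_scan(transcript, matg)}
        if spec.forbid_stray_atg:
            strays = [p for p in recs if p not in planted_starts]
            strays += [
                w for w in range(matg + 1, stray_limit)
                if transcript[w : w + 3] == "ATG"
            ]
            if strays:
                continue
        realized: list[UOrf] = []
        good = True
        for (u, stop, utype), p in zip(chosen, spec.planted):
            r = recs.get(u)
            if r is None or r["utype"] is not utype or r["stop_start"] != stop:
                good = False
                break
            realized.append(
                UOrf(u, r["stop_start"], r["stop_end"], r["length"], r["utype"],
                     u % 3, r["in_frame"])
            )
        if not good:
            continue

        ctx = LeaderContext(spec.transcript_id, leader, cds)
        truth = oracle_annotation(ctx)
        return TruthBundle(ctx, truth, tuple(realized))

    raise InfeasibleSpecError(
        f"could not realize spec within {spec.max_attempts} attempts "
        f"(leader_len={spec.leader_len}, planted={len(spec.planted)})"
    )


# ---------------------------------------------------------------------------
# Edit patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EditPattern:
    """Named edit-outcome profile.

    kind:
      * ``preserve_all_uatg`` — lesions placed so no uATG is destroyed or
        created (default lesions: a 29-bp deletion plus a 4-bp insertion).
      * ``disrupt_k_uatg`` — exactly ``k`` uATGs destroyed, none created;
        optional deletion ``lesions`` sizes (first ``k`` cover the targets).
      * ``convert_to_type3`` — the stop of an in-frame uORF (and any other
        stop in its frame) is substituted away so it shares the mORF stop;
        ``k`` additional uATGs may be disrupted.
      * ``convert_to_type2`` — a frameshifting deletion inside a Type-1 uORF
        body pushes its stop into the mORF.
      * ``lesion_sizes`` — bare lesions with no uATG constraints.
    """

    kind: str
    k: int = 0
    lesions: tuple = ()
    #: for ``preserve_all_uatg``: additionally require unchanged counts and
    #: no type transitions (lesions are then confined to uORF-free regions,
    #: e.g. the 5'-proximal segment upstream of the first uATG)
    preserve_types: bool = False


SAFE_CODONS = ("CTC", "CCT", "TCC", "CAC", "CTT", "GCC", "CCA")


def _overlaps(span: tuple[int, int], spans: list[tuple[int, int]], pad: int = 0) -> bool:
    s, e = span
    return any(s - pad < e2 and s2 < e + pad for s2, e2 in spans)


def _neutral_spot(rng: random.Random, truth: TruthBundle, size: int,
                  taken: list[tuple[int, int]], avoid_bodies: bool = False) -> int | None:
    """A leader start for a size-long span avoiding uATG codons and edits.

    With ``avoid_bodies`` the whole uORF spans are off limits, so lesions
    can only land in uORF-free leader segments and cannot reshape any uORF.
    """
    matg = truth.context.matg_pos
    if avoid_bodies:
        protected = [
            (u.uatg_pos, u.stop_end if u.stop_end is not None else matg)
            for u in truth.truth_annotation.uorfs
        ]
    else:
        protected = [(u, u + 3) for u in truth.truth_annotation.uatg_positions()]
    for _ in range(200):
        s = rng.randint(0, matg - size)
        if not _overlaps((s, s + size), protected) and not _overlaps((s, s + size), taken, pad=1):
            return s
    return None


def _place_lesions(rng: random.Random, truth: TruthBundle, lesions,
                   taken: list[tuple[int, int]], avoid_bodies: bool = False) -> list[Edit] | None:
    edits: list[Edit] = []
    for item in lesions:
        kind, size = item if isinstance(item, tuple) else ("DEL", item)
        if kind == "DEL":
            s = _neutral_spot(rng, truth, size, taken, avoid_bodies)
            if s is None:
                return None
            edits.append(Edit(EditKind.DEL, s, del_len=size))
            taken.append((s, s + size))
        elif kind == "INS":
            s = _neutral_spot(rng, truth, 1, taken, avoid_bodies)
            if s is None:
                return None
            alt = "".join(rng.choice("CT") for _ in range(size))
            edits.append(Edit(EditKind.INS, s, alt_seq=alt))
            taken.append((s, s + 1))
        else:
            raise InfeasibleSpecError(f"unknown lesion kind {kind!r}")
    return edits


def simulate_edit_pattern(truth: TruthBundle, pattern: EditPattern,
                          seed: int | None = None,
                          config: ScanConfig = ScanConfig(),
                          max_tries: int = 200) -> list[Edit]:
    """Edits realizing ``pattern`` on a planted leader, verified before return."""
    rng = random.Random(seed)
    ctx = truth.context
    uatgs = list(truth.truth_annotation.uatg_positions())
    by_pos = {u.uatg_pos: u for u in truth.truth_annotation.uorfs}
    matg = ctx.matg_pos

    for _ in range(max_tries):
        taken: list[tuple[int, int]] = []
        edits: list[Edit] | None = None
        want = None  # predicate on the DeltaReport

        if pattern.kind == "preserve_all_uatg":
            lesions = pattern.lesions or (("DEL", 29), ("INS", 4))
            edits = _place_lesions(rng, truth, lesions, taken,
                                   avoid_bodies=pattern.preserve_types)
            if pattern.preserve_types:
                want = (
                    lambda d: d.n_destroyed == 0 and d.n_created == 0
                    and d.counts_before == d.counts_after
                    and not d.type_transitions
                )
            else:
                want = lambda d: d.n_destroyed == 0 and d.n_created == 0

        elif pattern.kind == "disrupt_k_uatg":
            if pattern.k > len(uatgs):
                raise InfeasibleSpecError("k exceeds number of planted uATGs")
            targets = rng.sample(uatgs, pattern.k)
            edits = []
            sizes = list(pattern.lesions[: pattern.k]) or []
            for j, u in enumerate(targets):
                size = sizes[j] if j < len(sizes) else 5
                size = size if isinstance(size, int) else size[1]
                lo = max(0, u + 3 - size)
                s = rng.randint(lo, min(u, matg - size))
                if _overlaps((s, s + size), taken, pad=1):
                    edits = None
                    break
                edits.append(Edit(EditKind.DEL, s, del_len=size))
                taken.append((s, s + size))
            if edits is not None and len(pattern.lesions) > pattern.k:
                extra = _place_lesions(rng, truth, pattern.lesions[pattern.k :], taken)
                edits = None if extra is None else edits + extra
            k = pattern.k
            want = lambda d: d.n_destroyed == k and d.n_created == 0

        elif pattern.kind in ("convert_to_type3", "convert_to_type2"):
            to3 = pattern.kind == "convert_to_type3"
            # For the Type-3 conversion the edit is pure substitution, so the
            # uORF must already be in frame with the mORF; a frameshifting
            # deletion (Type-2 conversion) moves the mATG frame itself, so no
            # pre-edit frame requirement applies there.
            cands = [
                u for u in uatgs
                if by_pos[u].utype is UOrfType.TYPE1
                and (not to3 or u % 3 == matg % 3)
                and (to3 or by_pos[u].length_nt >= 12)
            ]
            if not cands:
                raise InfeasibleSpecError(
                    f"no Type-1 uORF eligible for {pattern.kind}"
                )
            target = rng.choice(cands)
            edits = []
            if to3:
                seq = ctx.transcript_seq
                for q in range(target + 3, matg - 2, 3):
                    if seq[q : q + 3] in STOPS:
                        codon = rng.choice(SAFE_CODONS)
                        edits.append(Edit(EditKind.SUB, q, alt_seq=codon))
                        taken.append((q, q + 3))
                others = [u for u in uatgs if u != target]
                targets = rng.sample(others, pattern.k) if pattern.k else []
                for u in targets:
                    s = max(0, u - 1)
                    if _overlaps((s, s + 5), taken, pad=1):
                        edits = None
                        break
                    edits.append(Edit(EditKind.DEL, s, del_len=5))
                    taken.append((s, s + 5))
                k = pattern.k
                tgt = target
                want = (
                    lambda d: d.n_created == 0 and d.n_destroyed == k
                    and any(t[0] == tgt and t[2] is UOrfType.TYPE3
                            for t in d.type_transitions)
                )
            else:
                stop_start = by_pos[target].stop_start
                size = 5
                if stop_start - (target + 3) < size:
                    edits = None
                else:
                    s = rng.randint(target + 3, stop_start - size)
                    edits.append(Edit(EditKind.DEL, s, del_len=size))
                    tgt = target
                    want = (
                        lambda d: d.n_created == 0 and d.n_destroyed == 0
                        and any(t[0] == tgt and t[2] is UOrfType.TYPE2
                                for t in d.type_transitions)
                    )

        elif pattern.kind == "lesion_sizes":
            edits = _place_lesions(rng, truth, pattern.lesions, taken)
            want = lambda d: True

        else:
            raise InfeasibleSpecError(f"unknown pattern kind {pattern.kind!r}")

        if edits is None:
            continue
        if not edits:
            return []
        try:
            _, _, delta = predict_edit_outcome(ctx, edits, config)
        except EditError:
            continue
        if want(delta):
            return edits

    raise InfeasibleSpecError(
        f"pattern {pattern.kind!r} unsatisfiable on this leader "
        f"within {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# Clone and quantification table simulators
# ---------------------------------------------------------------------------


def simulate_clones(
    alleles: list[tuple[str, str]],
    proportions: list[float],
    n_clones: int,
    error_rate: float = 0.001,
    seed: int | None = None,
) -> list[Clone]:
    """Clones drawn from an allele mixture with per-base substitution noise.

    Clone counts follow the proportions by largest-remainder allocation (so
    small clone sets honour the mixture exactly), then the clone order is
    shuffled.  ``error_rate`` must lie in [0, 0.02].
    """
    if not math.isclose(sum(proportions), 1.0, abs_tol=1e-9):
        raise ValueError("proportions must sum to 1")
    if not 0.0 <= error_rate <= 0.02:
        raise ValueError("error_rate outside [0, 0.02]")
    rng = random.Random(seed)

    quotas = [p * n_clones for p in proportions]
    counts = [int(q) for q in quotas]
    rem = n_clones - sum(counts)
    order = sorted(range(len(quotas)), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1

    assignment = [i for i, c in enumerate(counts) for _ in range(c)]
    rng.shuffle(assignment)

    clones: list[Clone] = []
    for j, i in enumerate(assignment):
        allele_id, seq = alleles[i]
        bases = list(seq)
        for k in range(len(bases)):
            if rng.random() < error_rate:
                bases[k] = rng.choice([b for b in BASES if b != bases[k]])
        clones.append(Clone(f"clone_{j + 1:02d}", "".join(bases), allele_id))
    return clones


#: Study-condition defaults.  TTA totals are the printed values; the control
#: per-analyte split (fractions of TTA) is synthetic plumbing.
DEFAULT_TTA = {"CK": 2.85, "Del1": 3.39, "Del2": 5.11, "Del3": 5.15, "Del4": 2.85}
CK_ANALYTE_FRACTIONS = {"TanI": 0.16, "TanIIA": 0.42, "CPT": 0.28, "DHT": 0.14}
DEFAULT_GENE_FOLDS = {
    "SmCPS1": 1.0,
    "SmHMGR1": 1.96,
    "SmKSL1": 2.22,
    "SmCYP76AH1": 4.83,
    "SmCYP76AH3": 2.76,
    "SmIPPI": 2.35,
}


def simulate_expression_tables(
    gene_folds: dict[str, float] | None = None,
    tta_by_line: dict[str, float] | None = None,
    ct_sd: float = 0.1,
    analyte_cv: float = 0.05,
    n_bio: int = 3,
    n_tech: int = 3,
    n_met_reps: int = 3,
    seed: int | None = None,
    reference_gene: str = "SmActin",
    ck_line: str = "CK",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct and metabolite tables with planted effects.

    Ct values satisfy the planted fold under the 2^-ddCt model in
    expectation: treatment target Ct = base - log2(fold), with Gaussian
    noise of sd ``ct_sd`` per well.  Metabolite concentrations are the line
    TTA split by the control analyte fractions, under mean-one lognormal
    noise of coefficient ``analyte_cv``.
    """
    gene_folds = DEFAULT_GENE_FOLDS if gene_folds is None else gene_folds
    tta_by_line = DEFAULT_TTA if tta_by_line is None else tta_by_line
    if any(f <= 0 for f in gene_folds.values()):
        raise ValueError("folds must be positive")
    if ct_sd < 0 or analyte_cv < 0:
        raise ValueError("noise parameters must be non-negative")
    rng = random.Random(seed)

    ref_base, tgt_base = 19.0, 24.0
    ct_rows = []
    for cond in ("calibrator", "treatment"):
        for b in range(1, n_bio + 1):
            sample = f"{cond}_s{b}"
            for gene, fold in gene_folds.items():
                ideal = tgt_base - (math.log2(fold) if cond == "treatment" else 0.0)
                for t in range(1, n_tech + 1):
                    ct_rows.append(
                        dict(sample_id=sample, gene=gene, role="target",
                             condition=cond, replicate=t,
                             ct=ideal + rng.gauss(0.0, ct_sd))
                    )
            for t in range(1, n_tech + 1):
                ct_rows.append(
                    dict(sample_id=sample, gene=reference_gene,
                         role="reference_gene", condition=cond, replicate=t,
                         ct=ref_base + rng.gauss(0.0, ct_sd))
                )
    ct_df = pd.DataFrame(ct_rows)

    met_rows = []
    for line, tta in tta_by_line.items():
        for analyte, frac in CK_ANALYTE_FRACTIONS.items():
            conc = tta * frac
            for r in range(1, n_met_reps + 1):
                noise = math.exp(rng.gauss(0.0, analyte_cv) - analyte_cv**2 / 2.0)
                met_rows.append(
                    dict(line_id=line, analyte=analyte,
                         mg_per_g_dw=conc * noise, replicate=r)
                )
    met_df = pd.DataFrame(met_rows)
    _ = ck_line
    return ct_df, met_df
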