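"""CRISPR-style edit application and uORF landscape comparison.

Edits (deletions, insertions, substitutions) are expressed in reference
coordinates and applied as if simultaneous: spans must be pairwise
non-overlapping and are applied in descending position order so earlier
coordinates stay valid.  A coordinate map from surviving reference positions
to edited positions supports tracking of individual uATGs across alleles.

A reference uATG *survives* an edit set when its three bases map, un-deleted
and consecutively, into the edited allele and still read ATG there — a
substitution that leaves (or re-creates) an ATG therefore counts as
surviving, because only the resulting sequence matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .annotate import (
    AnnotationError,
    LeaderContext,
    ScanConfig,
    UOrfAnnotation,
    UOrfType,
    annotate_leader,
)


class EditError(ValueError):
    """Raised for malformed, overlapping, or integrity-breaking edit sets."""


class EditKind(str, Enum):
    DEL = "DEL"
    INS = "INS"
    SUB = "SUB"


@dataclass(frozen=True, order=True)
class Edit:
    """One indel/substitution.

    ``pos`` is the 0-based reference position of the first affected base
    (for INS, the base before which the insertion occurs).
    """

    kind: EditKind
    pos: int
    del_len: int = 0
    alt_seq: str = ""

    def __post_init__(self) -> None:
        if self.kind is EditKind.DEL and self.del_len < 1:
            raise EditError("DEL requires del_len >= 1")
        if self.kind is EditKind.INS and len(self.alt_seq) < 1:
            raise EditError("INS requires a non-empty alt_seq")
        if self.kind is EditKind.SUB and len(self.alt_seq) < 1:
            raise EditError("SUB requires a non-empty alt_seq")
        if self.pos < 0:
            raise EditError("negative edit position")

    @property
    def span(self) -> tuple[int, int]:
        """Affected reference half-open interval (zero-width for INS)."""
        if self.kind is EditKind.DEL:
            return (self.pos, self.pos + self.del_len)
        if self.kind is EditKind.SUB:
            return (self.pos, self.pos + len(self.alt_seq))
        return (self.pos, self.pos)

    @property
    def net_length_change(self) -> int:
        if self.kind is EditKind.DEL:
            return -self.del_len
        if self.kind is EditKind.INS:
            return len(self.alt_seq)
        return 0


@dataclass(frozen=True)
class EditedAllele:
    allele_id: str
    seq: str
    edits: tuple[Edit, ...]
    net_length_change: int
    coord_map: dict[int, int]  # surviving (non-deleted) ref pos -> edited pos


@dataclass(frozen=True)
class DeltaReport:
    """Before/after comparison of the uORF landscape of two alleles."""

    counts_before: dict[UOrfType, int]
    counts_after: dict[UOrfType, int]
    total_before: int
    total_after: int
    percent_change_total: float | None
    uatgs_destroyed: tuple[int, ...]  # reference coordinates
    uatgs_created: tuple[int, ...]  # edited-allele coordinates
    type_transitions: tuple[tuple[int, UOrfType, UOrfType], ...]

    @property
    def n_destroyed(self) -> int:
        return len(self.uatgs_destroyed)

    @property
    def n_created(self) -> int:
        return len(self.uatgs_created)


def _check_overlap(edits: list[Edit]) -> None:
    spans = sorted((e.span, e) for e in edits)
    for ((s1, e1), a), ((s2, e2), b) in zip(spans, spans[1:]):
        # Zero-width INS spans may abut other spans but two INS at the same
        # position are ambiguous under simultaneous semantics.
        if s2 < e1 or (s1 == s2 and e1 == e2 == s1):
            raise EditError(f"overlapping edit spans: {a} and {b}")


def apply_edits(reference: str, edits: list[Edit], allele_id: str = "edited") -> EditedAllele:
    """Apply a pairwise non-overlapping edit set to ``reference``.

    Edits are simultaneous in reference coordinates (implementation: sorted
    by descending position).  ``coord_map`` is defined for every reference
    position that is not deleted; substituted positions remain mapped so the
    surviving-uATG rule can inspect the resulting sequence.
    """
    for e in edits:
        s, t = e.span
        if t > len(reference) or s > len(reference):
            raise EditError(f"edit {e} outside reference of length {len(reference)}")
    _check_overlap(list(edits))

    seq = reference
    # Descending positions keep earlier coordinates valid; at equal positions
    # the DEL/SUB must precede the INS or the insertion would be clobbered.
    order = sorted(edits, key=lambda e: (-e.pos, 0 if e.kind is not EditKind.INS else 1))
    for e in order:
        if e.kind is EditKind.DEL:
            seq = seq[: e.pos] + seq[e.pos + e.del_len :]
        elif e.kind is EditKind.INS:
            seq = seq[: e.pos] + e.alt_seq + seq[e.pos :]
        else:
            seq = seq[: e.pos] + e.alt_seq + seq[e.pos + len(e.alt_seq) :]

    deleted = set()
    ins_at: dict[int, int] = {}
    for e in edits:
        if e.kind is EditKind.DEL:
            deleted.update(range(e.pos, e.pos + e.del_len))
        elif e.kind is EditKind.INS:
            ins_at[e.pos] = ins_at.get(e.pos, 0) + len(e.alt_seq)

    coord_map: dict[int, int] = {}
    shift = 0
    for p in range(len(reference)):
        shift += ins_at.get(p, 0)
        if p in deleted:
            shift -= 1
            continue
        coord_map[p] = p + shift

    net = sum(e.net_length_change for e in edits)
    assert len(seq) == len(reference) + net
    return EditedAllele(allele_id, seq, tuple(edits), net, coord_map)


def _surviving_image(uatg_pos: int, allele: EditedAllele) -> int | None:
    """Edited-allele position of a surviving reference uATG, else None."""
    cm = allele.coord_map
    if not all(uatg_pos + i in cm for i in range(3)):
        return None
    p0, p1, p2 = (cm[uatg_pos + i] for i in range(3))
    if p1 != p0 + 1 or p2 != p0 + 2:
        return None
    if allele.seq[p0 : p0 + 3] != "ATG":
        return None
    return p0


def diff_annotations(
    before: UOrfAnnotation,
    after: UOrfAnnotation,
    allele: EditedAllele,
) -> DeltaReport:
    """Compare two annotations of the same transcript through the edit map.

    ``destroyed``: reference uATGs with no surviving image among the edited
    allele's uATGs; ``created``: edited-allele uATGs with no reference
    preimage.  Type transitions are recorded only where the type changed.
    """
    after_positions = set(after.uatg_positions())
    after_by_pos = {u.uatg_pos: u for u in after.uorfs}

    destroyed: list[int] = []
    survived_images: set[int] = set()
    transitions: list[tuple[int, UOrfType, UOrfType]] = []
    for u in before.uorfs:
        img = _surviving_image(u.uatg_pos, allele)
        if img is None or img not in after_positions:
            destroyed.append(u.uatg_pos)
            continue
        survived_images.add(img)
        if after_by_pos[img].utype is not u.utype:
            transitions.append((u.uatg_pos, u.utype, after_by_pos[img].utype))

    created = sorted(after_positions - survived_images)

    tb, ta = before.total_complete, after.total_complete
    pct = 100.0 * (ta - tb) / tb if tb > 0 else None
    return DeltaReport(
        counts_before=dict(before.counts_by_type),
        counts_after=dict(after.counts_by_type),
        total_before=tb,
        total_after=ta,
        percent_change_total=pct,
        uatgs_destroyed=tuple(destroyed),
        uatgs_created=tuple(created),
        type_transitions=tuple(transitions),
    )


def predict_edit_outcome(
    ctx: LeaderContext,
    edits: list[Edit],
    config: ScanConfig = ScanConfig(),
    allow_cds_edits: bool = False,
    allele_id: str = "edited",
) -> tuple[LeaderContext, UOrfAnnotation, DeltaReport]:
    """Apply edits to a transcript and report the uORF landscape delta.

    Edits must stay within the leader unless ``allow_cds_edits`` is set; the
    edited CDS must still be a valid ORF (starts ATG, multiple of 3, stop at
    the end), otherwise an integrity error is raised.
    """
    matg = ctx.matg_pos
    for e in edits:
        s, t = e.span
        boundary = matg if e.kind is EditKind.INS else matg
        if not allow_cds_edits and (t > boundary or s > boundary):
            raise EditError(f"edit {e} reaches into the CDS (mATG at {matg})")

    allele = apply_edits(ctx.transcript_seq, edits, allele_id)
    new_matg = _surviving_image(matg, allele)
    if new_matg is None:
        raise EditError("edit set destroys the main start codon")

    edited_leader = allele.seq[:new_matg]
    edited_cds = allele.seq[new_matg:]
    try:
        edited_ctx = LeaderContext(f"{ctx.transcript_id}|{allele_id}", edited_leader, edited_cds)
    except AnnotationError as exc:
        raise EditError(f"edited allele breaks CDS integrity: {exc}") from exc

    before = annotate_leader(ctx, config)
    after = annotate_leader(edited_ctx, config)
    delta = diff_annotations(before, after, allele)
    return edited_ctx, after, delta
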