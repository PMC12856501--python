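"""Upstream ORF detection and classification in 5' leader sequences.

A transcript is modelled as ``leader + CDS``; every ATG strictly upstream of
the main start codon (mATG) opens an upstream ORF (uORF) that is extended
codon by codon until the first in-frame stop.  Classification follows the
standard positional scheme:

* **TYPE1** (non-overlapping): the uORF stop lies at or before the mATG.
* **TYPE2** (out-of-frame overlapping): the stop falls inside the main ORF
  while the uORF reads in a different frame.
* **TYPE3** (N-terminal extension): the uATG is in frame with the mATG and no
  stop intervenes, so the uORF shares the main ORF's stop codon.
* **INCOMPLETE**: an out-of-frame uORF that never reaches a stop codon before
  the end of the transcript.

Coordinates are 0-based half-open internally; report writers emit 1-based
inclusive positions.  ``N`` bases never form a start or a stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_VALID_BASES = frozenset("ACGTN")


class AnnotationError(ValueError):
    """Raised for malformed sequences or out-of-contract scan requests."""


class UOrfType(str, Enum):
    TYPE1 = "TYPE1"
    TYPE2 = "TYPE2"
    TYPE3 = "TYPE3"
    INCOMPLETE = "INCOMPLETE"


def _check_sequence(seq: str, what: str = "sequence") -> None:
    for i, base in enumerate(seq):
        if base not in _VALID_BASES:
            raise AnnotationError(
                f"invalid character {base!r} at position {i} in {what}"
            )


@dataclass(frozen=True)
class LeaderContext:
    """A transcript model: 5' leader plus CDS, fixing the mATG position."""

    transcript_id: str
    leader_seq: str
    cds_seq: str

    def __post_init__(self) -> None:
        _check_sequence(self.leader_seq, "leader_seq")
        _check_sequence(self.cds_seq, "cds_seq")
        if not self.cds_seq.startswith("ATG"):
            raise AnnotationError("cds_seq must begin with ATG")
        if len(self.cds_seq) % 3 != 0 or len(self.cds_seq) == 0:
            raise AnnotationError("cds_seq length must be a positive multiple of 3")
        if self.cds_seq[-3:] not in STOP_CODONS:
            raise AnnotationError("cds_seq must end with a stop codon (TAA/TAG/TGA)")

    @property
    def transcript_seq(self) -> str:
        return self.leader_seq + self.cds_seq

    @property
    def matg_pos(self) -> int:
        """0-based transcript index of the main ORF's A of ATG."""
        return len(self.leader_seq)


@dataclass(frozen=True)
class UOrf:
    """One upstream ORF located at ``uatg_pos`` on the transcript."""

    uatg_pos: int
    stop_start: int | None
    stop_end: int | None
    length_nt: int | None  # uATG through stop codon inclusive; None if incomplete
    utype: UOrfType
    frame_offset: int
    in_frame_with_morf: bool

    @property
    def complete(self) -> bool:
        return self.utype is not UOrfType.INCOMPLETE


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters.

    ``min_length_nt`` defaults to 6 (start + stop, no intervening codon), the
    smallest possible complete uORF, so nothing is dropped by default.
    """

    min_length_nt: int = 6
    include_incomplete: bool = False
    stop_codons: frozenset[str] = STOP_CODONS

    def __post_init__(self) -> None:
        if self.min_length_nt < 6 or self.min_length_nt % 3 != 0:
            raise AnnotationError("min_length_nt must be >= 6 and a multiple of 3")


@dataclass(frozen=True)
class UOrfAnnotation:
    """Full per-transcript uORF annotation with counts by type."""

    context: LeaderContext
    uorfs: tuple[UOrf, ...]
    counts_by_type: dict[UOrfType, int]
    total_complete: int

    def uatg_positions(self) -> tuple[int, ...]:
        return tuple(u.uatg_pos for u in self.uorfs)


def find_start_codons(seq: str, region_end: int) -> list[int]:
    """Every position ``p < region_end`` where ``seq[p:p+3] == "ATG"``.

    The codon may extend past ``region_end`` but not past the end of ``seq``.
    ``N`` never matches.
    """
    _check_sequence(seq)
    if region_end > len(seq):
        raise AnnotationError("region_end beyond end of sequence")
    limit = min(region_end, len(seq) - 2)
    return [p for p in range(max(limit, 0)) if seq[p : p + 3] == "ATG"]


def scan_uorf(ctx: LeaderContext, uatg_pos: int, config: ScanConfig = ScanConfig()) -> UOrf:
    """Extend the uORF at ``uatg_pos`` to its first in-frame stop and classify it."""
    matg = ctx.matg_pos
    if uatg_pos >= matg:
        raise AnnotationError(
            f"uatg_pos {uatg_pos} is not upstream of the mATG at {matg}"
        )
    seq = ctx.transcript_seq
    if seq[uatg_pos : uatg_pos + 3] != "ATG":
        raise AnnotationError(f"no ATG at position {uatg_pos}")

    in_frame = (uatg_pos % 3) == (matg % 3)
    stop_start: int | None = None
    for p in range(uatg_pos + 3, len(seq) - 2, 3):
        if seq[p : p + 3] in config.stop_codons:
            stop_start = p
            break

    if stop_start is None:
        # An in-frame scan always terminates at the CDS stop; reaching here
        # means the uORF runs off the transcript out of frame.
        return UOrf(uatg_pos, None, None, None, UOrfType.INCOMPLETE,
                    uatg_pos % 3, in_frame)

    stop_end = stop_start + 3
    length_nt = stop_end - uatg_pos
    if stop_end <= matg:
        utype = UOrfType.TYPE1
    elif in_frame:
        utype = UOrfType.TYPE3
    else:
        utype = UOrfType.TYPE2
    return UOrf(uatg_pos, stop_start, stop_end, length_nt, utype,
                uatg_pos % 3, in_frame)


def annotate_leader(ctx: LeaderContext, config: ScanConfig = ScanConfig()) -> UOrfAnnotation:
    """Annotate every uORF whose uATG lies strictly upstream of the mATG.

    Overlapping and nested uORFs are all retained.  Complete uORFs shorter
    than ``config.min_length_nt`` are excluded from the listing and the
    counts; INCOMPLETE uORFs are always tallied in ``counts_by_type`` but
    listed only when ``config.include_incomplete`` is set.
    """
    counts = {t: 0 for t in UOrfType}
    kept: list[UOrf] = []
    for pos in find_start_codons(ctx.transcript_seq, ctx.matg_pos):
        u = scan_uorf(ctx, pos, config)
        if u.complete:
            if u.length_nt is not None and u.length_nt < config.min_length_nt:
                continue
            counts[u.utype] += 1
            kept.append(u)
        else:
            counts[UOrfType.INCOMPLETE] += 1
            if config.include_incomplete:
                kept.append(u)
    total = counts[UOrfType.TYPE1] + counts[UOrfType.TYPE2] + counts[UOrfType.TYPE3]
    return UOrfAnnotation(ctx, tuple(kept), counts, total)
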