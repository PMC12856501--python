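"""SpCas9 protospacer enumeration and uATG-proximity ranking.

Candidates are 20-nt protospacers immediately 5' of an NGG PAM on either
strand.  The predicted cut is the canonical SpCas9 blunt cut 3 nt 5' of the
PAM, i.e. between protospacer bases 17 and 18; ``cut_pos`` is reported as the
reference index of the first base 3' of the cut (a boundary coordinate).
Ranking follows the strategy of placing cuts adjacent to uORF start codons:
ascending distance between the cut and the nearest uATG first base, with
deterministic tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GuideCandidate:
    protospacer: str  # 5'->3' on its strand
    strand: str  # '+' or '-'
    pam: str  # as read 5'->3' on the guide strand (NGG)
    pam_start: int  # reference position of the PAM's leftmost base
    cut_pos: int  # reference boundary coordinate of the blunt cut
    gc_fraction: float
    dist_to_nearest_uatg: int | None = None

    def with_distance(self, uatg_positions: list[int]) -> "GuideCandidate":
        d = min(abs(self.cut_pos - u) for u in uatg_positions)
        return GuideCandidate(self.protospacer, self.strand, self.pam,
                              self.pam_start, self.cut_pos, self.gc_fraction, d)


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def enumerate_protospacers(seq: str) -> list[GuideCandidate]:
    """All 20-mers immediately 5' of an NGG on either strand.

    Minus-strand candidates report the reverse-complement protospacer with
    coordinates on the reference.  Windows containing ``N`` are skipped.  A
    sequence shorter than 23 nt yields an empty result.
    """
    out: list[GuideCandidate] = []
    n = len(seq)
    # Plus strand: protospacer [i, i+20), PAM [i+20, i+23) == NGG.
    for i in range(0, n - 22):
        pam = seq[i + 20 : i + 23]
        proto = seq[i : i + 20]
        if pam[1:] == "GG" and "N" not in proto and "N" not in pam:
            out.append(GuideCandidate(proto, "+", pam, i + 20, i + 17, _gc(proto)))
    # Minus strand: reference [i, i+20) read as revcomp; PAM occupies
    # reference [i-3, i) and reads NGG on the minus strand, i.e. CCN here.
    for i in range(3, n - 19):
        pam_ref = seq[i - 3 : i]
        proto_ref = seq[i : i + 20]
        if pam_ref[:2] == "CC" and "N" not in proto_ref and "N" not in pam_ref:
            out.append(
                GuideCandidate(revcomp(proto_ref), "-", revcomp(pam_ref),
                               i - 3, i + 3, _gc(proto_ref))
            )
    out.sort(key=lambda c: (c.pam_start, c.strand))
    return out


def rank_guides(
    candidates: list[GuideCandidate],
    uatg_positions: list[int],
    max_dist: int = 50,
    gc_bounds: tuple[float, float] = (0.30, 0.80),
) -> list[GuideCandidate]:
    """Filter by GC and cut-to-uATG distance, then rank.

    Sort is ascending by distance, ties broken by ascending ``cut_pos`` and
    then '+' before '-', so the ordering is deterministic.
    """
    if not uatg_positions:
        raise ValueError("uatg_positions must be non-empty")
    lo, hi = gc_bounds
    kept = [c.with_distance(list(uatg_positions)) for c in candidates]
    kept = [
        c
        for c in kept
        if lo <= c.gc_fraction <= hi and c.dist_to_nearest_uatg <= max_dist
    ]
    kept.sort(key=lambda c: (c.dist_to_nearest_uatg, c.cut_pos, c.strand != "+"))
    return kept


def locate_guide(reference: str, protospacer: str) -> list[tuple[int, str, bool]]:
    """Exact matches of a 20-nt protospacer on either strand of ``reference``.

    Returns ``(position, strand, pam_ok)`` with ``position`` the reference
    index of the match's leftmost base and ``pam_ok`` flagging an adjacent
    NGG on the guide's strand.
    """
    if len(protospacer) != 20:
        raise ValueError("protospacer must be 20 nt")
    hits: list[tuple[int, str, bool]] = []
    rc = revcomp(protospacer)
    for i in range(len(reference) - 19):
        window = reference[i : i + 20]
        if window == protospacer:
            pam = reference[i + 20 : i + 23]
            hits.append((i, "+", len(pam) == 3 and pam[1:] == "GG"))
        if window == rc:
            pam_ref = reference[i - 3 : i] if i >= 3 else ""
            hits.append((i, "-", len(pam_ref) == 3 and pam_ref[:2] == "CC"))
    return hits
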