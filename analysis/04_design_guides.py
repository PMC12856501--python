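#!/usr/bin/env python
"""Design uATG-proximal SpCas9 guides against the CK leader.

Enumerates every 20-nt protospacer next to an NGG PAM on both strands of
the reference transcript, ranks candidates by distance from the predicted
blunt cut (3 nt 5' of the PAM) to the nearest uATG, filters on GC content,
and writes the ranked table.  The top four guides stand in for the study's
four-guide design strategy.
"""

from pathlib import Path

from uorfkit import io
from uorfkit.annotate import annotate_leader
from uorfkit.guides import enumerate_protospacers, locate_guide, rank_guides

OUT = Path("results")


def main() -> None:
    ctx = io.read_leader_context(OUT / "ck_reference.fa")
    ann = annotate_leader(ctx)
    uatgs = list(ann.uatg_positions())

    candidates = enumerate_protospacers(ctx.transcript_seq)
    ranked = rank_guides(candidates, uatgs, max_dist=50, gc_bounds=(0.30, 0.80))
    io.write_tsv(OUT / "guides_ranked.tsv", io.guides_frame(ranked), io.provenance())

    print(f"{len(candidates)} protospacer candidates, {len(ranked)} pass "
          f"filters (GC 0.30-0.80, cut within 50 nt of a uATG)")
    for c in ranked[:4]:
        hits = locate_guide(ctx.transcript_seq, c.protospacer)
        print(f"  {c.protospacer} [{c.strand}] PAM {c.pam} cut@{c.cut_pos + 1} "
              f"dist {c.dist_to_nearest_uatg} nt, GC {c.gc_fraction:.2f}, "
              f"{len(hits)} exact site(s) in reference")


if __name__ == "__main__":
    main()
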