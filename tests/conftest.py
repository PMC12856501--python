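"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by direct substring
inspection or exhaustive recursion, independently of the library's code
paths, so tests compare two routes to the same answer.
"""

from __future__ import annotations

import random
from functools import lru_cache

import pytest
from hypothesis import settings

from uorfkit.annotate import LeaderContext, UOrfType
from uorfkit.simulate import ck_spec, plant_leader

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

STOPS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# uORF scanning oracle
# ---------------------------------------------------------------------------


def naive_uorf_scan(transcript: str, matg: int) -> list[dict]:
    """Test every leader position for ATG and every downstream triplet for
    stop membership, by direct comparison."""
    out = []
    for p in range(matg):
        if p + 3 > len(transcript) or transcript[p : p + 3] != "ATG":
            continue
        stop = None
        q = p + 3
        while q + 3 <= len(transcript):
            if transcript[q : q + 3] in STOPS:
                stop = q
                break
            q += 3
        in_frame = p % 3 == matg % 3
        if stop is None:
            out.append(dict(uatg=p, stop_end=None, length=None,
                            utype=UOrfType.INCOMPLETE, in_frame=in_frame))
        else:
            end = stop + 3
            if end <= matg:
                t = UOrfType.TYPE1
            elif in_frame:
                t = UOrfType.TYPE3
            else:
                t = UOrfType.TYPE2
            out.append(dict(uatg=p, stop_end=end, length=end - p,
                            utype=t, in_frame=in_frame))
    return out


def random_context(rng: random.Random, max_leader: int = 300,
                   with_n: bool = False) -> LeaderContext:
    """Random valid transcript: arbitrary leader + stop-free CDS body."""
    alphabet = "ACGTN" if with_n else "ACGT"
    leader = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, max_leader)))
    body = []
    for _ in range(rng.randint(1, 30)):
        while True:
            codon = "".join(rng.choice("ACGT") for _ in range(3))
            if codon not in STOPS:
                break
        body.append(codon)
    cds = "ATG" + "".join(body) + rng.choice(STOPS)
    return LeaderContext("rand", leader, cds)


# ---------------------------------------------------------------------------
# Global affine-gap alignment score oracle (exhaustive recursion)
# ---------------------------------------------------------------------------


def brute_align_score(a: str, b: str, match=2.0, mismatch=-3.0,
                      gap_open=-5.0, gap_extend=-1.0) -> float:
    """Max score over all global alignments; a length-L gap costs
    ``gap_open + L * gap_extend``."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, 0))
        if i < len(a):
            cost = gap_extend if state == 1 else gap_open + gap_extend
            best = max(best, cost + rec(i + 1, j, 1))
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open + gap_extend
            best = max(best, cost + rec(i, j + 1, 2))
        return best

    result = rec(0, 0, 0)
    rec.cache_clear()
    return result


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def ck_truth():
    """The control-leader emulation: 192 nt, five Type-1 uORFs (57/15/30/54/84)."""
    return plant_leader(ck_spec(seed=20250101))


@pytest.fixture()
def rng():
    return random.Random(1234)
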