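#!/usr/bin/env python
"""Genotype a simulated transformation cohort and summarize editing rates.

Simulates the study cohort — 93 explants yielding 30 transgenic lines
(13 heterozygous, 6 chimeric, 6 homozygous, 5 unedited) — as clone sets
(12 base-called clones per line), genotypes every clone by global
alignment and variant calling, classifies line zygosity, and writes the
cohort summary.  A separate recovery experiment repeats the genotyping
under 0.1% per-base Sanger noise.

Expected printed rates: 32.26% transformation, 83.33% editing,
43.33% / 20% / 20% heterozygous / chimeric / homozygous.
"""

from pathlib import Path

from uorfkit import io
from uorfkit.experiments import genotyping_recovery, simulated_cohort_summary

SEED = 1
OUT = Path("results")


def main() -> None:
    summary = simulated_cohort_summary(seed=SEED)
    io.write_tsv(OUT / "cohort_summary.tsv", io.cohort_frame(summary),
                 io.provenance(seed=SEED))

    s = summary
    print(f"explants {s.n_explants}, transgenic {s.n_transgenic}, "
          f"edited {s.n_edited}")
    print(f"transformation efficiency {s.transformation_efficiency_pct}%")
    print(f"editing efficiency {s.editing_efficiency_pct}%")
    print(f"heterozygous {s.heterozygous_pct}%  chimeric {s.chimeric_pct}%  "
          f"homozygous {s.homozygous_pct}%")

    rate = genotyping_recovery(n_sims=500, seed=SEED, error_rate=0.001)
    print(f"category recovery under 0.1% per-base clone noise: {rate:.1%} "
          f"(500 simulated lines)")


if __name__ == "__main__":
    main()
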