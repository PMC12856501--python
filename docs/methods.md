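# Methods

## Scanning model and conventions

A transcript is the concatenation of a 5′ leader and a CDS; the mATG
position equals the leader length. Scanning walks from each leader ATG in
steps of three across the whole transcript and stops at the first stop
codon (TAA/TAG/TGA). Classification: stop end at or before the mATG →
Type 1; beyond the mATG and out of frame → Type 2; in frame with the mATG
with no intervening stop → Type 3 (shared stop); out of frame with no stop
before the transcript end → incomplete. Frame arithmetic forbids an
in-frame stop from straddling the mATG; an out-of-frame stop whose span
crosses it classifies by its end coordinate. `N` never matches a start or
stop, and a codon containing `N` is neither.

Internally all coordinates are 0-based half-open; reports emit 1-based
inclusive positions and say so in their headers. uORF length includes the
stop codon — the published lengths are all multiples of three under either
convention, so this is fixed by decree and stated here. The default
minimum uORF length is 6 nt (start + stop), the smallest possible, so
nothing is filtered by default; incomplete uORFs are tallied in the
per-type counts but listed only on request. Overlapping and nested uORFs
are all retained. Because the CDS itself begins with ATG, no ATG window
can begin at mATG−1 or mATG−2, so "uATG strictly upstream" is the only
boundary condition needed.

## Edit semantics

Edits are DEL/INS/SUB in reference coordinates with pairwise disjoint
spans, applied as if simultaneous (implemented in descending position
order; at a shared position the DEL/SUB applies before the INS so the
insertion lands outside the removed block). Overlapping edits are an
error, not a merge — observed CRISPR alleles are discrete lesions. The
coordinate map covers every non-deleted reference position, including
substituted ones: a uATG survives when its three bases map consecutively
into the edited allele and still read ATG there, so a substitution that
rewrites but preserves (or restores) an ATG counts as surviving. Type
transitions are recorded only for surviving uATGs whose class changed.
The percent change in total counts complete uORFs (Types 1–3). Edits are
confined to the leader unless explicitly allowed into the CDS, and any
edit set that destroys the mATG or breaks CDS integrity is rejected.

## Guide design

SpCas9 candidates are every 20-mer immediately 5′ of an NGG on either
strand. The cut is the canonical blunt cut 3 nt 5′ of the PAM (between
protospacer bases 17/18), reported as a boundary coordinate. Ranking is
ascending absolute distance from the cut to the nearest uATG first base —
a simple monotone proxy for "PAM adjacent to the uATG" — with ties broken
by cut position and then `+` strand first, so output order is
deterministic. Defaults: GC fraction within [0.30, 0.80], cut within
50 nt of a uATG; both configurable. Off-target assessment is delegated to
external tools; the report carries a free-text column for their scores.

## Genotyping

Clones are aligned globally to the reference amplicon under affine-gap
scoring (match +2, mismatch −3, gap open −5, extend −1; a length-L gap
scores −5 − L, mapped onto Biopython's PairwiseAligner by folding one
extension into its open score). The aligner's first optimal traceback is
taken, which is deterministic; score-level behaviour is what downstream
steps rely on, and the variant-call → re-apply round trip is exact by
construction. Gap and mismatch runs become DEL/INS/SUB edits; adjacent
substituted bases merge; indels are left-aligned within repeat context,
never across a previously emitted edit.

Zygosity rules are a reconstruction — the categories are named in the
field but thresholds rarely stated. Each clone's normalized edit set is
its allele signature; signatures supported by fewer than `min_support`
clones (default 2) are discarded as noise, because independent sequencing
errors make an affected clone's signature unique. Remaining signatures S:
all empty → wild type; one non-empty → homozygous (indistinguishable from
hemizygous by clone counting; flagged); two → heterozygous; three or more
→ chimeric. Cohort percentages are reported half-up to two decimals,
matching how such rates are printed.

## Quantification

Technical replicates are averaged per sample before ΔCt; ΔCt pairs target
and reference-gene wells within a sample; ΔΔCt subtracts the calibrator
mean, so the calibrator RQ is exactly 1; per-sample RQs carry dispersion.
Relative translational efficiency divides each condition's LUC/REN
activity ratio by its LUC/REN mRNA ratio and then takes the
treatment/control quotient. TTA is the exact four-analyte sum; folds are
reported to two decimals, per-analyte percent increases to one. The
two-sample t test is pooled-variance by default with Welch on request
(Welch–Satterthwaite df); two identical zero-variance samples yield
t = 0, p = 1 rather than NaN. No multiple-testing correction by default
(raw t tests are what the field reports); a Benjamini–Hochberg helper
exists but is opt-in.

## Synthetic data

The published leader is only available as a figure, so the generator
plants its summary statistics rather than its bases: 192-nt leader, five
Type-1 uORFs of 57/15/30/54/84 nt (240 nt of uORF in 192 nt of leader, so
overlap is forced — the only reading consistent with the printed
arithmetic), no stray ATGs on the sense strand within the leader plus a
30-nt CDS prefix window, and a 60-nt stop-free filler CDS ending in TAA
(long enough for Type-2/3 stops to land inside it). Planting writes each
uATG and stop into a template, fills the remaining bases left-to-right
from letters that create neither an unplanned ATG nor a premature stop in
any planted frame, and then validates the candidate against an
independent brute-force scan; failures are resampled (default 500
attempts) before an infeasibility error names the constraint. Truth is
always the oracle's reading of the final sequence, never the request —
incidental interactions cannot desynchronize truth from sequence.

Edit-pattern profiles (preserve-all-uATGs, disrupt-k-uATGs, convert to
Type 3 by substituting away in-frame stops, convert to Type 2 by a
frameshifting in-body deletion, bare lesion sizes) sample lesion
placements and verify each candidate through the edit-outcome predictor
before returning; unsatisfiable profiles raise infeasibility errors. The
strict preserve profile confines lesions to uORF-free leader segments,
emulating the reported allele whose lesions sat upstream of the first
uORF. Clone simulation allocates clones to alleles by largest-remainder
rounding of the mixing proportions (small clone sets then honour the
mixture exactly) before seeded shuffling and per-base substitution noise.

Quantification tables plant effects directly: treatment target Ct is the
base Ct minus log2(fold) with Gaussian per-well noise, so the planted
fold is recovered in expectation; metabolite concentrations split each
line's planted TTA total by a fixed control composition (Tan I 16%,
Tan IIA 42%, CPT 28%, DHT 14% — a synthetic split, since only the totals
are published) under mean-one lognormal noise. Gene-fold defaults carry
the published pathway inductions; TTA defaults are the published totals
(control 2.85, edited lines 3.39/5.11/5.15/2.85 mg/g DW).

## Study-scale experiment sizes

The cohort reconstruction genotypes 30 lines of 12 clones each against a
252-nt amplicon; clean base-called clones reproduce the printed
percentages exactly, and a separate experiment measures category recovery
under noise. The recovery experiment runs 500 simulated lines at 0.1%
per-base substitution error — a realistic rate for Sanger-sequenced
plasmid clones, within the sub-0.5% regime the genotyper is specified
for — with 12 clones per line and support threshold 2. ΔΔCt recovery uses
200 seeded tables per fold (3 biological × 3 technical replicates, Ct
noise sd 0.1 cycles) and checks the mean recovered RQ, the consistent
statistical reading of estimator recovery at this design size; single
tables at this noise have ≈5% multiplicative spread. The t-test
calibration uses 10 000 null replicates at n = 6 per group.

## What passing tests do and do not show

The generator emulates summary statistics, not the real sequence: real
leaders have biased composition, the real lesion coordinates are unknown
(profiles reproduce lesion sizes and uATG-disruption counts, not
positions), Sanger chromatogram artefacts are not modelled (inputs are
base-called sequences), and qPCR amplification-efficiency deviations from
2.0 (Pfaffl-type corrections) are out of scope. Passing therefore shows
the machinery is self-consistent and recovers planted truth under the
stated noise models — not that any biological conclusion transfers to a
particular real transcript. Kozak-context strength, reinitiation and
leaky scanning, minus-strand ORFs, off-target scanning and repair-outcome
spectra are deliberately out of scope.
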