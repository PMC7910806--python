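# Methods

This note documents the models, rules and numerical choices behind the
package, and what the synthetic fixtures do and do not establish about
behaviour on real collections data.

## Identifier and label model

Sampling events are keyed by version-4 UUIDs (canonical lowercase
8-4-4-4-12 text). Seeded generation draws the 128-bit value from a
deterministic stream and stamps the version/variant bits, which makes
fixtures reproducible; production use without a seed falls back to the
standard library's random UUIDs. Uniqueness is enforced at generation and
re-checked at every ingest.

QR labels use byte mode at error-correction level M with automatic version
selection (a 36-character UUID fits a version-3 symbol), a fixed mask
pattern, and the bare UUID text as payload — no URL framing, so the symbol
stays as small and scannable as possible on a coin envelope. The decoder
binarises at the grey-level midpoint, finds finder patterns by their
1:1:3:1:1 run signature (row scan with a vertical cross-check, stride 3
with a stride-1 fallback), groups centre triples by right-angle geometry
and consistent module size, samples the grid between finder centres, and
then applies format-information matching, unmasking, de-interleaving and
Reed–Solomon correction (Berlekamp–Massey, Chien search, Forney with
first root α⁰). Axis-aligned symbols at any rotation decode; perspective
distortion is out of scope because envelope photographs are taken face-up.
Candidate centres are merged only when their module sizes agree within
~30%; averaging in spurious stroke-induced hits was the one observed
failure mode on composited photographs.

Decoding policy: several codes in one image that agree on a UUID are a
consistent re-shoot; codes that disagree make the photo unreadable
("multiple conflicting codes"), because one photograph documents one
envelope. Payloads that are not UUID-shaped are unreadable, not errors.

## Database and audit model

One SQLite file per project. Raw sheet exports are stored row-by-row as
JSON alongside an ingest log keyed by content hash — re-ingesting an
identical file is a recorded no-op — and all derived tables are rebuildable
from the raw tables plus the image scan, which the test suite checks by
digesting the derived tables, dropping them and re-running the pipeline.
Violations (`duplicate_sample_id`, `unreadable_code`,
`multi_taxon_mapping`, `orphan_reference`, `malformed_row`) are stored
permanently and deduplicated on (kind, subject, details, source); audits
report in sorted (kind, subject) order so diffs are stable. Corrections
are made by adding rows, never by deleting evidence.

Two mapping choices worth noting: an unknown determination (a name absent
from the master taxonomy) is recorded as `orphan_reference` — the sample
references a taxon that does not exist — while an ambiguous determination
(a synonym shared by several accepted names) is `multi_taxon_mapping`; and
a duplicated (sample, locus) row in the assembly summary is recorded as a
`malformed_row` with the first row kept.

## Error-rate accounting

Error rates are percentages of sampling events (envelope scans), with
union semantics: the overall rate counts events affected by at least one
error class once, so it can be below the sum of the component rates.
Duplicate detection means one UUID decoded from distinct photographs of
*different* events — two envelopes printed with the same code — where
events are identified through the photo log (filename → provider barcode)
written during sampling; repeated photographs of one event are re-shoots,
not errors. Without a photo log, unreadable images cannot be attributed
and each is counted as a distinct affected event (an upper bound), and any
repeated-UUID pair of distinct images is treated as a duplicate
(conservative). Both group counts and affected-event rates are reported,
since "a duplicated pair" and "two affected events" are different
denominators.

## Plates and submission reformatting

Extraction plates are 8×12 grids (wells A1–H12, row-major) entered through
spreadsheet-style templates with a plate UUID and metadata block. Entry
fail-safes reject malformed UUIDs, duplicates within the plate, duplicates
against all previously ingested plates, and samples without a sampling
event — before ingestion, which is where plate errors are cheapest to fix.

Submission reformatting processes samples in deterministic order (plate
ingest order, then row-major wells) and includes a sample iff its yield is
at least 10 ng — strictly: 9.9 ng is excluded, 10.0 ng included — and its
genus is still under quota at decision time. The per-genus goal defaults
to ceil(0.5 × accepted species in the genus), counting distinct included
species ("species" mode; a "samples" mode counts included samples against
the same target). The greedy order makes the tie-break explicit:
earlier-plated samples win at the quota boundary, and raising the quota
fraction can only add included samples (monotonicity, covered by a test).
Included samples are packed row-major onto destination plates; every
exclusion carries its reason into a side-file next to the submission
manifest.

## Locus-recovery QC and statistics

A locus is recovered at coverage ≥ 6× and assembled length ≥ 350 bp.
Coverage is whatever per-locus summary the assembler provides (typically a
mean); the ingest does not recompute it from reads. High-copy loci (14 by
default — organellar/rDNA-like targets that recover trivially) are
excluded from numerator and denominator; a sample whose loci are all
high-copy is "unscorable", a distinct outcome. Failure is strict:
fraction < 0.05 fails, exactly 0.05 does not.

The family analysis is a one-way fixed-effects ANOVA on the per-sample
count of recovered loci (a fraction-based response is available in the
config), with η² = SS_between/SS_total computed directly from the sums of
squares and the p-value from the F distribution; the per-family
five-number summary table is restricted to families with ≥ 50 samples by
default (a reporting cutoff, not part of the test). scipy/statsmodels
serve as independent cross-checks in the test suite, not as the
implementation.

Nearest-bait distance is the minimum over the seven bait-design taxa of
the branch-length path sum to the sample's species tip, computed by
traversal of the tree's edge graph (one pass per bait; paths in trees are
unique). Tip matching uses the same binomial normalisation as the
taxonomy module (author citations and infraspecific ranks stripped,
case-insensitive); species absent from the tree are counted as unmapped,
never imputed. The regression of recovered-locus count (raw counts, not
transformed) on distance is plain OLS with adjusted
R² = 1 − (1 − R²)(n − 1)/(n − 2); zero-variance distances raise a typed
error rather than returning a degenerate fit.

## Synthetic projects and what they establish

`simulate_project` draws everything from one seed through named substreams
(taxonomy, uuids, sampling, errors, images, yields, loci, tree), so
changing one rate never shuffles unrelated draws, and equal seeds produce
byte-identical bundles. Defaults are the conditions the workflow is
designed around: 0.28% unreadable photographs, 0.95% of events carrying a
printer-duplicated code (planted as event pairs sharing one UUID, which at
16,000 events is 76 pairs), a 2% re-shoot rate, yields lognormal with
σ = 0.9 and the median placed so that exactly 5% of the mass falls below
10 ng, mean locus recovery 0.872 across 100 loci of which 14 are
high-copy, a between-family spread calibrated so the planted η² is ≈ 0.16
for a count response (σ_p = √(η²/(1−η²)·L·p̄(1−p̄))/L), a 0.2% planted
sequencing-failure rate, and 78% of species present in the distance tree.
The manifest records expected detections analytically from the planting —
including which duplicate pairs are detectable (both events need a
readable photo) and the union error rates under the same attribution rules
the pipeline uses — so pipeline-equals-manifest tests are genuine oracle
comparisons, not self-comparisons.

Mock photographs are flat composites (background, dark strokes, pasted QR
at module scale 3–4); they establish that linking, attribution and error
accounting are correct, not that the decoder handles glare, blur, curled
sheets or perspective. The statistics tests at n = 5,000 establish
parameter recovery (planted η² within ±0.02) under binomial within-family
variance; real within-family variance is overdispersed, which widens
confidence intervals but does not change the estimators.

Test problem sizes — 150–1,000-sample bundles for pipeline tests, 5,000
events for planted-error recovery, 10⁴ QR round trips — were chosen to
exercise every error class at realistic rates while keeping the suite
fast enough to run on every change.

## Orchestration

`run-all` executes taxonomy → samples → images → plates → yields →
reformat → QC → statistics → report. Each stage stores a content hash of
its direct inputs chained with its predecessors' hash, so re-running an
unchanged project skips every stage (make-like behaviour without an
external build tool) and editing any input re-runs exactly the stages
downstream of it. A fatal error (e.g. a taxonomy with duplicate accepted
names) stops the chain before later stages touch the database.

## Known limitations

- The QR decoder targets printed labels photographed face-up; it does not
  handle perspective, strong blur, or partial occlusion of finder
  patterns.
- Name matching is exact on the normalised binomial; there is no fuzzy
  matching, by design — near-miss determinations surface as unknown names
  for human review.
- Error-rate attribution without a photo log over-counts overlapping
  errors (documented upper bound).
- The single-file database has whole-file concurrency semantics; it is a
  project artifact, not a multi-user server.
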