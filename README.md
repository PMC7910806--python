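# slims

A Specimen-to-Laboratory Information Management System (SLIMS) for
high-throughput, collections-based phylogenomics: the software layer that
lets a small team sample tens of thousands of herbarium specimens, push
them through plate-based DNA extraction and target-capture (Hyb-Seq)
sequencing, and keep every sample, image, well and sequencing outcome
linked and audited along the way.

It is written for phylogeneticists and collections staff running large
destructive-sampling campaigns. The design replaces hand-filled
spreadsheets with three ideas:

1. **Pre-generated UUIDs as QR codes.** Every sampling event is keyed by a
   version-4 UUID pre-printed as a QR code on a coin envelope. The envelope
   is photographed on the specimen sheet, so the UUID links the tissue, the
   voucher image, the taxonomy, the extraction well and the sequence data.
   The QR encoder/decoder (`slims.qrcodec`) is self-contained: byte-mode
   symbols at error-correction level M with full Reed–Solomon decoding over
   GF(2^8), plus finder-pattern detection for reading codes out of
   specimen photographs.
2. **One portable SQLite database.** Raw sheet exports are ingested as
   close to their original form as possible; derived tables (taxon↔sample
   links, wells, sequencing outcomes) are rebuilt from them, and every
   error class — duplicated sample IDs, unreadable codes, names mapping to
   multiple taxa, orphan references, malformed rows — is kept permanently
   in audit tables.
3. **Quality control as statistics.** A targeted locus counts as recovered
   when it assembles to ≥ 6× reference coverage and ≥ 350 bp (high-copy
   loci excluded); a sample fails when < 5% of scored loci recover; samples
   under 10 ng total DNA are excluded at submission, as are samples from
   genera whose sequencing goal is met. Recovery structure is tested with a
   one-way ANOVA by family (effect size η² = SS_between/SS_total) and an
   OLS regression of recovered-locus count on the patristic distance to the
   nearest bait-design taxon (*Glycine soja*, *Juglans nigra*, *Polygala
   lutea*, *Quercus shumardii*, *Quillaja saponaria*, *Rosa palustris*,
   *Ulmus alata*), reporting adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2).

A seeded synthetic-project generator (`slims.fixtures`) emulates every
input — taxonomy with synonyms, sampling sheets, QR-bearing mock
photographs with planted unreadable/duplicate errors, plate templates,
yields and family-structured locus recovery — together with a ground-truth
manifest used as the oracle by the test suite.

## Worked example

Simulate a 300-event project and run the whole pipeline:

```
$ slims simulate --dir demo --seed 7 --samples 300
simulated 300 events, 134 expected submissions
$ slims run-all --dir demo
{
  "taxonomy": 160,
  "samples":  {"events": 300, "violations": 2},
  "images":   {"n_images": 313, "n_linked": 310, "n_unreadable": 1,
               "n_duplicate_images": 2, "n_duplicate_groups": 1},
  "plates":   {"plates": 4, "filled_wells": 298},
  "yields":   298,
  "reformat": {"included": 134, "total": 298},
  "qc":       {"locus_rows": 13400, "samples_scored": 134},
  "stats":    {...},
  "report":   {"html": "sample_selection.html", "species_rows": 299}
}
```

300 envelopes were scanned; one sheet row re-used a printer-duplicated
UUID (hence 299 distinct samples) and one photograph was unreadable. The
audit table names every problem:

```
$ slims audit --dir demo
duplicate_sample_id  93f9a773-…  uuid decoded from 2 images of 2 events: …
duplicate_sample_id  93f9a773-…  uuid recorded again in sampling row 295 …
multi_taxon_mapping  93f9a773-…  already linked to T00124, determination …
unreadable_code      img_00018_0.png  no QR code detected
```

`demo/stats.json` holds the QC statistics for the 134 sequenced samples:

```
"anova":  {"F": 3.82, "p": 8.6e-04, "eta_squared": 0.175}
"median_recovery_pct": 87.2
"regression": {"slope": -0.169, "p": 0.038, "adjusted_r_squared": 0.031}
```

Median locus recovery is 87.2%; family membership is significantly
associated with recovery (the fixture plants a family effect of η² ≈ 0.16,
noisy at this cohort size), and distance to the nearest bait taxon explains
almost nothing — the pattern this QC is designed to surface. The
reformatting step excluded low-yield samples and genus-quota overflow
(`demo/submission_manifest.csv`, `demo/submission_exclusions.csv`), and
`demo/reports/sample_selection.html` is a single-file interactive report
(collapsible family/genus levels, text filter, hover-glyph legend) whose
species rows mirror `sample_selection.csv` exactly. Stage survival is in
`demo/reports/progress.csv`:

```
stage,n_samples
sampled,299
imaged,298
extracted,297
quantified,297
submitted,133
sequenced,133
qc_passed,133
```

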