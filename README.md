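# cgivarscan

In silico assessment of promoter variants at CpG sites: does swapping the
reference allele for an alternate allele abolish, shrink, enlarge or split a
promoter CpG island, and does it gain or lose predicted transcription-factor
binding at the site?

CpG islands (CGIs) in promoters are the substrate of DNA methylation, and a
single-nucleotide change at a CpG dinucleotide can push an island below the
calling thresholds — with potential downstream consequences for methylation
and expression of the gene. `cgivarscan` implements the full desk pipeline:
promoter windows in, per-allele island comparisons and TF-binding differences
out, plus a synthetic-promoter generator that plants variants whose impact
label is guaranteed by construction, so every stage is testable without
external databases.

## Model

An island is an interval `I` of the promoter sequence satisfying, strictly,

* length(`I`) > 100 bp,
* GC% = 100 · (#C + #G) / |I| > 50.0,
* Obs/Exp CpG = (#CpG · |I|) / (#C · #G) > 0.60,

the classical composition criteria with the Gardiner-Garden–Frommer
observed/expected ratio. Calling is a deterministic sliding-window scan
(100 bp windows, 1 bp step): windows passing both composition criteria are
merged, each merged candidate is re-verified in aggregate, and failing
candidates are trimmed base-by-base from the less island-like end (exact
ties trim both ends, which keeps calls invariant under reverse
complementation).

For each variant allele the wild-type and mutated promoter are called
separately; islands overlapping the variant locus (padded by one window) are
compared after shifting variant-side coordinates by the indel length change,
and the change is labelled `unchanged`, `reduced`, `enlarged`, `abolished`,
`split` or `gained`. A position-weight-matrix log-odds scanner (JASPAR /
MEME-minimal motif input) reports TF names hitting the locus on each side and
the gained/lost sets.

## Worked example

Classify a planted knife-edge construct — an island whose statistics sit one
base above threshold — against the C→T variant that breaks it:

```python
from cgivarscan import PromoterSequence, Variant, classify_variant

rec = classify_variant(promoter, variant)   # promoter: 4001 bp window
print([(i.start, i.end, round(i.gc_percent, 2), round(i.obs_exp, 3))
       for i in rec.wild_islands])
print(rec.status, rec.wild_size_bp, rec.variant_sizes_bp, rec.delta_bp)
```

```
[(1200, 1301, 50.5, 0.622)]
abolished 101 () -101
```

The wild allele carries a 101 bp island at 50.5 % GC and Obs/Exp 0.622; the
variant allele drops every calling window to exactly 50 % GC, the island
disappears, and the record reports `abolished` with a −101 bp size change.

Summarising the bundled 200-row study table (`cgivarscan fixtures`):

```
                     metric  value
                    n_total  200.0
                n_abolished   17.0
              pct_abolished    8.5
                  n_reduced   64.0
                 n_enlarged    2.0
                    n_split    4.0
                n_unchanged  113.0
             n_size_changed   70.0
           pct_size_changed   35.0
               n_tf_changed   10.0
pct_tf_changed_of_abolished   58.8
```

Of 200 CpG-site variant alleles across 15 promoters, 17 (8.5 %) abolish
their island, 70 (35 %) change its size, and 10 of the 17 abolishing
variants (58.8 %, i.e. 59 %) differ in predicted TF binding.

The command line mirrors the library: `cgivarscan classify`, `tfdiff`,
`fixtures` and `simulate` (see `--help` on each).

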