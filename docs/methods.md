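# Methods

## Problem setting

A promoter is modelled as the closed window [−2000, +2000] around the
transcription start site — 4001 bp including the TSS base — on the strand
declared in its metadata. Variants are allelic changes anchored at a 1-based
genomic position: substitutions, multi-nucleotide substitutions, insertions
written with the shared anchor base (`G/GGCGGT`), and deletions written as an
explicit reference string with a `-` alternate (`TCCCCCGCCGCCCC/-`).
Multi-allelic records expand to one row per alternate allele. Alleles are
assumed reported on the + genomic strand (the dbSNP convention); on − strand
promoters they are reverse-complemented and the coordinate mirrored before
injection. Internally all coordinates are promoter-local, 0-based,
half-open; the interfaces speak 1-based genomic (variant tables, metadata)
and half-open interval (BED) conventions.

## Island calling

An island must strictly satisfy length > 100 bp, GC% > 50.0 and Obs/Exp
CpG > 0.60, where Obs/Exp = (#CpG · L) / (#C · #G) and the ratio is defined
as 0 when a sequence has no C or no G (a windowed region with no C or G
holds no CpG and cannot qualify). `N` bases count toward length but never
toward G+C or CpG content — ambiguity never helps a window qualify.

The caller is a deterministic scan:

1. slide a 100 bp window at 1 bp step; a window qualifies iff it passes both
   composition criteria;
2. merge overlapping/adjacent qualifying windows into candidates;
3. verify each candidate in aggregate; while a criterion fails and the
   candidate is long enough, trim one base from the end whose removal most
   improves the failing statistic (GC first, then Obs/Exp, when both fail);
4. accept candidates that pass all three criteria after trimming.

Window width 100 bp and step 1 bp are the defaults because the finest step
makes the scan deterministic and directly checkable against a brute-force
window enumeration; both are configurable (`cgi:` block of the YAML config)
along with the three thresholds.

**Tie-breaking.** When removing either terminal base improves the failing
statistic equally — an exact tie, and a common one, since removing an A or T
from either end changes GC and Obs/Exp identically — the caller trims one
base from *both* ends. This is the one boundary rule with a genuine design
choice behind it: any positional preference (say, always trimming the right
end) makes island calls depend on sequence orientation, and we hold
reverse-complement invariance to be non-negotiable for a strand-symmetric
statistic. The comparison is safe in floating point because mirrored
intervals produce identical statistics bit-for-bit (GC from the same integer
counts; Obs/Exp via the commutative product #C · #G).

The published island coordinates and sizes this package's bundled tables
carry were produced by a different caller whose window/merge/trim internals
are unpublished; per-coordinate agreement with those printed sizes is
therefore not an evaluation target. The bundled tables are the reference for
*count-level* reproduction, and the algorithmic core is validated against
oracles and planted constructs instead.

## Impact classification

For each (variant, allele) the wild and mutated promoter sequences are
called independently. Only islands overlapping the variant locus padded by
one window length enter the comparison — under a 100 bp-window caller a
local change cannot move an island boundary farther than one window, so
distal islands are unchanged context. For indels, variant-side island
coordinates right of the locus are shifted back by the net length change so
both sides are compared in wild coordinates. Labels:

| wild overlap | variant overlap | label |
|---|---|---|
| none | none | unchanged |
| some | none | abolished |
| none | some | gained |
| one | two or more | split |
| otherwise | otherwise | reduced / enlarged / unchanged by the sign of Δbp |

Δbp is the summed variant-side size minus the summed wild size, one scalar
consistent across labels (a 964 → 315+641 split has Δ = −8). A merge (two
wild islands, one variant island) is labelled `enlarged` with an explanatory
note, since the label set of the study tables contains splits but no merges.
Substitutions outside a CpG dinucleotide are rejected by default and
processed with a warning when `allow_non_cpg` is set, because the study
design restricts attention to CpG-site variants.

## TF-binding differences

The binding-site step generalises the original study's web-tool lookup
(matrices built on the fly from a licensed site collection, not
reproducible) to a standard PWM log-odds scan over a user-supplied motif
library. Counts plus a 0.5 pseudocount are column-normalised, divided by a
uniform background and log2-transformed; a hit requires the summed log-odds
to reach `threshold_frac` (default 0.8) of the motif's maximum achievable
score. Scanning covers both strands of the locus ± 20 bp flank; the wild and
variant TF-name sets overlapping the locus give the gained/lost sets. The
relative score normalises by the maximum score (not min–max) because it is
simple and monotone. A small bundled library (an Sp1-like GC-box among five
toy motifs) backs the tests; the published per-variant TF lists carry no
positions, strands or scores, so only their changed/unchanged bookkeeping is
recomputed, from the bundled transcription.

## Bundled study tables

`data/table1_snvs.tsv` (200 rows: gene, island label, wild size, rsid,
allele notation as printed, coordinate as printed, wild/variant status,
variant sizes) and `data/table2_tfs.tsv` (17 rows: wild/variant TF sets)
are verbatim transcriptions, guarded by SHA-256 checksums and loader-time
invariant checks. Summary counting follows the tables' own arithmetic: the
published "70 (35 %) size-reduced" tally is reproduced by counting every row
whose printed variant size differs from the wild size — 64 strictly smaller,
2 larger (a 298 → 304 insertion and a 931 → 932 row) and 4 splits — reported
here as `n_size_changed` alongside the fine-grained reduced / enlarged /
split counts. Percentages are computed exactly and rounded half away from
zero (17/200 → 8.5, 70/200 → 35.0, 10/17 → 58.8 ≈ 59 %); per-gene
percentages round to integers (LDLR 5/16 → 31 %, 7/16 → 44 %). One prose
tally in the source conflicts with its own table (three vs two size-reduced
rows in the first island of one gene); the table is taken as authoritative
since the published totals only work out from the table rows.

## Synthetic data generator

The generator emulates the two compositional regimes the study contrasts,
and nothing else about real promoters:

* **Background** — a first-order Markov chain with stationary GC exactly the
  requested value (default 0.40, a typical bulk-promoter flank composition)
  and the C→G transition scaled by 1 − depletion (default 0.75), the removed
  mass going to C→C so CpG depletion is orthogonal to GC. The defaults give
  Obs/Exp ≈ 0.26, far below the 0.60 threshold.
* **Generic islands** — even interleaves of `CG` and `GC` tokens in A/T
  filler with at least one filler base between tokens, so base and CpG
  counts are exact by construction (defaults: 300 bp, GC 0.65, Obs/Exp
  margin 0.15 above threshold — comfortably inside the calling region, as
  promoter CGIs typically are).
* **Knife-edge islands** — 101 bp blocks whose two possible calling windows
  each hold exactly 51 G+C bases; a single C→T drops every window to 50 %,
  below the strict threshold, abolishing the island. The G+C bases span
  positions 1..99 exactly, so the qualifying-window union is the block
  itself and no trimming is involved in the wild call.
* **Periodic islands** — a window-length tile with 51 G+C bases repeated n
  times; every window of the repeat then has identical, marginal GC, and one
  C→T kills precisely the windows covering it: an edge hit truncates the
  island (reduce), a central hit cuts it in two (split).

Planted constructs are flanked by 150 bp A/T quiet zones so background
windows cannot merge into them. Every emitted truth record is verified by
running the package's own classifier at generation time, with bounded,
seeded retries (fresh background, next candidate site) — the caller's
merge/trim behaviour at boundaries makes analytic guarantees brittle,
whereas verified emission makes label fidelity 100 % by construction.
Synthetic rsIDs carry a `synth:` prefix to avoid collision with real
identifiers. What passing recovery shows is that the classifier assigns the
intended labels under the generator's idealised composition; it does not
show calling accuracy on real promoters, whose islands have no ground truth
at this resolution.

## Problem sizes and determinism

The default validation scales are: 500 random sequences of 1–4 kb for
caller soundness, oracle agreement and reverse-complement symmetry; 200
planted variants (50 per label) for recovery; 1000 seeded injection round
trips; all 4^w k-mers for PWM motifs of width ≤ 6. All randomness flows
through numpy Generators seeded from a single integer; identical seeds give
byte-identical datasets and reports.

## Known limitations

* Island boundary placement is caller-specific; only count-level agreement
  with the published tables is meaningful, and sizes from other callers will
  differ by a few bases at the edges.
* The TF step depends entirely on the supplied motif library and threshold;
  it reproduces the published TF difference *accounting*, not the original
  tool's matrices.
* The background model captures GC and CpG structure only — no isochores,
  repeats, or positional composition gradients across the promoter.
* VCF support is deliberately minimal (CHROM/POS/ID/REF/ALT); INFO, FORMAT,
  genotypes and structural alleles are out of scope, as are liftover and
  indel left-alignment against a reference genome.
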