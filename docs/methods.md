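# Methods

## The model

A mature miRNA's canonical seed is a short 5' window, by default nucleotides
2–7 (a hexamer). A *seed site* on a genome is a position whose bases can pair
with the seed. `mitomirscan` treats site finding as exact string matching of
a derived DNA pattern against both strands of a (usually circular) reference:

- **Duplex geometry.** In the canonical antiparallel duplex the target
  strand carries the *reverse complement* of the seed (`match_mode =
  "antiparallel"`). Some published mitochondrial seed-site tables instead
  follow a *parallel* reading — the seed laid alongside the target 5'→3' and
  complemented base by base without reversal (`match_mode = "parallel"`).
  Both geometries are first-class, because the second demonstrably underlies
  published MitomiR site coordinates for the bundled panel.
- **Strands.** A forward hit is an occurrence of the pattern on the printed
  reference strand; a reverse hit an occurrence of its reverse complement.
  For human mtDNA the printed strand is the light (C-rich) strand, so
  forward = L-strand and reverse = H-strand; reverse sites are displayed
  with descending coordinates and a trailing `r`. `orientation = "flipped"`
  swaps the labels; geometry × labelling spans the four conceivable
  conventions.
- **Circularity.** Coordinates are 1-based inclusive; an interval with
  start > end wraps the origin. The scanner searches the doubled sequence so
  origin-spanning sites are found exactly once; overlapping occurrences are
  all reported; `N` never matches. A brute-force per-position oracle
  (`scan_oracle`, genomes ≤ 10 kb) re-derives the same contract
  independently and backs the randomized equivalence tests.

## Convention calibration

Published site tables rarely state window, geometry, or labelling, and may
be internally inconsistent. `calibrate_convention` enumerates windows
{2–7, 1–6, 1–7, 2–8, 3–8} × geometry × labelling, scores each candidate by
the number of anchor rows (published sites bundled as a fixture) it
reproduces exactly, and returns the unique best scorer — ties raise an
error, and "no anchor reproduced" returns an explicit failure report. A
miRNA whose anchors all fail under the global convention but all pass under
a single alternative receives a per-miRNA override. Anchors nothing
reproduces are diagnosed: the report prints the genomic word at the anchored
interval and which panel miRNA's pattern it actually equals. miRNAs whose
effective seeds coincide are flagged as indistinguishable, since no
exact-window convention can give them different hit sets.

On the bundled fixtures the calibration selects *parallel geometry,
reference labelling, window 2–7*, with one override (miR-378 → window 3–8,
demanded by its own anchor rows) and two indistinguishable pairs
(let-7a/let-7d-5p and miR-107/miR-103a-3p). The bundled anchor attributed to
miR-24 at 41–46 is reproduced by no convention; the diagnosis shows the site
carries let-7a/let-7d-5p's parallel-complement hexamer (`CTCCAT`) — the
published table's miR-24 block is internally garbled, and miR-24's own
count is excluded from any claim.

## Reference fixture and coordinates

The bundled genome is **NC_001807.4** (16,571 bp, circular), the public
human mitochondrial genome sequence available to this package. The bundled
feature map carries the standard rCRS (NC_012920) annotation values —
HVR1 16024–16383, HVR2 57–372, HVR3 438–574, control region 16024..576
(origin-wrapping), and the usual gene boundaries with the ATP8/ATP6 and
ND4L/ND4 overlaps. NC_001807.4 differs from rCRS numbering by at most 2 bp:
it carries two extra C's in the D-loop poly-C tract (~rCRS 303–315), lacks
the rCRS position-3107 placeholder N, and carries one extra C in the HVR1
poly-C tract (~rCRS 16184–16193). None of the observed seed sites fall
within 2 bp of a feature boundary, so gene-area assignments are unaffected;
bundled anchor coordinates are lifted to NC_001807.4 numbering using these
piecewise offsets (documented in the anchor fixture header). One sequence
variant of NC_001807.4 relative to rCRS creates a single extra reverse
miR-378 site (window 3–8) near position 12,849, so its calibrated count on
the bundled fixture is 6 where rCRS-based coordinates list 5; all other
panel counts are unaffected.

## Annotation precedence

When a hit overlaps several features: gene features (protein-coding, tRNA,
rRNA) outrank non-coding regions; among genes, larger overlap with the hit
wins, exact ties break to the earlier start and flag the row `ambiguous`;
among non-coding regions the narrowest wins, so an HVR outranks the
enclosing control region. A hit overlapping nothing is `intergenic`,
non-coding, and flagged (the mitochondrial genome has essentially no
intergenic sequence, so this indicates either a boundary quirk or a
non-mitochondrial input). The precedence is a package design choice — the
published tables print one gene area per row without stating a tie-break —
and all overlapping features are always retained in `all_overlaps`.

## Proteome filter and partition

Targets carry a prediction score in [50, 100] (miRDB-style; records outside
the range are rejected with the offending rows listed) and an optional IMPI
localization score in [0, 1]. The filter keeps `impi > threshold` (default
0.7, strict); "0.7 or greater" semantics are available via `strict=False` —
the packaged snapshot's minimum IMPI is 0.72, so the choice does not affect
it. Records lacking IMPI never survive but are tallied. ORF protein length
is `nt/3 − 1` (stop codon excluded), defined only for positive multiples
of 3.

The partition cross-classifies each panel miRNA by (MitomiR, mt-genome
sites, mt-proteome targets). The site axis is evaluated **only for
MitomiRs**: seed pairing with the organellar genome presupposes the miRNA is
present in mitochondria, so non-MitomiRs are recorded as "no interaction"
regardless of incidental sequence matches. Cells are disjoint and
exhaustive. The MitomiR flags and database target counts in the evidence
fixture are a versioned snapshot (2017-era databases) displayed as-is, never
recomputed.

## Synthetic data

`generate_genome(length, gc_fraction, rng_seed)` draws i.i.d. bases with
P(G)+P(C) = gc split evenly; the default gc 0.44 is roughly
mitochondrial-like. `plant_sites` overwrites the pattern (forward) or its
reverse complement (reverse) in place — genome length and coordinates are
preserved — at random non-overlapping positions or explicit (possibly
origin-wrapping) ones, and returns the exact truth set together with the
analytic background expectation 2·L/4^k. `generate_target_table` draws IMPI
from separated high/low ranges so any threshold between them has an exact
expected survivor count; overlapping ranges set a warning flag in the truth
output. All generators are deterministic under their seed and emit their
parameters in a manifest.

What the synthetic generator does *not* emulate: real mtDNA base
composition structure (strand-asymmetric skew, homopolymer tracts), real
miRNA expression, or database prediction noise. Passing planted-site
recovery therefore demonstrates scanner correctness, not biological validity
of any predicted site.

## Numerical and procedural choices

- Problem sizes for the randomized checks: 1,000 scanner-vs-oracle instances
  (genomes 20–120 bp, windows 6–8, both geometries and labellings, circular
  and linear), 500 planted-site configurations (80–600 bp), 200 replicates ×
  2,000 bp for the background-rate check against 2·L/4096 (3 standard
  errors). These sizes make the full suite run in seconds on one CPU while
  keeping the standard-error bound meaningful.
- Hits are deduplicated by (miRNA, start, end, strand); a wrap-found and
  linear-found occurrence counts once. Matching is case-insensitive.
- G:U wobble support expands the pattern set positionally (seed G pairs
  target T, seed U pairs target G); it is off by default and exists as an
  extension hook, not used by any bundled result.
- Pipeline outputs are byte-identical across reruns of the same
  configuration: JSON is key-sorted, no timestamps are written, and the
  manifest records sha256 checksums of every output file.
- The default pipeline scans the 10 MitomiRs (mirroring the published table
  layout); `scan_all` includes the full 16-miRNA panel. The partition always
  covers the full panel.

## Known limitations

- No thermodynamic duplex scoring, bulges, or knowledge-base lookups; sites
  are exact-complementarity predictions only.
- The bundled reference is NC_001807.4, not the rCRS (NC_012920); see the
  coordinate caveats above. Users with an rCRS FASTA can pass it via
  `--genome`, in which case anchor coordinates should be supplied in rCRS
  numbering.
- Heteroplasmy, variants and non-human mitochondrial genomes are out of
  scope beyond what the generic circular-genome model permits.
- The per-miRNA database target counts in the evidence fixture
  (miRDB/MitoMiner snapshots) depend on 2017 database versions and are
  display-only.
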