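# Methods

This note documents the models, parameter choices and numerical conventions
behind `editscan`, and what the simulator-based validation does and does not
demonstrate.

## Pipeline model

An amplicon experiment is modeled as: one reference amplicon per locus,
reads that each derive from either (a) the unedited locus, (b) the locus
carrying one repair product (indel at the cut site, or a donor integration),
(c) an off-target locus amplified by the same primers, or (d) a primer-dimer
artifact; plus uniform sequencing noise. Every pipeline stage targets one of
these sources.

Controls are first-class experiments: they run through the identical
assignment/alignment/filtering path, and their event tables define the
background for their treatments. A treatment is linked to the union of all
control rows sharing its amplicon and barcode, or to an explicit
`Control_ID`.

## Alignment

Global Needleman–Wunsch with affine gap costs (Gotoh three-state DP, numba-
compiled) and free end gaps. Defaults: match +5, mismatch −4, gap open −25,
gap extension 0. A gap run of length *k* costs `open + k·extension`; with
extension 0 the cost of an indel is independent of its length, which (i)
makes long indels (>10 bp) exactly as alignable as short ones and (ii)
penalizes fragmented multi-indel alignments — two separate runs always cost
two openings. Changing the extension penalty restores conventional affine
behaviour. Free end gaps mean terminal gap runs in either sequence cost
nothing and produce no events: a read covering part of the amplicon is not
"deleted" at its unsequenced flanks.

Numerical conventions, chosen for fully deterministic output:

- Traceback ties prefer diagonal > gap-in-read (deletion) > gap-in-amplicon
  (insertion); end-cell ties prefer the full-length corner, then longer
  alignments.
- Indels are then left-normalized: an indel slides to its leftmost
  placement while the preceding reference base equals the last base of the
  deleted/inserted run and no other event is crossed. Identical edits
  therefore always receive identical coordinates, which is what makes exact
  event-identity matching (normalization, HDR) well defined.
- Internal coordinates are 0-based half-open; exported tables are 1-based
  inclusive, with insertions anchored on the base immediately left of the
  insertion point (width 1 on export, 0 internally).
- Degenerate inputs: empty sequences are rejected; two completely disjoint
  1-nt sequences legitimately align with score 0 via two free end gaps.

Reads identical to their amplicon bypass the DP (score `5·L`, no events);
alignments are cached per distinct read sequence within an experiment.

Paired-end consensus: the reverse mate is reverse-complemented before
alignment so both mates share forward coordinates. Within the interval
covered by both mates the higher-scoring mate decides all disagreements,
including event-vs-no-event; outside it each mate contributes its own
events. Ties go to the forward mate.

## Filters

- **Quality** (defaults: mean Phred ≥ 30, no per-base floor, ambiguous
  bases rejected). The per-base floor is available but disabled by default
  because a single low-quality base is better handled as an alignment
  mismatch than by discarding the read.
- **Primer matching**: anchored at position 0 (sequencing starts at the
  primer), Hamming only, ≤ 2 mismatches by default; a scan-window option
  relaxes anchoring. Reads matching zero or several experiments are
  reported unassigned — with ≤ 3 allowed mismatches two experiments whose
  primers differ at ≥ 8 positions can never both match, so assignment
  is unambiguous for any realistic primer set.
- **Primer dimers**: any single deletion strictly wider than
  `amplicon − len(fwd primer) − len(rev primer) − buffer` (buffer default
  30 nt, configurable) marks the read as a dimer.
- **Off-target/artifact reads**: the per-base mismatch noise rate p̂ is
  pooled over all reads ((total mismatches + 1)/(total covered bases + 2);
  the pseudocount keeps an error-free library from declaring every stray
  mismatch significant). A read with *k* mismatches over *L* covered bases
  is flagged when P(X ≥ k), X ~ Binomial(L, p̂), falls below α = 10⁻³, or
  when it carries more than 4 indel events. With 25% contaminants at a 30%
  per-base mismatch rate, p̂ ≈ 0.08 and a contaminant's tail probability is
  astronomically small while clean reads sit at P ≈ 1, so the classes
  separate cleanly across the whole 10–50% contamination-divergence range
  (verified against simulator truth labels).

## Control normalization

An event is background iff an identical event — same type, same
left-normalized coordinates, same replacement sequence — occurs in the
pooled control at frequency strictly greater than the threshold (default
1%, "above the threshold" read as strict). Removal is per-event, never
per-read: `read_count_total` is invariant, normalized efficiency is
therefore monotonically ≤ raw efficiency, normalization is idempotent, and
a genuine edit co-occurring with an inherited variant on one read is
retained. A positional slack option (default 0) additionally matches
control events of identical type/width/replacement within ±slack bp, for
noisy data where left-normalization alone cannot canonicalize placement
across error-containing reads.

## Quantification

- **Cut window**: for a guide of length *L* at amplicon position *p* (either
  strand), the cut coordinate is `p + L − 3` (blunt SpCas9 cut 3 nt 5' of
  the PAM; the offset is configurable for other nucleases) and the window is
  ±5 bp, clamped to the amplicon; TALEN/nickase designs supply an explicit
  window instead. Window overlap is half-open interval overlap; an
  insertion overlaps iff its anchor lies inside the window — zero-width
  events need this convention made explicit.
- **Efficiency**: percentage of retained reads with ≥ 1 window-overlapping
  indel. Mismatches never count.
- **Frameshift**: net indel length over *all* retained indels on the read
  (not only window-overlapping ones) mod 3 ≠ 0, counted among edited reads,
  so `frameshift_pct ≤ efficiency_pct` holds by construction.
- **HDR**: expected events come from aligning the donor to the amplicon
  with the standard scoring; a read is HDR iff it carries every expected
  event (exact identity), extra events tolerated — a partial integration is
  not counted as HDR, and an integration plus an incidental extra indel is.
  Non-HDR reads with window indels are NHEJ; the classes are disjoint.
  Treating "all expected events present, extras tolerated" as HDR was a
  genuinely open design point; the simulator's donor-integration recovery
  (estimates within 3 binomial SE of truth) validates it under the stated
  read model.
- **Heterogeneity**: reads are grouped by their sorted event signature;
  the spectrum's Shannon entropy (bits) summarizes mosaicism. Unedited
  reads form the reference signature.
- **Aggregation** pools counts and recomputes percentages from summed
  counts (never averages percentages); tie-breaks are lexical so all
  outputs are byte-deterministic.

## Simulator

`editscan.simulate` generates the validation conditions: per locus a random
amplicon (default 200 nt) whose first/last 20 nt are the primers, with a
unique 20-nt guide site given an NGG PAM near the center. Reads are
full-length amplicon copies. Editing efficiency defaults to the benchmark
grid {0%, 33.3%, 66.7%, 90%} (default 33.3%); edited reads carry one indel
whose length regime follows the short (<10 bp) / mixed / long (≥10 bp)
partition, with the indel start drawn uniformly within ±2 nt of the cut —
inside the ±5 counting window with a 3-bp margin so that left-normalization
through a chance repeat cannot carry an edit out of the window.
Contaminants substitute each base independently at a fixed rate (default
30%); HDR experiments use a donor with a 6-bp insert (GGATCC) at the cut;
sequencing errors are uniform substitutions (default rate 0); qualities are
constant Phred 37. One seeded generator drives every draw, and gzip output
is written with a zeroed timestamp, so outputs are byte-identical per seed.

What the simulator does *not* emulate — and hence what passing validation
does not show about real data: position- or cycle-dependent sequencing
error, indel sequencing errors, homopolymer artifacts, coverage variation
along the amplicon (reads always span the full locus), PCR chimeras,
multi-indel repair products, and real population genetic background
(controls in the validation share the amplicon exactly). The control
normalization scenario is exercised with a constructed shared variant
rather than a population model.

## Problem sizes used in validation

The bundled validation runs the 20-locus × 1000-read design (the benchmark
grid above) per efficiency level and indel regime, 20 × 500 reads per
contamination rate, and 10 × 1000 reads for HDR recovery, with stochastic
checks at 3 binomial standard errors throughout.

## Known limitations

- Single-end simulated reads exercise the paired-end consensus path only
  through constructed unit fixtures.
- The artifact filter models mismatch counts only; an off-target locus of
  near-identical sequence (< a few % divergence) with an incidental cut-site
  indel can evade it.
- Exact-identity normalization is conservative on data with high
  sequencing-error rates (an inherited variant observed with an adjacent
  error is not matched); the slack option trades specificity for that case.
- The configuration schema's column names are this package's own fixed
  header (documented in `config_io`), not an interchange standard.
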