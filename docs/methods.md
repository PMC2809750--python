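# Methods

## Background and scope

Small activating RNAs (saRNAs) are 19-bp RNA duplexes with 2-nt 3′
overhangs that upregulate a gene when they target its promoter (RNA
activation, RNAa). This package implements the *in silico* half of that
workflow: given a promoter sequence anchored at its transcription start
site (TSS), it selects, scores and names candidate targets, and analyses
how well a designed target is conserved in an orthologous promoter.
Wet-lab readouts (expression fold changes, immunoblots, phenotypes) are
out of scope, as are genome-wide TSS discovery and off-target searches.

## Coordinate system

All user-facing positions are TSS-relative with the biological "+1, no
zero" convention: the TSS base is +1, the base immediately upstream is
−1. This matches the customary naming of promoter-targeting duplexes
(`dsP21-322` targets position −322). Internally all arithmetic is done
on 0-based sequence offsets; the conversion is exact and round-trips for
every base (`to_tss_coordinate` / `from_tss_coordinate`).

## The design procedure

1. **Scan.** Every 19-nt window on the sense strand whose bases all lie
   in [−`region_upstream`, −`region_downstream`] (defaults −1200 to
   −200, inclusive hard bounds) is a candidate. Scanning is sense-strand
   only; the guide strand is derived, never scanned.
2. **Hard filters.** A candidate is retained iff all of: GC ∈
   [`gc_min`, `gc_max`] = [40, 65] %; longest homopolymer run ≤
   `max_run` = 4 (evaluated within the 19-mer only, not the flanks);
   end-stability asymmetry strictly positive (below); position 19 = A
   and position 18 ∈ {A, T} (positions 1-based 5′→3′ on the sense
   target, forced by the flank being "positions 20–23"); no N; no
   overlap with the enabled masks; no internal CpG (see masking). All
   verdicts are recorded per rule for retained *and* rejected
   candidates, so rejection reasons are always auditable.
3. **Soft score.** Rules phrased as preferences enter a weighted sum:
   position 18 preferably A (w = 1), position 7 preferably T (w = 1),
   each A/T among flank positions 20–23 (w = 0.5/base; bases missing at
   the promoter edge contribute 0), and the positive part of the
   asymmetry (w = 1 per kcal/mol). The split into hard filters
   (declarative rules) versus weighted soft terms ("preferably") is a
   design reading of the rule set; the published rule list does not give
   weights, so these defaults are this package's own choice and every
   report carries a hash of the configuration used. Ranking is
   descending by sum score with a deterministic total order (ties:
   greater asymmetry, then proximity to the TSS, then lexicographic
   target).
4. **Duplex assembly.** sense = RNA copy of the target + overhang;
   guide = RNA reverse complement + overhang, so the 3′ end of the DNA
   target corresponds to the 5′ end of the guide strand by
   construction. The dTdT overhang is represented as literal `TT` with
   a per-duplex deoxy flag, keeping each strand a single-alphabet
   string. Names use the TSS position of the target's 5′-most base;
   a 3′-most anchor is selectable (`name_anchor`) because the naming
   convention does not pin down which base the number refers to.

## End-stability asymmetry

"The 3′ end less stable than the 5′ end" is quantified as
`asymmetry = ΔG(3′ window) − ΔG(5′ window)` where ΔG is the sum of
nearest-neighbor stacking free energies (kcal/mol, 37 °C) over the
window's consecutive dinucleotides, assuming a fully Watson-Crick paired
duplex. Positive asymmetry = weaker 3′ end = the desired guide-loading
bias. Choices:

* **Parameter set.** Xia/Turner 1998 RNA/RNA stacks by default, shipped
  as a versioned plain-text table (`data/xia_turner_1998_rna.tsv`),
  because the functional molecule is an RNA duplex; the SantaLucia 1998
  unified DNA set is shipped alongside and selectable for comparison.
  Tables load/dump losslessly; a table keyed by sense-strand
  dinucleotide is strand-reversal symmetric (stack XY = stack
  revcomp(XY)), which makes the asymmetry negate exactly under reversal
  of which strand is called sense.
* **Window size.** `thermo_k` = 5 terminal bases. Nothing in the rule
  set defines how many bases an "end" is; 5 covers the seed-proximal
  terminus without reaching the middle of the 19-mer, and is exposed as
  configuration.
* **Initiation and terminal penalties.** Initiation terms cancel in the
  3′−5′ difference and are omitted. The terminal A-U penalty is off by
  default (a simplification: it only matters when the two termini differ
  in composition) and can be enabled (`include_terminal_au`), charging
  the table's penalty at each window's outer terminus.
* **Strictness.** The filter demands `asymmetry > thermo_margin`
  (default 0): equality carries no strand-selection information, so it
  does not pass. Raising the margin is a monotone restriction.
* Overhangs are never part of the energy windows; only the 19 paired
  bases count.

## Masking of methylation-prone regions

DNA methylation at the target site interferes with RNAa, so three mask
classes are avoided. The rule set names no algorithms, so:

* **CpG islands** use the Gardiner-Garden–Frommer community defaults
  (window ≥ 200 bp, GC ≥ 50 %, observed/expected CpG =
  `#CG × L / (#C × #G)` ≥ 0.6), implemented as the union of all
  qualifying minimum-length windows (step 1) merged per class — exactly
  the brute-force all-windows union, which is what the oracle tests
  compare against. Note that a *merged* run of qualifying windows is
  reported as one interval; its aggregate GC/obs-exp can in principle
  dip marginally below the thresholds at union seams (the multi-phase
  Takai–Jones trimming is deliberately not used).
* **CpG sites**: masking every CG dinucleotide as an interval would
  blank out most promoters, so the default mode rejects any *candidate
  containing* a CG (`cpg_site_mode = per_candidate`); literal interval
  masking and "off" are selectable.
* **GC-rich regions**: union of 100-bp sliding windows with GC ≥ 60 % —
  thresholds invented here (no published criterion exists), configurable
  and documented as such.

Raising any mask threshold never enlarges the masked area; masks export
to BED (0-based half-open, name = reason) for genome-browser inspection.

## Conservation analysis

A designed target is mapped onto an ortholog as the **ungapped** 19-nt
window maximising the match count (ties: window closest to the
original's TSS-relative position, then most upstream; N matches
nothing). Gapped alignment is deliberately excluded — a 19-mer target
interrupted by an indel is not a functional saRNA target, and the best
gapless window then simply reports low identity. Percent identity is
`100 × matches / 19` — denominator fixed at the target length, not the
alignment length — rounded to one decimal, half away from zero
(18/19 → 94.7, 16/19 → 84.2). For imperfect matches a species-specific
duplex is redesigned as the perfect complement of the ortholog window,
named `<original>-<species_tag>`; hard-rule compliance of the redesigned
target is re-evaluated and reported as flags but **not** enforced,
mirroring how species-matched duplexes are made even when the ortholog
sequence violates a preference.

## Synthetic promoter generator

The generator (`synth_fixtures`) emulates only the statistical structure
the design rules touch:

* **Background**: first-order Markov sequence at a requested GC level
  (default 45 %) with CpG dinucleotides suppressed by `cpg_factor`
  (default 0.25), mimicking the CpG depletion of bulk genomic DNA —
  without it, an i.i.d. background of moderate GC has obs/exp ≈ 1 and
  rings with spurious CpG islands.
* **Islands**: placed stretches (~66 % GC, a CpG planted every 6 bp)
  that satisfy the island criteria by construction.
* **Planted targets**: `"auto"` entries are rejection-sampled 19-mers
  passing every intrinsic hard rule; `"decoy:<rule>"` entries fail
  exactly the named rule and pass all others (mask overlap is contextual
  and therefore not a plantable decoy class); explicit sequences are
  recorded with their computed verdict. If a stochastic GC-rich window
  from the background happens to cover a pass-all planted target, the
  background is re-drawn (bounded, still derived from the spec seed), so
  "planted targets satisfy the filters" holds by construction and
  deterministically per seed.
* **Orthologs**: a copy with exactly *n* substitutions placed uniformly
  inside named target windows (never recreating the original base) plus
  optional background divergence sparing those windows.

All randomness flows through one numpy `Generator` seeded per call via
`SeedSequence`; there is no global random state, and identical inputs
give byte-identical outputs across runs and platforms.

What the generator does **not** model: promoter grammar (TATA boxes,
Inr elements, transcription-factor motifs), realistic indel divergence,
chromatin context. Passing tests on synthetic promoters therefore
demonstrate the correctness of the scanning/filtering/scoring logic and
the conservation arithmetic — not that the rule set itself predicts
biologically active saRNAs on real promoters.

## Problem sizes and numerical choices

The test suite and the acceptance script run on 1–2.5 kb promoters
(one scan ≈ 10³ windows) and panels of 20–100 seeds — ample to exercise
every code path while keeping the whole suite in seconds. Scores are
plain float sums (exact linearity in the weights); identity rounding
uses decimal half-away-from-zero to match the conventional printing of
18/19 and 16/19; report floats are rounded to 2 decimals at the
formatting boundary only. Degenerate inputs are defined behaviors:
promoters not covering the design region yield an empty candidate list
with a warning; sequences shorter than the island window yield an empty
mask; empty sequences and out-of-range coordinates raise.

## Known limitations

* The true weighting used in the original Excel-macro implementation of
  these rules is unpublished; the defaults here are reasoned choices,
  and ranked orders under different weights will differ (the hard-filter
  retained *set* does not depend on the weights).
* Which base of the 19-mer anchors the name's position number is not
  fixed by convention; both anchors are supported and reports always
  carry explicit offsets.
* End stability is a two-window nearest-neighbor proxy: no full duplex
  folding, melting temperature, or target-site secondary structure.
* Conservation mapping is ungapped by design; an indel inside a target
  window surfaces as low identity rather than as an alignment.
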