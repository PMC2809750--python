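# sarna-design

Rule-based design of **small activating RNAs (saRNAs)** against gene
promoters, plus cross-species analysis of the designed target sites.

RNA activation (RNAa) is the upregulation of a gene by a 19-bp RNA
duplex with 2-nt 3′ overhangs that targets its promoter. This package
implements the target-selection procedure used to design such duplexes:
it scans the sense strand of a promoter, applies a set of hard
sequence rules, ranks the survivors by a weighted soft score, and
assembles named duplexes. A companion module maps designed targets onto
orthologous promoters (e.g. chimpanzee or African green monkey) to
quantify conservation and to redesign species-specific perfect-match
duplexes. A seeded synthetic-promoter generator makes every part of the
pipeline testable without any sequence download.

## The design rules

Targets are 19-nt windows on the sense DNA strand whose every base lies
between −1200 and −200 relative to the transcription start site
(TSS = +1; there is no position 0). A window survives the hard filters
iff, simultaneously:

* GC content within 40–65 %;
* no homopolymer run longer than 4 nt;
* the 3′ end is thermodynamically **less** stable than the 5′ end:
  ΔG°₃₇(last *k* bases) − ΔG°₃₇(first *k* bases) > 0, with ΔG from
  nearest-neighbor stacking sums (Xia/Turner 1998 RNA parameters,
  *k* = 5 by default) — this biases the RISC machinery toward loading
  the guide strand;
* position 19 (1-based, 5′→3′ on the target) is `A`; position 18 is
  `A` or `T`;
* no overlap with methylation-prone regions: CpG islands
  (Gardiner-Garden–Frommer criteria: ≥ 200 bp, GC ≥ 50 %,
  obs/exp CpG ≥ 0.6), GC-rich stretches (100-bp window ≥ 60 % GC), and
  no CpG dinucleotide inside the target itself.

Survivors are scored
`S = w₁·[pos18 = A] + w₂·[pos7 = T] + w₃·#AT(flank 20–23) + w₄·max(0, asymmetry)`
and returned in descending score order. The RNA strand complementary to
the sense DNA target is the guide strand, so the 3′ end of the target
corresponds to the guide's 5′ end. Duplexes carry dTdT (deoxy) or UU
overhangs and are named `ds<PROMOTER>-<position>` after the TSS-relative
position of the target's 5′-most base (e.g. `dsP21-322` targets −322).

Every threshold and weight above is configuration (`DesignConfig` /
YAML); each report records a hash of the configuration that produced it.

## Worked example

```python
import sarna_design as sd

# a seeded 2.5-kb synthetic promoter with a CpG island and planted targets
record, truth = sd.generate_promoter(sd.default_spec(11))
report = sd.design_promoter(record)          # ranked, retained candidates
print(report[["name", "tss_position", "target_dna",
              "gc_percent", "asymmetry", "sum_score"]].head())
```

```text
     name  tss_position          target_dna  gc_percent  asymmetry  sum_score
dsSYN-888          -888 ACCCAGTAAGCATCTGAAA       42.11       4.55       8.05
dsSYN-661          -661 CTGCCTCTGGTGGGACAAA       57.89       4.66       7.16
dsSYN-937          -937 CTGCAATCTATCCCCTTTA       42.11       4.45       6.95
dsSYN-658          -658 CCTCTGGTGGGACAAATTA       47.37       5.48       6.48
dsSYN-662          -662 TCTGCCTCTGGTGGGACAA       57.89       2.33       6.33
```

35 of the ~983 scanned windows survive the hard filters here. The top
candidate `dsSYN-888` targets position −888, has 42.1 % GC and a +4.55
kcal/mol end-stability asymmetry (3′ end weaker, as required); its
duplex is `sense ACCCAGUAAGCAUCUGAAATT` / `guide UUUCAGAUGCUUACUGGGUTT`
(trailing `TT` = dTdT overhang).

Conservation against a simulated ortholog carrying one substitution in
the −760 target:

```python
ortho = sd.generate_ortholog(record, [(-760, 1)], seed=7, species_tag="PT")
sd.conservation_table(report[report.tss_position == -760], ortho)
```

```text
target_name  n_matches  percent_identity redesigned_name
  dsSYN-760         18              94.7    dsSYN-760-PT
```

18/19 matches is 94.7 % identity; the imperfect match triggers an
automatic species-specific redesign (`dsSYN-760-PT`) that perfectly
complements the ortholog sequence, with any design-rule violations of
the redesigned target reported as flags.

The same workflows are available on the command line:

```sh
sarna synth    --spec spec.yaml --out-prefix syn
sarna design   --fasta syn.fasta --tss-table syn.tss.tsv --out-prefix out
sarna conserve --targets out.design.tsv --ortholog-fasta ortho.fasta \
               --tss-table ortho.tss.tsv --species-tag PT --out cons.tsv
sarna mask     --fasta syn.fasta --tss-table syn.tss.tsv --out masks.bed
```

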