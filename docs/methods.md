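# Methods

`dhblocks` reconstructs, from a multi-sample VCF of a biparental doubled-haploid
(DH) population, which parent each chromosome segment of each line descends
from, and then asks which genes or regions co-segregate perfectly with a
binary phenotype grouping — the inference chain behind mapping a
high-glucosinolate locus in a *Brassica rapa* yellow sarson × pak choi DH
panel. This note records the models, the parameter choices that matter, and
the limits of what the simulation-based validation shows.

## Parent-informative markers

Both parents of a DH panel are fully homozygous, so any biallelic site where
they carry different homozygous alleles is informative: a DH line's allele
there identifies the donor parent. `variants.extract_informative_markers`
keeps exactly those sites and drops multiallelic records (origin calling is
binary-parental; decomposition would add no information), parent-missing and
parent-heterozygous sites. SNPs and small indels both count as markers; a
`snp_only` switch restricts to SNPs. Sites with a QUAL value below 20 (Phred)
are dropped; records without QUAL (e.g. simulator output) pass. Genotypes are
read unphased — `0/1` and `1/0` are equivalent — because origin calling needs
allele content only. Coordinates are 1-based inclusive throughout; only BED
exports convert to 0-based half-open.

Per marker, a line's genotype maps to one of four origin calls: `P1`
(homozygous for the first parent's allele), `P2`, `HET` (one of each), or
`MISSING` (absent or carrying a third allele).

## Block calling: a 3-state HMM

Raw origin calls carry genotyping error, so segmentation into recombinant
blocks uses a hidden Markov model over states {P1, P2, HET} rather than a
windowed majority vote: the HMM handles uneven marker spacing and isolated
errors without a window-size parameter (a `windowed_vote_path` cross-check
mode exists but is not the normative path).

**Emissions.** The observed call equals the hidden state with probability
1 − ε and is each of the two wrong labels with probability ε/2; `MISSING` is
emitted with probability 1 by every state, so missing markers carry no
evidence but their positions still count toward transition distances.
Default ε = 0.02.

**Transitions.** Over a physical gap of *d* bp the P1↔P2 switch probability
is the Haldane recombination fraction r = ½(1 − e^(−2·d·ρ·10⁻⁸)) with ρ the
recombination density in cM/Mb. The 3×3 kernel is T = (1−a)I + a·**1**π with
stationary distribution π = ((1−h)/2, (1−h)/2, h) and a = 2r/(1−h), which
makes the P1→P2 entry exactly r and scales entry into HET by its stationary
weight h (`het_prior`, default 0.01 — ideal DH lines are homozygous, but HET
is kept as a first-class state because residual heterozygosity is real).
Default ρ = 3.5 cM/Mb approximates a ~1000 cM map over a ~283 Mb genome; it
is a tuning default, not a measured value.

**Decoding.** Viterbi returns the maximum-a-posteriori path; ties are broken
by staying in the previous state, and at the first marker by preferring P1
over P2 over HET. Maximal constant-label runs become blocks bounded by their
first and last marker (block coordinates are marker-bounded, never
midpoint-extended, matching how mapped intervals are reported). Runs with
fewer than `min_block_markers` (default 5) supporting markers are merged
into the better-supported flank (left flank on ties), repeatedly until
stable; `n_discordant` is then recomputed against the raw calls. Gaps
between consecutive blocks carry no label; downstream gene assignment
decides how to treat features falling in gaps.

**Resolution limit.** A true segment supported by too few markers cannot
survive decoding at ε = 0.02: absorbing k clean markers costs k·log(ε/2)
against two switch penalties of log r each, so segments of ≲3 markers are
smoothed away even from error-free input. The noiseless-exactness experiment
therefore decodes with a vanishing ε (10⁻¹²) and merging disabled — the
parameterization a user with error-free genotypes would choose — and then
recovery is exact and every inferred breakpoint falls in the same
inter-marker interval as a true crossover.

**Boundary localization.** With ε = 0.02 the exact placement of a block
boundary is uncertain by about one inter-marker interval: a single flipped
call adjacent to a true crossover makes the *true* MAP path put the switch
one gap off (a flip to the opposite parent always does; a flip to HET does
whenever the farther flanking gap is wider, since switching over a wider gap
is cheaper). No decoder can beat this from one line's data. This bounds how
often region endpoints are recovered exactly (below).

## Co-segregation

A gene takes the label of the block containing its midpoint ⌊(start+stop)/2⌋;
a midpoint in an unlabeled gap gives NA, and a gene whose interval overlaps a
block of a different label is flagged boundary-spanning rather than split.
Gene × line matrices carry parent columns filled with the parents' own
labels.

Perfect co-segregation is the normative filter: a gene qualifies when every
group-A line carries one parental label and every group-B line the other, in
either orientation, with any HET or NA cell disqualifying. A
`max_violations` relaxation exists for exploration and defaults to 0.
Statistical association testing is deliberately excluded from this path —
the operation is set logic over definite labels — but a permutation control
(random regrouping of lines) is run in the validation experiments as a
false-discovery check.

Region-level discovery scans each chromosome's markers for maximal runs at
which all group-A lines share one parental block label and all group-B lines
the other; runs under `min_region_markers` (default 10) are suppressed.
Gene-level and region-level discovery agree when marker density suffices:
every co-segregating gene midpoint falls inside a co-segregating marker run.

## Metabolite statistics

Concentration tables come in replicate form (line, replicate, compound,
value) or summary form (line, compound, mean, sd; printed tables are
mean ± sd of n = 3 biological replicates). Not-detected entries are missing
values that count as zero in totals — printed totals still sum over ND rows —
but are excluded from variance calculations, where ND is meaningless.
Rounding is half away from zero at the printed precision: 2 decimals for
µmol-scale glucosinolates, 1 decimal for µg-scale hydrolysis products and
fold ratios. Fold enrichments divide unrounded component sums and round the
ratio; reproduction from printed means is asserted at 1-decimal precision,
since the original folds may have been computed on unrounded lab values.

One-way fixed-effects ANOVA is computed from (n, mean, sd) per level — exact
for replicate input after reduction, and the only option for summary input,
which is flagged `summary_based`. Post-hoc comparisons offer Tukey's HSD
(single studentized-range critical value, Tukey–Kramer standard error for
unequal n; the default) and Duncan's multiple range test (critical value
grows with the span of ordered means, protection level 1 − (1−α)^(r−1), and
pairs inside a non-significant span are non-significant). Both appear in the
source material's statistics and the discrepancy between them is surfaced
here rather than resolved; Tukey is the default because it is the method the
methods section names. The compact letter display uses insert-and-absorb:
every significant pair splits each column containing both members, subset
columns are absorbed, and letters are assigned from the highest-mean level
('a') downward, so levels sharing a letter are not significantly different
at α.

## The synthetic-data generator

The generator is first-class, tested code that defines the study conditions
for every recovery experiment. It emulates: two fully homozygous parents
differing at density 1 marker / 10 kb (Poisson counts, uniform positions,
~10% indels, random parent carrying the reference allele); DH lines as
recombinant mosaics with Poisson(λ) crossovers per chromosome, uniform in
physical coordinates (no interference — the simplest null consistent with a
Poisson crossover count), start label P1/P2 with probability ½, alternating
at crossovers; whole-segment relabeling to HET with probability
`residual_het_rate` (default 0 — residual heterozygosity in DH lines is
regional, hence segment granularity); observation noise that replaces a call
with a wrong label with probability ε = 0.02 or MISSING with probability
0.01; and a total-glucosinolate phenotype with two regimes,
Normal(50, 5) µmol/g dw when the line's origin at the causal-region midpoint
is the high label and Normal(7, 2) otherwise — straddling the observed high
(44.1–57.0) and low (3.3–10.8) ranges, linearly separable at 25. Three
replicates per line are split into compounds by fixed fractions with
gluconapin at 0.85, mirroring its observed 80–91% share. All outputs are
pure functions of (config, seed); substreams are derived per (stage, line,
chromosome) so partial regeneration is stable, and the emitted VCF is
byte-reproducible.

What the generator does **not** emulate: read-level data and genotype
likelihoods, crossover interference, segregation distortion, marker-density
heterogeneity (pericentromeric deserts), linked minor-effect loci, and
compound-level biological variation beyond a fixed fraction split. Passing
recovery experiments therefore demonstrate correctness of the inference
chain under idealized noise, not performance on real resequencing data.

## Validation experiments and their study conditions

Problem sizes were chosen to exercise the method at meaningful scale while
keeping each experiment in the tens of seconds.

* **Marker-label recovery** — 1 chromosome × 10 Mb, 1 marker/10 kb, 50 DH
  lines, λ = 2, ε = 0.02: ≥99% of non-missing markers receive their true
  label (measured ≈99.99%).
* **Viterbi optimality** — 200 random 10-marker sequences: the decoded
  path's joint probability equals the exhaustive maximum over all 3¹⁰ paths.
* **Planted-region recovery** — 100 simulations of 20 DH lines on a 10 Mb
  chromosome with λ = ρ·L = 0.35, making the simulated crossover density
  consistent with the decoder's map assumption; causal locus at
  4.45–4.55 Mb. The oracle is the same region scan run on the true origin
  labels at the same 10-marker minimum; recovery means exact agreement of
  the called and oracle regions over the causal interval. The MAP boundary
  ambiguity above caps this near ~95% (measured 95.3% over 150 design-stage
  seeds); permuted group labels yield no surviving region in ~100% of
  simulations.
* **ANOVA oracle** — F and the SS decomposition match closed-form arithmetic
  on a 3×2 toy table to 10⁻⁹ relative; a 10-sd-shifted level is separated by
  the letter display in 100/100 simulations.

## Known limitations

* Block boundaries are uncertain by ±1 inter-marker interval at realistic
  error rates; reported region endpoints inherit that uncertainty.
* True segments below the marker/merge resolution (< `min_block_markers`
  markers) are invisible by design.
* Per-marker posterior probabilities (forward–backward) are not computed;
  the output is the single MAP segmentation.
* Duncan's test is implemented from its textbook definition; no reference
  implementation exists in the installed stack to cross-check against, so
  its tests assert structural properties (it is never more conservative than
  Tukey; letter consistency) rather than external agreement.
* The count of "recombinant blocks" in a population can be defined per line,
  as union breakpoint intervals, or as distinct population-level segments;
  the pipeline reports per-line blocks and labels them as such.
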