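# Methods

## Scope and model

`sexmarker` operates downstream of variant calling: its input is a set of
diploid genotypes with per-sample sex labels (a VCF plus a sex map, or a
compact genotype table), never reads or alignments. The scientific object
is the *sex-specific marker*: a biallelic site that is heterozygous in
every individual of one sex and homozygous in every individual of the
other. Under female heterogamety (ZW) this is the expected genotype
pattern of a W/Z-divergent site with suppressed recombination; under male
heterogamety (XY) the mirror. Heterozygosity — not allele identity —
carries the signal, because orthologous divergent sites in related
species can segregate different base pairs while preserving the pattern.

## The scan

Per locus, called genotypes are summarised as het/hom/missing counts per
sex and classified:

* `INSUFFICIENT_DATA` — fewer than `min_called_per_sex` (default 3)
  called genotypes in either sex. The default reflects the smallest
  per-sex cohort in the cross-species tables this tool targets; set it
  to 1 to accept pattern rows.
* `MONOMORPHIC` — no heterozygote in either sex. Because the
  classification consumes counts only, "all the same homozygote" cannot
  be distinguished from "two different homozygote classes split across
  sexes"; with het/hom state as the unit of evidence this distinction is
  deliberately out of model.
* `FEMALE_HET_MALE_HOM` — at most `tolerance` homozygous females and at
  most `tolerance` heterozygous males (and at least one individual of
  the dominant state per sex). `tolerance` (default 0) exists to absorb
  genotyping error in noisy reduced-representation data; at 0 the rule
  is the exact all-or-nothing pattern. `MALE_HET_FEMALE_HOM` mirrors it.
  In the degenerate case (possible only at `tolerance > 0`) where both
  directions qualify, the locus is classed `NOT_SEX_LINKED`: the only
  symmetric resolution, preserving label-swap duality.

Each locus gets a two-sided Fisher exact p-value (scipy) on the
`(het/hom) × (female/male)` table of called genotypes, and
Benjamini–Hochberg q-values across the scan (step-up
`q_(i) = min_{j>=i} p_(j)·m/j`, clipped to `[p, 1]`; the clip guards the
`q >= p` guarantee against float round-off). Significance is informative
rather than gating: at the 3-vs-3 scale a perfect pattern reaches only
p = 0.1, so an `alpha` gate is opt-in. The heterogamety call counts
candidates by direction; strict majority calls ZW or XY, ties (including
zero candidates) are `UNDETERMINED`.

Cross-species conservation re-applies the classifier to a congener's
table and requires the *same* direction (female-het) as the reference
panel, since the claim being tested is homologous W-linkage.

## Primer design and in-silico PCR

Allele-specific PCR discriminates haplotypes at the primer's 3' terminus,
where polymerase extension is most sensitive to a mismatch. The designed
forward primer ends on a chosen divergent site (the *anchor*) carrying
the W allele: it matches the W haplotype at the terminus and mismatches Z
there. Up to `n_extra_snp_mismatches` further spanned divergent sites
(nearest the 3' end first) also carry the W allele, sharpening
discrimination; remaining spanned sites keep the Z allele. An optional
artificial 5'-terminal substitution (to a base matching neither
haplotype) mimics the published assay's fourth designed mismatch; being
5'-terminal it barely perturbs annealing. Primer length (default range
18–30 nt) is chosen to span the requested number of usable sites, ties
to the shortest primer — which also minimises spanned-but-unused sites,
each of which costs a mismatch against the W template. When a divergent
cluster is so dense that no anchor satisfies the budget, the design
raises; `choose_anchor_site` scans anchors 3'-most first and returns the
first feasible one, which is how `design_sex_specific_pair` picks its
anchor when none is given. Control pairs are placed entirely outside the
divergent sites (perfect match on both haplotypes) with primer melting
temperatures jointly closest to the target, ties to the leftmost, then
shortest, product.

In-silico PCR is deliberately binary, mirroring band/no-band gel
readouts: a primer anneals iff its 3'-terminal base matches, mismatches
in the 3'-terminal window (5 nt) are at most `max_window_mismatches`
(1), and total mismatches are at most `max_internal_mismatches` (3).
Product length uses the inclusive span between the two primers' 5'
plus-strand positions. Quantitative effects — the "extremely weak band"
a near-matching template can yield in a real reaction — are out of
model. Melting temperatures are deterministic closed forms: Wallace
`2(A+T) + 4(G+C)` up to 14 nt, else `64.9 + 41·(n_GC − 16.4)/N`;
nearest-neighbour thermodynamics, dimer and hairpin screening are
intentionally excluded.

Band-based sexing then follows the assay logic: control band plus
sex-specific band = female; control only = male; no control = invalid
reaction (guards against false negatives from template failure).

## Sex-ratio test

Offspring cohorts are tested against 1:1 with the two-category Pearson
statistic `Σ(O−E)²/E`, `E = n/2`, df = 1, upper-tail p. Ratios are
female/male rounded half-up to two decimals. Yates' continuity
correction is available via a flag and off by default. Note the
uncorrected statistic is anti-conservative against the exact discrete
binomial null at cohort sizes near 60 (p 0.121 vs exact 0.153 for a
24/36 split); the corrected statistic agrees with a binomial Monte-Carlo
null within 0.01 there, which is what the calibration test checks. The
published table this module mirrors prints p-values that match no
standard two-cell test (Pearson, Yates, G, exact binomial); only the
test-invariant equal-count row (p = 1.000) and the printed ratios are
treated as reproducible.

## Synthetic data

The simulator emulates the statistical structure of a RAD-style genotype
matrix from a sexing study: default 10 females + 10 males; autosomal
loci with minor-allele frequency uniform on (0.05, 0.5] and
Hardy–Weinberg genotypes independent of sex; fully penetrant sex-linked
loci (het in the heterogametic sex, hom in the other — no recombination
leakage, modelling suppressed recombination); genotyping error as
replacement by a uniform draw over the three genotypes at the locus
(rate 0.02) and missingness at rate 0.05. The error and missing rates
are illustrative defaults, not estimates. Default locus counts (2000
autosomal + 20 sex-linked) put the scan at the study's marker scale
while staying desk-sized. Haplotype pairs default to a 2315 bp sequence
whose 10 divergent sites cluster in a 285 bp window, mirroring the
short divergent fragment inside a longer cloned sequence.

What a green recovery test establishes: under the clean model the scan's
recall of planted sex-linked loci is 1.0 and autosomal loci essentially
never produce candidates at 10 + 10 samples. What it does not establish:
behaviour under allele-dropout-structured error, depth-dependent
missingness, relatedness among samples, or reference bias — none of
which the generator models.

Exact-test p-values on small discrete tables are super-uniform (much of
the mass sits at p = 1), so the "autosomal p-values look null" check is
one-sided: no anti-conservative excess of small p-values (one-sided
Kolmogorov–Smirnov at α = 0.001 plus a bound on the fraction below
0.05), rather than a two-sided uniformity test that discreteness would
fail by construction.

## Numerical and interface choices

* Genotypes are canonicalised (alphabetical allele order, uppercase);
  accepted missing tokens are `.`, `./.`, `-`.
* Coordinates are 1-based inclusive internally; BED export converts to
  0-based half-open.
* VCF input is biallelic-SNP-only by default (multiallelic records can
  be retained); table input accepts any base pair, since cross-species
  tables may segregate a third allele at an orthologous site.
* Genotype tables carry no coordinates; loci read from them get
  synthetic positions 1..k on pseudo-contig `TABLE`.
* The packaged four-species table encodes exactly the printed rows; the
  reference species' one-pattern-row-per-sex layout is expanded only via
  the explicit `replicate_samples` helper.
* Scans are deterministic: no randomness anywhere outside the simulator,
  which is fully reproducible from its seed.

## Known limitations

* The binary amplification model cannot represent partial amplification
  (weak bands), so a cross-species assay that amplifies faintly in the
  "wrong" sex is reported as a clean failure or clean success.
* Marker significance at very small cohorts is bounded by the exact
  test's granularity; the default pipeline therefore treats the
  all-or-nothing pattern, not the p-value, as the discovery criterion.
* The sexing-primer geometry against the deposited GenBank accession
  (320 bp / 282 bp products) requires that sequence at
  `data/MH133208.fa`; it is not redistributable here and the check
  fails with an explanatory message without it.
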