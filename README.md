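# sexmarker

Sex-specific SNP marker discovery, heterogamety-system inference and
PCR-based molecular sexing for diploid genotype data.

Many crustaceans — mud crabs (*Scylla* spp.) among them — have no
morphologically visible sex at early developmental stages and no
heteromorphic sex chromosomes, yet aquaculture of these species depends on
knowing (and ultimately controlling) sex. When one sex is heterogametic,
sites on the divergent region of the sex chromosome betray themselves in a
sexed genotype panel: under a ZW system every female (WZ) is heterozygous
at a W/Z-divergent site while every male (ZZ) is homozygous; an XY system
mirrors the pattern. `sexmarker` implements the full desk-side workflow
around that signature:

* **scan** a genotype matrix (VCF + sex map, or a compact genotype table)
  for loci whose heterozygosity separates the sexes, with an exact-test
  p-value and FDR control per locus, and call the heterogamety system;
* **cross-species** conservation counting of a reference marker panel in
  congeners;
* **primer design**: allele-specific (female-specific) primers anchored
  3' on a divergent site, control pairs, melting temperatures, and a
  binary in-silico PCR that predicts band patterns (female = control +
  sex-specific band, male = control only);
* **sex-ratio** chi-square goodness of fit against 1:1;
* **simulation** of genotype matrices with Hardy–Weinberg autosomal loci
  and fully penetrant sex-linked sites, W/Z haplotype pairs, and
  binomial offspring cohorts — the ground truth for every recovery test.

## The classification rule

At a locus let `(h_f, H_f)` be the numbers of called heterozygous and
homozygous females and `(h_m, H_m)` the same for males. With tolerance
`t` (default 0) and a minimum of `c` called genotypes per sex (default 3):

```
FEMALE_HET_MALE_HOM  iff  H_f <= t  and  h_m <= t  and  h_f >= 1, H_m >= 1
MALE_HET_FEMALE_HOM  iff  the mirror image
```

At `t = 0` this is exactly "heterozygous in *all* females, homozygous in
*all* males". Each locus also gets a two-sided Fisher exact p on the
`(het/hom) × (female/male)` table and a Benjamini–Hochberg q across the
scan; significance is reported, not used to gate candidacy (with 3 + 3
individuals a perfect pattern only reaches p = 0.1). A surplus of
female-het candidates calls the system ZW, the mirror XY, ties are
undetermined.

## Worked example

The package ships the published four-species, ten-marker genotype table
(`sexmarker.fixtures.load_fixture_table5`). The reference species prints
one genotype *pattern* row per sex; `replicate_samples` expands it into an
explicit cohort:

```python
import sexmarker as sm

table5 = sm.fixtures.load_fixture_table5()
ref = sm.replicate_samples(table5["S. paramamosain"], 3)
res = sm.SexLinkageScan(ref).fit()
print(len(res.candidates), res.heterogamety.system.value)

for sp in ("S. tranquebarica", "S. serrata", "S. olivacea"):
    c = sm.conserved_sex_markers(list(sm.fixtures.MARKER_NAMES), table5[sp])
    print(sp, c.n_conserved, c.conserved_marker_names)
```

prints

```
10 ZW
S. tranquebarica 9 ('SNP2', 'SNP3', 'SNP4', 'SNP5', 'SNP6', 'SNP7', 'SNP8', 'SNP9', 'SNP10')
S. serrata 4 ('SNP2', 'SNP3', 'SNP9', 'SNP10')
S. olivacea 0 ()
```

i.e. all ten markers are female-het/male-hom in the reference species
(female heterogamety, ZW), nine of them show the identical sex pattern in
*S. tranquebarica*, four in *S. serrata*, and none in *S. olivacea* — the
conservation gradient tracks the species' phylogenetic distances.

The offspring sex-ratio table of a full-sib family at three early stages:

```python
for r in sm.ratio_table(sm.fixtures.STAGE_SEX_COUNTS):
    print(r.label, r.n_female, r.n_male, r.ratio_2dp, round(r.p_value, 3))
```

```
Megalopa stage (M) 30 30 1.0 1.0
First crablet stage (C1) 24 36 0.67 0.121
Second crablet stage (C2) 25 35 0.71 0.197
Total 79 101 0.78 0.101
```

No stage deviates significantly from 1:1, consistent with a chromosomal
sex-determination system.

A command-line interface mirrors the library (`sexmarker scan`,
`cross-species`, `sexratio`, `design-primers`, `insilico-pcr`,
`simulate`); run `sexmarker --help`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computations from scratch: the four-species
conservation analysis, the sex-ratio table, a seeded simulation scan
(2000 autosomal + 20 sex-linked loci, 10 females + 10 males) reporting
recall of the planted loci and the system call, and a full sexing-assay
design (allele-specific + control pair) with in-silico PCR on a synthetic
W/Z haplotype pair. It prints each result and writes the results JSON to
`--out`.

One published quantity is *not* reproducible offline: checking the sexing
primers' 320 bp / 282 bp band sizes requires the deposited 2315 bp
GenBank sequence (accession MH133208), which cannot ship with this
repository; `tests/test_acceptance.py` documents how to supply it at
`data/MH133208.fa`.
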