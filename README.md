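# rvkt — the Rare Variant Kinship Test

Sequencing every participant of a family study is still expensive, so a
common design is to sequence only the individuals in the tails of a
quantitative trait distribution, where rare alleles of modest-to-large
effect are enriched. When dozens of traits are available, the question
becomes *which* trait (and which tail) to sequence. `rvkt` implements a
screen that answers it using nothing but pedigree and phenotype data —
no genotypes required — so it can run before any sequencing is bought.

## The test

For a trait *y* measured on pedigreed subjects, and a tail containing
the *k* most extreme individuals, the test statistic is the mean
pairwise kinship coefficient of the tail:

    S = (2 / (k (k−1))) · Σ_{i<j in tail} φ_ij

where φ_ij is the probability that random alleles drawn from *i* and
*j* at an autosomal locus are identical by descent through the pedigree
(φ = 1/4 for parent–offspring and full siblings, 1/16 for first
cousins, …). If a rare variant with a substantial effect segregates in
the sample, its carriers cluster in one tail **and** inside families, so
S rises above what a purely polygenic trait — the null hypothesis —
would produce.

The null distribution of S depends on the pedigrees and on the trait's
narrow-sense heritability h², and is discrete; there is no useful
closed form. It is therefore generated by simulation: many replicates
of a polygenic trait with the estimated h² are drawn *conditional on
the observed pedigrees* (Mendelian sampling of additive genetic values
down the pedigree, plus independent environmental noise), each
replicate is scored with the same statistic, and the one-sided
empirical p-value of the observed S is its exceedance proportion.
Both tails and several tail sizes (1, 2, 4, 6, 8% by default) are
tested; the smallest p-value per trait (p_min) is Bonferroni-corrected
across traits by the Li–Ji effective number of tests, computed from the
eigenvalues of the trait correlation matrix.

Because the null is discrete, a test of exactly size α may not exist;
rejection regions are chosen with size as close to α as possible
without exceeding it, and the achieved size (or the infeasibility, with
the minimum achievable size) is always reported.

## Worked example

Simulate a cohort of 200 four-person nuclear families (800 subjects)
with one trait at heritability 40% carrying an embedded rare variant
(allele frequency 2%, explaining 30% of the trait variance), then
screen it:

```
rvkt simulate --cohort nuclear --n-families 200 --h2 0.4 \
              --q 0.02 --v 0.3 --seed 7 --out-dir demo
rvkt test --ped demo/cohort.ped --phenotypes demo/phenotypes.tsv \
          --out-dir out --n-null 10000 --seed 1
```

The log reports the preparation and h² used for the null:

```
INFO rvkt: pedigree: 800 members, 800 study subjects
INFO rvkt: trait trait_1: n=800, transform=True, h2=0.268 (estimated)
INFO rvkt: screen complete: 1 traits, M_eff=1, 1 significant at alpha=0.05
```

`out/screen_report.tsv` flags the trait (p_min below the resolution of
10,000 null replicates, displayed as `<0.0001`), and
`out/tail_members.json` lists the sequencing candidates per tail. For
this run the best tail is the upper 2% (16 subjects) with an observed
mean pairwise kinship of 0.015 against a null expectation of 0.002
(95% interval 0.000–0.006): the tail members are far more related than
a polygenic trait allows — and indeed all 16 of them are carriers in
`demo/carriers.tsv`, versus an expected population carrier frequency of
2·0.02·0.98 + 0.02² ≈ 4%.

`rvkt power --config power.yaml` batches the same machinery over a
(q, v, h²) grid to estimate power per tail size, and `rvkt kinship`
exports kinship matrices on their own.

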