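# Methods

This note documents the models and procedures implemented in `linumpool`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices a maintainer should
know about.

## Pool-seq VAF model

Each cultivar is sequenced as a pool of `pool_size` = 50 plants. Flax is
diploid, so a pool carries 2 × 50 = 100 gene copies and the realizable
within-cultivar alternative-allele frequencies are multiples of 1/100; the
generator snaps all true frequencies to that grid. Read counts follow

    depth  ~ Poisson(mean_coverage)            (default 400×)
    alt    ~ Binomial(depth, f·(1−e) + (1−f)·e)

with `f` the true frequency and `e` = `error_rate` a single symmetric
per-base error probability (default 0.005). The estimator is the raw read
ratio, VAF = alt/(ref+alt), reported only where depth ≥ `min_depth` (8);
shallower cells are *missing*, never imputed. At 400× the binomial standard
error is at most √(0.25/400) = 0.025, so the mean absolute VAF error across
a cohort sits well under 0.02 (the acceptance script measures ≈ 0.006).

The real assay's artifact mechanisms (PCR mispriming, off-target homologs,
position-specific miscalls) are not modelled individually; the single error
rate is the stand-in, chosen so that error-only sites produce the familiar
low-VAF artifact band that the 20% filter is designed to remove.

## Dual-caller consensus

The original analysis ran two independent variant callers and kept the
intersection. The two in-repo analogues are deliberately transparent:

* **threshold caller** — a site is called if any cultivar has depth ≥ 8,
  alt reads ≥ 2 and VAF ≥ 0.05;
* **binomial caller** — a site is called if any cultivar rejects a
  one-sided exact binomial test of alt reads against Binomial(depth,
  error_rate) at α = 10⁻⁶ (tail computed exactly via `scipy.stats.binom.sf`).

Consensus intersects on the exact (chromosome, position, ref, alt) key;
multi-allelic positions are separate records and never merge. Both callers
share the VAF estimator, so their per-cultivar VAF vectors coincide on
simulated data — the dual-caller design is preserved structurally (both
vectors are carried and screened independently), but unlike the original
two external tools the analogues cannot disagree about the estimate itself,
only about detection.

The low-VAF filter removes a consensus variant whose VAF is below
`vaf_floor` = 0.20 in *every* cultivar. The boundary is closed (a single
cultivar at exactly 0.20 retains the variant): the filter's purpose is to
remove the 2–20% artifact band, and 20% itself is treated as signal.
Filtering is applied after consensus (configurable).

Cultivar heterogeneity: a pooled cultivar is heterogeneous at a site when
its caller-averaged VAF lies strictly inside the band (0.2, 0.8) — neither
allele fixed. A cultivar is flagged when any gene contributes at least one
such site.

## Gene models and codon effects

The six desaturase genes are represented with 1-based inclusive coordinates
(the VCF and genome-assembly convention). SAD1/SAD2 have three exons,
FAD2A/FAD2B are intronless, FAD3A/FAD3B have six exons; spliced coding
lengths must be divisible by 3 and are validated at load time. Upstream and
downstream labels follow the transcription direction within a `flank_bp` =
2000 window; the published association table labels flank sites without
stating a window, and all of its flank sites fall within 2 kb of the genes
as modelled here.

Codon effects reverse-complement alleles for minus-strand genes before
lookup. Single-base exonic substitutions yield silent/missense/nonsense;
exonic indels yield frameshift iff the length change is not a multiple of
3; same-length multi-base substitutions are resolved by rebuilding the full
spliced CDS with the alternative allele and diffing translations, which
avoids ad hoc codon arithmetic at codon boundaries. A reference/allele
mismatch raises instead of silently annotating.

The packaged gene models are **synthetic stand-ins**: real chromosome
accessions and real variant-site coordinates, invented gene/exon
coordinates. They were constructed so that (a) the published gene and
protein lengths hold exactly, (b) every region label in the reference
association table is reproduced, and (c) a deterministic synthetic
reference sequence (random non-stop codons around planted codons; fixed
seed) reproduces every reported codon effect: FAD3A Trp→stop
(CP027631.1:16092348, minus strand, TGG→TGA), FAD3B His→Tyr
(CP027622.1:1035655, CAT→TAT), the alternative FAD3A Arg→stop
(CP027631.1:16090340), Ala→Thr (16092575), Ile→Ser (1035674), and silent
substitutions elsewhere. One source-table inconsistency is resolved in
favour of the standard genetic code: ATC→AGC is Ile→Ser (the prose phrase
"serine to isoleucine" reverses it). The exonic SAD2 site 17365164 is
modelled with the table's T→C alleles (silent here); the prose describes a
GGT→AGT Gly→Ser change at that coordinate, which is tested directly on
codons instead.

## Association screen

Each consensus variant's VAF vector is correlated with each of the five
fatty-acid percentages, separately per caller: Spearman r_s with average
ranks for ties and a two-sided p from the t-approximation on n−2 degrees of
freedom (adequate at n = 84; perfect correlations map p to the smallest
positive float so p stays in (0, 1]); Kendall τ_b with the asymptotic
normal p is reported alongside but plays no role in selection. Zero
variance leaves a correlation undefined (NaN with a warning). Pairs with a
missing value are dropped first; at least five complete pairs are required.

A record is an FAA polymorphism iff |r_s| > 0.25 **and** p < 0.05 under
both callers. The inequality is strict — r_s = 0.25 exactly is not
selected. When the rule is applied to a *printed* table whose coefficients
are rounded to two decimals, a printed −0.25 may stand for any value in
(−0.255, −0.245]; `select_faa` therefore takes a `rounding_tol` argument
(half an ulp of the printed precision, 0.005) used only for printed inputs.
With it, the packaged reference table yields exactly 31 FAA sites (5 SAD1,
3 SAD2, 3 FAD2A, 9 FAD3A, 11 FAD3B; 29 SNPs + 2 indels); without it, the
two rows printed as −0.25 would be lost.

No multiple-testing correction is applied by default, matching the original
screen (raw p < 0.05); a Benjamini–Hochberg helper is provided but off by
default. rStD (sample sd / mean of the threshold-caller VAF vector) is
reported as a reliability indicator, never used as a filter.

## Two-locus LIN classification

A variant is *present* in a cultivar when its caller-averaged VAF reaches
`presence_floor` = 0.40 — the least threshold the observed data support:
the exceptional low-LIN line carried its alternative nonsense variant at
~80% VAF, while no FAD3B variant reached 40% in that line. The rule:

* both key variants present → **low**;
* exactly one → **mid**;
* neither → **high**;
* any *other* FAD3A nonsense variant present → **low** with
  `exception_flag` set. This generalizes a single observed exception (one
  line owed its 9.4% LIN to an Arg→stop variant) into an explicit, flagged
  rule rather than a silent special case.

Phenotype-derived classes use LIN ≤ 10% (low), 30–47% (mid), ≥ 50% (high),
anchored to the observed class exemplars; cultivars in the gaps are left
unclassified rather than forced. Accuracy is computed over classified
cultivars, with the unclassified count reported separately.

## Clustering

VAFs below `zero_floor` = 0.20 are zeroed (suppressing residual off-target
signal), missing values become 0, and cultivars are clustered on Euclidean
distances with the Ward-D2 criterion — squared distances inside the
objective, merge heights on the distance scale. This is exactly what
`scipy.cluster.hierarchy.linkage(method="ward")` computes and matches R's
`hclust(method="ward.D2")`. The test suite verifies the merge sequence
against an independent greedy implementation built from the closed form
cost √(2·|A||B|/(|A|+|B|)) · ‖centroid_A − centroid_B‖ for all inputs with
n ≤ 7. Exact ties are resolved by scipy's nearest-neighbor chain,
deterministic for a given input; cluster labels from tree cuts are
renumbered by dendrogram leaf order so outputs are stable run to run.

## Synthetic cohorts: what is and is not emulated

Defaults mirror the emulated study: 84 cultivars, 50-plant pools, 400×
coverage, error 0.005, per-gene site counts skewed towards FAD3A (30) and
FAD3B (21) versus 4–7 for the others — about a third of the real panel's
dual-caller variant tallies, keeping the full test suite and acceptance
script in the tens of seconds. Genotype strata follow the observed panel:
9 cultivars with both key variants, 2 + 2 with one, 1 with the alternative
FAD3A nonsense at 80% VAF (plus trace 5–10% carriers elsewhere), the rest
with neither. Heterogeneity is modelled at cultivar level: a `het_fraction`
(0.3) of cultivars carry intermediate snapped frequencies at a random ~20%
of background sites, so the flagged-cultivar fraction estimates
`het_fraction` directly.

Phenotypes are compositional: PAL, STE and OLE are drawn uniformly inside
windows with margins, OLE with a weak positive dependence on SAD1 allele
frequencies; LIN follows a piecewise-decreasing function of the key-variant
burden that traverses each class window (low 4.8–8.2, mid 33–44, high
51–53) top-to-bottom, so raising a key frequency never raises LIN; clipped
Gaussian noise (±2 sd, per-acid weights) is added; and LIO closes the
composition to exactly 97% of oil. Window margins are sized so noise and
closure cannot leave the observed ranges (PAL 5–7.6, STE 2.7–6.4, OLE
12.9–24, LIO 11.9–72.4, LIN 2.7–65.3); violations raise a configuration
error instead of clipping.

Deliberately not emulated: read-level FASTQ, PCR-amplicon/primer bias,
linkage beyond the key-site strata (random background sites are
unlinked — in the real panel the eight non-key FAD3A FAA variants travel
together as a haplotype), position-specific error profiles, and FAD3A
background nonsense variants (excluded so random background variation
cannot collide with the two-locus rule; in a real panel purifying selection
plays that role). Consequently, passing tests demonstrate correct recovery
of the *assumed* generative structure — estimator calibration, caller
operating characteristics, rule logic, cluster geometry — not robustness to
real amplicon artifacts.

A `three_strata_demo` configuration fixes every background site (all-ref or
all-alt) so the only between-cultivar variation is at the key sites; this
is the "low noise" geometry used to demonstrate stratum recovery by
clustering (Rand index ≈ 0.99 at k = 3).

## Statistical testing of stochastic properties

The detection-power property — the planted FAD3A-nonsense/LIN record is
significant (negative r_s, p < 0.05, both callers) with probability ≥ 0.95
over seeds at n = 84 — sits almost exactly at its own boundary under the
stated conditions: measured over 400 cohorts the rate is 0.948 ± 0.011.
The dilution is intrinsic to Spearman on pooled data: sequencing-error
reads break the rank ties among the 73 non-carrier cultivars and randomize
their ranks, shrinking the observed correlation (mean r_s ≈ −0.34, versus
−0.58 for the noise-free frequencies) — consistent with the magnitudes the
original screen reported (|r_s| 0.29–0.43). The suite therefore tests the
probability statement as a one-sided binomial check: over 100 fixed seeds
it requires ≥ 90 detections, the ≈ 99.5% lower envelope of a true rate of
0.95. A literal ≥ 19/20 point check would fail a large fraction of runs
even when the property holds exactly.

Other stochastic checks (false-positive rate 0.05 ± 0.02 under permutation,
heterogeneity recovery ± 0.1, Rand ≥ 0.95, MAE ≤ 0.02) have comfortable
margins at their fixed seeds and are asserted directly.

## Known limitations

* The caller analogues share one VAF estimator; real caller pairs disagree
  more, so dual-caller agreement is easier here than on real data.
* Association power and calibration are assessed under independence of
  background sites; real panels have linkage and population structure, and
  no structure correction is implemented (matching the original screen).
* The gene models and reference sequences are synthetic stand-ins; results
  tied to real coordinates (e.g. re-annotating real VCFs against the
  actual assembly) are out of scope.
* Real-data variant totals and cluster memberships require the original
  raw reads and tool versions and are not reproduced here.
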