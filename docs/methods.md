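# Methods

`terpomics` re-implements, as a tested library and pipeline, the combined
transcriptome–metabolome workflow used to propose candidate genes for
regionally differential terpene accumulation in grape berry (*Vitis
vinifera*, a muscat-type variety grown in a humid eastern region, CL, and
an arid northwestern region, GT, sampled at four Eichhorn–Lorenz stages —
E-L 31 pea-size, E-L 35 veraison onset, E-L 36 intermediate Brix, E-L 38
harvest — in two consecutive years). This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Expression quantification and differential expression

Reads are trimmed 2 nt at each end and kept when the trimmed length is
≥ 60 nt with ≤ 2 ambiguous bases. Alignment itself is out of scope (the
mapping settings "two mismatches, ten hits" are carried as provenance
metadata only); the package starts from per-library unique counts plus
multi-read groups.

**Multi-read rescue.** A group of reads mapping to several transcripts is
split across its candidates in proportion to the candidates' unique-read
counts, `share_t = U_t / Σ U`, with a uniform split when all candidate
uniques are zero (the source procedure is silent on that corner).
Assigned counts are fractional; totals are conserved exactly
(`Σ C = Σ U + Σ multiplicities`). Expression is
`RPKM = 1e9 · C / (N · L)` with transcript length `L` in nt and `N` total
mapped reads.

**Replicate-free DE testing.** The two-library comparison uses the exact
conditional binomial test (Audic–Claverie equivalent): conditional on
`k = x + y`, `x ~ Binomial(k, N1/(N1+N2))` under the null, two-sided
p = twice the smaller tail including the observed point, capped at 1.
This is the era-standard test for digital expression without replicates;
which proprietary test produced the original p-values is unknowable, so an
exact, assumption-light choice was made. Undetected genes default to a
count of 1 before testing (this also bounds the log2 ratio). Fractional
rescued counts are rounded to the nearest integer (ties up) for the exact
test only. Replicate libraries within a condition (two at E-L 35 and
E-L 38) are pooled by summation before testing. Multiplicity is handled
by the Bonferroni factor `m = number of transcripts tested`, reported as
`adjusted_p` (the source text conflates Bonferroni with FDR; the literal
Bonferroni rule is implemented and the column named for what it is).
A gene is called DE at `adjusted_p ≤ 0.05` and `|log2 ratio| ≥ 1`.
Calibration: over 2,000 simulated equal-rate Poisson pairs the raw test
rejects ≤ 5% at α = 0.05 (the exact test is mildly conservative).

## Metabolite semi-quantification

GC-MS peak areas are converted to internal-standard equivalents:
`c = (A_analyte / A_IS) · c_IS` with all response factors fixed at 1.
The default spike is 10 µL of 1.0018 g/L 4-methyl-2-pentanol into 5 mL of
juice, giving `c_IS = 2003.6 µg/L`. All concentrations are reported in
µg/L (the supplementary tables of the source study do not restate units;
µg/L is assumed and used consistently). Peak detection and compound
identification are out of scope.

Odor activity is `OAV = concentration / sensory threshold`; `OAV ≥ 1`
counts as potentially aroma-contributing. The boundary is inclusive so
threshold-equal compounds are flagged for review.

Per-form totals are the mean over replicates of the per-replicate sums
over compounds, with the SD taken over those replicate sums; free and
glycosidically bound fractions are never pooled, and empty cells are
reported as missing, never zero.

Group comparison is one-way ANOVA followed by Duncan's multiple range
test: ordered means are compared with studentized-range critical values
at protection levels `α_p = 1 − (1 − α)^(p−1)` for a span of `p` means
(harmonic-mean group size for unequal n); a non-significant range
protects all of its sub-ranges, making non-difference contiguous in mean
order, so letter codes encode the pairwise decisions exactly. Quantiles
come from `scipy.stats.studentized_range` and are cached (the underlying
quadrature is expensive). With zero residual variance and unequal means
the p-value is reported as 0.

## Profile analysis

Heatmap-style matrices are row-standardized with the R `scale` convention
(mean 0, SD 1 with the n−1 denominator); constant rows map to zeros with
a warning. Hierarchical clustering uses Euclidean distance and complete
linkage (the R `hclust`/`heatmap` defaults; both configurable) with
scipy's deterministic lowest-index tie-breaking, and dendrograms export
to Newick with branch lengths equal to merge-height differences, so the
tree is ultrametric with leaves at the root merge height.

Developmental trends over the four ordered stages are classified by the
Pearson correlation of the profile with the stage ranks 1–4 (calendar
days are not used): `increased` at r ≥ 0.7, `decreased` at r ≤ −0.7,
otherwise `stable`; `NC` (not clustered) when detected at ≤ 2 stages;
`ND` when absent from the reference annotation. A `peaked` subtype flags
an interior maximum ≥ 2-fold above both endpoint values. The |r| ≥ 0.7
and 2-fold settings are this package's explicit stand-ins for what the
original study judged by eye from heatmaps; both are configurable. The
class (though not the fold-based peak flag) is invariant to positive
affine transforms of the profile.

K-means trend clustering (for the 147-member glucosyltransferase family
screen) uses k-means++ with a fixed seed; k defaults to 9 (the original
cluster count is not recoverable — only the three upward clusters were
ever discussed). A cluster is "upward" when its centroid correlates
with the stage index at r ≥ 0.7, replacing the original visual selection.

## Gene–metabolite integration

Profiles are aligned on condition cells (region × year × stage, 16 cells
in the full design), averaging replicate libraries/extractions per cell —
matching per-condition reporting in the source — before Pearson
correlation; p-values use the exact t transform with n−2 df and no
multiple-testing correction (the screening usage reports raw p < 0.05).
`cumulative` mode first replaces expression by its running sum over
stages within each region-year series, which asks whether accumulated
transcript output tracks a metabolite pool (suited to stored products
such as monoterpenol glucosides made by an early-expressed enzyme).

Candidate nomination is the conjunction of correlation and regional DE
evidence: max |r| ≥ 0.8 (aligned with the network threshold) and a
significant regional DEG call at ≥ 1 stage. The supporting metabolite
set is the sign-concordant group containing the strongest correlation;
strong opposite-signed correlations do not disqualify a candidate — a
ripening-induced enzyme inevitably anti-correlates with compounds that
decline over ripening — but are reported in an `n_discordant` column.
Rank score is `max |r| · (1 + n_supporting/10)` with gene-id tie-breaks.

## Co-expression networks

All cross pairs between two profile sets are scored with Pearson r;
edges require |r| at or above the threshold. The original description of
the 0.8 cutoff is inconsistent between strict and inclusive (and some
qualifying correlations are quoted down to 0.78); this package defaults
to a single inclusive ≥ 0.8 with an `inclusive` flag and per-call
override rather than per-layer thresholds. Edges are undirected,
canonicalized by id order, signed by the sign of r.

The anchored three-layer network admits a transcription factor only when
it passes the threshold against **every** anchor (the anchors default to
the nominated candidate genes, e.g. the MEP-pathway reductase and the
monoterpenol glucosyltransferase); a ripening-associated gene is admitted
when it passes against ≥ 1 admitted factor; anchors never connect
directly to ripening genes. Factors wholly positive or wholly negative
toward the anchors are labelled accordingly; mixed-sign factors are kept
and labelled `mixed`. Whether the original correlations were computed
over all 16 cells or within-region subsets is not stated; all-cell is the
default and the cell convention is configurable. A threshold above every
observed |r| yields an empty network, never an error. Networks export to
Cytoscape-loadable SIF (`pos`/`neg` interaction types) and GraphML (r as
edge weight) with node/edge attribute tables; GraphML round-trips
losslessly.

## qPCR validation

Relative expression is `2^(−ΔCT)` with `ΔCT = CT_target − CT_ref`, where
`CT_ref` is the geometric mean of the reference genes (GAPDH, actin,
ubiquitin in the motivating assay). Technical replicates are averaged on
the CT scale (arithmetic mean) before transformation. RNA-seq agreement
is assessed per gene on log2 values across paired samples; a gene
validates at R² > 0.7 **and** r > 0 — R² alone is directionless and an
anti-correlated gene should not validate. Whether the original R² used
raw or log values is unstated; both are reported, log is the criterion.

## Climate summaries

Phenophase-level records (Flowering, Berry development, Veraison,
Ripening) carry days, radiation (kJ/m²), growing degree days (opaque
degree-day units; the base temperature is never stated), sunshine hours,
rainfall (mm) and mean day–night temperature difference (°C). Season
summaries sum the additive fields and average the temperature difference;
the published season-level temperature differences match the unweighted
phenophase mean for the recent year and only approximately a
days-weighted mean for one older row — unweighted is the default, a
days-weighted option exists, and totals are always recomputed from the
phenophase rows rather than trusted from printed total lines (one printed
radiation-sum line is internally inconsistent with its own rows).
Region contrasts report signed differences and ratios per metric, with a
zero denominator yielding a missing ratio.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design exactly: 2 regions × 2 years ×
4 stages; one RNA-seq library per region-year at E-L 31 and E-L 36, two
at E-L 35 and E-L 38 (24 libraries); two biological repeats per condition
cell for metabolites (32 samples). Each feature follows a log2 latent
profile: baseline + archetype stage trajectory (increasing / decreasing
/ peaked / stable, amplitude 3 log2 units) + a year effect
(sd 0.15) + cell noise (sd 0.1 by default). Planted effects override the
archetype, add a first-region multiplier ramped toward harvest (the
"higher in CL at maturity" pattern), and attach correlation partners
built as `r·z + sqrt(1−r²)·g` on the standardized target latent — the
realized sample correlation fluctuates honestly around the requested r
and is exported in `planted_truth.tsv` for verification. Counts are
negative-binomial (dispersion 0.05) around latent means scaled to 1e6
reads per library by default (library sizes are not published; this is a
config knob), with a configurable share of counts diverted into
multi-read groups under exact conservation. Concentrations are
log-normal in µg/L with the bound form 3× the free form by default
(bound terpenes are substantially more abundant in this system) and
replicate noise sd 0.15. The climate table reuses the published layout
with freshly drawn values expressing the regional contrast (arid region:
less rain, more sunshine, larger diurnal range).

What passing tests on these data show: the pipeline's arithmetic,
thresholds, admission rules and rankings recover planted structure at the
stated noise levels, and its test statistics are calibrated on true
nulls. What they do not show: performance under real read-mapping
artifacts, compound misidentification, batch effects, or biological
confounding — none of which the generator models. Two further honest
gaps: measured (count-level) correlations are attenuated a few percent
below the planted latent r by counting noise, and in very small gene
universes a strong planted effect perturbs all other genes' count
fractions (a compositional artifact); the recovery studies therefore use
a background universe of ~100 genes, small enough to run hundreds of
seeds cheaply but large enough that no single gene dominates a library.

## Problem sizes used by the test suite and acceptance script

Calibration uses 2,000 null gene pairs (DE type-I error) and 1,000
independent profile pairs at n = 16 (correlation p uniformity, KS
check). Recovery studies run 200 seeds each: candidate nomination on a
~100-gene universe with one gene planted at r = 0.9 to three bound-form
compounds and a 4-fold regional effect at harvest; anchored-network
recovery with two anchors sharing a latent ripening trajectory,
qualifying factors at in-sample |r| ≈ 0.99, single-anchor decoys placed
by exact rotation in the anchor plane (≈ 0.85/0.77 to one anchor, below
0.55/0.96 to the other, straddling the 0.8 threshold with wide margins),
and independent background factors. The planted-correlation check
regenerates 200 bundles with a 0.95-target partner at noise sd 0.05 and
verifies the mean realized r within 0.05 of target.

## Known limitations

* No replicate-aware dispersion modelling in DE testing (the source used
  none); the exact test's p-values are anti-conservative with respect to
  biological variability it cannot see.
* Trend classes depend on fixed thresholds standing in for visual
  curation; genes near |r| = 0.7 are classification-unstable.
* Duncan's test controls per-comparison error at its protection levels,
  not family-wise error; letters are descriptive, as in the source field.
* The cumulative correlation mode treats stages as equal steps (no time
  weighting by days between stages).
* Semi-quantification with unit response factors yields IS-equivalent
  concentrations, not absolute ones; OAVs inherit that approximation.
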