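# Methods

This note records the models, the generator's assumptions, the numerical
choices and the known limitations of `lncdev`.  The package analyses a
six-state neural lineage design — NSC (reference) and N/OP, GABAN, OLP,
PMO, MYO — profiled on two-colour arrays, three replicate arrays per stage,
each hybridizing the stage sample (channel 1) against the common NSC sample
(channel 2).

## Synthetic study generator

The generator exists so that every downstream stage can be tested against
planted ground truth.  It emulates the *statistical and structural*
properties the analysis relies on, not the biophysics of hybridization.

**Genomes and annotation.**  One synthetic chromosome per genome; loci are
placed on a fixed slot grid (15 kb per locus, ≥ 5 kb between unrelated
loci) so no context call can arise by accident.  Genes have three 300 bp
exons (all coding) separated by 1 kb introns.  ncRNAs realize the
configured context-class proportions by construction: antisense ncRNAs
overlap the middle exon of their host on the opposite strand; intronic
ncRNAs sit wholly inside intron 1 (orientation drawn at random);
bidirectional ncRNAs end 100–900 bp upstream of the host TSS on the
opposite strand; intergenic ncRNAs occupy their own slots (two exons, so
intron-only structure windows can be planted).  Genome B repeats the layout
with fresh sequence and shifted coordinates; all genes have orthologs, and
the configured conserved fraction of *anchored* ncRNAs (intergenic loci
have no anchor) receive a counterpart in the same class relative to the
ortholog.  Sequence is i.i.d. uniform ACGT — real genomes have repeats and
compositional structure, so mapper ambiguity rates on real data will be
higher than here; the duplicated-locus fixtures cover the ambiguity logic
explicitly.

**Probes.**  One probe per transcript (65-mers on mRNAs, 70-mers on
ncRNAs), drawn wholly within one exon so ungapped alignment is exact, plus
negative-control probes verified absent (both strands) from both genomes.

**Spot intensities.**  Per probe, a baseline log2 intensity
`a ~ N(10, 1.2²)` and a variance `σ² ~ s₀²·d₀/χ²_{d₀}` (defaults d₀ = 4,
s₀² = 0.02), so the moderation model's prior is *exactly* satisfiable and
hyperparameter-recovery tests are meaningful.  Channel log-intensities are
`a ± lfc/2` plus `N(0, σ²/2)` noise per channel (hence `Var(M) = σ²`), a
smooth cubic dye bias `amp·z³` in the centred intensity `z` is injected
into every spot, and foregrounds add a lognormal background whose reported
value carries measurement error.  Probes with no transcript present
("silent"; default fractions 0.69 of mRNA and 0.91 of ncRNA probes, the
emulated platform's expressed-above-background complement) and negative
controls carry background-level signal only; control spots get a small
positive nonspecific-binding offset (0.12 on the log scale), which makes
the control-derived background threshold conservative — random-sequence
oligos do pick up low-level cross-hybridization that truly absent targets'
probes do not.

**Planted effects.**  Outside the templates, each non-silent probe is DE
per contrast independently (defaults 0.16 for mRNA, 0.05 for ncRNA probes,
mirroring the emulated study's DE fractions) with |log2 FC| uniform on the
configured range and random sign.  Marker templates are fixed stage vectors
— OLP peak (0.3, −0.3, 2.8, 1.2, 0.5), monotone ramp up
(0.1, 0.3, 0.9, 2.0, 3.2), monotone decline (−0.2, −0.6, −1.2, −2.2, −3.0)
— shared (or inverted) by configurable ncRNA groups plus one mRNA marker
each, so correlation-screen membership is computable in advance.  Template
probes draw their variance at the prior scale rather than from the
inverse-chi-square tail: markers model well-measured genes, and a single
heavy-tail variance draw on a marker would randomize the whole screen.
Discordant and concordant ncRNA/host pairs are planted by overwriting one
contrast of an anchored ncRNA and its host (±2 log2 units).

**qPCR.**  Planted log2 fold changes per gene × arm × timepoint; one
Neat1-like gene responds +2 (stochastic arm) and −2 (instructive arm), most
other responders are repressed, a few induced, one gene is null.  Ct values
realize the fold changes at efficiency E = 2 with N(0, 0.2²) cycle noise;
the reference gene is condition-invariant.  Four replicates per group: the
exhaustive 4v4 fixed-reallocation test has 70 partitions, so its smallest
two-sided p (2/70 ≈ 0.029) can clear the 0.05 level, whereas 3v3 bottoms
out at 0.1.

**What the generator does not emulate** — realistic sequence composition,
splicing, probe thermodynamics, spatial array artifacts, print-tip effects,
between-array scale differences (none are planted; see the adaptive gate
below).  Passing tests therefore demonstrate correctness of the analysis
logic and calibration under the stated noise model, not robustness to every
real-data pathology.

## Probe mapping

Ungapped seed-and-extend: 11-mer exact seeds at stride 11 (plus the final
offset) on both strands over a sorted k-mer index; candidates are extended
to full length and scored (`score = matches − mismatches`; N never
matches).  At ≥ 99% identity a ≤ 70-mer admits zero gaps, so ungapped
search is lossless for acceptable hits, and any hit with ≤ 5 mismatches
keeps an intact seed, so all filter-relevant hits are found.  Hits failing
the identity (99%) or score (50) filters are retained with a rejection
status.  "Reliably mapped" is operationalized as: if more than one accepted
hit scores within 1 of the best, all are marked ambiguous and the probe is
excluded.  Target classification requires exactly one accepted hit and is
strand-aware (same-strand CDS exon ⇒ protein-coding, else same-strand ncRNA
exon ⇒ noncoding, else excluded).

## Differential expression

*Background correction*: `corrected = max(fg − bg, floor)` with the floor
at half the smallest positive corrected value per array-channel (flagged).

*Within-array normalization*: the intensity trend of M on A is a
least-squares cubic B-spline with knots at A quantiles (knot count
`max(2, round(1/span))`, default span 0.3).  The basis depends only on A,
so the fit is a linear projection and normalization is exactly idempotent —
a property a loess smoother cannot have (local regression is not a
projection; empirically an iterated-loess fixed point also stalls around
1e-2).  A loess fit with the same span gives visually identical trends on
this data.

*Normalization anchors*: both the trend fit and the scale target use
"anchor" spots — above the negative-control 95th percentile in *both*
channels (background-level spots have meaningless M and, worse, M spreads
that depend on each array's random floor), then iteratively trimmed at
3 MAD around a pilot trend (3 rounds) so that dense planted effects cannot
be absorbed into the trend.  With fewer than 30 anchors an array falls back
to all non-control spots.

*Between-array normalization*: MAD-scale equalization to the geometric-mean
target, computed on a probe set held consistent across arrays (probes whose
spots survive trimming on ≥ 80% of arrays) — per-array anchor sets would
let composition differences masquerade as scale differences.  Rescaling is
applied only when the spread of per-array log-MADs exceeds twice the MAD
sampling noise (relative sd ≈ 1.166/√n): equalizing statistically
indistinguishable MADs injects pure multiplicative jitter, which measurably
degrades effect recovery (planted-M MAE ≈ 0.43 → ≈ 0.10 at 750-probe scale
in our measurements) and is fatal in the noise-free limit.

*Expressed above background*: stage-channel corrected intensity above the
array's negative-control 95th percentile in ≥ 2 of 3 replicates for ≥ 1
stage.  The criterion is a declared convention; it is exposed
(`n_required`, percentile) rather than hard-coded.

*Linear model*: reference design — the contrast estimate is the mean
replicate M, the residual variance is pooled across contrasts,
`df = Σ(nᵢ − 1)`; contrasts with < 2 replicates are dropped with a warning.

*Moderation*: `(d₀, s₀²)` by moment matching on `log s²` (mean and variance
with the digamma/trigamma corrections; trigamma inverted by Newton), which
is the same estimator as limma's `fitFDist` — the cross-check test confirms
agreement of d₀, s₀², t and p with `eBayes` to better than 1e-8 on a shared
matrix.  Estimation is restricted to expressed probes: silent probes'
background-only variance is not drawn from the noise prior.  The effect
prior variance `v₀` is moment-matched on the top `p_prior` fraction of
|t̃| (per-statistic candidates `u²(t̃²(ν−2)/ν − 1)`, positive ones
averaged); `p_prior` defaults to 0.01.  The B-statistic is
`log(p/(1−p)) − ½log r + ((1+ν)/2)·log((t̃²+ν)/(t̃²/r+ν))` with
`r = (u²+v₀)/u²` (normal-limit kernel at infinite ν); it is strictly
increasing in |t̃| at fixed ν.  Forcing d₀ = 0 recovers the ordinary t;
d₀ = ∞ pools every probe to s₀².  Benjamini–Hochberg is applied per
contrast (NaNs excluded from ranking and propagated).  DE call: expressed
and B strictly greater than 1.

## Genomic context

Coordinates are 0-based half-open internally (GFF3 converted at the
boundary, BED native).  Antisense requires ≥ 1 nt exon–exon overlap, not
mere locus overlap; intronic requires whole containment in one intron;
bidirectional requires opposite strands, disjoint spans, and a head-to-head
TSS separation of 1…1000 bp (separation counts from the ncRNA's last base
to the gene's first, so abutting loci have distance 1).  Precedence
antisense > intronic > bidirectional for the primary label; all qualifying
relationships are retained, and ties inside the winning class resolve to
the nearest TSS then the lexicographically smallest gene id, making the
call independent of input order.  Conservation classifies the second
genome's ncRNAs the same way and demands the same class relative to the
ortholog of the host; intergenic ncRNAs and hosts without orthologs are
reported as not evaluable.  Enhancer association accepts locus overlap or a
nearest-base distance ≤ 5 kb from the TSS; structure intersection demands
an exon-overlapping window with P strictly above the threshold (0.9
working level; counts at 0.5 also reported).

## Screens and enrichment

Correlation screens use signed Pearson r with threshold √0.9 ≈ 0.9487 —
an R² criterion alone is sign-blind, and concordant vs anti-correlated
sets mean different biology — computed over the five contrast means.  The
candidate pool is the expressed *and differentially expressed* ncRNAs
(configurable): a probe with no real change has an arbitrary noise profile
whose correlation carries no information.  "Down during OL differentiation"
is ambiguous across OLP/PMO/MYO, so the lineage-switch screen has a strict
(all down-contrasts) and a non-strict (first only, default) mode.
Enrichment is the one-sided hypergeometric tail `P(X ≥ k)` with BH over the
tested terms; the universe is the expressed probes' genes, the standard
choice when the assayed background is known.

## qPCR / TSA

The ratio is `E_t^ΔCt_t / E_r^ΔCt_r` with `ΔCt = mean Ct(untreated) − mean
Ct(treated)` and E fixed at 2.0 by default (per-gene efficiencies accepted
via the Ct table's E column).  Significance uses a two-sided
fixed-reallocation randomization test on reference-normalized per-replicate
values (Ct_target − Ct_ref, paired by replicate): exhaustive over all
partitions when ≤ 10,000 exist, otherwise 2000 seeded permutations with
add-one smoothing.  The test is invariant to adding a constant to all Cts
and to group order.  A gene is flagged "opposite arms" when both arms are
significant at a timepoint with opposite-signed log ratios.

## Numerical details and degenerate inputs

Constant-A arrays fall back to median-M subtraction; constant profiles are
excluded from correlation with a flag; zero-MAD arrays are excluded from
the scale target; all-equal permutation inputs give p = 1; s² = 0 probes
get t = ∞ under d₀ = 0 (and finite moderated t otherwise); NaN p-values
pass through BH unranked.  B-statistic boundary: `B = 1` exactly is *not*
DE (strict inequality).  All writers emit a header comment with the
configuration hash and seed; every pipeline output is byte-reproducible
from (config, seed), and the manifest records per-file SHA-256.

## Problem sizes

The bundled demo uses 200 genes / 100 ncRNAs / 40 controls with planted-set
sizes scaled so the expressed and DE fractions stay realistic relative to
the pool (dense absolute planting at tiny scale would overwhelm the
normalization anchors, which no estimator survives).  The statistical
checks run at 2000 probes (null calibration, power, DE-fraction ordering,
default-noise marker recall) and 5000 probes (variance-prior recovery);
oracle equivalence uses a 50-probe mapping fixture and 1000 random loci.

## Limitations

Single-isoform gene models, one probe per transcript; no gapped or spliced
probe alignment; no dye-swap handling (the design has none); no print-tip
or spatial normalization, no array quality weights; conservation works
through the ortholog map abstraction, not sequence homology; enrichment has
no GO-topology propagation; and the trend fit, being a plain projection, is
not robust to a heavily one-sided DE load concentrated at one intensity
extreme (the trimming mitigates but cannot eliminate this).
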