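# Methods

`bsamap` maps a monogenic recessive locus by bulked-segregant sequencing
(QTL-seq): two pools of genomic DNA — one from plants showing the recessive
phenotype, one from wild-type siblings of the same segregating population —
are sequenced, and the allele-frequency contrast between the pools is scanned
along the genome. This note records the statistical model, the defaults and
why they hold, the numerical choices, and what the built-in simulator does
and does not emulate.

## The SNP-index statistic

At a biallelic SNP, the **SNP-index** of a bulk is the fraction of aligned
reads carrying the alternate allele (here: the mutant-parent allele),

    index = alt reads / (ref reads + alt reads),

and **Δ(SNP-index)** is the mutant-bulk index minus the wild-bulk index.
In an F₂ from inbred parents, plants selected for a fully recessive
phenotype are homozygous mutant at the causal locus, so the mutant bulk's
allele frequency at a fully linked SNP is 1. The wild-phenotype class is
⅓ AA : ⅔ AB, giving an expected frequency of ⅓. Hence

    E[Δ] = 1 − 1/3 = 2/3   at full linkage,   E[Δ] = 0   unlinked,

decaying as (2/3)(1 − 2r) with recombination fraction r. Read sampling is
binomial around the bulk allele frequency, so the index is an unbiased
estimator of it at any depth.

Zero-depth positions are dropped (the statistic is undefined), and two
removal rules follow: positions with read depth below 7 in **both** bulks,
and positions with SNP-index below 0.3 in **either** bulk. Both arms accept
`both`/`either` because usage differs between studies; the defaults are the
literal reading above. The index floor exists to purge spurious calls
(residual heterozygosity, repeats, paralogs) from real data — see
"Validation experiments" for why it is relaxed on clean simulated input.

## Sliding window and null confidence intervals

Windows of 1 Mb advance in 10 kb steps, anchored at position 1 of each
chromosome and truncated at its end; each window reports the unweighted
arithmetic mean of indexA, indexB and Δ over the SNPs it contains. Empty
windows are emitted (n_snps = 0, NaN means) and are never significant.

Thresholds come from Monte-Carlo simulation of Δ under the null of no
linkage: for each bulk independently, draw the bulk's mutant-allele dosage
sum (F₂ plants are Binomial(2, ½) in dosage, so the sum over a bulk of size
m is Binomial(2m, ½); a backcross to the mutant parent gives m +
Binomial(m, ½)), convert to a frequency p, draw alt ∼ Binomial(depth, p),
and form Δ as the difference of the two indices. Empirical 2.5/97.5 and
0.5/99.5 percentiles (order statistics, linear interpolation; 10,000
replicates by default) give the 95% and 99% bounds.

Per-SNP bounds are keyed by **min(depthA, depthB)** — conservative, since
the true sampling law at a SNP has both depths at least that large. Missing
depth keys are computed on demand and cached, each from its own
deterministic substream so the table is independent of evaluation order.
Bounds are window-averaged exactly as Δ is. A window is significant when
its mean Δ exceeds the averaged upper bound (one-sided: the mutant bulk is
bulk A by convention, so linkage pushes Δ positive; a two-sided mode exists
for unknown-direction scans). Overlapping or bookended significant windows
merge into regions; each region reports its peak window's Δ and center.

Because Δ at depth d lives on a lattice of spacing 1/d, no interval has
exactly 5% strict exceedance; calibration checks count boundary ties with
half weight (the mid-p convention for discrete statistics).

## Population and read simulator

The generator emulates the study design the package was validated against:
an F₂ (or BC₁-to-mutant) population of 185 plants segregating one fully
recessive locus, bulks of 21 plants per phenotype, one SNP per 50 kb along
a 40-Mb chromosome, Poisson(30) depth per SNP per bulk, and a per-read
allele-flip error of 10⁻³.

Gametes follow a Markov walk over the ordered loci of each chromosome with
crossover probability from Haldane's map function r = ½(1 − e^(−2d/100)),
d in centimorgans obtained from physical distance at 3 cM/Mb (a single
configurable knob; no crossover interference). An F₂ plant fuses two
independent gametes; a BC₁ plant one gamete with an all-mutant gamete.
Phenotype is fully penetrant by default; a misphenotyping probability knob
(default 0) exists for robustness studies. Bulks are uniform random samples
without replacement within phenotype class. Reads are sampled per SNP and
bulk as depth ∼ Poisson(mean), alt ∼ Binomial(depth, p(1−e) + (1−p)e).

What the simulator does **not** emulate: alignment and variant-calling
artifacts (mismapping, allele-balance bias, paralogous collapse), indels
and multi-allelic sites, depth autocorrelation along the genome, library
or GC biases, genotyping error in marker assays, and segregation
distortion. Passing recovery tests therefore demonstrate the statistics
and interval logic, not robustness to those real-data pathologies — which
is precisely what the depth/index filters exist to absorb.

The marker density (50 kb) and the depth law are stand-ins chosen as
typical for the design; the emulated study does not publish either.

## Region calling and fine mapping

Fine mapping uses mutant-phenotype plants only: each is homozygous mutant
at the locus, so its genotypes at ordered markers constrain the locus to
the union of maximal runs of consecutive markers called B (homozygous
mutant) or missing that contain at least one observed B, each run widened
to the open interval bounded by the nearest flanking non-B markers (or the
chromosome ends). Missing calls are non-informative by default
(`strict_missing` treats them as breaking a run). The candidate region is
the intersection of all plants' regions; when several disjoint intervals
survive, the reported interval is the one anchored by the most markers
that are B in every plant (ties: widest), with all intervals retained on
the result. Bounds are open — the locus lies strictly between the flanking
markers; BED export closes onto the marker coordinates.

A plant incompatible with the running intersection (apparent double
recombinant or phenotyping error) raises a conflict by default; with
sparse panels over multi-megabase regions genuine double crossovers
between distant markers are expected, so the end-to-end driver uses
`on_conflict="drop"`, which excludes the plant with a warning.
Wild-phenotype plants are accepted but only consistency-checked
(advisory, off by default). Adding a marker or a plant can only keep or
shrink the interval, never widen it.

## Segregation tests

Goodness of fit of phenotype counts to an integer ratio uses the
uncorrected Pearson χ² with E_i = N·ratio_i/Σratio, df = classes − 1, and
the upper-tail χ² probability (for df = 1 this equals erfc(√(χ²/2))). The
published statistics this package reproduces were computed without a
continuity correction — the uncorrected statistic matches all four printed
rows to 3 decimals — so Yates' correction is available but off. One
published backcross row lists 226 plants while its class counts sum to
225; computations use the class counts.

## Chlorophyll quantification

Arnon-type equations on extract absorbances at 663 and 645 nm, with V the
extraction volume (mL) and W the fresh weight (g), in mg per g fresh
weight:

    Chla = (12.7·OD663 − 2.69·OD645) · V/(1000·W)
    Chlb = (22.9·OD645 − 4.68·OD663) · V/(1000·W)
    Chl  = (20.21·OD645 + 8.02·OD663) · V/(1000·W)

The coefficient sets satisfy 12.7 − 4.68 = 8.02 and 22.9 − 2.69 = 20.21,
so Chl ≡ Chla + Chlb. Some printings of these formulas write "OD633" in
the Chlb/Chl lines; the measurement protocol reads 645 and 663 nm, and
only the 663-nm reading preserves the additivity identity, so OD663 is
used (an `od633=` argument supports the literal variant). Negative outputs
are returned but flagged: they indicate an unphysical absorbance pair.

## Validation experiments

`bsamap.experiments` runs the method end-to-end on ground-truthed
simulations at the design above; the reproduction script and the test
suite both call it. Problem sizes — 50 independent runs, 10,000 null
replicates, 10,000–20,000 calibration draws — were chosen to put
Monte-Carlo error well below the effect sizes being checked while keeping
a laptop run in seconds.

Two estimator choices matter:

* **Index floor off.** On clean simulated SNPs the 0.3 index floor
  truncates the wild-bulk index distribution at the causal locus
  (E[indexB | indexB ≥ 0.3] > ⅓), which would bias the measured peak Δ
  below its analytic value; the recovery experiment keeps the depth filter
  and sets the floor to 0. On real data the floor targets artifact classes
  the simulator does not produce.
* **Causal-window Δ vs global peak.** The scan's global maximum window Δ
  is upward-biased: it is the max of many noisy window means, so selection
  inflates it above the per-locus expectation. The comparison against the
  analytic 2/3 therefore uses the window centered nearest the planted
  locus (unbiased up to ~1% attenuation from flanking-SNP recombination);
  the global peak is reported alongside as the analog of a published scan
  peak.

## Known limitations

Single fully-penetrant recessive locus only (no quantitative traits, no
multi-QTL); Haldane map without interference; no G′/tricube-smoothed
alternatives to the windowed Δ; fine mapping takes marker order and
positions as given; the VCF reader handles exactly two samples with
FORMAT/AD. The published real-data results (peak Δ = 0.8 at 36.0–39.7 Mb
on chromosome 3; the 205-kb and 73-kb intervals) depend on the study's
sequencing deposits and reference genome and are not reproducible from
this package's synthetic data; the simulation experiments above are the
desk-scale substitute.
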