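# Methods

This note documents the statistical procedures `sagtools` implements, the
defaults it ships, and what its synthetic-data tests do and do not
demonstrate about real data.

## Coordinate and data conventions

Genomic intervals are 0-based half-open internally and converted to 1-based
inclusive at the GFF3 boundary (tested in both directions on boundary
genes). Strand is carried on gene models but ignored downstream — no
procedure here is strand-sensitive. The sample key throughout is
`(station, depth layer)`: surface (SRF) and deep-chlorophyll-maximum (DCM)
samples from the same station are distinct samples. Taxonomy domain tokens
in hit tables are restricted to the five superkingdom labels and rejected
otherwise, so alien-index inputs stay auditable.

## Decontamination screens

**Cross-genera sharing.** Scaffolds are cut into 1000-bp fragments every
500 bp; scaffolds shorter than 1000 bp are used whole. When the last
regular window does not reach the scaffold end, an end-anchored window of
full length is appended — the sources are silent on sub-window remainders,
and full coverage guarantees contamination at scaffold ends is visible.
Fragment matches are kept at identity ≥ 95% (inclusive) covering > 80% of
the fragment (strict), mirroring the rule's printed symbols; one kept match
to an assembly from a different taxon group (chrysophytes vs MAST-3 vs
MAST-4 level) flags the parent scaffold. Matches within a taxon group are
the expected self-similarity of sibling SAGs and never flag.

**Organelle.** A scaffold is organellar if a nucleotide hit against a
sequenced organelle genome exceeds bit score 1000, or if at least three
distinct genes on it hit curated chloroplast (CHL) or mitochondrial (MTH)
protein clusters; the two lists are unioned. Reference databases are not
curated here — hits arrive annotated with a subject class.

**Bacterial (alien index).** A scaffold is bacterial when it has at least
one gene with a defined AI and every such gene has AI > 45. Genes without
hits are neutral: they neither qualify nor disqualify, and a scaffold whose
genes are all hit-less is left to the eukaryotic-signature screen, which
governs fully anonymous scaffolds.

**Eukaryotic signature.** A scaffold is kept iff at least one gene is
taxonomically assigned to a eukaryote (assignment = superkingdom of the
best hit by e-value, ties broken by bit score) or none of its genes has any
hit. A scaffold with no genes is kept with a warning — the rule is vacuous
there.

**Composition.** Removal is the set union of the four flag sets. For
reporting, a scaffold is attributed to the first screen that caught it, in
the order cross-taxon → organelle → bacterial-AI → non-eukaryotic
signature, matching the order in which the screens are described in the
methods tradition this pipeline follows; attribution order never changes
what is removed. Kept plus removed base pairs equal the input assembly size
exactly (asserted).

## Alien index and HGT calls

`AI = ln(best_euk + 10⁻²⁰⁰) − ln(best_prok + 10⁻²⁰⁰)`, natural logarithm.
The 10⁻²⁰⁰ pseudocount caps |AI| near 460.5, and the 45 threshold lives on
that natural-log scale (on a log₁₀ scale 45 would be unreachable in
spirit). "Non-eukaryotic" means Bacteria ∪ Archaea; viral hits are excluded
by default (selectable), since the screen targets prokaryotic gene
acquisition. A side with no hits substitutes e-value 1.0, the "no signal"
limit, making one-sided prokaryotic genes strongly positive. Candidates
must have AI > 45 (strict), sit internally on their scaffold (not first or
last in coordinate order — a guard against chimeric ends) and the scaffold
must carry at least six genes.

Tree validation walks from the query leaf toward the root and stops at the
first ancestor with bootstrap support above 50. If that clade contains any
other eukaryote the candidate clusters with eukaryotes and is a false
positive of the index; otherwise the transfer is supported. Trees with no
supported ancestor at all are inconclusive and treated as rejected in
summaries — an unsupported topology cannot carry the burden of proof. The
decision is invariant under leaf-order rotation (tested) because it depends
only on clade membership and support.

## Read recruitment

The 25-mer prefilter keeps reads sharing at least one k-mer with the
assembly on either strand; it exists to emulate the cheap pre-selection
step of the original mapping pipeline, and on synthetic data it never drops
a read the tally would count. Alignments are kept at ≥ 95% identity with
≥ 30% of the read's bases in high-complexity sequence. Low complexity is
scored by the classic windowed DUST statistic: in windows of 64 bp (sliding
by 32, plus an end-anchored window), `score = 10 · Σ c_t(c_t−1)/2 / n_triplets`
over overlapping-triplet counts; windows scoring above level 20 are masked
entirely. Window 64 / level 20 are the long-standing defaults of this
algorithm family. The filter applies to the read sequence, not the
reference, since the rule speaks of the read's bases. Tests compare the
mask per-base against NCBI `dustmasker` on a 100-sequence panel of
homopolymers, short-period repeats and random sequences; agreement is
≥ 99.9% there, with the caveat that `dustmasker` implements the newer
symmetric variant, so boundary behavior on mixed sequences can differ.

A gene is *detected* in a sample when at least one kept read aligns at
≥ 95% identity over 100% of its length. RPKM divides a gene's count by
(gene length in kb) × (reads mapped to this organism's gene set in the
sample, in millions). Two denominators deliberately coexist: RPKM uses
mapped reads; raw relative abundance (below) uses the sample's sequenced
total.

## Inlier/outlier screen

Within a sample, the RPKM of detected genes is assumed roughly normal;
cross-mapping, multi-copy and foreign genes violate that. For every sample
where at least 20% (inclusive) of the organism's genes are detected, an
iterative two-sided Grubbs test runs on the detected genes' RPKM: the
maximum studentized deviation is compared to
`G_crit = ((n−1)/√n)·√(t²/(n−2+t²))` with `t` the upper `α/(2n)` quantile
of the t-distribution with `n−2` df, the extreme value is removed on
rejection, and the scan repeats until no rejection (α = 0.05). Undetected
genes stay out of the vector — they would mass at zero and break the
normality assumption. A one-sided mode (cross-mapping only inflates) and a
log1p mode (overdispersed data) are available but not default. Per-sample
outlier lists are unioned into the outlier gene set; scaffolds whose genes
are all outliers are discarded; inliers drive abundance.

Calibration: on 60 samples × 1000 i.i.d. normal values the merged union
false-positive rate of this implementation is ≈ 0.002. On Poisson counts
the rate is higher (≈ 0.01–0.04 across seeds at the default generator
settings) for two structural reasons: per-gene RPKM variance scales as
1/length, so the shortest genes are over-dispersed relative to the pooled
station vector, and Poisson right-skew at moderate means adds upper-tail
flags. Both effects are properties of the method on realistic count data,
not of this implementation; they are one reason the original screen's
outlier set is described as "noisy or random signal" rather than strictly
foreign genes. Sensitivity for genes inflated 8× across ≥ half the samples
is 1.0 throughout.

## Abundance

`raw(o, s) = Σ_{g ∈ inliers(o)} counts(g, s) / sequenced_total(s)`. Because
only gene space recruits reads and the genome is incomplete, the corrected
value multiplies by `assembly_size / (mapped_gene_space × completion)`,
where completion is the BUSCO-style complete-gene fraction supplied as
input and `mapped_gene_space` is the total length of the genes used for
recruitment ("size of the mapped genome" is read as gene space; reading it
as total reference length is a one-switch change). Normalized abundance
divides by the per-organism maximum over samples (all-zero organisms stay
zero); regional means average over a region's samples including zeros. The
whole chain is scale-equivariant under joint rescaling of counts and totals
(property-tested). Per-sample median read identity over inlier alignments
summarizes genotype divergence from the reference.

## Pfam ordination

Pfam domains are counted once per protein (repeats of a motif within one
protein collapse). Because genome completeness differs, each genome's
occurrence multiset is rarefied to 1400 domains — just under the smallest
observed repertoire of 1414 — by sampling without replacement
(multivariate hypergeometric), 10 independent replicates per genome; every
rarefied row sums to exactly 1400. Bray–Curtis dissimilarity
`Σ|a−b| / Σ(a+b)` is used instead of correlation or Euclidean distance
because double absences carry no signal between incomplete repertoires.
NMDS minimizes Kruskal stress-1 by monotone regression (best of 20 random
starts, k = 2 from the planar use of the ordination; convergence tolerance
1e-14 so duplicate profiles land on coincident points). Per-genome
positions are the means over the 10 replicate points; group separation is
reported as mean within-group vs between-group pairwise distance rather
than drawn confidence ellipses.

## Environmental statistics

Per parameter, the values at each lineage's eligible stations (≥ 20% of
genes detected) form one group and a tie-corrected Kruskal–Wallis test is
applied; lineages eligible at fewer than 5 stations are excluded, the
package's reading of the original analysis dropping its sparsest lineage
without printing a cutoff. The post-hoc default is Tukey's HSD on pooled
rank-transformed values — statistically heterodox after a rank test, but it
is what the source analysis names; pairwise Wilcoxon with Holm correction
is available by flag. Genotype splits partition a lineage's samples at 95%
median read identity (the figure convention does not print its threshold)
and compare the two groups' temperatures with a two-sided Mann–Whitney U:
exact enumeration when min(n, m) ≤ 8 without ties, normal approximation
with tie correction otherwise; stations are unweighted by default, with an
abundance-weighted mode provided.

## Synthetic data: what it emulates, and what not

The generator is a pure function of (config, seed). Defaults: three
organisms across the three taxon groups, 40 scaffolds each (3–12 kb,
uniform), genes tiled at ~1 kb (normal, sd 200 bp) with exponential
intergenic gaps; 10 cross-taxon scaffolds copied verbatim between taxon
groups (an optional mutation rate exercises the 95%/80% boundary), 5
organelle and 5 bacterial scaffolds, 10 HGT genes placed internally on
≥ 6-gene clean scaffolds. Hit tables are constructed so the AI rule
separates classes by design (prokaryotic best e-values at least e⁴⁵ below
eukaryotic for planted prokaryote-like genes). Stations carry Gaussian
temperature niches: expected count
`A·exp(−(T_s−T_opt)²/2σ²)·(len/1000)·depth_factor` with σ = 4 °C, peak
A = 150 reads/kb and 1.9×10⁸ reads sequenced per sample — the sequencing
depth of the study design this emulates — drawn Poisson (optional gamma
mixing adds overdispersion); 20 outlier genes are inflated 8× in 60% of
samples. The SRF/DCM contrast is a per-organism depth multiplier. Pfam
repertoires are multinomial draws of 1414 domains from group-specific
profiles (75% of mass on a group-private vocabulary block).

Not modelled: MDA amplification bias (no quantitative model exists to
emulate), read-level sequence errors, paired-end structure, chimeric
scaffolds, multiple HSPs per read, and spatial autocorrelation between
stations. Passing planted-truth tests therefore shows the screens recover
the signal structure they were designed for; it does not certify behavior
under amplification artifacts or alignment noise absent from the
generator.

## Problem sizes used in tests

The bundled checks run at: 500 vectors (n 5–50) for the Grubbs oracle;
1000 genes × 60 samples for outlier recovery; ~200 genes for the AI screen;
120 scaffolds for decontamination; 30 genomes × 10 replicates for the
ordination; 20 simulated worlds of 5 lineages × 50 samples for the
environmental ranking; 100 sequences for the DUST panel. These sizes keep
the full suite under a couple of minutes while leaving every statistic in
its intended regime.
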