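# Methods

## IR quantification

For each intron of a gene's representative transcript (most exons, ties
broken by spliced length then lexicographic ID — a deterministic rule for
multi-isoform genes, where no canonical choice exists), the IR ratio is
the median per-base read depth of the intron divided by the median of the
pooled per-base depths of its two flanking exons, clamped to [0, 1] and
set to 0 when the exon median is 0. Pooling the two flanking exons (rather
than, say, averaging two medians) is this package's reading of "flanking
exons"; it weights the two exons by length and is robust to one short
flank.

Calls are partitioned three ways. *Unmeasurable*: splicing depth < 4
reads exactly crossing the donor–acceptor junction, or splicing depth +
trimmed mean intron depth < 10, or evidence of splicing internal to the
intron (any junction strictly inside the intron supported by >= 2 reads;
a single read is treated as mismapping noise). *Not retained*: measurable
with IR ratio < 0.1. *Retained*: everything else. The trimmed mean
removes `floor(0.05 n)` values from each tail by default; the trim
fraction is configurable since published pipelines differ here.
Filtering is idempotent.

Per gene, the gene IR ratio is the maximum over retained introns (0 when
none), FPKM uses union-exon gene models (`count / (exonic kbp × mapped
reads / 10^6)`), expressed means FPKM >= 1, and the headline per-species
statistic is the fraction of expressed genes with >= 1 retained intron.
A gene-body-coverage QC profile (mean depth per percentile of the
transcript body, 5'→3', normalized to max 1) guards against 3' coverage
bias masquerading as 3'-biased retention.

Alternative estimator: `intronic depth / (intronic depth + splicing
depth)` is a selectable variant of the ratio in some published tools; the
median-ratio definition above is the package default, and no claim is
made about which variant any external pipeline runs internally.

## Maximum-entropy splice-site model

Donor sites are 9-nt windows (exon −3..−1, intron +1..+6), acceptor sites
23-nt windows (intron −20..−1, exon +1..+3). The model is the
maximum-entropy distribution over windows subject to marginal constraints
on position subsets; the default set is all singletons, all adjacent
pairs, and all skip-one pairs — a tractable subset of the full marginal
hierarchy. These constraints induce a triangulated chain with cliques
{i, i+1, i+2}, so partition function, constraint marginals, per-window
probabilities and exact forward sampling are all computed by sum-product
over 64-state cliques; nothing ever enumerates the 4^23 acceptor space
(the enumeration path exists only for small widths and is used by the
test oracles).

Fitting is iterative proportional fitting: sweeps over constraints, each
applying the full multiplicative update `λ_c += ln(empirical_c /
model_c)` against freshly computed exact marginals, until the maximum
absolute marginal deviation falls below 1e−4 (typically < 10 sweeps).
Simultaneous damped updates (classic generalized iterative scaling) were
rejected: with this heavily overlapping feature set they either diverge
at full step or need >10^4 iterations at the safe 1/C damping.

Smoothing mixes the empirical distribution with the uniform joint at a
weight equivalent to 0.5 observations per cell of a pairwise table. The
mixture is applied at the joint level because independent per-table
pseudocounts make the singleton and pairwise marginal systems mutually
inconsistent — no joint distribution satisfies both, and iterative
scaling then stalls at the scale of the inconsistency. The weight is
independent of the constraint set so that nested constraint sets share
consistent targets (this is what makes "adding constraints never
increases entropy" hold exactly).

A window scores `log2 P_model(x) / P_background(x)` bits against the
order-0 composition of the training sites. Retained vs other introns are
compared by the mean score shift and a one-sided rank test, and
summarized as 100×100 binned counts over the joint (donor, acceptor)
score plane.

## 3' UTR and miRNA analyses

A seed site is an exact Watson–Crick match to the reverse complement of
miRNA positions 2–8 (7-mer); G:U wobble is excluded, matching a strict
seed requirement. A pluggable duplex-energy hook (`energy_fn`, threshold
−14 kcal/mol) can further filter sites; it is disabled by default and no
energy model is bundled. Per-gene UTR length is the longest spliced 3'
UTR across isoforms; 3'-UTR introns (introns lying fully 3' of the stop
codon in >= 1 transcript of the gene) are excluded unless the
retained-intron-inclusive variant is requested.

Word enrichment follows the hypergeometric framing: per 6-mer, count
foreground and background sequences *containing* the word (presence/
absence — the per-sequence indicator is what the hypergeometric draws),
take the upper-tail cumulative hypergeometric probability of the
foreground count, and Bonferroni-correct over all 4096 words. The
canonical polyadenylation signal AATAAA is reported but flagged and
excluded from the significant set. Occurrence-count weighting is exposed
behind the presence/absence default.

## Gene architecture

Adjacent genes (nearest neighbours by TSS order per chromosome) are
classified HH (−/+, divergent), TT (+/−, convergent) or TH (same
strand), with distances TSS–TSS, end–end, and upstream-end to
downstream-TSS respectively; overlapping genes get distance 0. HH pairs
within 1 kb are counted as sharing a bidirectional promoter; enrichment
among pairs of IR genes uses a one-sided Fisher exact test. The
classification is covariant under a global strand flip (HH↔TT, TH and
distances preserved), which is enforced by test.

## Cross-species conservation

The profile matrix holds gene-level IR ratios per ortholog group ×
species; many-to-many groups collapse by maximum. Quantile normalization
forces every column onto the mean-of-sorted-columns distribution; with
missing values, ranks are taken over observed entries and mapped through
interpolated quantiles. It is exactly idempotent on complete matrices;
with missing entries a second pass can drift at interpolation scale
(~1e−3), which is why k-means receives complete rows only (rows with any
missing value are dropped, consistent with heat-map-style complete
profiles). k is a free parameter (default 8, with a gap-statistic
helper); species columns are clustered by average linkage at 1 − Pearson
distance (pairwise-complete) and serialized as Newick. Intersection
counts over IR-ortholog sets are reported for all 2^n − 1 exclusive
regions plus the inclusive all-species core.

The IR-fraction vs protein-coding-gene-count Pearson correlation is
computed from the bundled five-species summary table (printed genome
characteristics and granulocyte IR fractions) and reported to 2 dp;
rounding to 2 dp absorbs the unknowable difference between rounded and
unrounded inputs.

## Sponge (ceRNA) kinetics

State (T, S, M, C_TM, C_SM): free target, free sponge, free miRNA, and
the two complexes, in molecules. Mass action with transcription k_x,
first-order decay d_x, association a_TM and a_SM (the latter multiplied
by n_sites_S binding sites per sponge transcript), dissociation u_TM and
u_SM, and complex decay d_complex. The `catalytic` switch controls
whether complex decay destroys the miRNA (stoichiometric, default) or
recycles it. The underlying published supplement's exact equations were
not available to this package; the system here is the standard
mass-action ceRNA titration model, fully parameterized so an alternative
parameterization can be dropped in.

Integration uses LSODA with rtol 1e−8 / atol 1e−6 defaults; steady
states integrate from the origin with doubling horizons until the
relative derivative norm falls below 1e−9. Checked properties:
decoupled (association-free) subsystems match the k/d exponential
closed form to < 1e−6; the closed variant (no production/decay)
conserves T + C_TM, S + C_SM and M + C_TM + C_SM to solver precision;
steady-state free target is non-decreasing in sponge transcription and
non-increasing in miRNA transcription across a parameter lattice. The
dose–response curve reports the derepression ratio T*(k_S max)/T*(0).

## Synthetic data: what it emulates, and what it does not

The generator emulates the *structure* of a multi-species granulocyte
RNA-seq study: multi-intron gene models (geometric intron count, mean 7,
capped at 25), log-normal intron lengths (median 850 nt, σ_log 0.55)
with the retained class scaled to 0.35× and GC-enriched (0.55 vs 0.42),
splice sites drawn from consensus-shaped positional models sharpened or
flattened by a strength exponent (0.9 non-retained vs 0.35 retained,
GT/AG fixed), retention probability rising toward the 3' end
(position_bias 0.6), per-intron retention fractions ρ = 0.15 +
0.85·Beta(1.5, 6) (mass concentrated below 0.5), 3' UTRs log-normal with
IR-class median 1200 nt vs 600 nt, planted seed sites at 3.0/kb vs
1.5/kb in UTRs and 0.9/kb vs 0.3/kb in introns, head-to-head placement
of 23% of IR-gene pairs vs 5% of others within 1 kb, and Poisson
evidence: exonic depth c·e, intronic depth c·e·ρ, junction reads
c_j·e·(1−ρ) with c = c_j = 2 per expression unit.

Planting choices that make recovery checks sharp, all fixed in the
generator's design: categorical fractions (IR-gene fraction among
expressed genes, HH-pair fractions, expressed fraction) are planted as
exact rounded counts, so recovery error measures the estimator, not
multinomial planting noise; IR genes are drawn at expression >= 15 units
with one "anchor" retained intron at ρ <= 0.45, so conservation-set
recovery measures set arithmetic rather than borderline junction depth;
planted seed sites are collision-free and the surrounding sequence is
scrubbed of accidental word matches (including across spliced
junctions), so site counts recover exactly. A five-species panel shares
ortholog groups for a configurable fraction of genes, forces a conserved
IR core of configurable size (default 86 groups) IR in every species,
and forces every other shared group non-IR in at least one species, so
the all-species intersection equals the planted core by construction.

What the generator does **not** model — and therefore what green tests
do not establish about real data: sequencing error and mapping
ambiguity, fragment-length and positional coverage biases (coverage is
iid Poisson per base), isoform mixtures beyond one transcript per gene,
nuclear/cytoplasmic compartmentalization and NMD kinetics, real
splice-site sequence families beyond pairwise positional dependencies,
and real miRNA target-site context. Passing recovery tests show the
estimators are correct under their stated model, not that the model
captures every bias of a real library.

## Problem sizes and numerical choices

Default analysis runs use 200 genes × 5 pseudo-species plus one 200-gene
study species (~1.4 Mb of genome each); planted-effect checks that need
more power (positional bias, pair architecture) use 600–2000 genes
without sequence emission. Bootstrap bands use B = 200 seeded samples;
k-means uses 10 restarts under a fixed seed. All randomness flows from a
single integer seed per run through deterministic child seeds; fixed
seed implies byte-identical GTF/FASTA/TSV output (word iteration during
sequence scrubbing is explicitly order-stabilized for this reason).

Known limitations: GTF support is the Ensembl dialect only (no GFF3, no
alt contigs); the IR estimator assumes one representative transcript per
gene; quantile normalization's missing-data path is approximate (see
above); the sponge model's parameter values are illustrative defaults,
not fitted rates.
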