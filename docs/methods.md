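# Methods

This note documents the statistical models and design decisions behind
`duskit`: what each statistic assumes, why the defaults are what they are,
and what the synthetic data generator does and does not emulate.

## Genotype model

All SNP statistics operate on diploid biallelic *dosage* — the count of
alternate alleles (0, 1, 2) with a `MISSING` sentinel. For biallelic
diploids every quantity used here (MAF, heterozygosity, allele-sharing
distance, kinship) is a function of dosage, so allele strings are discarded
at import. Positions are 1-based as in VCF; loci are ordered by natural
chromosome sort ("chr2" before "chr10") then position, which keeps
per-chromosome gap statistics stable across inputs. Multiallelic and indel
records are skipped with a logged count (strict mode refuses them): the
intended input is a biallelic SNP panel, and mixed record types would make
dosage ill-defined.

## Marker filtering

A locus is retained when MAF ≥ `maf_min` (default 0.05) **and** integrity
(call rate) ≥ `integrity_min` (default 0.8). Both tests are inclusive —
one uniform boundary rule rather than a mix of strict and non-strict
comparisons. MAF is computed over called alleles only; a locus with no
calls has undefined MAF and never passes. The MAF rule is applied in the
*retention* direction (keep loci whose minor allele is common enough):
a fingerprinting panel must be polymorphic, and discarding everything with
MAF ≥ 0.05 would leave no signal for distance, PCA or kinship. Integrity is
evaluated over the full plant set, not per cultivar; per-cultivar call-rate
thresholds reappear inside the stable-heterozygosity analysis where they
matter.

Adjacent-SNP gaps are computed within chromosomes only (no artificial gap
across chromosome boundaries); the fraction of gaps under a threshold
(default 150 kb) summarizes panel coverage and is undefined (reported as
null) when every chromosome has at most one locus.

## Distances

**SNP**: allele-sharing distance, d(i,j) = Σ|gᵢ−gⱼ| / (2·n_shared), over
loci called in both plants. On complete data this is the p-distance on
alleles of the concatenated genotypes: 0 for identical plants, 1 for
opposite homozygotes everywhere, and a proper metric. Missing calls are
handled by pairwise deletion; per-pair locus counts are reported so weakly
supported pairs are visible. A pair with *no* shared called locus is a
fatal error by default — a DUS verdict must not rest on silently imputed
distances; `allow_missing_pairs` substitutes the matrix-wide mean with a
warning, and a matrix with no defined pair at all is never imputed.
Model-corrected distances (Jukes–Cantor and relatives) are deliberately out
of scope: within-species fingerprint panels sit far from saturation.

**SSR**: per marker, with s ∈ {0,1,2} the multiset intersection of the two
fragment-size pairs, the marker distance is 1 − s/2; the plant-pair distance
averages over markers called in both plants. Allele pairs are stored sorted,
so input order is irrelevant.

## Neighbor joining and patristic distances

The classical Saitou–Nei agglomeration: join the pair minimizing
Q(i,j) = (n−2)d(i,j) − rᵢ − rⱼ, with pendant lengths from the standard
formulas and the usual (dᵢₖ+dⱼₖ−dᵢⱼ)/2 distance update. Two choices make
trees bit-reproducible across platforms and input orders:

* **tie-breaking** — when several pairs share the minimal Q, the pair whose
  (sorted) cluster labels are lexicographically smallest is joined; a
  cluster's label is the smallest plant ID it contains;
* **negative branch lengths** are clamped to zero with the deficit moved to
  the sibling edge, preserving the joined pair's path length; clamps are
  logged.

Trees are unrooted; the trifurcation at the stored root is a representation
artifact. Patristic distance sums edge lengths whose induced bipartition
separates the two leaves (equivalent to the leaf-path length), computed by
one weighted incidence product over all edges. On exactly tree-additive
input, NJ provably reconstructs the generating topology and branch lengths;
the test suite verifies this on random trees with 4–8 leaves at 1e-9, and
cross-checks topology against scikit-bio's independent NJ and patristic
values against dendropy.

Bootstrap resamples **loci** (columns) with replacement — the universal
phylogenetic resampling unit, since loci are the exchangeable observations —
and annotates each internal edge of the full-data tree with the percentage
of replicates containing the same bipartition. Supports are reported but do
not feed the off-type or distinctness rules, which are defined on the
full-data tree alone. The default pipeline leaves bootstrap off
(`bootstrap_replicates: 0`); `duskit tree --bootstrap 500` computes it on
demand.

## PCA and kinship

Both operate on the column-centered dosage matrix with per-locus mean
imputation: an imputed value contributes exactly zero after centering, so
imputation keeps the matrix dense without inventing structure (the distance
module, by contrast, uses pairwise deletion — in distance space imputation
*would* invent genotypes). PCA is an SVD of the centered matrix; component
signs follow a fixed convention (largest-magnitude locus loading positive)
for cross-platform determinism. Kinship is the VanRaden genomic
relationship K = ZZᵀ / (2 Σ pₗ(1−pₗ)). Other kinship variants exist in
association-mapping toolkits; VanRaden is the standard, fully specified
choice and the method tag is recorded in the output.

## DUS statistics

**Purity** of a plant is homozygous calls / called calls; missing calls are
excluded from numerator and denominator (the alternative — a fixed
panel-wide denominator — would conflate missingness with heterozygosity).
Cultivar purity is the mean over plants, reported with min/max/sample-sd in
percent; a single-plant cultivar gets sd 0 and a flag.

**Stable heterozygous loci**: a locus is stably heterozygous within a
cultivar when every non-missing call among its plants is heterozygous and
the within-cultivar call rate is ≥ 0.8 (the integrity threshold reused) —
tolerant of sporadic missingness, strict on zygosity. The cultivar ×
cultivar sharing matrix holds set sizes on the diagonal and intersection
sizes off it. Note that an undetected off-type plant suppresses its host
cultivar's detected set (its homozygous calls veto most loci); in practice
the analysis is read together with the off-type report.

**Off-type classification**: with r(p) the mean patristic distance from
plant p to the other plants declared as the same cultivar, p is flagged iff

    r(p) > median(r) + 5·MAD(r)   and   r(p) > 3·median(r).

Observed contaminants sit at 6–12× the within-cultivar mean distance, which
both rules pass comfortably; the MAD rule alone would be fragile when the
clean distribution is extremely tight (MAD near zero), so the ratio guard
prevents flagging plants that are only marginally farther in absolute
terms. The rule is invariant to plant order and to uniform rescaling of
distances. Cultivars with fewer than three plants have no baseline and are
skipped with a warning. Per-cultivar distance summaries (max/min/average)
are computed after excluding flagged plants.

**Distinctness** is read off tree bipartitions, not distance thresholds: a
cultivar is distinct iff its (non-flagged) plants are exactly one side of
some edge-induced bipartition, and two cultivars are separated iff some
edge puts them entirely on opposite sides. Bipartitions are scale-free, so
the verdicts do not depend on branch-length units; flagged off-types are
removed from both the cultivar sets and the bipartition sides before the
comparison.

**Downsampling robustness** re-runs distance → NJ → off-type →
distinctness on random locus subsets (default 10,000/5,000/1,000/500, three
replicates). Child generators are spawned from the master seed with the
(size-index, replicate) key and each row records the derived key and a hash
of the chosen subset, so any cell of the grid replays exactly.

## Synthetic data generator

The generator emulates a seed-lot trial of registered selfing-crop
cultivars: for each cultivar, every sampled plant is an **independent
single-seed-descent lineage** from the F1 of two fully homozygous founders.
Per generation each heterozygous locus fixes to either homozygote with
probability ¼ each and stays heterozygous with probability ½, so residual
heterozygosity after g generations is 0.5ᵍ per segregating locus — the
closed form used for parameter-recovery checks. Defaults follow release
practice for inbred lines: g = 6 selfing generations, 20 plants per
cultivar, 20 chromosomes of 48 Mb carrying 40,000 SNPs.

Founder genomes derive from a common all-reference ancestor by independent
per-locus flips: unrelated cross ancestors at flip probability 0.2
(pairwise divergence ≈ 0.32), within-cross founder pairs anchored at 0.04 —
the narrow elite background that makes real DUS testing hard. This yields
within-cultivar patristic distances near 0.02–0.03 against between-cultivar
distances of 0.05–0.35, the regime reported for real inbred panels. The
bundled design has five cultivars: a **sister pair** bred from the same
cross (cv1/cv2 — indistinguishable by construction, including an identical
pinned-heterozygosity profile), a **parent–offspring pair** (cv4's first
founder is an inbred line drawn from cv3's cross; its second founder is
anchored nearby at 0.08), and one unrelated cultivar (cv5). One off-type
seed from a distant donor is planted into each sister cultivar.

Stable heterozygosity is modeled *phenomenologically*: each cultivar pins a
set of loci (default 40, sampled from a shared 150-locus pool so that
pairwise overlaps arise) permanently heterozygous in all its plants; the
cultivar's second founder is forced to the opposite allele there so pinned
loci are always segregating. The biological mechanism that maintains such
loci (balancing selection, structural heterozygosity) is out of scope — the
pinned set is a stand-in with the right observable signature.

Genotyping noise: calls drop to missing at rate μ = 0.05 (compatible with
the 0.8 integrity filter at n = 100) and surviving calls are perturbed at
rate ε = 0.01 — homozygote→heterozygote or heterozygote→random homozygote,
the two dominant biallelic miscall modes of reduced-representation
pipelines.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: linkage (loci segregate independently; all
statistics here are locus-exchangeable, but LD would change bootstrap
variance on real panels), allele-frequency spectra of natural populations,
batch effects or per-plant coverage variation, and read-level artifacts
upstream of genotype calls. Observed purity in the default design
(~98.7 %) is what six selfings plus 1 % miscalls produce; real panels
report lower purity, consistent with higher platform-specific heterozygous
miscall rates, which users can emulate by raising ε.

## Problem sizes and numerics

The test suite and the acceptance script run desk-scale versions of every
study: 200 random additive trees (4–8 leaves) for NJ correctness; 100
random matrices (≤10 plants × ≤50 loci, 10 % missing) against brute-force
counting oracles; 50 plants × 20,000 loci per selfing-recovery point; ten
independent 100-plant × 40,000-locus panels for off-type sensitivity (20
injected contaminants vs 980 clean plant-instances) and distinctness; and a
12-cell downsampling grid from the ~23,000-locus filtered panel. Tolerances:
patristic reconstruction 1e-9 on additive input; oracle comparisons 1e-12;
Monte-Carlo recoveries within three standard errors. Distance matrices are
symmetrized explicitly after floating-point assembly; degenerate inputs
(no-call loci, zero-call plants, sub-baseline cultivars, fully undefined
distance matrices) raise or warn as documented rather than propagating NaN.

## Reproducibility

Every stochastic stage draws from a generator spawned from one master
`SeedSequence` with a fixed integer key, so a single seed reproduces the
simulator outputs, the bootstrap, and the robustness grid exactly. The
pipeline canonicalizes plant order after reading, making all outputs
invariant to VCF row order; the run manifest records input/output SHA-256
hashes and every threshold, and re-running with identical inputs yields
byte-identical files.
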