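# Methods

`promkit` implements a CAGE (Cap Analysis of Gene Expression) promoterome
analysis: from per-position counts of capped 5' ends (CTSSs) to a catalog of
promoters with sequence-architecture, translational-signal and
developmental-dynamics annotations.  This note records the models, the
defaults and the design choices that were genuinely open.

## Tag clustering and quantification

CTSSs on the same chromosome and strand are merged into tag clusters (TCs)
whenever consecutive positions are strictly less than 20 bp apart
(`ctss_max_dist`, the distance-based clustering used by CAGEr-style
workflows).  Each TC is quantified by:

* **tag count** and **TPM** (count x 1e6 / library size);
* **dominant CTSS** — the position with the highest count; ties break
  toward the 5'-most position on the transcribed strand, which is
  deterministic and strand-symmetric;
* **interquantile width (IQW)** — cumulative tag fractions are accumulated
  in transcribed order and the q=0.1 and q=0.9 positions are the first
  positions at which the cumulative fraction reaches the quantile; IQW is
  their inclusive span.  The 0.1/0.9 pair is the common CAGE convention for
  separating sharp from broad promoters.

Expression filters: TCs with TPM < 0.1 are discarded,
as are single-position TCs ("singletons") with TPM < 5.  Both comparisons
keep the boundary value.

Replicates are handled by clustering each replicate separately, keeping
regions for which a region in the other replicate covers at least 90% of
their length (checked reciprocally), then pooling replicate counts within
the kept regions and re-clustering.  The order — filter regions first, then
pool — is this package's choice; the reciprocal form of the 90% rule is
likewise a documented convention.

Consensus clusters merge the filtered TCs of all stages by single linkage
whenever the gap between interval ends is strictly below 100 bp.  Per-stage
TPM is the sum of member-TC TPMs (0 for absent stages); the consensus
dominant position is taken from the stage with the highest TPM, with ties
broken by lexicographic stage name so the result does not depend on input
order.  The consensus IQW is recomputed over the pooled member CTSSs of the
dominant stage, so it reflects a single sample's initiation shape.

## Feature annotation and the primary/secondary split

The dominant CTSS (not the cluster edges) anchors all distances, measured
on the transcribed strand of the assigned gene (negative = upstream of the
annotated TSS, aTSS).  Candidate categories are ranked by the hierarchy

    promoter > 5'UTR > 3'UTR > exon > intron > proximal

with promoter = [-500, +100] and proximal = [-1000, -501] around the
nearest aTSS.  The two windows share the -500 boundary; here it belongs to promoter.  Promoter/proximal candidacy is evaluated against the
nearest gene by |signed distance|; body categories against every
overlapping gene, so a cluster in gene A's intron that sits within the
promoter window of gene B's aTSS is annotated as B's promoter.  Clusters
more than 1000 bp from any aTSS and outside every gene body are
*unassociated*.  Gene assignment ignores strand; antisense clusters are
flagged by an orientation field.

Per gene, the hierarchically best cluster (ties: smallest |distance|, then
cluster id) is the **primary promoter**; every other associated cluster and
all unassociated clusters form the **secondary set**.  Multi-isoform genes
are reduced to one representative mRNA — the 5'-most start on the
transcribed strand, ties to the longest — before the aTSS is computed.

Concordance between dominant CTSSs and aTSSs is reported as cumulative
fractions within 20/100/500 bp over the genes whose distance does not
exceed the largest threshold.

## Core-promoter sequence features

Windows of -50..+50 (TSS base = +1; relative coordinates skip zero) are
extracted on the transcribed strand.  Features:

* **Initiator class** — the (-1, +1) dinucleotide: CA, CG or TG (the named
  plant classes), otherwise "other-PyPu" for any pyrimidine-purine pair,
  otherwise "non-PyPu".
* **PWM scans with exact p-values** — log-odds scores (base 2, pseudocount
  0.25, uniform background by default) are scaled by 1000 and rounded to
  integers; the exact null distribution of the integer score under the
  background is built by dynamic-programming convolution across motif
  positions, so p(s) = P(random motif-length sequence scores >= s).  This
  is the FIMO construction; agreement with exhaustive enumeration is
  limited only by the rounding granularity of the scale factor.
* **TATA box** — scanned strand-specifically on the transcribed strand at
  p <= 1e-4 (a lenient 1e-3 fraction is also reported).  The shipped
  default matrix is built from the four members of the TATAWAWA consensus
  family.  An 8-position family is the shortest strictly-degenerate
  consensus whose best match can reach p <= 1e-4 (a k-member family of
  length L cannot score below k/4^L; at L=7 that floor is 2.4e-4).  Any
  JASPAR-PFM or MEME-minimal matrix can be substituted.  A promoter is
  TATA+ when a hit starts within [-40, -20], a band bracketing the
  observed -36..-29 occurrence range with margin; the positional mode of
  hit starts is reported.
* **Y patch** — the pyrimidine-rich element CTTCTTCCTC; a single-consensus
  PWM and its reverse complement (GAGGAAGAAG) are both scanned on the
  transcribed strand at p <= 1e-4, which admits at most one mismatch.
* **Architecture label** — the pure function of the three features, e.g.
  `TATA+/CA` or `TATA-/CG/Ypatch+`.  This rule-based labeler stands in for
  unsupervised sequence-architecture clustering (NMF-based factorization of
  the promoter sequence matrix), which is out of scope.
* **Dinucleotide and base-frequency matrices** — per-offset fractions over
  a window cohort (columns are probability distributions); the
  base-frequency table is the input a sequence-logo renderer needs.
* **TE overlap** — the fraction of promoters whose +/-50 bp TSS window
  intersects a transposable-element interval by >= 1 bp, reported per
  architecture group.

## TOPscore and tau

The 5'TOP motif — a cap-adjacent cytosine followed by a pyrimidine run —
is scored per gene as the read-fraction-weighted pyrimidine tract length
over the CTSSs of the gene's primary cluster: tract length is 0 unless the
TSS base is C, otherwise the maximal C/T run from the TSS (N terminates the
run), capped at 41 nt by the extracted window.  The weighting makes the
score invariant to count rescaling; genes with TOPscore strictly greater
than 3 are candidate TOP mRNAs.  The exact weighting and tract definition
follow the widely used CAGE TOP-scoring approach; the C-start requirement,
cap and per-primary-cluster restriction are documented conventions isolated
behind one function.

tau tissue specificity is computed per gene from an expression matrix
(an external genes x tissues TSV, or the primary cluster's per-stage TPMs
when none is supplied): values are transformed by log2(x+1) (configurable
to identity), normalized by the row maximum, and
tau = sum(1 - x_hat)/(n - 1); 0 = uniform, 1 = single-tissue, undefined
(flagged) for all-zero rows.

## Promoter shifts and set overlaps

For each gene with at least two consensus clusters and each stage pair, the
stage-wise dominant cluster is the one with the highest TPM in that stage.
A shift is called when the two dominants differ, each reaches TPM >= 0.5 in
its own stage, each is >= 2-fold above the other cluster within its own
stage, and at least one of the pair is annotated promoter, 5'UTR or
proximal.  The TPM floor (0.5) and fold requirement (2) are this package's
defaults; both are configurable and logged.  The consequence is
*coding* when the genomic interval between the two dominant positions
intersects the CDS, else *utr5_promoter*; the downstream-most TSS base is
excluded from the interval so a TSS exactly at the start codon does not
spuriously count as coding.  Gene-set overlaps (e.g. between secondary
cluster groups) are tested with the two-sided Fisher exact test
(hypergeometric enumeration).

## Synthetic data: what it emulates and what it does not

The generator plants six promoter classes (defaults: 20% TATA-sharp, 40%
broad, 10% each Y-patch, TOP, intron-singleton, shifted) on an i.i.d.
background genome (GC 0.45) with genes every 5 kb on random strands.  Tag
placement is a discretized Gaussian around the planted dominant TSS (sigma
1.5 bp sharp, 20 bp broad; TOP promoters put 85% of mass on the tract
start), and counts are negative binomial (size 10) around the kernel, per
stage and replicate — the overdispersion typical of CAGE.  Each replicate's
expected library is 1e6 tags; intergenic noise is planted as ~200 sparse
singleton positions per replicate (count 1-2, TPM 0.5-1 after pooling),
above the 0.1 TPM floor but below the singleton TPM-5 floor and
non-reproducible across replicates, so the filter chain observably removes
it.  (On integer counts, the 0.1 TPM floor itself can only bite at
libraries above ~1e7 tags; it is exercised by unit boundary tests.)
Shifted genes carry a second promoter 500 +/- 20 bp downstream whose
activity trades 8:1 against the first promoter between stage 1 and later
stages.  Intron-singleton genes receive a CAG splice-acceptor spike at the
first intron/exon-2 junction.  All randomness flows through per-gene
integer RNG streams spawned in a fixed order from the root seed, so every
output file is byte-identical across runs and platforms for a given seed.

The simulation does **not** emulate: mapping artifacts and multi-mapping
bias, promoter-width continua (classes are discrete), correlated
biological replicate variation (replicates share the exact expected
profile), nucleosome or chromatin structure, TE-derived sequence (TE
intervals are planted as coordinates only), or realistic genome composition
(no repeats, isochores or real gene structures).  Passing recovery tests
therefore demonstrates the correctness of the algorithms under the stated
generative model, not performance on real CAGE libraries.

## Numerical and engineering choices

* Internal coordinates are 1-based inclusive; BED/bedGraph convert at the
  I/O boundary.  TSS-relative coordinates skip zero.
* Quantile positions compare integer cumulative counts against q x total
  with a 1e-9 absolute guard, so exact boundary fractions (e.g. 0.1 of 10
  tags) are reached at the intended position.
* PWM p-value granularity is set by the integer scale (1000); exhaustive
  enumeration tests pin the DP to machine precision at that granularity.
* Degenerate inputs: empty clusters, zero library sizes, all-zero
  expression rows, windows crossing contig edges, and empty stage outputs
  are either explicit errors or flagged records — never silent drops,
  except contig-edge windows which are counted and logged.
* The pipeline is file-based: each stage reads only TSV/JSON intermediates
  from the working directory, so re-running one stage reproduces the full
  run's artifact for that stage byte for byte.
* Default problem sizes (500 genes, 3 stages x 2 replicates, 1e6
  tags/replicate) keep a full simulate-plus-analyse cycle around 10-15
  seconds on one CPU while leaving every filter, recovery statistic and
  stage transition observable.

## Known limitations

* The rule-based architecture labeler cannot discover unanticipated motif
  arrangements; it only recognizes the TATA/initiator/Y-patch grammar.
* TATA percentages depend entirely on the matrix used; with the shipped
  consensus-family matrix they are not comparable to fractions obtained
  with empirically derived matrices.
* The nearest-aTSS rule for promoter/proximal candidacy can mis-assign a
  cluster when two aTSSs are nearly equidistant; real annotations with
  overlapping genes may need the orientation flag to disambiguate.
* tau computed from three developmental stages is a coarse specificity
  measure; the external-matrix route should be preferred when a broad
  tissue panel is available.
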