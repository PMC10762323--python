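# promkit

**CAGE promoterome analysis for plant (and other eukaryotic) genomes.**

Cap Analysis of Gene Expression (CAGE) sequences the capped 5' ends of
mRNAs and maps transcription start sites (TSSs) at single-base resolution.
`promkit` turns per-position capped-5' counts (CTSS tracks) into an
annotated promoter catalog:

1. **Tag clustering** — CTSSs < 20 bp apart merge into tag clusters (TCs),
   each quantified by tag count, TPM, dominant CTSS and interquantile
   width (IQW, the q0.1–q0.9 span of the tag distribution: small = sharp
   promoter, large = broad). TCs with TPM < 0.1 and singletons with
   TPM < 5 are discarded; replicate-inconsistent regions (< 90% reciprocal
   coverage) are removed before replicates are pooled.
2. **Consensus promoters** — per-stage TCs < 100 bp apart merge across
   developmental stages, carrying per-stage TPMs.
3. **Annotation** — each cluster's dominant CTSS is placed relative to the
   nearest annotated TSS (aTSS) using the hierarchy
   promoter (−500..+100) > 5'UTR/3'UTR > exon > intron >
   proximal (−1000..−501); per gene the best cluster is the **primary**
   promoter, the rest (and everything > 1 kb from any aTSS) form the
   **secondary** set.
4. **Core-promoter architecture** — strand-aware −50..+50 windows around
   the dominant CTSS (TSS = +1) are scored for the initiator class
   (the −1/+1 pyrimidine–purine dinucleotide: CA/CG/TG/other-PyPu), a
   positioned TATA box (PWM scan with *exact* p-values via
   dynamic-programming convolution of integer log-odds scores, hits at
   p ≤ 1e-4 in −40..−20), and the pyrimidine-rich Y patch
   (CTTCTTCCTC / GAGGAAGAAG).
5. **TOPscore** — the read-fraction-weighted pyrimidine tract length over
   a gene's primary-cluster CTSSs (tract = cap-adjacent C followed by
   C/T); genes with TOPscore > 3 are candidate 5'TOP mRNAs
   (TOR-responsive translational control).
6. **tau tissue specificity** — tau = Σ(1 − x̂ᵢ)/(n − 1) on a normalized
   expression matrix (0 = uniform, 1 = single-tissue).
7. **Promoter shifts** — genes whose dominant cluster changes between two
   stages (reciprocal ≥ 2-fold dominance, TPM ≥ 0.5, at least one
   promoter/5'UTR/proximal element), classified as *coding* or
   *utr5_promoter* by whether the inter-TSS interval touches the CDS.
8. **Synthetic data** — a truth-tagged generator that plants TATA-sharp,
   broad, Y-patch, TOP, intron-singleton ("recapping") and stage-shifted
   promoter architectures, so the entire pipeline is testable without
   external data.

The intended users are regulatory-genomics researchers who have mapped
CAGE libraries (or any 5'-end counting assay) and want reproducible
promoter catalogs with architecture and dynamics annotations.

## Worked example

Simulate a 60-gene dataset and run the full pipeline:

```bash
promkit simulate --seed 1 --out demo/data --n-genes 60
promkit run-all --data demo/data --out demo/run --seed 1
```

The run prints the report (`demo/run/report.txt`):

```
consensus clusters: 69
primary promoters:  60
secondary clusters: 9

per-stage tag clusters:
  stage1: 70 raw -> 69 after TPM filters
  ...

feature categories:
  exon: 5
  intron: 3
  promoter: 60
  utr5: 1

TATA fraction (primary, strict p): 0.150 (lenient: 0.167)
TATA positional mode: -32
architecture composition (primary):
  TATA+/CA: 6
  ...

TOP candidates (TOPscore > 3): 3
promoter shifts per stage pair:
  stage1xstage2: 6
  stage1xstage3: 6
```

Reading this: all 60 genes received a primary promoter (category
`promoter`, i.e. within −500..+100 of the annotated TSS); the 9 secondary
clusters are the planted intron-singleton spikes (`intron`) and the
alternative promoters of shifted genes (`exon`/`utr5`).  The planted TATA
promoters are recovered with the positional mode at −32, the planted TOP
genes exceed the TOPscore-3 threshold, and the 6 planted promoter shifts
are called in both stage pairs that involve stage 1 (the stage whose
promoter differs), at a mean distance near the planted 500 bp.

Every stage can be re-run in isolation from its cached intermediates, e.g.
`promkit features --data demo/data --out demo/run`, and real datasets are
described by a YAML config (`promkit run-all --config cfg.yaml`) listing
the genome FASTA, GFF3 annotation, per-stage/replicate CTSS tracks
(bedGraph pairs or 4-column text), optional TE BED and optional external
expression matrix for tau.

### Library use

```python
from promkit import SimulationConfig, simulate_dataset
from promkit.clustering import cluster_and_quantify, filter_clusters

ds = simulate_dataset(SimulationConfig(seed=1, n_genes=60))
tcs = filter_clusters(cluster_and_quantify(ds.tables[("stage1", 1)]))
print(len(tcs), "tag clusters;", "median IQW", sorted(t.iqw for t in tcs)[len(tcs)//2])
```

which prints `69 tag clusters; median IQW 51` — the 60 planted promoters
plus their secondary clusters, with the median width set by the broad
(sigma ~20 bp) promoter class.

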