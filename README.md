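# cavemap

Linkage mapping and comparative genomics for a genotyping-by-sequencing (GBS)
F2 intercross between the surface- and cave-dwelling morphotypes of the
Mexican tetra — and, more generally, for any biparental cross genotyped with
biallelic SNP tags in a species whose genome exists only as unplaced draft
scaffolds.

The package implements the full analysis chain as a tested library plus CLI:

1. **Marker QC and coding** (`cavemap.marker_qc`) — parental-consensus allele
   assignment from small founder panels (≥3-of-4 identical calls), F1
   heterozygote confirmation, discard rules (no parental assignment /
   identical parents / uninformative), and a segregation-distortion filter
   that removes markers with Pearson χ² > 50 against the F2 expectation of
   1 : 2 : 1 for genotype classes *SS* : *SC* : *CC*.
2. **De-novo linkage maps** (`cavemap.linkage`) — two-point recombination
   fractions by EM over the 9-cell joint genotype table (the
   double-heterozygote cell is a phase mixture with weight
   r²/(r² + (1−r)²)), independence-LOD single-linkage grouping over an
   integer threshold ladder, regression-style marker ordering by incremental
   insertion against a weighted least-squares criterion, and map distances by
   the Kosambi function *d* = 25 ln((1+2r)/(1−2r)) cM, with the multi-round
   drop/split/trim protocol used to consolidate groups.
3. **Binary-trait QTL scans** (`cavemap.qtl`) — marker regression (MR),
   Haley–Knott regression (HK) and EM interval mapping on
   hidden-Markov genotype probabilities, with genome-wide significance from
   permutation thresholds. LOD = (n/2)·log₁₀(RSS₀/RSS₁) for the regression
   methods, mixture-likelihood ratio for EM.
4. **Cross-genome synteny** (`cavemap.synteny`) — resolution of 12-column
   tabular BLAST hits (direct 64-bp tags, ~2-kb genomic flanks, transcript
   routes): per marker–target collapse to the lowest e-value alignment,
   top-hit determination (lowest e-value, identity breaking ties), and
   positional support from single-hit markers on the same linkage group,
   yielding the categories *single robust* / *top supported* /
   *top unsupported* / *not top, supported* / *unresolved*.
5. **Scaffold anchoring** (`cavemap.anchoring`) — modal-group assignment of
   draft scaffolds, colocalization percentages, and colinearity (Kendall τ
   between scaffold bp order and map cM order) with orientation calls.
6. **Synthetic data** (`cavemap.simcross`) — a generator producing GBS-style
   datasets with the statistical structure the analysis assumes (founder
   panels, F1s, F2 meioses through a Markov recombination model, planted QC
   artifacts, decoy alignments, a fully penetrant recessive trait), so every
   stage is testable against known ground truth.

## Worked example

Simulate a 25-chromosome cross (1000 markers, 170 F2 individuals, a fully
penetrant recessive trait at 42 cM on chromosome 13), then run QC, mapping,
and the three-method scan:

```bash
printf 'trait_locus: [13, 42.0]\n' > sim.yaml
cavemap simulate --config sim.yaml --out demo --seed 7
cavemap qc   --genotypes demo/genotypes.tsv --out demo/qc
cavemap map  --coded demo/qc/coded.tsv --out demo/map
cavemap scan --map demo/map/map.tsv --coded demo/qc/coded.tsv \
             --phen demo/phenotypes.tsv --n-perm 1000 --seed 7 --out demo/scan
cavemap synteny --direct demo/hits_direct.tsv --genomic demo/hits_genomic.tsv \
             --transcript demo/hits_transcriptomic.tsv \
             --map demo/map/map.tsv --out demo/syn
cavemap anchor --map demo/map/map.tsv --scaffolds demo/scaffolds.tsv \
             --out demo/anchor
```

prints

```
simulated 1000 markers -> demo
25 groups, 1000 markers, 1684.6 cM
mr: peak LOD 129.04 at LG13 36.3 cM (marker M13_020)
em: peak LOD 314.78 at LG13 37.0 cM (marker None)
hk: peak LOD 133.60 at LG13 37.0 cM (marker None)
539 syntenic links (53.9% of mapped markers)
```

All 1000 markers pass QC (no artifacts were planted), the map recovers the
25 simulated chromosomes exactly, and every scan method places its
genome-wide peak on linkage group 13 next to the trait locus, far above the
α = 0.001 permutation thresholds (≈ 6.4 LOD here; `marker None` marks a
between-marker grid position). The trait is fully penetrant and essentially
noise-free at n = 170, so peak LODs are very large. The synteny stage
resolves each marker to a single target chromosome despite planted paralog
decoys, and `demo/anchor/anchor_summary.json` reports 100% scaffold
colocalization for this error-free map.

`cavemap run --out dir --seed N` drives the same stages end-to-end from one
seed and writes a manifest of input/output hashes; re-running with the same
seed reproduces every file byte for byte.

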