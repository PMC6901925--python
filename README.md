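# xkmir

Cross-kingdom miRNA target discovery toolkit. Given a set of plant miRNAs,
a plant transcriptome and a human 3′ UTRome, `xkmir` runs three
complementary strategies to find biological processes and genes potentially
targeted in both kingdoms:

1. **Target prediction** (`xkmir.targets`) — a plant-style complementarity
   scanner (weighted mismatch "expectation" score with seed-region rules,
   psRNATarget-like parameters) and an animal-style scanner that minimizes
   the nearest-neighbor free energy of the miRNA:site duplex (RNAhybrid-like,
   Turner/Mathews 1999 parameters packaged as JSON and calibrated against
   RNAhybrid 2.1.2).
2. **Alignment strategy** (`xkmir.align`) — for each miRNA, all plant ×
   human target-gene pairs are compared by Smith–Waterman local alignment of
   CDS and protein sequences; significance via a 200-shuffle permutation
   p-value of the human-side sequence; plus a protein homology mapper
   (best reference by relative SW similarity, 85% threshold).
3. **Network strategy** (`xkmir.coexnet`, `xkmir.netmodules`) — Spearman-MI
   co-expression network with ARACNE-style DPI pruning, miRNA-target
   sub-network extraction and small-component filtering; graph clustering
   (greedy modularity and cohesiveness-based overlapping clusters);
   right-tail hypergeometric GO enrichment with BH correction, the
   target-retention rule, and cross-species shared-process intersection.

A synthetic-data generator (`xkmir.synth`) produces every input with planted
ground truth (target sites, ortholog pairs at controlled identity,
co-expression modules, enriched terms), so the whole pipeline is testable
offline.

## CLI

```bash
# generate a synthetic dataset with planted truth
xkmir synth --config generator.yaml --out data/

# scan targets (plant expectation score / human duplex MFE)
xkmir predict --mode plant --mirnas mirnas.fasta --targets transcripts.fasta --out out/

# the three strategies (single YAML config with paths + parameter blocks)
xkmir xalign  --config run.yaml --nperm 200 --seed 1
xkmir coexnet --config run.yaml --mi-threshold 0.06 --eps 0 --min-component 10
xkmir modules --config run.yaml
xkmir all     --config run.yaml
```

A run config lists input paths and optional parameter blocks:

```yaml
outdir: out
seed: 1
paths:
  mirnas: data/mirnas.fasta
  plant_transcripts: data/plant_transcripts.fasta
  human_utrs: data/human_utrs.fasta
  plant_cds: data/plant_cds.fasta
  plant_proteins: data/plant_proteins.fasta
  human_cds: data/human_cds.fasta
  human_proteins: data/human_proteins.fasta
  plant_network: data/plant_network.tsv     # edge list or GraphML
  human_network: data/human_network.tsv
  plant_annotations: data/plant.gmt
  human_annotations: data/human.gmt
  expression: data/expression.tsv
plant_params: {expectation_max: 2.5, top_n: 50}
duplex_params: {mfe_threshold: -36.5}
```

Exit codes: 0 success, 2 configuration error, 3 input error. Every strategy
writes a manifest (config hash, per-stage output checksums and timings);
reruns with the same config and seed are byte-identical.

## Packaged data

- `turner1999_duplex.json` — RNA duplex nearest-neighbor parameters
  (Turner/Mathews 1999, 37 °C), parsed from ViennaRNA's parameter file.
- `rnahybrid_calibration.json` — frozen RNAhybrid 2.1.2 MFEs for 30
  perfect-complement duplexes, used as an external oracle in the tests.
- `mirbase_mir168.fasta`, `mirbase_families.fasta` — mature miRNA sequences
  from miRBase v22.
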