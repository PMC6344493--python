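# ampkit

Reconstruction of the fine structure of focally amplified genomic regions
(ecDNA and HSR amplicons) from paired-end WGS alignments: copy-number
segmentation, discordant-pair breakpoint detection, breakpoint-graph
construction with balanced-flow copy numbers, and simple-cycle
decomposition. The package also ships:

* a built-in amplicon **simulator** (circular viral-hybrid structures built
  by iterative rearrangements, emitting aligned read-pair records directly),
* the **RDCJ** (repeat-aware double-cut-and-join) edit distance for scoring
  reconstructions against ground truth, with a random permutation-predictor
  baseline,
* **seed selection** filters for CNV calls, **human–viral fusion signature**
  classification (unifocal / strong / weak bifocal), and the downstream
  statistics (Fisher exact concordance, exact Poisson-Binomial enrichment,
  exponential tail fits).

## Layout

| module | role |
|---|---|
| `ampkit.records` | columnar read-pair store, contig tables, SAM round trip |
| `ampkit.simgen` | structure + alignment simulator, parameter grids, viral sets |
| `ampkit.seqstats` | library/coverage parameter estimation |
| `ampkit.segmentation` | meanshift CNV boundary detection (10 kbp + 300 bp refinement) |
| `ampkit.svdetect` | discordant pairs, bicluster clustering, support thresholds |
| `ampkit.interval_search` | amplicon interval growth from a seed |
| `ampkit.bpgraph` | breakpoint graph + balanced-flow copy numbers |
| `ampkit.cycledecomp` | max-bottleneck simple-cycle decomposition, cycle files |
| `ampkit.rdcj` | RDCJ distance, permutation predictor, error rates |
| `ampkit.seedselect` | CNV-call merging and seed filters |
| `ampkit.signatures` | fusion amplicon selection + signature calls |
| `ampkit.ampstats` | Fisher / Poisson-Binomial / exponential-fit statistics |
| `ampkit.cli` | pipeline orchestration + command line |
| `ampkit.benchmark` | reduced-grid simulate→reconstruct→score experiment |

## Command line

```sh
# simulate one instance (SAM + truth file)
ampkit simulate --seed 7 --interval-size 160000 --copy-number 16 \
    --rearrangements 8 --p-duplication 0.25 --coverage 10 \
    --sam sim.sam --truth truth.txt

# reconstruct from alignments + a seed interval (BED)
printf 'hpv16\t0\t7904\n' > seed.bed
ampkit reconstruct --sam sim.sam --seed-bed seed.bed \
    --graph-out graph.txt --cycles-out cycles.txt

# score the predicted cycles against the simulation truth
ampkit evaluate --truth truth.txt --cycles cycles.txt --sam sim.sam \
    --out rdcj.tsv

# classify human-viral fusion signatures from the graph
ampkit classify --graph graph.txt --sam sim.sam --out signatures.tsv

# standalone statistics
ampkit stats --fisher 11 6 6 22
```

`reconstruct` accepts `--mode {default,sensitive}`, `--coverage-cap`
(default 10×), `--content-target` (default 0.8) and `--runtime-log` for
runtime-vs-DNA-content records.

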