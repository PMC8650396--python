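# methylbench

A toolkit for benchmarking multi-assay DNA methylation data: normalize
per-CpG call sets to a common coverage, score coverage/efficiency/concordance
metrics, call and cross-validate differential methylation between two groups
of genomes, and evaluate microarray beta matrices with a variance-partition
harness and a SNP-probe-derived low-variance filter. A seeded synthetic-data
module generates inputs with the statistical structure these analyses assume,
so the full pipeline runs and tests without any external data.

## Modules

| Module | Purpose |
| --- | --- |
| `methylbench.synthio` | Seeded synthetic truth tables, call sets, read sets, beta matrices, annotations, FASTA |
| `methylbench.methylio` | 6-column methylation bedGraph I/O, strand merging (`merge_context`), replicate merging, region subsetting |
| `methylbench.covmetrics` | Coverage summaries/ECDFs, capture fractions, reads-to-target, usable bases, spike-in conversion, nucleotide enrichment, annotation profiles |
| `methylbench.downsample` | Count-level binomial thinning to a target mean coverage plus the read-level (BAM-analogue) comparison |
| `methylbench.concord` | Replicate SD vs the iid-binomial expectation, Pearson/Spearman matrices, UpSet-style site intersections |
| `methylbench.diffmeth` | Per-site binomial GLM (LRT), BH correction, DMA/DMk+ concordance, agreement-by-coverage mosaics, array PMDs |
| `methylbench.arrayqc` | Per-site crossed random-effects variance partition, pipeline ranking, SNP-probe genotype clusters and the technical-variance threshold |
| `methylbench.cli` | `methylbench` command with `simulate`, `downsample`, `qc`, `concord`, `dm`, `arrayqc` subcommands |

## CLI

All randomness flows from a single `--seed`; every subcommand writes a
`manifest.json` with the version, parameters and input checksums.

```sh
# generate a synthetic benchmark data set
methylbench simulate --seed 7 -o simdir

# normalize a call set to 20x mean CpG coverage
methylbench downsample --target 20 --seed 7 simdir/callsets/EMSeq_A1.bedGraph out.bedGraph

# coverage + conversion QC against the truth table
methylbench qc --reference simdir/truth.json -o qcdir simdir/callsets/EMSeq_A1.bedGraph

# cross-assay concordance
methylbench concord -o concdir simdir/callsets/*.bedGraph

# differential methylation (config lists per-assay group1/group2 bedGraphs)
methylbench dm --config dm.yaml -o dmdir

# array variance partition + SNP-probe filter
methylbench arrayqc --betas simdir/array_betas.csv --samples simdir/array_samples.csv \
    --sites simdir/array_sites.csv -o aqdir
```

## Library quick start

```python
from methylbench import synthio, downsample, diffmeth

cfg = synthio.SimConfig(seed=1, n_sites=10_000, dm_fraction=0.1, dm_pmd=0.3)
truth = synthio.generate_truth(cfg)
g1 = [synthio.generate_callset(truth, "EMSeq", g) for g in cfg.groups["A"]]
g2 = [synthio.generate_callset(truth, "EMSeq", g) for g in cfg.groups["B"]]
table = diffmeth.dm_analysis(g1, g2, alpha=0.05)   # per-site LRT + BH q-values
print(table[table.significant].head())
```
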