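# regulonkit

Identifying the direct regulon of a transcriptional repressor from an
acute-depletion RNA-seq time course — and characterizing how that regulon
behaves during meiotic induction.

The motivating biology: in budding yeast, the DNA-binding factor Ume6
silences the early meiotic genes (EMGs) during vegetative growth by binding
the URS1 element (core 5′-GGCGGC-3′) in their promoters, and switches to an
activator at meiotic entry.  Acutely depleting the protein with an
auxin-inducible degron and sequencing a short time course separates direct
derepression from the pleiotropic, indirect effects of a constitutive null.
`regulonkit` implements the full calling procedure on top of a synthetic-data
generator with planted ground truth, so every stage is testable without
external data.

## What it computes

Given counts, a sample sheet (control vs depletion, timepoints, replicates),
gene annotation, ChIP peak scores and a staged expression atlas:

1. **Time-series NB LRT** — per gene, a negative-binomial GLM
   (condition + time + condition:time vs time-only, time categorical),
   statistic 2(ℓ_full − ℓ_reduced) ~ χ²_df, BH-adjusted.
2. **Baseline filter** — drop candidates already DE at −30 or 0 min
   (padj < 0.05 and |log2FC| > 1).
3. **Acute filter** — keep candidates responding at 15 min
   (padj < 0.05 and |log2FC| > 0.3).
4. **TPM-ratio rescue** — average depletion/control TPM ratio over
   15–120 min; genes ≥ 1.4 or ≤ 0.6 join the composite list.
5. **ChIP curation** — mean peak score ÷ reference gene's mean score ≥ 0.5
   marks a direct target.
6. **Timing classification** — the atlas stage of peak expression
   (entry/replication/recombination roll up to the EMG count),
   plus a URS1 core scan (both strands) over promoter/ORF/downstream regions.

Downstream: baseline-normalized meiotic response (log2 TPM vs the 2 h
pre-induction point), k-means with a second-difference elbow rule, per-group
percent change between conditions, Spearman sample correlations, gene-set
enrichment (running-sum ES, gene-set permutation, sign-stratified NES) with
stepwise early-meiotic set curation, and ChIP-/RT-qPCR quantification from
dilution standard curves.  See `docs/methods.md` for models, assumptions and
numerical choices.

## Worked example

Run the whole study on synthetic data (2,000 genes; 150 planted direct
targets, 30 pre-existing-DE confounders, 50 slow responders):

```python
from regulonkit.pipeline import PipelineConfig, run_all

report = run_all(PipelineConfig(seed=1))
print(report["sizes"])
print(report["stage_counts"])
print(report["meiosis"]["cluster_sizes"], report["meiosis"]["pct_decrease"])
```

prints

```
{'lrt_hits': 258, 'after_baseline_filter': 226, 'after_acute_filter': 133,
 'tpm_rescued': 234, 'rescue_overlap': 130, 'composite': 237, 'direct': 150}
{'meiotic entry': 51, 'DNA replication': 12, 'recombination': 69,
 'mid': 18, 'late': 0, 'emg': 132}
{1: 72, 2: 40, 3: 32} {1: 13.46, 2: 41.92, 3: -1.33}
```

Reading this: the time-series LRT flags 258 genes (the planted 230
responders plus the confounders); the baseline filter removes the 30-odd
pre-existing-DE genes, the acute filter narrows to 133, the TPM-ratio path
adds back what the count test missed (all 50 slow responders arrive by this
route), and ChIP curation leaves exactly the 150 planted direct targets —
none of the planted nulls survive.  Their atlas peaks fall 51/12/69 in the
three early stages (132 EMGs of 150).  In the meiotic course the elbow rule
picks k = 3 with the planted 40/72/32 grouping recovered exactly; at 2.5 h
the strongly dependent cluster is ~42% lower under depletion, the
moderately dependent one ~13–20% lower, and the third essentially unchanged.

The same run is available from the shell:

```sh
regulonkit run-all --outdir out/ --seed 1
regulonkit simulate --outdir sim/ --seed 1      # inputs + ground truth only
regulonkit de --counts sim/counts.tsv --samples sim/samples.csv \
    --mode pairwise --timepoint 15 --out de15.tsv
```

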