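# epiconserve

Epigenetic conservation analysis of DNA methylation data.

## The problem

Genes that are essential to a cell's survival tend to keep their DNA
methylation configuration: random replication errors ("epigenetic drift")
accumulate freely in genes whose regulation the cell can tolerate varying,
but changes in functional genes reduce fitness and the affected cells are
lost to purifying selection. Two methylation measurements of the same cell
population separated by enough time therefore carry a signal of gene
function — conserved genes are candidates for being essential — without any
experimental gene disruption. This is useful to anyone who wants to rank
gene importance in normal human tissues or tumours, where CRISPR-style
knockout screens are impossible.

## The statistic

For a CpG site with *k* methylation proportion (beta-value) measurements
*A₁…A_k*, the conservation statistic is the **pairwise difference (PWD)**:

```
PWD = (1 / C(k,2)) · Σ_{i<j} |A_i − A_j|,     C(k,2) = k(k−1)/2
```

a number in [0, 1]; lower = more conserved. A gene's PWD is the unweighted
mean over all CpG sites annotated to it. Around this core the package
provides:

* **I/O** (`epiconserve.io`) — validated readers for beta matrices
  (GEO-style delimited exports), sample sheets, CpG→gene annotations,
  DepMap-style gene-effect matrices and long-format drug-response tables.
* **Conservation** (`epiconserve.pwd`) — CpG and gene PWD, group-aware
  aggregation (e.g. crypts within individuals), PWD histograms.
* **Essentiality diagnostics** (`epiconserve.essentiality`) — essential =
  mean gene-effect < −0.4; sensitivity/specificity/PPV/NPV of PWD cutoffs
  as an essentiality classifier; Welch's t-test between gene classes.
* **Time courses** (`epiconserve.temporal`) — drift accumulation in clonal
  cultures, recovery after a demethylating (5-azacitidine-like) shock,
  aging trends; Pearson trend tests.
* **Tissue comparison** (`epiconserve.tissue`) — genes conserved in one
  tissue but drifted in another; gene-family tagging (e.g. HOXA/HOXB).
* **Drug sensitivity** (`epiconserve.drugs`) — per-cell-line target-gene
  conservation vs drug sensitivity, Pearson r per (drug, target) pair.
* **Simulator** (`epiconserve.simulate`) — a Wright–Fisher forward model of
  per-cell binary CpG states with replication-error drift, purifying
  selection on essential-gene configurations, demethylation shocks and
  array-style measurement, emitting fully ground-truthed synthetic datasets
  for all of the above.

## Worked example

Simulate a clonal culture passaged in triplicate for 500 generations with
purifying selection (the default configuration), score conservation across
the replicates at the final passage, and ask whether essential genes are
more conserved:

```python
from epiconserve import (SimConfig, generate_scenario, grouped_gene_pwd,
                         call_essential, compare_classes)

cfg = SimConfig(seed=1)                      # 100 genes, 20% essential, s=2
data = generate_scenario("clonal_drift", cfg)
final = data.sheet[data.sheet["group"] == "t500"]
table = grouped_gene_pwd(data.beta, data.annotation, final)
calls = call_essential(data.gene_effect)     # mean effect < -0.4
res = compare_classes(table, calls)
print(f"essential genes:     n={res.n_a:3d}  mean gene PWD = {res.mean_a:.4f}")
print(f"non-essential genes: n={res.n_b:3d}  mean gene PWD = {res.mean_b:.4f}")
print(f"Welch t = {res.t:.2f}, df = {res.df:.1f}, p = {res.p:.2e}")
```

prints

```
essential genes:     n= 20  mean gene PWD = 0.0032
non-essential genes: n= 80  mean gene PWD = 0.3711
Welch t = -42.33, df = 79.1, p = 4.16e-56
```

After 500 generations of drift the non-essential genes have diverged
substantially between replicates (mean PWD 0.37) while selection has held
the essential genes' methylation nearly identical (mean PWD 0.003) — the
conservation signal the pipeline detects. The same run's threshold
diagnostics (`threshold_diagnostics(table, calls)`) classify essentiality
from PWD < 0.05 with 100% sensitivity and specificity at this strong,
noise-free separation; on real tissue data the separation is much weaker
and the diagnostics table is the honest summary of the overlap.

The same stages are available from a shell:

```sh
epiconserve simulate --scenario clonal_drift --seed 1 --out sim/
epiconserve pwd --beta sim/beta_matrix.tsv --sheet sim/sample_sheet.csv \
    --annotation sim/annotation.tsv --out pwd/
epiconserve diagnostics --pwd pwd/gene_pwd.tsv --effects sim/gene_effect.csv \
    --thresholds 0.05,0.10,0.15 --out diag/
```

Every output directory contains a `manifest.json` with the tool version,
parameters and input hashes; repeat runs are byte-identical.

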