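# gsrlab

Rank-conservation gene-set scoring for bulk and single-cell transcriptomics: the **gene
set regularity (GSR) index** and its downstream functionome analyses.

Complex diseases deregulate many functions at once, and most of the signal lives in
*which genes outrank which* rather than in absolute expression.  For a gene set
G = {G1, …, Gm} (a GO term or canonical pathway), gsrlab first learns a **baseline
ordering template** from control samples — for every gene pair (i, j), orientation "A" if
Pr(Ei < Ej | control) > 0.5, else "B" — and then scores each sample by

    R = (number of pairs matching the template) / (m(m−1)/2)

R = 1 reproduces the normal ordering exactly, R = 0 reverses every pair, and random
expression averages R ≈ 0.5.  Because only order relations enter, R is invariant under
any strictly increasing per-sample transform — which is what lets expression data from
different platforms be integrated and compared.  The vector of R values over a gene-set
collection (the "functionome") feeds the rest of the toolkit:

* **Deregulation ranking** — two-sided Mann-Whitney U per set (stage vs control),
  Benjamini-Hochberg adjustment, deterministic ranks.
* **Set analysis** — exact region counts of the stages' top-k lists, including the
  commonly deregulated intersection.
* **Progressive-ranking selection** — sets significant at every stage whose rank climbs
  by more than a threshold between consecutive stages.
* **Classification harness** — repeated stratified 5-fold linear-SVM cross-validation
  (sensitivity/specificity/accuracy/AUC from cumulative counts) and complete-linkage
  clustering of group-mean GSR vectors.
* **Interaction networks** — Kraskov kNN mutual information between set profiles with
  ARACNE multiplicative-model pruning, exported as GML.
* **Cross-platform integration** — per-sample cumulative-proportion rescaling,
  common-gene merging with a minimum-intersection rule, and limma-style moderated-t
  differential expression.
* **Synthetic cohorts** — multi-stage generators with exact pair-order ground truth, so
  every stage of the pipeline is testable without downloads.

See `docs/methods.md` for the model details, conventions and design decisions.

## Worked example

A synthetic four-stage cohort (60 controls, 30 cases per stage; an increasing fraction of
gene sets perturbed at increasing pair-flip intensity across stages I→IV):

```python
from gsrlab import staging_preset, generate_cohort, gsr_matrix
from gsrlab.deregulation import test_deregulation
from gsrlab.classify import svm_cv

expr, phenotypes, collection, truth = generate_cohort(staging_preset(seed=1))
gsr = gsr_matrix(expr, phenotypes, collection)

for group in ["control", "I", "II", "III", "IV"]:
    cols = [s for s in gsr.sample_ids if phenotypes[s] == group]
    print(f"mean GSR {group:>7}: {gsr.data[cols].to_numpy().mean():.4f}")

records = test_deregulation(gsr, phenotypes, case_label="IV")
injected = set(truth.perturbed["IV"])
top = {r.set_name for r in records if r.rank <= len(injected)}
print(f"injected sets recovered in top-{len(injected)}: {len(top & injected)}/{len(injected)}")

report = svm_cv(gsr, phenotypes, ["IV", "control"], seed=0)
print(f"stage IV vs control: accuracy {report.accuracy:.4f}, AUC {report.auc:.4f}")
```

Output:

```
mean GSR control: 0.7877
mean GSR       I: 0.7655
mean GSR      II: 0.7369
mean GSR     III: 0.6820
mean GSR      IV: 0.6095
injected sets recovered in top-100: 100/100
stage IV vs control: accuracy 1.0000, AUC 1.0000
```

The stage means fall strictly from I to IV — functional regularity deteriorates with
severity — while the controls stay high; the Mann-Whitney ranking recovers every
perturbed set, and the functionome pattern separates stage IV from controls perfectly.

The same workflow runs from the shell:

```
gsr simulate --preset staging --seed 1 --out-dir sim/
gsr run --expr sim/expression.tsv --pheno sim/phenotypes.tsv \
        --gmt sim/gene_sets.gmt --out-dir results/
```

which writes the GSR matrix, per-stage deregulation tables, Venn region counts, the
progressive-ranking table, classification reports, the cluster merge sequence and the
pruned interaction network (`net.gml`), with a manifest that makes re-runs incremental.

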