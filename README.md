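# kldnet

Tumor/normal classification from bulk RNA-seq expression counts, built
around two ideas: **Kullback–Leibler (KL) divergence gene selection** to cut
tens of thousands of genes down to a small disease-related feature set, and
a **two-hidden-layer neural classifier trained with focal loss** so that a
heavily imbalanced cohort (e.g. ~9 tumor samples for every normal) does not
collapse the model onto the majority class. Performance is estimated with
stratified 5-fold cross-validation (accuracy, recall, precision, ROC/AUC).

It is aimed at people analysing gene × sample count matrices of the
TCGA/ICGC kind — a few hundred samples, ~20,000 protein-coding genes,
strong class imbalance — who want a small, fully deterministic, inspectable
pipeline rather than a framework.

## Method

**Gene selection.** For each gene, the expression values of the disease
group and the control group are turned into binned probability vectors
*P* and *Q* over shared bin edges (equal-width histograms of log2(x+1)
values, additive pseudocount so every bin has positive mass). The gene is
scored with the KL divergence

$$D(P \| Q) = \sum_i P(i)\,\ln\frac{P(i)}{Q(i)} \;\ge\; 0 ,$$

which is 0 exactly when the two distributions coincide — an invariant gene
carries no disease signal — and grows with their separation. Genes with
score > 3 nats (configurable) become the model features.

**Classifier.** A multilayer perceptron

$$\hat y = \sigma\big(\mathrm{relu}(\mathrm{relu}(x W_1 + b_1) W_2 + b_2)\cdot w_3 + b_3\big)$$

trained with Adam on either binary cross-entropy or the focal loss

$$\mathcal{L} = -\,y\,\alpha\,(1-\hat y)^{\gamma}\log \hat y \;-\; (1-y)\,\hat y^{\gamma}\log(1-\hat y),$$

whose modulating factors $(1-\hat y)^\gamma$ / $\hat y^\gamma$ shrink the
contribution of confidently classified samples so the gradient is spent on
the hard (typically minority-class) ones; $\alpha$ re-weights the classes.

**Evaluation.** Confusion-matrix metrics at threshold 0.5, rank-based AUC
(equal to the trapezoidal area under the ROC curve), and stratified k-fold
cross-validation in which gene selection is re-fit inside each training
fold (no information leaks from held-out samples into the feature set).

A negative-binomial simulator (`kldnet.synthetic_data`) generates
imbalanced two-group count matrices with a planted differential gene set,
so the whole pipeline is testable end to end without any data download.

## Worked example

Simulate a cohort shaped like a real lung-cancer dataset (2,000 genes,
180 tumor vs 20 normal samples, 50 planted differential genes at log2 fold
change 2), select genes, and cross-validate the classifier:

```console
$ kldnet simulate --out-dir fixture --n-genes 2000 --n-tumor 180 \
      --n-normal 20 --n-differential 50 --seed 7
wrote fixture/matrix.tsv (2000 genes x 200 samples), 50 planted genes

$ kldnet select --matrix fixture/matrix.tsv --labels fixture/labels.tsv \
      --out-dir selection --threshold 3
scored 2000 genes, selected 49 at threshold 3.0

$ head -4 selection/kl_scores.tsv
gene_id	kl_score
g1839	3.979527786
g1175	3.950658795
g1576	3.869508515

$ kldnet run-all --matrix fixture/matrix.tsv --labels fixture/labels.tsv \
      --out-dir results --seed 7
{"mean": {"accuracy": 1.0, "recall": 1.0, "precision": 1.0, "auc": 1.0}, "best_fold": 0}
```

All 49 genes passing the threshold are planted differential genes (49/50
recovered), and the classifier separates the held-out folds perfectly —
at this effect size the tumor and normal expression distributions of a
planted gene barely overlap. `results/` contains the per-fold report
(`cv_report.json`), the best fold's checkpoint and gene list, per-fold ROC
curves, and a manifest with the config hash and seed; repeating the command
with the same seed reproduces every analysis output byte for byte (only the
manifest's stage timings change).

The same steps are available as library calls (`simulate`, `score_genes`,
`select_genes`, `train`, `stratified_kfold_cv`); see the docstrings and
`docs/methods.md` for the model details and design choices.

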