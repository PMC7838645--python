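# Methods

## Problem setting

Primary cultured airway smooth muscle cells exposed to IL-13, IL-17, both
cytokines, or vehicle define a four-class classification problem over
omics features: methylation beta values (fractions in [0,1] per CpG probe)
and expression log2 intensities (roughly 7–13 on array scale), analysed
separately or as a concatenated "combined" layer. The number of features
vastly exceeds the number of samples, which is the regime Monte Carlo
feature selection targets.

## Monte Carlo feature selection

An ensemble of s projections × t splits is drawn: each projection is m
features sampled uniformly without replacement from the M available; each
split is a stratified holdout with `train_fraction` (default 0.66) of
samples for growing and the rest for evaluation. One binary decision tree
per (projection, split) is grown greedily on entropy information gain to
purity with a minimum leaf of 2 and no pruning — the trees exist to expose
feature usefulness, not to predict. The tree construction is delegated to
scikit-learn's `DecisionTreeClassifier` (its entropy criterion is in bits);
the per-node (feature, IG, node size, root size) records are extracted from
the fitted tree arrays.

The relative importance of feature f is

    RI_f = Σ_trees (wAcc)^u · Σ_{nodes on f} IG(node) · (n_node / n_root)^v

with u = v = 1 by default. wAcc is the *unweighted mean of per-class
sensitivities* on the tree's held-out samples (classes present in the
held-out split only): a tree that labels everything with the majority class
of a 9:1 split earns 0.5, not 0.9. This choice — the originators'
definition — discounts trees that ignore rare classes. By construction
Σ_f RI_f equals the summed per-tree weighted gain, a bookkeeping identity
the test suite checks to 1e-9.

Parameter defaults: m = max(⌈0.05·M⌉, 30) (capped at M), t = 5,
s = 2000/t, giving 2,000 trees. These stand in for the reference
implementation's unpublished defaults and are all overridable. Projections
are drawn by index over the *canonically sorted* feature ids, so a
permutation of input columns cannot change the ranking; RI ties are broken
lexicographically on feature id.

## Incremental feature selection

Nested prefixes of the ranking (top 1, top 2, …) are each scored by
stratified k-fold cross-validation (default 10 folds, capped by the rarest
class size with a warning). Scoring pools the out-of-fold predictions and
computes one record — per-class accuracies, overall accuracy, and the
Gorodkin multiclass MCC — rather than averaging per-fold metrics, because
the MCC is defined on whole indicator matrices. The fold plan depends only
on (labels, folds, seed), so every prefix size of one dataset is scored
under the identical partition and the curve reflects feature content
rather than fold noise. The optimum is the maximum-MCC prefix; ties go to
the smallest k (parsimony). The full-scale sweep is k = 1..min(5000, M)
step 1; desk-scale runs pass a coarser explicit grid.

Degenerate MCC denominators (e.g. an all-one-class prediction) are defined
as 0, keeping curves finite for collapsed classifiers.

## Classifiers

Four back-ends sit behind one adapter: random forest (10 trees),
SVM with polynomial kernel and C = 1.0 (one-vs-one multiclass, degree 1 —
the defaults of the SMO implementation this configuration mirrors),
1-nearest-neighbour with Euclidean distance, and the rule learner below.
The first three are scikit-learn estimators; hyperparameters are fixed, not
tuned.

## Rule learning

The inducer is IREP-style sequential covering, the core of the RIPPER
family: classes are processed from rarest to most frequent (ties by name),
the most frequent class becomes the default and receives no rules. Each
rule is a conjunction of threshold conditions `(feature >= x)` /
`(feature <= y)`, grown greedily by FOIL information gain on a 2/3 growing
split (candidate thresholds are midpoints between consecutive observed
values, subsampled to at most 32 per feature), pruned on the remaining
third by maximising (p − n)/(p + n) over condition prefixes, and accepted
only if held-out precision exceeds 0.5; covered samples are then removed.
RIPPER's MDL-based global optimisation passes are omitted: the contract
is an ordered decision list, and grow/prune is what shapes it. On
label-independent data the precision gate stops induction almost
immediately (at most one spurious rule is tolerated by the tests).

Decision lists serialise to a one-rule-per-line grammar with a final
`default => CLASS` line; only non-strict inequalities are grammatical, and
the combined-stimulation consequent "IL-13 and IL-17" is an atomic class
label. Two published decision lists for this biological system are
packaged verbatim as fixtures (their differing defaults — combined
stimulation for the expression-layer list, control for the combined-layer
list — are preserved as printed). Parsed thresholds retain their printed
precision through round-trips.

## Synthetic data generator

The generator emulates the study design: four groups of `n_per_group`
(default 64) samples; expression as per-feature baseline ~ U(7, 12) plus
group shift plus N(0, noise_sd); methylation as the inverse logit of a
latent normal with baseline ~ U(−2, 2) on the logit scale and the same
additive shift structure, which keeps beta values in [0,1] without
truncation. IL-13-responsive features shift in the IL-13 and combined
groups, IL-17-responsive in the IL-17 and combined groups, and
combination-only features in the combined group alone — the combined
condition is additive plus dedicated combo features, matching decision
lists that need combination-specific markers. Desk-scale feature counts
(2,000 expression / 5,000 methylation, 20 responsive per factor per layer)
keep a full MCFS run in tens of seconds while preserving the
needle-in-haystack structure; full-scale counts are configurable.
The expression baseline range was chosen so published rule thresholds
(7.2–12.8) fall inside the simulated dynamic range. Methylation is emitted
on the beta scale; the pipeline accepts any numeric matrix, so M-value
inputs work unchanged.

What the generator does *not* emulate: probe-chemistry artefacts, batch
effects, correlated co-regulated feature blocks, heavy-tailed noise, or
realistic methylation–expression coupling. Passing recovery tests on this
generator therefore demonstrates correctness of the algorithms under the
stated statistical model, not performance on real arrays.

## Pipeline and reproducibility

`run_pipeline` derives one seed per (stage, layer) from the single
configured seed via CRC32-tagged `SeedSequence` children (all below 2^31),
so runs are bit-reproducible end to end and independent of process hash
randomisation. Outputs per layer: ranking TSV, one IFS curve TSV + JSON
optimum sidecar per classifier, a rule file induced on the rule learner's
optimum subset, an optimum summary table across layers × algorithms, and a
manifest echoing config, seed and package version. The combined layer is
built by column concatenation with `meth:`/`expr:` prefixes, letting both
feature families compete in a single MCFS run. Dataset directories hold
`matrix.tsv` (samples × features), `labels.tsv` (sample id, class) and a
small `meta.json` carrying the layer tag so round-trips preserve it.

## Numerical choices and limitations

- Tiny negative information gains from floating-point round-off are
  clamped to 0.
- wAcc^u uses the convention x^0 = 1 so u = 0 cleanly disables accuracy
  weighting.
- Test problem sizes (hundreds of features, tens of samples per group,
  40–2,000 trees) were chosen so the default suite completes in minutes;
  they are stated in each test.
- The published real-data optima (e.g. SVM MCC 0.831/0.990/0.969 across
  the three layers) depend on the original arrays and on the reference
  MCFS implementation's exact defaults, which are not public; this package
  reproduces the method's structure and behaviour, not those numbers.
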