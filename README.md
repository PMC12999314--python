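# ppifern

Sequence-based prediction of protein–protein interactions (PPIs) from
evolutionary profiles: position-specific scoring matrix (PSSM)
cross-product features, stacked denoising autoencoder (SDAE)
representation learning, and a random-ferns semi-naive Bayes classifier,
with cross-validated evaluation and a seeded synthetic benchmark
generator so the whole pipeline runs with no external downloads.

## Who this is for

Computational biologists who have per-protein PSSM profiles (from an
iterative profile search such as PSI-BLAST) and a table of labelled
protein pairs, and want a reproducible, dependency-light baseline for
sequence-only interaction prediction — plus anyone who needs the
individual pieces: a PSI-BLAST ASCII PSSM parser, a fixed-size PSSM
featurizer, a pure-numpy SDAE, or a random-ferns classifier.

## The method

1. **Profiles.** Each protein of length *L* is an *L*×20 PSSM
   *P = [p(i,j)]* of log-odds substitution scores.
2. **Fixed-size features.** The cross-product *PᵀP* (20×20) removes the
   length dependence; flattened row-major it gives 400 values per
   protein, and a pair is the 800-vector concatenation A‖B.  By default
   scores are squashed through the logistic function before the product
   and the result is divided by *L*, keeping features in [0, 1].
3. **SDAE.** Denoising autoencoder layers *h = σ(Wₑx + bₑ)*,
   *y = σ(W_d h + b_d)* are pretrained greedily on corrupted inputs
   (masking noise, rate 0.3) against mean-squared reconstruction error,
   then fine-tuned end-to-end with a softmax head; the head is dropped
   and the deepest encodings become the classifier input.
4. **Random ferns.** *M* ferns of *S* binary threshold tests each
   (defaults S=20, M=50); class-conditional outcome probabilities are
   smoothed as *p(k|c) = (Nr + N_{k,c}) / (2^S·Nr + N_c)* and multiplied
   across ferns in the log domain; the posterior argmax decides.
5. **Evaluation.** Stratified 5-fold cross-validation with the full
   pipeline retrained per fold; accuracy, sensitivity, precision,
   Matthews correlation and rank-based AUC, reported as mean ± sample
   standard deviation over folds.

See `docs/methods.md` for assumptions, parameter guidance and the
synthetic-benchmark design.

## Worked example

```python
import ppifern as pf

# A seeded synthetic dataset: 80 proteins, 300 balanced pairs with a
# planted latent interaction signal.
ds = pf.generate_dataset(pf.SynthConfig(n_proteins=80, n_pairs=300, seed=42))

config = pf.PipelineConfig(
    sdae=pf.sdae.SDAEConfig(layer_dims=(128, 64), epochs_pretrain=10,
                            epochs_finetune=300, learning_rate=1.0),
    seed=42,
)
results = pf.PPIModel.from_pair_table(ds.pairs, ds.pssms, config).fit()
print(results.summary())
```

```
Protein-pair interaction model (cross-product PSSM features)
==============================================================
representation     : SDAE [128, 64] -> 64-d encodings
ferns              : M=50 ferns, depth S=20 (K=2^20 outcomes), Nr=1.0
training pairs     : 300 (150 positive / 150 negative)
featurization      : {'elementwise_transform': 'logistic', 'length_normalization': 'divide_by_L'}
seed               : 42
--------------------------------------------------------------
training-set fit (resubstitution, optimistic):
  ACC=0.9767  SN=0.9933  PE=0.9613  MCC=0.9539  AUC=0.9960
```

The resubstitution block scores the training pairs themselves and is
optimistic by construction; the honest estimate comes from
cross-validation, which retrains everything inside each fold:

```python
report = pf.evaluate.cross_validate(ds.pairs, ds.pssms, config, k=5, seed=42)
for m in ("acc", "sn", "pe", "mcc", "auc"):
    print(f"{m.upper():4s} {report.mean[m]:.4f} +/- {report.std[m]:.4f}")
```

```
ACC  0.9200 +/- 0.0139
SN   0.9200 +/- 0.0650
PE   0.9241 +/- 0.0443
MCC  0.8447 +/- 0.0258
AUC  0.9500 +/- 0.0192
```

So on this small planted-signal benchmark the pipeline recovers the
interactions at ~92 % cross-validated accuracy (at the default study
size of 1000 pairs it reaches ~96 %); with `signal=0` the same numbers
collapse to chance.

`results.save("model.json")` writes a versioned JSON bundle whose
reload reproduces predictions bit-for-bit;
`results.predict_pairs(pairs, pssms)` scores new pairs with the
featurization settings recorded in the bundle.

## Command line

The same pipeline as composable subcommands:

```sh
ppifern simulate  --out data/ --n-proteins 200 --n-pairs 1000 --seed 1
ppifern featurize --pairs data/pairs.tsv --pssm-dir data/pssm --out features.tsv
ppifern train     --pairs data/pairs.tsv --pssm-dir data/pssm --out model.json
ppifern predict   --model model.json --pairs other/pairs.tsv \
                  --pssm-dir other/pssm --out scores.tsv
ppifern evaluate  --pairs data/pairs.tsv --pssm-dir data/pssm --out cv.json
```

`train --no-sdae` fits the ferns on the raw 800-d features (the
representation-learning ablation); `train` on dataset A followed by
`predict`/`evaluate` on dataset B gives the cross-dataset workflow.
Exit codes: 0 success, 2 validation error, 1 runtime failure.

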