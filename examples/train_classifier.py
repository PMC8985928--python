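"""Train the RMDL ensemble and measure held-out ranking quality.

The labeled corpus grows over three cycles against a note pool (scooter
keyword notes, then brand-keyword notes, then keyword-free negatives for
balance), is split 70/30 with label stratification, and the ensemble — 3
feedforward nets on TF-IDF plus 3 convolutional nets on locally trained
embeddings, soft-voted — is fitted on the training side only.
"""
import scootersurv as ss
from scootersurv.ensemble import binary_labels, build_labeled_corpus
from scootersurv.synthetic import demo_pool_config

pool = ss.generate_corpus(demo_pool_config(seed=4))
labeled = build_labeled_corpus(pool, seed=4)
y = binary_labels(labeled)
print(f"labeled corpus: {len(labeled)} notes, {y.sum()} injuries "
      f"({100 * y.mean():.1f}% positive)")

train_set, test_set = ss.split_labeled(labeled, train_fraction=0.70, seed=4)
ensemble = ss.build_ensemble(ss.EnsembleSpec(seed=5))
for m in ensemble.members:
    print("  member:", m.kind, m.hidden or m.conv)

trained = ss.train(ensemble, train_set)
preds = ss.predict_proba(trained, test_set)
auc = ss.evaluate_auc(preds.probability, binary_labels(test_set))
print(f"full-training-data AUC: {trained.metrics['train_auc']:.3f}")
print(f"held-out AUC: {auc:.3f}")
print("(AUC is the probability a random injury note outranks a random non-injury note)")
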