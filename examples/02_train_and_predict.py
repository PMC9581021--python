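"""Train the boosted meta-classifier on a planted-signal dataset.

Generates a balanced synthetic dataset in which interacting pairs share
annotation evidence with probability 0.9 per channel (0.1 for
non-interacting pairs), trains AdaBoost over the six evidence features
with stratified 10-fold cross-validation, and predicts a few pairs.
"""

from ppistack import FeatureMatrix, build_feature_vector, predict, train
from ppistack.fixtures import (
    FixtureSpec,
    generate_go_dag,
    generate_interaction_dataset,
    generate_proteins,
)

spec = FixtureSpec(seed=7, n_proteins=300, n_pairs=400, p_pos=0.9, p_neg=0.1)
dag = generate_go_dag(spec)
store = generate_proteins(spec, dag)
dataset = generate_interaction_dataset(spec, store, dag)

vectors = [
    build_feature_vector(pair, store, dag, dataset.known_domains)
    for pair in dataset.pairs
]
matrix = FeatureMatrix.from_vectors(vectors, labels=dataset.labels)
model, report = train(matrix, seed=7)

print(f"10-fold CV on {len(matrix)} pairs:")
print(f"  accuracy  {report.accuracy:.3f}")
print(f"  precision {report.precision:.3f}")
print(f"  recall    {report.recall:.3f}")
print(f"  f1        {report.f1:.3f}")
print(f"  AUC       {report.auc:.3f}")
print(f"  confusion [[TN FP] [FN TP]] = {report.confusion.tolist()}")

probs, calls, positives = predict(model, matrix)
print(f"\npositively predicted pairs: {len(positives)} of {len(matrix)}")
print("first three:", positives[:3])
print(
    "\nAccuracy well above 0.5 reflects recovery of the planted evidence\n"
    "sharing; the pooled confusion matrix sums to the dataset size."
)
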