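"""Run the built-in subject-independent cross-validation benchmark.

Generates the desk-scale synthetic dataset (5 subjects x 20 recordings),
trains the width-reduced classifier on five folds with one held-out
subject each, and prints the per-fold and aggregate metrics. Takes on the
order of 15 minutes on one CPU core.
"""

from radarcough.benchmark import run_benchmark

out = run_benchmark(seed=0, verbose=True)

print("\nper-fold test metrics:")
for i, fold in enumerate(out["folds"]):
    print(f"  fold {i + 1}: F1 {fold['f1']:.3f}  accuracy {fold['accuracy']:.3f}"
          f"  AUC {fold['auc']:.3f}")

print("\naggregate (mean +- sample std over folds):")
for name in ("f1", "accuracy", "recall", "specificity", "auc", "brier"):
    s = out["summary"][name]
    print(f"  {name:12s} {s['mean']:.3f} +- {s['std']:.3f}")
print("\nF1/accuracy near 1.0 indicate the cough class is recovered for "
      "subjects never seen in training.")
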