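"""Train the functional-capacity regressor on the synthetic benchmark.

Generates the default study, holds out whole subjects (70/15/15), trains
the 2-10-1 feed-forward network with adaptive-rate gradient descent and
early stopping, and reports the held-out correlation and error.
"""

from neurotap import (
    GeneratorConfig,
    NetworkSpec,
    TrainConfig,
    count_parameters,
    evaluate_on,
    extract_features,
    generate_dataset,
    split_by_subject,
    train_ffbp,
)

spec = NetworkSpec(n_inputs=2, n_hidden=10, n_outputs=1)
print(f"architecture: 2-10-1 feed-forward, {count_parameters(spec)} trainable weights")

records, labels, _ = generate_dataset(GeneratorConfig(seed=42))
rows = extract_features(records, tfc=labels)
split = split_by_subject(rows, seed=42)
print(f"subject-level split: {len(split.train)}/{len(split.validation)}/"
      f"{len(split.test)} attempts (train/validation/test)")

net = train_ffbp(split, TrainConfig(seed=42))
print(f"trained for {len(net.history)} epochs "
      f"(early stopping on validation error)")

for name, part in [("train", split.train), ("validation", split.validation),
                   ("test", split.test)]:
    r, mse = evaluate_on(net, part)
    print(f"  {name:10s} R = {r:.4f}   MSE = {mse:.4f}")

print("\nR is the correlation between predicted and true capacity on a 0-10"
      "\nscale; MSE ~ 0.04 sits at the label-noise floor (noise sd 0.2), so the"
      "\nnetwork has recovered the underlying capacity function for unseen"
      "\nsubjects.")
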