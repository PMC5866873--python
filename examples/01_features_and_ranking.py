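"""Feature extraction and ranking on a simulated tap-test cohort.

Generates the default synthetic study (20 subjects, ~3000 tap attempts),
checks that the two features need a log transform to look normal, and ranks
their power to separate healthy from HD attempts via relative entropy.
"""

import numpy as np

from neurotap import (
    GeneratorConfig,
    compute_delta,
    extract_features,
    generate_dataset,
    normality_report,
    rank_features,
)

# the touch-error feature for one attempt: target centre vs touch point
delta = compute_delta(target=(580, 377), touch=(618, 449))
print(f"touch error for a ({580},{377}) target touched at ({618},{449}): {delta:.3f} px")

records, labels, _ = generate_dataset(GeneratorConfig(seed=42))
rows = extract_features(records, tfc=labels)
rt = np.array([r.rt for r in rows])
de = np.array([r.delta for r in rows])
print(f"\n{len(rows)} attempts from 20 subjects; "
      f"rt {rt.min():.2f}-{rt.max():.2f} s, delta {de.min():.2f}-{de.max():.2f} px")

print("\nnormality screen (|skew| < 2 and |kurtosis| < 7 acceptable for n > 300):")
for name, values in [("rt", rt), ("delta", de),
                     ("log rt", np.log(rt + 1e-3)), ("log delta", np.log(de + 1e-3))]:
    rep = normality_report(values)
    print(f"  {name:10s} skew={rep.gamma:6.3f}  kurt={rep.kappa:6.3f}  "
          f"acceptable={rep.acceptable}")

print("\nrelative-entropy class separation, healthy vs HD (bits, higher = more"
      " discriminative):")
print(rank_features(rows).pivot(index="feature", columns="n_objects",
                                values="kl_bits").round(3))
print("\nThe touch error (delta) separates the classes better than reaction time"
      "\nin every test mode, so it carries more weight in the capacity label.")
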