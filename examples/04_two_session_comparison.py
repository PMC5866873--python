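"""End-to-end deterioration detection on a simulated patient.

Trains the capacity regressor, then simulates the same HD patient taking
the tap test twice — the second time with substantially progressed motor
severity — and runs the full hybrid pipeline: per-attempt predictions,
per-mode averages, fuzzy staging, and the two-session verdict.
"""

from neurotap import (
    GeneratorConfig,
    TrainConfig,
    compare_sessions,
    default_system,
    evaluate_session,
    extract_features,
    generate_dataset,
    simulate_session,
    split_by_subject,
    train_ffbp,
)
from neurotap.simulate import SubjectProfile

cfg = GeneratorConfig(seed=42)
records, labels, _ = generate_dataset(cfg)
split = split_by_subject(extract_features(records, tfc=labels), seed=42)
net = train_ffbp(split, TrainConfig(seed=42))
fls = default_system()

patient_before = SubjectProfile(user_id=101, is_sick=1, severity=0.35)
patient_after = SubjectProfile(user_id=101, is_sick=1, severity=0.75)
session1 = simulate_session(patient_before, cfg, attempts_per_mode=4, seed=7, session_id="1")
session2 = simulate_session(patient_after, cfg, attempts_per_mode=4, seed=8, session_id="2")

for label, session in [("before", session1), ("after", session2)]:
    ev = evaluate_session(net, fls, session)
    print(f"{label}: AVG = ({ev.avg1:.2f}, {ev.avg2:.2f}, {ev.avg3:.2f})  "
          f"eval = {ev.eval_score:.2f}  stage = {ev.stage}")

verdict = compare_sessions(
    evaluate_session(net, fls, session1), evaluate_session(net, fls, session2)
)
print(f"\nConclusion: {verdict.message}")
print("\nBetween sittings the simulated patient's severity rose from 0.35 to"
      "\n0.75; slower, less accurate taps lower the per-mode capacity averages"
      "\nand the fuzzy stage drops, which the decision module reports as an"
      "\nimpaired reaction condition.")
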