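"""Call binders from simulated PBM replicate scores and build a PWM.

Simulates an array in which a third of the consensus-derived probes are
true binders, derives the binder threshold from the random controls
(mean + 2 sample SD), calls binders with empirical p-values, and builds a
position weight matrix from the bound sequences.
"""

import numpy as np

from alucensus import (Probe, SimulationConfig, aggregate_replicates,
                       build_pwm, call_binders, compute_threshold,
                       generate_random_controls, pwm_to_text,
                       simulate_pbm_scores)

rng = np.random.default_rng(0)
candidates = ["".join("ACGT"[b] for b in rng.integers(0, 4, 13))
              for _ in range(90)]
probes = [Probe(f"cand{i:03d}", seq, "alu_frequency")
          for i, seq in enumerate(dict.fromkeys(candidates))]
probes += generate_random_controls(100, 13, seed=1,
                                   exclude={p.sequence for p in probes})

cfg = SimulationConfig(seed=42)   # control mean 0.452, SD 0.08, binder mean 0.75
binder_ids = [p.id for p in probes[:30]]
table = simulate_pbm_scores(probes, cfg, binder_ids=binder_ids)

means = aggregate_replicates(table)
control_ids = [p.id for p in probes if p.category.startswith("random_control")]
controls = means[control_ids].tolist()
threshold = compute_threshold(controls, multiplier=2.0)
print(f"control mean {threshold.control_mean:.3f}, SD {threshold.control_sd:.3f} "
      f"-> binder threshold {threshold.threshold:.3f} (strictly above = binder)")

candidate_ids = [p.id for p in probes if p.category == "alu_frequency"]
calls = call_binders(means[candidate_ids], threshold, controls)
binders = [c for c in calls if c.is_binder]
true_positives = sum(c.probe_id in binder_ids for c in binders)
print(f"called {len(binders)} of {len(calls)} candidate probes as binders "
      f"({true_positives} of the 30 designated binders recovered)")
worst = max(binders, key=lambda c: c.empirical_p)
print(f"weakest binder: score {worst.mean_score:.3f}, "
      f"empirical p = {worst.empirical_p:.4f} vs the control distribution")

sequences = {p.id: p.sequence for p in probes}
pwm = build_pwm([sequences[c.probe_id] for c in binders])
print(f"\nPWM from {pwm.counts} bound 13-mers "
      f"(mean information {pwm.info_content.mean():.2f} bits/position):")
print(pwm_to_text(pwm))
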