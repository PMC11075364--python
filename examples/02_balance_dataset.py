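"""Class balancing: undersample to the minority class, then replicate.

First shows the balancing arithmetic on the real per-species class counts
(sugar beet 1046/5852/1164 and faba bean 2908/1793 seeds), then executes a
balance plan on phantom crops and verifies the per-class output counts.
"""

import seedxray as sx

for species, counts in [
    ("sugar beet", {"M": 1046, "N": 5852, "E": 1164}),
    ("faba bean", {"D": 2908, "UD": 1793}),
]:
    plan = sx.compute_balance_plan(counts, replication_factor=2)
    print(f"{species}: counts {counts}")
    print(f"  original shares %: {plan.shares_in_pct()}")
    print(f"  minority {plan.minority_count} x factor "
          f"{plan.replication_factor} -> {plan.target_per_class} per class "
          f"({plan.shares_out_pct()[next(iter(counts))]}% each)")
# Every class is first cut down to the minority count, then each retained
# seed gains one augmented copy, doubling the class to 2 x minority.

spec = sx.PhantomSpec(class_mix={"M": 12, "N": 4, "E": 8}, rng_seed=2)
crops, _ = sx.generate_phantom_crops(spec)
plan = sx.compute_balance_plan({"M": 12, "N": 4, "E": 8}, 2)
balanced = sx.execute_balance_plan(crops, plan, sx.AugmentationSpec(),
                                   rng_seed=3)
out_counts = {}
for c in balanced:
    out_counts[c.label] = out_counts.get(c.label, 0) + 1
print(f"phantom crops {{'M': 12, 'N': 4, 'E': 8}} balanced -> {out_counts}")
augmented = sum(any(h.startswith("geom(") for h in c.history)
                for c in balanced)
print(f"{augmented} of {len(balanced)} crops are augmented replicates "
      "(rotation 0-180, scale 0.5-4, shear 0-0.2, flips)")
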