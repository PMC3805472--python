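"""Generate and validate intertemporal-choice task schedules.

Builds one episodic and one monetary session, checks every design
invariant, and prints the factorial structure.
"""

import delaychoice as dc

catalog = dc.default_catalog()
episodic = dc.generate_episodic_schedule("exp2", catalog, seed=1)
monetary = dc.generate_monetary_schedule("exp2", seed=1)

print("episodic session:", len(episodic), "trials")
print(episodic.trials["subtype"].value_counts().to_string())
print("delays (days):", episodic.delays)
print("\nmonetary immediate payoffs: "
      f"{monetary.trials['imm_amount'].min():.1f}-"
      f"{monetary.trials['imm_amount'].max():.1f} EUR")

report = dc.validate_schedule(episodic)
print(f"\nvalidation: {sum(c['passed'] for c in report.checks)}/"
      f"{len(report.checks)} checks passed")
# 72 trials split 36 obs/sim (ecological: immediate pictured, delayed
# text-only) and 18+18 same-mode control trials; domain x condition x delay
# fully crossed, so every delay is seen equally often in every condition.
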