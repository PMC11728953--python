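"""Simulate a synthetic diabetes cohort with planted rapid-decline episodes.

Generates a patient roster, a long-format laboratory table and the ground
truth behind them, then prints the headline numbers.
"""

import rdpredict as rp

config = rp.GeneratorConfig(n_patients=200, seed=42)
patients, labs, truth = rp.generate_cohort(config)

print(f"patients:          {len(patients)}")
print(f"lab observations:  {len(labs)} rows over {labs['test_code'].nunique()} test codes")
print(f"planted episodes:  {int(truth['rd_planted'].sum())} "
      f"({truth['rd_planted'].mean():.0%} of patients)")
print(f"dialysis events:   {int(truth['dialysis_date'].notna().sum())}")
print()
print(labs.head(8).to_string(index=False))
print()
print("Each row is one dated measurement of one coded test; eGFR and Cre")
print("rows are mutually consistent through the JSN creatinine equation,")
print("and every planted patient's eGFR switches to the rapid slope at the")
print("episode_start recorded in the ground-truth table.")
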