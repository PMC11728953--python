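"""Classify every eGFR test date as RD or not_RD.

RD means the LOWESS-smoothed eGFR is below 60 mL/min/1.73 m^2 and at least
5 mL/min/1.73 m^2 below the smoothed value one year earlier.
"""

import rdpredict as rp

config = rp.GeneratorConfig(n_patients=200, seed=42)
_, labs, truth = rp.generate_cohort(config)

indications = rp.label_cohort(labs, rp.RdCriteria())

n = len(indications)
rd = int(indications["rd_flag"].sum())
print(f"indication points: {n}")
print(f"RD indications:    {rd} ({rd / n:.1%})")
print()
print("reason breakdown:")
print(indications["reason"].value_counts().to_string())
print()
flagged = indications.loc[indications["rd_flag"]].head(5)
print(flagged[["patient_id", "date", "egfr", "smoothed", "reference"]].to_string(index=False))
print()
print("Every flagged row has smoothed < 60 and reference - smoothed >= 5;")
print("dates with under a year of history report insufficient_lookback.")
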