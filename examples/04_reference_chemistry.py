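"""Reference chemistry: titration PV, UV extinction coefficients, FA classes,
and the univariate three-way ANOVA with Tukey post hoc.
"""

import oxispec as ox
from oxispec.chemistry import TitrationRecord, UvRecord

# Iodometric titration: 1 mL of 0.01 N thiosulfate for 2 g of oil.
pv = ox.peroxide_value(TitrationRecord(titrant_volume=1.0,
                                       titrant_normality=0.01,
                                       sample_mass=0.002))
print(f"peroxide value: {pv:.2f} meq O2/kg")

# 0.25 g oil in 50 mL isooctane (c = 0.5 g/100 mL), 1 cm cell, A232 = 2.13.
k232 = ox.extinction_coefficient(UvRecord(absorbance=2.13,
                                          concentration=0.5,
                                          path_length=1.0))
print(f"K232 = {k232:.2f}  (fresh hempseed oil; conjugated dienes)")

sums = ox.fa_class_sums(ox.load_fa_table())
print("fatty-acid classes (% of total FAME):",
      {k: round(v, 2) for k, v in sums.items()})
# Hempseed oil is ~75% polyunsaturated — which is why it oxidises so readily.

design, chem, _ = ox.simulate_dataset(seed=1)
res = ox.threeway_anova(chem["pv"].to_numpy(), design)
print("\nthree-way ANOVA of PV:")
print(res.table[["effect", "df", "F", "p_value"]].round(4).to_string(index=False))
sig = res.tukey["mat"].query("reject")[["level_a", "level_b", "p_value"]]
print(f"\nTukey (material): {len(sig)} of {len(res.tukey['mat'])} pairs differ at 0.05")
# All three storage factors (and their interactions) shift the peroxide value;
# Tukey pinpoints which packaging materials differ from each other.
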