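"""Hemocytometer yield arithmetic, a thermal-biology profile and ordinal
enzyme grades for the bundled reference isolates.
"""

from epfassay.data_model import TemperatureAssay
from epfassay.datasets import load_enzyme_reference
from epfassay.phenotyping import (
    cadaver_spore_yield,
    enzyme_grade,
    hemocytometer_concentration,
    temperature_profile,
)

# 20 spores per large Neubauer square at a 5-fold dilution
conc = hemocytometer_concentration(mean_count_per_square=20, dilution_factor=5)
print(f"hemocytometer concentration: {conc:.2g} spores/ml")
print(f"yield per cadaver in 1 ml suspension: {cadaver_spore_yield(conc):.2g} spores")

assays = [
    TemperatureAssay(isolate_id="DEMO", temperature=t, germination_pct=g,
                     radial_diameter_mm=d)
    for t, g, d in [(15, 17, 18), (20, 90.7, 42), (28, 95, 48), (35, 50, 20), (40, 0, 6)]
]
prof = temperature_profile(assays)
print(f"\noptimum germination temperature: {prof.optimum_temperature} degC")
print("net radial growth (mm, plug subtracted):",
      {t: round(v, 1) for t, v in prof.radial_net_growth_mm.items()})

print("\nenzyme clear-zone grades (0 = none ... 3 = large):")
for row in load_enzyme_reference().itertuples():
    grades = {e: enzyme_grade(getattr(row, e)) for e in ("lipase", "protease", "chitinase")}
    print(f"  {row.isolate_id}: {grades}")
print("larger protease zones track the most virulent isolates.")
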