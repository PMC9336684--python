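"""Margins of exposure and interspecies dose bridging.

Computes the monkey-over-child exposure ratios from the observed TK
metrics of the toxicity program, then bridges a monkey dose to the human
weekly dose with the same steady-state AUC and expresses it as a fold
over the 0.2 mg/kg/week clinical dose.
"""

from pegtk import fold_over_clinical, human_equivalent_dose, margin_of_exposure
from pegtk import gh_to_peg_mass, gh_to_peg_molar
from pegtk.config import HUMAN_TRUTH, MONKEY_TRUTH
from pegtk.reference import HUMAN_TK_METRICS, MONKEY_TK_METRICS

print("dose (mg/kg/wk)   MoE Cmax   MoE AUC")
for dose, metrics in MONKEY_TK_METRICS.items():
    moe = margin_of_exposure(metrics, HUMAN_TK_METRICS)
    print(f"{dose:14}   {moe.moeCmax:8}   {moe.moeAUC:7}")
# 3 mg/kg/week (the NOAEL) gives 136.1-fold on Cmax and 120.5-fold on
# AUC over the pediatric clinical exposure; 0.3 mg/kg/week (the NOEL)
# still gives 9.3- and 4.9-fold.

hed = human_equivalent_dose(0.55, MONKEY_TRUTH, HUMAN_TRUTH)
print(f"\nmonkey 0.55 mg/kg/week ~ child {hed:.2f} mg/kg/week "
      f"({fold_over_clinical(hed)}x the clinical dose)")

print(f"\n1 mg GH/kg carries {gh_to_peg_mass(1.0)} mg PEG/kg "
      f"({gh_to_peg_molar(1.0)} umol PEG/kg)")
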