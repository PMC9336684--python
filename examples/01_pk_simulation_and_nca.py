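"""Simulate serum PK of the weekly PEGylated rhGH and summarise exposure.

Builds the canonical monkey and pediatric parameter sets, simulates a
single 1 mg/kg subcutaneous dose and the weekly steady state, and prints
non-compartmental metrics (Cmax ng/ml, Tmax h, AUC ng*h/ml).
"""

import numpy as np

from pegtk import DoseRegimen, nca, simulate_monkey_pk, steady_state_metrics
from pegtk.config import HUMAN_TRUTH, MONKEY_TRUTH

grid = np.linspace(0.0, 168.0, 337)
profile = simulate_monkey_pk(MONKEY_TRUTH, DoseRegimen(dose=1.0), grid)
m = nca(profile)
print(f"monkey, single 1 mg/kg dose : Cmax {m.Cmax:8.0f}  Tmax {m.Tmax:5.1f}  AUClast {m.AUClast:9.0f}")

for dose in (0.3, 1.0, 3.0):
    ss = steady_state_metrics(MONKEY_TRUTH, DoseRegimen(dose=dose))
    print(f"monkey, {dose:3} mg/kg/week ss  : Cmax {ss.Cmax:8.0f}  AUCtau,ss {ss.AUCtauSS:9.0f}")

ss = steady_state_metrics(HUMAN_TRUTH, DoseRegimen(dose=0.2))
print(f"child,  0.2 mg/kg/week ss  : Cmax {ss.Cmax:8.0f}  AUCtau,ss {ss.AUCtauSS:9.0f}")

# The monkey model's saturable elimination makes exposure rise faster
# than dose (AUC/dose grows with dose); the pediatric values sit near the
# observed clinical exposure (Cmax ~340 ng/ml, AUC ~37,000 ng*h/ml).
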