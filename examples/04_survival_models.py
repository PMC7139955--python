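"""Multivariable Cox models for immune signatures, with the
covariate-inclusion rule and Kaplan-Meier curves.

Fits signature + age + stage + cytoreduction on a simulated cohort
whose true TCT:M2TAM hazard ratio is 0.6 per standardized unit.  The
cytoreduction block is kept only when its joint Wald p <= 0.10 (here
the generator gives it no effect, so it is dropped, mirroring a cohort
where surgical debulking carries no residual prognostic signal).
"""

import numpy as np
import pandas as pd

from immunosig import SimulationConfig, build_model, kaplan_meier, simulate_cohort

cohort = simulate_cohort(SimulationConfig(seed=1, samples_per_type=150))
clinical = cohort.clinical

for signature in ["CLIS", "TCT", "TCT:M2TAM"]:
    model = build_model(clinical, signature)
    t = model.final.terms[f"Z_{signature}"]
    dropped = " [cytoreduction dropped, p > 0.10]" if model.cytoreduction_dropped else ""
    print(
        f"{signature}: HR = {t.hr:.3f} (95% CI {t.ci_low:.3f}-{t.ci_high:.3f}), "
        f"p = {t.p:.2g}{dropped}"
    )

z = clinical["Z_TCT:M2TAM"]
groups = pd.Series(np.where(z > z.median(), "High", "Low"), index=clinical.index)
curves, two_group = kaplan_meier(clinical, groups)
t = two_group.terms["group[High]"]
print(
    f"median split on TCT:M2TAM: 5-year survival High = "
    f"{curves['High'].survival_at(5.0):.2f} vs Low = "
    f"{curves['Low'].survival_at(5.0):.2f}; two-group HR = {t.hr:.3f} "
    f"(95% CI {t.ci_low:.3f}-{t.ci_high:.3f})"
)
# The fitted signature HRs recover the generating values (0.6 for the
# ratio; the single signatures act through their shared activity), and
# the High group survives longer, as a protective signature implies.
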