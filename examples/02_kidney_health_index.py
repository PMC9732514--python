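"""Compute eGFR and the composite kidney health index for a few individuals.

The index is "optimal" only when every evaluable component passes: the
three CKD-EPI eGFR estimates >= 60 mL/min/1.73m2, BUN in the normal range,
uACR < 3 mg/mmol, and no kidney-disease ICD-10 code.
"""

from renalmr import (BiomarkerPanel, build_index, egfr_crea_cys,
                     egfr_creatinine, egfr_cystatin)

people = [
    ("healthy 45y male", BiomarkerPanel(age=45, sex="male",
                                        serum_creatinine=70.0,
                                        serum_cystatin_c=0.8, bun=5.0,
                                        uacr=1.0), []),
    ("albuminuric 45y male", BiomarkerPanel(age=45, sex="male",
                                            serum_creatinine=70.0,
                                            serum_cystatin_c=0.8, bun=5.0,
                                            uacr=12.0), []),
    ("CKD-coded 60y female", BiomarkerPanel(age=60, sex="female",
                                            serum_creatinine=95.0,
                                            serum_cystatin_c=1.1, bun=6.5,
                                            uacr=2.0), ["N18.3"]),
]

for label, panel, codes in people:
    idx = build_index(panel, codes)
    print(f"{label}:")
    print(f"  eGFR crea/cys/combined = {egfr_creatinine(panel):.1f} / "
          f"{egfr_cystatin(panel):.1f} / {egfr_crea_cys(panel):.1f} mL/min/1.73m2")
    failed = [k for k, ok in idx.component_flags.items() if not ok]
    print(f"  optimal kidney health: {idx.optimal}"
          + (f"  (failed: {', '.join(failed)})" if failed else ""))
# A single failing component (raised uACR, or a renal ICD-10 code) removes
# the optimal label even when every eGFR is well above threshold.
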