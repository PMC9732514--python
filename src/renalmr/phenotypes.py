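"""Renal phenotypes: CKD-EPI eGFR equations and the composite kidney health index.

The kidney health index is a binary phenotype: an individual is "optimal"
only if every evaluable component passes — eGFR from creatinine, cystatin C
and the combined equation all above threshold, blood urea nitrogen within a
normal range, urinary albumin-to-creatinine ratio below threshold, and no
kidney-disease ICD-10 diagnosis.  Thresholds are configurable; the defaults
are conventional clinical cut-offs (eGFR >= 60 mL/min/1.73m2, uACR < 3
mg/mmol, BUN 2.5-7.8 mmol/L, ICD-10 prefixes N00-N29) and should be read as
reconstructions of a study-specific definition rather than a standard.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BiomarkerPanel",
    "IndexThresholds",
    "KidneyHealthIndex",
    "egfr_creatinine",
    "egfr_cystatin",
    "egfr_crea_cys",
    "icd_kidney_flag",
    "build_index",
    "build_index_table",
    "DEFAULT_KIDNEY_ICD_PREFIXES",
]

UMOL_PER_MGDL = 88.4

# N00-N29: glomerular, tubulo-interstitial, renal failure and urolithiasis-free
# kidney chapters of ICD-10
DEFAULT_KIDNEY_ICD_PREFIXES = tuple(f"N{i:02d}" for i in range(0, 30))

_ICD_RE = re.compile(r"^[A-Za-z][0-9]{2}(\.[0-9A-Za-z]{0,4})?$")


@dataclass(frozen=True)
class BiomarkerPanel:
    """One individual's serum/urine biomarkers.

    Concentrations: creatinine in umol/L (use :meth:`from_mgdl` for mg/dL),
    cystatin C in mg/L, BUN in mmol/L, uACR in mg/mmol.  Missing values are
    ``None``.
    """

    age: float
    sex: str  # "female" | "male"
    serum_creatinine: float | None = None
    serum_cystatin_c: float | None = None
    bun: float | None = None
    uacr: float | None = None

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.age < 18:
            raise ValueError("adult equations only: age must be >= 18")
        for name in ("serum_creatinine", "serum_cystatin_c", "bun", "uacr"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be strictly positive when present")

    @classmethod
    def from_mgdl(cls, age, sex, serum_creatinine_mgdl=None, **kw) -> "BiomarkerPanel":
        scr = None if serum_creatinine_mgdl is None else serum_creatinine_mgdl * UMOL_PER_MGDL
        return cls(age=age, sex=sex, serum_creatinine=scr, **kw)

    @property
    def creatinine_mgdl(self) -> float | None:
        if self.serum_creatinine is None:
            return None
        return self.serum_creatinine / UMOL_PER_MGDL


def egfr_creatinine(panel: BiomarkerPanel) -> float:
    """CKD-EPI 2009 creatinine equation (no race term), mL/min/1.73m2.

    eGFR = 141 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.209 * 0.993^age
           * 1.018 [female], with k = 0.7 (F) / 0.9 (M) mg/dL and
           a = -0.329 (F) / -0.411 (M).
    """
    scr = panel.creatinine_mgdl
    if scr is None:
        raise ValueError("serum creatinine required")
    female = panel.sex == "female"
    kappa = 0.7 if female else 0.9
    alpha = -0.329 if female else -0.411
    r = scr / kappa
    egfr = 141.0 * min(r, 1.0) ** alpha * max(r, 1.0) ** -1.209 * 0.993 ** panel.age
    return egfr * 1.018 if female else egfr


def egfr_cystatin(panel: BiomarkerPanel) -> float:
    """CKD-EPI 2012 cystatin C equation, mL/min/1.73m2.

    eGFR = 133 * min(Scys/0.8, 1)^-0.499 * max(Scys/0.8, 1)^-1.328
           * 0.996^age * 0.932 [female].
    """
    cys = panel.serum_cystatin_c
    if cys is None:
        raise ValueError("serum cystatin C required")
    r = cys / 0.8
    egfr = 133.0 * min(r, 1.0) ** -0.499 * max(r, 1.0) ** -1.328 * 0.996 ** panel.age
    return egfr * 0.932 if panel.sex == "female" else egfr


def egfr_crea_cys(panel: BiomarkerPanel) -> float:
    """CKD-EPI 2012 combined creatinine-cystatin C equation, mL/min/1.73m2."""
    scr, cys = panel.creatinine_mgdl, panel.serum_cystatin_c
    if scr is None or cys is None:
        raise ValueError("both creatinine and cystatin C required")
    female = panel.sex == "female"
    kappa = 0.7 if female else 0.9
    alpha = -0.248 if female else -0.207
    rc, ry = scr / kappa, cys / 0.8
    egfr = (135.0
            * min(rc, 1.0) ** alpha * max(rc, 1.0) ** -0.601
            * min(ry, 1.0) ** -0.375 * max(ry, 1.0) ** -0.711
            * 0.995 ** panel.age)
    return egfr * 0.969 if female else egfr


def icd_kidney_flag(codes, code_patterns=DEFAULT_KIDNEY_ICD_PREFIXES) -> bool:
    """True iff any syntactically valid code starts with a kidney prefix.

    Matching is case-insensitive prefix matching on the code with the dot
    removed.  Malformed codes are skipped with a warning.
    """
    patterns = [p.upper().replace(".", "") for p in code_patterns]
    for code in codes:
        if not isinstance(code, str) or not _ICD_RE.match(code.strip()):
            warnings.warn(f"malformed ICD-10 code skipped: {code!r}", stacklevel=2)
            continue
        c = code.strip().upper().replace(".", "")
        if any(c.startswith(p) for p in patterns):
            return True
    return False


@dataclass(frozen=True)
class IndexThresholds:
    """Component cut-offs for the kidney health index (reconstructed defaults)."""

    egfr_min: float = 60.0            # mL/min/1.73m2, all three equations
    uacr_max: float = 3.0             # mg/mmol, strict <
    bun_range: tuple[float, float] = (2.5, 7.8)  # mmol/L, closed interval
    icd_prefixes: tuple[str, ...] = DEFAULT_KIDNEY_ICD_PREFIXES
    strict_missing: bool = False      # True: any missing component -> rejection


@dataclass
class KidneyHealthIndex:
    optimal: bool
    component_flags: dict
    missing_components: list = field(default_factory=list)


_COMPONENTS = ("egfr_crea_ok", "egfr_cys_ok", "egfr_creacys_ok",
               "bun_ok", "uacr_ok", "no_icd_kidney_disease")


def build_index(panel: BiomarkerPanel, codes=(),
                thresholds: IndexThresholds | None = None) -> KidneyHealthIndex:
    """Composite kidney health index for one individual.

    ``optimal`` is the conjunction of all evaluable component flags; missing
    components are recorded and excluded from the conjunction (or, in strict
    mode, cause rejection).
    """
    th = thresholds or IndexThresholds()
    flags: dict = {}
    missing: list = []

    def component(name, available, check):
        if available:
            flags[name] = bool(check())
        else:
            missing.append(name)

    has_scr = panel.serum_creatinine is not None
    has_cys = panel.serum_cystatin_c is not None
    component("egfr_crea_ok", has_scr, lambda: egfr_creatinine(panel) >= th.egfr_min)
    component("egfr_cys_ok", has_cys, lambda: egfr_cystatin(panel) >= th.egfr_min)
    component("egfr_creacys_ok", has_scr and has_cys,
              lambda: egfr_crea_cys(panel) >= th.egfr_min)
    component("bun_ok", panel.bun is not None,
              lambda: th.bun_range[0] <= panel.bun <= th.bun_range[1])
    component("uacr_ok", panel.uacr is not None, lambda: panel.uacr < th.uacr_max)
    component("no_icd_kidney_disease", codes is not None,
              lambda: not icd_kidney_flag(codes, th.icd_prefixes))

    if not flags:
        raise ValueError("no evaluable kidney-health component")
    if th.strict_missing and missing:
        raise ValueError(f"strict mode: missing components {missing}")
    return KidneyHealthIndex(optimal=all(flags.values()), component_flags=flags,
                             missing_components=missing)


def build_index_table(biomarkers: pd.DataFrame, icd_codes=None,
                      thresholds: IndexThresholds | None = None) -> pd.Series:
    """Vectorised convenience wrapper: 0/1 index per row of a biomarker table.

    Expects columns ``serum_creatinine`` (umol/L), ``serum_cystatin_c``,
    ``bun``, ``uacr``, ``age`` and ``sex`` (0=female/1=male or strings).
    """
    th = thresholds or IndexThresholds()
    out = np.zeros(len(biomarkers), dtype=int)
    codes_iter = icd_codes if icd_codes is not None else [()] * len(biomarkers)
    for i, ((_, row), codes) in enumerate(zip(biomarkers.iterrows(), codes_iter)):
        sex = row["sex"]
        if not isinstance(sex, str):
            sex = "male" if sex else "female"
        panel = BiomarkerPanel(
            age=float(row["age"]), sex=sex,
            serum_creatinine=row.get("serum_creatinine"),
            serum_cystatin_c=row.get("serum_cystatin_c"),
            bun=row.get("bun"), uacr=row.get("uacr"))
        out[i] = int(build_index(panel, codes, th).optimal)
    return pd.Series(out, index=biomarkers.index, name="kidney_health_index")
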