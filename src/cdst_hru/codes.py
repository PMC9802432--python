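"""Default code sets.

Real claims extracts identify services through long proprietary ICD/CPT code
lists; here every service category is an arbitrary, configurable set of code
strings.  The standard billing-code ranges that are stable across US payers —
emergency-department revenue centers 0450-0459 and 0981, laboratory revenue
centers 0300-0319, established-patient office-visit CPT codes 99211-99215 —
are used verbatim.  Disease, procedure and drug codes use a compact synthetic
vocabulary (``DX_``/``PX_``/``RX_`` prefixes) that the bundled claims
generator emits, so the default configuration works out of the box.
"""

from __future__ import annotations

ED_REVENUE_CODES = frozenset(f"{c:04d}" for c in range(450, 460)) | frozenset({"0981"})
LAB_REVENUE_CODES = frozenset(f"{c:04d}" for c in range(300, 320))
OFFICE_VISIT_CPT = frozenset(str(c) for c in range(99211, 99216))

CD_DIAGNOSIS = frozenset({"DX_CD"})
FISTULA_DIAGNOSIS = frozenset({"DX_FISTULA"})
STRICTURE_DIAGNOSIS = frozenset({"DX_STRICTURE"})
SURGERY_PROCEDURES = frozenset({"PX_BOWEL_SURG"})
ENDOSCOPY_SCAN_CPT = frozenset({"PX_ENDOSCOPY", "PX_SCAN"})

VEDOLIZUMAB = frozenset({"RX_VEDO"})
ANTI_TNF_AGENTS = frozenset({"RX_TNF_IFX", "RX_TNF_ADA", "RX_TNF_CZP"})
IMMUNOMODULATORS = frozenset({"RX_IMM"})
CORTICOSTEROIDS = frozenset({"RX_CS"})


def default_code_sets() -> dict[str, frozenset[str]]:
    """Named code lists keyed the way :class:`~cdst_hru.cohort.CohortConfig` expects."""
    return {
        "cd_diagnosis": CD_DIAGNOSIS,
        "fistula_diagnosis": FISTULA_DIAGNOSIS,
        "stricture_diagnosis": STRICTURE_DIAGNOSIS,
        "surgery_procedures": SURGERY_PROCEDURES,
        "anti_tnf_drugs": ANTI_TNF_AGENTS,
        "vedolizumab": VEDOLIZUMAB,
        "immunomodulators": IMMUNOMODULATORS,
        "corticosteroids": CORTICOSTEROIDS,
        "ed_revenue": ED_REVENUE_CODES,
        "office_visit_cpt": OFFICE_VISIT_CPT,
        "lab_revenue": LAB_REVENUE_CODES,
        "endoscopy_scan_cpt": ENDOSCOPY_SCAN_CPT,
    }
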