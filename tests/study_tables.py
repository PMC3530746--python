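"""Frozen published tables of the bundled monitoring study.

These are the study's printed results — campaign mean concentrations, dose
matrices, risk and hazard matrices — used as reference values by the tests.
All figures are 4-significant-figure (concentrations: 2-decimal) roundings
as printed, so comparisons carry the stated relative tolerances rather than
machine precision.
"""

PCB_ROW = "Polychlorinated biphenyls (sum)"
GROUPS = ("children_0_6", "children_7_17", "adults")
ANALYTE_ROWS = (PCB_ROW, "gamma-HCH", "DDE", "DDD", "DDT")

#: printed cross-site ("Average I-III") mean per analyte name, ng/dm^3 (2 dp)
CROSS_SITE_MEANS = {
    "PCB18": 139.88,
    "PCB20": 5.36,
    "PCB28": 125.37,
    "PCB44": 98.29,
    "PCB52": 59.87,
    "PCB101": 3.99,
    "PCB118": 2.43,
    "PCB105": 3.70,
    "PCB153": 2.96,
    "PCB138": 5.26,
    "PCB170": 4.73,
    "PCB180": 0.04,
    "PCB194": 0.08,
    "gamma-HCH": 55.72,
    "DDE": 3.68,
    "DDD": 5.99,
    "DDT": 8.12,
}

#: class totals as printed, ng/dm^3
PCB_TOTAL = 451.96
COP_TOTAL = 73.53

#: LADD matrix, mg/(kg*day): rows ANALYTE_ROWS, columns GROUPS
LADD = {
    PCB_ROW: (5.036e-07, 1.004e-06, 2.518e-06),
    "gamma-HCH": (6.209e-08, 1.237e-07, 3.105e-07),
    "DDE": (4.104e-09, 8.179e-09, 2.052e-08),
    "DDD": (6.678e-09, 1.331e-08, 3.339e-08),
    "DDT": (9.044e-09, 1.802e-08, 4.522e-08),
}

#: ADD matrix, mg/(kg*day)
ADD = {
    PCB_ROW: (5.875e-06, 6.386e-06, 5.875e-06),
    "gamma-HCH": (7.244e-07, 7.874e-07, 7.244e-07),
    "DDE": (4.788e-08, 5.205e-08, 4.788e-08),
    "DDD": (7.791e-08, 8.469e-08, 7.791e-08),
    "DDT": (1.055e-07, 1.147e-07, 1.055e-07),
}

#: ELCR matrix (one-hit, uniform slope factor 2.0) and per-group totals
ELCR = {
    PCB_ROW: (1.007e-06, 2.007e-06, 5.035e-06),
    "gamma-HCH": (1.242e-07, 2.474e-07, 6.209e-07),
    "DDE": (8.208e-09, 1.636e-08, 4.104e-08),
    "DDD": (1.336e-08, 2.661e-08, 6.678e-08),
    "DDT": (1.809e-08, 3.604e-08, 9.043e-08),
}
ELCR_TOT = (1.171e-06, 2.333e-06, 5.855e-06)

#: expected extra cancer cases per cell, per group, and overall
ECC = {
    PCB_ROW: (9.406e-04, 4.106e-03, 4.099e-02),
    "gamma-HCH": (1.160e-04, 5.063e-04, 5.054e-03),
    "DDE": (7.666e-06, 3.346e-05, 3.341e-04),
    "DDD": (1.247e-05, 5.445e-05, 5.436e-04),
    "DDT": (1.689e-05, 7.374e-05, 7.361e-04),
}
ECC_POP = (1.094e-03, 4.774e-03, 4.766e-02)
ECC_GEN = 5.34e-02

#: whole-population burden under the duration-matched convention for children
ECC_GEN_DURATION_MATCHED = 0.091

#: hazard quotient matrix and per-group hazard indices
HQ = {
    PCB_ROW: (2.938e-01, 3.193e-01, 2.938e-01),
    "gamma-HCH": (2.415e-03, 2.625e-03, 2.415e-03),
    "DDE": (1.596e-05, 1.735e-05, 1.596e-05),
    "DDD": (8.657e-06, 9.410e-06, 8.657e-06),
    "DDT": (2.110e-04, 2.294e-04, 2.110e-04),
}
HI = (2.964e-01, 3.222e-01, 2.964e-01)


def rel_err(actual: float, expected: float) -> float:
    return abs(actual - expected) / abs(expected)
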