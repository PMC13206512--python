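"""Unit constants and conversions for lipid concentrations and exposure.

Cumulative LDL-C exposure is book-kept in mg/dL-years ("mg-years"): the
time-integral of the LDL-C concentration expressed in mg/dL.  Concentrations
elsewhere in the package are in mmol/L, the SI-style clinical convention, so a
single conversion constant bridges the two scales.
"""

#: mg/dL of LDL cholesterol per mmol/L (molar mass of cholesterol, 386.7 g/mol).
MG_DL_PER_MMOL_L: float = 38.67


def mmol_to_mgdl(x: float) -> float:
    """Convert an LDL-C concentration from mmol/L to mg/dL."""
    return x * MG_DL_PER_MMOL_L


def mgdl_to_mmol(x: float) -> float:
    """Convert an LDL-C concentration from mg/dL to mmol/L."""
    return x / MG_DL_PER_MMOL_L


def mg_years_to_mmol_years(x: float) -> float:
    """Convert cumulative exposure from mg/dL-years to mmol/L-years."""
    return x / MG_DL_PER_MMOL_L
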