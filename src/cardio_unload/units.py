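"""Unit conventions and conversions.

The package works in a single fixed unit system:

* length: millimetre (mm)
* pressure / stress: kilopascal (kPa)
* volume: millilitre (mL), with 1 mL = 1000 mm^3

The empirical single-beat EDPVR (see :mod:`cardio_unload.klotz`) is defined
in mmHg internally; conversions are centralized here.
"""

MMHG_PER_KPA = 7.50062
MM3_PER_ML = 1000.0


def kpa_to_mmhg(p_kpa: float) -> float:
    return p_kpa * MMHG_PER_KPA


def mmhg_to_kpa(p_mmhg: float) -> float:
    return p_mmhg / MMHG_PER_KPA


def mm3_to_ml(v_mm3: float) -> float:
    return v_mm3 / MM3_PER_ML


def ml_to_mm3(v_ml: float) -> float:
    return v_ml * MM3_PER_ML
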