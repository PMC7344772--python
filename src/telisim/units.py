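"""Unit conventions and conversion helpers.

Internal computation is SI throughout (m, s, K, W, V, mol, mol/m^3).
The I/O boundary uses the units practitioners quote for this platform:
geometry in micrometres, enzyme amounts in femtomoles, substrate
concentrations in millimolar and voltages in microvolts.

Note that 1 mM of a dilute aqueous solute is exactly 1 mol/m^3, so the
concentration "conversion" is the identity; it is kept explicit so the
unit of every interface value is visible at the call site.
"""

UM = 1e-6  #: metres per micrometre
FMOL = 1e-15  #: moles per femtomole
AMOL = 1e-18  #: moles per attomole
UV = 1e-6  #: volts per microvolt
MM = 1.0  #: (mol/m^3) per millimolar — identity for dilute solutes


def fmol_to_mol(x: float) -> float:
    return x * FMOL


def mol_to_fmol(x: float) -> float:
    return x / FMOL


def mm_to_molm3(x: float) -> float:
    return x * MM


def uv_to_v(x: float) -> float:
    return x * UV


def v_to_uv(x: float) -> float:
    return x / UV
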