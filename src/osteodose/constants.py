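"""Physical constants and elemental data for electron transport.

Mean excitation energies follow the standard ICRU recommendations; radiation
lengths are computed from the usual Tsai-style fit when needed.
"""

from __future__ import annotations

ELECTRON_REST_MEV = 0.51099895  # electron rest energy, MeV
MEV_PER_J = 1.0 / 1.602176634e-13
J_PER_MEV = 1.602176634e-13
CLASSICAL_COEFF = 0.1535374  # 2*pi*Na*re^2*mc^2, MeV cm^2 / mol

#: element -> (Z, A [g/mol], I [eV])
ELEMENTS: dict[str, tuple[int, float, float]] = {
    "H": (1, 1.008, 19.2),
    "C": (6, 12.011, 78.0),
    "N": (7, 14.007, 82.0),
    "O": (8, 15.999, 95.0),
    "Na": (11, 22.990, 149.0),
    "Mg": (12, 24.305, 156.0),
    "P": (15, 30.974, 173.0),
    "S": (16, 32.06, 180.0),
    "Ca": (20, 40.078, 191.0),
    "Fe": (26, 55.845, 286.0),
}


def radiation_length(Z: int, A: float) -> float:
    """Approximate radiation length of an element, g/cm^2."""
    import math

    return 716.4 * A / (Z * (Z + 1) * math.log(287.0 / math.sqrt(Z)))
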