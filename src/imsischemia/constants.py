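"""Physical constants used throughout the package.

Monoisotopic atomic masses (Da) of the most abundant isotope of each
element, frozen here so that annotation results are reproducible across
environments.  Values follow IUPAC/CODATA tabulations at 8 decimal places.
"""

#: Monoisotopic atomic masses in Da.  ``C`` is exactly 12 by definition.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376200,
    "S": 31.97207117,
    "Na": 22.98976928,
    "K": 38.96370649,
    "Cl": 34.96885268,
    "F": 18.99840322,
    "Se": 79.91652176,
}

#: Mass of a proton in Da.  Deprotonation [M-H]- removes H+ while the
#: electron stays with the ion, so the m/z of the anion is M minus this.
PROTON_MASS: float = 1.00727646

#: Version tag for the constants table, recorded in run manifests.
CONSTANTS_VERSION = "2024.1"
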