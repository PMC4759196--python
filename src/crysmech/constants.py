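"""Physical constants and package-wide defaults.

Units follow single-molecule AFM convention throughout the package:
forces in pN, lengths in nm, energies in pN nm, rates in 1/s.
"""

#: Boltzmann constant in pN nm / K.
KB = 0.0138065

#: Thermal energy at room temperature (pN nm); the value used for all
#: worm-like-chain and Bell-model arithmetic unless a temperature is given.
KBT_ROOM = 4.11

#: Contour length contributed by one amino acid residue (nm/residue).
#: Used for every residue-count <-> length conversion in the ledger model.
RESIDUE_CONTOUR_NM = 0.4

#: Persistence length of an unfolded polypeptide (nm); held fixed in all
#: worm-like-chain fits so that contour-length increments are well defined.
DEFAULT_PERSISTENCE_NM = 0.4


def thermal_energy(temperature: float | None = None) -> float:
    """kBT in pN nm; room temperature when ``temperature`` is None."""
    if temperature is None:
        return KBT_ROOM
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    return KB * temperature
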