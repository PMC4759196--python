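"""Packaged construct presets.

The named polyprotein constructs of the gammaD-crystallin pulling study,
ready to simulate or to use as gating/classification references:

========================  ====================================================
preset name               construct
========================  ====================================================
``crys_i27_tetramer``     (HgD-crys-I27)4 — four crystallin monomers, four I27
``ntd_tetramer``          (I27-Ntd)4 — isolated N-terminal domains
``ctd_tetramer``          (I27-Ctd)4 — isolated C-terminal domains
``dimer``                 [I27-(HgD-crys)2-I27] — the swap-competent dimer
``dimer_long_linker``     dimer with 14 extra (GS)7 linker residues
``r14c_tetramer``         (HgD-crys(R14C)-I27)4 — juvenile-cataract variant
``r14c_dimer``            [I27-(HgD-crys(R14C))2-I27]
========================  ====================================================

Domain mechanics: contour-length increments are the measured values
(Ctd 29.9 nm, Ntd 29.3 nm; I27 28.4 nm, the field-standard value, since the
fingerprint fits are shown but not tabulated — treat it as an assumption).
Bell intrinsic rates are calibrated so the modal rupture force at the
reference 400 nm/s / 12 pN/nm protocol matches the measured mean forces
(Ctd 96.1, Ntd 136.2, I27 251.9 pN; R14C variant 83.7/112.6/197.9 pN).
The crystallin monomer is 173 residues: Ntd (82) + 7-residue hinge +
Ctd (84).  The dimer's engineered inter-monomer linker is 12 residues, which
places the predicted swapped-pathway dL3 at 30.5 nm; terminal cloning-site
linkers are 2 residues.  The Ctd carries a weak ~50 pN / ~8 nm unfolding
intermediate.
"""

from __future__ import annotations

from .constructs import ConstructTopology, DomainSpec, LinkerSpec, SwapMotif
from .errors import InputError
from .simulate import _cached_k0

#: (modal force pN at reference protocol, Bell dx nm, typical branch Lc nm)
CLASS_MECHANICS = {
    "Ctd": (96.1, 0.35, 60.0),
    "Ntd": (136.2, 0.35, 100.0),
    "I27": (251.9, 0.30, 170.0),
}

#: R14C variant targets (same dx; weaker folds).
R14C_MECHANICS = {
    "Ctd": (83.7, 0.35, 60.0),
    "Ntd": (112.6, 0.35, 100.0),
    "I27": (197.9, 0.30, 170.0),
}

CTD_INTERMEDIATE = (50.0, 8.0)

NTD_RESIDUES, HINGE_RESIDUES, CTD_RESIDUES = 82, 7, 84
I27_RESIDUES = 89
INTER_LINKER_RESIDUES = 12
TERMINAL_LINKER_RESIDUES = 2
LONG_LINKER_EXTRA = 14  # the (GS)7 insertion

DEFAULT_SWAP = SwapMotif(donor_domain="Ntd2", acceptor_domain="Ntd1",
                         motif_residue_span=(3, 18), loop_n_residues=16)


def _domain(name: str, cls: str, mech: dict) -> DomainSpec:
    target, dx, lc_ref = mech[cls]
    k0 = _cached_k0(target, dx, lc_ref)
    if cls == "Ntd":
        return DomainSpec(name, NTD_RESIDUES, 3.5, 29.3, k0, dx, "Ntd")
    if cls == "Ctd":
        return DomainSpec(name, CTD_RESIDUES, 3.7, 29.9, k0, dx, "Ctd",
                          intermediate=CTD_INTERMEDIATE)
    return DomainSpec(name, I27_RESIDUES, 4.4, 28.4, k0, dx, "I27")


def _hinge() -> LinkerSpec:
    return LinkerSpec(HINGE_RESIDUES, "hinge")


def _term() -> LinkerSpec:
    return LinkerSpec(TERMINAL_LINKER_RESIDUES, "terminal")


def _monomer(i: int, mech: dict) -> list:
    return [_domain(f"Ntd{i}", "Ntd", mech), _hinge(),
            _domain(f"Ctd{i}", "Ctd", mech)]


def _dimer(name: str, mech: dict, linker_residues: int) -> ConstructTopology:
    elements = ([_domain("I27a", "I27", mech), _term()]
                + _monomer(1, mech)
                + [LinkerSpec(linker_residues, "inter-monomer")]
                + _monomer(2, mech)
                + [_term(), _domain("I27b", "I27", mech)])
    return ConstructTopology(name=name, elements=tuple(elements),
                             swap=DEFAULT_SWAP)


def _crys_i27_tetramer(name: str, mech: dict) -> ConstructTopology:
    elements: list = []
    for i in range(1, 5):
        elements += _monomer(i, mech)
        elements.append(_term())
        elements.append(_domain(f"I27_{i}", "I27", mech))
        if i < 4:
            elements.append(_term())
    return ConstructTopology(name=name, elements=tuple(elements))


def _flanked_tetramer(name: str, cls: str, mech: dict) -> ConstructTopology:
    elements: list = []
    for i in range(1, 5):
        elements.append(_domain(f"I27_{i}", "I27", mech))
        elements.append(_term())
        elements.append(_domain(f"{cls}{i}", cls, mech))
        if i < 4:
            elements.append(_term())
    return ConstructTopology(name=name, elements=tuple(elements))


_BUILDERS = {
    "crys_i27_tetramer": lambda: _crys_i27_tetramer("crys_i27_tetramer",
                                                    CLASS_MECHANICS),
    "ntd_tetramer": lambda: _flanked_tetramer("ntd_tetramer", "Ntd",
                                              CLASS_MECHANICS),
    "ctd_tetramer": lambda: _flanked_tetramer("ctd_tetramer", "Ctd",
                                              CLASS_MECHANICS),
    "dimer": lambda: _dimer("dimer", CLASS_MECHANICS, INTER_LINKER_RESIDUES),
    "dimer_long_linker": lambda: _dimer(
        "dimer_long_linker", CLASS_MECHANICS,
        INTER_LINKER_RESIDUES + LONG_LINKER_EXTRA),
    "r14c_tetramer": lambda: _crys_i27_tetramer("r14c_tetramer",
                                                R14C_MECHANICS),
    "r14c_dimer": lambda: _dimer("r14c_dimer", R14C_MECHANICS,
                                 INTER_LINKER_RESIDUES),
}

PRESET_NAMES = tuple(sorted(_BUILDERS))

_cache: dict[str, ConstructTopology] = {}


def preset(name: str) -> ConstructTopology:
    """Return a packaged construct by name (see module docstring)."""
    if name not in _BUILDERS:
        raise InputError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    if name not in _cache:
        _cache[name] = _BUILDERS[name]()
    return _cache[name]
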