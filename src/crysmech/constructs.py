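"""Polyprotein topologies and contour-length bookkeeping.

A polyprotein construct is an ordered N-to-C chain of folded domains and
unstructured linkers.  Under ramped force each folded domain releases a fixed
contour-length increment (delta Lc) when it unfolds, so an entire pulling
trajectory can be summarised as an ordered ledger of length increments.  This
module predicts those ledgers for the two pathways seen with tandem
gammaD-crystallin dimers:

* the *regular* pathway, where every domain is loaded from the start and
  unfolds in ascending order of mechanical stability (Ctd < Ntd < I27); and
* the *swapped* pathway, where the beta1-beta2 hairpin of one N-terminal
  domain (Ntd2) is donated to its neighbour (Ntd1).  The intertwined dimer
  shields Ctd1 from force until the swapped remnant of Ntd2 unravels, which
  produces the four-step ledger  dL1 = dLc(Ctd2),
  dL2 = dLc(Ntd1) + a*loop,  dL3 = dLc(Ntd2 remnant) + a*(hinge + linker),
  dL4 = dLc(Ctd1),  followed by the I27 fingerprint steps.

All residue-count <-> length conversions use a single per-residue contour
length ``a`` (0.4 nm by default).  The same arithmetic run backwards infers
the size of the swapping loop from measured ledgers (`infer_swap_loop`) and
predicts the effect of lengthening the engineered inter-monomer linker
(`predict_linker_edit`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

from .constants import RESIDUE_CONTOUR_NM
from .errors import InconsistencyError, InputError, StateError, TopologyError

#: Mechanical-stability rank used to order regular-pathway ledger steps;
#: lower rank unfolds first under ramped force.
CLASS_RANK = {"Ctd": 0, "Ntd": 1, "other": 2, "I27": 3}

CRYSTALLIN_CLASSES = ("Ctd", "Ntd")


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainSpec:
    """One folded domain of a polyprotein.

    ``folded_extension`` is the end-to-end distance the *folded* domain
    contributes along the pulling axis; ``delta_Lc`` is the contour length it
    releases on unfolding.  ``unfold_k0`` / ``unfold_dx`` are the Bell-model
    intrinsic rate (1/s) and transition-state distance (nm).  ``intermediate``
    optionally describes a weak unfolding intermediate as a
    (force-scale pN, delta_Lc nm) pair, as observed for the crystallin Ctd
    (~50 pN, ~8 nm).
    """

    name: str
    n_residues: int
    folded_extension: float
    delta_Lc: float
    unfold_k0: float
    unfold_dx: float
    class_label: str = "other"
    intermediate: tuple[float, float] | None = None
    residue_nm: float = RESIDUE_CONTOUR_NM

    def __post_init__(self) -> None:
        if self.n_residues <= 0:
            raise InputError(f"{self.name}: n_residues must be > 0")
        if self.delta_Lc <= 0:
            raise InputError(f"{self.name}: delta_Lc must be > 0 nm")
        if not 0 <= self.folded_extension < self.residue_nm * self.n_residues:
            raise InputError(
                f"{self.name}: folded_extension must lie in [0, a*n_residues)")
        if self.delta_Lc > self.residue_nm * self.n_residues:
            raise InputError(
                f"{self.name}: delta_Lc exceeds the backbone contour a*n_residues")
        if self.unfold_k0 <= 0 or self.unfold_dx <= 0:
            raise InputError(f"{self.name}: Bell parameters must be > 0")
        if self.class_label not in CLASS_RANK:
            raise InputError(
                f"{self.name}: class_label must be one of {sorted(CLASS_RANK)}")
        if self.intermediate is not None:
            f_int, dlc_int = self.intermediate
            if f_int <= 0 or dlc_int <= 0 or dlc_int >= self.delta_Lc:
                raise InputError(
                    f"{self.name}: intermediate must have positive force scale "
                    "and 0 < delta_Lc < the domain delta_Lc")


@dataclass(frozen=True)
class LinkerSpec:
    """An unstructured linker: ``role`` is inter-monomer, hinge, or terminal."""

    n_residues: int
    role: str = "terminal"

    def __post_init__(self) -> None:
        if self.n_residues < 0:
            raise InputError("linker n_residues must be >= 0")
        if self.role not in ("inter-monomer", "hinge", "terminal"):
            raise InputError("linker role must be inter-monomer, hinge or terminal")


@dataclass(frozen=True)
class SwapMotif:
    """A donated structural element between two crystallin monomers.

    ``motif_residue_span`` is the 1-based inclusive residue range of the
    swapped element within the donor Ntd (default beta1-beta2, residues
    3-18).  ``loop_n_residues`` is the length of the swapping loop that
    tethers the motif to the donor core and is released together with the
    acceptor domain's unfolding.

    .. warning::
       A beta7-strand swap variant is constructible (set the span near the
       Ntd C terminus), but the beta1-beta2 assignment is strongly favoured
       by secondary-structure and B-factor evidence; treat beta7 variants as
       hypothetical.
    """

    donor_domain: str
    acceptor_domain: str
    motif_residue_span: tuple[int, int] = (3, 18)
    loop_n_residues: int = 16

    def __post_init__(self) -> None:
        lo, hi = self.motif_residue_span
        if hi < lo or lo < 1:
            raise InputError("motif_residue_span must be a 1-based inclusive range")
        if self.loop_n_residues < 0:
            raise InputError("loop_n_residues must be >= 0")

    @property
    def span_length(self) -> int:
        lo, hi = self.motif_residue_span
        return hi - lo + 1


@dataclass(frozen=True)
class ConstructTopology:
    """Ordered N-to-C chain of domains and linkers, with an optional swap."""

    name: str
    elements: tuple
    swap: SwapMotif | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))
        if not any(isinstance(e, DomainSpec) for e in self.elements):
            raise InputError(f"{self.name}: topology needs at least one domain")
        for e in self.elements:
            if not isinstance(e, (DomainSpec, LinkerSpec)):
                raise InputError("elements must be DomainSpec or LinkerSpec")

    # -- accessors ---------------------------------------------------------
    @property
    def domains(self) -> tuple[DomainSpec, ...]:
        return tuple(e for e in self.elements if isinstance(e, DomainSpec))

    @property
    def linkers(self) -> tuple[LinkerSpec, ...]:
        return tuple(e for e in self.elements if isinstance(e, LinkerSpec))

    @property
    def crystallin_domains(self) -> tuple[DomainSpec, ...]:
        return tuple(d for d in self.domains if d.class_label in CRYSTALLIN_CLASSES)

    @property
    def i27_count(self) -> int:
        return sum(1 for d in self.domains if d.class_label == "I27")

    def slack_nm(self, residue_nm: float = RESIDUE_CONTOUR_NM) -> float:
        """Contour length of all linkers plus the folded end-to-end lengths:
        the chain length already load-bearing before any unfolding event."""
        linker = residue_nm * sum(l.n_residues for l in self.linkers)
        folded = sum(d.folded_extension for d in self.domains)
        return linker + folded

    def monomers(self) -> list[list[DomainSpec]]:
        """Group crystallin domains into monomers (consecutive Ntd/Ctd pairs
        in chain order; a lone crystallin domain forms its own monomer)."""
        groups: list[list[DomainSpec]] = []
        current: list[DomainSpec] = []
        for d in self.domains:
            if d.class_label not in CRYSTALLIN_CLASSES:
                if current:
                    groups.append(current)
                    current = []
                continue
            current.append(d)
            if len(current) == 2:
                groups.append(current)
                current = []
        if current:
            groups.append(current)
        return groups


@dataclass(frozen=True)
class ContourLengthLedger:
    """Ordered predicted (or measured) contour-length increments.

    ``steps`` is an ordered tuple of (step_label, delta_L nm, contributing
    element names).  ``initial_slack_nm`` is the chain length that extends
    before the first rupture; steps + slack equals the construct's fully
    unfolded contour length, which is pathway-independent.
    """

    pathway: str
    steps: tuple[tuple[str, float, tuple[str, ...]], ...]
    initial_slack_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.pathway not in ("regular", "swapped"):
            raise InputError("pathway must be 'regular' or 'swapped'")
        for label, delta, _ in self.steps:
            if delta <= 0:
                raise InputError(f"ledger step {label}: delta_L must be > 0 nm")

    @property
    def deltas(self) -> tuple[float, ...]:
        return tuple(s[1] for s in self.steps)

    @property
    def total_nm(self) -> float:
        """Fully unfolded contour length: slack plus all released increments."""
        return self.initial_slack_nm + sum(self.deltas)

    def crystallin_steps(self) -> tuple[tuple[str, float, tuple[str, ...]], ...]:
        return tuple(s for s in self.steps if not s[0].startswith("I27"))


# ---------------------------------------------------------------------------
# Residue/length arithmetic
# ---------------------------------------------------------------------------

def contour_length_of_span(n_residues: int,
                           residue_nm: float = RESIDUE_CONTOUR_NM) -> float:
    """Contour length (nm) of a span of ``n_residues`` amino acids."""
    if n_residues < 0:
        raise InputError("n_residues must be >= 0")
    return residue_nm * n_residues


def residues_from_extension(delta_L: float,
                            residue_nm: float = RESIDUE_CONTOUR_NM,
                            rounding: str = "floor") -> int:
    """Number of residues accounting for an extension of ``delta_L`` nm.

    Default rounding is *floor* (a partial residue does not count), applied
    with a 1e-9 relative guard so exact multiples of the per-residue length
    are not lost to floating-point representation.  ``rounding="nearest"``
    is available as a documented alternative.
    """
    if delta_L < 0:
        raise InputError("delta_L must be >= 0 nm")
    ratio = delta_L / residue_nm
    if rounding == "floor":
        return int(math.floor(ratio + 1e-9))
    if rounding == "nearest":
        return int(round(ratio))
    raise InputError("rounding must be 'floor' or 'nearest'")


# ---------------------------------------------------------------------------
# Ledger prediction
# ---------------------------------------------------------------------------

def predict_regular_ledger(topology: ConstructTopology,
                           residue_nm: float = RESIDUE_CONTOUR_NM
                           ) -> ContourLengthLedger:
    """Ledger for the regular pathway: one step per folded domain.

    All hinge/linker slack extends before the first rupture, then domains
    unfold in ascending mechanical stability (Ctd before Ntd before I27);
    equal-stability domains keep chain order.
    """
    domains = topology.domains
    if not domains:
        raise InputError("topology has no domains")
    order = sorted(range(len(domains)),
                   key=lambda i: (CLASS_RANK[domains[i].class_label], i))
    steps = []
    counters: dict[str, int] = {}
    for i in order:
        d = domains[i]
        k = counters.get(d.class_label, 0) + 1
        counters[d.class_label] = k
        steps.append((f"{d.class_label}{k}", d.delta_Lc, (d.name,)))
    return ContourLengthLedger(pathway="regular", steps=tuple(steps),
                               initial_slack_nm=topology.slack_nm(residue_nm))


def _swapped_parts(topology: ConstructTopology):
    """Identify (Ntd1, Ctd1, Ntd2, Ctd2, hidden hinge+linker residues) for a
    two-monomer swapped dimer; element order is N->C chain order."""
    if topology.swap is None:
        raise StateError(f"{topology.name}: topology carries no swap motif")
    monomers = topology.monomers()
    if len(monomers) != 2 or any(len(m) != 2 for m in monomers):
        raise TopologyError(
            f"{topology.name}: swapped-ledger prediction requires exactly two "
            "crystallin monomers (Ntd+Ctd each)")
    (m1, m2) = monomers

    def split(mono):
        ntd = next((d for d in mono if d.class_label == "Ntd"), None)
        ctd = next((d for d in mono if d.class_label == "Ctd"), None)
        if ntd is None or ctd is None:
            raise TopologyError("each monomer must contain one Ntd and one Ctd")
        return ntd, ctd

    ntd1, ctd1 = split(m1)
    ntd2, ctd2 = split(m2)
    # Linkers sequestered inside the swapped complex until dL3: the hinge of
    # monomer 1 (its Ctd is the shielded domain) and the inter-monomer linker.
    hinges = [l for l in topology.linkers if l.role == "hinge"]
    inter = [l for l in topology.linkers if l.role == "inter-monomer"]
    if not hinges or not inter:
        raise TopologyError(
            f"{topology.name}: swapped prediction needs a hinge and an "
            "inter-monomer linker")
    hidden_res = hinges[0].n_residues + inter[0].n_residues
    return ntd1, ctd1, ntd2, ctd2, hidden_res


def predict_swapped_ledger(topology: ConstructTopology,
                           ntd2_part_delta_Lc: float | None = None,
                           residue_nm: float = RESIDUE_CONTOUR_NM
                           ) -> ContourLengthLedger:
    """Four-step ledger of the domain-swapped pathway, then fingerprints.

    Steps dL1..dL4 follow the shielded-topology sequence (Ctd2, Ntd1 with the
    swapping loop, the swapped Ntd2 remnant with the hidden hinge and
    inter-monomer linker, Ctd1); the I27 fingerprint steps are appended so
    the ledger accounts for the construct's full unfoldable length.

    ``ntd2_part_delta_Lc`` overrides the contour length of the Ntd2 remnant;
    by default it is dLc(Ntd2) - a*loop, the decomposition under which the
    swapped and regular pathways release exactly the same total length.
    """
    ntd1, ctd1, ntd2, ctd2, hidden_res = _swapped_parts(topology)
    swap = topology.swap
    loop_nm = contour_length_of_span(swap.loop_n_residues, residue_nm)
    if ntd2_part_delta_Lc is None:
        ntd2_part_delta_Lc = ntd2.delta_Lc - loop_nm
    if ntd2_part_delta_Lc <= 0:
        raise InputError("Ntd2 remnant delta_Lc must be > 0 nm")
    hidden_nm = contour_length_of_span(hidden_res, residue_nm)
    steps = [
        ("dL1", ctd2.delta_Lc, (ctd2.name,)),
        ("dL2", ntd1.delta_Lc + loop_nm, (ntd1.name, "swap-loop")),
        ("dL3", ntd2_part_delta_Lc + hidden_nm,
         (ntd2.name, "hinge", "inter-monomer-linker")),
        ("dL4", ctd1.delta_Lc, (ctd1.name,)),
    ]
    n_i27 = 0
    for d in topology.domains:
        if d.class_label == "I27":
            n_i27 += 1
            steps.append((f"I27-{n_i27}", d.delta_Lc, (d.name,)))
    slack = topology.slack_nm(residue_nm) - hidden_nm
    # Account for any override of the remnant length so the ledger still sums
    # to the construct's fully unfolded contour length.
    slack += (ntd2.delta_Lc - loop_nm) - ntd2_part_delta_Lc
    return ContourLengthLedger(pathway="swapped", steps=tuple(steps),
                               initial_slack_nm=slack)


def predict_linker_edit(ledger: ContourLengthLedger, delta_residues: int,
                        residue_nm: float = RESIDUE_CONTOUR_NM
                        ) -> ContourLengthLedger:
    """Ledger after adding ``delta_residues`` to the inter-monomer linker.

    Only the dL3 step changes, by exactly a*delta_residues — the signature
    the long-linker control construct is designed to test.
    """
    if ledger.pathway != "swapped":
        raise InputError("linker edits apply to swapped-pathway ledgers")
    shift = residue_nm * delta_residues
    new_steps = []
    found = False
    for label, delta, contrib in ledger.steps:
        if label == "dL3":
            found = True
            new_delta = delta + shift
            if new_delta <= 0:
                raise InputError(
                    f"linker edit of {delta_residues} residues drives dL3 to "
                    f"{new_delta:.2f} nm (must stay > 0)")
            new_steps.append((label, new_delta, contrib))
        else:
            new_steps.append((label, delta, contrib))
    if not found:
        raise InputError("ledger has no dL3 step")
    return replace(ledger, steps=tuple(new_steps))


def infer_swap_loop(combined_L23: float, L3: float, ntd_delta_Lc: float,
                    residue_nm: float = RESIDUE_CONTOUR_NM,
                    rounding: str = "floor") -> tuple[float, int]:
    """Swapping-loop extension and residue count from measured ledger steps.

    Given the combined increment (dL2 + dL3), the resolved dL3, and the
    contour-length increment of an isolated Ntd, the loop extension is

        loop = (dL2 + dL3) - dL3 - dLc(Ntd) = dL2 - dLc(Ntd),

    i.e. whatever part of the Ntd1 unfolding step is not explained by the
    Ntd backbone must be the swapping loop released with it.

    Returns ``(loop_extension nm, loop_residues)``.
    """
    if L3 < 0 or combined_L23 <= L3:
        raise InputError("need combined_L23 > L3 >= 0")
    if ntd_delta_Lc <= 0:
        raise InputError("ntd_delta_Lc must be > 0 nm")
    loop = (combined_L23 - L3) - ntd_delta_Lc
    if loop < -1e-9:
        raise InconsistencyError(
            f"measured ledger gives a negative swapping-loop length "
            f"({loop:.3f} nm): incompatible with an Ntd-swap model")
    loop = max(loop, 0.0)
    return loop, residues_from_extension(loop, residue_nm, rounding)


# ---------------------------------------------------------------------------
# Serialisation (JSON topology configs)
# ---------------------------------------------------------------------------

def topology_to_dict(topology: ConstructTopology) -> dict:
    """JSON-ready dict; schema: {name, elements: [{kind: domain|linker, ...}],
    swap: {...} | null}."""
    elements = []
    for e in topology.elements:
        if isinstance(e, DomainSpec):
            elements.append({
                "kind": "domain", "name": e.name, "n_residues": e.n_residues,
                "folded_extension": e.folded_extension, "delta_Lc": e.delta_Lc,
                "unfold_k0": e.unfold_k0, "unfold_dx": e.unfold_dx,
                "class_label": e.class_label,
                "intermediate": list(e.intermediate) if e.intermediate else None,
            })
        else:
            elements.append({"kind": "linker", "n_residues": e.n_residues,
                             "role": e.role})
    swap = None
    if topology.swap is not None:
        s = topology.swap
        swap = {"donor_domain": s.donor_domain,
                "acceptor_domain": s.acceptor_domain,
                "motif_residue_span": list(s.motif_residue_span),
                "loop_n_residues": s.loop_n_residues}
    return {"name": topology.name, "elements": elements, "swap": swap}


def topology_from_dict(data: dict) -> ConstructTopology:
    elements = []
    for e in data["elements"]:
        kind = e.get("kind")
        if kind == "domain":
            inter = e.get("intermediate")
            elements.append(DomainSpec(
                name=e["name"], n_residues=e["n_residues"],
                folded_extension=e["folded_extension"], delta_Lc=e["delta_Lc"],
                unfold_k0=e["unfold_k0"], unfold_dx=e["unfold_dx"],
                class_label=e.get("class_label", "other"),
                intermediate=tuple(inter) if inter else None))
        elif kind == "linker":
            elements.append(LinkerSpec(n_residues=e["n_residues"],
                                       role=e.get("role", "terminal")))
        else:
            raise InputError(f"unknown element kind {kind!r}")
    swap = None
    if data.get("swap"):
        s = data["swap"]
        swap = SwapMotif(donor_domain=s["donor_domain"],
                         acceptor_domain=s["acceptor_domain"],
                         motif_residue_span=tuple(s["motif_residue_span"]),
                         loop_n_residues=s["loop_n_residues"])
    return ConstructTopology(name=data["name"], elements=tuple(elements), swap=swap)


def save_topology(topology: ConstructTopology, path) -> None:
    Path(path).write_text(json.dumps(topology_to_dict(topology), indent=2))


def load_topology(path) -> ConstructTopology:
    return topology_from_dict(json.loads(Path(path).read_text()))
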