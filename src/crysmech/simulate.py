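"""Monte-Carlo constant-velocity pulling of polyprotein constructs.

The simulator reproduces the geometry and kinetics of a constant-velocity
AFM experiment: the stage retracts at ``velocity`` nm/s, the tethered chain
(worm-like chain, persistence length 0.4 nm) balances against a Hookean
cantilever, and every force-loaded folded unit ruptures stochastically with
the Bell rate k(F) = k0 * exp(F dx / kBT).  Each rupture adds the unit's
contour-length increment to the chain, producing the characteristic sawtooth
force-extension pattern.  Traces carry a ground-truth event log so analysis
code can be benchmarked against what was actually injected.

Two pathway modes are sampled per trace:

* *regular* — every domain is load-bearing from the start and the unfolding
  order emerges from the stability hierarchy alone;
* *swapped* — the domain-swapped dimer conformation, in which the crystallin
  units unfold in the fixed shielded order Ctd2 -> Ntd1(+loop) ->
  Ntd2 remnant -> Ctd1, each with its own Bell parameters (the remnant is
  mechanically weak because the swap changes its pulling axis).

Bell parameters are calibrated against target modal rupture forces at the
reference condition (400 nm/s, 12 pN/nm cantilever) with
:func:`calibrate_bell`; pulling the same construct faster then shifts rupture
forces up with log(velocity), as in experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .constants import DEFAULT_PERSISTENCE_NM, thermal_energy
from .constructs import (ConstructTopology, ContourLengthLedger,
                         predict_regular_ledger, predict_swapped_ledger)
from .errors import CalibrationError, ConfigError, InputError
from .wlc import WlcParams, _ms_stiffness, solve_force_balance_array, wlc_extension

#: Reference pulling condition all preset Bell parameters are calibrated at.
REFERENCE_VELOCITY = 400.0      # nm/s
REFERENCE_SPRING = 12.0         # pN/nm

#: Per-state mechanics of the swapped pathway: target modal rupture force
#: (pN) at the reference condition, Bell dx (nm), and a typical contour
#: length (nm) of the branch on which the state ruptures.  The weak Ntd2
#: remnant reflects the changed pulling direction of the swapped fold.
DEFAULT_SWAPPED_TARGETS: dict[str, tuple[float, float, float]] = {
    "Ctd2": (82.2, 0.35, 50.0),
    "Ntd1_swap": (118.4, 0.35, 85.0),
    "Ntd2_part": (35.0, 0.40, 120.0),
    "Ctd1": (95.3, 0.35, 155.0),
}


@dataclass(frozen=True)
class PullConfig:
    """Constant-velocity pulling protocol.

    Defaults are the standard experimental condition: 400 nm/s retraction,
    ~12 pN/nm cantilever, 10 pN Gaussian force noise, 0.1 ms sampling
    (0.04 nm stage steps).  ``swap_probability`` is the per-trace chance of
    the domain-swapped conformation; ``intermediate_probability`` the
    per-domain chance that a Ctd unfolds through its weak ~50 pN / ~8 nm
    intermediate.  ``tether_k0``/``tether_dx`` optionally give the tether a
    Bell-type detachment channel so traces can end prematurely.
    """

    velocity: float = 400.0
    spring_constant: float = 12.0
    time_step: float = 1e-4
    force_noise_sd: float = 10.0
    temperature: float | None = None
    seed: int = 0
    swap_probability: float = 0.0
    intermediate_probability: float = 0.5
    detach_force: float = 400.0
    persistence_nm: float = DEFAULT_PERSISTENCE_NM
    tether_k0: float = 0.0
    tether_dx: float = 0.3

    def __post_init__(self) -> None:
        if self.velocity <= 0 or self.spring_constant <= 0 or self.time_step <= 0:
            raise InputError("velocity, spring_constant and time_step must be > 0")
        if not 0.0 <= self.swap_probability <= 1.0:
            raise InputError("swap_probability must lie in [0, 1]")
        if not 0.0 <= self.intermediate_probability <= 1.0:
            raise InputError("intermediate_probability must lie in [0, 1]")
        if self.force_noise_sd < 0 or self.tether_k0 < 0:
            raise InputError("force_noise_sd and tether_k0 must be >= 0")
        if self.detach_force <= 0:
            raise InputError("detach_force must be > 0 pN")

    @property
    def kbt(self) -> float:
        return thermal_energy(self.temperature)

    def to_metadata(self) -> dict:
        return {
            "velocity_nm_s": self.velocity,
            "spring_constant_pN_nm": self.spring_constant,
            "time_step_s": self.time_step,
            "force_noise_sd_pN": self.force_noise_sd,
            "seed": self.seed,
            "swap_probability": self.swap_probability,
            "persistence_nm": self.persistence_nm,
        }


@dataclass(frozen=True)
class Stage:
    """One sequential unfolding step of a folded unit."""
    class_label: str
    delta_L: float
    k0: float
    dx: float


@dataclass(frozen=True)
class FoldedUnit:
    """A folded unit and its (possibly multi-stage) unfolding sequence.

    ``sequential_rank`` orders units that shield one another (the swapped
    crystallin queue); ``None`` means the unit is load-bearing from the
    start.
    """
    label: str
    stages: tuple[Stage, ...]
    sequential_rank: int | None = None


@dataclass(frozen=True)
class PathwayState:
    """Sampled pathway: the ordered unit queue and the initial slack."""
    pathway: str
    units: tuple[FoldedUnit, ...]
    initial_Lc_nm: float
    ledger: ContourLengthLedger | None = None


@dataclass(frozen=True)
class TruthEvent:
    """Ground-truth rupture record written by the simulator."""
    index: int
    time_s: float
    unit_label: str
    class_label: str
    force_pN: float
    delta_Lc_nm: float
    pathway: str


@dataclass
class ForceExtensionTrace:
    """A simulated (or loaded) constant-velocity recording.

    ``extension`` is the tip-sample separation, i.e. stage position minus
    cantilever deflection.  ``truth`` is present for synthetic data only.
    """
    time: np.ndarray
    stage_position: np.ndarray
    extension: np.ndarray
    force: np.ndarray
    metadata: dict = field(default_factory=dict)
    truth: list[TruthEvent] | None = None
    trace_id: str = "trace"

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.stage_position) == len(self.extension)
                == len(self.force) == n):
            raise InputError("trace series must have equal length")
        if n > 1 and not np.all(np.diff(self.stage_position) > 0):
            raise InputError("stage_position must be strictly increasing")

    @property
    def complete(self) -> bool:
        """True if the tether survived until every folded unit had unfolded."""
        return bool(self.metadata.get("complete", True))


# ---------------------------------------------------------------------------
# Bell kinetics and calibration
# ---------------------------------------------------------------------------

def bell_rate(force: float, k0: float, dx: float,
              temperature: float | None = None):
    """Bell unfolding rate k(F) = k0 exp(F dx / kBT), in 1/s."""
    if k0 <= 0 or dx <= 0:
        raise InputError("k0 and dx must be > 0")
    return k0 * np.exp(np.asarray(force, dtype=float) * dx / thermal_energy(temperature))


def loading_rate_at(force: float, config: PullConfig, contour_length: float) -> float:
    """Geometric loading rate dF/dt (pN/s) on a branch of given contour
    length: the cantilever and chain stiffnesses act in series."""
    params = WlcParams(config.persistence_nm, contour_length,
                       config.temperature)
    x = wlc_extension(force, params)
    k_wlc = float(_ms_stiffness(x, contour_length, config.persistence_nm,
                                config.kbt))
    k_eff = 1.0 / (1.0 / config.spring_constant + 1.0 / k_wlc)
    return config.velocity * k_eff


def sample_rupture_forces(k0: float, dx: float, config: PullConfig,
                          contour_length: float, n: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` rupture forces of a single Bell unit on a deterministic
    constant-velocity ramp at fixed contour length (no refolding)."""
    if n <= 0:
        raise InputError("n must be > 0")
    kbt = config.kbt
    dz = config.velocity * config.time_step
    z0 = 0.0
    forces = np.empty(0)
    hazard_cum = np.array([0.0])
    f_grid = np.array([0.0])
    # grow the ramp until essentially every draw ruptures inside it
    while hazard_cum[-1] < 40.0 and f_grid[-1] < 4.0 * config.detach_force:
        z = z0 + dz * (1.0 + np.arange(20000))
        _, f = solve_force_balance_array(z, contour_length, config.persistence_nm,
                                         kbt, config.spring_constant)
        h = k0 * np.exp(np.clip(f * dx / kbt, None, 700.0)) * config.time_step
        hazard_cum = np.concatenate([hazard_cum,
                                     hazard_cum[-1] + np.cumsum(h)])
        f_grid = np.concatenate([f_grid, f])
        z0 = z[-1]
    draws = rng.exponential(size=n)
    forces = np.interp(draws, hazard_cum, f_grid)
    return forces


def modal_force(forces: np.ndarray, grid_points: int = 512) -> float:
    """Most probable rupture force, from a Gaussian KDE of the sample."""
    forces = np.asarray(forces, dtype=float)
    if forces.size < 10:
        raise InputError("need >= 10 rupture forces for a modal estimate")
    kde = gaussian_kde(forces)
    grid = np.linspace(forces.min(), forces.max(), grid_points)
    return float(grid[np.argmax(kde(grid))])


def calibrate_bell(target_modal_force: float, config: PullConfig, dx: float,
                   contour_length: float = 60.0, refine: bool = False,
                   n_samples: int = 4000, rng: np.random.Generator | None = None,
                   tolerance: float = 0.02, max_iter: int = 5) -> float:
    """Intrinsic rate k0 whose modal rupture force matches the target.

    Uses the constant-loading-rate closed form
    ``F* = (kBT/dx) ln(r dx / (k0 kBT))`` with the geometric loading rate of
    the pulling protocol evaluated at the target force, i.e.
    ``k0 = (r dx / kBT) exp(-F* dx / kBT)``.  With ``refine=True`` the
    estimate is polished by simulated rupture sampling until the realised
    mode sits within ``tolerance`` (fractional) of the target.
    """
    if target_modal_force <= 0:
        raise InputError("target_modal_force must be > 0 pN")
    if dx <= 0:
        raise InputError("dx must be > 0 nm")
    kbt = config.kbt
    r = loading_rate_at(target_modal_force, config, contour_length)
    k0 = (r * dx / kbt) * math.exp(-target_modal_force * dx / kbt)
    if not (1e-30 < k0 < 1e12):
        raise CalibrationError(
            f"no physical k0 for target {target_modal_force} pN at dx={dx} nm "
            f"(closed form gives {k0:.3g} 1/s)")
    if refine:
        rng = np.random.default_rng(0) if rng is None else rng
        for _ in range(max_iter):
            f = sample_rupture_forces(k0, dx, config, contour_length,
                                      n_samples, rng)
            mode = modal_force(f)
            if abs(mode - target_modal_force) <= tolerance * target_modal_force:
                break
            k0 *= math.exp((mode - target_modal_force) * dx / kbt)
        if not (1e-30 < k0 < 1e12):
            raise CalibrationError("refinement left k0 outside physical bounds")
    return k0


_REFERENCE_CONFIG = PullConfig(velocity=REFERENCE_VELOCITY,
                               spring_constant=REFERENCE_SPRING)
_calibration_cache: dict[tuple, float] = {}


def _cached_k0(target: float, dx: float, lc_ref: float) -> float:
    key = (round(target, 6), round(dx, 6), round(lc_ref, 3))
    if key not in _calibration_cache:
        _calibration_cache[key] = calibrate_bell(target, _REFERENCE_CONFIG, dx,
                                                 contour_length=lc_ref)
    return _calibration_cache[key]


# ---------------------------------------------------------------------------
# Pathway sampling
# ---------------------------------------------------------------------------

def _domain_stages(domain, rng: np.random.Generator, config: PullConfig,
                   delta_L: float | None = None, k0: float | None = None,
                   dx: float | None = None) -> tuple[Stage, ...]:
    """Unfolding stages for one domain; splits off the weak intermediate
    sub-step (Bernoulli per trace) when the domain defines one."""
    delta = domain.delta_Lc if delta_L is None else delta_L
    k0 = domain.unfold_k0 if k0 is None else k0
    dx = domain.unfold_dx if dx is None else dx
    main = Stage(domain.class_label, delta, k0, dx)
    if (domain.intermediate is not None
            and rng.random() < config.intermediate_probability):
        f_int, dlc_int = domain.intermediate
        if delta > dlc_int:
            k0_int = _cached_k0(f_int, domain.unfold_dx, 80.0)
            return (Stage(domain.class_label, delta - dlc_int, k0, dx),
                    Stage("intermediate", dlc_int, k0_int, domain.unfold_dx))
    return (main,)


def sample_pathway(topology: ConstructTopology, config: PullConfig,
                   rng: np.random.Generator, pathway: str | None = None,
                   swapped_bell: dict[str, tuple[float, float]] | None = None
                   ) -> PathwayState:
    """Draw the pathway of one trace and build its folded-unit queue.

    A Bernoulli(``swap_probability``) draw selects the swapped conformation
    (requires a swap motif on the topology).  ``pathway`` forces the outcome;
    ``swapped_bell`` overrides the per-state (k0, dx) of the swapped queue.
    """
    if config.swap_probability > 0 and topology.swap is None and pathway != "regular":
        raise ConfigError(
            f"{topology.name}: swap_probability > 0 but the topology carries "
            "no SwapMotif")
    if pathway is None:
        swapped = rng.random() < config.swap_probability
    elif pathway in ("regular", "swapped"):
        swapped = pathway == "swapped"
    else:
        raise InputError("pathway must be 'regular' or 'swapped'")

    if not swapped:
        ledger = predict_regular_ledger(topology)
        units = tuple(
            FoldedUnit(d.name, _domain_stages(d, rng, config))
            for d in topology.domains)
        return PathwayState("regular", units, ledger.initial_slack_nm, ledger)

    ledger = predict_swapped_ledger(topology)
    ntd1, ctd1, ntd2, ctd2, _ = _swapped_domains(topology)
    deltas = dict(zip(("dL1", "dL2", "dL3", "dL4"),
                      [s[1] for s in ledger.steps[:4]]))

    def bell(state: str) -> tuple[float, float]:
        if swapped_bell and state in swapped_bell:
            return swapped_bell[state]
        target, dx, lc_ref = DEFAULT_SWAPPED_TARGETS[state]
        return _cached_k0(target, dx, lc_ref), dx

    units = []
    k0, dx = bell("Ctd2")
    units.append(FoldedUnit("Ctd2", _domain_stages(ctd2, rng, config,
                                                   deltas["dL1"], k0, dx), 0))
    k0, dx = bell("Ntd1_swap")
    units.append(FoldedUnit("Ntd1_swap",
                            (Stage("Ntd", deltas["dL2"], k0, dx),), 1))
    k0, dx = bell("Ntd2_part")
    units.append(FoldedUnit("Ntd2_part",
                            (Stage("swap-weak", deltas["dL3"], k0, dx),), 2))
    k0, dx = bell("Ctd1")
    units.append(FoldedUnit("Ctd1", _domain_stages(ctd1, rng, config,
                                                   deltas["dL4"], k0, dx), 3))
    for d in topology.domains:
        if d.class_label == "I27":
            units.append(FoldedUnit(d.name, _domain_stages(d, rng, config)))
    return PathwayState("swapped", tuple(units), ledger.initial_slack_nm, ledger)


def _swapped_domains(topology: ConstructTopology):
    from .constructs import _swapped_parts
    return _swapped_parts(topology)


# ---------------------------------------------------------------------------
# Trace simulation
# ---------------------------------------------------------------------------

def simulate_from_state(state: PathwayState, config: PullConfig,
                        rng: np.random.Generator,
                        construct_name: str = "construct",
                        trace_id: str = "trace") -> ForceExtensionTrace:
    """Integrate one pulling trace for an already-sampled pathway state."""
    dt, v, kc = config.time_step, config.velocity, config.spring_constant
    kbt, p = config.kbt, config.persistence_nm
    lc = state.initial_Lc_nm
    if lc <= 0:
        raise InputError("initial contour length must be > 0 nm")

    stage_idx = [0] * len(state.units)
    force_parts: list[np.ndarray] = []
    truth: list[TruthEvent] = []
    i_global = 0
    complete = True

    def seq_head() -> int | None:
        ranks = [u.sequential_rank for j, u in enumerate(state.units)
                 if u.sequential_rank is not None and stage_idx[j] < len(u.stages)]
        return min(ranks) if ranks else None

    while True:
        head = seq_head()
        exposed = [j for j, u in enumerate(state.units)
                   if stage_idx[j] < len(u.stages)
                   and (u.sequential_rank is None or u.sequential_rank == head)]
        # branch grid up to the stage position where force reaches detachment
        params = WlcParams(p, lc, config.temperature)
        z_det = wlc_extension(config.detach_force, params) + config.detach_force / kc
        n_branch = max(int(math.ceil((z_det - i_global * v * dt) / (v * dt))) + 2, 2)
        z = v * dt * (i_global + 1 + np.arange(n_branch))
        x, f = solve_force_balance_array(z, lc, p, kbt, kc)

        cands = [(j, state.units[j].stages[stage_idx[j]]) for j in exposed]
        rates = [s.k0 * np.exp(np.clip(f * s.dx / kbt, None, 700.0))
                 for _, s in cands]
        if config.tether_k0 > 0:
            rates.append(config.tether_k0
                         * np.exp(np.clip(f * config.tether_dx / kbt, None, 700.0)))
        if rates:
            k_tot = np.sum(rates, axis=0)
            hazard = np.cumsum(k_tot) * dt
            idx = int(np.searchsorted(hazard, rng.exponential()))
        else:
            idx = n_branch  # nothing left to rupture: ramp to detachment
        if idx >= n_branch:  # force reached the detachment threshold
            force_parts.append(f)
            i_global += n_branch
            complete = all(stage_idx[j] >= len(u.stages)
                           for j, u in enumerate(state.units))
            break
        # discretisation guard: at the modal rupture force of a Bell unit the
        # rate equals r_load*dx/kBT, so the expected ruptures per step there
        # are r_load*dx/kBT*dt; this must stay well below 1
        if cands:
            k_wlc = float(_ms_stiffness(x[idx], lc, p, kbt))
            r_load = v / (1.0 / kc + 1.0 / k_wlc)
            dx_max = max(s.dx for _, s in cands)
            if r_load * dx_max / kbt * dt > 0.1:
                raise ConfigError(
                    f"time_step too coarse: expected ruptures per step at "
                    f"peak force {r_load * dx_max / kbt * dt:.2f} > 0.1")
        weights = np.array([r[idx] for r in rates])
        choice = int(rng.choice(len(weights), p=weights / weights.sum()))
        force_parts.append(f[: idx + 1])
        i_global += idx + 1
        if choice >= len(cands):  # tether detached
            complete = all(stage_idx[j] >= len(u.stages)
                           for j, u in enumerate(state.units))
            break
        j, st = cands[choice]
        truth.append(TruthEvent(index=i_global - 1, time_s=i_global * dt,
                                unit_label=state.units[j].label,
                                class_label=st.class_label,
                                force_pN=float(f[idx]), delta_Lc_nm=st.delta_L,
                                pathway=state.pathway))
        stage_idx[j] += 1
        lc += st.delta_L

    n_tail = max(50, int(round(0.005 / dt)))
    force_parts.append(np.zeros(n_tail))
    force = np.concatenate(force_parts)
    n = force.size
    z_all = v * dt * (1 + np.arange(n))
    if config.force_noise_sd > 0:
        force = force + rng.normal(0.0, config.force_noise_sd, size=n)
    extension = z_all - force / kc
    meta = config.to_metadata()
    meta.update({"construct": construct_name, "pathway": state.pathway,
                 "complete": complete, "initial_Lc_nm": state.initial_Lc_nm})
    return ForceExtensionTrace(time=z_all / v, stage_position=z_all,
                               extension=extension, force=force,
                               metadata=meta, truth=truth, trace_id=trace_id)


def simulate_pull(topology: ConstructTopology, config: PullConfig,
                  rng: np.random.Generator | None = None,
                  pathway: str | None = None,
                  trace_id: str | None = None) -> ForceExtensionTrace:
    """Simulate one constant-velocity pull of ``topology``.

    The pathway (regular vs swapped) is drawn with ``swap_probability``
    unless forced via ``pathway``.  With ``rng`` omitted, a fresh generator
    is seeded from ``config.seed`` so equal configs give identical traces.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = sample_pathway(topology, config, rng, pathway=pathway)
    return simulate_from_state(state, config, rng,
                               construct_name=topology.name,
                               trace_id=trace_id or f"{topology.name}_0")


def generate_dataset(entries, out_dir=None) -> list[ForceExtensionTrace]:
    """Generate a reproducible batch of traces.

    ``entries`` is an iterable of dicts with keys ``construct`` (preset name
    or ConstructTopology), ``n`` (trace count), ``seed`` (batch seed) and
    optional ``config`` (PullConfig field overrides).  Per-trace seeds are
    spawned deterministically from the batch seed.  With ``out_dir`` given,
    traces are written as TSV with a truth-log CSV sidecar.
    """
    from . import io as trace_io
    from .presets import preset

    traces = []
    written: set = set()
    for entry in entries:
        construct = entry["construct"]
        topology = preset(construct) if isinstance(construct, str) else construct
        overrides = dict(entry.get("config", {}))
        overrides.setdefault("seed", entry.get("seed", 0))
        config = PullConfig(**overrides)
        seeds = np.random.SeedSequence(config.seed).spawn(int(entry["n"]))
        for i, ss in enumerate(seeds):
            rng = np.random.default_rng(ss)
            tid = f"{topology.name}_s{config.seed}_{i:04d}"
            trace = simulate_from_state(
                sample_pathway(topology, config, rng), config, rng,
                construct_name=topology.name, trace_id=tid)
            traces.append(trace)
            if out_dir is not None:
                path = trace_io.trace_path(out_dir, tid)
                if path in written:
                    raise InputError(f"duplicate output path {path}")
                written.add(path)
                trace_io.write_trace(trace, path)
    return traces
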