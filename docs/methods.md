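# Methods

This note documents the models inside `crysmech`, the defaults they carry,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Contour-length bookkeeping

Every residue contributes a fixed contour length `a = 0.4 nm`
(`crysmech.constants.RESIDUE_CONTOUR_NM`; configurable in every operation
that uses it). A construct is an ordered N→C chain of folded domains
(`DomainSpec`) and unstructured linkers (`LinkerSpec`). The *regular* ledger
assigns one step per folded domain, ordered by mechanical stability class
(Ctd < Ntd < other < I27), with all linker slack plus the folded end-to-end
lengths extending before the first rupture. The *swapped* ledger follows the
shielded topology: Ctd2 first, then Ntd1 together with the swapping loop of
the donated β1–β2 element, then the Ntd2 remnant together with the hinge and
inter-monomer linker that had been sequestered inside the intertwined
complex, then the shielded Ctd1, then the I27 fingerprints.

Two bookkeeping choices matter:

* **Conservation.** Both pathways must release the same fully unfolded
  contour length. The swapped ledger therefore carries the I27 fingerprint
  steps after ΔL4, and the default ΔL꜀ of the Ntd2 remnant is
  `ΔLc(Ntd) − a·loop` — the unique decomposition under which conservation
  holds to machine precision. The remnant length remains an explicit
  override (`ntd2_part_delta_Lc`) because the decomposition is a model,
  not a measurement; overriding it moves the discrepancy into the initial
  slack so the total stays conserved.
* **Rounding.** `residues_from_extension` floors (a partial residue does
  not count) with a 1e-9 guard against floating-point representation, so
  6.6 nm → 16 residues and the floor is exact on integer multiples of `a`.
  Nearest-integer rounding is available.

`infer_swap_loop` is the exact algebraic inverse of the ΔL2 construction;
a negative inferred loop raises an inconsistency error because it means the
measured ledger cannot come from an Ntd swap. Residue numbering is 1-based
inclusive (the default motif span 3–18 has 16 residues). A β7-strand swap
variant can be constructed but is documented as disfavoured
(secondary-structure and B-factor evidence point to β1–β2).

The dimer presets use Ntd = 82, hinge = 7, Ctd = 84 residues (173 total),
a 12-residue inter-monomer linker — chosen so the predicted ΔL3
(22.9 + 0.4·19 = 30.5 nm) matches the measured regular-linker value — and
2-residue terminal cloning-site linkers. The long-linker variant adds the
14-residue (GS)₇ insertion. I27 uses the field-standard ΔL꜀ = 28.4 nm; the
fingerprint fits are shown but not tabulated in the source data, so this
value is an assumption.

## Worm-like-chain mechanics

The Marko–Siggia interpolation `F = (kBT/p)·[1/(4(1−x/Lc)²) − 1/4 + x/Lc]`
with persistence length `p = 0.4 nm` (standard for unfolded polypeptide)
and `kBT = 4.11 pN·nm` (room temperature) backs all force–extension
arithmetic. The interpolation error (<~10 % in force at intermediate
extensions) is irrelevant here because the same law is used for synthesis
and analysis, and because contour-length *increments* between fits are the
observable. Inversion and the cantilever force balance are solved to
<1e-6 pN residual (bisection/Brent); the simulator uses a vectorised
bisection on whole stage ramps.

Segment fits hold `p` fixed and optimise `Lc` alone over a bounded interval
that keeps every point below the fitted contour length — the standard AFM
protocol that makes ΔL꜀ well defined. Two refinements matter at realistic
noise:

* when the extension coordinate is derived from the cantilever deflection
  (`x = z − F/k_c`), the force noise leaks into the extension and the force
  residuals are amplified by `(1 + k_wlc/k_c)` on stiff branches.
  `fit_wlc_segment` accepts the spring constant and weights accordingly;
* the event extractor goes one step further: when the stage position and
  spring constant are available it rebuilds the fit extension from the
  noise-free stage ramp and the *smoothed* deflection, which removes a
  curvature bias of order 1 nm on short, stiff branches.

## Pulling simulator

Constant-velocity pulling (default 400 nm/s, 12 pN/nm cantilever, 0.1 ms
sampling = 0.04 nm stage steps). Between ruptures the trace is
deterministic; each load-bearing folded unit carries a Bell rate
`k(F) = k0·exp(F·dx/kBT)` and rupture times are drawn exactly from the
integrated hazard along the branch. On rupture the chain gains the unit's
ΔL. The trace ends when force reaches a detachment threshold (400 pN)
after the last unit, plus a short zero-force tail so the detachment appears
as a final peak. Refolding is ignored (the pull is fast and monotone);
optional Bell-type tether detachment (`tether_k0`, `tether_dx`) produces
premature, gate-rejectable recordings.

**Calibration.** `calibrate_bell` solves the constant-loading-rate closed
form `k0 = (r·dx/kBT)·exp(−F*·dx/kBT)` with the geometric loading rate
`r = v / (1/k_c + 1/k_wlc)` evaluated at the target force on a
class-typical contour length; optional stochastic refinement polishes the
realised mode. Calibration targets are the measured class means at 400 nm/s
(Ctd 96.1, Ntd 136.2, I27 251.9 pN; R14C variants 83.7/112.6/197.9 pN).
Preset k0 values are fixed at this reference, so pulling faster shifts
rupture forces up with log(velocity), as in experiment.

**Transition-state distances** are not printed in the source data and are
this package's choice: `dx = 0.35 nm` for the crystallin domains — the
implied rupture-force spread (π/√6·kBT/dx ≈ 15 pN) matches the measured
16.8/18.0 pN standard deviations — and `dx = 0.30 nm` for I27, slightly
above the textbook 0.25 nm so that the fingerprint distribution stays
essentially entirely above the 180 pN classification window (the measured
34 pN I27 spread contains molecule-to-molecule and instrument variance this
noise model does not represent; reproducing it would make the fingerprint
gate reject ~5 % of complete recordings for no physical reason).

**Swapped-pathway states** get their own Bell parameters, calibrated to the
measured anomalous-step forces (Ctd2 82.2, swapped Ntd1 118.4, Ntd2 remnant
35 with dx = 0.40, Ctd1 95.3 pN); the remnant's weakness reflects its
changed pulling axis, for which no quantitative model exists. The
crystallin queue of the swapped pathway is strictly sequential
(Ctd2 → Ntd1 → remnant → Ctd1); the I27 flanks are load-bearing throughout.
In the regular pathway all domains are load-bearing from the start and the
order emerges from the kinetics alone.

**Intermediates.** Ctd domains carry a weak unfolding intermediate
(~50 pN, 8 nm). Per trace and per domain it is sampled with probability
0.5 — its real frequency is described only as "often", so this default is
a package choice — and splits the domain's release into (ΔL꜀ − 8) + 8 nm.

**Noise** is i.i.d. Gaussian on force (default sd 10 pN, a typical AFM
thermal noise figure; not printed in the source data); the reported
extension is `stage − F_noisy/k_c`, i.e. the deflection-derived tip–sample
separation, which makes the extension noise anti-correlated with the force
noise exactly as in a real instrument.

**Discretisation guard.** At a Bell unit's modal rupture force the rate
equals `r·dx/kBT`, so the expected ruptures per step there are
`r·dx/kBT·dt` (~0.02 at the defaults). If that exceeds 0.1 the simulator
raises a configuration error; the guard is evaluated at the modal force,
not at the sampled rupture force, so rare tail draws do not trip it.

## Trace analysis

**Peaks.** Candidate maxima above 25 pN are segmented by an explicit
running-max drop criterion: a candidate becomes a rupture when the force
falls at least 20 pN below it before exceeding it again. The drop
criterion — not peak prominence — is what keeps the ~35 pN weak
swapped-state peak, which rises from an elevated trough and has a
prominence of only ~9 pN despite a ~25 pN rupture drop. The force is
pre-smoothed with an 11-sample moving average. Ruptures whose release is
too small to drop the force by 20 pN (an 8 nm intermediate at small
contour length drops it by only a few pN) are invisible by construction.

**Events.** Each rising edge is fitted; an event's ΔL꜀ is the difference
of consecutive fitted contour lengths and its rupture force is the smoothed
peak value (the fit window is trimmed by the smoothing width so no
post-rupture samples leak in). If the edge *between* two peaks cannot be
fitted — a cascade too fast to resolve — the two peaks merge into one
event carrying the combined increment; unfittable leading/trailing edges
leave the event flagged `unknown`, never silently dropped.

**Classification windows** (configurable, validated for overlaps):
I27 ≥ 180 pN; Ntd 110–180 pN; Ctd 60–110 pN; below 60 pN the increment
decides — ≥ 20 nm is the weak swapped state, < 20 nm an intermediate.
Boundaries sit between the measured class force distributions.

**Fingerprint gate.** A recording is analysed only if its number of
I27-class events equals the construct's I27 count — the single-molecule
certification rule. Reasons are recorded on rejection.

**Trajectory verdicts.** Intermediate-scale events (< 20 nm) are folded
back into their parent rupture, then the crystallin ΔL꜀ sequence is
aligned against the construct's two predicted ledgers by an
order-preserving block alignment: one measured step may cover a run of
template steps (an undetected weak peak yields the combined
ΔL2+ΔL3 ≈ 67 nm step), a run of measured steps may cover one template step
(a lumped cascade), and a 2↔2 block repairs a mis-partitioned adjacent
pair. A block spanning k steps must agree within k × 3 nm (the tolerance
reflects the 1.2–3.7 nm spreads of the measured steps). Alignments with
fewer merges are strictly preferred — a merged block's residual is never
larger than its parts', so without that preference everything would merge —
and unrestricted many-to-many blocks are forbidden outright: the total
released length is conserved across pathways, so a whole-sequence block
would let either ledger match any trace. Feasible templates are ranked by
residual; ties are left unclassified, as are traces matching no ledger.

**Statistics.** The anomalous fraction is `anomalous/(anomalous+regular)`
with a Wilson 95 % interval; unclassified and rejected traces are reported
separately rather than folded into the split. Distribution summaries quote
the sample standard deviation (ddof = 1), matching the
"mean ± sd (n = …)" convention of force-spectroscopy figure legends.

## Extended Kalman filter

The filter tracks the instantaneous contour length as a scalar random-walk
state (default process variance 1e-4 nm²/sample). The observation is the
measured *force*, predicted from the noise-free stage position by solving
the chain/cantilever force balance at the current Lc; the Jacobian is the
bare WLC sensitivity `∂F/∂Lc` damped by the stiffness divider
`k_c/(k_c + k_wlc)`. Predicting from the stage, rather than from the
deflection-derived extension, keeps the innovations independent and
Gaussian — the deflection-based formulation has correlated innovations
with heavy quadratic tails near full extension, which destabilises any
innovation gate.

Rupture detection uses the mean normalised innovation over the last 10
samples against a threshold of 2.0 (≈ 6.3 σ for white noise, yet sensitive
to the sustained ~2.5 σ offset left by a weak ~30 pN rupture). On a trip
the filter rolls back to a 10-sample-old buffered estimate (updates made
while a rupture is developing are discarded), re-acquires by inverting a
40-sample post-break batch average and then *replaying* that batch as
ordinary updates (removing the curvature bias of inverting at the mean),
and records the step — the difference of the converged estimates on the
adjacent branches — at the rupture time. Single-sample outliers beyond
twice the gate are excluded from updates with the variance frozen;
divergence (variance overflow) raises a filter error.

On noiseless traces the detected steps equal the injected increments to
better than 0.1 nm. At 10 pN noise the steps agree with the segment-fit
increments within 0.5 nm on ≥ 95 % of *commonly resolved, isolated*
ruptures (both methods found exactly this rupture and its neighbours).
That restriction defines the benchmark: on cascade branches shorter than a
few hundred samples the Cramér–Rao bound for the branch contour length is
itself ≈ 1 nm, so no two estimators can agree to 0.5 nm there, and when
the two methods partition a cascade differently the comparison measures
partitioning, not estimation. The benchmark therefore runs on two-state
unfolding (intermediates disabled); the pipeline itself always runs with
intermediates on.

## What the synthetic data do not emulate

No cantilever hydrodynamics, baseline drift, 1/f noise, multiple-molecule
tethers, refolding, or molecule-to-molecule parameter variance; force noise
is white and Gaussian. Passing tests therefore demonstrate that the
analysis recovers what the generative model injects under realistic
thermal noise — not that it is robust to every instrumental artifact of a
real AFM. The anomalous-pathway step lengths are injected from the ledger
model itself, so end-to-end recovery validates the inference chain's
consistency, not the structural assignment; the assignment rests on the
measured-ledger arithmetic (6.6 nm → 16 residues → β1–β2) and the
linker-edit control, both of which the package reproduces exactly from the
measured inputs.

Two measured features are deliberately not forced on the generator: the
anomalous ΔL1 (32.3 nm) exceeds the isolated-Ctd ΔL꜀ (29.9 nm) by 2.4 nm
for reasons the data do not resolve (hinge slack or a context effect), and
the simulator uses the conserved 29.9 nm; and whether the 15-residue β2–β3
structural loop and the 16-residue inferred extension are the same object
is left open — the motif keeps both fields.

## Problem sizes

The test suite simulates batches of 40–150 traces per benchmark and 1000
traces for the end-to-end recovery; the reproduction script uses 2500
ruptures per force-calibration class and 1000 traces for the swap-fraction
and loop recovery. A 1000-trace dimer batch simulates and analyses in
roughly half a minute on one core.
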