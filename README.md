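# crysmech

Single-molecule force-spectroscopy analysis of human γD-crystallin
polyproteins: a constant-velocity AFM pulling simulator, a worm-like-chain
trace-analysis pipeline, and the contour-length bookkeeping that identifies
a domain-swapped dimer and infers the size of its swapping loop.

## The problem

γD-crystallin is a two-domain (Ntd + Ctd) lens protein that must stay folded
for a lifetime; its misfolding seeds cataract. When two crystallin monomers
sit next to each other in an engineered polyprotein
[I27-(HγD-crys)₂-I27] and the construct is stretched by AFM, most
recordings show the *regular* hierarchy — the weaker Ctds unfold first
(~96 pN), then the Ntds (~136 pN), then the I27 fingerprint modules
(~252 pN), each releasing ΔL꜀ ≈ 30 nm of contour length. A minority
(~15 %) unfold *anomalously* in four steps whose forces violate the
hierarchy, ending with a very weak (~35 pN) rupture. That pattern is the
signature of an intertwined, domain-swapped dimer: the β1–β2 hairpin of one
Ntd is donated to its neighbour, and the swapped topology shields one Ctd
from force until the donated element unravels.

The contour-length ledger of the anomalous pathway is what identifies the
swap. With per-residue contour length a = 0.4 nm/aa:

```
ΔL1 = ΔLc(Ctd2)
ΔL2 = ΔLc(Ntd1) + a·(swapping loop)
ΔL3 = ΔLc(Ntd2 remnant) + a·(hinge + inter-monomer linker)
ΔL4 = ΔLc(Ctd1)
```

so the loop length falls out of measured quantities:
`loop = (ΔL2+ΔL3) − ΔL3 − ΔLc(Ntd) = 66.9 − 31.0 − 29.3 = 6.6 nm ≈ 16 aa`,
which places the swapped element at the β1–β2 hairpin (residues ~3–18).
Lengthening the engineered inter-monomer linker by 14 residues must move
ΔL3 — and only ΔL3 — by 14 × 0.4 = 5.6 nm, a prediction the long-linker
control construct verifies.

## What the package provides

| module            | role |
|-------------------|------|
| `crysmech.constructs` | polyprotein topologies, ledger prediction (regular & swapped), swap-loop inference, linker-edit prediction |
| `crysmech.wlc`        | Marko–Siggia worm-like chain: force law, inversion, cantilever force balance, segment fitting |
| `crysmech.simulate`   | Monte-Carlo constant-velocity pulling with Bell kinetics, calibrated to the measured modal forces; ground-truth event logs |
| `crysmech.analyze`    | peak detection, per-edge WLC fits, ΔL꜀ extraction, event classification, I27 fingerprint gating, EKF contour-length tracking |
| `crysmech.classify_report` | trajectory verdicts (regular / anomalous-swap), swap-fraction estimation with Wilson CI, distribution summaries, swap-loop inference reports |
| `crysmech.presets`    | the named constructs: (HγD-crys-I27)₄, (I27-Ntd)₄, (I27-Ctd)₄, the dimer, its long-linker variant, R14C variants |

## Worked example

```python
import crysmech as cm
from crysmech.analyze import analyze_trace, fingerprint_gate
from crysmech.classify_report import (classify_trajectory,
                                      estimate_swap_fraction,
                                      run_swap_inference)

# the measured-ledger arithmetic
loop_nm, loop_res = cm.infer_swap_loop(66.9, 31.0, 29.3)
print(f"swapping loop: {loop_nm:.1f} nm ~ {loop_res} residues")

# end to end: simulate, gate, classify, infer
dimer = cm.preset("dimer")
traces = cm.generate_dataset([{"construct": dimer, "n": 200, "seed": 42,
                               "config": {"swap_probability": 0.15,
                                          "seed": 42}}])
calls = []
for trace in traces:
    events = analyze_trace(trace)
    gate = fingerprint_gate(events, dimer)
    calls.append(classify_trajectory(events, dimer, gate=gate,
                                     trace_id=trace.trace_id))
frac, (lo, hi) = estimate_swap_fraction(calls)
print(f"anomalous fraction: {frac:.3f} (95% CI {lo:.3f}-{hi:.3f})")
print(run_swap_inference(calls, 29.3).to_text())
```

prints

```
swapping loop: 6.6 nm ~ 16 residues
anomalous fraction: 0.120 (95% CI 0.081-0.173)
construct dimer:
  anomalous trajectories: 23 (20 with resolved weak peak)
  mean dL2+dL3 = 66.1 nm, mean dL3 = 30.4 nm => dL2 = 35.7 nm
  swapping loop = dL2 - dLc(Ntd) = 6.4 nm ~ 15 residues
```

The first line is the exact arithmetic on the measured ledger values; the
rest is the same inference recovered blindly from 200 synthetic recordings
(the generator injected a 16-residue loop and a 15 % swap probability; with
200 traces the recovered loop is within one residue, with 1000 traces it is
exact — see the reproduction script below).

A command-line interface mirrors the library:

```bash
crysmech simulate --construct dimer --n 100 --swap-prob 0.15 --seed 1 --out traces/
crysmech analyze --in traces/ --out events.csv --gate-construct dimer
crysmech classify --events events.csv --construct dimer --report report/
```

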