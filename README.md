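# osteoflux

Mechanistic poroelastic remodelling of a single trabecula, and the
strain-based phenomenological adaptation laws distilled from it.

## The problem

Trabecular bone adapts its architecture to mechanical demand, and a leading
hypothesis places the mechanosensor in the interstitial fluid: osteocytes
respond to fluid motion through the lacuno-canalicular pores, adding bone
where flow is high and removing it where flow is low.  Mechanistic models
built on that hypothesis operate at the single-trabecula scale and are far
too expensive to embed in whole-bone simulations, which instead represent
each trabecula as a beam element driven by simple strain-based rules.
`osteoflux` bridges the two scales: it runs the mechanistic model — a
transient Biot poroelastic finite-element simulation of a 2D trabecula
whose boundary remodels iteratively under a fluid-velocity stimulus — over
a sweep of loading scenarios, reduces each adapted geometry to an
equivalent beam, and fits the phenomenological laws that a mesoscale
structural model can consume.

For users in computational bone mechanobiology: the package is a library
(`osteoflux`) plus a thin CLI (`remodel`).

## The models

**Poroelastic trabecula.**  A 1 × 0.2 mm plane-strain strut (spline-bounded,
remeshed every iteration) tied to elastic bone plates, fluid-saturated Biot
medium (E = 18 kN/mm², ν = 0.3, K_s = 20, K_f = 2.3 kN/mm², φ = 0.05) with
Darcy transport q = −(κ/μ)∇p, loaded by a 1 s triangular force pulse and
integrated with backward Euler (10 increments, equal-order stabilised u–p
quadrilaterals).

**Remodelling rule.**  Each of 24 characteristic boundary points carries a
characteristic fluid velocity V (disc-of-influence average of per-element
time-median |q|) and moves horizontally by

    dX = ± min(0.005 · V / V_target, 0.05)  [mm per iteration]

outward where V ≥ V_apposition, inward where V ≤ V_resorption, not at all
inside the lazy zone.  The thresholds are calibrated so that pure
compression at F_target = E·πr²·ε_target (ε_target = 1250 µε, Frost's
Mechanostat set point) is remodelling-neutral.

**Beam twin and laws.**  A 3-node Timoshenko beam between the same plates,
with end rotational springs k = 4EI/t, supplies the strain drivers at its
second Gauss point: axial strain ε_a, bending strain difference ε_b, and
K_ε = ε_b/ε_a.  Across scenarios the adapted cross-section ratio R_A and
reorientation Δφ follow

    Δφ  = a·K_ε³ + b·K_ε
    R_A = (i·K_ε + sign(ε_a)·j)·ε_a + k_mean

fitted by ordinary least squares (per-angle lines for R_A, odd cubic for
Δφ), which is what `laws.json` reports.

## Worked example

Calibrate the velocity thresholds on the coarse study mesh, run the
inclined-trabecula benchmark, and read a beam strain state:

```
$ remodel calibrate --mesh-h 0.03
V_target=1.08e-08 mm/s  band=[1.037e-08, 1.123e-08] mm/s

$ remodel run-validation
final angle between axis and load line: 4.49 deg (initial 30 deg); \
apparent width change: -19.1 % after 100 iterations (converged=True)
```

The first command finds the homeostatic velocity target for this mesh
resolution (the near-surface stimulus scale is resolution-limited, so the
thresholds are always calibrated where they are used).  The second runs the
classic benchmark — a 0.92 × 0.2 mm strut loaded 30° off its axis through a
stiff plate — and shows the two expected outcomes: near-complete
reorientation onto the load line and roughly 20 % thinning (the load is
0.79·F_target, and the adapted width is close to linear in the load).

```python
>>> import numpy as np
>>> from osteoflux import (BeamSection, BeamSupport, LoadPulse,
...                        solve_beam_static, extract_beam_strains)
>>> pulse = LoadPulse(amplitude=0.70686, theta=np.pi / 4)
>>> st = extract_beam_strains(solve_beam_static(BeamSection(), BeamSupport(), pulse))
>>> print(f"eps_a={st.eps_a:.4e}  eps_b={st.eps_b:.4e}  K_eps={st.K_eps:.4f}")
eps_a=1.7175e-03  eps_b=1.1620e-03  K_eps=0.6766
```

At 45° the beam carries 1.7 millistrain axially with a bending-to-axial
ratio of 0.68 — the x-coordinate this scenario contributes to the
reorientation law.

The full sweep (14 angles × 3 amplitudes, remodelling, equivalent-beam
reduction and law fitting) is

```
remodel run-study --config study.yaml --out study_out
```

writing `equivalent_beams.csv`, `beam_strains.csv`, `fits.csv`,
`laws.json`, per-scenario histories and a run manifest.  See
`docs/methods.md` for the model details, numerical choices and known
limitations.

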