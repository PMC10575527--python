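# vppgait

Virtual pivot point (VPP) analysis of walking, from raw force-plate and
motion-capture streams to condition-level statistics — with a fully
synthetic gait generator so every stage can be validated against planted
ground truth.

## The problem

During the single support phase of walking, the ground reaction force
(GRF) vectors, drawn from the centre of pressure (CoP) in a coordinate
frame centred on the body's centre of mass (CoM), tend to intersect at a
single point above the CoM: the **virtual pivot point**. When it exists,
the body behaves like a pendulum hanging from that point, which is one
candidate mechanism for how humans stabilise upright gait. Gait labs ask
two questions of a trial: *where* is the VPP, and *does it exist at all*?

`vppgait` answers both:

* **Position.** The VPP is the minimiser of the summed squared
  perpendicular distances to the GRF lines of single support. With unit
  force directions $d_{ij}$ and CoM-relative CoP origins $p_{ij}$, the
  minimiser solves the normal equations

  $$\Big[\sum_{ij} (I - d_{ij} d_{ij}^\top)\Big]\, v \;=\; \sum_{ij} (I - d_{ij} d_{ij}^\top)\, p_{ij},$$

  a closed-form linear least-squares problem (degenerate only when all
  lines are parallel).

* **Existence.** An angle-based coefficient of determination compares
  the measured force angles $\theta_{\mathrm{Exp},ij}$ (angle between the
  ground and the GRF) with the angles $\theta_{\mathrm{VPP},ij}$ of the
  CoP-to-VPP connections, pooled over all trials $i$ and instants $j$ of
  one participant-condition:

  $$R^2 \;=\; 1 - \frac{\sum_{i}\sum_{j} (\theta_{\mathrm{Exp},ij} - \theta_{\mathrm{VPP},ij})^2}{\sum_{i}\sum_{j} (\theta_{\mathrm{Exp},ij} - \bar\theta_{\mathrm{Exp}})^2},$$

  where $\bar\theta_{\mathrm{Exp}}$ is the grand mean. $R^2 \in
  (-\infty, 1]$; the VPP counts as a point iff $R^2 > 0.6$ (strict).

Around this core the package provides the standard gait-lab chain:
zero-phase Butterworth filtering of kinematics, body-weight
normalisation, threshold-based touchdown/take-off detection on a
three-plate walkway, segment-parameter CoM reconstruction, centroidal
angular momentum, quasi-static ankle torque, joint/trunk angles,
spatio-temporal parameters, and repeated-measures ANOVA with Šidák
post-hoc tests plus one-sample t-tests of the VPP position against the
CoM.

## Worked example

```python
from vppgait import (FanSpec, TrialSpec, generate_gait_trial,
                     analyze_trial, fit_vpp, compute_r_squared)

spec = TrialSpec(participant_mass=62.0, participant_height=1.70,
                 speed=0.6, cadence=80.0, condition="shoes",
                 vpp=FanSpec(vpp_x=0.0, vpp_z=0.30, angle_noise_sd=0.5),
                 seed=42)
trial, truth = generate_gait_trial(spec)   # three-plate walkway trial
result = analyze_trial(trial)              # events -> CoM -> force lines
fit = fit_vpp(result["lines"])
r2 = compute_r_squared(result["lines"], fit)
```

prints (via the obvious f-strings):

```
planted VPP : x = 0.000 m, z = 0.300 m
fitted VPP  : x = -0.001 m, z = 0.258 m  (141 force lines)
R^2 = 0.978  ->  VPP is a point: True
speed = 0.60 m/s, contact = 0.91 s, rel. SSP = 64.0 %, cadence = 80.0 steps/min
```

The fitted pivot sits 0.26 m above the CoM with a near-perfect R², so
this trial "has" a VPP. The ~0.04 m shortfall against the plant is the
documented downward attenuation of noisy line-bundle fits (see
`docs/methods.md`); with `angle_noise_sd=0` the plant is recovered to
machine precision. A command-line interface wires the same chain over
directories of trials:

```bash
vppgait simulate --out trials/ --seed 1            # synthetic cohort
vppgait analyze  --input trials/ --out results/    # per-condition VPPs
vppgait stats    --results results/results.csv --out report/
```

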