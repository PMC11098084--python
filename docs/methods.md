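# Methods

## Model and assumptions

Each chromosome arm is a chain of `nodes_per_arm` beads connected by Hookean
springs of rest length 1 (the simulation length unit; 1 lu = 0.2 µm under
the documented conversion, so the default 48-node arm is a ~9.4 µm contour).
The chain is a phantom polymer: nodes of different chains and of the same
chain may pass through each other, and pairing requires contact, so no
excluded volume is modelled.  Bending is penalized by pulling every interior
node toward the midpoint of its neighbours with stiffness `k_bend`; this
midpoint form also mildly penalizes unequal consecutive bond lengths, which
is harmless at the default backbone stiffness.  Chains live in a spherical
nucleus (harmonic wall, `k_confine`) and each chain's node 0 — the
centromere — is tethered to the nearest point of a spherical cap around the
+z pole of the envelope (`k_tether`), producing the Rabl configuration:
centromeres clustered at one pole, telomeres toward the other, and a nearly
linear map from genomic position to height z.  Dynamics are overdamped
Euler–Maruyama with per-node friction γ and thermal noise of per-step scale
sqrt(2·kBT·dt/γ).

Adhesion is completely nonspecific.  Each iteration: (1) every existing
button–button bond dissolves with probability `p_unpair`; (2) all free
buttons within `capture_radius` of each other are matched greedily, nearest
pair first (ties broken lexicographically), including cis and nonhomologous
combinations, with formation probability 1 on contact; (3) forces are
evaluated and positions updated.  A freshly broken pair still in capture
range may re-bond in the same iteration unless a nearer free partner claims
one of its endpoints — this is what makes pairing robust even at
`p_unpair = 1` while still allowing strained (mismatched) contacts to be
edited out.  Bonds are zero-rest-length springs of stiffness `k_pair`;
one-to-one exclusivity is enforced.

## Parameters (simulation units; defaults in `SimulationConfig`)

| parameter | default | meaning / why |
|---|---|---|
| kBT | 1 | energy unit |
| friction | 1 | sets the time unit γ·lu²/kBT |
| k_spring | 100 | stiff backbone; bond-length sd ≈ 0.1 lu |
| k_bend | 25 | measured persistence length ≈ 7–8 lu ≈ 1.5 µm, inside the plateau where spacing discrimination works; Lp ≈ k_bend/4 in the small-angle limit |
| k_pair | 20 | firm but correctable bonds: with much stiffer pairing springs a bound pair sits so deep inside the capture radius that unbinding can never separate it and errors lock in |
| k_confine, k_tether | 100 | hard wall / tether penalties |
| dt | 0.002 | explicit-integrator stability: the stiffest chain mode has Hessian eigenvalue ≈ 4·k_spring, and dt·λ/γ must stay below 2 (0.8 at default) |
| nucleus_radius | 24 | diameter equals the 47-lu contour, so a tethered chain spans the nucleus pole-to-pole and genomic position maps linearly to z (measured no-pairing Rabl correlation ≈ −0.96) |
| rabl_patch_radius | 5 | ~1 µm centromere cluster: small enough for a strong Rabl gradient, large enough that four chains are not forced into a single bundle |
| capture_radius | 1.0 | contact range = one bond length; smaller values starve binding, larger ones allow long-range wrong grabs |
| p_unpair | 0.8 | reversibility optimum of the kinetic scan |
| n_steps | 300,000 | standard run; compact barcodes anneal fully on this scale, whole-arm codes approach their plateau |
| burn_in_steps | 5,000 | pairing disabled while the initial geometry relaxes |

Centromere-tether, confinement, spring, bending and pairing forces are the
exact negative gradient of `elastic_energy` (finite-difference-checked to
1e-4 relative), so noiseless integration is gradient descent.

## What the simulations emulate — and what they do not

The generator of "data" here is the simulator itself: chains start in an
extended Rabl layout (centromeres sampled on the envelope cap, chains
extended inward at rest length with 0.1-lu lateral jitter, folding
tangentially along the wall if they reach it).  The model is deliberately
generic: no species-specific genome sizes, no chromatin heterogeneity, no
loop extrusion, no excluded volume, no hydrodynamics, and a single arm per
chromosome.  Passing tests therefore show that *this mechanism* — polymer
elasticity plus Rabl ordering plus reversible nonspecific adhesion — yields
selective pairing under the stated conditions; they do not calibrate any
real organism's pairing kinetics.

## Numerical and design choices

- **Same math, two routes.** All force/kinetics operations exist as plain
  NumPy reference functions (the public module surface) and as a numba
  kernel used by `run`; a test pins one kernel iteration to the reference
  composition in the deterministic limit.  Runs are bit-reproducible given a
  seed.
- **Bending as midpoint deviation** rather than an angular cosine potential;
  the k_bend → Lp map is established empirically with the
  orientation-correlation estimator (`estimate_persistence_length`), which
  fits log⟨cosθ(s)⟩ = −s/Lp over separations with ⟨cosθ⟩ > 0.1 and returns
  the freely-jointed floor of 0.5 lu (with a warning) when even adjacent
  bonds are uncorrelated.
- **Equilibration windows.** The 5,000-step pairing burn-in is enough for
  local geometry, but orientation statistics remember the straight initial
  condition for a Rouse time (~50,000 steps at 48 nodes); calibration runs
  for persistence length and Rabl correlation therefore discard the first
  50,000 steps (the analysis honors `burn_in_steps` as the discard window).
- **Fidelity conventions.** `final_fidelity` averages the last 10% of
  recorded frames.  Whole-arm parameter scans are reported in chromosome
  mode (paired to any button of the homolog), barcode-reliability and
  multi-chromosome results in locus mode (paired in register); both are
  always computed.
- **Degenerate inputs.** Chains need ≥2 nodes for spring forces and ≥3 for
  bending; a rigid synthetic chain makes the Lp fit diverge and is reported
  as ≥ contour length with a "rigid" warning; numerical blow-up (non-finite
  coordinates) raises an error naming dt.
- **Discrimination energy** relaxes the two bonded systems (matching codes
  vs rank-order-bonded mismatched codes) with L-BFGS-B on the analytic
  gradient to force tolerance 1e-6, using internal terms only (stretch,
  bending, pairing), so the result is translation/rotation invariant;
  surplus buttons of the longer code stay unbonded.  Mismatched uniform
  5-button codes cost ~12 kBT — several kBT per mismatched interval.
- **Barcode edits.** Inversion (button/gap swap) takes an explicit span so
  that double inversion is an involution; min-gap 2 is enforced by
  constructors but not by the validator, because inversion and
  translocation legitimately produce adjacent buttons (the engine then
  warns that cis neighbours start within capture range).

## Problem sizes in the bundled checks

The test suite and `scripts/acceptance.py` run reduced but honest replicas
of the full 30-run × 300,000-iteration protocol, sized to the method's
convergence: 2-of-5 digit discrimination 10–20 runs × 300k (compact codes
need full annealing); reversibility scan 10 runs × 150–200k per grid point;
random-code survey 8–10 runs × 250–300k per code; Rabl ablation 8–12 runs ×
300k; persistence-length recovery from one chain with ≥1,000 post-discard
frames.  Per-run seeds derive from a single base seed.

## Known limitations

- Whole-arm uniform codes anneal slowly: chromosome-mode fidelity is still
  drifting upward at 300k iterations (~0.75 plateau in the mid-range of the
  reversibility scan), so scan results at desk scale have sizeable run-to-run
  spread, and the reversibility curve is a plateau over p_unpair 0.2–1.0
  with a clear minimum at 0 rather than a sharp interior peak.
- Multivalent error states can be metastable.  Because a freshly broken
  bond whose endpoints are still within the capture radius re-bonds
  immediately, a cluster of several strain-free wrong bonds (e.g. the three
  buttons the 2-of-5 digits 0 and 1 share) can only dissolve if all its
  bonds break and the chains separate within about one iteration — which
  the stability-bounded timestep makes vanishingly rare.  A minority of
  barcode-discrimination runs therefore end cross-locked well below the
  ensemble mean, giving the fidelity distribution a low tail.
- Some random code pairs are intrinsically cross-compatible (several buttons
  at matching genomic offsets) and plateau near 50% fidelity regardless of
  run length, and distal buttons of sparse whole-arm codes are
  contact-search-limited; random whole-arm codes consequently discriminate
  less well here than compact centromere-proximal codes, which are the
  strong performers.
- With ≥8 homolog pairs carrying five-button centromere-proximal codes,
  crowding in the Rabl cap degrades fidelity sharply; the multi-chromosome
  preset is qualitative.
- The mapping of iterations to wall-clock developmental time is not
  derivable from first principles here; `length_unit_um` is the only
  documented unit conversion.
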