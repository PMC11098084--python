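# chrompair

Brownian-dynamics simulation of homologous chromosome pairing driven by
**nonspecific adhesive buttons arranged in chromosome-specific spacing
patterns** — "button barcodes".

## The scientific problem

In *Drosophila* and some other systems, homologous chromosomes pair along
their whole length in somatic cells.  A common explanation posits "buttons":
loci that selectively bind the matching locus on the homolog.  But no
molecular mechanism is known that would give each button its own binding
specificity.  This package simulates an alternative: every button is
*identical* and can stick to any other button, and specificity comes from the
**spacing pattern** of buttons along each chromosome, exactly as an
industrial bar code encodes identity in the widths of its bars.  Pairing two
chromosomes with different spacings forces the intervening polymer segments
to stretch or buckle, so mismatched pairing costs elastic energy and, given
reversible bonds, is eventually edited out.

## Model

Each chromosome arm is a bead–spring worm-like chain of N nodes in a
spherical nucleus of radius R, integrated by overdamped (Euler–Maruyama)
Langevin dynamics:

    x_i <- x_i + (dt/γ) F_i + sqrt(2 kBT dt / γ) η_i,   η_i ~ N(0, I3)

with forces from: Hookean backbone springs (stiffness k_s, rest length 1
length unit = 0.2 µm), a worm-like-chain bending penalty that pulls each
interior node toward the midpoint of its neighbours (k_bend, setting the
persistence length Lp), a harmonic confinement wall at radius R, a tether
that keeps each centromere in a spherical cap around the +z pole of the
envelope (the Rabl configuration), and zero-rest-length springs (k_pair)
between bonded buttons.  Bond kinetics per iteration: every existing bond
breaks with probability `p_unpair`; then all free buttons within the capture
radius are matched greedily, nearest pair first, with no specificity of any
kind — homologous, nonhomologous and cis (same-chain) contacts are all
allowed and treated identically.

Pairing fidelity is the fraction of buttons bonded to the correct homolog,
either to any button on it (*chromosome* mode) or to the identically indexed
button (*locus* mode); unpaired buttons and cis bonds count as incorrect.
The chance baseline with n homolog pairs is 1/(2n) (for 2 pairs: 25%).

Barcodes include uniform spacings (e.g. buttons every 3 nodes on one
chromosome and every 4 on the other), random layouts, and the industrial
"code 2 of 5" symbology, where each decimal digit is five bars, exactly two
wide, mapped onto the chain as inter-button gaps of 6 (wide) or 2 (narrow)
nodes.  Editing operations — shifts, button/gap inversion and reciprocal
translocations — reproduce chromosome-rearrangement experiments.

## Worked example

Pair two homolog pairs carrying the code-2-of-5 digits 0 and 1:

```python
import chrompair as cp
from chrompair.barcode import encode_2of5, gaps_to_barcode

codes = [gaps_to_barcode(encode_2of5(d), start=0, arm_length=48) for d in (0, 1)]
print(codes[0].button_indices)   # (0, 2, 4, 10, 16, 18)
print(codes[1].button_indices)   # (0, 6, 8, 10, 12, 18)

traj = cp.run(cp.SimulationConfig(n_steps=300_000, seed=0), barcodes=codes)
print(round(cp.final_fidelity(traj, "locus"), 3))        # 0.919
print(round(cp.final_fidelity(traj, "chromosome"), 3))   # 0.919
```

Each of the four chains carries six identical sticky buttons; only the gap
patterns differ, yet 92% of buttons end bonded to the matching button on the
true homolog in this run.
Time courses, kymographs (per-locus homolog distance vs time), Rabl
correlation, persistence-length estimates and time-to-90%-pairing are in
`chrompair.analysis`.

Figure-level experiments are packaged as presets:

```bash
chrompair scenario list
chrompair scenario fig3c --runs 10 --steps 150000 --seed 1 --out out/
chrompair barcode encode25 7
chrompair simulate -c config.yaml --out out/
```

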