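# chokepoint

Conformational analysis of substrate-access channels and active-site geometry
in protein structure ensembles, aimed at flavoprotein monooxygenases and any
other enzyme whose buried catalytic site is reached through a tunnel.

Many enzymes — the ubiquinone-biosynthesis hydroxylase family among them —
bury their catalytic site ~14 Å under the protein surface, next to the flavin
isoalloxazine ring. Whether a substrate can reach that site depends on two
things that fluctuate along a molecular-dynamics trajectory: whether the
access channel's choke point is wide enough, and whether the active-site
atoms happen to adopt the geometry seen in substrate-bound homologs
(conformational pre-selection). `chokepoint` quantifies both, frame by frame,
and uses them to pick docking-ready receptor conformations and to classify
channel-blocking mutants.

## The statistics it computes

* **Active-site descriptor score.** From a reference holo structure, a small
  set of site atoms (substrate H-bonding partners plus the reactive flavin
  C4X atom) defines all pairwise distances *d<sub>ij</sub>*(ref). Each frame
  is scored

  S = Σ<sub>i&lt;j</sub> | d<sub>ij</sub>(frame) − d<sub>ij</sub>(ref) |  (Å)

  S = 0 means the frame reproduces the substrate-bound reference geometry;
  low-S frames are catalytically plausible receptors. Deviations are summed
  as absolute values so opposite distortions cannot cancel (a signed mode
  exists for comparison).

* **Tunnel detection.** A clearance field (distance to the nearest
  van-der-Waals surface, Bondi radii) on a regular grid; probe-blocked nodes
  removed; a widest-path search (maximise the minimum clearance) from a
  start point in front of the cofactor to bulk solvent. A boundary node is
  an exit when a 6 Å sphere centred 6 Å outward of it contains no protein
  atoms. Each tunnel reports its centerline, per-point free radius, and
  bottleneck.

* **Choke-point tracking.** For a bottleneck residue pair, the per-frame
  diameter = min over heavy-atom pairs of (center distance − both vdW
  radii). A frame is *open* when the diameter clears a threshold (default
  4.0 Å, roughly aromatic-ring clearance); a channel is *persistently
  blocked* when no frame opens. Salt bridges are flagged by the minimal
  side-chain N–O distance (≤ 4.0 Å).

* **Conservation and residue mapping.** Per-column normalized-entropy
  conservation (1 − H/log 20, gaps excluded), projected onto the structure's
  B-factor column; global affine-gap alignment (BLOSUM62) maps residue
  numbers between homologs — e.g. transferring a disease mutation reported
  in one species onto another's numbering.

* **Assay arithmetic.** Beer–Lambert concentrations, flavin occupancy per
  monomer, NADH oxidation rates, and internal-standard recovery correction
  for lipid extraction losses.

## Worked example

`examples/03_mutant_blocking.py` builds a synthetic breathing channel
(12 frames, gate ring radius 4.0 ± 0.15 Å) and its salt-bridge-blocked
double-mutant analogue, then classifies both:

```
wild-type:
  diameters (A):  5.21  3.83  4.73  4.43  4.46  4.54  3.99  4.53  4.34  5.60  4.67  4.49
  open fraction: 0.83   blocked persistently: False   salt-bridge persistence: 0.00
double mutant:
  diameters (A): -0.07 -0.07 -0.07 ...
  open fraction: 0.00   blocked persistently: True   salt-bridge persistence: 1.00
```

The wild type fluctuates around an open state (83 % of frames clear the 4 Å
threshold); the double mutant's gate surfaces interpenetrate (negative
diameter) behind a permanent salt bridge — the geometric signature of a
channel-blocking double mutation. The other scripts in `examples/` cover
descriptor scoring, tunnel detection, conservation mapping and the assay
arithmetic, each printing the numbers it computes and what they mean.

A thin CLI wraps the same operations:

```
chokepoint simulate --frames 20 --radius 4.0 --out tube.pdb
chokepoint track --ensemble tube.pdb --pair A:248,A:382
chokepoint run --config run.json     # full score→track→classify→select workflow
```

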