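# chearray

Structural analysis of the bacterial chemosensory array and the CheA kinase
conformational switch.

Chemoreceptors in bacteria such as *Thermotoga maritima* and *Escherichia
coli* assemble into large hexagonal membrane-proximal arrays: receptor
trimers-of-dimers (TODs) form a honeycomb with a ~12 nm repeat, coupled at
their cytoplasmic tips by rings of the adaptor CheW and the histidine kinase
CheA.  Cryo-electron tomography of such arrays and all-atom simulations of
the array unit cell raise four recurring computational problems, which this
package implements as a tested, reusable library:

1. **Lattice geometry** (`chearray.lattice`) — build the idealized baseplate
   lattice: TOD honeycomb, three-colored ring lattice (two kinase-filled
   P5/CheW rings and one CheW-only ring per unit cell), CheA dimers bridging
   kinase rings, core-signaling-unit / CheA₂-trimer / CheA₂-hexamer motifs,
   and the hexagonal unit-cell box *a* = *b* = L√3, γ = 120°.
2. **Density-map validation** (`chearray.maps`) — simulate maps from
   coordinates, gold-standard Fourier shell correlation (FSC) between
   half-maps, conical (directional) FSC with 42° cones along 13 standard
   axes, resolution at FSC = 0.143, and anisotropic low-pass filtering
   driven by per-direction resolutions.  MRC2014 I/O via gemmi.
3. **Rigid-body docking** (`chearray.docking`) — exhaustive randomized
   fitting of a domain into a density map (uniform rotations, shifts in a
   ball), two-stage cross-correlation refinement, greedy clustering of fits
   into classes separated by 3° and 3 Å, class occupancy as the
   goodness-of-fit metric, and linker-feasibility checks for candidate
   poses.
4. **Conformational-switch analysis** (`chearray.switch`) — the CheA-P4
   "dipping" pipeline: P5-domain alignment (residues 543–671), PCA on P4
   Cα (residues 352–542), projection onto the dipping mode, detection of
   extended (>10 ns) dip events, UPGMC (centroid-linkage) clustering of
   pairwise-RMSD matrices into state populations, and salt-bridge contact
   occupancy for the state-linked pairs (dipped: R297/E397, E390/R379;
   undipped: D333/K390, D345/R379).

`chearray.synth` generates every input with known ground truth: a labelled
toy CheA-dimer bead model with a two-state Markov dipping hinge, half-map
pairs with isotropic or direction-attenuated noise, multi-state
conformational ensembles, and rigid-fit ensembles around planted poses.

## Worked example

Build the default lattice and read off the printed geometry:

```python
>>> from chearray import lattice as lat
>>> spec = lat.LatticeSpec()            # 120 A repeat, 334 A box height
>>> box = lat.unit_cell_box(spec)
>>> round(box.a), box.c, box.gamma
(208, 334.0, 120.0)
>>> model = lat.build_lattice(spec)
>>> lat.stoichiometry_report(model).counts
{'TOD': 6, 'CheA_dimer': 3, 'CheW': 12, 'P5_domain': 6,
 'kinase_filled_rings': 2, 'chew_only_rings': 1}
```

One unit cell holds six receptor TODs, three CheA dimers and twelve CheW
monomers — three coupled core-signaling units (2 TOD + 1 CheA dimer +
4 CheW each) — in a hexagonal box of 208 × 208 × 334 Å.

Run the dipping pipeline on a synthetic switching trajectory:

```python
>>> import numpy as np
>>> from chearray import switch, synth
>>> model = synth.make_toy_dimer()
>>> traj, truth = synth.generate_switching_trajectory(
...     model, synth.SwitchingParams(seed=7, n_frames=10_000))
>>> aligned = switch.align_trajectory(traj, model.coords, switch.P5_ALIGN)
>>> pca = switch.fit_pca(aligned, switch.P4_CA)
>>> series = switch.project(aligned, pca)
>>> events = switch.detect_dips(series, min_duration=10.0)
>>> len(events) == len(truth.events)
True
```

The projection onto the first principal component separates undipped from
dipped frames; maximal runs on the dipped side become events, and events
longer than 10 ns are flagged extended.

A command-line surface wraps the same operations:

```sh
chearray build-lattice --lattice-constant 120 --cells 3 3 --report model.json
chearray fsc half1.mrc half2.mrc --threshold 0.143
chearray conical-fsc half1.mrc half2.mrc --half-angle 42 --axes default13
chearray dock --map target.mrc --template p4.pdb --resolution 12 \
    --n-starts 10000 --max-shift 20 --seed 7
chearray synth traj --preset mutant --seed 3 --out synth_out/
```

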