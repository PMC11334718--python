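# cntchan — a biomimetic CNT potassium-channel toolkit

`cntchan` is a Python package for studying a *biomimetic potassium
channel*: a (7,7) armchair single-walled carbon nanotube whose wall is
decorated with four rings of five inward-pointing carbonyl (C=O) groups,
mimicking the carbonyl cages of the KcsA selectivity filter.  Such a
channel conducts K⁺ at near-biological rates while discriminating against
Na⁺, and is a standard testbed for understanding selectivity by
coordination chemistry rather than by pore size.

The package is aimed at molecular-simulation practitioners and covers the
full desk-scale workflow around such a study:

* **Model construction** — rolled-lattice CNT coordinates
  (diameter `d = (a_cc√3/π)·√(n²+nm+m²)`), affine axial strain (10% takes
  the 2.45 Å hexagonal-ring period to ~2.7 Å, the KcsA carbonyl-layer
  spacing), excision of the 13.34 Å mid-section, carbonyl decoration
  (20 oxygens in four rows), DFT-style partial charges from a configurable
  table, and assembly into a graphene-membrane / electrolyte box
  (5.1 nm, 0.5 M KCl + 0.5 M NaCl).
* **Synthetic trajectories with ground truth** — stepwise K⁺ hopping over
  the four binding sites S1–S4 with knock-on, the two water-spacing
  permeation modes (mode 1: two waters between consecutive cations,
  mode 2: one), and off-axis Na⁺ traversals, so every analysis operator is
  testable without running MD.
* **Permeation analysis** — event detection, cumulative fluxes, permeation
  rates (slope of the flux staircase, #/s), the K⁺/Na⁺ selectivity ratio
  SR = k_K/k_Na (with a lower-bound convention when no Na⁺ permeates),
  per-site occupancy, mode classification and knock-on annotation.
* **Solvation structure** — ion–oxygen RDFs decomposed into water and
  carbonyl contributions, coordination/hydration profiles with
  first-shell radii 3.6 Å (K⁺) and 3.2 Å (Na⁺), water-dipole orientation
  histograms, and axial/radial/planar densities.
* **Electrostatics** — the axial potential profile from a Gaussian-smeared
  Coulomb sum, `φ(r) = k_e Σ q_i erf(r_i/√2σ)/r_i`.
* **Free energies** — Metropolis umbrella sampling of packaged analytic
  reference profiles (windows −10…10 Å every 0.5 Å, spring
  20 kcal/mol/Å², 300 K) and a self-consistent WHAM solver with barrier
  extraction: the entrance barrier ΔE₁ and first-binding-site barrier ΔE₂.

## Worked example

Build the channel model and reconstruct the K⁺ free-energy profile of the
two-binding-site channel:

```sh
$ cntchan build --out chan
160 atoms, 20 carbonyl oxygens, diameter 0.95 nm

$ cntchan wham --profile k_two_site --seed 3 --out pmf_k.tsv
dE1 = 3.07 kcal/mol, dE2 = 3.41 kcal/mol
```

The first command writes `chan.pdb` / `chan.xyz` (charges in the PDB
B-factor column) and a charge-table sidecar.  The second samples the
packaged K⁺ reference profile with the umbrella protocol, solves WHAM on
0.1 Å bins and reports the two barriers a K⁺ ion must cross to enter the
channel: ~3.1 kcal/mol at the entrance and ~3.5 kcal/mol into the first
binding site (the Na⁺ profile gives ~6.2 and ~6.6 kcal/mol — the origin
of the channel's selectivity).  Equivalent library calls live in
`cntchan.channel_model`, `cntchan.synthetic` and `cntchan.wham`; the
whole pipeline runs via `cntchan run --config examples/demo.yaml`.

## Layout

```
src/cntchan/
  channel_model.py   tube building, strain, decoration, charges, assembly
  synthetic.py       trajectory / umbrella / snapshot generators
  permeation.py      events, fluxes, rates, selectivity, modes, knock-on
  solvation.py       RDF, coordination, hydration, orientation, densities
  electrostatics.py  smeared-Coulomb axial potential
  wham.py            WHAM solver and barrier extraction
  profiles.py        packaged analytic reference free-energy profiles
  io.py              XYZ / PDB / WHAM-metadata / table / config I/O
  pipeline.py, cli.py
```

See `docs/methods.md` for the modelling assumptions, parameter defaults
and numerical choices.
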