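# Methods

This note documents the models, parameter defaults and numerical choices
behind `cntchan`, in the spirit of a simulation-methods section.  Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Channel construction

The channel is an armchair (7,7) single-walled carbon nanotube.  Atoms are
generated on the rolled graphene lattice: chiral vector
`C = n·a1 + m·a2`, translation vector `T` perpendicular to it, atoms
enumerated over the tube unit cell and wrapped onto the cylinder of radius
`|C|/2π`.  The closed-form diameter `(a_cc√3/π)·√(n²+nm+m²)` is exact by
construction and is cross-checked in the tests against the widest x–y
chord of the generated coordinates.

**C–C bond length.** Default `a_cc = 1.415 Å`, chosen so the pristine
hexagonal-ring period `√3·a_cc` is 2.45 Å; the (7,7) diameter is then
0.946 nm (0.95 nm to two figures).

**Ring spacing measurement.** In an armchair tube the atomic z-planes are
spaced `√3·a_cc/2 ≈ 1.23 Å`, but consecutive planes are azimuthally
staggered; the *hexatomic-ring* period quoted for such tubes is the
distance between crystallographically equivalent planes.  `ring_spacing`
therefore clusters wall carbons into z-planes and finds the smallest
inter-plane offset at which the azimuthal atom pattern repeats.

**Strain.** The 10% axial stretch is applied as an exact affine scaling
`z → (1+ε)z` about the tube centre.  A bond-order force-field relaxation
would distribute the strain anharmonically and slightly contract the
radius; the affine surrogate is deterministic, desk-scale, and preserves
the one observable that matters downstream — the ~2.7 Å strained ring
period that matches the KcsA carbonyl-layer spacing.  The 13.34 Å
mid-section can be excised before or after straining
(`strain_before_excision`); the default strains first.

**Carbonyl decoration.** Four layers of five carbonyls are grafted onto
consecutive equivalent wall planes nearest the channel centre (layer
spacing = strained ring period).  Five oxygens on a 14-carbon ring are
incommensurate: the placement minimises the variance of circular gaps by
exhaustive subset search, giving gaps within ~21° of the ideal 72° (mean
exactly 72°).  The C=O bond is 1.23 Å, oriented radially inward in the
carbonyl carbon's z-plane.  Re-decoration of a decorated model is
rejected rather than silently duplicated.

**Charges.** Partial charges are assigned per group tag from a table;
the default is the backbone-carbonyl convention ±0.51 e on the C=O pair
with neutral wall carbons, giving an electroneutral channel.  Any table
can be supplied (e.g. DFT-derived values), and the net charge is
reported.

**Membrane system.** Two porous graphene sheets cap the channel ends
(pore radius = tube radius + 1.7 Å, a bonded-scale rim gap).  Water
oxygens are packed on a jittered cubic lattice at 0.0334 Å⁻³ in the two
reservoir chambers; ion pairs per salt are
`round(concentration · N_A · chamber volume)` and replace random lattice
sites.  The packing clash metric (minimum distance over pairs involving a
solvent particle) is checked against a 2 Å cutoff.  This is a geometric
starting structure, not an equilibrated liquid.

## Synthetic trajectory generator

The generator emulates the *statistical* structure of channel MD so that
analysis operators can be validated against exact ground truth.  It is a
waypoint model, not dynamics: a fixed five-particle roster (two K⁺, one
Na⁺, two water tracers) moves piecewise-linearly between stations (bulk,
inlet, S4…S1, outlet) and is sampled every `frame_dt = 0.01 ns`.

* K⁺ events hop bulk → S4 → S3 → S2 → S1 → bulk with exponential dwells
  (mean `1/hop_rate`, default 0.125 ns, clipped to [2·dt, 8·mean]);
  optionally the per-site means are Boltzmann-weighted by a reference
  profile evaluated at the site positions.
* During the S4 dwell a partner K⁺ from the upper reservoir transiently
  occupies S1 with the event's water tracers spaced between the two
  cations — two waters for mode 1, one for mode 2 — then returns upward.
  Because the partner never crosses the entrance plane it is not a
  permeation event, so the ground-truth event count equals `n_events`
  exactly under the maximal-crossing event definition.
* Na⁺ events enter off-axis (default 2 Å from the axis), bind S3, and
  advance to the exit only after an incoming K⁺ arrives at S4 behind
  them; the knocker retreats without permeating.
* Defaults encode the mixed-solution low-field condition:
  `mode1_prob = 0.76`, `na_fraction = 1/2000` (Na⁺ traversals are rare at
  low field), K⁺ on-axis within 0.3 Å.

What the generator does **not** emulate: absolute permeation rates
(real channels conduct at ~10⁷ #/s, which sets only the time axis here),
thermal positional noise, hydration-shell physics, field-dependent
kinetics, or correlated multi-ion files longer than two cations.  Tests
passing on this generator therefore validate the *operators* (detection,
classification, normalisation), not MD phenomenology.

## Umbrella sampling and WHAM

`generate_umbrella_samples` draws from each window's biased density
`∝ exp(−[U(z) + k/2 (z−z_i)²]/k_BT)` with a vectorised Metropolis chain
(proposal scale 1.5·√(k_BT/k)); the first half of each chain is discarded
as burn-in — mirroring the equilibration half of an umbrella window — and
the production half is thinned 8× so the kept `samples_per_window`
(default 10⁴) are nearly uncorrelated.  The sampler is validated against
closed forms: flat potential variance `k_BT/k`, and combined-spring
variance `k_BT/(k+κ)` under a harmonic landscape.

The WHAM solver iterates the standard self-consistency equations in log
space on 0.1 Å bins until window free energies move by less than
10⁻⁶ kcal/mol (`k_B = 0.0019872 kcal/mol/K`, T = 300 K).  The histogram
support range is set by per-window 0.1/99.9% quantiles so single outlier
samples cannot open spuriously empty bins; a genuine gap in support flags
non-overlapping ladders.  The PMF is zeroed on the mean over the 2 Å
nearest the entrance-side boundary.

**Barrier extraction** smooths the profile with a 5-point moving average,
locates maxima with a 0.3 kcal/mol prominence floor (ties toward smaller
z) and reports ΔE₁ = first maximum − bulk level and ΔE₂ = second maximum
− intervening well, then inter-site and exit barriers in order.  The
5-point smoothing attenuates sharp peaks by ~0.1–0.2 kcal/mol (measured
on the analytic profiles); reconstructed ΔE₂ values are therefore
slightly conservative.  ΔE₂ is measured from the preceding local well,
not the bulk plateau — the convention is configurable.

**Packaged reference profiles.** `na_two_site` and `k_two_site` are
shape-preserving cubic (PCHIP) interpolants through knots that encode the
two-binding-site channel's barriers — ΔE₁/ΔE₂ = 6.2/6.6 kcal/mol for Na⁺
and 3.1/3.5 kcal/mol for K⁺ — plus the qualitative features reported with
them (the Na⁺ inter-site barrier is lower than K⁺'s; exit barriers are
similar).  PCHIP is used instead of a natural cubic spline so knot
extrema are exact and no spurious stationary points appear.  A
second restrained ion in the original umbrella protocol is treated as
part of the 1-D reference landscape rather than an explicit degree of
freedom.

## Analysis conventions

* **Events**: a traversal runs from below `entrance − buffer` to above
  `exit + buffer` (buffer 2 Å — the published protocol does not state its
  crossing planes); an ion must return below the entrance buffer before a
  new event can start, guaranteeing single counting.
* **Sites**: S1–S4 are the carbonyl-layer planes, tolerance = half the
  layer spacing; positions between layers report as "inter-site" rather
  than as extra sites.
* **Modes**: per frame with the event ion in-channel and the nearest
  cation above it in-channel, the water tracers strictly between the pair
  are counted; the event label is the modal count.  The modal-count rule
  is this package's operationalisation for events with transiently
  varying water counts.
* **Knock-on**: a site advance is annotated when another cation sits
  within 6 Å below the advancing ion (recently arrived, window 20
  frames).  The 6 Å default accommodates an incoming ion at S4 displacing
  one bound at S2 (5.4 Å).
* **Rates**: least-squares slope of the cumulative flux vs time, with
  count/duration reported alongside; with zero Na⁺ events the selectivity
  ratio substitutes one pseudo-event over the observation time and is
  flagged a lower bound.
* **RDF**: normalised by shell volume and a partner density measured in a
  user-chosen bulk region, since confined-geometry RDFs are not globally
  normalisable — in-channel curves are shape-only.  First minimum: first
  local minimum after the global peak of the 3-point-smoothed total
  curve, ties toward smaller r.
* **Orientation**: the water dipole is the O → (H,H midpoint) vector,
  measured against +z (the field direction) by default; the supplementary
  OH-vector convention is switchable via `reference_axis`.
* **Densities** integrate to the mean in-domain particle count per frame;
  radial profiles are annulus-normalised; planar maps use in-channel
  frames (|z| ≤ half-length).
* **Electrostatics**: vacuum, non-periodic Gaussian-smeared Coulomb sum
  (σ default 1 Å), kT/e at 300 K by default.  The target is the interior
  profile shape of the bare channel; solvent screening and periodic
  electrostatics are out of scope.  The disc-averaging radius for the 1-D
  profile is configurable (default on-axis).

## Problem sizes

Defaults were chosen as the smallest sizes at which the statistical
claims are sharp: 41 umbrella windows × 10⁴ kept samples per profile
(round-trip recovery RMSD ≈ 0.05–0.1 kcal/mol, well under the
0.3 kcal/mol acceptance band), 2000 events for the mode mixture
(binomial σ ≈ 0.95 percentage points), 200-event fixtures for operator
oracles.

## Known limitations

* The generator's kinetics are schematic; only proportions, orderings and
  geometric structure are meaningful, never absolute rates or energies.
* The builder's carbonyl geometry (1.23 Å C=O, radially inward, ±0.51 e)
  is a convention; published DFT charge sets for this channel are not
  reproduced here and should be supplied via the charge table when
  available.
* WHAM error estimation (bootstrap) is not implemented; round-trip RMSD
  against the analytic references serves as the accuracy measure.
* The membrane system is a packing, not an equilibrated ensemble, and
  water in trajectories is a tracer species without hydrogens.
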