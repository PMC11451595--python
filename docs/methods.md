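# Methods

This note defines the geometric model, the stochastic generator and its
calibration, and the statistical conventions used by the analyses. All
lengths are in Å, times in ns or μs as stated, energies in kcal/mol, and
rates in events per μs.

## 1. Pore frame of reference

The pore axis runs through the centroids of the four V409:Cβ atoms
(intracellular anchor) and the four Y376:Cβ atoms (extracellular anchor);
the origin is the midpoint of the two centroids and the direction points
extracellularly. Every position is reduced to an axial coordinate z
(projection on the axis) and a radial coordinate r (perpendicular distance
to the axis). These coordinates, and therefore all analyses, are invariant
under rigid motions applied jointly to scaffold and trajectory.

Five reference oxygen planes span the selectivity filter: the backbone
carbonyls of Y376, G375, V374, T373 and the T373 hydroxyl (Oγ1). Each
plane offset is the mean axial projection of its four oxygens. The
compartment vocabulary, ordered extracellular → intracellular, is

```
EXT | S0 S1 S2 S3 S4 | SCAV CAVITY | GATE | CYTO
```

* **S0** lies between the Y376:O plane and a ceiling one mean inter-plane
  spacing above it; **S1–S4** lie between consecutive planes.
* Axial intervals are half-open **(lo, hi]**: a position exactly on a
  plane belongs to the more intracellular site.
* Filter-site labels additionally require r ≤ 6 (the 12-Å analysis
  cylinder); otherwise the position is cavity-adjacent (**CAVITY**).
* **S_cav** is centered midway between the T373:Oγ1 plane and the midpoint
  of that plane and the gate; the label requires |z − z_scav| ≤ 2 and
  r < 3.
* **GATE** is a 2-Å band below the S6 bundle-crossing marker (P408:Cα
  plane); **CYTO**/**EXT** are the reservoirs beyond.

On the default scaffold the planes sit at z = 14.0, 11.2, 8.4, 5.6, 2.8,
the gate at −10, S_cav at −0.4, and the S0 ceiling at 16.8.

## 2. Knock-on automaton

The generator is a continuous-time Markov automaton over compartments,
sampled with the Gillespie algorithm (exponential waiting times; a single
`numpy` Generator seeded by the mandatory `seed`). The resting state holds
three ions at S1/S3/S4. Transitions:

| channel | rate | effect |
| --- | --- | --- |
| load | k_enter·B/a | CYTO → S_cav (pore must be free) |
| return | k_return | S_cav → CYTO |
| eject | k_eject·B | concerted: S1→EXT, S3→S1, S4→S3, S_cav→S4 |
| top entry | k_enter/B | EXT → S0 (pore must be free) |
| S0 return | k_return | S0 → EXT |
| inward eject | (k_eject/B)/a | concerted mirror: S4→CYTO, file shifts down |

with voltage boost B = exp(V/V₀) (V₀ = 50 mV) and attenuation a = 4 in
RY785 mode (a = 1 otherwise). The mirrored pathway makes the net flux
vanish at 0 mV by construction. Each outward ejection advances every ion
one slot, so a tagged ion needs exactly **4 cycles** (S_cav→S4→S3→S1→EXT)
to cross.

**TEA mode**: binding (200/μs) requires an applied voltage and a free
pore; the bound state abolishes cytoplasmic loading and, at V > 0, is
absorbing. Unbinding (2/μs) occurs only at 0 mV, and rebinding is
impossible without a field.

**Calibration.** The automaton between ejections is a renewal process:
wait for a load (mean 1/(k_enter·B)), then resolve (mean 1/k_res with
k_res = k_eject·B + k_return), with ejection probability
p_e = k_eject·B/k_res per attempt. The mean inter-ejection interval is
T = (1/p_e)(1/(k_enter·B) + 1/k_res). With k_return = 180/μs,
k_eject = 12/μs and V = 100 mV, solving T = 24.5/45 μs for the entry rate
gives k_enter ≈ 0.769/μs (`calibrate_k_enter`, closed form). The expected
uninhibited/RY785 rate ratio at these defaults is T_RY/T_free ≈ 3.94, so
the 4-fold attenuation is recovered within bootstrap uncertainty.

**Induced knock-on protocol** (0 mV only): at t_pull the outermost ion is
ejected, the central ion takes its place and the innermost moves to the
filter center, leaving S4 vacant. During the follow-up window a
cytoplasmic ion reloads S4 at a separate rate k_reload = 280/μs, divided
by the RY785 attenuation or blocked entirely while TEA is bound (the
median RY785 reload latency is ln 2 · 4/280 μs ≈ 10 ns).

## 3. Coordinate emission

Frames are sampled on a uniform grid (default 1 ns). Each ion sits at its
compartment's on-axis center plus isotropic Gaussian noise (σ_z = σ_xy =
0.5). The TEA nitrogen proxy sits 1.5 Å below the S_cav center with
lateral spread σ = 0.8 while bound (Rayleigh 95th percentile
σ√(−2 ln 0.05) ≈ 1.96 Å), and far below the gate when free. The RY785
proxy is a rigid three-site body (ring carbon, thiadiazole sulfur,
benzimidazole nitrogen) parked against the S6 wall at a subunit interface
(45° between subunit axes) with a small rigid-body jitter (σ = 0.25); its
C/S atoms produce the modal contact pattern V398/I401/P406 in two
subunits and I405/V409 in one.

## 4. Analyses

**Permeation events.** Per-ion label series are stored compactly at
change points. A complete outward event requires the label to reach EXT
with z at least 1 Å above the S0 ceiling (hysteresis against boundary
jitter) after having visited a filter site; the entry time is the last
cytoplasmic departure, or t = 0 for ions that start inside the pore.
Inward events mirror this below the gate floor. On exact event-log series
the detector count equals the generator's ejection count identically.

**Conductance** g = N·e/(t·V) in pS, from CODATA constants; the worked
example (45 events, 24.5 μs at 100 mV) gives 2.9428 pS.

**Filter occupancy** counts ions in S0–S4 per frame (S_cav excluded); the
uninhibited modal occupancy is 3.

**Rate ratios** use a seeded percentile bootstrap (10,000 resamples):
renewal (interarrival) resampling when event times are supplied, Poisson
resampling for bare counts; a zero denominator yields NaN.

**Contacts.** A contact is a ligand C/S atom within 4.5 Å (inclusive) of
an S6 side-chain carbon of V398/I401/I405/P406/V409. The headline
statistic is the number of distinct subunits contacted per residue per
frame; neighbor search uses a k-d tree, validated in the tests against a
brute-force distance matrix.

**Density.** The axial K⁺ profile is a per-bin count inside the 12-Å
cylinder, normalized by frames × bin volume × bulk number density, so 1.0
means bulk concentration (default 300 mM); a uniform input at bulk density
normalizes to 1 everywhere.

## 5. Restraints and units

* **Dihedral bias** U(θ) = k Σ_{m=1..6} (1 − cos mΔ)/m!, Δ = θ − θ_ref,
  k = 1 k_BT at 298 K (0.5922 kcal/mol from CODATA constants). It is
  non-negative, 360°-periodic, even in Δ, and zero and stationary at the
  reference; U(Δ=180°) = 2.35 k exactly. A literal alternating-sign
  variant is selectable but not the default, since its minimum lies at
  Δ = 180°, contradicting a bias that favors the reference structure.
* **Flat-bottom confinements**: zero inside d₀ and ½k(d−d₀)² beyond, C¹
  at d₀; radial about the pore axis (d₀ = 10, k = 100) and axial about
  the V409:Cβ center (d₀ = 15).
* **Knock-on pull**: harmonic pull of the central filter ion toward the
  Y376/G375 carbonyls, target 3 Å, k = 3, activated at 100 ns.
* **Voltage/field**: 1 kcal·mol⁻¹·Å⁻¹·e⁻¹ = 43.364 mV/Å (computed from
  constants, rounds to 43.4); a constant field E = (V/L)/43.364 reproduces
  a transmembrane voltage V over a box of length L.

## 6. Reproducibility

All stochastic behavior derives from explicit integer seeds through
`numpy.random.default_rng`; identical configuration and seed give
byte-identical event logs and trajectories. The acceptance script
(`scripts/acceptance.py`) derives independent sub-seeds below 2³¹ from its
`--seed` argument and writes both target statistics with their sample
sizes.
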