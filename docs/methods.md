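# Methods

This note documents the estimators, their defaults, the numerical
choices behind them, and the scope of the synthetic ground-truth
generator. Everything stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external runs.

## Conventions and data model

The membrane normal is fixed to the z-axis and boxes are orthorhombic —
the standard setup for planar bilayer simulations; no normal estimation
is attempted. Lengths are nm, times ps, charges in elementary-charge
units. Coordinates are stored wrapped into the primary box; continuous
coordinates for the MSD are produced by an explicit unwrapping step.
Atom indices are 0-based internally and 1-based in file I/O (GRO/PDB
convention). GRO is the canonical plain-text fixture format (structure
and multi-frame trajectory, parsed with mdtraj); PDB is read-only and
converted from Å to nm on input.

Chemical identity (role, chain position, partial charge, mass, labels
such as `terminal`/`unsaturated`) comes from a user-editable YAML
species map keyed by residue and atom name, because bespoke lipid force
fields are usually not deposited with their papers and which atoms
constitute "the headgroup" is a per-lipid modelling decision the user
must make explicit. Each lipid must be net neutral (to 1e-6 e) and its
sn1/sn2 carbon indices contiguous from 1.

An analysis window `(t_start, t_end)` restricts all averages; it
defaults to the full file and is typically set to the equilibrated tail
of a production run (e.g. its final 100 ns).

Leaflets are assigned from the first analysis frame: the midplane is the
mean z of all lipid atoms, and a lipid is `upper` when the mean z of its
head atoms exceeds it. Lipids without head atoms stay `unassigned` with
a warning.

## Density profiles and thickness

Profiles are accumulated in midplane-centered coordinates: per frame the
midplane is recomputed from the lipid-atom mean z and coordinates are
shifted so it sits at z = 0 before binning. This cancels slow drift of
the bilayer along the normal that would otherwise smear the headgroup
peaks over long windows. The histogram grid is fixed on the
analysis-window mean box (semi-isotropic barostats make lz fluctuate;
per-frame re-gridding would introduce its own artifacts). The default
bin width is 0.05 nm — fine enough to resolve headgroup peaks at the
0.01 nm reporting precision customary for thickness tables without a
noise blow-up; a trailing partial bin is dropped with a warning.

Thickness is the distance between the two maxima of the smoothed head
density (centered moving average, default 5 bins), one per side of the
midplane; no sub-bin interpolation is applied, for strict
reproducibility, so the estimate is accurate to one bin. The uncertainty
is a block estimate: thickness recomputed on contiguous frame blocks
(default 5) and the standard error of the block values reported.

**Lamellar guard.** A profile qualifies as a bilayer only if (a) both
sides of the midplane carry head density and (b) the mean density over
the central half of the peak-to-peak span is below 0.35 of the smaller
peak. The mean (not the minimum) makes the criterion robust to Poisson
zeros in sparse histograms: a uniform scatter of heads has central mean
≈ its noise "peaks" (ratio ≈ 0.4–0.5) and is rejected, while any layered
profile with a depleted core passes. Non-lamellar inputs raise
`NoBilayerError("no bilayer peaks …")` rather than return a number —
aggregates that collapse away from the lamellar phase must be excluded
from thickness tables, not averaged into them.

## Electrostatic potential

The charge density ρ(z) is the sum of partial charges per slab over slab
volume (e nm⁻³). The 1-D Poisson equation is integrated twice with
cumulative trapezoids over the bin centers, V = 0 fixed at the profile
origin (the box start), and the result converted to volts with
ε₀ = 8.8541878128e-12 F/m and e = 1.602176634e-19 C.

Published tables rarely state which functional of V(z) their single
"potential difference" is. Two conventions are provided:
`center_vs_bulk` (default) — V at the profile center minus the mean over
the outermost 1 nm of each side; and `max_minus_min`. Both are reported
as magnitudes, and for a symmetric bilayer they agree to bin resolution.
The implementation is validated against the parallel-plate closed form
(plateau ΔV = σd/ε₀, exact to numerical precision at 0.01 nm bins) and
by the charge-neutrality consequence that V is flat in both bulk
regions.

## Chain order

S_CD(n) = ½⟨3cos²θ − 1⟩ with θ the angle between the membrane normal and
the minimum-image chord from carbon n−1 to carbon n+1; terminal carbons
have no chord and are omitted, not extrapolated. S is reported exactly
as defined — no sign flip or absolute value — since plotted conventions
(−S_CD) vary; the caller owns any sign convention. Averaging is
lipids-within-frame first, then block statistics over the per-frame
means: lipids within a frame are correlated, and blocks absorb time
correlation.

## Packing and diffusion

Area per lipid is `<lx·ly>/N_leaflet` over the window; packing density
is its exact reciprocal (the product is 1 to machine precision by
construction). The per-leaflet count comes from leaflet assignment or
can be set explicitly for mixed compositions.

For diffusion, each lipid is reduced to its (mass-weighted,
minimum-image-aware) center of mass; tracks are unwrapped by
accumulating minimum-image steps between consecutive frames, which
requires frame spacing fine enough that no lipid moves half a box edge
between frames (violations raise). Per-leaflet center-of-mass drift is
subtracted per frame — collective drift otherwise inflates D — and the
positions rescaled by √(N/(N−1)) to undo the variance shrinkage that
subtracting the mean of N lipids causes. The MSD uses all sliding
origins (configurable stride), and D = slope/4 from an ordinary
least-squares line over the 10–50 % fraction of the maximum lag (default
max lag: half the window), skipping short-lag transients and the noisy
long-lag tail. A negative fitted slope reports D = 0 with a warning
rather than silently. Units: nm²/ps → cm²/s is a factor 10⁻².

Uncertainties: block averaging,
`stderr = std(block means)/√n_blocks` (population std), with replicate
trajectories treated as additional independent blocks rather than
concatenated in time.

## Chain distances and RDFs

Intramolecular distances are minimum-image even within one molecule
(wrapped tails can straddle the box). Pair members are declared with
small selectors (atom name, `role:`, `sn1:k`, `label:`); a selector must
match exactly one atom per lipid, except that an identical selector pair
(e.g. terminal–terminal across the two tails) may match exactly two.

The RDF counts ordered inter-lipid pairs under the minimum image,
normalized per frame by N_a, the shell volume (4πr²dr, or 2πr·dr with an
areal density in lateral mode) and the ideal-gas density of the b
selection; r_max is capped at half the smallest box edge. The default
dr = 0.002 nm matches two-decimal nm reporting with ~0.001 nm standard
errors. The "average intermolecular chain distance" is read as the first
local maximum of the smoothed g(r) above 1 — the standard
nearest-neighbor-shell reading — with a plateau tie-breaking to the
lower-r bin; a count-weighted first-shell mean is available as an
alternative estimator. `end_to_end_length` measures a plain straight-line
distance on a single provided conformation (for the "twice the extended
lipid length ≈ bilayer thickness" comparison).

## Synthetic generator

The generator emulates the statistical structure of an equilibrated
two-leaflet bilayer while keeping all observables closed-form:

- lipids on a jittered square lattice (default 75 per leaflet in a
  6.1 × 6.1 × 24.1 nm box, matching a typical 150-lipid simulation);
- head beads at ±d/2 with Gaussian z-jitter (σ = 0.1 nm default;
  d = 6.3 nm default, a typical ionizable-lipid bilayer thickness);
- two tails per lipid, bead chains descending toward the midplane; all
  segments of a tail share one azimuth, so the carbon-n chord tilt is
  exactly the mean of its two segment tilts and
  S_CD(n) = ½(3cos²θ(n) − 1) exactly. The default schedule rises
  linearly 10°→50° along the chain, giving the monotonically decaying
  S_CD profile characteristic of acyl tails;
- a ±q charge-bead pair per head (+q inner, −q outer; q = 0.046 e,
  half-separation 0.15 nm) forming a neutral dipole bilayer whose
  plateau ΔV = σ·2δ/ε₀ ≈ 0.50 V — the half-volt scale typical of lipid
  bilayers;
- rigid-lipid lateral Brownian motion with per-component step variance
  2·D·dt (default D = 0.1×10⁻⁷ cm²/s, dt = 50 ps), so MSD(τ) = 4Dτ in
  expectation and the true unwrapped tracks are stored;
- deterministic for a fixed seed (integer lattice plus one seeded
  Gaussian stream).

A `nonlamellar_variant` scatters heads uniformly in z to exercise the
lamellar guard.

**What the generator does not emulate** — and hence what passing tests
do *not* show about real data: no excluded volume or interactions (over
long spans the Brownian motion washes out the constructed lattice pair
structure, so structural observables such as RDF peaks are measured over
windows short against that relaxation), no internal chain dynamics
(bond/dihedral fluctuations), no box fluctuations or barostat coupling,
no explicit water (profiles are invariant to zero-charge filler by
construction), and Gaussian rather than correlated, hydrodynamic
lateral motion. Recovery of ground truth validates the estimators, not
any force field.

## Problem sizes used in validation

Analytic checks run on constructed profiles (sub-second). Parameter
recovery uses 32–150 lipids and 20–60 frames for structural observables,
100 lipids × 1000 frames for diffusion (stochastic scatter a few
percent, tested to a 10 % band), and 10⁵ chains for the isotropic-limit
order-parameter check. `scripts/acceptance.py` uses the default system
at 800 frames (40 ns of 50 ps frames).

## Known limitations

- Thickness resolution is one histogram bin; enable finer bins rather
  than interpolation if sub-bin precision is needed.
- The MSD fit window is a convention; strongly subdiffusive real data
  would need an anomalous-exponent analysis that is out of scope.
- Lateral-mode RDF assumes leaflet-wise homogeneity; no finite-size
  (hydrodynamic) diffusion corrections are applied.
- Triclinic boxes, bond-based topology perception, and force-field
  handling are out of scope.
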