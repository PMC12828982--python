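# Methods

This note documents the models, the synthetic study conditions, and the
numerical choices behind `proteomicelle`.

## Thermal melt model

Melting curves are modelled as a logistic transition between two sloped
baselines,

    y(T) = b_low(T) + [b_high(T) - b_low(T)] / (1 + exp((Tm - T)/s)),
    b_low(T) = a_low + m_low*T,    b_high(T) = a_high + m_high*T.

This is the standard six-parameter "Boltzmann" sigmoid whose named
parameters (two asymptotes, two baseline slopes, Tm, transition slope) map
one-to-one onto how melt fits are reported for membrane proteins. The
reported "slope" is the parameter `s` in deg C — smaller values mean a
sharper, more cooperative unfolding transition. Melts are normalized
between their endpoint signals so the lowest-temperature point maps to 1
(folded) and the highest to 0; on that scale a constrained
high-temperature asymptote such as 0.07 is meaningful. Endpoint (raw)
values, not fitted asymptotes, define the normalization.

Fitting is deterministic trust-region least squares (SciPy `least_squares`,
`trf`, tolerances 1e-10, at most 1e4 evaluations). Initialisation is
derivative-free and deterministic: the transition midpoint starts at the
steepest point of a running-mean-smoothed curve (edge windows excluded,
since the running mean is biased there), the slope from the peak
derivative via s0 = span/(4 max|dy/dT|), and the asymptotes/baseline
slopes from straight-line fits over the outer 10% of points. Because a
single gradient-based start can fall into a baseline-only local minimum on
noisy data, three additional fixed starts (transition midpoint at 25/50/75%
of the temperature range) are evaluated and the lowest-residual solution
kept; there is no random restarting. `Tm` is bounded to the fitted
temperature range and `s > 0`. Standard errors come from the Jacobian at
the optimum with residual-variance scaling; constrained parameters are
returned exactly with SE 0. Per-fit SEs and across-replicate SDs answer
different questions, and batch outputs carry the per-fit SE so replicate
SDs can be formed downstream.

## Steady-state binding model

BLI steady-state responses are fitted to the exact single-site
mass-balance (the "quadratic" ligand-depletion equation) plus a linear
nonspecific term: y = Rmax * f(Rt; Lt, Kd) + ns * Rt. The bound fraction is
evaluated in the algebraically equivalent form 2Rt / (b + sqrt(b^2 -
4*Rt*Lt)), b = Rt + Lt + Kd, which is numerically stable for small Lt and
reduces smoothly to Rt/(Rt + Kd) as Lt -> 0. The immobilized ligand
concentration Lt is a design constant, never fitted. Confidence intervals
are asymptotic (Student t on the Jacobian SE) and labelled as such in the
output. Kd estimates are invariant under rescaling of the response axis
(Rmax and ns absorb the scale).

## Partitioning calculus

The detergent-driven component of stability is proxied by the apo tertiary
melting temperature and the ligand-driven component by the ligand-induced
tertiary Tm shift; both are normalized to a reference detergent (DM by
default), giving dimensionless `conf_rel` and `ligand_rel` per detergent.
Two deliberate conventions:

* Ratios are taken on the **Celsius scale as reported** — Kelvin ratios
  would compress the spread (e.g. 330.9/309.1 = 1.07, not 1.6) and would
  not reproduce the published trend values. These proxies are relative
  trend indicators, not absolute free energies, and no van't Hoff /
  calorimetric conversion of Tm shifts into kJ/mol is attempted anywhere.
* Presentation rounding is one decimal for ratios and Tm shifts, two
  decimals for correlation slopes and r^2; full precision is kept
  internally (0.141... rounds to 0.1).

Cross-level and energy-vs-stability correlations are ordinary least
squares with r^2 = 1 - SS_res/SS_tot.

## Synthetic study conditions

The generators define the conditions under which the pipeline is
exercised and tested:

* **Melts** — 5 to 100 deg C at 0.2 deg C intervals (a CD-style ramp, 476
  points), additive Gaussian noise of 0.02 on the normalized signal.
  Recovery studies use 200 seeded replicates.
* **Binding** — a duplicate two-fold dilution ladder from 200 nM plus a
  buffer blank (20 points), Lt = 5 nM, Gaussian noise of 1% of Rmax; this
  mirrors a standard BLI dilution-series design with typical instrument
  noise. Recovery studies use 200 seeded replicates.
* **Proteomicelle** — an ideal alpha-helical bundle (default 7 helices x 24
  residues; backbone N/CA/C/O built by natural-extension from phi = -63,
  psi = -42, omega = 180 and standard bond geometry, giving a rise of
  ~0.154 nm/residue) wrapped in coarse bead-chain detergents (4 tail + 2
  head beads, heads outermost, 0.18 nm spacing) placed on equator-biased
  directions, since a micelle wraps the hydrophobic span rather than the
  helix ends. Default 25 frames.

Detergent dynamics have two modes. Without a persistence profile, each
detergent performs a seeded Gaussian random walk of step `mobility_sd`
about its shell anchor, with the radius reflected into the shell — so
`mobility_sd = 0` yields exactly zero detergent RMSF. With a per-detergent
`persistence_profile`, each frame places each detergent either at a
protein-contact position (0.30 nm from the nearest bundle atom along its
ray) or at a detached position radially outward on the same ray, by an
independent seeded Bernoulli draw; empirical contact persistence then
tracks the target within binomial sampling error. The detached position is
extended outward until it clears the whole bundle, because an
outward-shifted anchor near an inter-helix groove can otherwise remain in
contact with a neighbouring helix. Per-detergent randomness uses
`SeedSequence.spawn` substreams, so results are independent of iteration
order.

The toy DM -> DDM -> LMNG series encodes the qualitative detergent
chemistry in three dials: shell tightness (packing radius 2.8 / 2.5 /
2.1 nm), mobility (0.05 / 0.03 / 0.015 nm per frame) and contact
persistence (0.12 everywhere / a mixed pool of 0.1 and 0.9 / 0.95
everywhere). These straddle the 20% persistence threshold so residual
hydrophobic mismatch decreases along the series while near-protein RDF
density increases and detergent RMSF decreases — the orderings the
analysis is expected to resolve. What passing these checks shows is that
the metrics rank shells correctly by density, mobility and coverage; it
does not validate force-field realism, absolute energies, or all-atom
detergent geometry, none of which the toy attempts.

## Trajectory metrics: numerical choices

* **Coordinates** in nm throughout; PDB/XYZ Angstroms converted at I/O.
* **Superposition** is Kabsch (via SciPy's quaternion solver). RMSF
  superposes frames onto frame 0, then onto the resulting mean structure,
  before measuring fluctuations.
* **Helicity** uses a Ramachandran-window surrogate: a residue is helical
  when phi in (-100, -30) and psi in (-80, -5) degrees within a run of at
  least 4 consecutive such residues of one helix; residues with undefined
  phi/psi (termini) never count. This deliberately approximates
  secondary-structure assignment tools without reimplementing them.
* **Micelle eccentricity** is shortest/longest principal axis of the
  mass-weighted gyration tensor (axes 2*sqrt(eigenvalue)), so 1 = sphere.
  The short-over-long orientation keeps the value in (0, 1]; collinear
  inputs return 0 with a degenerate flag.
* **RDF** bins shell-atom distances from the instantaneous core center of
  mass (default bin 0.02 nm), normalized per bin by 4*pi*r^2*dr and by the
  shell selection's mean number density inside the analysis sphere
  (default r_max 3.5 nm), averaged over frames. With this ideal-gas
  convention a uniformly filling selection gives g = 1 and g is invariant
  to a uniform rescaling of the shell atom count; near-protein density
  differences therefore reflect the *shape* of the radial distribution,
  which is also why micelle density comparisons are driven by shell
  compactness rather than molecule count. The 2 nm AUC is a trapezoid
  integral.
* **Interaction energy** is a plain-cutoff (default 1.2 nm) pairwise sum of
  Coulomb (f = 138.935458 kJ mol^-1 nm e^-2) and Lennard-Jones terms with
  Lorentz-Berthelot combination — the "short-range" decomposition contract,
  with no switching function, PME, or long-range corrections. Atoms
  lacking charge or LJ parameters cause a refusal, never a silent zero.
* **Contacts** use a closed boundary (distance <= cutoff counts); pair
  frequencies pool frames with equal weight. Persistence thresholds are
  strict: "> 40%" excludes exactly 40%, "< 20%" excludes exactly 20%.
  Interhelical analysis is atom-pair granular; ligand maps default to
  residue pairs. Hydrogen bonds require donor-acceptor <= 0.35 nm and an
  H-D-A angle <= 30 deg (hydrogens attached to the nearest same-residue
  heavy atom within 0.13 nm); vdW contacts are heavy-atom pairs <= 0.45 nm
  excluding same-frame hydrogen bonds. These geometric cutoffs are common
  MD-analysis defaults and are overridable.
* **SASA** is Shrake-Rupley with a deterministic golden-spiral point set
  (default 960 points), probe 0.14 nm, element radii C 1.7 / N 1.55 /
  O 1.52 / S 1.8 / H 1.2 / P 1.8 Angstrom. Residual mismatch sums the
  frame-averaged SASA (protein atoms as occluders) of hydrophobic TM
  residues (G, A, P, V, M, C, I, W, F, Y, L) whose detergent-contact
  frequency is strictly below 20%. Trajectory-averaged mismatch checks use
  240 sphere points and a frame stride of 5, which keeps the quadrature
  error well below the inter-condition differences being resolved.

## Known limitations

* The toy proteomicelle has no physical dynamics: no forces, thermostat,
  solvent, or periodic boundaries (the shell is kept intact by radial
  reflection instead). Absolute energies and areas are not comparable to
  all-atom systems; only relative and rank statements are meaningful.
* The helicity criterion is a dihedral-window surrogate, not a full
  secondary-structure assignment; it agrees with the construction of the
  ideal bundle but will differ from assignment tools near helix ends.
* Binding analysis is steady-state only; association/dissociation kinetics
  of the underlying traces are out of scope.
* SASA treats only the protein as occluder when averaging mismatch, so
  detergent shadowing of non-contact residues is not modelled; the
  persistence filter, not occlusion, carries the detergent dependence.
* The printed reference tables carry the published uncertainties but the
  package does not propagate them through the partitioning ratios.
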