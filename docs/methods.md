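# Methods

This note records the models, geometric conventions, numerical choices and
limitations behind nanopep's analyses. Units are angstrom, degrees,
kcal/mol and kelvin unless stated; the umbrella force constant is kept in
its conventional kJ mol⁻¹ nm⁻² and converted internally (1 kcal = 4.184 kJ
exactly; 1 nm² = 100 Å²).

## Nanomaterial models

All three surfaces are ideal, rigid, carbon-only lattices — appropriate
because in the simulations being analyzed the nanomaterial is restrained,
so its geometry is a fixed template rather than a dynamical object.

**C60.** A truncated icosahedron built analytically: a regular icosahedron
of edge L is truncated at fraction t from each vertex along every edge.
The surviving middle segment of an edge is a bond shared by two hexagons;
the cut corners become pentagons. Requiring the hexagon–hexagon bond to be
1.40 Å and the pentagon edge 1.46 Å gives L = 1.40 + 2·1.46 = 4.32 Å and
t = 1.46/4.32. Vertex transitivity puts all 60 atoms on one sphere; the
resulting mean radius is 3.564 Å. Euler's formula fixes the ring census of
any fullerene at 12 pentagons, here plus 20 hexagons.

**Armchair nanotube.** An (n,n) tube has circumference 3n·a_CC and
translational period √3·a_CC with 4n atoms per cell. The flat two-row
bond pattern is mapped arc-length-preservingly onto a cylinder of radius
3n·a_CC/2π, so all atoms are exactly equidistant from the axis; chord
shortening of the circumferential bonds (≈0.7% at n = 5) stays well within
the 1.38–1.47 Å band expected of graphitic bonds. The tube is assembled
from the fewest whole cells whose combined length reaches the requested
minimum — for n = 5, a_CC = 1.42 Å and 38 Å this is 16 cells, 320 atoms,
diameter 6.78 Å. Open ends are left as-is (edge atoms have degree 2).

**Graphene.** The 4-atom orthorhombic cell (√3·a_CC × 3·a_CC) is tiled by
whole cells only (ceiling per axis), so no partial hexagons exist; the
sheet is periodic in x and y. The published 2160-atom sheet corresponds to
an explicit 27 × 20 supercell, which `build_graphene(nx=27, ny=20)`
reproduces; when only minimum dimensions are given, the smallest covering
supercell is chosen.

**Ring perception.** Bonds are atom pairs within 1.7 Å (covering both 1.40
and 1.46 Å bond lengths unambiguously on ideal lattices; minimum-image
under the periodic cell). Rings are all chordless 5- and 6-cycles of the
bond graph, enumerated exhaustively — for these lattices that equals the
face census, which is the set the stacking analysis needs (a
strict smallest-set-of-smallest-rings basis would drop one hexagon of C60,
since a closed polyhedron has one more face than independent cycles). Any
atom with more than three bonds aborts ring perception: the input is not a
graphitic lattice. Ring normals are the smallest-singular-vector of the
centered member coordinates; their sign is oriented toward a supplied
reference point (e.g. the peptide centroid) or else made +z-dominant. Sign
is cosmetic: all angle tests fold the normal–normal angle into [0°, 90°].

## π-stacking classification

Thresholds (defaults): contact cutoff 4.5 Å, maximum tilt 30°, face-to-face
lateral displacement 0.71 Å = half a C–C bond at 1.42 Å. A peptide phenyl
ring is out of register (`NONE`) when its minimum pairwise atom distance to
the surface exceeds the contact cutoff *or* its tilt against the nearest
surface ring exceeds the limit; otherwise it is `FACE_TO_FACE` when the
lateral displacement to the nearest hexagonal surface ring is below the
threshold, else `OFFSET`. Two conventions needed fixing where the intuitive
notions are ambiguous on curved surfaces:

- **Displacement is lateral, not 3-D**: the peptide-ring centroid is
  projected along the partner hexagon's normal onto its plane, and the
  displacement is the in-plane distance to the hexagon centroid. A 3-D
  centroid–centroid distance could never drop below 0.71 Å at van der
  Waals contact (≈3.4 Å), so only the lateral reading makes the threshold
  meaningful.
- **The "surface normal" is the nearest surface ring's normal** (by
  centroid distance). On graphene this is the sheet normal; on C60 and the
  nanotube it generalizes to the local facet. Pentagons participate in the
  contact and tilt tests but are never face-to-face partners — only the
  nearest *hexagonal* ring can be.

Boundary equalities follow the strict inequalities of the defining
phrases: distances *over* the cutoff and angles *greater than* the limit
are non-stacking, displacements *less than* 0.71 Å are face-to-face, so a
tie at exactly 0.71 Å counts as offset.

The unordered pair of the two rings' states maps onto six arrangement
categories — (N,N)→1, (O,N)→2, (O,O)→3, (F,N)→4, (F,O)→5, (F,F)→6 — with
occupancy reported per category and aggregated into the three main groups
(no stacking | offset-involving | double face-to-face). The tracking map
pairs each frame's peptide center of mass with the number of stacked rings
(0–2).

## Contact statistics

Contact stability counts, per residue, the frames in which any residue
atom lies strictly within 4 Å of any surface atom (van der Waals contact
range). Buried contact area is (SASA_peptide + SASA_surface −
SASA_complex)/2 with SASA from Shrake–Rupley sampling on a deterministic
Fibonacci sphere lattice (960 points per atom by default; halving the
area change on doubling to 1920 points is under 1%), probe 1.4 Å, Bondi
radii (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å). The "contact area" axis
of adsorption-energy plots is not uniquely defined in the literature;
buried SASA is the realization chosen here and is labelled as such.

RDFs histogram minimum-image A–B distances and normalize by the ideal-gas
shell population at the B-group number density, so uncorrelated groups
give g → 1; r_max must stay below half the smallest periodic cell length.
RMSF superposes every frame onto the first by Kabsch rotation (unweighted,
all atoms), then reports per residue the square root of the mean over
residue atoms of each atom's mean-square fluctuation about its time mean.

## Clustering

Pairwise minimal RMSD under rigid superposition (SVD-based Kabsch with
reflection exclusion) over the entire peptide; frames closer than the 2 Å
cutoff (strict, symmetric with the stacking conventions) are linked and
clusters are the connected components — single linkage, so chains merge.
Clusters are ordered by decreasing size (ties: lowest member frame index);
representatives are the medoids (minimum summed intra-cluster RMSD, ties
to the lowest frame index) of the up-to-three largest clusters. The
full-pipeline convention is to cluster separately within each arrangement
category. Where a workflow instead wants three representatives of a single
dominant cluster, the medoid rule applies unchanged; taking the three
largest clusters is the more informative default.

## Umbrella sampling and WHAM

The reaction coordinate d is the distance from the mass-weighted
nanomaterial center of mass to the glycine Cα of the peptide. Windows
carry a harmonic restraint ½k(d − d_i)² with k = 8000 kJ mol⁻¹ nm⁻²
(= 19.12 kcal mol⁻¹ Å⁻²) at 0.5 Å spacing by default; temperature 300 K.

The solver iterates the standard self-consistent WHAM equations on a
0.1 Å histogram grid until the largest change in any window free-energy
constant falls below 10⁻⁷ kcal/mol (cap 10⁵ iterations; non-convergence
flags the profile rather than raising, and downstream ΔG extraction
refuses flagged profiles). Two numerical points matter at this stiffness:

- the restraint varies by several kT across one 0.1 Å bin, so the bias
  Boltzmann factor is averaged *analytically over each bin* (an erf
  integral) instead of being evaluated at the bin center — center-point
  evaluation measurably biases the window constants;
- all accumulations run in log space (log-sum-exp), so deep wells and
  far-apart windows cannot underflow.

Adjacent-window overlap is monitored as the histogram intersection
fraction of the normalized sample histograms; zero overlap between
neighbors emits a warning and flags the profile. A single window reduces
exactly to Boltzmann inversion of its histogram. The PMF is zeroed at its
minimum bin ("associated form" = zero of free energy); ΔG is the mean
free energy over the final 2 Å of the profile, a plateau-mean realization
of "separation until fully dissociated". The binding-energy combination
E_b = E_complex − E_peptide − E_nano is plain arithmetic on externally
supplied total energies (the electronic-structure calculations that
produce them are out of scope).

## Synthetic data: what it emulates, and what not

The generator produces inputs with *provable* labels rather than physical
dynamics:

- **Peptide model.** Exact all-atom composition per residue (zwitterionic
  NH₃⁺/COO⁻ termini, Asp/Glu ionized, Lys/Arg protonated, His neutral):
  MSTYTGIFTDQ gives 169 atoms and formal charge −1, consistent with the
  single neutralizing Na⁺ in the simulated systems. The printed 169-atom
  count matches the all-atom composition, not the united-atom convention
  of the force field named in the original study; the generator follows
  the printed count. Geometry is an idealized extended chain — only
  composition, labels and the two phenyl hexagons (C–C 1.39 Å, planar)
  are contractual.
- **Posed rings and trajectories.** Rings are placed over a chosen surface
  hexagon at prescribed height, lateral shift and tilt. Every pose is
  verified by an independent brute-force geometric check that each
  classification criterion clears its threshold by a safety margin
  (0.15 Å distance, 3° angle, 0.12 Å displacement), so the Gaussian
  coordinate jitter added to trajectory frames (σ = 0.05 Å) provably
  cannot flip a label. Random pose generators sample within ranges that
  respect those margins (offset shifts 0.95–1.15 Å stay nearest to the
  anchor hexagon; "none" poses are lifted beyond 5.3 Å or tilted 38–55°).
- **Umbrella windows.** A 1-D Metropolis chain samples U(d) + bias with
  step size auto-tuned to 30–60% acceptance during burn-in (1000 steps)
  and records every 10th state, so the returned n samples are effectively
  decorrelated — histogram-based WHAM error estimates presume that.
  Potentials: flat (hard walls), harmonic ½a(d−d₀)², and a Morse-like
  well D(1−exp(−α(d−d₀)))² whose plateau equals the printed depth D.
- **Hydration shells.** Water-oxygen points at Gaussian radii around
  solute atoms plus a uniform background, for RDF validation (first-shell
  peak at the prescribed radius).

All randomness descends from explicit integer seeds (per-window seeds are
spawned from one root); identical seeds give identical arrays.

What passing the synthetic tests does **not** show: real solvated MD has
correlated frames, flexible rings, thermal surface motion, competing
peptide–peptide stacking and genuine solvent structure. In particular, the
nanosecond-scale dissociation free energies of the real peptide–nanomaterial
systems (order 1–15 kcal/mol depending on curvature) require MD sampling
and are deliberately not reproduced; WHAM is validated by parameter
recovery on analytic potentials instead (flat profile flat to within
0.15 kcal/mol; harmonic curvature and well depths of 1, 5 and 10 kcal/mol
recovered within 10% at 5000 samples per window, ~20 windows — sizes
chosen to keep the whole validation at desk scale).

## Known limitations

- Only armchair (n,n) tubes; no chiral or zigzag tubes, multi-wall tubes
  or lattice defects; surfaces are rigid.
- Periodic minimum-image support is orthorhombic only.
- The stacking taxonomy has no T-shaped/edge-on class, and peptide–peptide
  ring stacking is not tracked.
- Error bars on the PMF (bootstrap over windows) are not implemented.
- The extended-chain peptide geometry is not a physical conformation;
  analyses that depend on realistic internal geometry (beyond ring poses,
  composition and labels) should not use it as-is.
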