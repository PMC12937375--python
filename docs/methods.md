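# Methods

This note documents the models, conventions and numerical choices behind
`contactatlas`, and what the synthetic validation does and does not show
about real trajectories.

## Scope and data model

The package analyses *pre-computed* coordinate trajectories of multi-chain
glycoprotein complexes; it performs no simulation, force-field typing,
protonation prediction or missing-atom reconstruction, and it does not
analyse water-mediated bridges or solvent accessibility. Author residue
numbering from the input structure is preserved verbatim — axes and tables
report the numbers a structural biologist expects (e.g. EU numbering for
antibody Fc residues).

Structures are read from PDB or mmCIF via gemmi; trajectories (multi-model
PDB, DCD, XTC) stream through MDAnalysis one frame at a time, so peak
memory is independent of trajectory length. The frame→time mapping
(`dt_ns`, `t0_ns`) is a required input: a saved stride cannot be inferred
from coordinates and is never guessed.

Covalent structure is taken from explicit records (mmCIF `struct_conn`,
PDB `LINK`/`SSBOND`) merged with distance inference on the first model:
heavy–heavy < 1.9 Å, X–H < 1.25 Å, and the N-glycosidic ND2–C1 bond at
< 2.0 Å. Residues are classed *protein* (standard amino-acid names),
*glycan* (saccharide-name whitelist **and** a covalent path to an
asparagine — robust to nonstandard sugar codes, and a whitelisted sugar
without such a path is kept as *other* with a warning, never dropped
silently), or *other*. Glycan units are indexed by breadth-first distance
from the anchor (1 = innermost GlcNAc); sibling branch residues share a
position, with atom-serial order breaking traversal ties
deterministically. For layer classification a glycan inherits the
*carrier* chain of its anchor Asn, so an Asn-linked glycan contacting its
own CH2 domain counts as intrachain.

## Geometric contact criteria

The detection thresholds are package defaults, config-overridable, and
embedded in every output's provenance — reported results are always
interpretable against the exact parameter set used.

| interaction | criterion | default |
|---|---|---|
| hydrogen bond | donor–acceptor distance; D–H–A angle when H present | ≤ 3.5 Å; ≥ 120° |
| ionic | minimum atom–atom distance between oppositely charged *groups* | ≤ 4.0 Å |
| van der Waals | heavy-atom distance ≤ r_i + r_j + slack | slack 0.5 Å |

Conventions, each chosen for determinism or to avoid double counting:

- All thresholds are inclusive (≤/≥), so boundary geometries behave
  reproducibly.
- Charged groups act as units (Asp OD1+OD2, Glu OE1+OE2, Arg NE/NH1/NH2,
  Lys NZ, chain termini): one contact per residue pair per frame no matter
  how many atom pairs qualify. Histidine is neutral by default
  (`protonated_his=True` adds the imidazole nitrogens).
- An atom pair that satisfies the H-bond criterion in a frame is excluded
  from that frame's vdW count: one physical contact, one booking.
- Covalently adjacent residues and i,i±1 neighbours within a chain are
  excluded from every type.
- Heavy-atom-only trajectories switch H-bond detection to distance-only
  mode; the mode is flagged in the role table and recorded in output
  provenance (`implicit_hydrogens`).
- No π-stacking or cation-π detection.

Detection uses a k-d tree per frame but is *defined* by the all-pairs
rules; the test suite holds the accelerated implementation exactly equal
to an independently coded O(n²) oracle on randomized systems.

## Persistence statistics

The analysis window is half-open, \[start, end) ns — windows tile a
trajectory without double counting — with the default discarding the
first 100 ns of a 1 µs run (900 ns window; occupancy denominators follow
from the window alone). Per pair, type and replica:
occupancy = present frames / window frames; cumulative duration =
occupancy × window length; segment statistics (count, longest run)
distinguish a long-lived anchor from accumulated short episodes.
"Duration" throughout means *cumulative* time in contact, not the longest
continuous segment, which is reported alongside.

Replica aggregation uses a fixed denominator: a pair absent from a
replica contributes 0 ns, and the SD is the sample SD (ddof = 1, zero for
a single replica). The occupancy filter is applied per replica *before*
averaging (keep if the maximum per-replica occupancy reaches the
threshold), so a contact stable in a subset of replicas — real replica
heterogeneity — survives to be seen with its large SD rather than being
averaged away; duration floors (45 ns display, 200 ns persistent, 90 ns or
any other value as configured) are inclusive and compose monotonically.

## Cross-variant comparison

Welch's two-sample t-test (unequal variances, Welch–Satterthwaite df,
two-sided p) is applied to per-replica cumulative durations of each pair
present in both atlases, zero-filled to the replica count; pairs
surviving filters in only one atlas are listed as unique without a test.
Degenerate zero-variance cases are explicit: equal means → t = 0, p = 1;
different means → p = 0, flagged. Atlases must share detector parameters
and window length (like-for-like is enforced, violations name the
offending key). No multiple-testing correction is applied, matching the
single-threshold α = 0.05 reporting convention of interface-persistence
studies; the number of tests is printed so users can post-correct. With
four replicas per side the test has few degrees of freedom — the null
calibration in the acceptance suite shows the realised type-I error is
compatible with α, but power for subtle differences is limited; durations
(not occupancies) are the default tested scalar, both are exported.

## Flexibility and convergence metrics

Superposition uses the Kabsch SVD solution with a determinant correction
guaranteeing a proper rotation; degenerate (collinear or < 3 point) sets
are rejected since the optimum is not unique. RMSF is computed after
superposing each frame onto the first frame over a fit selection (protein
backbone heavy atoms by default, config-overridable and recorded), with a
one-pass accumulator that sums deviations from the first aligned frame to
avoid catastrophic cancellation. The glycan flexibility reporter is the
per-atom RMSF of each monosaccharide's anomeric C1, ordered by glycan
position; both the mean across replicas and the across-replica SD are
exported, since either dispersion convention is found in the literature.
R_g is mass-weighted about the selection's centre of mass. Frames are
assumed PBC-whole; no unwrapping is attempted, and a per-frame
displacement jump > 20 Å per atom raises a warning.

## Synthetic study conditions

The generator exists so that every pipeline stage can be validated
against known ground truth without any external data. Default fixture
(the package's study conditions):

- three protein chains (two Fc-like, one receptor-like; ~30 residues
  total) and three N-glycans (3–5 sugars) on designated asparagines;
- four replicas of 10 000 frames at dt = 0.1 ns (1 µs each), analysis
  window [100, 1000) ns = 9000 frames — the window arithmetic of a
  microsecond production run at toy size;
- five designated pairs covering every analysis layer: a persistent
  interchain salt bridge (k_on 0.05, k_off 0.005 /ns), a medium-lived
  interchain H-bond (0.02/0.01), an intrachain protein–glycan H-bond
  (0.01/0.01), a transient interchain glycan–glycan H-bond (0.005/0.02),
  and a long-lived interchain vdW packing contact (0.02/0.002) — spanning
  the long-lived/medium/transient phenomenology of interface contacts;
- Gaussian positional jitter σ = 0.1 Å on every atom, small enough that
  bound/unbound geometries stay ≥ 5σ from every threshold;
- a two-variant pair of specs sharing one layout, variant B destabilising
  the salt bridge twenty-fold and abolishing the glycan–glycan bridge —
  a known differential signal for the comparison stage.

Contacts follow an exact two-state continuous-time Markov chain per pair
(Gillespie exponential waiting times; stationary initial state), chosen
over per-frame Bernoulli flips so dwell times are exponential and
segment statistics are analytically checkable: occupancy →
k_on/(k_on+k_off) with asymptotic estimator variance
2p(1−p)/((k_on+k_off)·T) per replica, mean dwell → 1/k_off. Geometry is
schematic: chains are straight residue strings with 15 Å spacing, glycans
extend perpendicular with correct glycosidic link distances, and mobile
residues teleport between bound/unbound positions along per-pair
directions. A construction-time validator re-detects both extreme poses
with all thresholds inflated by 6σ of a jittered pair distance and
rejects any layout in which a non-designated pair could ever fire.

What passing these tests shows: the bookkeeping, statistics, filters and
detection geometry are correct, and kinetic parameters round-trip through
the full pipeline. What it does not show: real force-field geometry
(rotameric donor orientations, correlated motions, PBC artefacts), real
glycan conformational ensembles, or detector threshold *choices* matching
any particular physical definition of a contact — on real data the
thresholds remain a declared convention, not a validated inference. A
bound pair can also satisfy a second criterion (a salt bridge at 3.3 Å is
within H-bond and near vdW distance); these shadow records share the
designated residue pair and are expected, as in real interfaces.

## Numerical and reproducibility choices

- All randomness flows from `numpy.random.SeedSequence` spawns keyed by
  (master seed, replica, pair): replicas and pairs are independent
  streams, and regeneration is bit-identical before any lossy file write.
- XTC fixtures are written at 10⁻⁴ nm precision (0.001 Å) so cross-format
  round-trips agree to the format's quantisation.
- TSVs are written with fixed float formatting and sorted keys; reruns
  with one config + seed are byte-identical, which the acceptance suite
  asserts.
- Empty selections, empty windows and unlinked sugars warn; structural
  contradictions (duplicate atoms, atom-count mismatches, parameter
  mismatches between compared atlases) are errors naming the offender.
- Figures are rendered only from exported TSVs' data values (cells equal
  atlas means exactly; colour mapping happens at render), so the data
  layer is toolkit-independent.

## Validation problem sizes

The test suite and acceptance script run at desk scale: unit and property
tests use 100–2000-frame windows where only bookkeeping (not statistics)
is asserted; statistical assertions (occupancy/dwell recovery over a 3×3
rate grid, Welch null calibration over 500 replications) run at the full
default scale of 9000 analysed frames × 4 replicas, where analytic
standard errors are small enough for 3σ checks to be meaningful. These
sizes are the package's chosen validation conditions and complete in a
few minutes on one CPU.

## Known limitations

- H-bond detection without hydrogens cannot enforce the angular
  criterion; donor orientation is unconstrained in that mode.
- The occupancy filter's max-over-replicas rule is one of several
  defensible conventions (pre- vs post-averaging); it is recorded in
  output metadata, and users can re-filter exported atlases differently.
- Welch on n = 4 replicas has limited power; the package reports test
  counts but deliberately applies no multiplicity correction.
- Dwell-time estimates from discretised series include window-censored
  segments; at dwell times approaching the window length they are biased
  short (the acceptance check uses Monte-Carlo confidence intervals that
  absorb this at the tested rates).
- No π interactions, no energetic scoring, no binding-affinity claims:
  durations describe contact stability of a pre-formed complex, not free
  energies.
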