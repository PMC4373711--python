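# Methods

## Model

starpot implements a residue-specific all-atom probability discriminatory
function (RAPDF): a knowledge-based potential that compares the observed
distance distribution of each atom-type pair in a reference library with a
type-independent reference state.

Atom types. The pair alphabet is the 167 residue-specific heavy atom
types: every non-hydrogen atom of the 20 standard amino acids, under PDB
v3 naming, with backbone N/CA/C/O shared per residue but typed per
residue (ALA CB ≠ SER CB). Enumerating all standard heavy atoms yields
exactly 167 entries (GLY 4 … TRP 14); the registry is frozen, dense
(indices 0–166) and exportable as TSV for audit. Terminal OXT is not a
canonical type and is skipped (reported in skip counts). Selenomethionine
is remapped to MET (SE→SD) because it is a routine crystallographic
substitution; other nonstandard residues are skipped and counted rather
than guessed at.

Distance binning. Pair distances are Euclidean, in Å, unrounded, assigned
to 18 half-open bins [lo, hi): one 0–3 Å bin (short contacts are sparse
and would otherwise fragment), then 1 Å bins to an exclusive 20 Å cutoff.
Half-open intervals make boundary membership unambiguous and
reproducible.

Score. With N_obs(a,b,r) the library count of type pair {a,b} in bin r,
and marginals N_obs(a,b), N_obs(r), N_total:

    s_ab(r) = −ln[ (Ñ(a,b,r)/Ñ(r)) / (Ñ(a,b)/Ñ_total) ]

where Ñ are smoothed counts (below). A structure's score is the sum of
s_ab(r) over its eligible pairs; scores are dimensionless log-odds (no RT
factor), and lower = more stable. This convention matches the packaged
consensus-TPR benchmark, where scores decrease monotonically with repeat
number while unfolding free energy grows.

## Pair eligibility

Intra-residue pairs are excluded (their geometry is fixed by covalent
chemistry, not folding); all inter-residue pairs of the same chain are
included (min_residue_separation = 1, configurable upward); cross-chain
pairs are excluded by default because the intended use is scoring single
domains/chains. Both knobs live in `PairingPolicy` and apply identically
to counting and scoring, which is what makes training and evaluation
self-consistent.

## Smoothing

The raw log-odds diverges wherever N_obs(a,b,r) = 0, which is common for
rare type pairs in small libraries (a repeat-family library may be only a
few dozen chains). Default: Laplace smoothing with pseudocount α = 1 per
pair class, spread evenly over bins (α/18 per cell), all marginals
recomputed from smoothed cells. This guarantees finite scores, perturbs
well-sampled cells negligibly (a cell with hundreds of counts moves by
<1%), and makes an unseen short-range contact strongly penalized rather
than undefined — exactly the behaviour wanted for decoys with steric
clashes. α = 0 disables smoothing for exact hand-checked oracles; then
0/0 cells (a pair class never seen, or a bin empty across the library)
are defined as score 0 (no information), while a zero cell inside a
populated class and bin is honestly +inf.

## Structure input

PDB parsing is delegated to gemmi. Policies: first coordinate model by
default (or an explicit model number); explicit chain selection with
all-chains fallback; altloc resolution keeps the highest-occupancy
conformer, ties broken alphabetically; hydrogens, waters and HETATM
records other than MSE are dropped. Coordinates are used as deposited —
no symmetry expansion, assembly reconstruction or repair. mmCIF is out of
scope.

## Library curation

Pairwise sequence identity uses one global alignment (Biopython
PairwiseAligner, BLOSUM62, gap open 11, extend 1) and is defined as
identical columns / alignment length, X never matching. The published
libraries' exact alignment tool is not documented, so this is a
reproducible standard choice, not a reconstruction. Redundancy removal is
greedy: candidates sorted by resolution (ascending, NMR last, id as
tiebreak); an entry is retained iff its identity to every retained entry
is below the cutoff. The output is therefore a mutually non-redundant set
biased toward high-resolution representatives. Note that greedy selection
under a fixed order is not formally monotone in the cutoff for
adversarial identity matrices; on realistic panels (and the seeded test
panels) raising the cutoff grows the retained set.

## Synthetic data

The generator exists to make the pipeline testable without downloads; it
emulates compact all-heavy-atom α-helical repeat architecture, not any
natural family's coordinates.

- Helices are ideal poly-alanine: built from ideal internal coordinates
  (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, standard angles) with
  backbone dihedrals φ = −57°, ψ = −47°, ω = 180°. The canonical helix
  parameters emerge rather than being imposed: rise ≈ 1.55 Å and twist
  ≈ 101° per residue, CA–CA ≈ 3.80 Å (asserted in tests). Poly-alanine
  keeps atom typing trivially complete (5 heavy atoms per residue).
- Repeat arrays stack a two-helix antiparallel unit (10 residues per
  helix, axes 10 Å apart) by a screw transform of 10.5 Å translation and
  24° rotation per repeat, giving an elongated solenoid reminiscent of
  TPR/AR architecture. These are fixed documented constants chosen for
  geometric plausibility (no steric clashes, growing bounding box), not
  fitted to real repeats.
- Decoys add i.i.d. Gaussian noise of standard deviation σ to every
  coordinate (expected RMSD σ√3); σ = 2 Å is the default benchmark level,
  enough to scramble the tight sub-3 Å contact statistics while leaving
  the global shape recognizable.
- `toy_library` varies repeat count (2–6) and jitters the stacking
  geometry slightly (±1°, ±0.3 Å) under a seeded generator, so panels are
  deterministic given a seed.

What passing synthetic tests shows: the counting/normalization/scoring
machinery is exact (brute-force oracle agreement), invariant to rigid
motion, and sharp enough to separate clean geometry from 2 Å noise. What
it does not show: performance on real decoy sets, side-chain packing
quality, or transferability across folds — those require curated
experimental libraries and decoys outside this package's scope.

## Benchmark fixture and correlations

The packaged TSV holds the published nine-protein consensus-TPR panel:
ΔG_D-N (Gibbs–Helmholtz analysis of thermal denaturation), ΔG_0→j
(1D homozipper Ising fit; measured only for the seven CTPRan proteins)
and the repeat-specific scores, digit-for-digit with column checksums
guarding transcription. R² of score vs ΔG_D-N is computed over all nine
proteins (0.8418 ≈ 0.84); vs ΔG_0→j over the seven CTPRan proteins
(0.9384 ≈ 0.94). Central values only; the published ± uncertainties are
stored but not used as weights. Correlations use scipy's Pearson r,
cross-checked in tests against an independent routine.

## Numerical choices

Natural log, double precision, no intermediate rounding. Counting and
scoring share one vectorized pair enumeration (upper-triangle distance
matrix); the test suite and the acceptance script verify it against a
scalar double-loop oracle exactly (counts) and to 1e-9 relative (score
sums, which are order-sensitive in floating point). The potential file
format is deterministic UTF-8 TSV (scores at 9 significant digits, rows
sorted), so rebuilding from identical inputs is byte-identical.

## Problem sizes

Default verification sizes: potentials trained on 50 synthetic arrays
(~10⁶ pairs), 50 decoy panels × 20 decoys, 100 random structures ≤ 200
atoms for oracle equivalence. These sizes give stable statistics (the
native-rank criterion passes at 100% across seeds) while keeping a full
run under a minute on one CPU.

## Known limitations

- The 167-type enumeration is the standard one; if an upstream variant
  differs in edge-case atom naming, this registry is the authority here.
- Scores from libraries of different sizes are not directly comparable
  (N_total enters the reference state); compare structures against one
  potential at a time.
- No orientation dependence, no explicit solvent or electrostatics; β-rich
  or disulfide-stabilized folds need their own reference libraries.
- The greedy curation order is a heuristic, not a maximum independent set.
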