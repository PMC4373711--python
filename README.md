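# starpot

All-atom distance-dependent statistical potentials for assessing protein
stability, aimed at α-helical repeat proteins (tetratricopeptide and
ankyrin repeats) but usable for any single-chain structure.

## Who this is for

Protein designers and structural bioinformaticians who need a fast,
training-data-transparent way to rank candidate structures — e.g. to
prioritize consensus-designed repeat proteins from a combinatorial library
by predicted stability, or to tell a native fold from a perturbed or
misfolded model.

## The score

Every heavy atom of the 20 standard residues is one of 167
residue-specific atom types. For a reference library of structures, all
inter-residue atom pairs (a, b) within 20 Å are histogrammed into 18
distance bins r (one 0–3 Å bin, then 1 Å bins). The potential is the
negative log odds of the observed pair distribution against a
type-independent reference state:

```
s_ab(r) = −ln [ (N_obs(a,b,r) / N_obs(r)) / (N_obs(a,b) / N_total) ]
```

and a structure's score is the sum over its eligible pairs,

```
S = Σ_pairs s_ab(r(d_ab)).
```

Lower scores mean more native-like, more stable structures. Zero counts
are handled by Laplace smoothing (pseudocount α = 1 per pair class spread
over the bins; configurable, α = 0 disables it). See `docs/methods.md`
for assumptions, parameter choices and limitations.

The package also ships the published stability benchmark for designed
consensus TPR proteins (CTPRa2…CTPRa10, CTPR2, CTPR3): equilibrium
unfolding free energies ΔG_D-N, Ising-model folding free energies ΔG_0→j,
and their repeat-specific scores, used for the score-vs-stability
correlation analysis.

## Worked example

Build a potential from a synthetic repeat-protein library, score a member,
and rank it against a 2 Å-jittered decoy:

```
$ starpot make-fixtures fx --n-structures 5 --seed 5
manifest        fx/manifest.tsv
expected_scores fx/expected_scores.tsv

$ starpot build-potential fx/manifest.tsv tpr_like.pot
structures      5
n_total 251755
potential       tpr_like.pot

$ starpot score tpr_like.pot fx/SYN0000.pdb --chain A
source_id  chain  length  n_typed_atoms  n_pairs  raw_score     per_pair_score
SYN0000    A      40      200            19096    -1163.454894  -0.060927

$ starpot eval-decoys tpr_like.pot fx/SYN0000.pdb decoy.pdb
native_score    -1163.454894
best_decoy      3056.202462
delta           -4219.657356
rank_of_native  1
```

The library's 251,755 atom pairs define the reference statistics; the
40-residue member scores −1163 (negative: its contacts are much more
probable than the reference state), while the noise-perturbed decoy scores
+3056, so the native ranks first with a margin of −4220.

Correlating the packaged consensus-TPR scores with measured unfolding free
energies:

```
$ starpot correlate --builtin-ctpr --energy dg_dn
n       9
r       0.9175
r_squared       0.8418
```

R² ≈ 0.84 over the nine proteins (0.94 against the Ising-model ΔG_0→j over
the seven CTPRan proteins): more negative scores track larger unfolding
free energies, i.e. the potential predicts relative stability of designed
repeat arrays.

Other subcommands: `filter-library` (resolution and sequence-identity
redundancy curation of a structure manifest) and `correlate` on your own
`label/score/energy` TSV. The same operations are available as a library
(`starpot.potential`, `starpot.curation`, `starpot.evaluation`,
`starpot.synthetic`).

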