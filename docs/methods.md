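# Methods

## Model

A backbone hydrogen bond (BHB) is directional: the amide N–H of a donor
residue to the carbonyl O of an acceptor residue.  Formation is a purely
geometric decision per structure or per frame:

- full criterion: N–O distance r < r_max AND N–H–O angle θ > θ_min, with
  the angle vertex at the hydrogen;
- distance-only criterion: r < r_max (for per-frame N–O distance tables,
  where the angle is unavailable; over a trajectory the distance test is
  an adequate stand-in for occupancy counting).

Defaults r_max = 3.5 Å, θ_min = 140°.  Both inequalities are strict, so a
frame sitting exactly on a cutoff counts as broken; this makes the
boundary behaviour reproducible across platforms.

The static contact matrix holds the 0/1 state of every candidate bond on
one PDB model; the dynamic matrix holds the fraction of frames formed
(a count divided by n_frames, so exactly representable).  Their per-bond
difference

    D = static_state − propensity  ∈ [−1, 1]

classifies bonds: |D| > 0.5 (strict) is *chameleonic* — the solution
behaviour contradicts the crystal.  A borderline band, 0.4 ≤ |D| ≤ 0.5 by
default, flags bonds close enough to the threshold that a user may
promote them by judgement; the classifier never promotes them silently.
The 0.5 threshold is justified by the bimodality of the D distribution
over protein structures; it is exposed as a parameter.

For a ligand complex in which every monitored bond is formed in the PDB,
D reduces to 1 − propensity, the fraction of time broken.  The DM score
of a molecule is the unweighted arithmetic mean of D over the
binding-site chameleonic set (determined once on the apo protein and
frozen), with replica averaging applied to the per-bond values first.
DM is compared with potency via Pearson correlation of DM against
log₁₀ IC50 (default; IC50 values typically span orders of magnitude) or
raw IC50 — both scales are computed because neither is canonical.

## Structure handling

PDB parsing goes through Biopython.  Per model: alternate locations
resolve to the highest-occupancy conformer, occupancy ties to altloc 'A'
(deterministic parsing); waters are discarded; non-water HETATM heavy
atoms are kept in a separate partner pool used for interface selection.
Residue identity is the author (chain, number, insertion code) triple —
never renumbered — and is what bond keys compare by; the residue name is
annotation.

Missing amide hydrogens (X-ray entries usually lack them) are rebuilt
in-plane: H = N + 1.01 Å · unit(unit(N−C_prev) + unit(N−CA)), the
bisector pointing away from the two heavy neighbours.  Chain-initial
residues and prolines get no hydrogen and are marked non-donors; their
carbonyl O still accepts.  Only the amide hydrogen is ever used; all
other hydrogens are ignored.  A degenerate bisector (norm < 1e-6) is an
error naming the residue rather than a silent skip.

Alanine truncation keeps the backbone and CB bit-identical, removes all
other side-chain atoms and renames the residue ALA.  Glycine is rejected
(no CB to retain).

## Candidate enumeration and interface selection

Candidate bonds are all ordered donor→acceptor pairs with a
donor-capable residue and |Δseq| ≥ min_separation (default 2, excluding
i→i±1 artifacts; helical bonds at i→i−4 are unaffected).  No
symmetrization and no exclusivity rule: a donor satisfying the criterion
with two acceptors in one frame yields two entries (bifurcated bonds).

A bond belongs to the binding site when the minimum distance from its
donor N or acceptor O to any partner heavy atom in the complex is
strictly below 6 Å (default).  Selection is monotone in the cutoff by
construction.

## Synthetic fixtures

`make_ideal_helix` builds a canonical α-helix backbone by sequential
internal-coordinate placement (φ = −57°, ψ = −47°, ω = 180°; N–CA 1.458,
CA–C 1.525, C–N 1.329, C=O 1.231 Å; angles N–CA–C 111.2°, CA–C–N 116.2°,
C–N–CA 121.7°, CA–C–O 120.5°).  With hydrogens placed, every i → i−4
bond evaluates to r ≈ 3.09 Å, θ ≈ 165° — formed — and no other pair
passes the criterion, so the expected static map is known exactly.

`simulate_telegraph_series` models one bond as a two-state Markov chain
with stationary formation probability p: transition probabilities are
s·p (broken→formed) and s·(1−p) (formed→broken), where s is the
per-frame switch probability (default 0.05).  The chain starts from the
stationary law, and the integrated-autocorrelation factor (1+ρ)/(1−ρ)
with ρ = 1−s inflates the variance of the time average by (2−s)/s ≈ 39
at the default — deliberately, because real hydrogen-bond trajectories
are autocorrelated and an i.i.d. fixture would make recovery tests
unrealistically easy.  Formed frames draw r ~ N(2.9 Å, 0.1 Å) and
θ ~ N(160°, 5°), broken frames r ~ N(5.0 Å, 0.1 Å), all truncated at
3σ so the two classes can never straddle the 3.5 Å cutoff: the fixture's
ground truth is exact, not probabilistic.  A constructor check rejects
jitter values that would break this guarantee.

What the fixtures do **not** emulate: solvent, side-chain packing,
coupled motion between bonds, drift/non-stationarity, and the
force-field physics that sets real propensities.  Passing tests
demonstrate that the bookkeeping — counting, averaging, thresholding,
selection, scoring — is correct, not that the geometric criterion is the
right physical model for any particular protein.

## Numerical choices

- Angles via arccos of the clipped dot product; coincident points are an
  error, not NaN.
- Propensities and D are reported at 4 decimals (matching the precision
  propensity tables are usually printed at); internal values are full
  precision.
- Windowed propensity splits frames into contiguous equal blocks with the
  remainder assigned to the last block (10 frames, 3 windows → 3, 3, 4).
- Replica summaries use the unweighted mean and the sample SD (ddof = 1;
  SD = 0 for a single replica).  Averaging fraction-broken values or
  averaging propensities first gives the same mean.
- Relative labilization is 100·(D_variant − D_ref)/D_ref and is undefined
  (error) at D_ref = 0.
- delta_matrix takes the union of key sets: a key missing from the static
  map has state 0, one missing from the dynamic map has propensity 0.
- PDB coordinates are fixed-width with 3 decimals, so write/read round
  trips are guaranteed only to 1e-3 Å.

## Design choices where the design was open

- Multi-model (NMR) input defaults to model 1 but any model can be
  requested; which ensemble member best seeds an analysis is a user
  decision, as is any trimming of disordered termini — a residue-range
  choice the tool never guesses (bonds excluded by construct truncation
  are dropped via an explicit exclude list, recorded in the output).
- Bond keys are directional and never symmetrized, matching the
  "donor 57 – acceptor 53" naming convention of propensity tables.
- The DM correlation defaults to log₁₀ IC50 but the linear scale is one
  flag away, since the appropriate scale depends on the assay range.
- The CLI is a thin layer over the library; every output carries a
  sidecar JSON with the fully resolved configuration and tool version so
  that deterministic runs are reproducible bit-for-bit.

## Problem sizes

Synthetic recovery tests use 4 000-frame chains (100 seeds per stationary
probability for the coverage test) and 18-residue helices; these sizes
put the 3σ recovery bands in the few-percent range while keeping the full
suite fast.  All published-number checks (D arithmetic, DM means,
classification, correlation) are exact desk-scale computations over the
tabulated inputs.

## Known limitations

- No mmCIF reader; no force-field protonation or side-chain rebuilding.
- No side-chain or protein–water hydrogen bonds, and no energetic
  scoring of bonds.
- Error bars on propensities are not autocorrelation-corrected outside
  the test suite's internal bands.
- Running the molecular dynamics that produces real trajectories, and
  binding free-energy estimation (MM-GBSA/PBSA), are out of scope.
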