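# Methods

This note documents the models, conventions and numerical choices behind
`cpcompare`, and what the synthetic-data generators do and do not emulate.

## Structure model and selections

Structures are chain → residue → atom hierarchies carrying author residue
numbering only (the numbering that appears in structure papers, "residues
2–272"); all ranges are 1-based and inclusive at both ends.  Parsing and
writing go through gemmi; only the first model of a file is used, and
alternate locations are resolved at read time to the highest-occupancy
conformer (ties broken by file order), so no downstream statistic ever sees
duplicate atoms.  Waters (HOH/WAT/DOD) are retained in the hierarchy but
excluded from every statistic unless a selection explicitly reaches them.
Modified residues keep their three-letter names; sequence extraction maps
them to parent one-letter codes (MSE → M) and unknown residues to X.

A `Selection` names a chain, optional include/exclude residue ranges and an
atom-name set (default `{CA}`; an empty set means all atoms).  A residue is
selected iff it lies in some include range (or include is empty) and in no
exclude range.  This is the idiom for every stated exclusion — "the flexible
β-subunit C-termini were excluded" becomes an exclude range in a config, not
code.

## Correspondence

Equivalent-residue maps are derived from sequences, not structures: the
one-letter sequences of the CA-bearing residues are aligned globally
(BLOSUM62, affine gap penalties open 10 / extend 0.5 in matrix units) and
every column with residues on both sides becomes an equivalence, mismatches
included — superposition compares positions, not identities.  For
chain-to-chain mapping the terminal gaps are left unpenalised (semi-global),
because modeled-residue sequences are fragments whose overhangs have no
homologous partner; the toy identity-scoring mode keeps end-to-end penalties
so that small hand-checkable examples have unique optima.

Limitation: with sequences this machinery recovers ≥ 95 % of true homologous
positions down to roughly 50 % identity (measured on star-evolved pairs);
toward 30 % identity recovery degrades to ~80 % because patternless synthetic
sequences offer the aligner no conserved blocks to latch onto.  Real
remote-homolog comparisons at that distance should use a structure-derived
correspondence and feed it in directly.

## Superposition

The Kabsch/SVD construction returns the proper rotation and translation
minimising Σ‖R·aᵢ + t − bᵢ‖².  The reflection branch is corrected by the sign
of det(V·Uᵀ) applied to the axis of the smallest singular value, which also
resolves the planar-cloud case (one zero singular value) to a pure rotation.
Collinear input — covariance rank < 2, rotation about the line undetermined —
is an error, not a silent answer.  Superpositions are unweighted (no B-factor
or occupancy weighting).

Fit and report are deliberately separate.  Conventions used by the pipeline:

* **whole-molecule r.m.s.d.** — one global fit over all mapped Cα of all
  chain pairings, pooled;
* **per-subunit r.m.s.d.** — an independent local fit per chain pairing.
  This matches how homolog papers quote subunit numbers (each subunit
  superposed on its own) and is *not* the subunit's deviation in the global
  frame — under a relative domain motion the two differ materially;
* **named regions** — reported in the global-fit frame, so a rigidly
  displaced region shows its full displacement rather than having the fit
  absorb it.  No automatic outlier trimming anywhere; exclusions are always
  explicit selections.

## Flexibility and disorder

Region B statistics default to Cα atoms (all-atom mode available); the
z-score of a region mean is taken against the per-atom B distribution of the
whole chain, waters excluded.  If the reference distribution is flat the
z-score is reported as 0 with a flag rather than dividing by zero.  The
model-wide mean B is computed over all protein atoms of all chains,
altloc-resolved, occupancy-unweighted.

Disordered segments are maximal runs of expected author numbers with no
CA-bearing residue in the chain; by construction
(modeled + missing = expected span) always holds.

## Crystal packing

Cell volume uses the triclinic closed form
V = abc·√(1 − cos²α − cos²β − cos²γ + 2cosα·cosβ·cosγ).  The Matthews
coefficient is V_M = V / (Z · n_AU · M) with Z the space-group multiplicity
(looked up from gemmi's tables by symbol, with an explicit numeric override),
and solvent content 1 − 1.660·v̄ / V_M with v̄ = 0.74 cm³/g by default; the
single constant 1.660 = 10²⁴/N_A folds the Dalton-gram and Å³-cm³
conversions.  Non-physical solvent fractions clamp to 0 with a warning.  The
default crystal fixture is the tetragonal P4₁ form with a = b = 124.5 Å,
c = 77.5 Å and two heterodimers per asymmetric unit; the 66 000 Da heterodimer
mass is inferred from the subunit masses (32 + 34 kDa) rather than taken from
any published table.

## Sequence conservation

Pairwise identity: columns gapped in both rows are removed, identities are
counted over equal non-gap letters (case-insensitive; ambiguity codes
B/Z/X/J/U/O never count), and the denominator is the ungapped length of the
longer sequence — so one-sided insertions dilute identity instead of being
ignored.  Histograms bin scores rounded half-up to integer percent
("percentage of sequences" is interpreted as percentage of sequence *pairs*,
the matrix's natural unit); five-number summaries use the unrounded values
with linear-interpolation quartiles.  The column filter keeps columns whose
gap fraction is ≤ a threshold (default 0.5) and reports the kept-column index
map so logo positions remain traceable to the original alignment numbering —
it is a deliberately simple, documented stand-in for block-filtering tools,
and pre-filtered alignments are accepted as input.  Logo information content
is IC = log₂20 − H over the non-gap distribution, frequencies scaled by the
non-gap fraction, no small-sample correction.

## Synthetic data

`make_chain` builds Cα-only traces: ideal helix (rise 1.5 Å/residue, radius
2.3 Å, 100° twist → Cα–Cα 3.83 Å), an extended zigzag or a persistent random
walk, both with exact 3.8 Å steps.  `perturb` applies, in order: a global
rigid transform, per-region rigid displacements, per-chain rigid offsets,
i.i.d. Gaussian coordinate noise, B-factor painting and deletion of missing
ranges — and returns the ground truth.  Noise goes on only one member of a
pair, so the expected pair r.m.s.d. is exactly σ√3.  Every generator takes
its own seed; streams never interleave.

`evolve_msa` grows a family on a star tree: each leaf mutates each site of a
random ancestor with probability s, replacement uniform over the other 19
letters, so two leaves agree with probability (1−s)² + s²/19; s is solved
from that quadratic for a requested expected pairwise identity (valid down to
0.05).  Deletions start at rate `gap_rate` per site with geometric run
lengths (mean 3).

### The comparison scenario

`make_comparison_scenario` assembles the full study situation with known
truth: a cytoplasmic-type heterodimer (α 281 residues, β 272) crystallised
with two copies per asymmetric unit, and a sarcomeric-type homolog.  All of
its numbers are generator *inputs*:

* modeled ranges: α copy 1 2–272, copy 2 2–270; β all but 1, 140–145,
  251–272 (copy 2: 253–272); homolog α 9–272, β 3–250.  These alone fix the
  bookkeeping: 514 modeled residues per copy, 512 common AU Cα, 264 mapped α
  and 242 mapped β positions;
* AU-copy noise σ = 0.3/√3 Å → expected copy-copy r.m.s.d. 0.3 Å;
* homolog pair: β noise σ_β = 1.0/√3 (β local fit 1.0 Å).  The α region
  101–117 is rigidly displaced by d and the α noise set so the region lands
  at ~3.0 Å while the whole α subunit fits at ~1.7 Å:
  d² = (3.0² − 1.7²)/(1 − 17/264), 3σ_α² = 3.0² − d²;
* a rigid whole-α offset δ along the inter-subunit axis (the domain
  "bending") sized from δ²·w_α·w_β = 1.7² − (264·1.7² + 242·1.0²)/506 so the
  pooled global fit lands at ~1.7 Å.  The region displacement is drawn
  orthogonal to the offset axis so the two modes add in quadrature;
* B-factors painted flat (jitter sd 1.5 Å²): cytoplasmic baseline 15 Å² with
  the region at 24.2 Å²; sarcomeric baseline 30 Å² with the region at
  86.8 Å²;
* homolog sequences at 70 % identity with conserved anchor residues at
  modeled-segment boundaries and a linker whose letters avoid the flanking
  anchors.  This keeps the alignment-derived register exact — the scenario's
  purpose is to carry the structural contrasts, and a single misplaced gap
  (an exact-score tie at a segment boundary) would corrupt every downstream
  truth.  Real cytoplasmic/sarcomeric CP subunits are more divergent;
  register fidelity was chosen over divergence realism here, and the
  limitation above describes how the mapping degrades with distance.

What the generators do **not** emulate: real backbone geometry beyond Cα
traces, side chains, secondary-structure-dependent B profiles, correlated
(TLS-like) displacements, crystal contacts, or insertion codes.  Passing
tests therefore demonstrate that the *calculations* recover known inputs
through the full pipeline (including PDB round-trips), not that the package
reproduces any particular deposited structure — for that, feed the deposited
files through `examples/cap32_capz.yaml`.

Because several metrics are stochastic under coordinate noise (a 17-residue
region r.m.s.d. has a sampling sd of ~0.2 Å), the acceptance script averages
5 replicate scenarios; problem sizes there are the scenario's own (506
mapped Cα, 50-sequence families of length 300).

## Numerical conventions

r.m.s.d. values print with 2 decimals, B-factors with 1, identities with 3;
reports are written with stable ordering so re-running a config reproduces
byte-identical files.  Rotation matrices are validated orthonormal to 1e-8
with determinant +1; degenerate geometry raises rather than guessing.
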