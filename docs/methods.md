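# Methods

## Step detection

A structure (mmCIF or PDB, parsed with gemmi) is scanned chain by chain and
model by model. Two residues form a step when they are consecutive in the
chain, their O3′(1)–P(2) distance is at most the linkage cutoff (default
2.5 Å — a covalent O–P bond is ~1.6 Å; the generous margin tolerates poorly
refined linkages), and all 18 canonical atoms resolve. Residue eligibility
is decided purely by atom-name presence, not by a residue-name whitelist, so
modified nucleotides that keep the standard atom names are handled
automatically. A residue with N9 is treated as a purine (base atoms N9/C4),
otherwise N1/C2 is used. Waters and hydrogens are ignored; occupancy is not
filtered by default (a minimum-occupancy option exists). Alternate locations
are expanded into one step per altloc id present among the required atoms,
with blank-altloc atoms serving as the shared fallback; combinations that
cannot be completed are skipped. Names and reports use author numbering;
malformed files fail loudly with a parse diagnostic rather than being
repaired.

## Geometry

Torsions follow the IUPAC crystallographic convention (cis = 0°, range
(−180°, 180°], right-hand sign); a torsion whose defining atoms are
collinear (cross-product norm below 1e−8 of the bond-length scale) is an
error rather than a number. Rigid superposition of 18-atom sets is
least-squares over proper rotations only (determinant +1), via
`scipy.spatial.transform.Rotation.align_vectors`; restricting to proper
rotations means a mirrored conformer cannot masquerade as a match.

## Classification

The parameter-space metric divides each axis displacement (circular
difference for the ten angular axes, absolute difference for the two
distances) by a per-axis scale and takes the Euclidean norm. The default
scale is the class-pooled e.s.d. per parameter, which makes degrees and
ångströms commensurate; a user-supplied 12-vector can replace it. Votes are
weighted 1/d²; a zero-distance hit assigns immediately. Ties break by
smaller nearest-member distance, then lexicographic class code, so
assignment is deterministic.

Defaults worth knowing:

* `k` — 11 when a multi-point training set is supplied, 1 when only class
  means are available (one training point per class makes larger k
  meaningless). Configurable.
* rejection cutoff — 4.5 scaled units; the nearest training point farther
  than this sends the step to the unassigned class (`NANT`). Configurable;
  with e.s.d.-based scaling this means "about 4.5 pooled standard deviations
  away along a single axis, or the equivalent combined over axes".
* The main fidelity gap versus the original service: its classifier votes
  over a curated multi-thousand-step "golden set" that is not distributed
  with the published conformer table. Without such a file this package falls
  back to one training point per class (the class means), i.e. weighted k-NN
  degenerates to nearest-class assignment. Supplying a labeled training CSV
  (`--training`) restores the full behavior.

## Confal scoring

Per parameter, with m the class mean and borders b_lo < m < b_up (circularly
for angles): f(x) = 100·exp(−ln 100·(d(x, m)/d(b_near, m))²) for x inside
the borders, 0 outside, with d the circular difference on angular axes.
The Gaussian width is calibrated on the nearer border only — taken literally
from the published definition — so with asymmetric borders the farther side
decays below 1 before the clamp to 0, and the value-1→0 jump happens exactly
at the nearer border. Step score: harmonic mean of the 12 values, defined as
0 whenever any value is 0 (the limit convention; also avoids division by
zero). Structure score: arithmetic mean over assigned steps; unassigned
steps are excluded. Reports print integer confals; full precision is kept
internally and in JSON. When the published tables provide only e.s.d.
values, borders default to mean ± 3·e.s.d. (factor configurable); explicit
asymmetric `lower_*`/`upper_*` columns in the means CSV take precedence.
The structure percentile is computed only against a user-supplied score
distribution (one score per line); no PDB-wide distribution ships with the
package.

## Diagnostics

The similarity profile records, per reference class, both the scaled
parameter-space distance to the class means and the Cartesian r.m.s.d. to
the class representative, with the color bands green < 0.5 Å ≤ yellow ≤
1.0 Å < red. Connectivity superposes each of two overlapping steps'
assigned-class representatives onto that step's own experimental atoms and
measures the distance between the two superposed references' copies of the
shared residue's C5′ and O3′ atoms. The shared residue is the only region
both references model, which pins down the atom attribution; the
reference-vs-reference contract reproduces the "perfect overlap → 0"
behavior for a chain cut from one continuous reference geometry.
Alternative suggestions list classes within an r.m.s.d. margin (default
0.2 Å) of the assigned class, re-ranked by total overlap distance when
neighbor context is available.

## Restraints

Each assigned step within the r.m.s.d. cutoff (default 1.0 Å, the
yellow/red boundary) — or any step with an explicit edit, which also
overrides the target class — contributes one torsion restraint per
prescribed torsion (the seven backbone torsions, χ₁, χ₂ and μ), targeting
the class mean with sigma = class e.s.d. / scale. The N–N and C1′–C1′
distances are not restrained: only torsions map naturally onto refinement
dictionaries. Dialects: a generic CSV (canonical, stable columns) and a
best-effort REFMAC external-torsion text format, versioned in its header.

## Synthetic structures

The generator builds 18-atom steps by sequential internal-coordinate (NeRF)
placement from idealized bond lengths and angles (standard nucleotide
stereochemistry, hard-coded as an overridable constant table). The nine
bonded torsions are placed directly. μ is not a bonded torsion: the second
base nitrogen is constrained to its chemical circle (C1′–N bond, N–C1′–O4′
angle) and the placement torsion is solved numerically (grid bracketing +
Brent refinement) so the measured μ equals the target. Only an arc of μ is
attainable for a given backbone (about a quarter of uniformly random
backbones have a restricted arc); an unattainable request is a build error,
and the random sampler draws μ inside the attainable arc so every sampled
parameter set is realizable by construction. Torsion round-trips
(build → measure) are exact to ~1e−12 degrees.

Synthetic reference classes share δ and χ values and differ in ε, ζ, α, β,
γ, which keeps every class chain-compatible with every other while the
pairwise scaled separation stays far above the 3× pooled-e.s.d.
distinguishability floor (asserted at generation time). μ and the two
distances of a class are emergent from the probe build at the class-mean
torsions and become that class's means, which makes the two residues of a
representative internally congruent. Polymers are therefore built by rigid
concatenation of representatives (superposing each next representative's
first residue onto the current terminal residue, with a 1e−6 Å congruence
check); incompatible consecutive classes fail that check with a build
error. Training vectors add wrapped-normal noise on angular axes and
truncated-normal noise on distances, seeded; defaults are 8° on torsions,
10° on μ, and 0.25–0.30 Å on distances, spreads typical of a well-populated
backbone conformer class.

What the generator does not emulate: real sugar puckers (the ring is not
closed; only the measured atoms are placed), base rings beyond the two
measured atoms, steric clashes, thermal motion, correlated torsion
distributions within a class, and experimental noise structure. Passing
tests on synthetic data therefore demonstrate the correctness of the
measurement/assignment/scoring machinery, not classification accuracy on
experimental conformer tables.

## Problem sizes and numerical choices

The test suite and the acceptance checks run on deliberately small synthetic
problems — 3–5 classes, tens of training points per class, chains of up to
12 residues, 500-sample round-trips, 1000-query oracle comparisons — sizes
at which the exhaustive oracles (grid rotation search, pure-Python k-NN) are
comfortable. Collinearity tolerance is 1e−8 on cross-product norms;
superposition degeneracy is detected on the second singular value of the
centered point set; the μ solver uses a 1° bracketing grid with 1e−12
refinement and picks the solution nearest the natural placement torsion when
several exist.

## Known limitations

* The published 96-class table, its CANA mapping and representatives are
  inputs, not shipped data; all defaults are exercised against synthetic
  references. Loading the published CSV/ZIP files is supported via the
  documented schema (case-insensitive column aliases, directory or ZIP of
  representative PDBs).
* Exact server-side constants (k, scaling, rejection cutoff, border
  semantics) are not published; the defaults above are this package's own
  and are all configurable.
* Only the generic and REFMAC restraint dialects are implemented.
* Percentiles require a user-supplied distribution.
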