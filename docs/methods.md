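# Methods

`agostruct` re-implements, as a tested pipeline, the computational analyses
behind an agonistic-antibody/receptor-clustering study: a bivalent IgG that
binds the membrane-proximal Fn3 domain of the endothelial receptor tyrosine
kinase Tie2 tethers preformed Tie2 homodimers into closed polygonal
assemblies, and was humanized by CDR grafting with structure-guided back
mutations. This note records the models, parameter choices and numerical
conventions behind each stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Coordinate model

Structures are flat atom lists in Å with PDB author numbering; no implicit
renumbering ever occurs, so residue symbols such as V730 or D682 mean the
same thing in the code as on a printed structure figure. The PDB reader is
a deliberate in-house fixed-width parser because its contract is part of the
toolkit's surface: parse errors name the offending line, alternate locations
resolve to the highest-occupancy conformer (ties to the alphabetically first
altloc id), only single-model files are accepted, and waters are excluded by
default (heteroatoms too, with switches for both — interface statistics are
computed without waters by convention, and whether the original analysis
retained them is not stated, hence the switch). Insertion codes are carried
but never used arithmetically. `write_pdb ∘ read_pdb` preserves coordinates
to the format's three decimals.

## Solvent-accessible and buried surface area

SASA uses Shrake–Rupley sphere sampling with a deterministic Fibonacci
lattice (default 960 points/atom), probe radius 1.4 Å, and Bondi-type van
der Waals radii (C 1.70, N 1.55, O 1.52, S 1.80 Å; unknown elements fall
back to 1.70 Å with a warning). Hydrogens, if present, are ignored
(united-atom convention). A surface point is occluded when it lies strictly
inside a neighbour's solvent-expanded sphere; a point exactly on that sphere
(coincident duplicate atoms) is ceded to the lower-indexed atom, making the
degenerate-overlap case well defined: exact duplicates contribute one
sphere's area in total. At 960 points the two-sphere error against the
analytic spherical-cap formula is ≈0.2%, comfortably inside the 0.5% the
test suite demands; point density is configurable where tests can afford
less.

Buried surface area of sides A and B is `(SASA_A + SASA_B − SASA_AB)/2`,
symmetric by construction and zero for non-contacting partners up to
sampling noise. The published interface numbers this machinery targets are
897.5 Å² for the Fab/Fn2–3 interface (≈57% heavy chain, 512.8 Å²; 43% light
chain, 384.7 Å²) and 704 Å² for the homotypic Fn3–Fn3′ dimer interface;
because the deposited coordinates are an external input, the suite verifies
the machinery on fixtures with analytic or constructive ground truth and an
independent Shrake–Rupley implementation, not on the accession.

**Per-part decomposition.** Splitting a side's BSA among parts (heavy vs
light chain) is exact on the A side (per-atom ΔSASA sums). The B side's
ΔSASA is attributed to parts by leave-one-part-out occlusion — how much of
B's surface each part alone buries — and renormalised so parts sum exactly
to the undivided BSA. When parts occlude disjoint patches of B (the usual
case for paratope chains) the renormalisation is a no-op; when patches
overlap, the shared area is split proportionally. This is a design choice;
the alternative (assigning shared occlusion to the nearest part) changes
nothing in the fixtures and was not pursued.

Interface residues are those losing more than 0.1 Å² of SASA on
complexation (threshold configurable), sorted by ΔSASA.

## Contact typing

Residue–residue contacts across an interface are typed by the first
matching rule in precedence order ionic > hydrogen bond > hydrophobic,
using community-standard heavy-atom criteria: ionic = opposing
formal-charge sidechain atoms (Lys NZ, Arg NH1/NH2/NE, His ND1/NE2 vs
Asp OD1/OD2, Glu OE1/OE2) within 4.0 Å; hydrogen bond = donor–acceptor
heavy atoms within 3.5 Å (hydrogens are generally absent at the relevant
resolutions, so no explicit D–H···A angle is evaluated — a documented
approximation); hydrophobic = apolar carbon pair within 4.5 Å, where
"apolar" excludes only the backbone carbonyl carbon (a deliberate coarse
rule: polarised sidechain carbons such as Tyr CZ are not excluded).
Hydrogen bonds whose atoms are both backbone N/O are flagged
`mainchain_hbond`, the signature of the antiparallel β-sheet that mediates
homotypic Fn3 dimerisation. For a winning hydrogen-bond kind every
qualifying atom pair is emitted (a β-ladder reports its full rung list);
ionic and hydrophobic contacts report the closest atom pair per residue
pair. One consequence of the charge-based ionic rule: the reciprocal
D682–N691′ pair the structure paper groups with its "electrostatic"
interactions types as a hydrogen bond here, since asparagine carries no
formal charge.

Epitope residues are assigned to the packaged A/B/C interface regions
(A: E643, N644, I645, K646, I647, H727 — heavy-chain ionic/H-bond contacts;
B: I647, I650, A707, V730, L732 — the central hydrophobic core;
C: Q677, E705, E728 — light-chain framework contacts). Assignment is a set:
I647 belongs to both A and B. The B region's published 413.5 Å² sub-total
depends on an unstated residue-subset definition and is therefore not an
acceptance quantity.

## Conservation

Orthologs are aligned end-to-end (global) under BLOSUM62 with affine gaps
(open 10, extend 0.5), via Biopython's `PairwiseAligner`; a simple
match/mismatch mode exists mainly so a brute-force dynamic-programming
oracle can verify optimality on short sequences. Identity is counted over
aligned columns where neither sequence is gapped — the convention that
matters when matching any printed percentage, with alternatives available.
Cross-reactivity is predicted iff **every** epitope position is conserved;
the rule is strict because the specificity argument is exact-residue based
(the central epitope valine is replaced by arginine in mouse and rat,
abolishing binding, while every epitope position is conserved in monkey).
A relaxed conservative-substitution mode was considered and rejected as the
default for that reason. Positions outside alignment coverage are reported
as uncovered and count against the prediction, never silently conserved;
an empty epitope list is vacuously cross-reactive, with a warning.

## Humanization

Numbering follows the IMGT unique scheme with fixed CDR intervals 27–38 /
56–65 / 105–117. A query is numbered by aligning it to the best-matching
IMGT-gapped germline (end gaps in the germline free, so CDR3/FR4 tails are
not penalised) and inheriting that germline's position frame; insertions
take letter codes, and the CDR3 tail is numbered symmetrically from both
ends, with lettered insertions around positions 111/112 for loops longer
than 13. Without a packaged J-segment reference, CDR3 is capped at 13
positions and the remainder numbered as FR4 from 118 — adequate for the
V-region analyses here, documented as a limitation. Identity below 40% to
every reference is rejected as "not a V region". This germline-anchored
scheme is deterministic and much simpler than a profile-HMM; it will
misnumber V domains far from the reference set.

Germline identity is counted over shared numbered positions, with and
without CDR columns (printed humanization identities do not always state
the convention). The FR donor is the argmax-identity germline, ties broken
by gene name with a warning. Grafting keeps parental CDRs on donor
frameworks; positions past the donor frame stay parental. Flank-rule
positions (heavy-chain 59 by default, mirroring the published S59→R59 swap
that preserves the HCDR2 conformation) always stay parental, and the swap
is recorded whenever the donor differs — note position 59 sits on the CDR2
boundary of the numbering scheme, so recording the substitution explicitly,
rather than relying on span membership, is what keeps the graft report
faithful.

Back-mutation flagging operates on a template complex containing the
parental Fv and antigen (here, the parental crystal Fv stands in for a
homology model — model building is out of scope). For each framework
position where graft and parent differ, the parental sidechain is tested,
in order, for heavy atoms within 4.5 Å of the antigen (`antigen_contact`),
of the partner V domain (`vh_vl_interface`), or of any CDR residue
(`cdr_support`); all triggered rules are reported, the first being primary.
The three cutoffs default to 4.5 Å — the value that reproduces the
published six back mutations on the deposited template (light chain G34N,
Y36L, Q55D, G66R; heavy chain R72V, T74K) — and are configuration, not
constants. `build_variant` applies a mutation list with per-position
verification, so the published sets turn the grafted chains into the
affinity-restored variants.

## Binding kinetics

The 1:1 Langmuir model `dR/dt = kon·C·(Rmax − R) − koff·R` is simulated by
its closed forms (association `R(t) = C·kon·Rmax/(C·kon+koff)·(1−e^{−(C·kon+koff)t})`,
dissociation `R0·e^{−koff t}`), verified against adaptive ODE integration
to 10⁻⁶ relative across the experimental ladder. The experimental design is
seven analyte concentrations (0, 2, 4, 8, 16, 32, 64 nM), 300 s association
and 300 s dissociation, sampled at 1 s; the zero-concentration blank is
subtracted before fitting. Global fitting shares one (kon, koff, Rmax)
across all traces, in log space for the rates, by trust-region nonlinear
least squares with bounds kon ∈ [10², 10⁹] M⁻¹s⁻¹, koff ∈ [10⁻⁶, 1] s⁻¹.
Initialisation: koff from the dissociation tail's log-slope, kon from the
observed half-rise time of the highest concentration, Rmax from the maximum
response with 20% headroom. Noiseless data refit to better than five
significant digits; with 2 RU Gaussian noise the median relative rate error
over 100 seeds is well under 5%. KD is reported as the exact quotient
koff/kon and at two significant figures for comparison with printed tables.
One printed-table curiosity is reproduced rather than hidden: the parental
antibody's printed rates quotient to 4.3 × 10⁻⁹ M at two significant
figures while its table prints 4.2 × 10⁻⁹ M (rounding before division);
the humanized-variant rows are self-consistent and are the ones used for
KD arithmetic checks. Mass-transport limitation, drift and bivalent-analyte
models are deliberately out of scope.

## Assembly geometry and shape statistics

The ring-feasibility argument identifies the Fab–Fab hinge angle with the
interior vertex angle of a regular n-gon, 180·(n−2)/n. An n-ring is
feasible iff that angle lies within the hinge range (IgG1: 115–148°)
widened by ±`vertex_tolerance`, a single parameter absorbing everything the
planar regular-polygon idealisation leaves out: Fab elbow flexibility, the
~15° epitope tilt, out-of-plane pucker, non-regular rings. At zero
tolerance the feasible set is {6,…,11}; 25° of tolerance admits the
tetragonal and pentagonal rings actually observed. The companion length
check — receptor-dimer epitope spacing (~120 Å) vs two-paratope reach
(~130 Å) — is a simple slack comparison (default 20 Å). Per-subclass hinge
distributions (IgG2, IgG4) are descriptive inputs, not predictions.

Assemblies are bipartite graphs of IgG hubs and receptor-dimer edges, both
degree ≤ 2. A connected graph with such degrees is a path (linear) or a
single cycle; a cycle with k hubs maps to <tetragonal (k ≤ 3; the
degenerate doubly-bridged k = 2 pair is folded into the same bin),
tetragonal, pentagonal, hexagonal, or >hexagonal (k ≥ 7). Category
statistics report exact counts, percentages to one decimal, and the
polygonal fraction (tetragonal through >hexagonal pooled, computed from raw
counts before rounding) — the summary statistic that separates the
flexible-hinge subclasses (≈73% and ≈70% polygonal for IgG1 and IgG4) from
the rigid one (≈11% for IgG2). The published figure gives only those pooled
totals per subclass, not per-category counts, so the acceptance script's
round trip uses a category mix constructed to make the polygonal total
exactly 1010 of 1381 particles (73.1%).

## Synthetic data

Generators emit fixtures with exact ground truth so every stage is testable
offline; all are seed-deterministic (byte-identical for equal spec + seed)
and small (≤ 500 atoms, ≤ 2000 particles; the full suite runs in seconds).

* **Sphere pairs** — two atoms with a custom radii set and the analytic
  spherical-cap union areas; the SASA oracle.
* **Slab complexes** — n isolated, identical two-atom contact sites
  apportioned among the A-side chains by largest remainder, so per-chain
  BSA fractions equal count ratios exactly by symmetry. This is what makes
  the 57/43-style decomposition checkable without the crystal structure.
* **β-ladders** — two antiparallel strands with hand-placed backbone
  geometry: even residues lean their N/O toward the partner (N···O 2.9 Å),
  odd residues lean away; the ground truth lists every intended
  mainchain hydrogen bond. Nine residues mirror the span of the receptor's
  homotypic strand.
* **Fv/germline pairs** — a random 104-column germline frame and a parent
  differing at exactly the designed number of scattered positions (a
  contiguous mismatch block would let the aligner trade mismatches for
  gaps), giving exact identity targets like 66% or 68%.
* **Sensorgram sets** — the closed forms at the experimental ladder, with
  optional Gaussian noise; defaults are the parental rates
  (kon 1.4 × 10⁵ M⁻¹s⁻¹, koff 6.0 × 10⁻⁴ s⁻¹, Rmax 100 RU).
* **Assembly sets** — graphs per category with largest-remainder counts.

What these fixtures do **not** emulate: real protein packing (no rotamers,
no realistic density, no crystal contacts), real sensorgram artifacts
(drift, mass transport, injection spikes), real EM classification noise
(misclassified particles), or real antibody sequence statistics. Passing
tests therefore demonstrate the correctness of the computational machinery
under its stated model, not robustness to experimental pathology.

## Numerical conventions and degenerate inputs

Ties and degeneracies are resolved deterministically throughout: altloc
ties alphabetically; coincident SASA points to the lower atom index;
germline-identity ties lexicographically by gene name; co-optimal
alignments by the production aligner's fixed traceback preference (verified
score-optimal against exhaustive dynamic programming). Empty structures,
empty candidate sets, empty epitopes, non-partitions, overlapping
selections, all-zero sensorgrams and disconnected assembly graphs raise
informative errors rather than guessing. All randomness flows through
`numpy.random.default_rng(seed)`.

## Problem sizes

Default suite sizes were chosen so the whole pipeline exercises its real
code paths at laptop scale: 960 SASA points/atom (240 where the tolerance
allows), 100-site slab complexes, 100-position Fv frames, 7 × 601-point
sensorgrams, 100-seed noise studies, and 1381-particle assembly sets.
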