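# Methods

`dimerscreen` triages and interprets two-chain structural models of
G-protein-coupled receptor (GPCR) dimers and of receptor/truncated-isoform
complexes. It consumes coordinates (PDB), transmembrane (TM) annotations
(UniProt-style 1-based inclusive ranges) and MMPBSA binding free energies
(BFE, kcal/mol; mean ± SEM), and produces compliance reports, interface
characterisations, model selections, blocking/competition verdicts and
clash-checked oligomer assemblies. It never runs structure prediction,
docking, molecular dynamics or MMPBSA itself — those numbers are inputs.

## Membrane frame and topology compliance

With no explicit bilayer present, each protomer's membrane is inferred
from its TM annotation. Every TM helix contributes an axis vector; for
helices of more than 18 residues the axis is the mean 18-residue
C-alpha offset (18 residues = five exact turns of an ideal alpha-helix,
so the C-alpha spiral cancels and the estimate is exact for ideal
geometry); shorter helices fall back to end-window centroids. Axes are
sign-corrected for the serpentine up/down alternation of a 7TM bundle
(odd-numbered TMs run extracellular to intracellular) and combined by a
singular-value decomposition into one unit normal, oriented so the
N-terminus falls on the extracellular side. The midplane passes through
the centroid of the per-helix C-alpha midpoints; the RMS scatter of
those midpoints about the midplane is reported as the fit residual.

A two-chain pose is *topology compliant* when

1. **orientation** — the angle between the two protomers' membrane
   normals is at most `orientation_tol_deg` (default 30°);
2. **layers** — the midplane offset along the mean normal is at most
   `layer_tol_A` (default 8 Å);
3. **symmetry** (homodimers only, detected by sequence equality) — both
   protomers contribute the same set of TM helices to the interface.

Rules 1–2 are stated only qualitatively in the modelling literature
("consistent orientation", "basically spatially consistent"); the
numeric defaults are this package's quantification, chosen to separate
in-membrane poses from upside-down or layer-shifted ones by a wide
margin (a flipped protomer scores 180°, a bilayer-hopping one ≥ 12 Å),
and every report echoes the thresholds used. Rule 3 is evaluated at
helix granularity, matching how interface compositions are tabulated in
the field.

## Interfaces, helix ranking and E/M/I qualifiers

A residue is an interface residue when any of its heavy atoms lies
strictly within `cutoff_A` (default 5 Å, the conventional print
threshold for per-residue MMPBSA decompositions) of a heavy atom of the
opposite protomer. Hydrogens are discarded on file read.

TM helices are ranked by their contribution to the interface: when a
per-residue energy decomposition is available, the score is the summed
negated contribution of the helix's interface residues; otherwise the
count of interface residues serves as a contact-extent proxy. Ties
break toward the lower helix index. Loops and the amphipathic Helix 8
participate in contact computation but are excluded from the ranking
and the formatted string, which shows TM helices only, in descending
contribution order, e.g. `TM2, TM1, TM3 (E), TM4 (I)`.

The parenthesised qualifier localises an interface patch along the
membrane normal: each helix's span is split into three equal thirds
(extracellular/middle/intracellular) and a third's letter is assigned
when at least `qualifier_frac` (default 0.6) of that helix's interface
residues fall inside it; otherwise no qualifier is printed, meaning the
majority of the helix is involved. The 0.6 default encodes "clear
majority" while letting a 2-of-3 residue patch qualify; it is
configurable because the verbal definition admits a range of cutoffs.

Residues "significantly contributing" to binding are those with a
per-residue decomposition below −1 kcal/mol (strict inequality).

## Model selection

Within a group of candidate models of one complex, only topology-
compliant models with a BFE are eligible. The minimum-mean model is
always kept. Additional models are retained — up to `max_keep` = 3 —
when their mean lies within `delta_keep` (default 15 kcal/mol) of the
best and their subject interface helix set has Jaccard similarity below
`distinct_jaccard` (default 0.5) with every model already kept: i.e.
comparably stable *and* structurally distinct binding modes are all
reported, reflecting that GPCR dimerization is dynamic and one complex
can populate several interfaces. SEMs are carried for reporting but do
not enter the decision.

## Blocking and competition

A truncated isoform *blocks* a dimerization interface when both

1. its interface on the shared subject receptor covers at least
   `overlap_min` (default 0.25) of the dimer's subject interface
   (residue-level set overlap; `frac_of_dimer` = |shared| / |dimer
   interface|), and
2. its complex binds at least as strongly as, or close to, the dimer:
   blocker mean ≤ dimer mean + `delta_close`.

`delta_close` defaults to 15 kcal/mol. This is the package's
quantification of "lower than or close to": the weakest published
blocking margin in the curated reference set is a blocker about
13 kcal/mol above the dimer that is still called blocking, so a 5
kcal/mol allowance would contradict the reported verdicts while 15
covers them with headroom and matches the `delta_keep` scale used for
"comparably stable" models. Both thresholds are printed with every
verdict.

Competition groups are connected components (≥ 2 members) of the graph
over same-subject complexes in which two models are linked when each
covers at least `overlap_min` of the other's subject interface.

Kabsch superposition (SVD with the usual reflection guard) over shared
subject TM C-alpha atoms aligns two complexes for steric inspection and
anchors oligomer extension; the test suite checks it against an
independent quaternion (Horn) implementation to 1e-6 Å.

## Oligomer assembly

Assemblies grow from a seed protomer: a dimer model whose subject
matches an anchor protomer is superposed onto the anchor and its
partner is added with the induced rigid transform. Placed protomers
never move. A clash is any heavy-atom pair from different placements
closer than `clash_cutoff_A` (default 2.0 Å — clearly below van der
Waals contact); residue pairs forming the designed parent/child
interface are exempt, since they are in legitimate contact. The builder
detects clashes and reports them; repair (side-chain rotation,
translation) is modelling work outside its scope.

## Synthetic structure generator

The generator emulates the *geometry* of the inputs the pipeline would
receive from structure prediction, docking and MD — not their physics:

- **Bundles**: `n_tm` (2–7) straight ideal alpha-helices (backbone
  N/CA/C/O plus a CB marker; 1.5 Å rise, 100°/residue, 2.27 Å C-alpha
  radius) on a circle of radius 12 Å at 2π/7 spacing, alternating
  up/down, 26 residues per TM (a 39 Å crossing, typical of a bilayer),
  joined by 6-residue notional loops that advance the numbering but
  carry no coordinates (as with unresolved loops in a PDB entry). Each
  helix uses a distinct marker residue type so interface membership is
  verifiable by sequence inspection. `n_tm` < 7 yields the Iso_XTM
  truncated-isoform topologies.
- **Dimer poses**: the partner bundle is spun about its own vertical
  axis until its designated facing helices point at the subject's, then
  translated in the membrane plane to a designated facing-helix axis
  separation (default 10 Å, which puts CB atoms of facing helices at
  ~3.4 Å — inside the 5 Å interface cutoff — while non-facing helices
  stay far outside). Equal facing sets give an exactly C2-symmetric
  homodimer, compliant by construction.
- **Decoys**: `flip` (partner upside down, violates orientation),
  `offset` (partner translated 15 Å along the normal, violates layers),
  `asymmetric` (partner spun two helix positions, violates homodimer
  interface symmetry), `tilt` (small tilt, stays compliant at default
  tolerances). Each decoy violates exactly its targeted rule.
- **Energy tables**: a requested total BFE is distributed with fraction
  `interface_frac` (default 0.9) over interface residues of both chains
  proportionally to their heavy-atom contact counts, the remainder
  uniformly over all other residues, plus seeded Gaussian noise
  (default SD 0.05 kcal/mol) — mimicking decompositions whose mass
  concentrates on the interface.

Everything is deterministic given the spec and seed. What passing tests
on these fixtures show is that the *decision logic* (frames, rules,
rankings, overlaps, selections, clash checks) behaves correctly on
structures whose ground truth is known exactly. They do not show
robustness to loop geometry, side-chain packing, helix kinks, or
docking-pose noise, which real AlphaFold/ClusPro/MD-derived structures
contain.

## Curated reference data

`data/reference_models.tsv` records the published most-stable models
for the four chemokine receptor systems (CXCR2, CXCR7, CCR2, CCR7):
designation, interface composition on subject and partner, and BFE mean
± SEM. `data/blocking_cases.tsv` records each published dimer/blocker
pairing, the helices stated to overlap (`none` where the report found
no interface overlap — note this is the stated relationship, which for
one CXCR7 case is finer-grained than a naive helix-name intersection),
and the reported outcome. Feeding these inputs through the standard
blocking rules reproduces all 13 published verdicts; this truth table
is part of the test suite.

The bundled receptor FASTA files (`*.synthetic.fasta`) are best-effort
transcriptions of the UniProt entries P41597 (CCR2), P51681 (CCR5) and
P61073 (CXCR4) written without database access; they are stand-ins, not
authoritative downloads. With BLOSUM62, affine gaps (−10/−0.5) and
identity counted over the full alignment length, they give CCR2/CCR5 =
71% and CCR2/CXCR4 = 31%, versus published values of 79% and 33%
produced by the UniProt align tool with unstated parameters; the
alignment parameters are therefore exposed in configuration rather than
fixed, and identity figures from the bundled sequences should be read
as approximate.

## Numerical choices and degenerate inputs

- Distances are strict inequalities at both the interface (5 Å) and
  clash (2 Å) cutoffs.
- Helix ranking ties break to the lower helix index; selection ties on
  equal means break by designation label, making selection invariant to
  input order.
- An empty interface yields an empty ranking and an empty interface
  string; overlap against an empty dimer interface is an error (the
  fraction would be undefined).
- Fewer than two TM segments make the membrane frame unfittable and
  the pose unfilterable (hard error naming the chain).
- Antiparallel membrane normals have an ill-defined mean; the layer
  offset then falls back to the first frame's normal (the pose has
  already failed orientation at any sane tolerance).
- Superposition requires at least three common subject TM C-alpha
  atoms; the Kabsch sign correction excludes reflections.
- Co-optimal global alignments can differ in identity count, so
  `pairwise_identity` canonicalises its argument order internally and
  is exactly symmetric.

## Problem sizes

The test suite and the acceptance script run entirely on generated
structures: 50 compliant poses plus 150 decoys for filter
discrimination, 20 poses for ranking-oracle agreement, 100 random point
sets for the superposition oracle, 4-protomer assemblies for clash
checks, and the 26-row curated table for the verdict truth table and
formatting round-trip. These sizes give exact, exhaustive coverage of
the decision logic at interactive runtimes (the whole suite runs in a
few seconds).
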