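# Methods

## Problem and scope

`rebelscan` analyses structural divergence inside protein domain
superfamilies. Members of a SCOP-style superfamily share an evolutionary
origin and a structural core, often at low (< 40%) sequence identity, but
individual members can deviate strongly — through topology changes,
insertions of secondary-structure elements, terminal extensions, circular
permutation or domain swapping. The package quantifies that deviation and
flags the deviant ("outlier") members, then asks whether the outliers are
also functionally distinct by comparing Gene Ontology annotations.

The pipeline starts *after* structure alignment: it consumes per-member Cα
traces (PDB) and a structure-based multiple alignment (gapped FASTA) of
the kind produced by MATT → COMPARER → JOY protocols. Producing that
alignment is out of scope; every non-gap alignment position is treated as
a structural equivalence.

## Deviation protocol

1. **Multiple superposition** (MNYFIT-style consensus fitting). The
   consensus is initialised from the member with the most aligned
   positions (ties broken lexicographically — the procedure needs *a*
   deterministic reference, and the most complete member perturbs the
   consensus least). Iteratively, every member is Kabsch-superposed onto
   the consensus over the *core columns* (columns ungapped in every
   member) and the consensus is re-estimated as the coordinate-wise mean;
   iteration stops when no consensus point moves more than `tol = 0.01 Å`
   (`max_iter = 100`). At these settings convergence typically takes 3–6
   iterations and the fixed-point residual is below the tolerance, so the
   stopping rule never dominates runtime. Equivalences stay fixed to
   alignment columns throughout; reflections are rejected (a mirror-image
   superposition is physically meaningless for backbones).

2. **Pairwise RMSD and mean RMSD.** Entry (a, b) of the RMSD matrix is
   computed over the columns ungapped in *both* a and b, using the
   coordinates as placed by the multiple superposition (the
   "common-frame" mode, matching the protocol order superpose-then-
   measure). An optional `repair` mode re-superposes each pair optimally
   and is clearly non-default. A member's **mean RMSD** is the arithmetic
   mean of its one-against-all row; pairs with fewer than 3 matched
   columns are excluded from means with a logged warning. Whether the
   threshold should apply to common-frame or re-paired RMSD is not
   determined by the protocol description we follow; common frame is the
   default because it preserves the stage order.

3. **TM-score confirmation.** TM = (1/L_N) Σ 1/(1 + (dᵢ/d0)²) over
   matched columns, maximised over superpositions, with
   d0 = max(0.5 Å, 1.24·(L_N − 15)^⅓ − 1.8) and L_N the *shorter*
   member's length by default (configurable: longer/first/second). The
   0.5 Å floor keeps d0 positive for domains shorter than ~21 residues.
   Maximisation is a deterministic seed-and-extend search: each seed
   fragment is Kabsch-fitted, then refined by repeatedly re-fitting on
   the residue pairs closer than d0 + 1 Å (never fewer than 4; if fewer
   qualify, the 4 closest) until the score changes by < 1e-6 or 20
   rounds. With ≤ 48 matched columns the seeds are *all* contiguous
   fragments of length ≥ 4, making the search exhaustive over seeds; we
   found strided seed subsets can miss the best basin by up to ~0.04 on
   noisy small instances, while exhaustive seeding is cheap at these
   sizes. Above 48 columns, seeds are fragments of lengths
   {L, L/2, L/4, 4} at stride L/10 — at realistic domain sizes the
   landscape is dominated by large rigid blocks these always intersect,
   and exhaustive seeding would be quadratically more expensive.

4. **Outlier call.** Member m is a structural outlier iff
   `mean_rmsd(m) > 5.5 Å` **and** its median TM-score against the other
   members is `< 0.5` (strict inequalities; a member at exactly 5.5 Å is
   not an outlier). The 5.5 Å and 0.5 values are the thresholds
   established for this analysis style; the conjunction reads the
   TM-score as *confirmation* of the RMSD flag, which also lets the
   implementation skip TM computation for members under the RMSD cut
   (an `or` rule and full TM matrices are available behind flags).
   Median (not mean) TM aggregation is used so one aberrant partner
   cannot drag a member below the cut. Superfamilies are categorised by
   outlier count: none / single / two / multiple.

5. **Family specificity.** An outlier set is family-specific when all
   outliers carry one family label and no non-outlier carries it — the
   situation where structural deviation coincides with a family boundary
   and hence suggests a functional reason.

6. **Reason hints.** Two screening heuristics annotate outliers:
   gap-run summaries (maximal runs where a member is ungapped while > 50%
   of others are gapped = insertion, and vice versa = deletion; runs
   touching an alignment end are terminal extensions) and a
   circular-permutation scan (cyclic shifts of one member's residue
   order at a 5-residue grid with ±4 refinement, positionally matched
   and Kabsch-fitted; a CP signal requires the RMSD improvement over the
   unshifted fit to exceed both 1 Å and half the unshifted RMSD, which
   unrelated structures do not reach while a true CP pair collapses to
   near-zero RMSD at the correct shift). Both are hints for inspection,
   not classifiers; categories like domain swapping or topology change
   require visual/structural analysis and are out of scope.

## GO semantic similarity

Term-level similarity follows the Wang (G-SESAME) scheme: S-values
propagate from a term up the DAG (S = 1 at the term; at each ancestor the
maximum over child paths of the child's S times an edge factor — 0.8 for
`is_a`, 0.6 for `part_of`, the conventional contribution factors,
configurable), and two terms are compared through the S-value mass of
their shared ancestors. Aggregation is two-level: a domain pair's
similarity is the plain mean over all cross term pairs, and a member's
score is the grand average of its pair means against every other
annotated member. Cross-namespace pairs (no shared ancestor) score 0
rather than being skipped — "all pairs that could be compared" includes
them, and 0 is the natural value for disjoint ancestry — with a
`skip_disjoint` flag for the alternative reading. A best-match-average
aggregation is available behind a flag but is not the default. Evidence
codes and annotation propagation to ancestors are not applied; the
annotated terms themselves are compared. All means use compensated
summation in sorted member order, reproducible to 1e-12.

Outlier vs non-outlier contrast: group means of member scores, plus a
per-member table (mean RMSD, GO score, outlier flag) that is the
plot-ready form of the structural-vs-functional comparison.

## Synthetic superfamilies

No real superfamily corpus can be bundled, so all recovery experiments
run on generated ensembles with known ground truth.

* **Core trace.** A self-avoiding Cα trace of alternating idealised
  helical segments (rise 1.5 Å, 100°/residue, radius solved so
  consecutive spacing is exactly 3.8 Å) and extended zigzag segments,
  connected at random bend angles of 20–70°; segment placements that
  would bring non-consecutive atoms within 2.4 Å are redrawn (up to 200
  tries). This reproduces the two statistical features the metrics care
  about — uniform Cα spacing and compact, self-avoiding geometry —
  and nothing else (no side chains, hydrogen bonding or Ramachandran
  statistics).
* **Members.** Each member is the core plus per-atom isotropic Gaussian
  noise (default σ = 0.3 Å, a typical within-family coordinate spread)
  in a random rigid frame. Planted perturbations: hinge rotations
  (about an axis through the hinge point, auto-chosen perpendicular to
  the rotated block so displacement is maximal; chain connectivity at
  the hinge stretches slightly, acceptable since only Cα geometry enters
  the metrics), insertions (a semicircular loop leaving the surface),
  deletions, circular permutation and segment swap. Insertions add
  alignment columns gapped in all non-carriers; deletions gap the
  carrier. Circular permutation and segment swap deliberately keep a
  *positionally naive* alignment — exactly what a linear alignment
  produces for a permuted member, and why such members surface as
  outliers.
* **Canonical outlier.** The two-hinge plan on a 120-residue core
  rotates residues [40, 80) by 120° and [80, 120) by 150° about
  orthogonal axes, leaving a largest rigid block of 40 residues so no
  single superposition can fit more than ~⅓ of the member well. Under
  the default thresholds this member's mean RMSD is ~30–45 Å and its
  TM-scores ~0.36 — robustly on the outlier side of 5.5 Å / 0.5 without
  being tuned to sit near them.
* **Toy ontology.** A single root with disjoint `is_a` chains (one per
  branch; occasional within-branch `part_of` shortcuts exercise the
  second edge type without creating cross-branch ancestry). One branch
  is reserved for planted-outlier families, so their annotations share
  only the root with everyone else's — the planted form of the
  structural-functional contrast. Within-branch term similarity always
  exceeds cross-branch similarity by construction.
* **Determinism.** One integer seed per spec drives a single generator
  with a fixed draw order (core trace; then per member: noise, frame);
  regeneration is byte-identical, and emitted files (PDB, FASTA, TSV,
  OBO) are written in sorted, fixed-format order.

## Study conditions and what the tests show

The standing experiment is 200 simulated superfamilies of 10 members,
120-residue core, σ = 0.3 Å, with the canonical two-hinge member: the
planted member's mean RMSD exceeds 5.5 Å and its TM-scores fall below
0.5 in ≥ 95% of seeds, null ensembles (no perturbation, σ ≤ 0.5 Å) yield
zero outliers in ≥ 99% of seeds, and planted branch-disjoint annotations
put every outlier's GO score strictly below every non-outlier's. These
sizes keep the complete suite within a few minutes on one CPU while the
fractions estimate the recovery probabilities to ~±2%. Passing them
shows the statistics, thresholds and plumbing behave correctly under the
generative model; it does not certify performance on real superfamilies,
where deviation is not rigid-block-shaped, alignments contain errors,
and annotation quality varies.

## Numerical choices and edge cases

* Kabsch via SVD with sign correction of the smallest singular direction
  (proper rotations only); rank < 2 point sets raise an error in the
  public API, while internal TM seeding tolerates them (short fragments
  of extended segments are nearly collinear and any optimal rotation
  serves as a seed).
* RMSD matrices are symmetric with exact zero diagonals by construction;
  missing pairs are NaN and excluded from means, never imputed.
* TM-score of identical inputs is exactly 1.0 under shorter-length
  normalisation.
* Tie-breaks are lexicographic (reference member, CP shift) so all
  outputs are deterministic; report values are fixed at 4 decimals.
* Boundary convention: thresholds are strict (`>`, `<`).

## Known limitations

* The outlier rule inherits the thresholds' calibration; on superfamilies
  whose members are systematically shorter than ~50 residues the 5.5 Å
  cut is conservative and d0 sits at its floor.
* The CP scan assumes comparable lengths and a single permutation point;
  it is a screening hint only.
* GO aggregation treats annotation sets as flat term lists; no
  information-content weighting or evidence-code filtering.
* The synthetic generator plants rigid-body perturbations; gradual,
  distributed divergence (e.g. uniform loop flexibility) is represented
  only through isotropic noise.
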