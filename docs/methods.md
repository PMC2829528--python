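# Methods

## Model and objective

A protein structure is reduced to its Cα trace: an ordered sequence of
coordinate triples in Å. A multiple alignment of K structures is a
gapped matrix H of K+1 rows, where row 0 holds the consensus
pseudo-structure and removing the gaps from any row reproduces that
structure's residue sequence in order. Column costs are squared
distances: ‖a − b‖² for two triples, ρ² for a triple against a gap,
0 for two gaps. The objective is the sum-of-consensus (SC) distance —
the total column cost between the consensus row and every protein row
after each protein has been moved by its own rigid transform
G = (B − e·t)R (row-vector convention; the consensus frame is fixed).

The consensus is geometric only: a sequence of pseudo-Cα positions,
not a real protein. It is written out as a PDB chain of UNK residues.

## The three closed-form sub-problems

The iteration rests on three exact optimizations, each for one block
of variables with the others held fixed:

* **Rotation.** For matched, centered point sets A (consensus) and B
  (protein), the proper rotation minimizing ‖A − BR‖² is R = UWVᵀ
  where UΣVᵀ is the SVD of BᵀA and W = diag(1, 1, det(UVᵀ)). The
  determinant correction excludes reflections; for rank-deficient
  covariances (collinear or coplanar sets) the optimum may be
  non-unique and any optimal rotation is acceptable — tests therefore
  check residuals, not matrices. All-zero covariances (n = 1, or
  coincident points) return the identity with a warning.
* **Translation.** For a fixed rotation, t = centroid(B) −
  centroid(A)·Rᵀ matches the centroids of the two matched sets.
  Mismatch columns (any gap) are removed before superposition, since
  a transform does not change a gap's cost.
* **Consensus column.** For a fixed correspondence and frames, the
  optimal consensus decomposes per column: the candidate triple is the
  centroid x of the m protein triples present (the centroid minimizes
  the sum of squared distances), with total column cost
  spread + g·ρ², against m·ρ² for a gap (g = number of protein gaps,
  spread = Σ‖x − pᵢ‖²). The default rule compares exactly these two
  totals, which is what makes the consensus update non-increasing in
  SC. A `rule="literal"` variant drops the g·ρ² term from the triple
  branch (the textbook two-case comparison); the two coincide on
  gap-free columns, but the literal rule can increase SC on columns
  with protein gaps and is therefore not the default. Ties keep the
  triple, keeping the consensus maximal and deterministic.

## Pairwise alignment

Alignment against a fixed consensus in a common frame is global
dynamic programming (Needleman–Wunsch recurrences) over the squared
distance matrix, with a constant per-gap-column cost ρ² — no affine
open/extend distinction and no special treatment of terminal gaps,
so the column cost bookkeeping of the consensus theorem stays exact.
Tie-breaking is deterministic: match over gap-in-moving over
gap-in-fixed. The DP fill is JIT-compiled with numba.

The bootstrap aligner for two structures in arbitrary frames seeds
with the best of three gapless window superpositions (N-terminal,
centered, C-terminal; window = min(l_P, l_Q, 40)), then iterates
{superpose on current match columns → re-run the DP} until the cost
improvement drops below 10⁻⁶ Å². Both half-steps are optimal for what
they minimize, so the cost sequence is non-increasing. Any other
pairwise structure aligner could be plugged in here; only the
resulting alignment and transform are consumed downstream.

## Center-star merge

The K pairwise alignments against the consensus are merged into one
matrix: consensus positions become shared columns; each protein's
insertions get private columns placed immediately before the consensus
position they precede, ordered by protein index (the order of mutually
gapped columns does not affect SC). Projecting the merge back onto any
(consensus, protein) pair and deleting mutual-gap columns reproduces
the input pairwise alignment exactly — the property the convergence
argument needs, and the contract the tests enforce.

## Main loop and convergence

Outer iteration: re-align every protein to the current consensus
(iteration 0: bootstrap pairwise alignment around the chosen center;
later: DP in the current frames), merge, then interleave per-protein
superposition with per-column consensus updates until the objective
stalls (tolerance 10⁻⁶ Å², cap 100 inner iterations), strip all-gap
columns, and update the consensus once more. The loop stops when the
relative SC decrease falls below η (default 10⁻⁴; an absolute-change
mode is available). Each step is non-increasing in SC: the DP is
optimal per pair, the merge preserves pair costs, superposition and
consensus updates are exact minimizers, and stripping all-gap columns
costs nothing. Termination within the 100-iteration cap follows; in
practice 2–4 outer iterations suffice on the synthetic families.

Initial-consensus strategies: *median* (lower median length, lowest
index on ties), *center* (minimum sum of pairwise alignment costs),
*minmax* (minimum worst-case pairwise cost), and the default *maxcore*
(largest strict core of the candidate's initial center-star merge).
All pairwise strategies reuse one cache of the K(K−1)/2 bootstrap
alignments, flipping alignment and transform for the reverse
direction.

## Parameters

| parameter | default | meaning |
|---|---|---|
| ρ² (`gap_cost_sq`) | 16.0 Å² | squared cost of a triple/gap column; ρ = 4 Å matches the 4.0 Å core cutoff scale. A `linear` mode squares the given value instead, for users who quote ρ directly. |
| η (`eta`) | 10⁻⁴ | relative SC convergence threshold |
| `inner_tol` | 10⁻⁶ Å² | objective tolerance of the inner loops |
| core cutoff | 4.0 Å | strict-core mutual distance bound |
| `max_outer_iters` / `max_inner_iters` | 100 | safety caps |

## Evaluation metrics

The strict core is the set of columns with no gap in any protein whose
K triples are mutually within the cutoff ("all-pairs" rule; a
consensus-referenced variant is available). Core RMSD is the average
over the K(K−1)/2 structure pairs of the RMSD over core columns in
the final frames, with no re-superposition — it measures the multiple
alignment as produced. An empty core is reported as "no core", never
as 0.0. Core size is also expressed as a percentage of the shortest
protein's length.

## Synthetic families

The generator emulates a family of close homologs: a template backbone
(random walk, Cα–Cα distance fixed at 3.8 Å, bend angles 40–105° from
the previous bond direction, resampling steps that approach an earlier
atom closer than 3.2 Å), copied K times with recorded indels, iid
Gaussian coordinate noise, and recorded random rigid motions. Defaults:
80 residues, K = 5, σ = 0.3 Å (sub-Å backbone agreement typical of
close homologs), 5% per-residue indel rate with events of 1–3
residues. Inserted residues are placed perpendicular to the local
backbone direction, as insertion loops protrude from a conserved fold;
an insertion that continued the backbone trace would make the declared
ground truth unidentifiable in principle. All randomness flows from a
single seed.

What the generator does **not** model: secondary-structure geometry
and Ramachandran statistics, correlated (domain-level) motions,
hinge/flexible alignment cases, sequence similarity, or alternate
conformers. Passing the synthetic closed-loop tests therefore shows
that the optimization machinery is correct and convergent, not that
alignment quality on divergent real folds matches any particular
benchmark.

## Known limitations and behaviour worth knowing

* **Consensus coverage is bounded by the initial center.** Consensus
  columns can be dropped but never created, so template regions absent
  from the chosen center protein can never be aligned across the other
  structures. On indel families a few percent of true residue pairs
  are structurally unrecoverable for this reason; recovery is perfect
  on indel-free families and, empirically, ≥99% (pooled) on pairs the
  center can represent.
* **Register slips near adjacent indels.** With coordinate noise, a
  one-register mismatch over a short run (≈3.8² ≈ 14.4 Å² per column)
  can undercut the two gap columns (2ρ² = 32 Å²) that the true
  placement requires; occasional single-column slips at indel
  boundaries are inherent to the cost model at ρ = 4 Å.
* **maxcore is tie-sensitive.** Core sizes are small integers; a tie
  broken to a different center changes which regions the consensus can
  represent and hence the final SC. The cost-based *center* strategy
  is order-robust and is what the permutation-robustness test uses.
* Sequential alignments only: no non-sequential or hinge/flexible
  correspondence. Low-support columns (e.g. a single protein present
  with several gaps) are dropped from the consensus by the SC rule;
  use `rule="literal"` to reproduce the more permissive textbook
  comparison.

## Problem sizes used by the automated checks

The test suite and acceptance script run on synthetic families with
K ∈ {2..8} and template lengths 20–120 (200 families for the
convergence check, 30 for the acceptance summary), 100-point-set
oracles with 10,000 random rotations each, exhaustive alignment
enumeration up to length 6, and a (K, n) timing grid up to K = 8,
n = 160 for the O(K²n²) scaling check.
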