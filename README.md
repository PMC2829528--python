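# mapsci

Multiple protein structure alignment with consensus identification.

`mapsci` simultaneously superposes a set of protein backbones — each
represented as the ordered sequence of its Cα coordinate triples — and
builds a **consensus pseudo-structure** that captures their common
geometry. It is aimed at structural bioinformaticians who need a fast,
coordinate-based multiple alignment of homologous folds together with
the standard conserved-core quality metrics.

## The objective

Let P₁,…,P_K be the input backbones and P₀ the consensus, arranged in a
gapped correspondence matrix H (row 0 = consensus). Each protein is
moved by a rigid transform Gᵢ = (Hᵢ − e·tᵢ)Rᵢ with rotation Rᵢ and
translation tᵢ; the consensus frame never moves. The quality of the
alignment is the **sum-of-consensus (SC) distance**

    SC = Σᵢ Σ_columns d(P₀[col], Gᵢ[col])²

where d is the Euclidean distance for two coordinate triples, the gap
penalty ρ for a triple against a gap (ρ² = 16 Å² by default) and 0 for
two gaps. The algorithm approximates the minimum by iterative
refinement:

1. choose an initial consensus protein (by default the *maxcore*
   candidate, whose initial center-star alignment yields the largest
   strict core);
2. align every protein to the consensus (full pairwise structure
   alignment on the first pass, plain dynamic programming in the
   current frames afterwards) and merge the pairwise alignments
   center-star-style into one matrix;
3. interleave the closed-form optimal rigid superposition of each
   protein onto the consensus (SVD/Kabsch rotation with determinant
   correction, centroid-matching translation) with the per-column
   optimal consensus (column centroid or gap, whichever contributes
   less to SC);
4. drop all-gap columns and repeat until the relative SC decrease
   falls below η = 10⁻⁴.

Every step is optimal for the quantity it changes while the rest is
held fixed, so the SC-distance is non-increasing and the iteration
converges to a local minimum. Runtime is O(K²n²) for K structures of
length ≤ n.

The package reports the **strict core** — alignment columns with no
gap in any protein whose K superposed triples are mutually within
4.0 Å — and the **core RMSD**, the average over structure pairs of the
RMSD across core columns in the final frames.

## Worked example

Generate a synthetic family of 4 structures (60-residue template, 0.3 Å
coordinate noise, 5% indel rate, arbitrary frames) and align it:

```sh
$ mapsci synth --length 60 --k 4 --noise 0.3 --indel-rate 0.05 --seed 2 --outdir family
wrote 4 structures + ground_truth.json to family

$ mapsci align family/fam2_m0.pdb family/fam2_m1.pdb \
               family/fam2_m2.pdb family/fam2_m3.pdb --outdir aligned
aligned 4 structures in 2 iteration(s); SC = 270.5730 A^2
strict core: 54 columns (93.1% of shortest), core RMSD 0.734 A
outputs written to aligned
```

The final SC of ≈270 Å² is the residual cost of noise and indels
(about 0.3 Å-scale deviations per matched column plus ρ² = 16 Å² per
gap column); 54 of the 58 residues of the shortest structure (93.1%)
form a strict core whose average pairwise RMSD, 0.734 Å, is consistent
with the injected σ = 0.3 Å per-coordinate noise (pair deviation
≈ √(2·3)·σ ≈ 0.73 Å). `aligned/` contains the transformed structures
and the consensus in PDB format, the alignment in NBRF/PIR format, and
`report.json` with the SC trace and core statistics. Real PDB files
work the same way; append `:A` to a path to select chain A.

The same pipeline is available as a library:

```python
from mapsci import align, core_report, read_structure

structures = [read_structure(p) for p in ["1abc.pdb", "2def.pdb:A"]]
result = align(structures)                  # AlignmentResult
print(result.sc_trace, core_report(result))
```

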