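# Methods

## The model

`pbsuper` compares two protein structures by reducing each backbone to a
sequence over the Protein Block (PB) structural alphabet and aligning the
sequences. The underlying assumption is that local backbone conformation,
captured by the φ/ψ torsions of overlapping pentapeptides, carries enough
signal to recover the residue correspondence between two related folds;
the subsequent Kabsch fit and distance-based scores then quantify how well
that correspondence superposes in 3D.

### PB encoding

The alphabet has 16 prototypes `a`–`p`, each an 8-vector of reference
torsions spanning five consecutive residues in the order ψ(i−2), φ(i−1),
ψ(i−1), φ(i), ψ(i), φ(i+1), ψ(i+1), φ(i+2). The prototype table ships as a
versioned TSV (`data/pb_prototypes.tsv`) with its provenance in the header;
`m` is the α-helix core and `d` the central β-strand. Assignment is to the
prototype minimising the RMSDA

    RMSDA(w, p) = sqrt( (1/8) Σ_k wrap(w_k − p_k)² ),   wrap(d) = ((d+180) mod 360) − 180,

with ties broken alphabetically (ties have measure zero but the rule makes
the encoder fully deterministic). A chain of N residues yields N−4 assigned
letters; positions whose window is incomplete get `Z`. A window is
incomplete when it touches a chain terminus, a residue missing any of
N/CA/C, an author-numbering gap, or a geometric chain break
(Cα(i)–Cα(i+1) > 4.5 Å — generous versus the bonded ~3.8 Å but below any
genuinely broken chain). Torsions are signed IUPAC angles in degrees in
(−180, 180]; exact trans is +180, never −180.

### Substitution matrix

Alignment is driven by a symmetric 16×16 PB similarity table with a
dominant diagonal. The bundled default (`data/pb_substitution.tsv`) is
derived from the alphabet's own geometry:

    s(x, y) = 6 − 0.15 · RMSDA(prototype_x, prototype_y),  rounded to 0.1,

giving a uniform diagonal of 6 and off-diagonal scores from −14.3 (the two
most dissimilar prototypes) up to 1.9 (near-identical helical caps). This
is a transparent, reproducible stand-in for matrices estimated from
observed PB substitutions in curated structure alignments; users with such
a matrix can pass it via `load_matrix()`/`--matrix` (same validation:
16×16, symmetric within 1e-9, diagonal-dominant). `Z` is not part of the
matrix: any column involving `Z` scores a fixed neutral 0 — `Z` encodes
absence of structural signal, so it neither rewards nor penalises, and it
can never seed an anchor.

### Two-pass anchored alignment

Plain global alignment uses affine gaps (Gotoh three-state DP). A gap run
of length L costs `gap_open + (L−1)·gap_extend`; defaults −5 and −0.5 in
the units of the matrix, i.e. opening a gap forfeits roughly one good
column and extending is cheap, which favours few long gaps as expected
between homologous folds. Traceback tie order is fixed (diagonal > up >
left) for reproducibility. The DP allows adjacent opposite-side gap runs
(each paying its own opening), which is exactly the convention the
brute-force enumeration oracle scores, so optimality is testable to
machine precision.

The two-pass procedure: (i) align once under *stringent* parameters —
substitution scores and both gap penalties multiplied by a weight
(default 10) — and extract anchors: maximal runs of consecutive aligned
columns whose unweighted per-column score is at least 80% of the maximum
diagonal entry (4.8 by default, so near-identical PBs only) and whose
length is at least 5 (one PB window); (ii) freeze the anchors and align
each inter-anchor and flanking region independently with the relaxed
(ordinary) parameters. With no anchors found the result is bit-identical
to plain global alignment — the procedure can only ever restrict, never
invent, correspondence. The three anchor constants are configuration, not
code, since published variants of the idea differ in their exact values.

### Superposition

The rigid transform minimising Σ‖R·a + t − b‖² over aligned Cα pairs is
computed by the closed-form SVD solution with the determinant-sign
correction on the smallest singular vector, so reflections are excluded
even for pathological (mirror-image) input. Degenerate inputs — fewer than
3 pairs, collinear point sets — raise descriptive errors. Optional
trimming (off by default; `--trim CUTOFF`) alternates fitting with
re-selecting, from *all* aligned pairs, those within the cutoff of their
partner, until the retained set reaches a fixed point; re-selection rather
than monotone deletion lets pairs excluded under an early compromise fit
re-enter once outliers are gone, and a seen-set guard terminates the rare
oscillating case. Both `rmsd_all` (all aligned pairs) and `rmsd_fitted`
(retained pairs) are reported under the final transform, since published
RMSDs are often ambiguous about which of the two they are.

### Scores

**GDT_TS** = 100 × mean over τ ∈ {1, 2, 4, 8} Å of the largest found
fraction of aligned Cα pairs simultaneously within τ. The exact optimum is
exponential, so the search is the standard iterative approximation: seed
superpositions from the full pair set and from every contiguous segment of
length 3 and 7, iterate fit → keep-pairs-within-τ → refit to a fixed point
(cycle-guarded, ≤20 iterations), and keep the best count. Thresholds are
processed in ascending order and the best transform found at each is
re-evaluated at the looser ones, which guarantees the reported fractions
are monotone nondecreasing in τ. The denominator is min(complete residues
of the two chains) — the model-evaluation convention — so unaligned
residues count against the score. The search is deterministic; it can in
principle undercount the true optimum, never overcount.

A note on a tempting "obvious" expectation: for a chain whose second half
is rigidly displaced by D, per-threshold fractions are *not* ½ whenever
τ < D. A compromise fit holds both halves at D/2, and rotations pivoting
near the junction legitimately capture more than half the pairs at
intermediate thresholds. Fractions of exactly ½ are only guaranteed when D
is much larger than every threshold (the test suite uses 200 Å), and the
direct-counting checks are written against that geometry.

**GDT_PB** transplants the four-bin construction onto PB space: each
aligned non-`Z` column gets a normalised similarity
u = (s(x,y) − s_min) / (min(s(x,x), s(y,y)) − s_min), clipped to [0, 1]
(1 for identical letters, 0 at the matrix floor), and the score is the
mean over the quartile thresholds {0.25, 0.5, 0.75, 1.0} of the fraction
of columns with u ≥ q. The denominator is the number of aligned non-`Z`
columns; with none, the score is undefined and reported as such. The
binning is configurable; no claim is made that it numerically matches
other published GDT_PB variants.

**PB identity** is the fraction of aligned non-`Z` columns with equal
letters.

## Synthetic fixtures

The generator grows N/CA/C backbones from per-residue (φ, ψ) lists by
NeRF-style internal-coordinate extension with fixed bond lengths
(N–CA 1.458, CA–C 1.525, C–N 1.329 Å), fixed bond angles (N–CA–C 111.2°,
CA–C–N 116.2°, C–N–CA 121.7°) and ω fixed trans — standard backbone
geometry; only torsions vary, which is exactly the degree of freedom PBs
measure. Round-trip (build → measure) reproduces prescribed torsions to
well below 1e-6°. `perturb` adds seeded Gaussian coordinate noise;
`make_pair` applies torsion substitutions and deletions to produce aligned
pairs with known ground truth.

What the fixtures do *not* emulate: side chains, non-trans peptide bonds,
bond-geometry variation, steric exclusion (chains may self-intersect), and
the long-range compactness of real folds. A deletion in torsion space
reorients everything downstream of the cut, so synthetic deletion pairs
have locally identical but globally divergent geometry — ideal for testing
the aligner (the PB tracks are unaffected) but unlike a real loop
deletion, where the flanking domains usually still superpose. Passing
tests therefore demonstrate correctness of the encoding, alignment,
fitting and counting machinery, not field performance on crystallographic
data; the end-to-end check on a real monooxygenase pair covers the latter
when the structures are available.

## Problem sizes and defaults

Synthetic checks use chains of 5–80 residues and a 60-residue mixed
helix/strand fold for the seeded acceptance runs — large enough to contain
every window/terminus/gap case and several anchors, small enough that
exhaustive oracles (brute-force alignment enumeration at length ≤ 8,
direct GDT counting) stay exact. Coordinate noise of σ = 0.3 Å matches
typical experimental precision; the 0.2 Å envelope test brackets the
expected Kabsch RMSD of such noise. Alignment of two ~530-residue chains
(the real-structure example) takes a few seconds; the DP is O(n·m) in time
and memory.

## Known limitations

- The bundled substitution matrix is geometry-derived, not
  substitution-count-derived; alignments of genuinely divergent folds may
  differ from those produced with an empirical matrix (which can be
  supplied by the user).
- The GDT superposition search is an approximation (seeds + refinement);
  reported GDT_TS is a lower bound on the exhaustive-search value.
- Anchors are taken from a single stringent alignment; alternative
  consistent anchor sets are not explored.
- mmCIF is read, but output is always PDB fixed-format (3-decimal
  coordinates), which bounds round-trip fidelity at ~1e-3 Å.
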