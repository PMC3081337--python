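# Methods

## Overview

`seqspace` maps a protein family into a low-dimensional "sequence space"
and asks two questions: how are the family's sub-groups organized in that
space, and which alignment positions make a group what it is.  The
pipeline is: gap-filter the multiple sequence alignment → squared
identity-distance matrix → classical (metric) multidimensional scaling →
out-of-sample projection of further sequence sets → consensus K-means with
silhouette model selection → per-column group-contrast statistics.

## Distances

The dissimilarity between two aligned sequences is the p-distance: the
proportion of comparable sites at which they differ.  Comparable sites are
defined by *pairwise* gap deletion by default (each pair ignores the
columns where either member is gapped); *complete* deletion (drop every
column that is gapped anywhere in the set before comparing) is available
and coincides with pairwise deletion on gap-free alignments.  Because the
analysis is restricted to columns with < 2% gaps, the two modes differ
negligibly in practice.  The matrix is stored **squared**, since the
squared-distance matrix is what double centering consumes.

The unknown residue `X` is scored as a mismatch against everything,
including another `X` (configurable).  This is a deliberate, conservative
choice: `X` asserts ignorance, not identity.  No evolutionary-model
correction (Poisson, JTT…) is applied — the p-distance is nearly Euclidean
for alignments of this diversity, which is exactly what the negative-
eigenvalue diagnostic (below) measures.

## Classical scaling and the supplementary projection

With **D** the N×N squared-distance matrix, the cross-product matrix is

    S = -1/2 · C D C,   C = I - (1/N)·1,

eigendecomposed as S = U Λ Uᵀ.  Factor scores F = U₊ Λ₊^{1/2} over the
components with positive eigenvalue give coordinates whose Euclidean
distances reproduce the input distances exactly when the input is
Euclidean.  Negative eigenvalues are retained as a diagnostic — their
share of the absolute spectrum measures how non-Euclidean the distances
are — but are excluded from F (Λ^{1/2} is undefined there).

A supplementary set with squared distances **D**_sup (N_sup×N, to the
active elements only) is placed in the same space by Gower's add-a-point
formula:

    S_sup = -1/2 · (D_sup - (1/N)·1_sup·D) · C
    F_sup = S_sup · U₊ · Λ₊^{-1/2}

The centering uses only *active-set* statistics (the column means and
grand mean of D, cached on the fitted model).  This is the core contract
of the projection: an active element re-presented as supplementary lands
exactly on its fitted coordinates, and a held-out point of an exactly
Euclidean configuration is recovered at its true position.  Both
properties are enforced at rtol 1e-8 in the test suite.  Supplementary
sequences never alter the active space — there is no refit.

Numerical conventions: eigenvalues with |λ| < 1e-9·max|λ| are treated as
zero; eigenvector signs are fixed by making each vector's largest-|entry|
positive, so scores are reproducible across linear-algebra backends (signs
are mathematically arbitrary in MDS); ties in the eigenvalue sort are
broken stably.

## Consensus clustering

K-means is run many times (1000 by default) on the first three components.
Partitions are canonicalized (clusters numbered by first appearance), the
most frequent partition becomes the reference, and each element's
*stability* is the fraction of runs in which it lands in its reference
cluster after optimally matching each run's labels to the reference
(Hungarian assignment on the contingency table).  Modal-frequency ties are
broken by the tied partition with the highest within-run mean silhouette.

Each run is plain Lloyd iteration: assignment by Euclidean distance,
convergence when assignments stabilize (cap 300 iterations), an empty
cluster re-seeded at the point farthest from its current centroid.  The
**initial centroids** are drawn by D²-weighted sampling of data points
(k-means++); plain uniform sampling is available via `init="random"`.
The default matters: with k well-separated groups, uniform sampling covers
all of them with probability only k!/kᵏ (≈ 9% for k = 4), so a large share
of runs converges to merged/split local optima and the modal partition is
only a plurality; reproducibility then depends on fragile basin geometry.
The D²-weighted draw spreads the initial centroids across the clusters and
makes the repeated protocol converge on a single dominant partition, which
is the regime the consensus statistics are designed to summarize.

The number of clusters is chosen by the silhouette profile: for each K in
1..13 (defaults), the mean silhouette width is averaged over 1000 runs.
The silhouette is undefined at K = 1; that entry is pinned to 0, reported,
and excluded from the argmax.  Elements whose silhouette cluster is a
singleton get silhouette 0 (the library convention).

## Group-contrast position statistics

For a partition of the sequences into a focus group g and complement g^C,
two statistics are computed per column l:

* **Frequency correlation**
  FC(l) = f(g)·f(g^C) · Σ_i (f_i(l,g) − f_i(l,g^C))² / f_i(l),
  where f(g), f(g^C) are the group frequencies and f_i(l,·) the frequency
  of amino acid i at l in each set.  FC equals φ² = χ²/N of the
  group-by-residue contingency table (an identity the tests verify at
  rtol 1e-10 against an independent χ² route), hence lies in [0, 1]: 0
  when the residue distribution is identical in both groups, 1 when
  residue identity perfectly determines group membership.
* **Entropy difference** ΔS(l) = S(l,g) − S(l,g^C), with S the Shannon
  entropy over residues (natural log; the downstream Z-scores are
  base-invariant).  Negative ΔS means the position is specifically
  conserved in g.  No small-sample entropy correction is applied; with
  the sequence counts this analysis targets (tens per group) the bias
  cancels to first order in the *difference* of two entropies.

Gaps are excluded from the frequency counts and the remaining frequencies
renormalized; a column where either group is entirely gapped is flagged
undefined and excluded from standardization.  Both statistics are
standardized to Z-scores across columns, and positions with |Z| ≥ 2.58
(the two-sided 99% standard-normal critical value) are flagged.

The pattern census reports, per group, the fraction of sequences matching
a residue pattern (e.g. proline at any of three neighbouring positions, or
a W-x-F-G motif with wildcard), optionally banded as −/+/++/+++ for 0%,
(0, 50]%, (50, 80)% and ≥80%.  Association between two binary patterns is
tested with the Pearson χ² test of independence on the 2×2 table (1 df, no
continuity correction by default).

## Residue numbering

Helix-relative numbering is supplied by configuration, not inferred: an
anchor table gives, per helix n, the alignment column of the n.50 residue
and an inclusive column span; the column at offset k from the anchor is
labelled n.(50+k).  Anchors are a curation decision (for the weakly
conserved TM5 either P5.50 or Y5.58 may serve, and the choice is the
user's), so automatic detection is deliberately out of scope.  Column
indices are 0-based in the API and 1-based in all files.

## Synthetic data

The generators define the conditions under which the package's properties
are demonstrated.

* `random_msa(n=283, L=236)` — i.i.d. residues, uniform over the 20 amino
  acids (optionally composition-matched to an empirical profile), no gaps.
  Its MDS spectrum is near-flat (leading positive eigenvalue below 3× the
  median in the shipped check), the null against which a real alignment's
  leading eigenvalue drop is judged.
* `clustered_msa` — a three-level radiation: a uniform-random root
  sequence, group ancestors mutated from it with per-column probability
  p_group, sub-family ancestors with p_subfam, leaves with p_leaf
  (mutation = replacement by a uniformly chosen different residue).
  Defaults are 4 groups × 3 sub-families × 6 leaves (72 sequences), 236
  columns, p_group = 0.6, p_subfam = 0.3, p_leaf = 0.1: a desk-scale
  mirror of a four-group, twelve-sub-family receptor family in which
  between-group divergence dominates, sub-family structure is present but
  subordinate (it lives largely above the third component), and the full
  1000-restart protocols complete in seconds.  Marker columns can be
  forced to group-specific residues to plant perfectly determining
  positions (FC = 1 by construction).
* `drifting_supplementary` — supplementary sets generated from a mosaic
  ancestor taking each column from a peripheral group ancestor with
  probability t, else from a central one; as t goes 0 → 1 the projected
  barycenter moves monotonically from the central toward the peripheral
  cluster, emulating cross-species drift of a sub-family.

What the generators do *not* emulate: realistic substitution processes
(no rate heterogeneity, no exchangeability structure), indel evolution
(gaps are i.i.d. noise if enabled at all), phylogenetic autocorrelation
within sub-families, and alignment error.  Passing tests therefore
demonstrate the correctness and stability of the *machinery* under
controlled cluster structure, not that any particular biological family
will cluster this cleanly.

## Degenerate inputs and edge rules

Gap filtering uses a strict bound (gap fraction < threshold) and errors if
nothing survives; `X` counts as a residue there.  A sequence pair with no
comparable sites is an error naming the pair.  Distance matrices reject
values outside [0, 1]; double centering rejects asymmetry.  A model with
no positive eigenvalues cannot project.  K > N is rejected; silhouette
requires max K ≤ N−1.  Constant FC or ΔS across columns makes Z-scores
undefined and is an error.  Triangle-inequality violations of the
un-squared distances are reported, never repaired — non-metricity is meant
to surface in the negative-eigenvalue fraction.

## Problem sizes

The shipped checks run classical scaling at N up to a few hundred (full
`numpy.linalg.eigh`, no truncation — simplicity over scalability; the
intended regime is N ≤ a few thousand), the consensus protocol at 1000
runs × K ∈ 1..13 on 72 points, and the random-alignment null at 283×236,
the scale of a complete non-olfactory class A receptor complement.

## Known limitations

* The FC statistic assumes unweighted sequences; no redundancy weighting.
* The modal partition is a consensus of *exact* partitions; on data where
  no partition repeats, the modal frequency is 1/runs and only the per-id
  stabilities remain informative.
* PDB export encodes cluster labels as chain identifiers and is limited to
  36 clusters and 99 999 points by the format.
* Boundary elements between clusters are reported with low stability but
  never reassigned automatically — that is a curation decision.
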