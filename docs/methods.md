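# Methods

## Model

An HLA class I allele is represented by the 179 residues of its peptide
binding domain (α chain residues 2–180, the α1/α2 groove). After trimming
and rigid superposition onto a shared reference frame, each residue *i* is
reduced to one labeled point: the mass-weighted centroid **x**ᵢ of its
side-chain heavy atoms, its residue identity, and a position weight wᵢ.
Comparison of two such clouds P1, P2 uses the kernel similarity

K(P1,P2) = Σᵢ Σⱼ √(wᵢwⱼ) · S(rᵢ, rⱼ) · cosh⁻ᵏ(σ‖xᵢ − xⱼ‖)

and the induced structure distance

SD(P1,P2) = √(K(P1,P1) + K(P2,P2) − 2K(P1,P2)).

The three factors separate the signal channels: spatial overlap (the cosh
kernel, a smooth bounded decay in the inter-point distance), physicochemical
similarity (a residue-pair lookup S ∈ [0,1]), and positional importance
(the geometric mean of the two weights). Because K is a sum of products of
positive-semidefinite factors over matched points, SD behaves as a
kernel-induced pseudometric: zero self-distance, symmetry, non-negativity,
and — verified on test fixtures whose Gram matrix of K is confirmed PSD —
the triangle inequality. SD scales as √c when all weights are scaled by c.

Key assumptions: all class I binding domains are homologous and closely
superposable, so a single rigid alignment to one reference replaces any
per-pair orientation search; side-chain centroids carry enough of the
groove's shape that atom-level detail (and any error in modeled side-chain
rotamers) can be ignored; and positional weights, not a hard contact
cutoff, decide how much each residue matters.

## Parameters

- **σ (sigma), default 0.3 Å⁻¹** — spatial kernel scale. At the default,
  residue pairs ~3 Å apart still overlap appreciably (kernel ≈ 0.45) while
  pairs beyond ~15 Å contribute essentially nothing.
- **k, default 2.0** — kernel exponent; sharpens the decay without changing
  the length scale. Both are explicit arguments everywhere (`KernelParams`);
  the defaults are declared package conventions chosen to give a smooth
  soft-contact falloff on the ~3–4 Å inter-residue spacing of a groove, not
  fitted values.
- **Residue similarity matrix S** — default `1 − G/215` where G is the
  Grantham chemical distance, recomputed from its
  composition/polarity/volume formula (ρ normalized to mean 100; integer
  rounding reproduces the published table, maximum 215 at Cys–Trp). The
  linear max-normalized flip is the simplest map satisfying S ∈ [0,1] with
  unit diagonal; any 20×20 symmetric matrix with those properties can be
  supplied as CSV (one- or three-letter headers).
- **Weight table** — `position → weight` mapping with a background default
  of 0.1 for unlisted positions. The shipped table assigns weight 1.0 to the
  classical peptide-contact pseudo-sequence positions lining the A–F pockets
  and is intended as an editable starting point, not a canonical set; any
  mapping can be passed per run.
- **Linkage, default complete** — hierarchical clustering merges by maximum
  inter-cluster SD; average and single linkage are exposed as options.
- **Anchor dictionary** — 33 anchor alleles with subtype and supertype
  labels for nearest-neighbor mode, shipped as an editable CSV.

## Procedure details and numerical choices

- **Trimming** requires every residue 2–180 present on the selected chain
  and errors with the missing positions otherwise; numbering is taken
  verbatim from the PDB records, no renumbering. Alternate locations other
  than blank/'A' are dropped; insertion codes are rejected outright.
- **Superposition** is the closed-form least-squares rigid fit (SVD/Kabsch,
  via Biopython's superimposer) over the 179 Cα positions, equally
  weighted, reflection excluded. It is idempotent and preserves internal
  geometry to rounding.
- **Coarse graining** averages side-chain heavy atoms with standard atomic
  masses; hydrogens are ignored so results do not depend on protonation.
  Glycine, having no side-chain heavy atoms, is represented by its Cα — a
  deterministic fallback for a case the model statement leaves open.
- **SD radicand**: mathematically ≥ 0 for a PSD kernel, but floating-point
  cancellation can push it slightly negative; it is clamped at zero, with a
  warning if it falls below −10⁻⁶·(K₁₁+K₂₂) (which indicates structures not
  sharing a frame rather than rounding).
- **Pairwise matrices** evaluate K once per needed pair into a cache keyed
  by allele-id pair (per run, not persisted): n(n+1)/2 evaluations for a
  symmetric matrix, m + q + m·q for anchor×query. The unit of parallel work
  is a whole K evaluation and each matrix cell is written once, so results
  are bit-identical for any worker count.
- **SSE centroid = medoid**: for a distance-only representation a
  coordinate average is unphysical, so the cluster center is the member
  minimizing total within-cluster SD, ties broken lexicographically by
  allele id. SSE is the sum of member-to-medoid distances; singletons
  contribute 0.
- **Silhouette**: a(i) is the mean within-cluster distance excluding self
  (0 for singletons), b(i) the minimum mean distance to another cluster,
  s(i) = (b−a)/max(a,b) with s(i) = 0 when both are 0; the coefficient is
  the mean over alleles and is undefined (an error) for one cluster.
- **Cluster-number choice is manual**: the scan emits the SSE and
  silhouette tables and plots; no automatic knee detection is applied.
- **Ties** in nearest-neighbor assignment keep the first anchor in
  dictionary order and warn; merge ties in the linkage follow scipy's
  ordered-pair convention, making every clustering deterministic.

## Synthetic data

Real inputs are predicted structural models, which are large and not
redistributable, so all testing runs on generated data. Two generators
ship as first-class code:

- `make_synthetic_pdb` writes a parseable single-chain PDB with ≥ 180
  consecutively numbered residues on a smooth helical backbone, each with
  N/CA/C/O and (except glycine) a CB atom — enough to exercise trimming,
  superposition and coarse graining. It emulates the *layout* of an HLA
  chain, not its fold: the geometry is a plain helix, not a groove.
- `make_planted_clusters` builds coarse clouds with known ground truth: a
  base 179-point cloud, cluster-level separation applied both geometrically
  (a rigid shift of half the positions, default 8 Å) and chemically
  (residue mutations, default rate 0.1), and Gaussian within-cluster jitter
  (default 0.1 Å). Both similarity channels of K are thereby exercised
  independently. Default sizes (3 clusters × 4 alleles) keep the planted
  separation ratio far above the recovery threshold.

Passing tests on these fixtures demonstrates the correctness of the
mathematics — the metric, the counting contracts, the clustering and
selection statistics — not that real HLA alleles cluster into the known
supertypes; that scientific claim depends on real predicted structures and
calibrated weights outside the package's test scope. Problem sizes in the
test suite and the acceptance script (clouds of 10–179 points, 5–12
alleles, 20 oracle pairs, 100 random assignment matrices) were chosen as
the smallest sets that exercise every contract convincingly.

## Limitations

- The shipped weight table and kernel defaults are conventions; reproducing
  any particular published supertype classification requires the weights,
  kernel constants and structure set of that study.
- SD is a pseudometric: distinct structures can in principle have SD 0
  (e.g., identical clouds under different ids), and the triangle inequality
  is guaranteed only where K is PSD over the compared set.
- Only single-model PDB input with plain integer numbering is supported; no
  mmCIF, no class II, no peptide:HLA complexes, no structure prediction.
- The nearest-neighbor mode is only as good as its anchors: queries outside
  every anchor's neighborhood are still assigned to the nearest one, with
  no outlier rejection.
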