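# hlaclust

Structure-based clustering of HLA class I alleles.

HLA class I proteins (HLA-A/B/C) present intracellular peptides to CD8+
T cells; which peptides an allele can present is determined by the 3D
landscape of its peptide binding groove. With thousands of known alleles and
experimental binding data for only a fraction of them, grouping alleles by
the *structural* similarity of their grooves — into supertypes and subtypes
of shared binding specificity — is a practical way to transfer knowledge
from well-characterized alleles to rare ones (affinity-predictor model
selection, disease-association grouping, transplant matching). `hlaclust`
is a small library plus command-line tool for exactly that, aimed at
computational immunologists working from predicted or experimental HLA
structures.

## The method

Each allele's binding domain (residues 2–180 of the α chain, trimmed and
superposed onto a common reference) is coarse-grained into 179 labeled
points: residue *i* becomes the mass-weighted side-chain centroid
*x<sub>i</sub>*, keeps its residue identity, and carries a weight
*w<sub>i</sub>* describing how strongly that position shapes peptide
binding. Two alleles P1, P2 are compared with the kernel similarity

```
K(P1, P2) = Σ_{i∈P1} Σ_{j∈P2} √(w_i w_j) · S_ij · 1 / cosh^k(σ·‖x_i − x_j‖)
```

where S is a 20×20 residue similarity matrix (by default the max-normalized
flip of the Grantham chemical distance, S = 1 − G/215, recomputed here from
the composition/polarity/volume formula) and the cosh kernel turns the
spatial offset of each residue pair into a similarity in (0, 1] with scale
σ (1/Å) and sharpness k. K is normalized into the **structure distance**

```
SD(P1, P2) = √( K(P1,P1) + K(P2,P2) − 2·K(P1,P2) )
```

which is zero for identical structures, symmetric, and — K being a
positive-semidefinite kernel — a pseudometric. Alleles are then grouped
either by **hierarchical clustering** of the symmetric pairwise SD matrix
(complete linkage by default, with medoid-based SSE elbow and silhouette
curves to choose the number of clusters) or by **nearest-neighbor
assignment**: each query inherits the subtype/supertype of its nearest
anchor allele from a labeled anchor dictionary (a 33-allele supertype
scheme ships as the editable default).

## Worked example

Scripts under `examples/` run each capability end to end on synthetic
inputs. `examples/02_structure_distance.py` prints:

```
K(a,a) = 272.5943  (self-similarity)
K(a,b) = 87.3512  (cross-similarity)
SD(a,a) = 0.0000  (always exactly 0)
SD(a,b) = 19.2255

Pairwise SD matrix (symmetric, zero diagonal, 6 K evaluations for 3 alleles):
         a        b        c
a   0.0000  19.2255  19.3833
b  19.2255   0.0000  19.3074
c  19.3833  19.3074   0.0000
```

K(a,a) is the structure's similarity to itself (the normalization anchor);
SD(a,b) grows as the two grooves diverge spatially or chemically, and the
3-allele matrix needs only n(n+1)/2 = 6 kernel evaluations.
`examples/03_hierarchical_clustering.py` plants three separated groups of
four alleles, recovers them exactly at N = 3, and shows the silhouette
coefficient peaking at the true N:

```
 n_clusters     sse  silhouette
          2 95.8032      0.3809
          3 57.6114      0.5588
          4 51.1378      0.3838
```

The same stages are available from the shell:

```sh
hlaclust fixtures --n-structures 4 --seed 1 --outdir work   # synthetic PDBs
hlaclust process work/*.pdb --reference work/synthetic_1_0.pdb --outdir work
hlaclust hclust work/*.csv --scan 2 3 --outdir work
```

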