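# nucsite

Fragment-based prediction of nucleotide-binding sites on protein
structures.

Nucleotides (AMP, ADP, ATP, GDP, GTP, their non-hydrolysable analogues
ANP/GNP, FMN, FAD, NAD and NADP) decompose into three kinds of chemical
modules — the **nucleobase** (adenine, guanine, nicotinamide, flavin,
…), the **carbohydrate** (ribose in closed or open form, deoxyribose)
and the **phosphate**. Each module is bound by small local structural
motifs that recur across unrelated folds. `nucsite` exploits this
modularity: it predicts a binding position for each module
independently, by local structural comparison against a template
library, and then reassembles the modules into whole binding-site
predictions.

The pipeline for a query chain is:

1. **Match** — every template binding site (the ≥ 3 residues of a
   solved complex with a heavy atom within 3.5 Å of a module) is
   compared against the query. Residues are reduced to two
   pseudo-atoms, the Cα and the side-chain geometric centre, and the
   matcher searches for the largest residue subsets superposable under
   a proper rotation with RMSD ≤ 0.6 Å, per-pair BLOSUM62 score ≥ 0,
   and every matched residue within 7.5 Å (Cα) of another.
2. **Transfer** — the template's module is placed on the query with
   the rigid transform of the match (Kabsch superposition).
3. **Filter** — placements from homologous template chains (global
   identity ≥ 30%, Needleman–Wunsch with EMBOSS Needle defaults) are
   discarded; so are placements with an atom inside the
   solvent-excluded surface (SES) or closer to it than the
   module-specific minima (nucleobase 0.407 Å, carbohydrate 0.124 Å,
   phosphate 0.830 Å).
4. **Cluster & score** — surviving placements of the same module type
   are merged by agglomerative centroid-linkage clustering at 2 Å; a
   cluster representative scores
   `total = (cluster size − 1) + mean conservation percentile`
   of its matched residues (conservation comes from an optional MSA).
5. **Assemble** — ranked modules are combined into the bound
   nucleotide's architecture (e.g. FAD = N-C-P-P-C-N), accepting a
   combination only if every centroid pair lies inside empirical
   distance envelopes (e.g. N–C 3.937–5.275 Å, P–P 2.654–7.148 Å);
   if the full architecture is unreachable, progressively shorter
   contiguous sub-architectures are tried, down to two consecutive
   different modules. A site's score is the sum of its member scores,
   and a protein whose best site scores ≥ 166.33 is classified a
   nucleotide binder.

A seeded fixture generator (decoy pseudo-chains, planted motifs, toy
holo complexes, toy alignments) gives every stage a ground-truth test
surface without any external downloads.

## Worked example

Generate a toy ADP complex, build a template library from it, and
predict its own binding site (the homology filter is disabled because
query and template chain are identical):

```
$ nucsite fixtures make --kind holo --ligand ADP --seed 7 --out .
wrote toy_ADP_seed7.pdb
$ nucsite build-templates --complexes . --out lib.json --seed 0
library: 3 sites -> lib.json
$ nucsite predict --structure toy_ADP_seed7.pdb --chain A \
      --library lib.json --no-homology-filter --out pred
3 module predictions -> pred.tsv / .pdb
$ cat pred.tsv
module_type  rank  clustering_score  conservation_score  total_score  cx       cy      cz      matched_residues  template_site_id
nucleobase   1     0                 NA                  0.0000       -4.6001  0.0000  0.0000  A:1,A:2,A:3,A:4   toy_ADP_seed7_A_ADP_A26_f0
carbohydrate 1     0                 NA                  0.0000       -0.0000  0.0000  0.0000  A:5,A:6,A:7,A:8   toy_ADP_seed7_A_ADP_A26_f1
phosphate    1     0                 NA                  0.0000       4.6000   -1.4002 -0.0003 A:13,A:14,A:15,A:16  toy_ADP_seed7_A_ADP_A26_f3
$ nucsite assemble --predictions pred.tsv --ligand ADP --out sites.tsv
1 assembled sites -> sites.tsv
$ cat sites.tsv
rank  architecture  score   mean_pair_distance  members
1     NCP           0.0000  6.2382              N:rank1:-4.600,0.000,0.000;C:rank1:-0.000,0.000,0.000;P:rank1:4.600,-1.400,-0.000
```

The rank-1 prediction of each module type sits exactly on the
crystallographic fragment (the centroids in `pred.tsv` match the toy
ligand's module centroids). The clustering score is 0 (each placement
is a singleton cluster) and conservation is `NA` because no alignment
was supplied. Library redundancy reduction kept a single phosphate
template for the chain — one template cannot occupy both phosphate
positions, so assembly emits the longest reachable sub-architecture,
NCP. Evaluating against the crystallographic ligand,

```
$ nucsite evaluate --predictions pred.tsv --holo toy_ADP_seed7.pdb \
      --ligand ADP --criterion rmsd --out report.json
```

reports a top-1 hit for all three module types and a correct assembled
site under the centroid-RMSD criterion.

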