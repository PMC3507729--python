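# Methods

This note documents the model behind `nucsite`, the parameters that
matter, the synthetic data the tests run on, and the numerical and
design choices made where more than one reasonable option existed.

## Residue model and structural matching

A residue is represented by two pseudo-atoms: the Cα and the geometric
centre of its heavy side-chain atoms (backbone N, CA, C, O and OXT
excluded). Glycine, and any residue without resolved side-chain heavy
atoms, reuses the Cα as its side-chain centre. This two-point model
keeps matching sensitive to side-chain orientation while remaining
robust to rotamer detail.

A structural match between a query chain and a template binding site
is an injective pairing of residues satisfying three constraints:

* **geometry** — the 2N pseudo-atoms (both points of every pair)
  superpose under a least-squares proper rotation with RMSD ≤ 0.6 Å
  (`MatchParams.rmsd_max`). Reflections are explicitly disallowed in
  the Kabsch solution (determinant +1). Cα and side-chain centre are
  weighted equally, and glycine contributes its Cα twice, so every
  residue carries the same weight.
* **chemistry** — every matched pair has BLOSUM62(query, template)
  ≥ 0 (`blosum_min`). The threshold is applied per pair, not summed;
  0 ("non-negative substitution") is the default and is configurable.
* **connectivity** — among the matched residues, none is isolated:
  each has another matched residue within 7.5 Å Cα–Cα, on the query
  side and on the template side.

The search enumerates pairings depth-first over candidate residue
pairs and returns all *maximal* (non-extendable) matches, sorted by
size, then RMSD, then lexicographic residue order, capped at 16 per
template. Two pruning rules keep it exact rather than heuristic:

* the optimal sum of squared deviations (SSD) is monotone under set
  growth, so a partial pairing is dead once its SSD exceeds
  `rmsd_max² · 2 · N_max`, the largest SSD any feasible completion of
  size ≤ N_max could carry;
* if a match of size N has 2N-point RMSD ≤ r, any two matched
  residues' intra-set distances (Cα–Cα and centre–centre) differ
  between query and template by at most 2·r·√N. Candidate pairs
  violating this bound for the maximum reachable N are never combined.

Both bounds are conservative, which is what the exhaustive-oracle
equivalence test verifies: on random instances (template ≤ 6, query
≤ 12 residues) the best match size and RMSD equal those found by
enumerating every injective pairing with an independent rotation fit
(SciPy's `align_vectors`).

Matches of fewer than 3 residues are never reported; 3 is also the
minimum size of a template site, so the two floors coincide.

## Template library

A template binding site is extracted from a holo complex for every
(decomposed module, contacting chain) pair: all residues of the chain
with a heavy atom within 3.5 Å (inclusive) of a module heavy atom,
kept only if at least three such residues exist. A module contacted by
several chains produces one site per qualifying chain, flagged with
the chain count. Redundancy is reduced by greedy single-linkage
clustering of source-chain sequences at 95% global identity; one site
per cluster and module type is kept, chosen by a seeded RNG recorded
in the library metadata so builds are byte-reproducible. The library
serializes to a self-contained JSON file (residue pseudo-atoms, module
atoms, provenance, build metadata) and both the ≥ 3-residue and the
contact invariants are re-validated on load. Note one practical
consequence: a ligand with repeated module types bound by a single
chain contributes only one template for that type after reduction, so
self-prediction of, say, both ADP phosphates needs the unreduced site
list.

## Ligand decomposition

Chemical components map to module fragments through a declarative
atom-name table (`data/fragment_definitions.yaml`) covering the eleven
nucleotide types plus free-module components. Every heavy atom belongs
to exactly one fragment; bridging ester oxygens (ribose O5′-type and
inter-phosphate bridges) are assigned to the phosphate they esterify.
NADP's 2′-phosphate is a `branch: true` fragment outside the linear
architecture string. A fragment missing more than half of its defined
heavy atoms is flagged incomplete and excluded. Fragment centroids are
unweighted means over heavy atoms; hydrogens are ignored everywhere.

## Solvent-excluded surface

The SES is approximated on a regular grid (default spacing 0.4 Å,
probe 1.4 Å) as the morphological closing of the van-der-Waals volume:
a grid point is interior if it lies inside a vdW sphere or cannot be
covered by any probe sphere placed entirely outside the vdW volume.
Implementation: the signed distance to the vdW surface is computed per
element-radius class with k-d trees; probe-centre positions are the
points at distance ≥ probe; the exterior is their Euclidean dilation
by the probe radius (a distance transform); surface vertices are the
interior voxels bordering the exterior. vdW radii (C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80 Å) ship as editable configuration.

Placed fragments with any heavy atom inside the surface are rejected;
survivors must keep a minimum vertex distance per module type
(nucleobase 0.407 Å, carbohydrate 0.124 Å, phosphate 0.830 Å,
inclusive keep). These sub-Ångström thresholds are resolution
sensitive: the default spacing is well below the smallest gap between
them, a convergence test checks that halving the spacing moves
distances by less than the coarser spacing, and a precomputed external
vertex list (e.g. an MSMS `.vert` file) can replace the internal grid.
With an external mesh the inside test falls back to the vdW spheres of
the chain.

## Homology filter, clustering, scoring

Matches whose template source chain reaches 30% global sequence
identity with the query (inclusive) are discarded. Identity is
computed with Biopython's `PairwiseAligner` configured to EMBOSS
Needle defaults (BLOSUM62, gap open 10, extend 0.5, free end gaps) as
identical aligned pairs over alignment length, cached per source
sequence.

Placements of one module type are merged by sequential agglomerative
clustering with centroid linkage: the closest pair of cluster
centroids (means of member fragment centroids) merges while that
distance is ≤ 2 Å; ties merge the lowest-index pair. The
representative is the member closest to the cluster centroid (ties:
lowest index). The implementation is the sequential procedure itself
rather than a dendrogram cut, because centroid linkage can produce
inversions that make cophenetic thresholding ambiguous; a plain-loop
oracle in the tests confirms the partition.

A representative scores `clustering + conservation`. The clustering
score counts the modules that clustered *with* it (cluster size − 1; a
`size` mode is available). The conservation score is the mean
percentile of its matched query residues, from an optional MSA that
must contain (a superstring of) the chain sequence: per column, the
fraction of non-gap rows with BLOSUM62 ≥ 1 to the query residue, rank
normalised to 0–100 with the inclusive empirical CDF over that
alignment's values (ties share the higher percentile; configurable).
Without an MSA conservation contributes 0 and predictions are flagged
`unscored-conservation`. Ranking is per module type by total score,
with deterministic tie-breaks (larger match, lower RMSD, then centroid
order) so outputs are byte-stable.

## Assembly and classification

Each nucleotide type has a linear architecture string over {N, C, P}
(AMP/FMN NCP; ADP/GDP NCPP; ATP/ANP/GTP/GNP NCPPP; FAD/NAD/NADP
NCPPCN). Sub-architectures are the distinct contiguous substrings of
length ≥ 2 containing at least one adjacent pair of *different*
module types (so PP alone never qualifies), ordered by decreasing
length then left position. Assembly backtracks over the top-10 ranked
predictions per type, assigning distinct predictions to positions and
checking the centroid-distance envelope of **every** unordered member
pair (the envelope table lists non-adjacent and same-type pairs, which
implies all-pairs checking; an adjacent-only mode exists for
sensitivity analysis). All valid sites at the first architecture
length that yields any are returned, deduplicated on their module set
and ranked by score, ties by compactness. NADP's branch phosphate can
be attached afterwards, constrained only by the P–P and P–C ranges.
Every emitted site re-validates its constraints post-hoc.

The envelopes can be re-derived from a user's holo complexes as the
1st/99th percentiles of pooled per-ligand module-pair distances; pair
classes with fewer than 10 observations fall back to the shipped
defaults, flagged.

A protein is classified as a nucleotide binder when its best
assembled-site score (minimum sub-architecture length 2) reaches
166.33, the threshold on the 0–100-commensurate conservation scale.

## Synthetic data

The fixture generator produces, reproducibly from a seed:

* **decoy chains** — self-avoiding Cα walks (consecutive spacing
  3.8 ± 0.05 Å, non-consecutive pairs ≥ 4 Å) with side-chain centres
  1.5–2.5 Å off the Cα and random non-glycine identities;
* **synthetic sites and planted motifs** — a phosphate-like fragment
  with 3+ residues on a spherical cap below it, rigidly placed beside
  a decoy with Gaussian coordinate noise. The placement re-samples the
  transform on a Cα clash (< 2 Å) and additionally keeps the fragment
  ≥ 4 Å from all decoy atoms so the ground-truth position remains
  solvent-reachable and survives the surface filter;
* **toy holo complexes** — module centroids on fixed per-architecture
  layouts chosen to satisfy every pairwise distance envelope
  simultaneously (for N-C-P-P-C-N this forces a folded, roughly
  octahedral arrangement); fragment atoms on small blobs whose mean is
  exactly the layout centroid; 4 contacting residues per linear
  fragment at 3.0–3.4 Å along an open direction. Residue identities
  within a site are distinct letters from seven mutually dissimilar
  amino acids (pairwise BLOSUM62 ≤ −1), with Fano-plane subsets across
  sites so two sites share at most two letters; this blocks almost all
  spurious residue correspondences. As a guarantee, the builder
  verifies that each extracted site matches the complex only through
  its identity mapping at zero RMSD and re-draws the geometry with a
  salted seed otherwise. The NADP branch fragment gets no residues of
  its own (its pocket is geometrically squeezed between the adenine
  and the linear phosphates);
* **toy MSAs** — conserved columns kept identical, others mutated to
  residues dissimilar to the reference (BLOSUM62 < 1), optional gaps.

These fixtures are geometry-only pseudo-proteins. They exercise every
geometric and statistical contract of the method — exact transfer,
filter boundaries, clustering, assembly, ranking — but they say
nothing about performance on real structures: real binding sites have
flexible side chains, partially buried ligands, sequence-similar
motifs and conservation signal entangled with structure. Passing the
fixture suite therefore demonstrates correctness of the machinery, not
the field performance of the method.

Problem sizes in the shipped tests and in `scripts/acceptance.py`
(200/100 matcher-oracle instances, 100/60 planted-motif trials with
as many negative controls, 11 toy complexes, 100 clustering sets) were
chosen as the smallest that make the pass criteria statistically
meaningful for a desk-scale run.

## Numerical choices

* Kabsch superposition via SVD with explicit reflection correction;
  RMSD thresholds compared inclusively with a 1e-9 slack only in
  re-validation.
* Alternate locations resolve to the highest occupancy, first in file
  on ties; only the first model of a PDB file is read; waters dropped.
* Percentile normalisation is the inclusive empirical CDF
  (maximum → exactly 100).
* All RNG flows through `numpy.random.Generator` seeded from
  user-facing `--seed` arguments; library builds and fixtures are
  byte-reproducible.
* Degenerate inputs: empty match/prediction/cluster lists propagate as
  empty results, not errors; an all-gap MSA column scores 0; an MCC
  with a zero denominator reports 0 with a flag.

## Known limitations

* The grid SES is an approximation; vertex distances carry O(spacing)
  error, which matters at the 0.124 Å carbohydrate threshold. Use a
  finer grid or an external mesh when that margin matters.
* The matcher's exhaustive-with-pruning search is exponential in the
  worst case; it is fast for realistic template sizes (3–8 residues)
  but not intended for template sets of tens of residues.
* Apo structures are evaluated against the holo ligand only if the
  caller superposes the frames first; the evaluation module assumes a
  common frame.
* NADP's branched architecture is handled as the linear N-C-P-P-C-N
  backbone plus an optional branch member; a truly branched string
  formalism is out of scope.
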