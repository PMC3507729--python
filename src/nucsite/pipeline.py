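"""Prediction pipeline for one query chain.

Scan the template library, discard matches from homologous source
chains (global identity >= 30%), transfer the template fragments with
the match transform, reject placements buried in or hugging the
solvent-excluded surface, merge the survivors by centroid-linkage
clustering at 2 Å, and score each cluster representative as

    total = clustering score + conservation score

where the clustering score counts the modules of the same type that
clustered with the representative and the conservation score is the
mean conservation percentile of the query residues in its structural
match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import matcher as _matcher
from . import structio
from . import surface as _surface
from .conservation import ConservationProfile
from .matcher import MatchParams, StructuralMatch
from .structio import Atom, ModuleFragment, Structure
from .templates import Library, TemplateBindingSite

HOMOLOGY_IDENTITY_MAX = 0.30
CLUSTER_THRESHOLD = 2.0   # Å, centroid linkage


@dataclass
class PipelineConfig:
    match_params: MatchParams = field(default_factory=MatchParams)
    surface_thresholds: _surface.SurfaceThresholds = field(
        default_factory=_surface.SurfaceThresholds)
    homology_identity_max: float = HOMOLOGY_IDENTITY_MAX
    cluster_threshold: float = CLUSTER_THRESHOLD
    homology_filter_enabled: bool = True
    surface_filter_enabled: bool = True
    clustering_score_mode: str = "co_members"   # or "size"
    grid_spacing: float = _surface.GRID_SPACING
    probe_radius: float = _surface.PROBE_RADIUS

    def __post_init__(self):
        if self.cluster_threshold <= 0 or self.homology_identity_max <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ModulePrediction:
    fragment: ModuleFragment          # placed on the query
    match: StructuralMatch
    template_site_id: str
    cluster_id: int = -1
    cluster_size: int = 1
    clustering_score: int = 0
    conservation_score: float | None = None
    total_score: float = 0.0
    rank: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def module_type(self) -> str:
        return self.fragment.module_type

    @property
    def centroid(self) -> np.ndarray:
        return self.fragment.centroid


@dataclass
class PredictionResult:
    predictions: dict[str, list[ModulePrediction]]
    dropped: list[tuple] = field(default_factory=list)
    config: PipelineConfig | None = None
    flags: list[str] = field(default_factory=list)

    def ranked(self, module_type: str) -> list[ModulePrediction]:
        return self.predictions.get(module_type, [])


_aligner = None


def _get_aligner():
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        # EMBOSS Needle defaults: gap open 10, extend 0.5, free end gaps
        a.open_gap_score = -10.0
        a.extend_gap_score = -0.5
        a.end_gap_score = 0.0
        a.mode = "global"
        _aligner = a
    return _aligner


def global_identity(seq_a: str, seq_b: str) -> float:
    """Needleman–Wunsch global identity: identical pairs / alignment length."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    seq_a = seq_a.upper()
    seq_b = seq_b.upper()
    aln = _get_aligner().align(seq_a, seq_b)[0]
    a_row, b_row = str(aln[0]), str(aln[1])
    identical = sum(1 for x, y in zip(a_row, b_row) if x == y and x != "-")
    return identical / len(a_row)


def homology_filter(matches: list[tuple[StructuralMatch, TemplateBindingSite]],
                    query_sequence: str,
                    identity_max: float = HOMOLOGY_IDENTITY_MAX):
    """Drop matches whose template source chain is homologous to the query.

    Identity is computed once per distinct source sequence and cached.
    Returns (kept, dropped).
    """
    cache: dict[str, float] = {}
    kept, dropped = [], []
    for m, site in matches:
        seq = site.source_sequence
        if seq not in cache:
            cache[seq] = global_identity(query_sequence, seq)
        if cache[seq] >= identity_max:
            dropped.append(((m, site), f"homology {cache[seq]:.3f}"))
        else:
            kept.append((m, site))
    return kept, dropped


def transfer_fragment(match: StructuralMatch,
                      template: TemplateBindingSite) -> ModuleFragment:
    """Place the template fragment on the query with the match transform."""
    frag = template.fragment
    atoms = [Atom(a.name, a.element, match.transform(a.pos))
             for a in frag.atoms]
    return ModuleFragment.from_atoms(
        frag.module_type, frag.subtype, atoms,
        provenance=f"predicted:{template.site_id}",
        arch_index=frag.arch_index, branch=frag.branch)


def cluster_predictions(fragments: list[ModuleFragment],
                        threshold: float = CLUSTER_THRESHOLD):
    """Agglomerative centroid-linkage clustering of fragment centroids.

    Clusters merge while the closest pair of cluster centroids (mean of
    member fragment centroids) is within ``threshold``; ties merge the
    pair with the lowest member indices first.  Returns
    ``(clusters, representatives)`` where clusters are lists of input
    indices and the representative is the member fragment closest to
    the cluster centroid (ties: lowest index).
    """
    n = len(fragments)
    if n == 0:
        return [], []
    pts = np.array([f.centroid for f in fragments])
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > 1:
        cents = np.array([pts[c].mean(axis=0) for c in clusters])
        d = np.linalg.norm(cents[:, None, :] - cents[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        # lowest-index tie-break: scan pairs in order, track strict minimum
        best = None
        best_d = np.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if d[i, j] < best_d - 1e-12:
                    best_d = d[i, j]
                    best = (i, j)
        if best is None or best_d > threshold:
            break
        i, j = best
        clusters[i] = sorted(clusters[i] + clusters[j])
        del clusters[j]
        clusters.sort(key=lambda c: c[0])
    clusters.sort(key=lambda c: c[0])

    reps = []
    for c in clusters:
        cent = pts[c].mean(axis=0)
        dists = np.linalg.norm(pts[c] - cent, axis=1)
        reps.append(c[int(np.argmin(dists))])
    return clusters, reps


def score_predictions(representatives: list[ModulePrediction],
                      clusters: list[list[int]],
                      profile: ConservationProfile | None,
                      mode: str = "co_members") -> list[ModulePrediction]:
    """Fill clustering/conservation/total scores and rank one module type."""
    for pred, cluster in zip(representatives, clusters):
        size = len(cluster)
        pred.cluster_size = size
        pred.clustering_score = size if mode == "size" else size - 1
        if profile is not None:
            refs = [ref for ref, _ in pred.match.pairs]
            cons = profile.mean_over(refs)
        else:
            cons = None
        pred.conservation_score = cons
        if cons is None:
            pred.flags.append("unscored-conservation")
        pred.total_score = pred.clustering_score + (cons or 0.0)

    representatives.sort(key=lambda p: (
        -p.total_score, -p.match.size, p.match.rmsd,
        tuple(np.round(p.centroid, 6))))
    for rank, pred in enumerate(representatives, start=1):
        pred.rank = rank
    return representatives


def predict(query: Structure, chain_id: str, library: Library,
            config: PipelineConfig | None = None,
            msa=None, msa_row_id: str | None = None,
            mesh: _surface.SurfaceMesh | None = None) -> PredictionResult:
    """Full prediction for one query chain (deterministic)."""
    config = config or PipelineConfig()
    descs = structio.residue_descriptors(query, chain_id)
    query_seq = "".join(d.aa for d in descs)
    result = PredictionResult(predictions={}, config=config)

    profile = None
    if msa is not None:
        from .conservation import map_profile
        profile = map_profile(msa, msa_row_id, query, chain_id)
    else:
        result.flags.append("unscored-conservation")

    if config.surface_filter_enabled and mesh is None:
        mesh = _surface.build_ses_mesh(query, chain_id,
                                       probe=config.probe_radius,
                                       spacing=config.grid_spacing)

    matches_by_type = _matcher.scan_library(descs, library, config.match_params)

    for module_type in structio.MODULE_TYPES:
        hits = matches_by_type.get(module_type, [])
        if config.homology_filter_enabled and hits:
            hits, dropped = homology_filter(hits, query_seq,
                                            config.homology_identity_max)
            result.dropped.extend(dropped)
        preds = []
        for m, site in hits:
            frag = transfer_fragment(m, site)
            preds.append(ModulePrediction(fragment=frag, match=m,
                                          template_site_id=site.site_id))
        if config.surface_filter_enabled and preds:
            preds, dropped = _surface.surface_filter(
                preds, mesh, config.surface_thresholds)
            result.dropped.extend(dropped)
        if preds:
            clusters, rep_idx = cluster_predictions(
                [p.fragment for p in preds], config.cluster_threshold)
            reps = []
            for cid, (cluster, ri) in enumerate(zip(clusters, rep_idx)):
                rep = preds[ri]
                rep.cluster_id = cid
                reps.append(rep)
            preds = score_predictions(reps, clusters, profile,
                                      config.clustering_score_mode)
        result.predictions[module_type] = preds
    return result


def predictions_to_tsv(result: PredictionResult) -> str:
    """Stable TSV rendering of ranked predictions."""
    lines = ["module_type\trank\tclustering_score\tconservation_score\t"
             "total_score\tcx\tcy\tcz\tmatched_residues\ttemplate_site_id"]
    for module_type in structio.MODULE_TYPES:
        for p in result.predictions.get(module_type, []):
            cons = "NA" if p.conservation_score is None else f"{p.conservation_score:.4f}"
            refs = ",".join(f"{c}:{n}{i}" for (c, n, i), _ in p.match.pairs)
            c = p.centroid
            lines.append(
                f"{module_type}\t{p.rank}\t{p.clustering_score}\t{cons}\t"
                f"{p.total_score:.4f}\t{c[0]:.4f}\t{c[1]:.4f}\t{c[2]:.4f}\t"
                f"{refs}\t{p.template_site_id}")
    return "\n".join(lines) + "\n"


def predictions_to_pdb(result: PredictionResult) -> str:
    """Placed fragments as HETATM blocks, rank in the B-factor column."""
    frags, ranks = [], []
    for module_type in structio.MODULE_TYPES:
        for p in result.predictions.get(module_type, []):
            frags.append(p.fragment)
            ranks.append(float(p.rank))
    return structio.write_fragments_pdb(frags, ranks)
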