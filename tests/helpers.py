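"""Independent oracles and small constructors shared by the tests.

The oracles deliberately avoid the package's search/cluster code paths:
structural matching is checked against exhaustive subset enumeration
with SciPy's rotation fitting, clustering against a plain-loop
agglomeration, thresholds against direct scans.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.transform import Rotation

from nucsite.matcher import StructuralMatch, blosum62
from nucsite.pipeline import ModulePrediction
from nucsite.structio import Atom, ModuleFragment, ResidueDescriptor
from nucsite.templates import TemplateBindingSite

AAS = "ARNDCQEHILKMFPSTWYV"


def random_descriptors(rng, n, box=12.0, prefix="Q"):
    out = []
    for i in range(n):
        ca = rng.uniform(0, box, 3)
        sc = ca + rng.uniform(-1.5, 1.5, 3)
        out.append(ResidueDescriptor((prefix, i + 1, ""),
                                     AAS[rng.integers(len(AAS))], ca, sc))
    return out


def descriptors_to_site(residues, site_id="tmpl") -> TemplateBindingSite:
    from nucsite.fixtures import _po4_atoms
    frag = ModuleFragment.from_atoms(
        "phosphate", "phosphate", _po4_atoms(np.zeros(3)),
        provenance=f"synthetic:{site_id}")
    return TemplateBindingSite(site_id, (site_id, "T"), list(residues), frag,
                               "".join(r.aa for r in residues))


def scipy_rmsd(P, Q):
    """Optimal superposition RMSD via scipy (independent of the package)."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    _, rssd = Rotation.align_vectors(Qc, Pc)
    return rssd / np.sqrt(len(P))


def oracle_best_match(query, template_residues, params):
    """Exhaustive enumeration of injective BLOSUM-compatible pairings,
    verified with scipy superposition and direct connectivity checks.
    Returns (best size, best rmsd) with (0, inf) when nothing matches."""
    nt, nq = len(template_residues), len(query)
    compat = [[blosum62(q.aa, t.aa) >= params.blosum_min for q in query]
              for t in template_residues]

    def connected(pts):
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        return bool(np.all(d.min(axis=1) <= params.ca_connectivity_max))

    best_size, best_rmsd = 0, np.inf
    for k in range(params.min_match_size, min(nt, nq) + 1):
        for tsub in itertools.combinations(range(nt), k):
            cand = [[qi for qi in range(nq) if compat[ti][qi]] for ti in tsub]
            for qsel in itertools.product(*cand):
                if len(set(qsel)) != k:
                    continue
                P = np.vstack([np.vstack([template_residues[ti].ca,
                                          template_residues[ti].sc_center])
                               for ti in tsub])
                Q = np.vstack([np.vstack([query[qi].ca, query[qi].sc_center])
                               for qi in qsel])
                rmsd = scipy_rmsd(P, Q)
                if rmsd > params.rmsd_max:
                    continue
                qca = np.array([query[qi].ca for qi in qsel])
                tca = np.array([template_residues[ti].ca for ti in tsub])
                if not (connected(qca) and connected(tca)):
                    continue
                if k > best_size or (k == best_size and rmsd < best_rmsd):
                    best_size, best_rmsd = k, rmsd
    return best_size, best_rmsd


def oracle_centroid_linkage(points, threshold):
    """Plain-loop sequential centroid-linkage agglomeration."""
    clusters = [[i] for i in range(len(points))]
    pts = np.asarray(points, float)
    while len(clusters) > 1:
        best = None
        best_d = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                ci = pts[clusters[i]].mean(axis=0)
                cj = pts[clusters[j]].mean(axis=0)
                d = float(np.linalg.norm(ci - cj))
                if best_d is None or d < best_d - 1e-12:
                    best_d = d
                    best = (i, j)
        if best_d is None or best_d > threshold:
            break
        i, j = best
        clusters[i] = sorted(clusters[i] + clusters[j])
        del clusters[j]
        clusters.sort(key=lambda c: c[0])
    return sorted((sorted(c) for c in clusters), key=lambda c: c[0])


def point_fragment(module_type, xyz, name="X") -> ModuleFragment:
    return ModuleFragment.from_atoms(
        module_type, "phosphate" if module_type == "phosphate" else "adenine",
        [Atom(name, "P", np.asarray(xyz, float))])


def make_prediction(module_type, xyz, total_score=0.0, rank=0,
                    matched_refs=()) -> ModulePrediction:
    frag = point_fragment(module_type, xyz)
    match = StructuralMatch("tmpl", [(r, i) for i, r in enumerate(matched_refs)],
                            np.eye(3), np.zeros(3), 0.0)
    return ModulePrediction(fragment=frag, match=match,
                            template_site_id="tmpl",
                            total_score=total_score, rank=rank)
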