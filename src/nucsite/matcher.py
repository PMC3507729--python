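"""Local structural matching of residue pseudo-atom sets.

Finds the largest subsets of query residues that superpose onto a
template binding site within an RMSD bound, subject to per-pair
BLOSUM62 compatibility and mutual Cα proximity.  Residues are compared
sequence-order-independently: a match is any injective pairing of
query residues to template residues whose 2N pseudo-atoms (Cα and
side-chain centre of every pair) superpose under a proper rotation.

The search enumerates pairings depth-first over compatible residue
pairs, pruning with two proven bounds:

* the optimal sum of squared deviations is monotone under set growth,
  so a partial pairing whose SSD already exceeds the largest value any
  feasible completion could carry is dead;
* if a full match of size N has 2N-point RMSD ≤ r, corresponding
  intra-set distances (Cα–Cα and sc–sc) differ by at most 2·r·√N.

Both bounds are conservative, so the returned maximal matches are
exactly those an exhaustive enumeration would find.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .structio import ResidueDescriptor

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_STANDARD_AA = "ARNDCQEGHILKMFPSTWYV"


@dataclass
class MatchParams:
    rmsd_max: float = 0.6            # Å, over the 2N pseudo-atoms
    blosum_min: int = 0              # per-pair substitution score floor
    ca_connectivity_max: float = 7.5  # Å, mutual Cα proximity
    min_match_size: int = 3
    max_matches_per_template: int = 16

    def __post_init__(self):
        if self.rmsd_max <= 0:
            raise ValueError("rmsd_max must be positive")
        if self.min_match_size < 3:
            raise ValueError("min_match_size must be >= 3")


@dataclass
class StructuralMatch:
    template_site_id: str
    pairs: list[tuple[tuple, int]]   # (query residue_ref, template residue index)
    rotation: np.ndarray             # (3,3), proper
    translation: np.ndarray          # (3,)
    rmsd: float
    query_indices: list[int] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.pairs)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the template→query rigid transform to (n,3) coordinates."""
        return coords @ self.rotation.T + self.translation


def blosum62(a: str, b: str) -> int:
    """Symmetric BLOSUM62 lookup; X scores as the minimum over the row."""
    a, b = a.upper(), b.upper()
    for code in (a, b):
        if code not in _STANDARD_AA and code != "X":
            raise ValueError(f"unknown amino-acid code {code!r}")
    if a == "X" and b == "X":
        return int(min(_BLOSUM62[x][y] for x in _STANDARD_AA for y in _STANDARD_AA))
    if a == "X":
        return int(min(_BLOSUM62[b][y] for y in _STANDARD_AA))
    if b == "X":
        return int(min(_BLOSUM62[a][y] for y in _STANDARD_AA))
    return int(_BLOSUM62[a][b])


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray):
    """Least-squares proper rigid superposition of ``moving`` onto ``fixed``.

    Returns ``(rotation, translation, rmsd)`` with
    ``fixed ≈ moving @ rotation.T + translation`` and reflections
    disallowed (det(rotation) = +1).
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(fixed, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or len(P) < 1:
        raise ValueError("point sets must be equal-length (n,3) arrays, n >= 1")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    diff = P @ R.T + t - Q
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return R, t, rmsd


def _kabsch_ssd(P: np.ndarray, Q: np.ndarray) -> float:
    """Optimal sum of squared deviations (monotone under set growth)."""
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    Pc = P - cp
    Qc = Q - cq
    H = Pc.T @ Qc
    s = np.linalg.svd(H, compute_uv=False)
    d = np.sign(np.linalg.det(H)) if np.linalg.det(H) != 0 else 1.0
    trace = s[0] + s[1] + d * s[2]
    ssd = float(np.sum(Pc * Pc) + np.sum(Qc * Qc) - 2.0 * trace)
    return max(ssd, 0.0)


def _no_isolated(ca: np.ndarray, cutoff: float) -> bool:
    """True if every point has a neighbour within ``cutoff`` (n >= 2)."""
    n = len(ca)
    if n < 2:
        return True
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return bool(np.all(d.min(axis=1) <= cutoff))


def validate_match(match: StructuralMatch,
                   query: list[ResidueDescriptor],
                   template_residues: list[ResidueDescriptor],
                   params: MatchParams) -> None:
    """Re-assert every contract on an emitted match (raises on violation)."""
    if match.size < params.min_match_size:
        raise AssertionError("match below minimum size")
    if match.rmsd > params.rmsd_max + 1e-9:
        raise AssertionError("match RMSD above threshold")
    if abs(np.linalg.det(match.rotation) - 1.0) > 1e-6:
        raise AssertionError("rotation is not proper")
    qd = {d.residue_ref: d for d in query}
    for ref, ti in match.pairs:
        if blosum62(qd[ref].aa, template_residues[ti].aa) < params.blosum_min:
            raise AssertionError("BLOSUM constraint violated")
    qca = np.array([qd[ref].ca for ref, _ in match.pairs])
    tca = np.array([template_residues[ti].ca for _, ti in match.pairs])
    if not _no_isolated(qca, params.ca_connectivity_max):
        raise AssertionError("isolated query residue in match")
    if not _no_isolated(tca, params.ca_connectivity_max):
        raise AssertionError("isolated template residue in match")


def find_matches(query: list[ResidueDescriptor],
                 template_site,
                 params: MatchParams | None = None) -> list[StructuralMatch]:
    """All maximal structural matches of ``query`` onto a template site.

    Sorted by (size desc, RMSD asc, lexicographic query residue refs)
    and capped at ``params.max_matches_per_template``.
    """
    params = params or MatchParams()
    tmpl: list[ResidueDescriptor] = template_site.residues
    nt, nq = len(tmpl), len(query)
    if nq == 0 or nt < params.min_match_size:
        return []

    q_pts = np.array([d.points() for d in query])       # (nq, 2, 3)
    t_pts = np.array([d.points() for d in tmpl])        # (nt, 2, 3)
    q_ca, q_sc = q_pts[:, 0, :], q_pts[:, 1, :]
    t_ca, t_sc = t_pts[:, 0, :], t_pts[:, 1, :]

    # candidate residue pairs (template index, query index)
    cand: list[tuple[int, int]] = []
    for ti in range(nt):
        for qi in range(nq):
            if blosum62(query[qi].aa, tmpl[ti].aa) >= params.blosum_min:
                cand.append((ti, qi))
    if not cand:
        return []
    # deterministic pair order: template index, then query residue ref
    cand.sort(key=lambda p: (p[0], query[p[1]].residue_ref))
    npairs = len(cand)

    n_cap = min(nt, nq)
    dist_tol = 2.0 * params.rmsd_max * np.sqrt(n_cap)
    ssd_cap = params.rmsd_max ** 2 * 2 * n_cap

    def _dm(X):
        return np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)

    qd_ca, qd_sc = _dm(q_ca), _dm(q_sc)
    td_ca, td_sc = _dm(t_ca), _dm(t_sc)

    compat = np.zeros((npairs, npairs), dtype=bool)
    for i, (ti, qi) in enumerate(cand):
        for j in range(i + 1, npairs):
            tj, qj = cand[j]
            if ti == tj or qi == qj:
                continue
            if (abs(qd_ca[qi, qj] - td_ca[ti, tj]) <= dist_tol
                    and abs(qd_sc[qi, qj] - td_sc[ti, tj]) <= dist_tol):
                compat[i, j] = compat[j, i] = True

    feasible: list[tuple[frozenset, list[int], float]] = []

    def grow(chosen: list[int], start: int):
        k = len(chosen)
        if k >= params.min_match_size:
            t_idx = [cand[c][0] for c in chosen]
            q_idx = [cand[c][1] for c in chosen]
            P = t_pts[t_idx].reshape(-1, 3)
            Q = q_pts[q_idx].reshape(-1, 3)
            rmsd = np.sqrt(_kabsch_ssd(P, Q) / (2 * k))
            if (rmsd <= params.rmsd_max
                    and _no_isolated(q_ca[q_idx], params.ca_connectivity_max)
                    and _no_isolated(t_ca[t_idx], params.ca_connectivity_max)):
                feasible.append((frozenset(chosen), chosen.copy(), rmsd))
        for nxt in range(start, npairs):
            if chosen and not all(compat[c, nxt] for c in chosen):
                continue
            chosen.append(nxt)
            if len(chosen) >= 3:
                t_idx = [cand[c][0] for c in chosen]
                q_idx = [cand[c][1] for c in chosen]
                ssd = _kabsch_ssd(t_pts[t_idx].reshape(-1, 3),
                                  q_pts[q_idx].reshape(-1, 3))
                if ssd <= ssd_cap:
                    grow(chosen, nxt + 1)
            else:
                grow(chosen, nxt + 1)
            chosen.pop()

    grow([], 0)
    if not feasible:
        return []

    # keep only maximal pairings
    sets = [f[0] for f in feasible]
    matches = []
    for s, chosen, rmsd in feasible:
        if any(s < other for other in sets):
            continue
        t_idx = [cand[c][0] for c in chosen]
        q_idx = [cand[c][1] for c in chosen]
        R, t, rmsd_final = kabsch_superpose(t_pts[t_idx].reshape(-1, 3),
                                            q_pts[q_idx].reshape(-1, 3))
        pairs = sorted(((query[qi].residue_ref, ti)
                        for ti, qi in zip(t_idx, q_idx)))
        matches.append(StructuralMatch(
            template_site_id=getattr(template_site, "site_id", "template"),
            pairs=pairs,
            rotation=R, translation=t, rmsd=rmsd_final,
            query_indices=sorted(q_idx)))

    matches.sort(key=lambda m: (-m.size, m.rmsd,
                                tuple(ref for ref, _ in m.pairs)))
    # drop duplicate pair-sets (possible only through numeric ties)
    seen = set()
    unique = []
    for m in matches:
        key = tuple(m.pairs)
        if key not in seen:
            seen.add(key)
            unique.append(m)
    return unique[:params.max_matches_per_template]


def scan_library(query: list[ResidueDescriptor], library,
                 params: MatchParams | None = None) -> dict[str, list]:
    """Run :func:`find_matches` against every template of every module type.

    Returns ``{module_type: [(match, template_site), ...]}`` so that
    downstream filters retain template provenance.
    """
    params = params or MatchParams()
    out: dict[str, list] = {}
    for module_type, sites in library.sites_by_type().items():
        hits = []
        for site in sites:
            for m in find_matches(query, site, params):
                hits.append((m, site))
        out[module_type] = hits
    return out
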