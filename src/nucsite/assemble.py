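"""Combination of module predictions into whole binding-site predictions.

Each nucleotide type has an architecture — its ordered module-type
string over {N, C, P} (e.g. ATP = NCPPP, FAD = NCPPCN).  Predicted
modules are assigned to architecture positions under empirical
centroid-distance constraints derived from bound nucleotides (1st/99th
percentile envelopes per module-type pair).  If the full architecture
cannot be realised, progressively shorter contiguous sub-architectures
are attempted; the minimum is two consecutive different module types.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .pipeline import ModulePrediction
from .structio import LETTER_TO_TYPE, TYPE_TO_LETTER, ModuleFragment

#: architecture strings per chemical component
ARCHITECTURES: dict[str, str] = {
    "AMP": "NCP", "ADP": "NCPP", "ATP": "NCPPP", "ANP": "NCPPP",
    "GDP": "NCPP", "GTP": "NCPPP", "GNP": "NCPPP",
    "FMN": "NCP", "FAD": "NCPPCN", "NAD": "NCPPCN", "NAP": "NCPPCN",
}
#: components with a branch module outside the linear architecture
BRANCH_MODULES: dict[str, str] = {"NAP": "P"}

_PAIR_KEYS = [("N", "C"), ("P", "C"), ("N", "P"),
              ("N", "N"), ("C", "C"), ("P", "P")]


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b)))  # type: ignore[return-value]


@dataclass
class PairConstraints:
    """(min, max) centroid distance in Å per unordered module-type pair."""
    ranges: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: {
            _pair_key("N", "C"): (3.937, 5.275),
            _pair_key("P", "C"): (3.079, 5.151),
            _pair_key("N", "P"): (5.189, 19.063),
            _pair_key("N", "N"): (8.846, 19.540),
            _pair_key("C", "C"): (5.528, 16.333),
            _pair_key("P", "P"): (2.654, 7.148),
        })

    def __post_init__(self):
        for key, (lo, hi) in self.ranges.items():
            if not (0 < lo < hi):
                raise ValueError(f"invalid range for {key}: ({lo}, {hi})")

    def range_for(self, type_a: str, type_b: str) -> tuple[float, float]:
        la = TYPE_TO_LETTER.get(type_a, type_a)
        lb = TYPE_TO_LETTER.get(type_b, type_b)
        return self.ranges[_pair_key(la, lb)]


DEFAULT_PAIR_CONSTRAINTS = PairConstraints()


@dataclass
class SitePrediction:
    architecture: str
    modules: list[ModulePrediction]     # one per architecture letter
    score: float
    rank: int = 0
    mean_pair_distance: float = 0.0
    branch_module: ModulePrediction | None = None
    correctness: dict[str, bool] = field(default_factory=dict)

    def member_centroids(self) -> np.ndarray:
        return np.array([m.centroid for m in self.modules])

    def validate(self, constraints: PairConstraints) -> None:
        for a, b in itertools.combinations(self.modules, 2):
            if not check_pair(a.fragment, b.fragment, constraints):
                raise AssertionError("emitted site violates a pair constraint")


def enumerate_subarchitectures(arch: str) -> list[str]:
    """Distinct contiguous substrings of length >= 2 that contain at
    least one adjacent pair of different module types, ordered by
    decreasing length then left position; the full architecture first.
    """
    if not arch or any(c not in LETTER_TO_TYPE for c in arch):
        raise ValueError(f"invalid architecture {arch!r}")
    seen = set()
    out = []
    for length in range(len(arch), 1, -1):
        for start in range(0, len(arch) - length + 1):
            sub = arch[start:start + length]
            if sub in seen:
                continue
            if not any(sub[i] != sub[i + 1] for i in range(len(sub) - 1)):
                continue   # identical consecutive modules only
            seen.add(sub)
            out.append(sub)
    return out


def check_pair(frag_a: ModuleFragment, frag_b: ModuleFragment,
               constraints: PairConstraints = DEFAULT_PAIR_CONSTRAINTS) -> bool:
    """True iff the centroid distance is inside the pair's [min, max]."""
    lo, hi = constraints.range_for(frag_a.module_type, frag_b.module_type)
    d = float(np.linalg.norm(frag_a.centroid - frag_b.centroid))
    return lo <= d <= hi


def _mean_pairwise(centroids: np.ndarray) -> float:
    if len(centroids) < 2:
        return 0.0
    d = [np.linalg.norm(a - b)
         for a, b in itertools.combinations(centroids, 2)]
    return float(np.mean(d))


def assemble_sites(predictions: dict[str, list[ModulePrediction]],
                   target_arch: str,
                   constraints: PairConstraints = DEFAULT_PAIR_CONSTRAINTS,
                   top_k_per_type: int = 10,
                   adjacent_only: bool = False,
                   min_length: int = 2) -> list[SitePrediction]:
    """Backtracking assembly of predictions into (sub-)architectures.

    Tries the target architecture first, then each sub-architecture in
    enumeration order, and returns every valid site found at the first
    (longest) architecture length that yields any.  Candidate modules
    are the ``top_k_per_type`` ranked predictions per type; a module
    may not occupy two positions in one site.  Sites are deduplicated
    on their module set and ranked by score descending, ties by
    shorter mean pairwise centroid distance.
    """
    cand: dict[str, list[ModulePrediction]] = {}
    for letter, module_type in LETTER_TO_TYPE.items():
        cand[letter] = list(predictions.get(module_type, []))[:top_k_per_type]

    def compatible(placed: list[ModulePrediction], pos: int,
                   nxt: ModulePrediction, arch: str) -> bool:
        for prev_pos, prev in enumerate(placed):
            if adjacent_only and abs(prev_pos - pos) != 1:
                continue
            if not check_pair(prev.fragment, nxt.fragment, constraints):
                return False
        return True

    def solve(arch: str) -> list[SitePrediction]:
        found: list[SitePrediction] = []
        seen_sets = set()
        placed: list[ModulePrediction] = []

        def backtrack(pos: int):
            if pos == len(arch):
                key = frozenset(id(m) for m in placed)
                if key not in seen_sets:
                    seen_sets.add(key)
                    mods = list(placed)
                    score = float(sum(m.total_score for m in mods))
                    found.append(SitePrediction(
                        architecture=arch, modules=mods, score=score,
                        mean_pair_distance=_mean_pairwise(
                            np.array([m.centroid for m in mods]))))
                return
            for c in cand[arch[pos]]:
                if any(c is p for p in placed):
                    continue
                if compatible(placed, pos, c, arch):
                    placed.append(c)
                    backtrack(pos + 1)
                    placed.pop()

        backtrack(0)
        return found

    subarchs = enumerate_subarchitectures(target_arch)
    sites: list[SitePrediction] = []
    current_len = None
    for arch in subarchs:
        if len(arch) < min_length:
            continue
        if current_len is not None and len(arch) < current_len:
            break
        hits = solve(arch)
        if hits:
            sites.extend(hits)
            current_len = len(arch)
    sites.sort(key=lambda s: (-s.score, s.mean_pair_distance))
    for rank, s in enumerate(sites, start=1):
        s.rank = rank
        s.validate(constraints)
    return sites


def attach_branch(site: SitePrediction,
                  predictions: dict[str, list[ModulePrediction]],
                  constraints: PairConstraints = DEFAULT_PAIR_CONSTRAINTS,
                  top_k_per_type: int = 10) -> SitePrediction:
    """Try to append a branch phosphate (NADP 2'-P) to an assembled site.

    The branch is constrained only against the site's phosphate and
    carbohydrate members (P–P and P–C ranges); the linear architecture
    string is unchanged.
    """
    from .structio import CARBOHYDRATE, PHOSPHATE
    used = {id(m) for m in site.modules}
    for c in list(predictions.get(PHOSPHATE, []))[:top_k_per_type]:
        if id(c) in used:
            continue
        ok = True
        for m in site.modules:
            if m.module_type in (PHOSPHATE, CARBOHYDRATE):
                if not check_pair(m.fragment, c.fragment, constraints):
                    ok = False
                    break
        if ok:
            site.branch_module = c
            site.score += c.total_score
            break
    return site


def derive_pair_constraints(complexes: list, defs,
                            min_observations: int = 10,
                            fallback: PairConstraints = DEFAULT_PAIR_CONSTRAINTS
                            ) -> tuple[PairConstraints, list[str]]:
    """Re-derive the distance envelopes from holo complexes.

    Pools all intra-ligand module-pair centroid distances per type pair
    and takes the 1st/99th percentiles; pair classes with fewer than
    ``min_observations`` fall back to the shipped defaults (flagged).
    """
    from . import structio

    pools: dict[tuple[str, str], list[float]] = {k: [] for k in
                                                 map(lambda p: _pair_key(*p), _PAIR_KEYS)}
    for cx in complexes:
        for ligand in cx.ligands:
            try:
                frags = structio.decompose_ligand(ligand, defs)
            except structio.UnknownLigandError:
                continue
            for fa, fb in itertools.combinations(frags, 2):
                key = _pair_key(TYPE_TO_LETTER[fa.module_type],
                                TYPE_TO_LETTER[fb.module_type])
                pools[key].append(float(np.linalg.norm(
                    fa.centroid - fb.centroid)))

    ranges = {}
    flags = []
    for key in pools:
        vals = pools[key]
        if len(vals) < min_observations:
            ranges[key] = fallback.ranges[key]
            flags.append(f"fallback:{key[0]}-{key[1]} ({len(vals)} observations)")
        else:
            lo, hi = np.percentile(vals, [1.0, 99.0])
            ranges[key] = (float(lo), float(hi))
    return PairConstraints(ranges=ranges), flags


def sites_to_tsv(sites: list[SitePrediction]) -> str:
    lines = ["rank\tarchitecture\tscore\tmean_pair_distance\tmembers"]
    for s in sites:
        members = ";".join(
            f"{TYPE_TO_LETTER[m.module_type]}:rank{m.rank}:"
            f"{m.centroid[0]:.3f},{m.centroid[1]:.3f},{m.centroid[2]:.3f}"
            for m in s.modules)
        if s.branch_module is not None:
            b = s.branch_module
            members += (f";branchP:rank{b.rank}:"
                        f"{b.centroid[0]:.3f},{b.centroid[1]:.3f},{b.centroid[2]:.3f}")
        lines.append(f"{s.rank}\t{s.architecture}\t{s.score:.4f}\t"
                     f"{s.mean_pair_distance:.4f}\t{members}")
    return "\n".join(lines) + "\n"
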