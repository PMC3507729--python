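"""Template library of module-binding sites.

A template binding site is the set of residues (at least three) of a
solved protein–ligand complex that contact one nucleotide module —
any heavy atom within 3.5 Å of any fragment heavy atom.  Libraries are
reduced for redundancy by greedy single-linkage clustering of source
chain sequences at 95% global identity, keeping one randomly selected
site per cluster and module type.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import structio
from .structio import (Atom, FragmentDefinition, ModuleFragment,
                       ResidueDescriptor, Structure)

CONTACT_CUTOFF = 3.5   # Å, heavy atom to heavy atom, inclusive
MIN_RESIDUES = 3
REDUNDANCY_IDENTITY = 0.95


@dataclass
class TemplateBindingSite:
    site_id: str
    source: tuple[str, str]                 # (structure id, chain id)
    residues: list[ResidueDescriptor]
    fragment: ModuleFragment                # in source coordinates
    source_sequence: str
    shared_chains: int = 1                  # chains contacting the fragment

    @property
    def module_type(self) -> str:
        return self.fragment.module_type

    def validate(self) -> None:
        if len(self.residues) < MIN_RESIDUES:
            raise ValueError(f"{self.site_id}: fewer than {MIN_RESIDUES} residues")


def _residue_heavy_coords(res) -> np.ndarray:
    return np.array([a.pos for a in res.atoms if not a.is_hydrogen()])


def extract_binding_sites(complex_structure: Structure,
                          defs: dict[str, FragmentDefinition],
                          contact_cutoff: float = CONTACT_CUTOFF,
                          min_residues: int = MIN_RESIDUES
                          ) -> list[TemplateBindingSite]:
    """Extract one candidate site per (fragment, contacting chain).

    Residues come from the single chain contributing the most contacting
    residues; additional contacting chains yield their own (flagged)
    sites.  Sites with fewer than ``min_residues`` contacts are dropped;
    ligands without a fragment definition are skipped.
    """
    sites = []
    for ligand in complex_structure.ligands:
        try:
            fragments = structio.decompose_ligand(ligand, defs)
        except structio.UnknownLigandError:
            continue
        for frag in fragments:
            frag_xyz = frag.heavy_coords()
            contacts_by_chain: dict[str, list[int]] = {}
            for chain in complex_structure.chains:
                idxs = []
                for ri, res in enumerate(chain.residues):
                    xyz = _residue_heavy_coords(res)
                    if xyz.size == 0:
                        continue
                    dmin = np.min(np.linalg.norm(
                        xyz[:, None, :] - frag_xyz[None, :, :], axis=-1))
                    if dmin <= contact_cutoff:
                        idxs.append(ri)
                if idxs:
                    contacts_by_chain[chain.chain_id] = idxs
            qualifying = {cid: idxs for cid, idxs in contacts_by_chain.items()
                          if len(idxs) >= min_residues}
            n_chains = len(qualifying)
            for cid in sorted(qualifying):
                descs = structio.residue_descriptors(complex_structure, cid)
                by_ref = {d.residue_ref: d for d in descs}
                chain = complex_structure.chain(cid)
                site_res = []
                for ri in qualifying[cid]:
                    res = chain.residues[ri]
                    ref = (cid, res.seqnum, res.icode)
                    if ref in by_ref:
                        site_res.append(by_ref[ref])
                if len(site_res) < min_residues:
                    continue
                sites.append(TemplateBindingSite(
                    site_id=f"{complex_structure.id}_{cid}_{ligand.key}"
                            f"_f{frag.arch_index}",
                    source=(complex_structure.id, cid),
                    residues=site_res,
                    fragment=frag,
                    source_sequence=structio.chain_sequence(complex_structure, cid),
                    shared_chains=n_chains))
    return sites


def greedy_identity_clusters(sequences: list[str],
                             identity_threshold: float,
                             identity_fn=None) -> list[list[int]]:
    """Single-linkage clustering of sequences on pairwise global identity.

    Clusters are lists of input indices; within each cluster indices are
    ordered representative-first (longest sequence, ties by input order).
    Deterministic given input order.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    if identity_fn is None:
        from .pipeline import global_identity
        identity_fn = global_identity
    n = len(sequences)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    cache: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            key = (i, j)
            if key not in cache:
                cache[key] = identity_fn(sequences[i], sequences[j])
            if cache[key] >= identity_threshold:
                parent[find(j)] = find(i)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters = []
    for root in sorted(groups, key=lambda r: min(groups[r])):
        members = groups[root]
        rep = min(members, key=lambda i: (-len(sequences[i]), i))
        clusters.append([rep] + [m for m in members if m != rep])
    return clusters


class Library:
    """Template sets keyed by module type, with build metadata."""

    def __init__(self, sites: list[TemplateBindingSite], metadata: dict | None = None):
        self.sites = list(sites)
        self.metadata = metadata or {}
        self._by_id = {s.site_id: s for s in self.sites}

    def sites_by_type(self) -> dict[str, list[TemplateBindingSite]]:
        out: dict[str, list[TemplateBindingSite]] = {t: [] for t in structio.MODULE_TYPES}
        for s in self.sites:
            out[s.module_type].append(s)
        return out

    def get(self, site_id: str) -> TemplateBindingSite:
        return self._by_id[site_id]

    def __len__(self):
        return len(self.sites)

    # --- serialization (self-contained structured text) ---

    def to_json(self) -> str:
        def atom_rec(a: Atom):
            return {"name": a.name, "element": a.element,
                    "xyz": [round(float(v), 6) for v in a.pos]}

        recs = []
        for s in self.sites:
            recs.append({
                "site_id": s.site_id,
                "source": list(s.source),
                "source_sequence": s.source_sequence,
                "shared_chains": s.shared_chains,
                "residues": [{
                    "ref": [s_.residue_ref[0], s_.residue_ref[1], s_.residue_ref[2]],
                    "aa": s_.aa,
                    "ca": [round(float(v), 6) for v in s_.ca],
                    "sc": [round(float(v), 6) for v in s_.sc_center],
                } for s_ in s.residues],
                "fragment": {
                    "module_type": s.fragment.module_type,
                    "subtype": s.fragment.subtype,
                    "arch_index": s.fragment.arch_index,
                    "branch": s.fragment.branch,
                    "provenance": s.fragment.provenance,
                    "atoms": [atom_rec(a) for a in s.fragment.atoms],
                },
            })
        return json.dumps({"metadata": self.metadata, "sites": recs},
                          indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str, validate: bool = True) -> "Library":
        raw = json.loads(text)
        sites = []
        for rec in raw["sites"]:
            residues = [ResidueDescriptor(
                residue_ref=(r["ref"][0], int(r["ref"][1]), r["ref"][2]),
                aa=r["aa"],
                ca=np.array(r["ca"], dtype=float),
                sc_center=np.array(r["sc"], dtype=float),
            ) for r in rec["residues"]]
            f = rec["fragment"]
            atoms = [Atom(a["name"], a["element"], np.array(a["xyz"], dtype=float))
                     for a in f["atoms"]]
            frag = ModuleFragment.from_atoms(
                f["module_type"], f["subtype"], atoms,
                provenance=f["provenance"], arch_index=f["arch_index"],
                branch=f["branch"])
            site = TemplateBindingSite(
                site_id=rec["site_id"], source=tuple(rec["source"]),
                residues=residues, fragment=frag,
                source_sequence=rec["source_sequence"],
                shared_chains=rec.get("shared_chains", 1))
            if validate:
                site.validate()
                _validate_contacts(site)
            sites.append(site)
        return cls(sites, raw.get("metadata", {}))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path, validate: bool = True) -> "Library":
        with open(path) as fh:
            return cls.from_json(fh.read(), validate=validate)


def _validate_contacts(site: TemplateBindingSite,
                       cutoff: float = CONTACT_CUTOFF) -> None:
    """Re-check the contact invariant on the stored pseudo-atoms.

    Only the Cα and side-chain centre survive serialization, so the
    check uses a relaxed bound: a residue whose nearest heavy atom was
    within 3.5 Å must have a pseudo-atom within contact + reach of the
    fragment (side-chain atoms lie within ~4 Å of their centre).
    """
    frag_xyz = site.fragment.heavy_coords()
    reach = 4.0
    for r in site.residues:
        d = min(np.min(np.linalg.norm(frag_xyz - r.ca, axis=1)),
                np.min(np.linalg.norm(frag_xyz - r.sc_center, axis=1)))
        if d > cutoff + reach:
            raise ValueError(
                f"{site.site_id}: residue {r.residue_ref} violates the "
                f"contact invariant (nearest pseudo-atom {d:.2f} Å)")


def build_library(complexes: list[Structure],
                  defs: dict[str, FragmentDefinition],
                  redundancy_identity: float = REDUNDANCY_IDENTITY,
                  seed: int = 0,
                  contact_cutoff: float = CONTACT_CUTOFF,
                  min_residues: int = MIN_RESIDUES) -> Library:
    """Extract sites from all complexes and reduce redundancy.

    Per module type, one site is kept per source-sequence cluster,
    selected by a seeded RNG so the library is byte-reproducible.
    """
    all_sites: list[TemplateBindingSite] = []
    for cx in complexes:
        all_sites.extend(extract_binding_sites(cx, defs, contact_cutoff,
                                               min_residues))
    sequences = sorted({s.source_sequence for s in all_sites})
    if sequences:
        clusters = greedy_identity_clusters(sequences, redundancy_identity)
    else:
        clusters = []
    seq_to_cluster = {}
    for ci, members in enumerate(clusters):
        for m in members:
            seq_to_cluster[sequences[m]] = ci

    rng = np.random.default_rng(seed)
    kept: list[TemplateBindingSite] = []
    for module_type in structio.MODULE_TYPES:
        typed = [s for s in all_sites if s.module_type == module_type]
        by_cluster: dict[int, list[TemplateBindingSite]] = {}
        for s in typed:
            by_cluster.setdefault(seq_to_cluster[s.source_sequence], []).append(s)
        for ci in sorted(by_cluster):
            members = sorted(by_cluster[ci], key=lambda s: s.site_id)
            kept.append(members[rng.integers(len(members))])

    metadata = {
        "seed": int(seed),
        "redundancy_identity": redundancy_identity,
        "contact_cutoff": contact_cutoff,
        "min_residues": min_residues,
        "n_complexes": len(complexes),
        "n_sites_raw": len(all_sites),
        "n_sites": len(kept),
    }
    return Library(kept, metadata)
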