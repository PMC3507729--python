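"""Seeded synthetic inputs for every other module.

Generates decoy pseudo-chains (self-avoiding Cα walks with side-chain
centres), synthetic module-binding sites, planted-motif queries with
known ground truth, toy holo complexes whose module centroids satisfy
the shipped inter-module distance envelopes, and toy multiple sequence
alignments with controlled conservation.  Everything is reproducible
from a seed; no physical realism is claimed — every tested contract is
geometric or statistical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _toybuild
from .assemble import ARCHITECTURES
from .evaluate import GroundTruth
from .matcher import blosum62
from .structio import (AA_1TO3, Atom, Chain, FragmentDefinition, Ligand,
                       ModuleFragment, Residue, ResidueDescriptor, Structure)
from .templates import TemplateBindingSite

#: amino acids with pairwise BLOSUM62 <= -1: residues drawn from
#: different letters can never satisfy a non-negative substitution
#: constraint, so matches cannot scramble residue correspondences
DISSIMILAR_AA = ["C", "P", "D", "W", "H", "K", "M"]

_DECOY_AA = "ARNDCQEHILKMFPSTWYV"   # no glycine: every decoy has a CB

CA_SPACING = 3.8          # Å between consecutive Cα
CA_SPACING_JITTER = 0.05
MIN_NONCONSEC_CA = 4.0    # Å self-avoidance
SC_OFFSET = (1.5, 2.5)    # Å side-chain centre off Cα


class FixtureError(RuntimeError):
    pass


@dataclass
class FixtureSpec:
    seed: int = 0
    n_decoy_residues: int = 30
    noise_sigma: float = 0.1
    n_motif_residues: int = 4


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def make_decoy_chain(n: int, seed=0, chain_id: str = "A",
                     structure_id: str = "decoy") -> Structure:
    """Self-avoiding pseudo-chain: consecutive Cα at 3.8 ± 0.05 Å, no
    non-consecutive pair below 4 Å, side-chain centre 1.5–2.5 Å off Cα."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    for _ in range(50):          # whole-chain restarts
        cas = [np.zeros(3)]
        ok = True
        for _ in range(n - 1):
            placed = False
            for _ in range(200):
                step = (CA_SPACING +
                        rng.uniform(-CA_SPACING_JITTER, CA_SPACING_JITTER))
                cand = cas[-1] + step * _unit(rng)
                if len(cas) < 2 or np.all(
                        np.linalg.norm(np.array(cas[:-1]) - cand, axis=1)
                        >= MIN_NONCONSEC_CA):
                    cas.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            break
    else:
        raise FixtureError(f"decoy placement failed for seed-derived walk (n={n})")

    residues = []
    for i, ca in enumerate(cas):
        aa = _DECOY_AA[rng.integers(len(_DECOY_AA))]
        cb = ca + rng.uniform(*SC_OFFSET) * _unit(rng)
        residues.append(Residue(AA_1TO3[aa], i + 1, "", [
            Atom("CA", "C", ca.copy()), Atom("CB", "C", cb)]))
    return Structure(id=structure_id,
                     chains=[Chain(chain_id, residues)])


def _po4_atoms(center: np.ndarray) -> list[Atom]:
    """Phosphate-like blob: P at the centre plus 4 tetrahedral oxygens,
    translated so the heavy-atom mean equals ``center`` exactly."""
    t = 1.0 / np.sqrt(3.0)
    verts = np.array([[t, t, t], [t, -t, -t], [-t, t, -t], [-t, -t, t]]) * 1.5
    pts = np.vstack([[0.0, 0.0, 0.0], verts])
    pts = pts - pts.mean(axis=0) + center
    names = ["P", "O1", "O2", "O3", "O4"]
    return [Atom(n, n[0], p) for n, p in zip(names, pts)]


def make_synthetic_site(n_residues: int = 4, seed=0,
                        site_id: str = "synthetic",
                        aa_choices: str | None = None) -> TemplateBindingSite:
    """A synthetic module-binding site: a phosphate-like fragment with
    residues on a spherical cap below it (the opposite side stays open
    so a solvent probe can always reach the fragment)."""
    if n_residues < 3:
        raise ValueError("a site needs at least 3 residues")
    rng = _rng(seed)
    frag_atoms = _po4_atoms(np.zeros(3))
    frag = ModuleFragment.from_atoms("phosphate", "phosphate", frag_atoms,
                                     provenance=f"synthetic:{site_id}")
    choices = aa_choices or _DECOY_AA
    down = np.array([0.0, 0.0, -1.0])
    residues = None
    for _site_try in range(60):
        residues = []
        for i in range(n_residues):
            for _ in range(100):
                d = down + 0.45 * rng.normal(size=3)
                d /= np.linalg.norm(d)
                anchor = max(frag_atoms, key=lambda a: float(a.pos @ d))
                cb = anchor.pos + rng.uniform(3.0, 3.4) * d
                ca = cb + 1.7 * d
                near_frag = min(np.linalg.norm(a.pos - cb) for a in frag_atoms)
                clash = any(np.linalg.norm(r.ca - ca) < 3.0 or
                            np.linalg.norm(r.sc_center - cb) < 2.5
                            for r in residues)
                if 2.9 <= near_frag <= 3.45 and not clash:
                    break
            else:
                residues = None
                break
            aa = choices[rng.integers(len(choices))]
            residues.append(ResidueDescriptor(("T", i + 1, ""), aa, ca, cb))
        if residues is None:
            continue
        # mutual Cα proximity must hold for the site to be matchable
        cas = np.array([r.ca for r in residues])
        d = np.linalg.norm(cas[:, None] - cas[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if np.all(d.min(axis=1) <= 7.5):
            break
        residues = None
    if residues is None:
        raise FixtureError("synthetic site placement failed")
    return TemplateBindingSite(
        site_id=site_id, source=(site_id, "T"), residues=residues,
        fragment=frag, source_sequence="".join(r.aa for r in residues))


def plant_motif(decoy: Structure, template: TemplateBindingSite,
                sigma: float = 0.1, seed=0, transform=None,
                max_tries: int = 100):
    """Rigidly place a template site (residues + fragment) next to a
    decoy chain, perturb the residue coordinates with isotropic
    Gaussian noise, and return (structure, ground truth).

    The transform is re-sampled if any planted Cα comes within 2 Å of a
    decoy Cα or the fragment comes within 4 Å of any decoy atom, so the
    true placement stays solvent-reachable.
    """
    rng = _rng(seed)
    chain = decoy.chains[0]
    decoy_ca = np.array([r.get_atom("CA").pos for r in chain.residues])
    decoy_all = np.array([a.pos for r in chain.residues for a in r.atoms])
    center = decoy_ca.mean(axis=0)
    radius = float(np.max(np.linalg.norm(decoy_ca - center, axis=1)))

    motif_pts = np.array([[*r.ca] for r in template.residues] +
                         [[*r.sc_center] for r in template.residues])
    motif_center = motif_pts.mean(axis=0)

    for _ in range(max_tries):
        if transform is not None:
            R, t = transform
        else:
            R = _random_rotation(rng)
            t = (center + (radius + 8.0) * _unit(rng)) - R @ motif_center
        new_ca = np.array([R @ r.ca + t for r in template.residues])
        frag_xyz = np.array([R @ a.pos + t for a in template.fragment.atoms])
        ca_clash = np.min(np.linalg.norm(
            new_ca[:, None, :] - decoy_ca[None, :, :], axis=-1)) < 2.0
        frag_clash = np.min(np.linalg.norm(
            frag_xyz[:, None, :] - decoy_all[None, :, :], axis=-1)) < 4.0
        if not (ca_clash or frag_clash):
            break
        if transform is not None:
            raise FixtureError("fixed transform clashes with the decoy")
    else:
        raise FixtureError("could not place motif without clashes")

    out = Structure(id=decoy.id + "+motif",
                    chains=[Chain(chain.chain_id, list(chain.residues))])
    next_num = max(r.seqnum for r in chain.residues) + 1
    for i, rdesc in enumerate(template.residues):
        ca = R @ rdesc.ca + t + rng.normal(0.0, sigma, size=3)
        cb = R @ rdesc.sc_center + t + rng.normal(0.0, sigma, size=3)
        out.chains[0].residues.append(Residue(
            AA_1TO3.get(rdesc.aa, "ALA"), next_num + i, "",
            [Atom("CA", "C", ca), Atom("CB", "C", cb)]))
    true_frag = ModuleFragment.from_atoms(
        template.fragment.module_type, template.fragment.subtype,
        [Atom(a.name, a.element, R @ a.pos + t)
         for a in template.fragment.atoms],
        provenance=f"planted:{template.site_id}")
    return out, GroundTruth(fragments=[true_frag])


def _norm(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


#: module centroid layouts satisfying all pairwise distance envelopes,
#: as (centroid, residue-placement direction) per architecture position;
#: directions point into empty space so no fragment gets enclosed
TOY_LAYOUTS: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {
    "NCP": [
        (np.array([-4.6, 0.0, 0.0]), _norm([-1, 0, 0])),
        (np.array([0.0, 0.0, 0.0]), _norm([0, -1, 0])),
        (np.array([0.0, 4.1, 0.0]), _norm([0, 1, 0])),
    ],
    "NCPP": [
        (np.array([-4.6, 0.0, 0.0]), _norm([-1, 0, 0])),
        (np.array([0.0, 0.0, 0.0]), _norm([0, 0, 1])),
        (np.array([4.3, 1.4, 0.0]), _norm([0.2, 1, 0])),
        (np.array([4.6, -1.4, 0.0]), _norm([0.2, -1, 0])),
    ],
    "NCPPP": [
        (np.array([-4.6, 0.0, 0.0]), _norm([-1, 0, 0])),
        (np.array([0.0, 0.0, 0.0]), _norm([0, 0, 1])),
        (np.array([4.3, 1.4, 0.0]), _norm([0.2, 1, 0])),
        (np.array([4.6, -1.4, 0.0]), _norm([0.2, -1, 0])),
        (np.array([2.2, -1.7, -2.8]), _norm([0, -0.5, -1])),
    ],
    "NCPPCN": [
        (np.array([-4.45, 0.0, 0.0]), _norm([-1, 0, 0])),
        (np.array([0.0, 2.8, 0.0]), _norm([0, 1, 0])),
        (np.array([0.0, 0.0, 3.0]), _norm([0, 0, 1])),
        (np.array([0.0, 0.0, -3.0]), _norm([0, 0, -1])),
        (np.array([0.0, -2.8, 0.0]), _norm([0, -1, 0])),
        (np.array([4.45, 0.0, 0.0]), _norm([1, 0, 0])),
    ],
}
_NAP_BRANCH = (np.array([3.0, 0.0, 3.0]), _norm([1, 0, 1]))
_BLOB_RADIUS = 1.0


def _fragment_atoms(names: list[str], center: np.ndarray,
                    rng) -> list[Atom]:
    """Atoms on a small blob whose heavy-atom mean is exactly ``center``."""
    m = len(names)
    if m == 1:
        pts = center[None, :]
    else:
        u = rng.normal(size=(m, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v = u - u.mean(axis=0)
        scale = _BLOB_RADIUS / max(np.max(np.linalg.norm(v, axis=1)), 1e-9)
        pts = center + scale * v
    atoms = []
    for name, p in zip(names, pts):
        elem = next(c for c in name if c.isalpha())
        atoms.append(Atom(name, elem.upper(), p.copy()))
    return atoms


def _build_toy_complex(component_id, definition, rng, residues_per_site,
                       chain_id, structure_id) -> Structure:
    arch = ARCHITECTURES.get(component_id, definition.architecture)
    layout = list(TOY_LAYOUTS[arch])
    specs = [f for f in definition.fragments if not f.branch]
    branch_specs = [f for f in definition.fragments if f.branch]
    if len(specs) != len(layout):
        raise ValueError(f"layout/definition mismatch for {component_id}")
    all_specs = list(zip(specs, layout)) + \
        [(b, _NAP_BRANCH) for b in branch_specs]

    lig_atoms: list[Atom] = []
    frag_atom_sets: list[list[Atom]] = []
    for spec, (center, _) in all_specs:
        atoms = _fragment_atoms(spec.atom_names, center, rng)
        frag_atom_sets.append(atoms)
        lig_atoms.extend(atoms)

    residues: list[Residue] = []
    for si, ((spec, (center, outward)), atoms) in enumerate(
            zip(all_specs, frag_atom_sets)):
        if spec.branch:
            continue
        aa_set = [DISSIMILAR_AA[k]
                  for k in _toybuild.FANO_SITE_AA[si % len(_toybuild.FANO_SITE_AA)]]
        placed = _toybuild.place_site_residues(
            rng, center, outward, atoms, lig_atoms, residues, aa_set,
            residues_per_site)
        if placed is None:
            raise FixtureError(
                f"residue placement failed for {component_id} site {si}")
        residues.extend(placed)

    for i, res in enumerate(residues):
        res.seqnum = i + 1
    ligand = Ligand(component_id, chain_id, len(residues) + 10, "", lig_atoms)
    return Structure(id=structure_id,
                     chains=[Chain(chain_id, residues)],
                     ligands=[ligand])


def _verify_exact_matching(structure: Structure) -> bool:
    """True iff every extracted site template matches the complex in
    exactly one way: its own identity mapping at (numerically) zero
    RMSD.  This is what makes toy self-predictions exact."""
    from . import matcher, structio, templates

    defs = structio.load_fragment_definitions()
    sites = templates.extract_binding_sites(structure, defs)
    descs = structio.residue_descriptors(structure,
                                         structure.chains[0].chain_id)
    for site in sites:
        ms = matcher.find_matches(descs, site)
        if len(ms) != 1:
            return False
        if ms[0].size != len(site.residues) or ms[0].rmsd > 1e-6:
            return False
    return True


def make_toy_complex(component_id: str,
                     defs: dict[str, FragmentDefinition],
                     seed=0, residues_per_site: int = 4,
                     chain_id: str = "A",
                     verify_matching: bool = True) -> Structure:
    """A holo toy complex for one nucleotide type.

    Module centroids follow a fixed layout that satisfies every
    pairwise distance envelope; each linear-architecture fragment gets
    contacting residues at 3.0–3.4 Å placed along an open direction so
    the ligand stays solvent-reachable.  Residue identities within a
    site are distinct and drawn from Fano-plane subsets of seven
    mutually dissimilar amino acids, which blocks almost all spurious
    residue correspondences; as a guarantee the builder verifies that
    each extracted site matches the complex only through its own
    identity mapping, re-drawing the geometry otherwise.  Branch
    fragments (the NADP 2'-phosphate) receive no residues of their own.
    """
    if component_id not in defs:
        raise KeyError(f"no fragment definition for {component_id}")
    definition = defs[component_id]
    structure_id = f"toy_{component_id}_{seed}"
    for salt in range(30):
        rng = _rng(np.random.SeedSequence([int(seed) % (2**31), salt]))
        try:
            st = _build_toy_complex(component_id, definition, rng,
                                    residues_per_site, chain_id, structure_id)
        except FixtureError:
            continue
        if not verify_matching or _verify_exact_matching(st):
            return st
    raise FixtureError(
        f"could not build a cleanly matching toy complex for {component_id}")


def make_toy_msa(reference_sequence: str, n_rows: int,
                 conserved_positions, seed=0,
                 gap_fraction: float = 0.0) -> MultipleSeqAlignment:
    """Alignment with controlled conservation.

    Row 0 (id ``query``) is the reference; other rows keep conserved
    columns identical and mutate the rest to residues dissimilar to the
    reference (BLOSUM62 < 1 where possible), with optional gaps.
    """
    rng = _rng(seed)
    conserved = set(conserved_positions)
    records = [SeqRecord(Seq(reference_sequence), id="query", description="")]
    standard = "ARNDCQEGHILKMFPSTWYV"
    for row in range(1, n_rows):
        chars = []
        for i, ref in enumerate(reference_sequence):
            if i in conserved:
                chars.append(ref)
                continue
            if gap_fraction > 0 and rng.random() < gap_fraction:
                chars.append("-")
                continue
            dissimilar = [a for a in standard if blosum62(a, ref) < 1]
            pool = dissimilar or list(standard)
            chars.append(pool[rng.integers(len(pool))])
        records.append(SeqRecord(Seq("".join(chars)),
                                 id=f"row{row}", description=""))
    return MultipleSeqAlignment(records)
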