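"""Internal helper: residue placement for toy holo complexes."""

from __future__ import annotations

import numpy as np

from .structio import AA_1TO3, Atom, Residue

#: Fano-plane complements: 4-letter index subsets of the 7 dissimilar
#: amino acids such that any two subsets share exactly two letters
FANO_SITE_AA = [(3, 4, 5, 6), (1, 2, 5, 6), (1, 2, 3, 4), (0, 2, 4, 6),
                (0, 2, 3, 5), (0, 1, 4, 5), (0, 1, 3, 6)]


def place_site_residues(rng, center, outward, atoms, lig_atoms,
                        prior_residues, aa_letters, n_residues,
                        max_site_tries=60):
    """Sample contacting residues for one fragment on its open side.

    Each residue's side-chain centre lands 3.0–3.4 Å from the fragment
    atom extremal along a direction drawn in a cone about ``outward``;
    the Cα continues 1.7 Å further out.  Rejection rules: the residue
    must not approach any other fragment below 3.6 Å (so it contacts
    exactly one site and the ligand keeps its surface clearance), must
    not clash with previously placed residues (2.8 Å), and the site's
    Cα set must stay mutually connected at 7.5 Å.  Returns the residue
    list or None if the constraints could not be met.
    """
    for _ in range(max_site_tries):
        placed = []
        for _ in range(n_residues):
            ok = False
            for _ in range(300):
                d = outward + 0.4 * rng.normal(size=3)
                d /= np.linalg.norm(d)
                anchor = max(atoms, key=lambda a: float((a.pos - center) @ d))
                cb = anchor.pos + rng.uniform(3.0, 3.4) * d
                ca = cb + 1.7 * d
                near = min(np.linalg.norm(a.pos - cb) for a in atoms)
                other = min((min(np.linalg.norm(a.pos - cb),
                                 np.linalg.norm(a.pos - ca))
                             for a in lig_atoms if a not in atoms),
                            default=np.inf)
                clash = any(
                    min(np.linalg.norm(at.pos - cb),
                        np.linalg.norm(at.pos - ca)) < 2.8
                    for r in prior_residues + placed for at in r.atoms)
                if 2.9 <= near <= 3.45 and other >= 3.6 and not clash:
                    aa = aa_letters[len(placed) % len(aa_letters)]
                    placed.append(Residue(AA_1TO3[aa], 0, "", [
                        Atom("CA", "C", ca), Atom("CB", "C", cb)]))
                    ok = True
                    break
            if not ok:
                placed = None
                break
        if placed is None:
            continue
        cas = np.array([r.get_atom("CA").pos for r in placed])
        dm = np.linalg.norm(cas[:, None] - cas[None, :], axis=-1)
        np.fill_diagonal(dm, np.inf)
        if np.all(dm.min(axis=1) <= 7.5):
            return placed
    return None
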