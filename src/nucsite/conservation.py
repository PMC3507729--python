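"""Residue conservation from a multiple sequence alignment.

For every alignment column covering the query sequence, the fraction
of rows carrying a residue similar to the query residue (BLOSUM62
score >= 1) is computed; the fractions are then rank-normalised to
percentiles over the distribution of values in that alignment, making
scores comparable across protein families.  Percentiles live on a
0–100 scale so that the combined site score is commensurate with the
binder/non-binder classifier threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
from Bio import AlignIO

from .matcher import blosum62
from .structio import Structure, residue_descriptors

GAP_CHARS = set("-.")
SIMILARITY_MIN_SCORE = 1   # BLOSUM62 floor for "similar"


class MappingError(ValueError):
    pass


@dataclass
class ConservationProfile:
    """Percentile score per structure residue; None marks no coverage."""
    scores: dict[tuple, float | None] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def score(self, residue_ref) -> float | None:
        return self.scores.get(residue_ref)

    def mean_over(self, residue_refs) -> float | None:
        """Mean percentile over residues, skipping uncovered ones."""
        vals = [self.scores[r] for r in residue_refs
                if self.scores.get(r) is not None]
        if not vals:
            return None
        return float(np.mean(vals))


def column_similarity(column: list[str], reference_aa: str) -> float:
    """Fraction of non-gap rows similar to the reference residue.

    Similar means BLOSUM62(row aa, reference) >= 1; gaps are excluded
    from the denominator.  An all-gap column scores 0.
    """
    rows = [c.upper() for c in column if c not in GAP_CHARS]
    if not rows:
        return 0.0
    similar = sum(1 for c in rows
                  if blosum62(c, reference_aa) >= SIMILARITY_MIN_SCORE)
    return similar / len(rows)


def percentile_normalize(values: list[float],
                         inclusive: bool = True) -> list[float]:
    """Map each value to 100 x (rank of values <= it) / n.

    The inclusive empirical CDF sends the maximum to exactly 100; with
    ``inclusive=False`` ties rank strictly below (values < it).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("no values to normalize")
    n = vals.size
    if inclusive:
        ranks = np.sum(vals[None, :] <= vals[:, None], axis=1)
    else:
        ranks = np.sum(vals[None, :] < vals[:, None], axis=1)
    return list(100.0 * ranks / n)


def read_msa(path_or_handle, fmt: str = "fasta"):
    """Read an aligned FASTA or Stockholm file."""
    return AlignIO.read(path_or_handle, fmt)


def read_msa_string(text: str, fmt: str = "fasta"):
    return AlignIO.read(StringIO(text), fmt)


def _row_records(msa):
    return [(rec.id, str(rec.seq).upper()) for rec in msa]


def _ungap(seq: str) -> str:
    return "".join(c for c in seq if c not in GAP_CHARS)


def map_profile(msa, query_row_id: str | None,
                structure: Structure, chain_id: str,
                inclusive: bool = True) -> ConservationProfile:
    """Column percentiles mapped onto structure residues.

    The chain's observed sequence must equal (or be a substring of) the
    ungapped sequence of the chosen alignment row; structure residues
    then correspond to columns through the ungapped index.
    """
    descs = residue_descriptors(structure, chain_id)
    chain_seq = "".join(d.aa for d in descs)
    rows = _row_records(msa)

    candidates = rows if query_row_id is None else \
        [r for r in rows if r[0] == query_row_id]
    row = None
    best_candidate = None
    for rid, seq in candidates:
        ungapped = _ungap(seq)
        pos = ungapped.find(chain_seq)
        if pos >= 0:
            row = (rid, seq, pos)
            break
        best_candidate = rid
    if row is None:
        raise MappingError(
            f"no alignment row contains the chain sequence "
            f"(best candidate: {best_candidate!r})")
    rid, row_seq, offset = row

    # ungapped index -> column index for the chosen row
    ungapped_to_col = [i for i, c in enumerate(row_seq) if c not in GAP_CHARS]

    ncols = len(rows[0][1])
    columns = [[seq[c] for _, seq in rows] for c in range(ncols)]

    # similarity fraction for every column covered by the chain
    covered_cols = []
    fractions = []
    for k in range(len(chain_seq)):
        col = ungapped_to_col[offset + k]
        ref_aa = row_seq[col]
        covered_cols.append(col)
        fractions.append(column_similarity(columns[col], ref_aa))

    percentiles = percentile_normalize(fractions, inclusive=inclusive)
    profile = ConservationProfile()
    for d, p in zip(descs, percentiles):
        profile.scores[d.residue_ref] = p
    # residues without Cα never enter descs; they are simply uncovered
    chain = structure.chain(chain_id)
    for res in chain.residues:
        ref = (chain_id, res.seqnum, res.icode)
        if ref not in profile.scores:
            profile.scores[ref] = None
            profile.flags.append(f"no-score:{ref}")
    return profile
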