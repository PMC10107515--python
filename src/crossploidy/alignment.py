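"""Marker-alignment summaries for the barrier-to-gene-flow argument.

Counts of variable columns, columns fixed-different between two groups, and
single-sequence (singleton) variants; plus pairwise Hamming distances for
AMOVA.  Gap and IUPAC-ambiguity characters are excluded from per-column
state counts: a column with a group rendered empty by gaps cannot be called
fixed-different.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment

_UNAMBIGUOUS = frozenset("ACGTacgt")


@dataclass
class AlignmentSummary:
    length: int
    n_variable: int
    n_fixed_diff: int
    n_singleton: int
    group_sizes: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "length": self.length, "variable": self.n_variable,
            "fixed_different": self.n_fixed_diff,
            "singleton": self.n_singleton,
            **{f"n_{g}": n for g, n in self.group_sizes.items()},
        }])


def _char_matrix(aln: MultipleSeqAlignment) -> np.ndarray:
    lengths = {len(rec.seq) for rec in aln}
    if len(lengths) > 1:
        for rec in aln:
            if len(rec.seq) != len(aln[0].seq):
                raise ValueError(
                    f"ragged alignment: sequence {rec.id!r} has length "
                    f"{len(rec.seq)} != {len(aln[0].seq)}")
    return np.array([list(str(rec.seq).upper()) for rec in aln])


def groups_from_names(aln: MultipleSeqAlignment) -> dict:
    """Group mapping from the id prefix before the first underscore."""
    return {rec.id: rec.id.split("_", 1)[0] for rec in aln}


def alignment_summary(aln: MultipleSeqAlignment, groups=None) -> AlignmentSummary:
    """Column classification of a grouped alignment.

    A column is *variable* if it shows >= 2 distinct unambiguous non-gap
    states; *fixed-different* if each group is monomorphic (ignoring
    gaps/ambiguities, and non-empty) for different states; *singleton* if it
    is two-state with exactly one sequence carrying the minority state and
    it is not already fixed-different (so that, with a degenerate group of
    size 1, diagnostic columns count once and fixed + singleton never
    exceeds the variable-column count).
    """
    if groups is None:
        groups = groups_from_names(aln)
    mat = _char_matrix(aln)
    ids = [rec.id for rec in aln]
    missing = [i for i in ids if i not in groups]
    if missing:
        raise ValueError(f"sequences without a group: {missing}")
    glabels = np.array([groups[i] for i in ids])
    uniq = list(dict.fromkeys(glabels))
    if len(uniq) != 2:
        raise ValueError("alignment_summary requires exactly two groups")
    gmask = [glabels == g for g in uniq]
    ok = np.isin(mat, list("ACGT"))

    n_var = n_fixed = n_single = 0
    for c in range(mat.shape[1]):
        col = mat[:, c]
        valid = ok[:, c]
        states, counts = np.unique(col[valid], return_counts=True)
        sets = [set(col[gm & valid]) for gm in gmask]
        fixed = all(len(s) == 1 for s in sets) and sets[0] != sets[1]
        if states.size >= 2:
            n_var += 1
            if fixed:
                n_fixed += 1
            elif states.size == 2 and counts.min() == 1 \
                    and (counts == 1).sum() == 1:
                n_single += 1
    return AlignmentSummary(
        length=mat.shape[1], n_variable=n_var, n_fixed_diff=n_fixed,
        n_singleton=n_single,
        group_sizes={g: int(m.sum()) for g, m in zip(uniq, gmask)},
    )


def pairwise_distance(aln: MultipleSeqAlignment) -> np.ndarray:
    """Hamming distance: proportion of differing comparable columns per pair.

    A column is comparable for a pair when both sequences carry unambiguous
    non-gap states.  Pairs with no comparable column get distance 0.
    """
    mat = _char_matrix(aln)
    ok = np.isin(mat, list("ACGT"))
    n = mat.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = ok[i] & ok[j]
            m = comp.sum()
            d = float((mat[i, comp] != mat[j, comp]).mean()) if m else 0.0
            D[i, j] = D[j, i] = d
    return D


def alignment_groups_vector(aln: MultipleSeqAlignment, groups=None) -> np.ndarray:
    if groups is None:
        groups = groups_from_names(aln)
    return np.array([groups[rec.id] for rec in aln])
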