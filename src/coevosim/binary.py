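"""Differential-binary re-encodings of a resorted alignment.

The differential binary translation marks, for each row after the first,
the positions where the symbol differs from the row directly above (1) or
matches it (0); the first row is all zeros.  The total number of 1s equals
the sum of Hamming distances between consecutive rows, so reordering the
sequences to place similar sequences next to each other minimizes it.
Minimizing the sum of changes lowers the mean entropy and mean mutual
information of the binary columns, which is what lets genuinely concerted
changes stand out.

Finding the row order with the globally minimal sum is a traveling-salesman
path problem; :func:`resort` uses greedy nearest-neighbor chaining, seeded
either at the most similar pair of sequences (default), at a fixed row, or
at every row in turn keeping the best chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from coevosim.alignment import Alignment, N_SYMBOLS


@dataclass
class BinaryAlignment:
    """0/1 change matrix of a resorted alignment.

    ``bits[r, c]`` is 1 iff the resorted symbol at (r, c) differs from the
    symbol at (r-1, c); row 0 is all zeros.  ``order[r]`` is the original row
    index placed at rank ``r``.
    """

    bits: np.ndarray
    order: np.ndarray

    @property
    def total_sum(self) -> int:
        """Number of 1s = sum of Hamming distances between consecutive rows."""
        return int(self.bits.sum())


@dataclass
class GlobalBinaryAlignment:
    """Change matrix expanded over the 21-symbol alphabet.

    Each source column ``c`` maps to the 21-column block
    ``[c*21 : c*21 + 21)``; at a changed position the block carries a single
    1 at the alphabet index of the new symbol.
    """

    bits: np.ndarray
    order: np.ndarray

    @property
    def n_pos(self) -> int:
        return self.bits.shape[1] // N_SYMBOLS


@dataclass
class NormalBinaryAlignment:
    """Resorted alignment masked by the change matrix.

    ``codes[r, c]`` is 0 where nothing changed and ``symbol_code + 1``
    (values 1..21) where the symbol changed — a 22-symbol alphabet in which
    'no change' is one symbol and each changed residue keeps its identity.
    """

    codes: np.ndarray
    order: np.ndarray

    @property
    def nonzero_count(self) -> int:
        return int(np.count_nonzero(self.codes))


def hamming_matrix(rows: np.ndarray) -> np.ndarray:
    """Pairwise Hamming distance between alignment rows."""
    return (rows[:, None, :] != rows[None, :, :]).sum(axis=2)


def chain_sum(rows: np.ndarray, order: np.ndarray) -> int:
    """Sum of Hamming distances along consecutive rows in ``order``."""
    ordered = rows[order]
    return int((ordered[1:] != ordered[:-1]).sum())


def _greedy_chain(dist: np.ndarray, start: list[int]) -> np.ndarray:
    n = dist.shape[0]
    placed = list(start)
    remaining = np.array([i for i in range(n) if i not in set(start)], dtype=np.intp)
    while remaining.size:
        # argmin returns the first minimum; remaining is sorted, so ties
        # resolve to the lowest original index.
        k = int(np.argmin(dist[placed[-1], remaining]))
        placed.append(int(remaining[k]))
        remaining = np.delete(remaining, k)
    return np.asarray(placed, dtype=np.intp)


def resort(
    aln: Alignment,
    seed_mode: str = "most_similar_pair",
    seed_index: int = 0,
) -> np.ndarray:
    """Row permutation that chains each sequence to its nearest neighbor.

    Parameters
    ----------
    seed_mode : {"most_similar_pair", "fixed_index", "scan_all"}
        ``most_similar_pair`` starts the chain at the two closest sequences
        (the default; fastest ordering that also performs best downstream).
        ``fixed_index`` starts at row ``seed_index``.  ``scan_all`` tries
        every row as chain seed and keeps the order with the smallest total
        change count, ties going to the lowest seed index.

    Returns
    -------
    ndarray of intp
        ``order[r]`` = original index of the sequence at rank ``r``.
    """
    if aln.n_seq < 2:
        raise ValueError("resorting requires at least 2 sequences")
    dist = hamming_matrix(aln.rows)

    if seed_mode == "most_similar_pair":
        masked = dist.astype(float).copy()
        np.fill_diagonal(masked, np.inf)
        # flat argmin scans row-major: ties resolve to lowest (i, j).
        i, j = np.unravel_index(int(np.argmin(masked)), masked.shape)
        if i > j:
            i, j = j, i
        return _greedy_chain(dist, [int(i), int(j)])
    if seed_mode == "fixed_index":
        if not 0 <= seed_index < aln.n_seq:
            raise ValueError(f"seed_index {seed_index} out of range")
        return _greedy_chain(dist, [seed_index])
    if seed_mode == "scan_all":
        best: np.ndarray | None = None
        best_sum = np.inf
        for s in range(aln.n_seq):
            order = _greedy_chain(dist, [s])
            total = int(dist[order[:-1], order[1:]].sum())
            if total < best_sum:
                best, best_sum = order, total
        assert best is not None
        return best
    raise ValueError(f"unknown seed_mode {seed_mode!r}")


def _resolve_order(aln: Alignment, order: np.ndarray | None) -> np.ndarray:
    if order is None:
        return np.arange(aln.n_seq, dtype=np.intp)
    order = np.asarray(order, dtype=np.intp)
    if sorted(order.tolist()) != list(range(aln.n_seq)):
        raise ValueError("order is not a permutation of the row indices")
    return order


def _change_mask(aln: Alignment, order: np.ndarray) -> np.ndarray:
    ordered = aln.rows[order]
    changed = np.zeros(ordered.shape, dtype=bool)
    changed[1:] = ordered[1:] != ordered[:-1]
    return changed


def to_differential_binary(
    aln: Alignment, order: np.ndarray | None = None
) -> BinaryAlignment:
    """Differential binary translation of ``aln`` under a row order.

    ``order=None`` keeps the input order (identity permutation).  A gap that
    persists across consecutive rows counts as 'no change'; gap-to-residue or
    residue-to-gap transitions count as changes — the gap is an ordinary 21st
    symbol.
    """
    order = _resolve_order(aln, order)
    return BinaryAlignment(
        bits=_change_mask(aln, order).astype(np.uint8), order=order
    )


def to_global_differential_binary(
    aln: Alignment,
    order: np.ndarray | None = None,
    encode: str = "new_symbol",
) -> GlobalBinaryAlignment:
    """Expand the change matrix over the 21-symbol alphabet.

    With the default ``encode="new_symbol"``, row r >= 1 carries, in the
    21-column block of each changed position, a single 1 at the alphabet
    index of the symbol the position changed *to*; unchanged blocks and the
    whole first row stay zero.  ``encode="one_hot"`` instead one-hot encodes
    every residue of the resorted alignment regardless of change (for
    comparison only; it is no longer differential).
    """
    order = _resolve_order(aln, order)
    ordered = aln.rows[order]
    n_seq, n_pos = ordered.shape
    bits = np.zeros((n_seq, n_pos * N_SYMBOLS), dtype=np.uint8)
    if encode == "new_symbol":
        changed = _change_mask(aln, order)
        r_idx, c_idx = np.nonzero(changed)
        bits[r_idx, c_idx * N_SYMBOLS + ordered[r_idx, c_idx]] = 1
    elif encode == "one_hot":
        r_idx, c_idx = np.indices(ordered.shape).reshape(2, -1)
        bits[r_idx, c_idx * N_SYMBOLS + ordered.reshape(-1)] = 1
    else:
        raise ValueError(f"unknown encode mode {encode!r}")
    return GlobalBinaryAlignment(bits=bits, order=order)


def to_normal_binary(
    aln: Alignment, order: np.ndarray | None = None
) -> NormalBinaryAlignment:
    """Mask the resorted alignment with its change matrix.

    Unchanged positions become the dedicated 'no change' symbol 0; changed
    positions keep their residue identity (codes 1..21), so repeated changes
    to the same residue pair at two positions become visible to mutual
    information.
    """
    order = _resolve_order(aln, order)
    ordered = aln.rows[order].astype(np.uint8)
    changed = _change_mask(aln, order)
    codes = np.where(changed, ordered + 1, 0).astype(np.uint8)
    return NormalBinaryAlignment(codes=codes, order=order)
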