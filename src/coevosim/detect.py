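"""Coevolution score matrices.

Building blocks: plug-in mutual information over any discrete alphabet,
average product correction (APC), the ZPX/ZPX2 cross-product z-score,
column covariance of binary encodings with Frobenius-norm block collapse,
and least-squares merging of an MI matrix with a covariance matrix.

Composite detectors:

* :func:`db_zpx2`  — MI + covariance of the differential binary translation,
  merged, then ZPX2.
* :func:`dgb_zpx2` — as above, but the covariance comes from the 21x-expanded
  global differential binary matrix, collapsed block-wise by Frobenius norm.
* :func:`nb_zpx2`  — MI of the normal/binary masked alignment (22 symbols),
  then ZPX2; no covariance merge.
* :func:`mi_method`, :func:`zpx2_method`, :func:`omes` — local baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from coevosim.alignment import Alignment, GAP_CODE, N_SYMBOLS
from coevosim.binary import (
    BinaryAlignment,
    GlobalBinaryAlignment,
    resort,
    to_differential_binary,
    to_global_differential_binary,
    to_normal_binary,
)


class InsufficientPositionsError(ValueError):
    """Raised when a matrix operation needs more positions than provided."""


@dataclass
class CoevolutionMatrix:
    """Symmetric position-by-position score matrix with a method label.

    The diagonal is not a meaningful score; :meth:`with_min_diagonal` sets it
    to the matrix minimum so it never enters a descending ranking.
    """

    scores: np.ndarray
    method: str

    @property
    def n_pos(self) -> int:
        return self.scores.shape[0]

    def with_min_diagonal(self) -> "CoevolutionMatrix":
        out = self.scores.copy()
        iu = np.triu_indices(out.shape[0], 1)
        if iu[0].size:
            np.fill_diagonal(out, out[iu].min())
        return CoevolutionMatrix(out, self.method)


def _entropy_bits(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log2(p)))


def mi_matrix(
    msa: np.ndarray,
    exclude_gaps: bool = False,
    gap_code: int = GAP_CODE,
) -> CoevolutionMatrix:
    """Mutual information MI(i,j) = H(i) + H(j) - H(i,j), in bits.

    Empirical plug-in frequencies over the rows of ``msa`` (any integer
    alphabet).  With ``exclude_gaps``, rows carrying ``gap_code`` at either
    column are dropped pairwise before the frequencies are taken.
    """
    msa = np.asarray(msa)
    if msa.shape[0] < 2:
        raise ValueError("mutual information requires at least 2 rows")
    n_pos = msa.shape[1]
    k = int(msa.max()) + 1 if msa.size else 1
    cols = msa.astype(np.int64)
    has_gaps = exclude_gaps and bool(np.any(cols == gap_code))

    mi = np.zeros((n_pos, n_pos))
    if not has_gaps:
        h = np.array(
            [_entropy_bits(np.bincount(cols[:, c], minlength=k)) for c in range(n_pos)]
        )
        joint_base = cols * k
        for i in range(n_pos):
            ji = joint_base[:, i]
            for j in range(i + 1, n_pos):
                hij = _entropy_bits(np.bincount(ji + cols[:, j], minlength=k * k))
                mi[i, j] = mi[j, i] = h[i] + h[j] - hij
    else:
        gap_free = cols != gap_code
        for i in range(n_pos):
            for j in range(i + 1, n_pos):
                valid = gap_free[:, i] & gap_free[:, j]
                if valid.sum() < 2:
                    continue
                xi, xj = cols[valid, i], cols[valid, j]
                hi = _entropy_bits(np.bincount(xi, minlength=k))
                hj = _entropy_bits(np.bincount(xj, minlength=k))
                hij = _entropy_bits(np.bincount(xi * k + xj, minlength=k * k))
                mi[i, j] = mi[j, i] = hi + hj - hij
    return CoevolutionMatrix(mi, "MI")


def apc(m: CoevolutionMatrix) -> CoevolutionMatrix:
    """Average product correction: m(i,j) - mean_i * mean_j / mean_all.

    Means are taken over off-diagonal entries.  A zero grand mean would make
    the correction undefined; the input is then returned unchanged with a
    warning.
    """
    s = m.scores
    n = s.shape[0]
    if n < 2:
        return CoevolutionMatrix(s.copy(), m.method + "+APC")
    row_mean = (s.sum(axis=1) - np.diag(s)) / (n - 1)
    off = ~np.eye(n, dtype=bool)
    grand = s[off].mean()
    if grand == 0:
        warnings.warn("APC undefined for zero-mean matrix; returning input")
        return CoevolutionMatrix(s.copy(), m.method + "+APC")
    out = s - np.outer(row_mean, row_mean) / grand
    np.fill_diagonal(out, np.diag(s))
    return CoevolutionMatrix(out, m.method + "+APC")


def zpx2(
    m: CoevolutionMatrix, signed: bool = False, apply_apc: bool = False
) -> CoevolutionMatrix:
    """Cross-product positional z-score, squared.

    Z(i,j) = (m(i,j) - mu_i) / sigma_i with mu_i, sigma_i over the
    off-diagonal entries of row i (population sigma); ZPX(i,j) =
    Z(i,j) * Z(j,i); ZPX2 = ZPX**2.  Squaring discards the sign, so a pair
    with two large *negative* z-scores ranks as high as one with two large
    positive ones; ``signed=True`` keeps the sign (sign(ZPX) * ZPX**2).
    Rows with sigma = 0 get Z = 0.
    """
    if m.n_pos < 3:
        raise InsufficientPositionsError("ZPX2 requires at least 3 positions")
    s = apc(m).scores if apply_apc else m.scores
    n = s.shape[0]
    off = ~np.eye(n, dtype=bool)
    rows_off = np.where(off, s, np.nan)
    mu = np.nanmean(rows_off, axis=1)
    sigma = np.nanstd(rows_off, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (s - mu[:, None]) / sigma[:, None]
    z[sigma == 0, :] = 0.0
    z[~np.isfinite(z)] = 0.0
    np.fill_diagonal(z, 0.0)
    zpx = z * z.T
    out = np.sign(zpx) * zpx**2 if signed else zpx**2
    return CoevolutionMatrix(out, m.method + "→ZPX2")


def binary_covariance(b: BinaryAlignment) -> CoevolutionMatrix:
    """Sample covariance (denominator n-1) between the 0/1 columns."""
    if b.bits.shape[0] < 2:
        raise ValueError("covariance requires at least 2 rows")
    cov = np.cov(b.bits.astype(float), rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    return CoevolutionMatrix(cov, "COV")


def collapse_global_cov(gb: GlobalBinaryAlignment) -> CoevolutionMatrix:
    """Frobenius-norm collapse of the expanded covariance matrix.

    The covariance of the (n_seq x 21*n_pos) global matrix holds the
    covariance between source columns i and j in the 21x21 submatrix at
    block (i, j); its Frobenius norm becomes entry (i, j) of an
    n_pos x n_pos collapsed matrix.
    """
    n_cols = gb.bits.shape[1]
    if n_cols % N_SYMBOLS:
        raise ValueError(f"column count {n_cols} not divisible by {N_SYMBOLS}")
    n_pos = n_cols // N_SYMBOLS
    cov = np.cov(gb.bits.astype(float), rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    blocks = cov.reshape(n_pos, N_SYMBOLS, n_pos, N_SYMBOLS)
    collapsed = np.sqrt((blocks**2).sum(axis=(1, 3)))
    return CoevolutionMatrix(collapsed, "gCOV")


def merge_mi_cov(
    mi: CoevolutionMatrix, cov: CoevolutionMatrix
) -> CoevolutionMatrix:
    """Scale the covariance onto the MI by least squares, then average.

    Ordinary least squares fits mi ~ a*cov + b over the off-diagonal upper
    triangle; the merged matrix is the elementwise mean of mi and the
    rescaled covariance.  A constant covariance makes the regression
    degenerate; mi is then returned with a warning.
    """
    if mi.scores.shape != cov.scores.shape:
        raise ValueError("MI and covariance matrices must have the same shape")
    iu = np.triu_indices(mi.n_pos, 1)
    x, y = cov.scores[iu], mi.scores[iu]
    if x.size < 2 or np.ptp(x) == 0:
        warnings.warn("degenerate regression (constant covariance); merged = MI")
        return CoevolutionMatrix(mi.scores.copy(), mi.method)
    a, b = np.polyfit(x, y, 1)
    merged = 0.5 * (mi.scores + (a * cov.scores + b))
    return CoevolutionMatrix(merged, f"{mi.method}+{cov.method}")


def _finish(scores: CoevolutionMatrix, label: str) -> CoevolutionMatrix:
    out = CoevolutionMatrix(scores.scores, label)
    return out.with_min_diagonal()


def db_zpx2(
    aln: Alignment,
    seed_mode: str = "most_similar_pair",
    merge_covariance: bool = True,
    apply_apc: bool = False,
    signed: bool = False,
) -> CoevolutionMatrix:
    """Differential binary ZPX2.

    Resort, translate to differential binary, take MI between binary
    columns; merge with the binary covariance matrix (the refined variant,
    default) and apply ZPX2.
    """
    if aln.n_seq < 3:
        raise ValueError("db_zpx2 requires at least 3 sequences")
    order = resort(aln, seed_mode)
    b = to_differential_binary(aln, order)
    mi = mi_matrix(b.bits)
    merged = merge_mi_cov(mi, binary_covariance(b)) if merge_covariance else mi
    return _finish(zpx2(merged, signed=signed, apply_apc=apply_apc), "dbZPX2")


def dgb_zpx2(
    aln: Alignment,
    seed_mode: str = "most_similar_pair",
    apply_apc: bool = False,
    signed: bool = False,
) -> CoevolutionMatrix:
    """Differential global binary ZPX2.

    As :func:`db_zpx2`, but the covariance merged into the MI comes from the
    21x-expanded global differential binary matrix collapsed block-wise by
    Frobenius norm, reintroducing which residue each change produced.
    """
    if aln.n_seq < 3:
        raise ValueError("dgb_zpx2 requires at least 3 sequences")
    order = resort(aln, seed_mode)
    b = to_differential_binary(aln, order)
    gb = to_global_differential_binary(aln, order)
    merged = merge_mi_cov(mi_matrix(b.bits), collapse_global_cov(gb))
    return _finish(zpx2(merged, signed=signed, apply_apc=apply_apc), "dgbZPX2")


def nb_zpx2(
    aln: Alignment,
    seed_mode: str = "most_similar_pair",
    apply_apc: bool = False,
    signed: bool = False,
) -> CoevolutionMatrix:
    """Normal/binary ZPX2: MI of the masked 22-symbol alignment, then ZPX2."""
    if aln.n_seq < 3:
        raise ValueError("nb_zpx2 requires at least 3 sequences")
    order = resort(aln, seed_mode)
    nb = to_normal_binary(aln, order)
    mi = mi_matrix(nb.codes)
    return _finish(zpx2(mi, signed=signed, apply_apc=apply_apc), "nbZPX2")


def mi_method(aln: Alignment) -> CoevolutionMatrix:
    """Plain amino-acid MI with pairwise gap exclusion (baseline)."""
    mi = mi_matrix(aln.rows, exclude_gaps=True)
    return _finish(mi, "MI")


def zpx2_method(aln: Alignment, signed: bool = False) -> CoevolutionMatrix:
    """ZPX2 of the plain amino-acid MI matrix (baseline)."""
    mi = mi_matrix(aln.rows, exclude_gaps=True)
    return _finish(zpx2(mi, signed=signed), "ZPX2")


def omes(aln: Alignment) -> CoevolutionMatrix:
    """Observed-minus-expected-squared covariance.

    For each column pair, rows with a gap at either column are dropped; over
    the N_valid remaining rows, sum over co-occurring symbol pairs of
    (N_obs - N_exp)^2 / N_valid with N_exp from the marginal counts.
    """
    if aln.n_seq < 2:
        raise ValueError("OMES requires at least 2 rows")
    cols = aln.rows.astype(np.int64)
    n_pos = aln.n_pos
    gap_free = cols != GAP_CODE
    k = N_SYMBOLS
    out = np.zeros((n_pos, n_pos))
    for i in range(n_pos):
        for j in range(i + 1, n_pos):
            valid = gap_free[:, i] & gap_free[:, j]
            n_valid = int(valid.sum())
            if n_valid == 0:
                warnings.warn(f"no gap-free rows for pair ({i + 1},{j + 1}); score 0")
                continue
            xi, xj = cols[valid, i], cols[valid, j]
            n_obs = np.bincount(xi * k + xj, minlength=k * k).reshape(k, k)
            mi_counts = np.bincount(xi, minlength=k)
            mj_counts = np.bincount(xj, minlength=k)
            n_exp = np.outer(mi_counts, mj_counts) / n_valid
            observed = n_obs > 0
            out[i, j] = out[j, i] = float(
                ((n_obs[observed] - n_exp[observed]) ** 2).sum() / n_valid
            )
    return _finish(CoevolutionMatrix(out, "OMES"), "OMES")


#: CLI-facing registry of detectors operating on a plain alignment.
METHODS = {
    "MI": mi_method,
    "ZPX2": zpx2_method,
    "OMES": omes,
    "dbZPX2": db_zpx2,
    "dgbZPX2": dgb_zpx2,
    "nbZPX2": nb_zpx2,
}
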