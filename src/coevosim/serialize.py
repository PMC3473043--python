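"""Plain-text serialization of matrices, permutations and curves.

Symmetric position-by-position matrices (scores, truth counts, contact maps)
travel as 3-column TSV — ``i``, ``j``, ``value`` with 1-based indices, upper
triangle only.  Curves are 2-column TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_matrix_tsv(matrix: np.ndarray, path: str | Path) -> None:
    """Write the upper triangle of a symmetric matrix as i/j/value TSV."""
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    with open(path, "w") as fh:
        fh.write("i\tj\tvalue\n")
        for i in range(n):
            for j in range(i + 1, n):
                fh.write(f"{i + 1}\t{j + 1}\t{matrix[i, j]:.10g}\n")


def read_matrix_tsv(path: str | Path, n_pos: int | None = None) -> np.ndarray:
    """Read an i/j/value TSV back into a symmetric matrix (zero diagonal)."""
    ii: list[int] = []
    jj: list[int] = []
    vv: list[float] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts[0] in ("", "i"):
                continue
            ii.append(int(parts[0]))
            jj.append(int(parts[1]))
            vv.append(float(parts[2]))
    if not ii:
        raise ValueError(f"no matrix entries in {path}")
    n = n_pos if n_pos is not None else max(max(ii), max(jj))
    out = np.zeros((n, n))
    a = np.asarray(ii) - 1
    b = np.asarray(jj) - 1
    out[a, b] = vv
    out[b, a] = vv
    return out


def write_curve_tsv(
    x: np.ndarray, y: np.ndarray, path: str | Path, header: tuple[str, str] = ("x", "y")
) -> None:
    with open(path, "w") as fh:
        fh.write(f"{header[0]}\t{header[1]}\n")
        for xi, yi in zip(x, y):
            fh.write(f"{xi:.10g}\t{yi:.10g}\n")


def read_curve_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for k, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if k == 0 and not _is_number(parts[0]):
                continue
            if len(parts) >= 2:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
    return np.asarray(xs), np.asarray(ys)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_binary_matrix(bits: np.ndarray, path: str | Path) -> None:
    """Write a 0/1 matrix as one digit-string row per line (for inspection)."""
    with open(path, "w") as fh:
        for row in np.asarray(bits):
            fh.write("".join(str(int(v)) for v in row) + "\n")


def write_permutation(order: np.ndarray, path: str | Path) -> None:
    """Write a row permutation as (new_rank, original_index) TSV, 1-based."""
    with open(path, "w") as fh:
        fh.write("new_rank\toriginal_index\n")
        for rank, orig in enumerate(np.asarray(order)):
            fh.write(f"{rank + 1}\t{int(orig) + 1}\n")
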