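"""Independent brute-force reference implementations used only by the tests.

Everything here is written with plain loops, dicts and math.log2 — no shared
code with the package — so the tests compare two genuinely separate routes
to the same quantity.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def entropy_oracle(values) -> float:
    counts = Counter(values)
    n = sum(counts.values())
    if n == 0:
        return 0.0
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def mi_oracle(msa: np.ndarray) -> np.ndarray:
    """MI(i,j) = H(i)+H(j)-H(i,j) from exhaustive frequency tables."""
    n_seq, n_pos = msa.shape
    out = np.zeros((n_pos, n_pos))
    for i in range(n_pos):
        for j in range(i + 1, n_pos):
            hi = entropy_oracle(msa[:, i].tolist())
            hj = entropy_oracle(msa[:, j].tolist())
            hij = entropy_oracle(list(zip(msa[:, i].tolist(), msa[:, j].tolist())))
            out[i, j] = out[j, i] = hi + hj - hij
    return out


def cov_oracle(bits: np.ndarray) -> np.ndarray:
    """Textbook sample covariance with denominator n-1, via explicit loops."""
    x = bits.astype(float)
    n, p = x.shape
    means = [sum(x[:, c]) / n for c in range(p)]
    out = np.zeros((p, p))
    for a in range(p):
        for b in range(p):
            s = sum((x[r, a] - means[a]) * (x[r, b] - means[b]) for r in range(n))
            out[a, b] = s / (n - 1)
    return out


def apc_oracle(m: np.ndarray) -> np.ndarray:
    """Average product correction with off-diagonal means, via loops."""
    n = m.shape[0]
    row_means = []
    for i in range(n):
        vals = [m[i, j] for j in range(n) if j != i]
        row_means.append(sum(vals) / len(vals))
    all_vals = [m[i, j] for i in range(n) for j in range(n) if i != j]
    grand = sum(all_vals) / len(all_vals)
    out = m.copy().astype(float)
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = m[i, j] - row_means[i] * row_means[j] / grand
    return out


def zpx2_oracle(m: np.ndarray) -> np.ndarray:
    """Row z-score cross product, squared; population sigma over off-diagonal."""
    n = m.shape[0]
    mu, sigma = [], []
    for i in range(n):
        vals = [m[i, j] for j in range(n) if j != i]
        mean = sum(vals) / len(vals)
        var = sum((v - mean) ** 2 for v in vals) / len(vals)
        mu.append(mean)
        sigma.append(math.sqrt(var))
    z = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and sigma[i] > 0:
                z[i, j] = (m[i, j] - mu[i]) / sigma[i]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = (z[i, j] * z[j, i]) ** 2
    return out


def omes_oracle(msa: np.ndarray, gap_code: int) -> np.ndarray:
    """Observed-minus-expected-squared over observed cells, via dicts."""
    n_seq, n_pos = msa.shape
    out = np.zeros((n_pos, n_pos))
    for i in range(n_pos):
        for j in range(i + 1, n_pos):
            rows = [
                (int(msa[r, i]), int(msa[r, j]))
                for r in range(n_seq)
                if msa[r, i] != gap_code and msa[r, j] != gap_code
            ]
            n_valid = len(rows)
            if n_valid == 0:
                continue
            obs = Counter(rows)
            mi_counts = Counter(a for a, _ in rows)
            mj_counts = Counter(b for _, b in rows)
            score = 0.0
            for (a, b), n_obs in obs.items():
                n_exp = mi_counts[a] * mj_counts[b] / n_valid
                score += (n_obs - n_exp) ** 2 / n_valid
            out[i, j] = out[j, i] = score
    return out


def lstsq_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple least squares slope and intercept."""
    n = len(x)
    xbar, ybar = sum(x) / n, sum(y) / n
    sxx = sum((v - xbar) ** 2 for v in x)
    sxy = sum((u - xbar) * (v - ybar) for u, v in zip(x, y))
    a = sxy / sxx
    return a, ybar - a * xbar
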