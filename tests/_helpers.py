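"""Shared helpers: random Ct matrices and an independent NormFinder oracle."""

import numpy as np
import pandas as pd

from rgstab import CtMatrix


def random_matrix(seed: int, n_genes: int = 12, n_samples: int = 6,
                  conditions: tuple[str, ...] = ("CTRL", "SF")) -> CtMatrix:
    """Random complete Ct matrix (no censoring), balanced conditions."""
    rng = np.random.default_rng(seed)
    vals = pd.DataFrame(
        rng.uniform(12, 26, size=(n_genes, 1))
        + rng.normal(0, 1.0, size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    half = n_samples // 2
    condition = {
        f"s{j}": (conditions[0] if j < half else conditions[-1]) for j in range(n_samples)
    }
    return CtMatrix(values=vals, condition=condition)


def normfinder_sigma2_oracle(arr: np.ndarray) -> list[float]:
    """Independent brute force of the variance estimating equations.

    Residuals via explicit loops; the bias relation
    s2_i = sigma2_i (1 - 2/k) + sum(sigma2)/k^2 solved as a k x k linear
    system instead of the closed-form two-step used by the implementation.
    """
    k, n = arr.shape
    grand = sum(sum(row) for row in arr) / (k * n)
    row_m = [sum(row) / n for row in arr]
    col_m = [sum(arr[i][j] for i in range(k)) / k for j in range(n)]
    s2 = []
    for i in range(k):
        resid = [arr[i][j] - row_m[i] - col_m[j] + grand for j in range(n)]
        s2.append(sum(r * r for r in resid) / (n - 1))
    a = np.full((k, k), 1.0 / k**2) + np.eye(k) * (1 - 2.0 / k)
    sigma2 = np.linalg.solve(a, np.array(s2))
    return [max(0.0, v) for v in sigma2]
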