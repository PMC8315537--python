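"""Mantel permutation test between two labeled distance matrices.

The statistic is the Pearson correlation of the n(n-1)/2 lower-triangle
entries; the null distribution is generated by simultaneous row+column
permutation of the second matrix. The p-value uses the +1 permutation
correction, so it can never be exactly zero. Default alternative is
the upper tail (positive association); a two-sided variant is
available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gower import DistanceMatrix


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int
    alternative: str
    n: int


def mantel_test(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test of matrix association.

    Label sets must match (the second matrix is reordered to the
    first); a matrix with constant off-diagonal entries has no defined
    correlation and is rejected.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if set(D1.labels) != set(D2.labels):
        raise ValueError("distance matrices have different label sets")
    n = D1.n
    if n < 3:
        raise ValueError("need at least 3 samples")
    D2 = D2.subset(D1.labels)
    iu = np.triu_indices(n, k=1)
    v1 = D1.d[iu]
    m2 = D2.d
    v2 = m2[iu]
    if v1.std() == 0.0 or v2.std() == 0.0:
        raise ValueError("constant distance matrix: correlation undefined")

    v1c = (v1 - v1.mean()) / v1.std()
    r_obs = _corr(v1c, v2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = m2[np.ix_(perm, perm)][iu]
        r_p = _corr(v1c, vp)
        if alternative == "greater":
            count += r_p >= r_obs
        else:
            count += abs(r_p) >= abs(r_obs)
    p = (1.0 + count) / (n_perm + 1.0)
    return MantelResult(r=float(r_obs), p=float(p), n_perm=n_perm, seed=seed, alternative=alternative, n=n)


def _corr(v1c: np.ndarray, v2: np.ndarray) -> float:
    s = v2.std()
    if s == 0.0:
        return 0.0
    return float(np.mean(v1c * (v2 - v2.mean()) / s))
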