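"""Classical principal coordinates analysis (metric MDS) of a distance matrix.

Gower double-centering of -0.5 * d^2 followed by eigendecomposition.
Coordinates are eigenvectors scaled by the square root of their
(positive) eigenvalues; percent variance per axis is computed over the
positive eigenvalues only. Negative eigenvalues — which arise when the
dissimilarity is not Euclidean-embeddable — are reported (count and
total magnitude) but excluded, and no Cailliez/Lingoes correction is
applied by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gower import DistanceMatrix

_EIG_TOL = 1e-9


@dataclass
class Ordination:
    labels: list[str]
    coordinates: np.ndarray  # samples x retained axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    percent_variance: np.ndarray  # per retained axis, sums to 100
    n_negative: int
    negative_magnitude: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            index=self.labels,
            columns=[f"axis{i + 1}" for i in range(self.coordinates.shape[1])],
        )
        df.index.name = "sample"
        return df


def pcoa(D: DistanceMatrix, n_axes: int | None = None) -> Ordination:
    """Principal coordinates of a labeled distance matrix.

    ``n_axes`` limits the number of returned coordinate axes; percent
    variance is always computed over all positive eigenvalues.
    """
    n = D.n
    d2 = D.d**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = _EIG_TOL * max(1.0, abs(eigval).max())
    pos = eigval > tol
    neg = eigval < -tol
    if neg.any():
        warnings.warn(
            f"{int(neg.sum())} negative eigenvalues (total magnitude "
            f"{-eigval[neg].sum():.3g}) excluded from the variance denominator",
            stacklevel=2,
        )
    lam = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(lam)
    pct = 100.0 * lam / lam.sum() if lam.size else lam
    if n_axes is not None:
        coords = coords[:, :n_axes]
    return Ordination(
        labels=list(D.labels),
        coordinates=coords,
        eigenvalues=lam,
        percent_variance=pct,
        n_negative=int(neg.sum()),
        negative_magnitude=float(-eigval[neg].sum()),
    )
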