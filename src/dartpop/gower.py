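"""Gower dissimilarity on marker matrices and square distance-matrix I/O.

Gower's coefficient averages per-variable contributions over the loci
where both samples are scored (pairwise deletion, no imputation):

* SNP dosages are treated as interval-scaled with range 2, contributing
  ``|x_i - x_j| / 2`` per comparable locus (a categorical treatment is
  available via ``snp_mode="categorical"``);
* dominant presence/absence scores are symmetric binary, contributing
  0 for a match and 1 for a mismatch — simple matching distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import MISSING, MarkerMatrix


@dataclass
class DistanceMatrix:
    """Labeled square symmetric dissimilarity matrix with zero diagonal."""

    labels: list[str]
    d: np.ndarray
    platform: str = ""

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance grid does not match labels")
        if not np.all(np.isfinite(self.d)) or (self.d < 0).any():
            raise ValueError("distances must be finite and non-negative")
        if not np.allclose(self.d, self.d.T, atol=1e-8):
            raise ValueError("distance matrix not symmetric")
        np.fill_diagonal(self.d, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])

    def subset(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(s) for s in labels]
        return DistanceMatrix(list(labels), self.d[np.ix_(idx, idx)], self.platform)

    def pairs(self):
        """Yield (label_i, label_j, d_ij) over unordered pairs, i < j."""
        for i in range(self.n):
            for j in range(i + 1, self.n):
                yield self.labels[i], self.labels[j], float(self.d[i, j])


def gower_matrix(m: MarkerMatrix, snp_mode: str = "interval") -> DistanceMatrix:
    """Gower dissimilarity between all sample pairs of a marker matrix.

    Raises if any sample pair has zero comparable (both-scored) loci.
    """
    if m.n_samples < 2 or m.n_markers < 1:
        raise ValueError("need >=2 samples and >=1 marker")
    X = m.scores.T.astype(float)  # samples x markers
    valid = m.scores.T != MISSING
    Xz = np.where(valid, X, 0.0)
    V = valid.astype(float)
    n = m.n_samples
    # counts of comparable loci per pair
    C = V @ V.T
    if m.platform == "snp" and snp_mode == "interval":
        # sum over comparable loci of |x_i - x_j| / 2, via chunked pairs
        S = np.zeros((n, n))
        for i in range(n):
            diff = np.abs(Xz[i] - Xz) / 2.0
            diff[~(valid[i] & valid)] = 0.0
            S[i] = diff.sum(axis=1)
    elif m.platform == "silico" or snp_mode == "categorical":
        # mismatch count on comparable loci
        S = np.zeros((n, n))
        for i in range(n):
            neq = (Xz[i] != Xz) & valid[i] & valid
            S[i] = neq.sum(axis=1)
    else:
        raise ValueError(f"unknown snp_mode {snp_mode!r}")
    if (C[~np.eye(n, dtype=bool)] == 0).any():
        i, j = np.argwhere((C == 0) & ~np.eye(n, dtype=bool))[0]
        raise ValueError(
            f"samples {m.sample_ids[i]!r} and {m.sample_ids[j]!r} share no comparable marker"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        D = S / C
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # exact symmetry against float noise
    return DistanceMatrix(list(m.sample_ids), D, m.platform)


def write_distance_csv(D: DistanceMatrix, path, precision: int = 6) -> None:
    """Write a square distance CSV (header row + label column)."""
    df = pd.DataFrame(np.round(D.d, precision), index=D.labels, columns=D.labels)
    df.to_csv(path, float_format=f"%.{precision}f")


def read_distance_csv(path, platform: str = "") -> DistanceMatrix:
    """Read a square labeled distance CSV; symmetrized after validation.

    Rejects non-square grids, row/column label mismatches, negative
    entries and asymmetries beyond 1e-6.
    """
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: distance matrix is not square {df.shape}")
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if rows != cols:
        raise ValueError(f"{path}: row labels do not match column labels")
    d = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(d)) or (d < 0).any():
        raise ValueError(f"{path}: non-finite or negative distance entries")
    if np.abs(d - d.T).max() > 1e-6:
        raise ValueError(f"{path}: asymmetry exceeds 1e-6")
    return DistanceMatrix(rows, (d + d.T) / 2.0, platform)


def distance_summary(D: DistanceMatrix, groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Min / max / mean of off-diagonal distances, overall and per class.

    Within-class statistics use unordered pairs with both members in
    the class; singleton classes are reported as NaN.
    """
    rows = []
    iu = np.triu_indices(D.n, k=1)
    vals = D.d[iu]
    rows.append({"group": "overall", "n_pairs": len(vals), "min": vals.min(), "max": vals.max(), "mean": vals.mean()})
    if groups is not None:
        missing = [s for s in D.labels if s not in groups]
        if missing:
            raise ValueError(f"groups do not cover labels: {missing[:3]}")
        for cls in sorted(set(groups.values())):
            idx = [i for i, s in enumerate(D.labels) if groups[s] == cls]
            if len(idx) < 2:
                rows.append({"group": cls, "n_pairs": 0, "min": np.nan, "max": np.nan, "mean": np.nan})
                continue
            sub = D.d[np.ix_(idx, idx)]
            v = sub[np.triu_indices(len(idx), k=1)]
            rows.append({"group": cls, "n_pairs": len(v), "min": v.min(), "max": v.max(), "mean": v.mean()})
    return pd.DataFrame(rows)
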