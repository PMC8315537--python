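"""Marker matrices and per-marker quality control.

Two DArT platforms are supported:

* ``silico`` — dominant SilicoDArT presence/absence markers, scored
  ``1`` (present), ``0`` (absent), ``-`` (missing);
* ``snp`` — codominant biallelic SNPs, scored as alternate-allele
  dosage ``0``/``1``/``2`` with ``1`` the heterozygote. Files using the
  DArT convention (1 = alternate homozygote, 2 = heterozygote) can be
  harmonized on read with ``snp_coding="dart"``.

Missing scores are held internally as ``-1`` in an int8 grid
(markers x samples). Technical replicate assays are ordinary sample
columns; the pairs are kept in a registry so reproducibility and
threshold calibration know which columns re-assay the same DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1
MISSING_TOKEN = "-"

#: score alphabet per platform (excluding missing)
ALPHABETS = {"snp": (0, 1, 2), "silico": (0, 1)}

#: sample classes used for per-class distance summaries
SAMPLE_CLASSES = ("landrace", "improved", "exotic", "replicate", "unknown")

REPLICATE_SUFFIX = "__rep"

_TRANSITIONS = frozenset({frozenset("AG"), frozenset("CT")})
_BASES = frozenset("ACGT")


class MarkerFormatError(ValueError):
    """Raised for malformed marker files or illegal score tokens."""


@dataclass
class MarkerMatrix:
    """A marker x sample score grid with per-marker metadata.

    Attributes
    ----------
    platform : {"snp", "silico"}
    scores : int8 array, shape (n_markers, n_samples); -1 = missing
    marker_ids, sample_ids : unique identifiers
    allele_pair : per-marker allele strings like ``"A>G"`` (SNP only)
    precomputed : optional provider QC columns keyed ``"call_rate"`` /
        ``"reproducibility"``
    replicate_pairs : (sample, sample) technical replicate assays
    sample_class : per-sample class label
    """

    platform: str
    scores: np.ndarray
    marker_ids: list[str]
    sample_ids: list[str]
    allele_pair: list[str] | None = None
    precomputed: dict[str, np.ndarray] = field(default_factory=dict)
    replicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    sample_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int8)
        if self.scores.ndim != 2:
            raise MarkerFormatError("scores must be a 2-D grid")
        if self.platform not in ALPHABETS:
            raise MarkerFormatError(f"unknown platform {self.platform!r}")
        nm, ns = self.scores.shape
        if len(self.marker_ids) != nm or len(self.sample_ids) != ns:
            raise MarkerFormatError("ID lists do not match grid shape")
        if len(set(self.marker_ids)) != nm:
            raise MarkerFormatError("duplicate marker IDs")
        if len(set(self.sample_ids)) != ns:
            raise MarkerFormatError("duplicate sample IDs")
        allowed = set(ALPHABETS[self.platform]) | {MISSING}
        bad = ~np.isin(self.scores, sorted(allowed))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MarkerFormatError(
                f"illegal score {int(self.scores[i, j])} at "
                f"(marker {self.marker_ids[i]!r}, sample {self.sample_ids[j]!r})"
            )
        known = set(self.sample_ids)
        for a, b in self.replicate_pairs:
            if a not in known or b not in known:
                raise MarkerFormatError(f"replicate pair ({a}, {b}) references unknown sample")

    @property
    def n_markers(self) -> int:
        return self.scores.shape[0]

    @property
    def n_samples(self) -> int:
        return self.scores.shape[1]

    def sample_index(self, sample: str) -> int:
        return self.sample_ids.index(sample)

    def select_markers(self, mask: np.ndarray) -> "MarkerMatrix":
        """Subset markers by boolean mask, keeping metadata aligned."""
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            scores=self.scores[mask],
            marker_ids=[m for m, k in zip(self.marker_ids, mask) if k],
            allele_pair=(
                None
                if self.allele_pair is None
                else [a for a, k in zip(self.allele_pair, mask) if k]
            ),
            precomputed={k: v[mask] for k, v in self.precomputed.items()},
        )

    def select_samples(self, samples: list[str]) -> "MarkerMatrix":
        """Subset/reorder sample columns; drops dangling replicate pairs."""
        idx = [self.sample_index(s) for s in samples]
        kept = set(samples)
        return replace(
            self,
            scores=self.scores[:, idx],
            sample_ids=list(samples),
            replicate_pairs=[p for p in self.replicate_pairs if p[0] in kept and p[1] in kept],
            sample_class={s: c for s, c in self.sample_class.items() if s in kept},
        )

    def missing_rate_per_sample(self) -> np.ndarray:
        return (self.scores == MISSING).mean(axis=0)


# ---------------------------------------------------------------------------
# CSV I/O
#
# Dialect: UTF-8 comma-separated; first column ``MarkerID``; optional
# metadata columns ``AllelePair``, ``CallRate``, ``Reproducibility``;
# remaining columns are samples. Missing score token "-". Samples named
# ``<accession>__rep`` are auto-registered as technical replicates of
# ``<accession>``.
# ---------------------------------------------------------------------------

_META_COLS = ("MarkerID", "AllelePair", "CallRate", "Reproducibility")


def read_marker_csv(
    path,
    platform: str,
    snp_coding: str = "dosage",
    sample_class: dict[str, str] | None = None,
) -> MarkerMatrix:
    """Read a marker-score CSV into a :class:`MarkerMatrix`.

    ``snp_coding="dart"`` recodes scores 1 (alt homozygote) and
    2 (heterozygote) to dosages 2 and 1 on read.
    """
    if platform not in ALPHABETS:
        raise MarkerFormatError(f"unknown platform {platform!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0] != "MarkerID":
        raise MarkerFormatError(f"{path}: first column must be MarkerID, got {df.columns[0]!r}")
    meta = [c for c in df.columns if c in _META_COLS]
    samples = [c for c in df.columns if c not in _META_COLS]
    if not samples:
        raise MarkerFormatError(f"{path}: no sample columns")
    marker_ids = df["MarkerID"].tolist()

    allowed = {str(s) for s in ALPHABETS[platform]} | {MISSING_TOKEN}
    raw = df[samples].to_numpy(dtype=object)
    scores = np.full(raw.shape, MISSING, dtype=np.int8)
    for j, col in enumerate(samples):
        col_vals = raw[:, j]
        for i, tok in enumerate(col_vals):
            tok = tok.strip()
            if tok not in allowed:
                raise MarkerFormatError(
                    f"{path}: illegal token {tok!r} at (marker {marker_ids[i]!r}, sample {col!r})"
                )
            if tok != MISSING_TOKEN:
                scores[i, j] = int(tok)
    if platform == "snp" and snp_coding == "dart":
        one = scores == 1
        scores[scores == 2] = 1
        scores[one] = 2
    elif snp_coding not in ("dosage", "dart"):
        raise MarkerFormatError(f"unknown snp_coding {snp_coding!r}")

    allele_pair = df["AllelePair"].tolist() if "AllelePair" in meta else None
    precomputed = {}
    if "CallRate" in meta:
        precomputed["call_rate"] = pd.to_numeric(df["CallRate"]).to_numpy(float)
    if "Reproducibility" in meta:
        precomputed["reproducibility"] = pd.to_numeric(df["Reproducibility"]).to_numpy(float)

    pairs = [
        (s[: -len(REPLICATE_SUFFIX)], s)
        for s in samples
        if s.endswith(REPLICATE_SUFFIX) and s[: -len(REPLICATE_SUFFIX)] in samples
    ]
    classes = dict(sample_class or {})
    for s in samples:
        classes.setdefault(s, "replicate" if s.endswith(REPLICATE_SUFFIX) else "unknown")
    return MarkerMatrix(
        platform=platform,
        scores=scores,
        marker_ids=marker_ids,
        sample_ids=samples,
        allele_pair=allele_pair,
        precomputed=precomputed,
        replicate_pairs=pairs,
        sample_class=classes,
    )


def write_marker_csv(m: MarkerMatrix, path) -> None:
    """Write a marker matrix in the CSV dialect read by :func:`read_marker_csv`."""
    cols: dict[str, object] = {"MarkerID": m.marker_ids}
    if m.allele_pair is not None:
        cols["AllelePair"] = m.allele_pair
    if "call_rate" in m.precomputed:
        cols["CallRate"] = m.precomputed["call_rate"]
    if "reproducibility" in m.precomputed:
        cols["Reproducibility"] = m.precomputed["reproducibility"]
    grid = m.scores.astype(object)
    grid[grid == MISSING] = MISSING_TOKEN
    for j, s in enumerate(m.sample_ids):
        cols[s] = grid[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# QC statistics
# ---------------------------------------------------------------------------


@dataclass
class MarkerQC:
    """Per-marker QC statistics (arrays aligned with ``marker_ids``)."""

    call_rate: np.ndarray
    reproducibility: np.ndarray
    repro_no_pair: np.ndarray  # bool flag: no scorable replicate pair
    pic: np.ndarray
    snp_type: list[str] | None  # "transition"/"transversion"/"NA"
    freq: np.ndarray  # alt-allele freq (snp) or presence freq (silico)


def call_rate(m: MarkerMatrix) -> np.ndarray:
    """Fraction of samples with a non-missing score, per marker."""
    if m.n_samples < 1:
        raise ValueError("call_rate needs at least one sample")
    return (m.scores != MISSING).mean(axis=1)


def reproducibility(m: MarkerMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Replicate concordance per marker.

    For each marker, among replicate pairs with both calls non-missing,
    the fraction of pairs with equal scores. Markers with no scorable
    pair are reported as 1.0 and flagged (absence of evidence does not
    demote a marker; the flag preserves auditability).

    Returns ``(values, no_pair_flag)``.
    """
    if not m.replicate_pairs:
        raise ValueError("replicate registry is empty; supply reproducibility externally")
    n_pair = np.zeros(m.n_markers, dtype=int)
    n_same = np.zeros(m.n_markers, dtype=int)
    for a, b in m.replicate_pairs:
        x = m.scores[:, m.sample_index(a)]
        y = m.scores[:, m.sample_index(b)]
        ok = (x != MISSING) & (y != MISSING)
        n_pair += ok
        n_same += ok & (x == y)
    no_pair = n_pair == 0
    vals = np.ones(m.n_markers, dtype=float)
    np.divide(n_same, n_pair, out=vals, where=~no_pair)
    return vals, no_pair


def allele_frequency(m: MarkerMatrix) -> np.ndarray:
    """Alternate-allele frequency (snp, from dosages) or presence frequency (silico)."""
    called = m.scores != MISSING
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore"):
        if m.platform == "snp":
            alt = np.where(called, m.scores, 0).sum(axis=1)
            f = alt / (2.0 * n_called)
        else:
            f = np.where(called, m.scores, 0).sum(axis=1) / n_called
    return np.where(n_called > 0, f, np.nan)


def pic(m: MarkerMatrix) -> np.ndarray:
    """Polymorphic information content, ``1 - sum(f^2)``, per marker.

    For SNPs the two allele frequencies are estimated from dosages; for
    SilicoDArT they are the presence/absence state frequencies. Bounded
    by 0.5 for two states/alleles; monomorphic loci give 0.
    """
    f = allele_frequency(m)
    return 1.0 - f**2 - (1.0 - f) ** 2


def classify_snp_type(allele_pair: str) -> str:
    """Classify a substitution as ``"transition"`` (A<->G, C<->T) or ``"transversion"``.

    Accepts ``"A>G"``, ``"A/G"``, ``"A:G"``; orientation-insensitive.
    """
    pair = allele_pair.strip().upper()
    for sep in (">", "/", ":"):
        if sep in pair:
            parts = pair.split(sep)
            break
    else:
        parts = list(pair)
    if len(parts) != 2:
        raise ValueError(f"cannot parse allele pair {allele_pair!r}")
    a, b = (p.strip() for p in parts)
    if a not in _BASES or b not in _BASES:
        raise ValueError(f"non-ACGT base in allele pair {allele_pair!r}")
    if a == b:
        raise ValueError(f"identical alleles in {allele_pair!r}: not a SNP")
    return "transition" if frozenset((a, b)) in _TRANSITIONS else "transversion"


def compute_qc(m: MarkerMatrix, prefer_precomputed: bool = True) -> MarkerQC:
    """Assemble all per-marker QC statistics.

    With ``prefer_precomputed`` (default) provider-supplied CallRate /
    Reproducibility columns take precedence over values derived from the
    matrix itself; reproducibility falls back to 1.0-with-flag when
    neither a precomputed column nor a replicate registry exists.
    """
    cr = call_rate(m)
    if prefer_precomputed and "call_rate" in m.precomputed:
        cr = m.precomputed["call_rate"]
    if prefer_precomputed and "reproducibility" in m.precomputed:
        rep = m.precomputed["reproducibility"]
        no_pair = np.zeros(m.n_markers, dtype=bool)
    elif m.replicate_pairs:
        rep, no_pair = reproducibility(m)
    else:
        rep = np.ones(m.n_markers)
        no_pair = np.ones(m.n_markers, dtype=bool)
    snp_type = None
    if m.platform == "snp" and m.allele_pair is not None:
        snp_type = []
        for ap in m.allele_pair:
            try:
                snp_type.append(classify_snp_type(ap))
            except ValueError:
                snp_type.append("NA")
    return MarkerQC(
        call_rate=cr,
        reproducibility=rep,
        repro_no_pair=no_pair,
        pic=pic(m),
        snp_type=snp_type,
        freq=allele_frequency(m),
    )


def filter_markers(
    m: MarkerMatrix,
    qc: MarkerQC,
    min_call_rate: float = 0.95,
    min_reproducibility: float = 1.0,
) -> tuple[MarkerMatrix, dict]:
    """Retain markers with call rate and reproducibility at or above thresholds.

    Defaults drop markers with >=5% missing data or any replicate
    discordance. Returns the filtered matrix and a report dict.
    """
    for name, t in (("min_call_rate", min_call_rate), ("min_reproducibility", min_reproducibility)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    keep = (qc.call_rate >= min_call_rate) & (qc.reproducibility >= min_reproducibility)
    out = m.select_markers(keep)
    report = {
        "platform": m.platform,
        "n_input": m.n_markers,
        "n_retained": int(keep.sum()),
        "n_removed": int((~keep).sum()),
        "min_call_rate": min_call_rate,
        "min_reproducibility": min_reproducibility,
        "mean_call_rate_retained": float(np.mean(qc.call_rate[keep])) if keep.any() else float("nan"),
        "mean_pic_retained": float(np.nanmean(qc.pic[keep])) if keep.any() else float("nan"),
    }
    return out, report


PIC_BIN_EDGES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


def summarize_pic_bins(pics) -> pd.DataFrame:
    """Bin PIC values into [0,0.1), ..., [0.4,0.5] and report counts and percentages."""
    pics = np.asarray(pics, dtype=float)
    pics = pics[~np.isnan(pics)]
    if pics.size and (pics.min() < 0 or pics.max() > 0.5 + 1e-12):
        raise ValueError("PIC values must lie in [0, 0.5]")
    edges = np.asarray(PIC_BIN_EDGES)
    counts, _ = np.histogram(pics, bins=edges)
    # np.histogram's last bin is closed on the right, matching [0.4, 0.5]
    pct = 100.0 * counts / pics.size if pics.size else np.zeros(len(counts))
    return pd.DataFrame(
        {
            "bin": [f"[{a:.1f},{b:.1f}{']' if b == edges[-1] else ')'}" for a, b in zip(edges, edges[1:])],
            "count": counts,
            "percent": pct,
        }
    )


TSTV_CLASSES = ("A/G", "C/T", "A/C", "A/T", "G/C", "G/T")


def tstv_table(m: MarkerMatrix) -> pd.DataFrame:
    """Tally SNP substitution classes and transition/transversion totals.

    Per-class frequency is count / number of classified markers; markers
    without a parseable allele pair are counted as NA and excluded from
    denominators. The ``total`` rows give the transition and transversion
    sums with their fractions (which sum to 1 over classified markers).
    """
    if m.platform != "snp" or m.allele_pair is None:
        raise ValueError("tstv_table needs a SNP matrix with allele pairs")
    counts = dict.fromkeys(TSTV_CLASSES, 0)
    n_na = 0
    for ap in m.allele_pair:
        try:
            classify_snp_type(ap)
        except ValueError:
            n_na += 1
            continue
        counts[_normalize_class(ap)] += 1
    n_classified = sum(counts.values())
    rows = []
    for cls in TSTV_CLASSES:
        kind = classify_snp_type(cls)
        freq = counts[cls] / n_classified if n_classified else float("nan")
        rows.append({"class": cls, "kind": kind, "count": counts[cls], "frequency": freq})
    ts = sum(r["count"] for r in rows if r["kind"] == "transition")
    tv = sum(r["count"] for r in rows if r["kind"] == "transversion")
    for kind, tot in (("transition", ts), ("transversion", tv)):
        rows.append(
            {
                "class": f"total_{kind}",
                "kind": kind,
                "count": tot,
                "frequency": tot / n_classified if n_classified else float("nan"),
            }
        )
    rows.append({"class": "NA", "kind": "NA", "count": n_na, "frequency": float("nan")})
    return pd.DataFrame(rows)


def _normalize_class(allele_pair: str) -> str:
    pair = allele_pair.strip().upper()
    for sep in (">", "/", ":"):
        pair = pair.replace(sep, "")
    a, b = sorted(pair)
    order = {"AC": "A/C", "AG": "A/G", "AT": "A/T", "CG": "G/C", "CT": "C/T", "GT": "G/T"}
    return order[a + b]
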