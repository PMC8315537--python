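"""Duplicate-accession detection calibrated on replicated DNAs.

The decision rule mirrors routine genebank curation: two accessions are
declared potential duplicates (synonyms of one clone) when their
dissimilarity falls within the range observed between technical
replicate assays of the same DNA. The threshold is taken as the maximum
replicate-pair distance — the most conservative value consistent with
"within the replicate range". Pairs flagged on both platforms form the
consensus; clone groups are the connected components of the consensus
pair graph (single-linkage transitive closure), and one representative
per group (lowest missing-data rate, ties broken alphabetically) is
retained while the rest go on the purge list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .gower import DistanceMatrix

Pair = tuple[str, str]


def _norm(pair: Pair) -> Pair:
    a, b = pair
    return (a, b) if a <= b else (b, a)


@dataclass
class CloneGroupSet:
    """Calibrated thresholds, duplicate pairs, clone groups and purge list."""

    tau_snp: float
    tau_silico: float
    pairs_snp: set = field(default_factory=set)
    pairs_silico: set = field(default_factory=set)
    consensus_pairs: set = field(default_factory=set)
    groups: list = field(default_factory=list)  # list of sorted member lists
    representatives: list = field(default_factory=list)
    purge_list: list = field(default_factory=list)

    @property
    def flagged(self) -> list[str]:
        """All members of nontrivial clone groups (the 'duplicates' count)."""
        return sorted({a for g in self.groups for a in g})


def calibrate_threshold(D: DistanceMatrix, replicate_pairs: list[Pair]) -> tuple[float, pd.DataFrame]:
    """Duplicate threshold from the replicate-distance distribution.

    tau = max over replicate pairs of d(pair). Returns the threshold and
    the full replicate-distance table for reporting.
    """
    rows = []
    for a, b in replicate_pairs:
        if a in D.labels and b in D.labels:
            rows.append({"sample": a, "replicate": b, "distance": D.get(a, b)})
    if not rows:
        raise ValueError(
            "no replicate pair present in the distance matrix; "
            "supply a threshold manually"
        )
    table = pd.DataFrame(rows)
    return float(table["distance"].max()), table


def find_duplicate_pairs(
    D: DistanceMatrix, tau: float, replicate_samples: set[str] | None = None
) -> set[Pair]:
    """All unordered sample pairs with d <= tau.

    Replicate assay columns are excluded from candidacy — they are the
    calibration set, not accessions.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    excl = replicate_samples or set()
    out = set()
    for a, b, d in D.pairs():
        if a in excl or b in excl:
            continue
        if d <= tau:
            out.add(_norm((a, b)))
    return out


def consensus_clone_groups(pairs_snp: set[Pair], pairs_silico: set[Pair]) -> tuple[set[Pair], list[list[str]]]:
    """Intersect per-platform pair sets and form clone groups.

    Groups are connected components of the consensus-pair graph; chained
    similarity (a~b, b~c) places a, b, c in one group even if a~c was
    not itself flagged.
    """
    consensus = {_norm(p) for p in pairs_snp} & {_norm(p) for p in pairs_silico}
    g = nx.Graph()
    g.add_edges_from(consensus)
    groups = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    return consensus, groups


def select_representatives(
    groups: list[list[str]], missing_rate: dict[str, float]
) -> tuple[list[str], list[str]]:
    """Keep the member with the lowest missing-data rate per group.

    Ties break to the lexicographically smallest ID. Returns
    ``(representatives, purge_list)``.
    """
    reps, purge = [], []
    for g in groups:
        if not g:
            raise ValueError("empty clone group")
        best = min(g, key=lambda a: (missing_rate[a], a))
        reps.append(best)
        purge.extend(a for a in g if a != best)
    return reps, sorted(purge)


def detect_duplicates(
    D_snp: DistanceMatrix,
    D_silico: DistanceMatrix,
    replicate_pairs: list[Pair],
    missing_rate: dict[str, float],
    tau_snp: float | None = None,
    tau_silico: float | None = None,
) -> CloneGroupSet:
    """Full duplicate-detection stage: calibrate, flag, intersect, group, purge.

    Thresholds may be supplied explicitly (e.g. from an external
    calibration); otherwise they are computed from the replicate pairs
    present in each matrix.
    """
    if tau_snp is None:
        tau_snp, _ = calibrate_threshold(D_snp, replicate_pairs)
    if tau_silico is None:
        tau_silico, _ = calibrate_threshold(D_silico, replicate_pairs)
    rep_samples = {s for p in replicate_pairs for s in p[1:]}
    p_snp = find_duplicate_pairs(D_snp, tau_snp, rep_samples)
    p_sil = find_duplicate_pairs(D_silico, tau_silico, rep_samples)
    consensus, groups = consensus_clone_groups(p_snp, p_sil)
    reps, purge = select_representatives(groups, missing_rate)
    return CloneGroupSet(
        tau_snp=tau_snp,
        tau_silico=tau_silico,
        pairs_snp=p_snp,
        pairs_silico=p_sil,
        consensus_pairs=consensus,
        groups=groups,
        representatives=reps,
        purge_list=purge,
    )


def groups_table(cgs: CloneGroupSet) -> pd.DataFrame:
    rows = []
    for gid, g in enumerate(cgs.groups):
        rep = cgs.representatives[gid]
        for a in g:
            rows.append({"group": gid, "accession": a, "role": "representative" if a == rep else "purge"})
    return pd.DataFrame(rows, columns=["group", "accession", "role"])
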