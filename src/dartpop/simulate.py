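"""Synthetic dual-platform germplasm collections with known ground truth.

The generator emulates a clonally propagated crop collection genotyped
on two DArT platforms: a codominant SNP panel (dosage 0/1/2) and a
dominant presence/absence panel (SilicoDArT). Population structure
follows a two-level model:

* ``K_true`` diverged founder pools with Balding–Nichols allele
  frequencies: an ancestral frequency per locus drawn Uniform(0.05,
  0.95) and pool frequencies drawn from a Beta with that mean and
  variance scaled by ``fst``;
* per-accession ancestry drawn from a symmetric Dirichlet
  (``alpha_admix``), shared between the two platforms so that
  cross-platform concordance is high by construction;
* SNP dosages ~ Binomial(2, sum_k q_k p_kl); dominant presence is the
  phenotype of an underlying biallelic locus, Bernoulli(1 - (1 - pi)^2)
  with pi the mixed dominant-allele frequency — correlated with, but
  not a copy of, the SNP platform.

On top of that, clone groups (synonymous accessions) are planted by
copying a founder column with small per-locus score flips, and
technical replicate assays are appended as ``<accession>__rep`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import MISSING, MarkerMatrix, REPLICATE_SUFFIX

_STREAMS = {
    "founders_snp": 1,
    "founders_silico": 2,
    "ancestry": 3,
    "genotypes_snp": 4,
    "genotypes_silico": 5,
    "clones": 6,
    "missing": 7,
    "replicates": 8,
    "allele_pairs": 9,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    # one independent stream per stage so reordering stages cannot
    # silently change unrelated draws
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass
class SimConfig:
    """Study-design parameters for a synthetic collection.

    Defaults emulate an 87-accession genebank holding (41 landraces of
    which 22 form two planted clone groups, 21 improved lines, 25
    exotic lines), ~10,000 markers per platform, 3 replicated DNAs and
    2 ancestral pools with widespread admixture.
    """

    n_accessions: int = 87
    n_landrace: int = 41
    n_improved: int = 21
    n_snp: int = 10_000
    n_silico: int = 10_000
    K_true: int = 2
    fst: float = 0.30
    alpha_admix: float = 0.30
    clone_groups: tuple = ((20, "landrace"), (2, "landrace"))
    n_replicates: int = 3
    err_clone: float = 0.0005
    err_tech: float = 0.004
    missing_rate: float = 0.01
    seed: int = 0

    @property
    def n_exotic(self) -> int:
        return self.n_accessions - self.n_landrace - self.n_improved

    def validate(self) -> None:
        if self.n_accessions < 2 or self.K_true < 1:
            raise ValueError("need >=2 accessions and K_true >= 1")
        if self.n_exotic < 0:
            raise ValueError("class counts exceed n_accessions")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must be in [0, 1)")
        if self.alpha_admix <= 0:
            raise ValueError("alpha_admix must be positive")
        for name, p in (("err_clone", self.err_clone), ("err_tech", self.err_tech)):
            if not (0.0 <= p < 0.05):
                raise ValueError(f"{name} must be in [0, 0.05), got {p}")
        if not (0.0 <= self.missing_rate < 0.3):
            raise ValueError("missing_rate must be in [0, 0.3)")
        n_clone_members = sum(size for size, _ in self.clone_groups)
        if any(size < 2 for size, _ in self.clone_groups):
            raise ValueError("clone groups must have size >= 2")
        if n_clone_members + self.n_replicates > self.n_accessions:
            raise ValueError("clone-group members plus replicates exceed n_accessions")
        if sum(1 for _, cls in self.clone_groups if cls == "landrace") and n_clone_members > self.n_landrace:
            raise ValueError("landrace clone-group members exceed n_landrace")


@dataclass
class SyntheticTruth:
    """Generator ground truth for recovery tests."""

    Q_true: np.ndarray  # accession x K ancestry proportions
    founder_freqs_snp: np.ndarray  # K x n_snp alternate-allele frequencies
    founder_freqs_silico: np.ndarray  # K x n_silico dominant-allele frequencies
    clone_map: dict[str, int]  # accession -> clone-group id
    replicate_map: dict[str, str]  # replicate sample -> source accession
    accession_ids: list[str] = field(default_factory=list)


def _balding_nichols(rng, K: int, L: int, fst: float) -> np.ndarray:
    anc = rng.uniform(0.05, 0.95, size=L)
    if fst == 0.0:
        return np.tile(anc, (K, 1))
    c = (1.0 - fst) / fst
    return rng.beta(anc * c, (1.0 - anc) * c, size=(K, L))


def _dirichlet(rng, alpha: float, n: int, K: int) -> np.ndarray:
    g = rng.gamma(alpha, 1.0, size=(n, K))
    tot = g.sum(axis=1)
    # guard the alpha -> 0 limit where all gammas underflow to zero:
    # the Dirichlet degenerates to a uniformly chosen vertex
    bad = tot <= 0
    if bad.any():
        q = np.zeros((int(bad.sum()), K))
        q[np.arange(len(q)), rng.integers(0, K, size=len(q))] = 1.0
        g[bad] = q
        tot = g.sum(axis=1)
    return g / tot[:, None]


def _flip_scores(scores: np.ndarray, rate: float, platform: str, rng) -> np.ndarray:
    """Per-locus score flips that keep the platform alphabet valid.

    SNP dosage errors move to an adjacent dosage (0->1, 2->1; from 1 to
    0 or 2 equiprobably); dominant scores toggle 0<->1. Missing entries
    are never flipped.
    """
    out = scores.copy()
    flip = (rng.random(out.shape) < rate) & (out != MISSING)
    if platform == "silico":
        out[flip] ^= 1
    else:
        here = out[flip]
        tgt = np.where(here == 0, 1, np.where(here == 2, 1, 0))
        mid = here == 1
        tgt[mid] = np.where(rng.random(int(mid.sum())) < 0.5, 0, 2)
        out[flip] = tgt.astype(out.dtype)
    return out


def generate_collection(config: SimConfig) -> tuple[MarkerMatrix, MarkerMatrix, SyntheticTruth]:
    """Generate SNP and SilicoDArT matrices plus ground truth.

    Both platforms are driven by the same per-accession ancestry, then
    clone groups, technical replicates and missingness are layered on.
    Fully deterministic given ``config.seed``.
    """
    config.validate()
    n, K = config.n_accessions, config.K_true

    ids = (
        [f"LR{i + 1:03d}" for i in range(config.n_landrace)]
        + [f"IM{i + 1:03d}" for i in range(config.n_improved)]
        + [f"EX{i + 1:03d}" for i in range(config.n_exotic)]
    )
    classes = dict.fromkeys(ids[: config.n_landrace], "landrace")
    classes.update(dict.fromkeys(ids[config.n_landrace : config.n_landrace + config.n_improved], "improved"))
    classes.update(dict.fromkeys(ids[config.n_landrace + config.n_improved :], "exotic"))

    P_snp = _balding_nichols(_rng(config.seed, "founders_snp"), K, config.n_snp, config.fst)
    P_sil = _balding_nichols(_rng(config.seed, "founders_silico"), K, config.n_silico, config.fst)
    Q = _dirichlet(_rng(config.seed, "ancestry"), config.alpha_admix, n, K)

    pi_snp = Q @ P_snp  # n x L mixed alternate-allele frequency
    pi_sil = Q @ P_sil
    g_snp = _rng(config.seed, "genotypes_snp").binomial(2, pi_snp).astype(np.int8).T
    present = 1.0 - (1.0 - pi_sil) ** 2  # dominant phenotype of a biallelic locus
    g_sil = (_rng(config.seed, "genotypes_silico").random(pi_sil.shape) < present).astype(np.int8).T

    snp = MarkerMatrix(
        platform="snp",
        scores=g_snp,
        marker_ids=[f"SNP{i + 1:05d}" for i in range(config.n_snp)],
        sample_ids=list(ids),
        allele_pair=_draw_allele_pairs(_rng(config.seed, "allele_pairs"), config.n_snp),
        precomputed={"reproducibility": np.ones(config.n_snp)},
        sample_class=dict(classes),
    )
    sil = MarkerMatrix(
        platform="silico",
        scores=g_sil,
        marker_ids=[f"SIL{i + 1:05d}" for i in range(config.n_silico)],
        sample_ids=list(ids),
        precomputed={"reproducibility": np.ones(config.n_silico)},
        sample_class=dict(classes),
    )

    # plant clone groups among the landraces: members become copies of
    # the group founder; their true ancestry is the founder's
    clone_map: dict[str, int] = {}
    rng_c = _rng(config.seed, "clones")
    landrace_pool = list(ids[: config.n_landrace])
    other_pool = list(ids[config.n_landrace :])
    for gid, (size, cls) in enumerate(config.clone_groups):
        pool = landrace_pool if cls == "landrace" else other_pool
        members = [pool.pop(0) for _ in range(size)]
        for a in members:
            clone_map[a] = gid
    idx = {a: i for i, a in enumerate(ids)}
    for gid in sorted(set(clone_map.values())):
        members = sorted(a for a, g in clone_map.items() if g == gid)
        founder = members[0]
        for a in members[1:]:
            Q[idx[a]] = Q[idx[founder]]
    snp = inject_clones(snp, clone_map, config.err_clone, seed=int(rng_c.integers(2**31)))
    sil = inject_clones(sil, clone_map, config.err_clone, seed=int(rng_c.integers(2**31)))

    rng_m = _rng(config.seed, "missing")
    for m in (snp, sil):
        miss = rng_m.random(m.scores.shape) < config.missing_rate
        m.scores[miss] = MISSING

    rng_r = _rng(config.seed, "replicates")
    rep_sources = sorted(rng_r.choice(ids, size=config.n_replicates, replace=False).tolist())
    snp = inject_replicates(snp, config.n_replicates, config.err_tech, seed=int(rng_r.integers(2**31)), accessions=rep_sources)
    sil = inject_replicates(sil, config.n_replicates, config.err_tech, seed=int(rng_r.integers(2**31)), accessions=rep_sources)

    truth = SyntheticTruth(
        Q_true=Q,
        founder_freqs_snp=P_snp,
        founder_freqs_silico=P_sil,
        clone_map=clone_map,
        replicate_map={f"{a}{REPLICATE_SUFFIX}": a for a in rep_sources},
        accession_ids=list(ids),
    )
    return snp, sil, truth


def _draw_allele_pairs(rng, L: int) -> list[str]:
    # substitution classes at roughly the transition-rich mix seen in
    # real biallelic SNP panels
    classes = ["A>G", "C>T", "A>C", "A>T", "G>C", "G>T"]
    weights = np.array([0.26, 0.25, 0.13, 0.14, 0.10, 0.12])
    return [classes[i] for i in rng.choice(6, size=L, p=weights / weights.sum())]


def inject_clones(matrix: MarkerMatrix, clone_map: dict[str, int], err_clone: float, seed: int) -> MarkerMatrix:
    """Overwrite clone-group member columns with noisy copies of the founder.

    The founder is the lexicographically smallest accession of each
    group; every other member gets the founder's scores with
    independent per-locus flips at rate ``err_clone``.
    """
    for a in clone_map:
        if a not in matrix.sample_ids:
            raise ValueError(f"clone_map references unknown accession {a!r}")
    rng = np.random.default_rng(seed)
    scores = matrix.scores.copy()
    idx = {a: matrix.sample_index(a) for a in clone_map}
    for gid in sorted(set(clone_map.values())):
        members = sorted(a for a, g in clone_map.items() if g == gid)
        founder_col = scores[:, idx[members[0]]]
        for a in members[1:]:
            scores[:, idx[a]] = _flip_scores(founder_col, err_clone, matrix.platform, rng)
    out = MarkerMatrix(
        platform=matrix.platform,
        scores=scores,
        marker_ids=list(matrix.marker_ids),
        sample_ids=list(matrix.sample_ids),
        allele_pair=matrix.allele_pair,
        precomputed=dict(matrix.precomputed),
        replicate_pairs=list(matrix.replicate_pairs),
        sample_class=dict(matrix.sample_class),
    )
    return out


def inject_replicates(
    matrix: MarkerMatrix,
    n_replicates: int,
    err_tech: float,
    seed: int,
    accessions: list[str] | None = None,
) -> MarkerMatrix:
    """Append technical replicate assay columns named ``<accession>__rep``.

    Each replicate is a copy of its source column with independent
    per-locus flips at rate ``err_tech`` (the pair-level discordance of
    two assays of the same DNA). Replicating a replicate is rejected.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    if accessions is None:
        pool = [s for s in matrix.sample_ids if not s.endswith(REPLICATE_SUFFIX)]
        accessions = sorted(rng.choice(pool, size=n_replicates, replace=False).tolist())
    if len(accessions) != n_replicates:
        raise ValueError("accessions list does not match n_replicates")
    for a in accessions:
        if a.endswith(REPLICATE_SUFFIX):
            raise ValueError(f"cannot replicate a replicate: {a!r}")
        if f"{a}{REPLICATE_SUFFIX}" in matrix.sample_ids:
            raise ValueError(f"replicate of {a!r} already present")
    cols = []
    for a in accessions:
        src = matrix.scores[:, matrix.sample_index(a)]
        cols.append(_flip_scores(src, err_tech, matrix.platform, rng))
    rep_ids = [f"{a}{REPLICATE_SUFFIX}" for a in accessions]
    classes = dict(matrix.sample_class)
    classes.update(dict.fromkeys(rep_ids, "replicate"))
    return MarkerMatrix(
        platform=matrix.platform,
        scores=np.column_stack([matrix.scores] + cols),
        marker_ids=list(matrix.marker_ids),
        sample_ids=list(matrix.sample_ids) + rep_ids,
        allele_pair=matrix.allele_pair,
        precomputed=dict(matrix.precomputed),
        replicate_pairs=list(matrix.replicate_pairs) + list(zip(accessions, rep_ids)),
        sample_class=classes,
    )


def write_truth(truth: SyntheticTruth, outdir) -> None:
    """Write ground truth as TSV files (Q_true, clone map, replicate registry)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    K = truth.Q_true.shape[1]
    q = pd.DataFrame(truth.Q_true, columns=[f"q{k + 1}" for k in range(K)])
    q.insert(0, "accession", truth.accession_ids)
    q.to_csv(outdir / "Q_true.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.clone_map.items()), columns=["accession", "clone_group"]
    ).to_csv(outdir / "clone_map.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.replicate_map.items()), columns=["replicate", "source"]
    ).to_csv(outdir / "replicates.tsv", sep="\t", index=False)
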