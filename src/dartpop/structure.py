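"""Bayesian admixture-model clustering of codominant biallelic genotypes.

The model is the classic no-linkage admixture model for unphased
diploid dosages: each individual i carries an ancestry vector q_i on
the K-simplex, each cluster k an allele frequency p_kl per locus l,
and each of the two allele copies at (i, l) originates independently
from cluster k with probability q_ik, then is the alternate allele with
probability p_kl. Priors: p_kl ~ Beta(lambda, lambda), q_i ~
Dirichlet(alpha, ..., alpha) with a single alpha shared across clusters
and individuals, given a uniform prior on (0, alpha_max] and updated by
a Metropolis step with a normal random-walk proposal.

Inference is by Gibbs sampling over the copy-origin indicators z,
allele frequencies P and ancestries Q, with the data log-likelihood
ln P(D | P, Q) traced every sweep. The model estimate of ln P(D) for a
given K is the deviance-based mean(lnL) - var(lnL)/2, and the number of
clusters is chosen by the Evanno delta-K statistic over replicate runs.

Missing genotypes contribute no allele copies and no likelihood terms.
All runs are bit-reproducible given a seed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import MISSING, MarkerMatrix

_LN2 = math.log(2.0)
_EPS = 1e-12


@dataclass
class McmcConfig:
    """Sampler settings; defaults follow common practice for this model."""

    burn_in: int = 20_000
    mcmc: int = 30_000
    K_range: tuple[int, int] = (1, 10)
    runs_per_K: int = 5
    lambda_: float = 1.0
    alpha_init: float = 1.0
    alpha_proposal_sd: float = 0.025
    alpha_max: float = 10.0
    update_alpha: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.burn_in <= 0 or self.mcmc <= 0:
            raise ValueError("burn_in and mcmc must be positive")
        if self.K_range[0] < 1 or self.K_range[1] < self.K_range[0]:
            raise ValueError("invalid K_range")
        if self.runs_per_K < 1:
            raise ValueError("runs_per_K must be >= 1")
        if self.lambda_ <= 0 or self.alpha_init <= 0 or self.alpha_max <= 0:
            raise ValueError("lambda_, alpha_init, alpha_max must be positive")


@dataclass
class StructureResult:
    K: int
    sample_ids: list[str]
    Q: np.ndarray  # samples x K posterior-mean ancestry
    P: np.ndarray  # K x loci posterior-mean alternate-allele frequency
    lnL_trace: np.ndarray  # post-burn-in data log-likelihood per sweep
    L_K: float  # estimated ln P(D)
    alpha_trace: np.ndarray
    seed: int = 0


def _genotype_arrays(m: MarkerMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if m.platform != "snp":
        raise ValueError("the admixture model requires codominant SNP dosages")
    G = m.scores.T  # samples x loci
    if G.size and G.max() > 2:
        raise ValueError("non-biallelic dosages")
    valid = G != MISSING
    # copy c of (i, l) carries the alternate allele iff c < dosage
    g = np.where(valid, G, 0)
    copy_alt = np.stack([g >= 1, g == 2], axis=2)  # n x L x 2
    return g, valid, copy_alt


def run_admixture(m: MarkerMatrix, K: int, cfg: McmcConfig, seed: int | None = None) -> StructureResult:
    """Gibbs-sample the admixture model at a fixed number of clusters K."""
    cfg.validate()
    if K < 1:
        raise ValueError("K must be >= 1")
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), K]))
    g, valid, copy_alt = _genotype_arrays(m)
    n, L = g.shape
    valid_copy = np.repeat(valid[:, :, None], 2, axis=2)  # n x L x 2
    lam = cfg.lambda_

    # log-binomial coefficient of each genotype, constant across sweeps
    ln_choose = np.where(valid & (g == 1), _LN2, 0.0)

    # initialization: pooled frequencies with a small symmetric prior,
    # uniform ancestry
    with np.errstate(invalid="ignore"):
        pooled = (g * valid).sum(axis=0) / np.maximum(1, 2 * valid.sum(axis=0))
    P = np.clip(np.tile(pooled, (K, 1)) + rng.normal(0, 0.01, size=(K, L)), 0.01, 0.99)
    Q = np.full((n, K), 1.0 / K)
    alpha = cfg.alpha_init

    total = cfg.burn_in + cfg.mcmc
    Q_sum = np.zeros_like(Q)
    P_sum = np.zeros_like(P)
    lnL_trace = np.empty(cfg.mcmc)
    alpha_trace = np.empty(cfg.mcmc)
    sum_log_q = 0.0  # refreshed each sweep for the alpha update

    for sweep in range(total):
        # (i) copy-origin indicators z
        w_alt = Q[:, None, :] * P.T[None, :, :]  # n x L x K
        w_ref = Q[:, None, :] * (1.0 - P.T)[None, :, :]
        W = np.where(copy_alt[:, :, :, None], w_alt[:, :, None, :], w_ref[:, :, None, :])
        cdf = np.cumsum(W, axis=3)
        u = rng.random((n, L, 2, 1)) * cdf[:, :, :, -1:]
        z = (u > cdf).sum(axis=3)  # n x L x 2 in [0, K)

        # (ii) allele frequencies and (iii) ancestries from assignment counts
        n_alt = np.empty((K, L))
        n_tot = np.empty((K, L))
        M = np.empty((n, K))
        for k in range(K):
            mk = (z == k) & valid_copy
            n_alt[k] = (mk & copy_alt).sum(axis=(0, 2))
            n_tot[k] = mk.sum(axis=(0, 2))
            M[:, k] = mk.sum(axis=(1, 2))
        P = rng.beta(lam + n_alt, lam + n_tot - n_alt)
        if K == 1:
            Q = np.ones((n, 1))
        else:
            gam = rng.standard_gamma(alpha + M)
            Q = gam / gam.sum(axis=1, keepdims=True)
            sum_log_q = np.log(np.clip(Q, _EPS, None)).sum()

        # (iv) Metropolis update of the shared Dirichlet concentration
        if K > 1 and cfg.update_alpha:
            prop = alpha + rng.normal(0.0, cfg.alpha_proposal_sd)
            if 0.0 < prop <= cfg.alpha_max:
                cur = _alpha_logpost(alpha, K, n, sum_log_q)
                new = _alpha_logpost(prop, K, n, sum_log_q)
                if math.log(rng.random()) < new - cur:
                    alpha = prop

        if sweep >= cfg.burn_in:
            t = sweep - cfg.burn_in
            Q_sum += Q
            P_sum += P
            nu = np.clip(Q @ P, _EPS, 1.0 - _EPS)
            ll = ln_choose + np.where(valid, g * np.log(nu) + (2 - g) * np.log1p(-nu), 0.0)
            lnL_trace[t] = ll[valid].sum() if valid.any() else 0.0
            alpha_trace[t] = alpha

    return StructureResult(
        K=K,
        sample_ids=list(m.sample_ids),
        Q=Q_sum / cfg.mcmc,
        P=P_sum / cfg.mcmc,
        lnL_trace=lnL_trace,
        L_K=estimate_LK(lnL_trace),
        alpha_trace=alpha_trace,
        seed=seed,
    )


def _alpha_logpost(a: float, K: int, n: int, sum_log_q: float) -> float:
    return n * (math.lgamma(K * a) - K * math.lgamma(a)) + (a - 1.0) * sum_log_q


def estimate_LK(lnL_trace) -> float:
    """Deviance-based estimate of ln P(D): mean(lnL) - var(lnL)/2."""
    t = np.asarray(lnL_trace, dtype=float)
    if t.size < 2:
        raise ValueError("trace must have length >= 2")
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite values in log-likelihood trace")
    return float(t.mean() - t.var(ddof=1) / 2.0)


def run_K_selection(
    m: MarkerMatrix, cfg: McmcConfig
) -> tuple[pd.DataFrame, dict[int, StructureResult]]:
    """Replicate runs over cfg.K_range.

    Returns the L-table (one row per K x run) and, per K, the result of
    the run with the highest L (used for reporting Q at the chosen K).
    """
    cfg.validate()
    rows = []
    best: dict[int, StructureResult] = {}
    for K in range(cfg.K_range[0], cfg.K_range[1] + 1):
        for run in range(cfg.runs_per_K):
            res = run_admixture(m, K, cfg, seed=int(np.random.default_rng(
                np.random.SeedSequence([cfg.seed, K, run])).integers(2**31)))
            rows.append({"K": K, "run": run, "L": res.L_K})
            if K not in best or res.L_K > best[K].L_K:
                best[K] = res
    return pd.DataFrame(rows), best


def evanno_deltaK(L_table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Evanno second-order statistic over an L-table with columns K, run, L.

    delta K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K) over
    runs); undefined at the endpoints of the K range. Returns the table
    and the argmax K.
    """
    grp = L_table.groupby("K")["L"]
    Ks = sorted(grp.groups)
    if len(Ks) < 3 or Ks != list(range(Ks[0], Ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    if (grp.count() < 2).any():
        raise ValueError("need >= 2 runs per K for delta K")
    mean = grp.mean()
    sd = grp.std(ddof=1)
    rows = []
    for K in Ks:
        row = {"K": K, "mean_L": mean[K], "sd_L": sd[K], "delta_K": np.nan}
        if Ks[0] < K < Ks[-1]:
            lpp = abs(mean[K + 1] - 2.0 * mean[K] + mean[K - 1])
            if sd[K] == 0.0:
                warnings.warn(f"zero across-run sd at K={K}; delta K reported as inf", stacklevel=2)
                row["delta_K"] = np.inf
            else:
                row["delta_K"] = lpp / sd[K]
        rows.append(row)
    table = pd.DataFrame(rows)
    interior = table.dropna(subset=["delta_K"])
    best_K = int(interior.loc[interior["delta_K"].idxmax(), "K"])
    return table, best_K


def expected_heterozygosity(P_k: np.ndarray) -> float:
    """Mean over loci of 1 - sum of squared allele frequencies (biallelic)."""
    p = np.asarray(P_k, dtype=float)
    return float(np.mean(1.0 - p**2 - (1.0 - p) ** 2))


def net_nucleotide_distance(P_k1: np.ndarray, P_k2: np.ndarray) -> float:
    """Allele-frequency divergence between two clusters.

    Cross-population mismatch probability minus the average of the two
    within-population mismatch probabilities, averaged over loci; tiny
    negative values from Monte-Carlo noise are clipped to 0.
    """
    p1, p2 = np.asarray(P_k1, float), np.asarray(P_k2, float)
    if p1.shape != p2.shape:
        raise ValueError("frequency vectors must cover matched loci")
    cross = 1.0 - (p1 * p2 + (1 - p1) * (1 - p2))
    within1 = 1.0 - (p1**2 + (1 - p1) ** 2)
    within2 = 1.0 - (p2**2 + (1 - p2) ** 2)
    d = float(np.mean(cross - 0.5 * within1 - 0.5 * within2))
    return max(d, 0.0) if d > -1e-9 else d


def assign_membership(Q: np.ndarray, admix_threshold: float = 0.01) -> tuple[list[str], np.ndarray]:
    """Label each sample as fully assigned to a cluster or admixed.

    A sample is fully assigned to cluster k when Q_ik >= 1 - threshold;
    otherwise it is admixed. Membership proportions are the column
    means of Q.
    """
    if not 0.0 < admix_threshold < 0.5:
        raise ValueError("admix_threshold must be in (0, 0.5)")
    Q = np.asarray(Q, dtype=float)
    labels = []
    for row in Q:
        k = int(np.argmax(row))
        labels.append(f"subpop{k + 1}" if row[k] >= 1.0 - admix_threshold else "admixed")
    return labels, Q.mean(axis=0)


@dataclass
class DiversityStats:
    He: np.ndarray  # per cluster
    D_net: dict[tuple[int, int], float]  # per unordered cluster pair (1-based)
    membership: np.ndarray  # proportions per cluster
    labels: list[str] = field(default_factory=list)  # per-sample assignment


def diversity_stats(res: StructureResult, admix_threshold: float = 0.01) -> DiversityStats:
    """Per-cluster expected heterozygosity, pairwise net distances and membership."""
    He = np.array([expected_heterozygosity(res.P[k]) for k in range(res.K)])
    D_net = {
        (a + 1, b + 1): net_nucleotide_distance(res.P[a], res.P[b])
        for a, b in itertools.combinations(range(res.K), 2)
    }
    labels, membership = assign_membership(res.Q, admix_threshold)
    return DiversityStats(He=He, D_net=D_net, membership=membership, labels=labels)


def align_clusters(Q: np.ndarray, Q_ref: np.ndarray) -> np.ndarray:
    """Column permutation of Q best matching Q_ref (L1 cost, Hungarian).

    Returns ``perm`` such that ``Q[:, perm]`` aligns with ``Q_ref``;
    used to make recovery metrics invariant to label switching.
    """
    from scipy.optimize import linear_sum_assignment

    K = Q.shape[1]
    cost = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            cost[i, j] = np.abs(Q[:, i] - Q_ref[:, j]).sum()
    row, col = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=int)
    perm[col] = row
    return perm
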