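"""Bayesian admixture for dominant (recessive-null) markers.

Model.  Each individual i carries an admixture vector Q_i over K clusters
(Dirichlet(alpha) prior) and each cluster k has a band-presence allele
frequency p_kl at every locus l (Beta(1,1) prior, uncorrelated across
clusters).  Individuals are diploid; at each locus the two gene copies
independently draw a cluster of origin from Q_i and then an allele from
that cluster's frequency.  The presence allele is dominant over a
recessive null: the band phenotype is shown iff at least one copy carries
the presence allele, so

    Pr(band | Q_i, P) = 1 - (sum_k q_ik (1 - p_kl))^2.

Inference is by Gibbs sampling with latent-variable augmentation: given
the phenotype, sample the unobserved diploid genotype (how many presence
alleles), then a cluster of origin for each gene copy, then conjugate
updates P | counts ~ Beta and Q | counts ~ Dirichlet.  This is the
admixture model with uncorrelated frequencies and recessive-allele coding
appropriate for RAPD/AFLP band data.

Model choice across K uses the Evanno delta-K statistic on the replicate
mean log-likelihoods: delta K = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)).
Label switching between replicate runs is resolved by permuting cluster
columns to minimise total absolute difference from a reference replicate.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import ConfigError, HybridDetectError
from .io_matrix import MarkerMatrix

log = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass
class AdmixtureConfig:
    """MCMC settings for one admixture run."""

    K: int
    n_burnin: int = 2000
    n_iter: int = 10000
    alpha: float = 1.0
    seed: int | None = None
    thinning: int = 10

    def __post_init__(self):
        if self.K < 1:
            raise ConfigError("K must be >= 1")
        if self.n_iter < 1:
            raise ConfigError("n_iter must be >= 1")
        if self.n_burnin < 0:
            raise ConfigError("n_burnin must be >= 0")
        if self.alpha <= 0:
            raise ConfigError("alpha must be > 0")
        if self.thinning < 1:
            raise ConfigError("thinning must be >= 1")


@dataclass
class AdmixtureResult:
    """Posterior summaries of one admixture run."""

    specimen_ids: list[str]
    Q: np.ndarray                # specimens x K posterior mean memberships
    P: np.ndarray                # K x loci posterior mean band-allele frequencies
    loglik_trace: np.ndarray     # per retained sweep
    config: AdmixtureConfig

    @property
    def mean_loglik(self) -> float:
        return float(self.loglik_trace.mean())

    @property
    def sd_loglik(self) -> float:
        return float(self.loglik_trace.std(ddof=1)) if len(self.loglik_trace) > 1 else 0.0

    def q_frame(self) -> pd.DataFrame:
        cols = [f"cluster_{k + 1}" for k in range(self.Q.shape[1])]
        return pd.DataFrame(self.Q, index=self.specimen_ids, columns=cols)


def _phenotype_loglik(x: np.ndarray, theta: np.ndarray) -> float:
    """Log-likelihood of the band phenotypes given mixture presence prob."""
    q0 = np.clip(1.0 - theta, _EPS, 1.0 - _EPS)  # per-copy null prob
    p_absent = q0**2
    return float(
        np.where(x == 1, np.log1p(-p_absent), np.log(p_absent)).sum()
    )


def _sample_categorical(rng, weights: np.ndarray) -> np.ndarray:
    """Vectorised categorical draw along the last axis of `weights`."""
    cum = np.cumsum(weights, axis=-1)
    u = rng.random(weights.shape[:-1])[..., None] * cum[..., -1:]
    return (u > cum).sum(axis=-1)


def run_admixture(matrix: MarkerMatrix, config: AdmixtureConfig) -> AdmixtureResult:
    """Gibbs sampler for the dominant-marker admixture model.

    Returns posterior mean Q and P over retained sweeps plus the retained
    phenotype log-likelihood trace.  Runs with the same seed are
    bit-reproducible.
    """
    x = matrix.values
    if not np.isin(x, (0, 1)).all():
        raise HybridDetectError("matrix must be binary")
    N, L = x.shape
    K = config.K
    if K > N:
        raise ConfigError(f"K={K} exceeds number of specimens ({N})")
    rng = np.random.default_rng(config.seed)
    x1 = x == 1
    l_idx = np.broadcast_to(np.arange(L), (N, L))
    i_idx = np.broadcast_to(np.arange(N)[:, None], (N, L))

    P = rng.uniform(0.2, 0.8, size=(K, L))
    Q = rng.dirichlet(np.full(K, config.alpha), size=N)

    n_keep = 0
    Q_sum = np.zeros((N, K))
    P_sum = np.zeros((K, L))
    trace: list[float] = []
    total = config.n_burnin + config.n_iter

    for sweep in range(total):
        theta = Q @ P                                   # (N, L) mixture presence prob
        theta = np.clip(theta, _EPS, 1.0 - _EPS)

        # latent genotype: number of presence alleles per (i, l)
        g = np.zeros((N, L), dtype=np.int8)
        # given band shown, Pr(two presence alleles) = theta / (2 - theta)
        p2 = theta / (2.0 - theta)
        g[x1] = 1 + (rng.random(size=x1.sum()) < p2[x1])

        # cluster of origin for each of the two gene copies
        w_pres = Q[:, None, :] * P.T[None, :, :]        # (N, L, K), presence-copy weight
        w_null = Q[:, None, :] * (1.0 - P.T[None, :, :])
        z_pres = _sample_categorical(rng, np.broadcast_to(w_pres[:, :, None, :], (N, L, 2, K)))
        z_null = _sample_categorical(rng, np.broadcast_to(w_null[:, :, None, :], (N, L, 2, K)))

        copy_slot = np.arange(2)[None, None, :]
        pres_mask = copy_slot < g[:, :, None]           # active presence copies
        null_mask = copy_slot < (2 - g)[:, :, None]     # active null copies

        # conjugate count updates (bincount over flattened (cluster, locus) /
        # (individual, cluster) indices)
        counts = []
        r = np.zeros((N, K))
        for z, mask in ((z_pres, pres_mask), (z_null, null_mask)):
            zm = z[mask]
            lm = np.broadcast_to(l_idx[:, :, None], (N, L, 2))[mask]
            im = np.broadcast_to(i_idx[:, :, None], (N, L, 2))[mask]
            counts.append(
                np.bincount(zm * L + lm, minlength=K * L).reshape(K, L).astype(float)
            )
            r += np.bincount(im * K + zm, minlength=N * K).reshape(N, K)
        n_pres, n_null = counts

        P = rng.beta(1.0 + n_pres, 1.0 + n_null)
        P = np.clip(P, _EPS, 1.0 - _EPS)
        if K == 1:
            Q = np.ones((N, 1))
        else:
            gamma = rng.standard_gamma(config.alpha + r)
            Q = gamma / gamma.sum(axis=1, keepdims=True)

        if sweep >= config.n_burnin and (sweep - config.n_burnin) % config.thinning == 0:
            n_keep += 1
            Q_sum += Q
            P_sum += P
            trace.append(_phenotype_loglik(x, np.clip(Q @ P, _EPS, 1.0 - _EPS)))

    Q_mean = Q_sum / n_keep
    Q_mean /= Q_mean.sum(axis=1, keepdims=True)
    return AdmixtureResult(
        specimen_ids=list(matrix.specimen_ids),
        Q=Q_mean,
        P=np.clip(P_sum / n_keep, _EPS, 1.0 - _EPS),
        loglik_trace=np.asarray(trace),
        config=config,
    )


# ------------------------------------------------------------ Evanno delta K

@dataclass
class DeltaKTable:
    """Replicate log-likelihood summary and delta-K statistic per K."""

    table: pd.DataFrame          # columns: K, n_reps, mean_loglik, sd_loglik, delta_K
    selected_K: int
    undefined_K: list[int] = field(default_factory=list)


def evanno_deltaK(runs: dict[int, list[AdmixtureResult]]) -> DeltaKTable:
    """Evanno delta-K model selection over replicate admixture runs.

    ``runs`` maps each K to its replicate results; K values must be
    consecutive with >=2 replicates each.  delta K is defined for interior
    K only; any K with zero replicate standard deviation is flagged and
    excluded from the argmax.
    """
    Ks = sorted(runs)
    if len(Ks) < 3:
        raise ConfigError("delta K needs >=3 consecutive K values (no interior K otherwise)")
    if Ks != list(range(Ks[0], Ks[-1] + 1)):
        raise ConfigError(f"K values must be consecutive, got {Ks}")
    for k in Ks:
        if len(runs[k]) < 2:
            raise ConfigError(f"K={k} has {len(runs[k])} replicate(s); >=2 required")

    mean_l = {k: float(np.mean([r.mean_loglik for r in runs[k]])) for k in Ks}
    sd_l = {k: float(np.std([r.mean_loglik for r in runs[k]], ddof=1)) for k in Ks}

    rows = []
    undefined = []
    for k in Ks:
        dk = np.nan
        if Ks[0] < k < Ks[-1]:
            second = abs(mean_l[k + 1] - 2.0 * mean_l[k] + mean_l[k - 1])
            if sd_l[k] > 0:
                dk = second / sd_l[k]
            else:
                undefined.append(k)
                log.warning("delta K undefined at K=%d (replicate sd is 0)", k)
        rows.append(
            {"K": k, "n_reps": len(runs[k]), "mean_loglik": mean_l[k],
             "sd_loglik": sd_l[k], "delta_K": dk}
        )
    table = pd.DataFrame(rows)
    defined = table.dropna(subset=["delta_K"])
    if defined.empty:
        raise HybridDetectError("delta K undefined at every interior K")
    selected = int(defined.loc[defined["delta_K"].idxmax(), "K"])
    return DeltaKTable(table=table, selected_K=selected, undefined_K=undefined)


# ------------------------------------------------------------ replicate alignment

def _alignment_cost(Q: np.ndarray, ref: np.ndarray, perm: tuple[int, ...]) -> float:
    return float(np.abs(Q[:, list(perm)] - ref).sum())


def align_replicates(
    Q_list: list[np.ndarray], reference: int = 0
) -> tuple[list[np.ndarray], np.ndarray]:
    """Resolve label switching across replicate membership matrices.

    Each replicate's cluster columns are permuted to minimise the total
    absolute difference from the reference replicate (exhaustive over the
    K! permutations for K <= 8, Hungarian assignment above).  Returns the
    aligned replicates and their element-wise mean.
    """
    if not Q_list:
        raise HybridDetectError("no replicates to align")
    shapes = {q.shape for q in Q_list}
    if len(shapes) != 1:
        raise HybridDetectError(f"replicate shapes differ: {sorted(shapes)}")
    ref = Q_list[reference]
    K = ref.shape[1]
    aligned = []
    for Q in Q_list:
        if K <= 8:
            best = min(
                itertools.permutations(range(K)),
                key=lambda p: _alignment_cost(Q, ref, p),
            )
        else:
            log.warning("K=%d > 8: using assignment-based alignment", K)
            cost = np.abs(Q[:, :, None] - ref[:, None, :]).sum(axis=0)  # (from, to)
            rows, cols = linear_sum_assignment(cost)
            best = tuple(rows[np.argsort(cols)])
        aligned.append(Q[:, list(best)])
    return aligned, np.mean(aligned, axis=0)
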