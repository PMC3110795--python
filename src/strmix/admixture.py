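"""Bayesian model-based clustering of multi-allelic genotypes.

This is a Gibbs sampler for the classic admixture model: individual i has
an ancestry vector q_i over K clusters; each of the 2L allele copies in
its genotype has a latent origin z drawn from q_i, and the allele is drawn
from the origin cluster's locus-specific frequency vector p_kl.  Priors
are Dirichlet(alpha) on q_i and Dirichlet(lambda) on each p_kl.  A
no-admixture variant assigns one origin cluster per individual.  Missing
calls are skipped in all counts and likelihood terms.

Model choice across K uses the second-difference statistic on replicate
log-probability-of-data estimates (the Evanno delta-K construction), with
L(K) estimated from the post-burn-in likelihood trace as
mean - variance/2.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix


@dataclass
class AdmixtureModelSpec:
    """Sampler settings.

    ``alpha`` is the symmetric Dirichlet parameter on individual ancestry
    (low alpha favours unadmixed genomes; alpha > 1 implies most genomes
    are admixed).  With ``infer_alpha`` a symmetric Metropolis update on
    log alpha is enabled.  ``lam`` is the Dirichlet prior on allele
    frequencies (1.0 = flat).
    """

    K: int = 2
    alpha: float = 1.0
    infer_alpha: bool = False
    lam: float = 1.0
    admixture_model: bool = True
    sweeps: int = 500
    burnin: int = 200
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha <= 0 or self.lam <= 0:
            raise ValueError("alpha and lambda must be positive")
        if not 0 <= self.burnin < self.sweeps:
            raise ValueError("need sweeps > burnin >= 0")


@dataclass
class AncestryEstimate:
    """Posterior-mean ancestry (Q), cluster allele frequencies (P) and the
    per-sweep data log-likelihood trace."""

    individual_ids: list[str]
    locus_ids: list[str]
    Q: np.ndarray  # (N, K) rows sum to 1
    P: list[np.ndarray]  # per cluster: list over loci of frequency vectors
    allele_codes: list[np.ndarray]  # per locus, codes indexing the P vectors
    loglik_trace: np.ndarray = field(repr=False)
    alpha: float = 1.0

    @property
    def K(self) -> int:
        return self.Q.shape[1]

    @property
    def L_hat(self) -> float:
        return estimate_log_prob_data(self.loglik_trace)


def _encode(matrix: GenotypeMatrix):
    """Dense per-locus allele indices; missing copies get index 0, masked."""
    N, L = matrix.n_individuals, matrix.n_loci
    codes = []
    A = np.zeros((N, L, 2), dtype=np.int64)
    for l in range(L):
        col = matrix.calls[:, l, :]
        uniq = np.unique(col[col != MISSING])
        codes.append(uniq)
        lookup = {c: j for j, c in enumerate(uniq)}
        for i in range(N):
            for c in range(2):
                v = col[i, c]
                A[i, l, c] = lookup[v] if v != MISSING else 0
    mask = matrix.calls[..., 0] != MISSING  # (N, L)
    return A, np.repeat(mask[:, :, None], 2, axis=2), codes


def gibbs_admixture(
    matrix: GenotypeMatrix, spec: AdmixtureModelSpec
) -> AncestryEstimate:
    """Run the Gibbs sampler and return posterior-mean Q and P.

    Each sweep cycles: (i) allele-copy origins z sampled proportionally to
    q_ik * p_k,l,allele; (ii) each p_kl row from Dirichlet(lambda + origin-
    specific allele counts); (iii) each q_i from Dirichlet(alpha + origin
    counts) in the admixture model, or one cluster label per individual in
    the no-admixture model.  Deterministic given ``spec.seed``.
    """
    if matrix.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    rng = np.random.default_rng(spec.seed)
    N, L, K = matrix.n_individuals, matrix.n_loci, spec.K
    A, mask, codes = _encode(matrix)
    J = np.array([len(c) for c in codes])
    Jmax = int(J.max())
    valid = np.zeros((L, Jmax), dtype=bool)
    for l in range(L):
        valid[l, : J[l]] = True

    lgrid = np.arange(L)[None, :, None]  # broadcast to (N, L, 2)
    lidx = np.broadcast_to(np.arange(L)[None, :, None], (N, L, 2))
    iidx = np.broadcast_to(np.arange(N)[:, None, None], (N, L, 2))
    alpha = spec.alpha

    # initialisation: flat Q, frequencies from a flat Dirichlet
    Q = np.full((N, K), 1.0 / K)
    P = np.zeros((K, L, Jmax))
    for k in range(K):
        for l in range(L):
            P[k, l, : J[l]] = rng.dirichlet(np.full(J[l], spec.lam))

    kept = spec.sweeps - spec.burnin
    Q_sum = np.zeros((N, K))
    P_sum = np.zeros_like(P)
    trace = np.empty(kept)
    alpha_trace = np.empty(kept)

    for sweep in range(spec.sweeps):
        # (i) origins: w[i,l,c,k] = q_ik * p_k,l,a
        gathered = P[:, lgrid, A]  # (K, N, L, 2)
        w = np.moveaxis(gathered, 0, -1) * Q[:, None, None, :]
        tot = w.sum(axis=-1, keepdims=True)
        loglik = float(np.log(tot[..., 0][mask]).sum())
        cdf = np.cumsum(w, axis=-1)
        u = rng.random((N, L, 2, 1)) * tot
        z = (cdf < u).sum(axis=-1)
        z[~mask] = 0
        zi = None

        if not spec.admixture_model:
            # one origin per individual: sample from per-cluster genotype lik.
            logp = np.log(np.moveaxis(gathered, 0, -1))
            logp = np.where(mask[..., None], logp, 0.0).sum(axis=(1, 2))
            logp -= logp.max(axis=1, keepdims=True)
            probs = np.exp(logp)
            probs /= probs.sum(axis=1, keepdims=True)
            zi = (np.cumsum(probs, axis=1) < rng.random((N, 1))).sum(axis=1)
            z = np.broadcast_to(zi[:, None, None], (N, L, 2)).copy()
            z[~mask] = 0

        # (ii) allele frequencies from origin-specific counts
        flat = (z[mask] * L + lidx[mask]) * Jmax + A[mask]
        counts = np.bincount(flat, minlength=K * L * Jmax).reshape(K, L, Jmax)
        shape = np.where(valid[None, :, :], spec.lam + counts, 0.0)
        g = np.where(shape > 0, rng.gamma(np.maximum(shape, 1e-12)), 0.0)
        P = g / g.sum(axis=2, keepdims=True)

        # (iii) ancestry vectors
        if spec.admixture_model:
            n_ik = np.bincount(
                iidx[mask] * K + z[mask], minlength=N * K
            ).reshape(N, K)
            g = rng.gamma(alpha + n_ik)
            Q = g / g.sum(axis=1, keepdims=True)
            if spec.infer_alpha:
                alpha = _update_alpha(alpha, Q, rng)
        else:
            Q = np.zeros((N, K))
            Q[np.arange(N), zi] = 1.0

        if sweep >= spec.burnin:
            j = sweep - spec.burnin
            trace[j] = loglik
            alpha_trace[j] = alpha
            Q_sum += Q
            P_sum += P

    P_mean = P_sum / kept
    P_list = [
        [P_mean[k, l, : J[l]] / P_mean[k, l, : J[l]].sum() for l in range(L)]
        for k in range(K)
    ]
    Q_mean = Q_sum / kept
    Q_mean /= Q_mean.sum(axis=1, keepdims=True)
    return AncestryEstimate(
        individual_ids=list(matrix.individual_ids),
        locus_ids=list(matrix.locus_ids),
        Q=Q_mean,
        P=P_list,
        allele_codes=codes,
        loglik_trace=trace,
        alpha=float(np.mean(alpha_trace)),
    )


def _update_alpha(
    alpha: float, Q: np.ndarray, rng: np.random.Generator, step: float = 0.3,
    alpha_max: float = 10.0,
) -> float:
    """Symmetric Metropolis step on log alpha, uniform prior on (0, max]."""
    from scipy.special import gammaln

    prop = float(alpha * np.exp(step * rng.normal()))
    if not 0.0 < prop <= alpha_max:
        return alpha
    K = Q.shape[1]
    logq = np.log(np.clip(Q, 1e-300, None)).sum()

    def loglik(a: float) -> float:
        n = Q.shape[0]
        return n * (gammaln(K * a) - K * gammaln(a)) + (a - 1.0) * logq

    # Jacobian of the log-scale proposal: + log(prop/alpha)
    log_accept = loglik(prop) - loglik(alpha) + math.log(prop / alpha)
    if math.log(rng.random()) < log_accept:
        return prop
    return alpha


def align_cluster_labels(
    reference: AncestryEstimate, other: AncestryEstimate
) -> AncestryEstimate:
    """Permute ``other``'s clusters to best match ``reference``.

    Chooses the permutation maximising the summed dot product of matched Q
    rows, exhaustively over the K! permutations (exact for the small K
    used in practice; K <= 8 enforced).
    """
    if reference.K != other.K:
        raise ValueError("estimates have different K")
    if reference.individual_ids != other.individual_ids:
        raise ValueError("estimates cover different individuals")
    K = reference.K
    if K > 8:
        raise ValueError("exhaustive alignment supported for K <= 8")
    best, best_score = None, -np.inf
    for perm in itertools.permutations(range(K)):
        score = float(np.sum(reference.Q * other.Q[:, perm]))
        if score > best_score:
            best, best_score = perm, score
    perm = list(best)
    return AncestryEstimate(
        individual_ids=list(other.individual_ids),
        locus_ids=list(other.locus_ids),
        Q=other.Q[:, perm],
        P=[other.P[k] for k in perm],
        allele_codes=other.allele_codes,
        loglik_trace=other.loglik_trace,
        alpha=other.alpha,
    )


def estimate_log_prob_data(trace) -> float:
    """Model log-probability estimate from the likelihood trace.

    L_hat = mean(trace) - var(trace)/2, with the sample (ddof=1) variance:
    the standard harmonic-style correction applied to MCMC likelihood
    traces for model choice across K.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ValueError("trace must contain at least 2 sweeps")
    return float(trace.mean() - trace.var(ddof=1) / 2.0)


def evanno_delta_k(L_runs: dict[int, list[float]]) -> pd.DataFrame:
    """Second-difference model-choice statistic over a K grid.

    ``L_runs`` maps K -> replicate L(K) values (same replicate count per
    K, consecutive K values, at least 3 of them).  For each interior K,
    delta_K = mean_r |L(K+1,r) - 2 L(K,r) + L(K-1,r)| / sd_r(L(K,r)).
    A zero replicate sd is reported as infinite with a warning.
    """
    ks = sorted(L_runs)
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K values must be consecutive")
    n_reps = {len(L_runs[k]) for k in ks}
    if len(n_reps) != 1 or min(n_reps) < 2:
        raise ValueError("need the same replicate count (>= 2) at every K")
    L = np.array([L_runs[k] for k in ks], dtype=float)  # (nK, R)
    rows = []
    for j, k in enumerate(ks):
        if j == 0 or j == len(ks) - 1:
            rows.append({"K": k, "delta_K": np.nan, "mean_L": L[j].mean(),
                         "sd_L": L[j].std(ddof=1)})
            continue
        second = L[j + 1] - 2.0 * L[j] + L[j - 1]
        sd = L[j].std(ddof=1)
        if sd == 0.0:
            warnings.warn(f"zero replicate sd at K={k}; delta_K infinite",
                          stacklevel=2)
            dk = math.inf
        else:
            dk = float(np.mean(np.abs(second)) / sd)
        rows.append({"K": k, "delta_K": dk, "mean_L": L[j].mean(), "sd_L": sd})
    return pd.DataFrame(rows)


def best_k(delta_table: pd.DataFrame) -> int:
    """K with the largest delta_K (interior K values only)."""
    interior = delta_table.dropna(subset=["delta_K"])
    if interior.empty:
        raise ValueError("no interior K values with a defined delta_K")
    return int(interior.loc[interior["delta_K"].idxmax(), "K"])


def mean_cluster_by_locale(
    estimate: AncestryEstimate, table: pd.DataFrame
) -> pd.DataFrame:
    """Per-locale arithmetic mean of the Q columns.

    Every individual in the estimate must appear in the sample table.
    """
    t = table.set_index("individual_id")
    missing = [i for i in estimate.individual_ids if i not in t.index]
    if missing:
        raise ValueError(f"individuals missing from sample table: {missing[:5]}")
    df = pd.DataFrame(
        estimate.Q,
        index=pd.Index(estimate.individual_ids, name="individual_id"),
        columns=[f"q_{k + 1}" for k in range(estimate.K)],
    )
    df["locale"] = t.loc[df.index, "locale"].values
    out = df.groupby("locale").mean()
    out["n"] = df.groupby("locale").size()
    return out.reset_index()
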