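"""Locus quality control: Hardy–Weinberg exact testing, null-allele
estimation, and inter-locus association screening.

The HWE test is a Monte-Carlo exact test conditioned on the observed
allele counts: alleles at a locus are pooled and re-paired uniformly at
random, and the test statistic is the conditional probability of the
genotype array given allele counts (the Levene/Guo–Thompson quantity),
which remains valid for the sparse multi-allelic tables typical of STRs.
The null-allele estimate is the closed form based on homozygote excess,
r = (He - Ho) / (1 + He), floored at zero.  The pairwise linkage screen is
a G-test on the two-locus genotype contingency table with a permutation
null.  QC flags are reported, never silently applied.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import GenotypeMatrix, summarize_locus


def _genotype_array_log_prob(pairs: np.ndarray) -> float:
    """Log conditional probability of a genotype array given allele counts.

    P = n! * 2^h * prod_a(m_a!) / ((2n)! * prod_g(n_g!)) where n is the
    number of genotypes, h the number of heterozygotes, m_a the allele
    counts and n_g the genotype counts.
    """
    n = len(pairs)
    h = int(np.sum(pairs[:, 0] != pairs[:, 1]))
    _, allele_counts = np.unique(pairs.ravel(), return_counts=True)
    _, geno_counts = np.unique(pairs, axis=0, return_counts=True)
    return float(
        gammaln(n + 1)
        + h * np.log(2.0)
        + gammaln(allele_counts + 1).sum()
        - gammaln(2 * n + 1)
        - gammaln(geno_counts + 1).sum()
    )


def hwe_exact_test(
    matrix: GenotypeMatrix, locus_id: str, n_permutations: int = 10_000, seed=None
) -> float:
    """Monte-Carlo exact Hardy–Weinberg test at one locus.

    Alleles are pooled and re-paired uniformly at random ``n_permutations``
    times; p is the add-one-corrected proportion of pairings whose
    conditional genotype-array probability is <= the observed one.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be at least 100")
    pairs = matrix.locus_calls(locus_id)
    if len(pairs) < 2:
        raise ValueError(f"locus {locus_id!r} has fewer than 2 non-missing calls")
    if len(np.unique(pairs)) == 1:
        return 1.0  # monomorphic: only one genotype array is possible
    obs = _genotype_array_log_prob(pairs)
    rng = np.random.default_rng(seed)
    alleles = pairs.ravel().copy()
    hits = 0
    tol = 1e-12
    for _ in range(n_permutations):
        rng.shuffle(alleles)
        perm = np.sort(alleles.reshape(-1, 2), axis=1)
        if _genotype_array_log_prob(perm) <= obs + tol:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def null_allele_estimate(he: float, ho: float) -> float:
    """Homozygote-excess null-allele frequency estimate, floored at 0.

    r = (He - Ho) / (1 + He): the standard closed form attributing the
    shortfall of observed heterozygosity to a segregating null allele.
    """
    if not (0.0 <= he <= 1.0 and 0.0 <= ho <= 1.0):
        raise ValueError("He and Ho must lie in [0, 1]")
    return max(0.0, (he - ho) / (1.0 + he))


def _g_statistic(table: np.ndarray) -> float:
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    mask = table > 0
    return float(2.0 * np.sum(table[mask] * np.log(table[mask] / expected[mask])))


def linkage_test(
    matrix: GenotypeMatrix,
    locus_a: str,
    locus_b: str,
    n_permutations: int = 10_000,
    seed=None,
) -> float:
    """Permutation G-test of genotypic association between two loci.

    Builds the two-locus genotype contingency table over individuals typed
    at both loci and permutes one locus's genotype column.  A degenerate
    table (a single genotype class at either locus) returns p = 1.0 with a
    warning.
    """
    ja, jb = matrix.locus_index(locus_a), matrix.locus_index(locus_b)
    a, b = matrix.calls[:, ja, :], matrix.calls[:, jb, :]
    ok = (a[:, 0] != -9) & (b[:, 0] != -9)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 individuals typed at both loci")
    a, b = a[ok], b[ok]
    _, ga = np.unique(a, axis=0, return_inverse=True)
    _, gb = np.unique(b, axis=0, return_inverse=True)
    na, nb = ga.max() + 1, gb.max() + 1
    if na < 2 or nb < 2:
        warnings.warn(
            f"degenerate genotype table for {locus_a}/{locus_b}; p set to 1.0",
            stacklevel=2,
        )
        return 1.0
    def table_of(x, y):
        t = np.zeros((na, nb))
        np.add.at(t, (x, y), 1)
        return t

    obs = _g_statistic(table_of(ga, gb))
    rng = np.random.default_rng(seed)
    hits = 0
    perm = gb.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        if _g_statistic(table_of(ga, perm)) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def qc_report(
    matrix: GenotypeMatrix,
    n_permutations: int = 2000,
    seed=None,
    null_threshold: float = 0.05,
    hwe_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-locus QC table: He, Ho, HWE p, null-allele estimate, flags.

    Flags are advisory; exclusion decisions belong to the caller's config.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for locus in matrix.locus_ids:
        s = summarize_locus(matrix, locus)
        p = hwe_exact_test(
            matrix, locus, n_permutations=n_permutations,
            seed=rng.integers(2**31 - 1),
        )
        r = null_allele_estimate(s.he, s.ho)
        rows.append(
            {
                "locus": locus,
                "n_typed": s.n_typed,
                "n_alleles": s.n_alleles,
                "He": s.he,
                "Ho": s.ho,
                "hwe_p": p,
                "null_allele_estimate": r,
                "flagged": (p < hwe_alpha) or (r > null_threshold),
            }
        )
    return pd.DataFrame(rows)


def linkage_matrix(
    matrix: GenotypeMatrix, n_permutations: int = 2000, seed=None
) -> pd.DataFrame:
    """Pairwise linkage p-values (raw and Bonferroni-adjusted).

    No single multiple-testing convention dominates for this screen, so
    both the raw permutation p and the Bonferroni-adjusted value are
    reported side by side.
    """
    rng = np.random.default_rng(seed)
    loci = matrix.locus_ids
    n_pairs = len(loci) * (len(loci) - 1) // 2
    rows = []
    for i, la in enumerate(loci):
        for lb in loci[i + 1 :]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = linkage_test(
                    matrix, la, lb, n_permutations=n_permutations,
                    seed=rng.integers(2**31 - 1),
                )
            rows.append(
                {
                    "locus_a": la,
                    "locus_b": lb,
                    "p_raw": p,
                    "p_bonferroni": min(1.0, p * n_pairs),
                }
            )
    return pd.DataFrame(rows)
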