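"""Shannon-information ranking of STR loci for geographic assignment.

For a pair of source populations with allele frequencies p1, p2 at a
locus, consider an allele drawn from a mixed population containing a
proportion m of population-1 ancestry.  The information the allele carries
about its population of origin is the mutual information between origin
and allele,

    SIC(m) = H(m p1 + (1-m) p2) - [m H(p1) + (1-m) H(p2)],

with H the base-2 Shannon entropy (0 log 0 := 0).  This is the reduction
in uncertainty about origin from observing the allele, in bits; it is zero
when the frequency vectors coincide, maximal for a fully diagnostic locus,
and scores alleles rare in one population highly (centrality).  The
maximum over m need not sit at 0.5: a locus can be better at identifying
members of one population within the other than vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


DEFAULT_M_GRID = np.linspace(0.01, 0.99, 99)


@dataclass
class SICProfile:
    locus_id: str
    pop_labels: tuple[str, str]
    m_grid: np.ndarray = field(repr=False)
    sic_values: np.ndarray = field(repr=False)
    m_star: float = 0.0
    sic_star: float = 0.0


def sic_profile(
    p1,
    p2,
    m_grid=None,
    locus_id: str = "locus",
    pop_labels: tuple[str, str] = ("pop1", "pop2"),
) -> SICProfile:
    """Information-content profile of one locus across admixture proportions.

    ``p1``/``p2`` are allele-frequency vectors over a shared allele set.
    The grid must lie strictly inside (0, 1).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("frequency vectors must cover the same allele set")
    for p in (p1, p2):
        if (p < 0).any() or not np.isclose(p.sum(), 1.0, atol=1e-6):
            raise ValueError("frequency vectors must each sum to 1")
    m_grid = DEFAULT_M_GRID if m_grid is None else np.asarray(m_grid, dtype=float)
    if m_grid.size == 0 or (m_grid <= 0).any() or (m_grid >= 1).any():
        raise ValueError("m grid must lie strictly inside (0, 1)")
    h1, h2 = _entropy_bits(p1), _entropy_bits(p2)
    sic = np.array(
        [
            _entropy_bits(m * p1 + (1 - m) * p2) - (m * h1 + (1 - m) * h2)
            for m in m_grid
        ]
    )
    sic = np.maximum(sic, 0.0)  # clip away negative rounding noise
    m_star, sic_star = max_sic_grid(m_grid, sic)
    return SICProfile(
        locus_id=locus_id,
        pop_labels=pop_labels,
        m_grid=m_grid,
        sic_values=sic,
        m_star=m_star,
        sic_star=sic_star,
    )


def max_sic_grid(m_grid: np.ndarray, sic_values: np.ndarray):
    """Grid argmax with ties broken toward m = 0.5."""
    if len(m_grid) == 0:
        raise ValueError("empty grid")
    best = sic_values.max()
    at_max = np.isclose(sic_values, best, rtol=0, atol=1e-12)
    candidates = m_grid[at_max]
    m_star = candidates[np.argmin(np.abs(candidates - 0.5))]
    return float(m_star), float(best)


def max_sic(profile: SICProfile):
    """(m_star, sic_star) of a computed profile."""
    return max_sic_grid(profile.m_grid, profile.sic_values)


def rank_loci(freqs1: dict, freqs2: dict, m_grid=None) -> pd.DataFrame:
    """Rank loci by maximum information content for one population pair.

    ``freqs1``/``freqs2`` map locus -> frequency vector (shared allele
    set per locus).  Descending by sic_star; ties broken lexicographically
    by locus id.  Loci monomorphic in both populations are retained with
    SIC 0 so rankings cover the full panel.
    """
    if not freqs1:
        raise ValueError("no loci supplied")
    if set(freqs1) != set(freqs2):
        raise ValueError("locus sets differ between populations")
    rows = []
    for locus in freqs1:
        prof = sic_profile(freqs1[locus], freqs2[locus], m_grid, locus_id=locus)
        rows.append(
            {"locus": locus, "m_star": prof.m_star, "sic_star": prof.sic_star}
        )
    df = pd.DataFrame(rows)
    return (
        df.sort_values(["sic_star", "locus"], ascending=[False, True])
        .reset_index(drop=True)
    )


def population_freqs(matrix: GenotypeMatrix, labels: dict):
    """Per-population per-locus frequencies over the union allele set.

    ``labels`` maps individual id -> population label.  Returns
    ``(freqs, sizes)`` where freqs is pop -> {locus -> vector} and sizes is
    pop -> number of individuals.  Frequencies use non-missing calls only.
    """
    from .ordination import group_allele_freqs

    freqs = group_allele_freqs(matrix, labels)
    sizes: dict = {}
    for pop in freqs:
        sizes[pop] = sum(1 for i in matrix.individual_ids if labels[i] == pop)
    return freqs, sizes


def evaluate_panel(
    panel,
    train_freqs: dict,
    train_sizes: dict,
    test_matrix: GenotypeMatrix,
    true_origins: dict,
    seed=None,
) -> float:
    """Assignment accuracy of a locus panel on labelled test individuals.

    Each test individual is assigned to the population maximising the
    product over panel loci of its genotype likelihood under that
    population's allele frequencies (HWE within populations; zero
    frequencies floored at 1/(2n+1)).  Ties are broken at random.  Returns
    the fraction of individuals assigned to their true origin.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("empty locus panel")
    pops = sorted(train_freqs)
    rng = np.random.default_rng(seed)

    def freq(pop, locus, code):
        vec = train_freqs[pop][locus]  # Series indexed by allele code
        floor = 1.0 / (2 * train_sizes[pop] + 1)
        return max(float(vec.get(code, 0.0)), floor)

    correct = 0
    total = 0
    for i, iid in enumerate(test_matrix.individual_ids):
        loglik = np.zeros(len(pops))
        informative = False
        for locus in panel:
            l = test_matrix.locus_index(locus)
            a, b = test_matrix.calls[i, l, :]
            if a == MISSING:
                continue
            informative = True
            for kp, pop in enumerate(pops):
                pa, pb = freq(pop, locus, a), freq(pop, locus, b)
                g = pa * pb * (2.0 if a != b else 1.0)
                loglik[kp] += np.log(g)
        if not informative:
            continue
        best = loglik.max()
        winners = np.flatnonzero(np.isclose(loglik, best, rtol=0, atol=1e-9))
        pick = pops[rng.choice(winners)]
        total += 1
        if pick == true_origins[iid]:
            correct += 1
    if total == 0:
        raise ValueError("no test individual typed at any panel locus")
    return correct / total
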