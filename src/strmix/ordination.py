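"""Ordination and distance-tree stages.

Correspondence analysis of the individuals x alleles dosage table (the
chi-square-metric ordination classically applied to genotype matrices),
the Cavalli-Sforza & Edwards chord distance between allele-frequency
profiles, and Saitou–Nei neighbor joining of locale distance matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix


def dosage_table(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Individuals x alleles count table (0/1/2 copies per allele).

    Missing calls contribute nothing, so row sums differ in the presence
    of missing data; correspondence analysis absorbs this through its row
    masses.
    """
    cols = {}
    for l, locus in enumerate(matrix.locus_ids):
        calls = matrix.calls[:, l, :]
        alleles = np.unique(calls[calls != MISSING])
        for a in alleles:
            cols[f"{locus}.{a}"] = (calls == a).sum(axis=1)
    return pd.DataFrame(cols, index=matrix.individual_ids)


def fca(matrix: GenotypeMatrix, n_axes: int | None = None):
    """Correspondence analysis of the genotype dosage table.

    Performs the chi-square-metric SVD of the standardized residual matrix
    of the dosage table.  Returns ``(coords, inertia_pct)``: principal row
    coordinates (individuals x axes, as a DataFrame) and the percentage of
    total inertia carried by each retained axis.  Axis signs are fixed by
    forcing the largest-magnitude column loading positive.
    """
    if matrix.n_individuals < 3:
        raise ValueError("correspondence analysis needs at least 3 individuals")
    X = dosage_table(matrix).to_numpy(dtype=float)
    keep = X.sum(axis=0) > 0
    X = X[:, keep]
    total = X.sum()
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r == 0).any():
        raise ValueError("an individual has no non-missing calls")
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    nz = sv > 1e-12
    if not nz.any():
        raise ValueError("no polymorphism: total inertia is zero")
    U, sv, Vt = U[:, nz], sv[nz], Vt[nz]
    if n_axes is not None:
        U, sv, Vt = U[:, :n_axes], sv[:n_axes], Vt[:n_axes]
    # principal coordinates; sign fixed from the column loadings
    for j in range(len(sv)):
        if Vt[j, np.argmax(np.abs(Vt[j]))] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    rows = (U * sv) / np.sqrt(r)[:, None]
    eig = sv**2
    inertia_pct = 100.0 * eig / eig.sum()
    coords = pd.DataFrame(
        rows,
        index=pd.Index(matrix.individual_ids, name="individual_id"),
        columns=[f"axis_{j + 1}" for j in range(rows.shape[1])],
    )
    return coords, inertia_pct


def chord_distance(freqs_a, freqs_b, angular: bool = False) -> float:
    """Multi-locus chord distance between two allele-frequency profiles.

    ``freqs_a``/``freqs_b`` map locus -> frequency vector over the union
    allele set (each summing to 1).  Per locus
    d_l = sqrt(2 (1 - sum_j sqrt(p_Aj p_Bj))) and loci are combined by
    root-mean-square.  ``angular=True`` applies the classical 2/pi
    normalisation to each per-locus term.
    """
    if set(freqs_a) != set(freqs_b):
        raise ValueError("locus sets differ between the two profiles")
    if not freqs_a:
        raise ValueError("empty frequency profile")
    d2 = []
    for locus in freqs_a:
        pa = np.asarray(freqs_a[locus], dtype=float)
        pb = np.asarray(freqs_b[locus], dtype=float)
        if pa.shape != pb.shape:
            raise ValueError(f"allele sets differ at locus {locus!r}")
        for p in (pa, pb):
            if (p < 0).any() or not np.isclose(p.sum(), 1.0, atol=1e-6):
                raise ValueError(f"frequencies at {locus!r} do not sum to 1")
        cos_theta = np.clip(np.sum(np.sqrt(pa * pb)), 0.0, 1.0)
        d = np.sqrt(2.0 * (1.0 - cos_theta))
        if angular:
            d *= 2.0 / np.pi
        d2.append(d * d)
    return float(np.sqrt(np.mean(d2)))


def group_allele_freqs(matrix: GenotypeMatrix, groups) -> dict:
    """Per-group per-locus frequency vectors over the union allele set.

    ``groups`` maps each individual id to a group label (e.g. locale).
    Returns group -> {locus -> pd.Series indexed by allele code}; all
    groups share the matrix-wide union allele set per locus, so vectors
    are aligned.  Loci with no data in a group get a uniform vector (no
    information, rather than a crash).
    """
    labels = [groups[i] for i in matrix.individual_ids]
    uniq = sorted(set(labels))
    out: dict = {g: {} for g in uniq}
    idx = {g: [i for i, lab in enumerate(labels) if lab == g] for g in uniq}
    for l, locus in enumerate(matrix.locus_ids):
        col = matrix.calls[:, l, :]
        union = np.unique(col[col != MISSING])
        pos = {a: j for j, a in enumerate(union)}
        for g in uniq:
            sub = col[idx[g]]
            sub = sub[sub != MISSING]
            v = np.zeros(len(union))
            if sub.size:
                for a in sub:
                    v[pos[a]] += 1
                v /= v.sum()
            else:
                v[:] = 1.0 / max(len(union), 1)
            out[g][locus] = pd.Series(v, index=union, name=locus)
    return out


def chord_distance_matrix(
    matrix: GenotypeMatrix, table: pd.DataFrame, angular: bool = False
):
    """Pairwise chord distances between locales. Returns (labels, D)."""
    groups = dict(zip(table["individual_id"], table["locale"]))
    freqs = group_allele_freqs(matrix, groups)
    labels = sorted(freqs)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = chord_distance(
                freqs[labels[i]], freqs[labels[j]], angular=angular
            )
    return labels, D


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(
            f"{child.newick()}:{bl:.10g}" for child, bl in self.children
        )
        return f"({inner})"


def neighbor_joining(D, labels) -> str:
    """Saitou–Nei neighbor joining; returns an unrooted newick string.

    Negative branch lengths are clamped to zero with the deficit shifted
    to the sister edge, preserving the pairwise path length.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix does not match label count")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distance matrix must be non-negative")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    nodes = [_Node(label=str(l)) for l in labels]
    D = D.copy()
    active = list(range(n))

    def clamp(bl_i, bl_j):
        if bl_i < 0:
            bl_j += -bl_i
            bl_i = 0.0
        if bl_j < 0:
            bl_i += -bl_j
            bl_j = 0.0
        return bl_i, bl_j

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        rsum = sub.sum(axis=1)
        Qm = (m - 2) * sub - rsum[:, None] - rsum[None, :]
        np.fill_diagonal(Qm, np.inf)
        i_, j_ = np.unravel_index(np.argmin(Qm), Qm.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        a, b = active[i_], active[j_]
        d_ab = D[a, b]
        bl_a = 0.5 * d_ab + (rsum[i_] - rsum[j_]) / (2.0 * (m - 2))
        bl_b = d_ab - bl_a
        bl_a, bl_b = clamp(bl_a, bl_b)
        new = _Node(children=[(nodes[a], bl_a), (nodes[b], bl_b)])
        # distances from the new node
        d_new = 0.5 * (D[a, active] + D[b, active] - d_ab)
        D = np.pad(D, ((0, 1), (0, 1)))
        k = D.shape[0] - 1
        D[k, active] = d_new
        D[active, k] = d_new
        D[k, k] = 0.0
        nodes.append(new)
        active = [x for x in active if x not in (a, b)] + [k]

    a, b, c = active
    bl_a = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    bl_b = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    bl_c = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    bl = [max(x, 0.0) for x in (bl_a, bl_b, bl_c)]
    root = _Node(children=[(nodes[a], bl[0]), (nodes[b], bl[1]), (nodes[c], bl[2])])
    return root.newick() + ";"


def tip_bipartition(newick: str, group_a: set[str]) -> bool:
    """True if some edge of the (midpoint-rooted) tree splits the tips
    exactly into ``group_a`` vs the rest."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    taxa = {t.label for t in tree.taxon_namespace}
    group_b = taxa - set(group_a)
    tree.encode_bipartitions()
    for edge in tree.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        side = {
            t.label
            for t in tree.taxon_namespace
            if edge.bipartition.leafset_bitmask
            & tree.taxon_namespace.taxon_bitmask(t)
        }
        if side == set(group_a) or side == group_b:
            return True
    return False
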