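"""Mito-nuclear discordance: per-locale clade frequencies, the concordance
of maternal-clade proportions against nuclear cluster means, and an exact
habitat x clade association test.

In a system with sex-biased introgression, the maternally inherited marker
(mtDNA clade) can be decoupled from the nuclear genome: repeated
backcrossing of hybrid females into one species leaves that species'
populations carrying the other species' mtDNA while their nuclear ancestry
stays essentially pure.  The functions here quantify that signature at the
locale level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln


def clade_frequencies(table: pd.DataFrame) -> pd.Series:
    """Per-locale proportion of S-clade mtDNA among classified individuals.

    Individuals with clade 'unknown' are excluded from the denominator; a
    locale with zero classified individuals gets NaN (missing), not zero.
    """
    bad = set(table["mt_clade"]) - {"F", "S", "unknown"}
    if bad:
        raise ValueError(f"unknown clade labels: {sorted(bad)}")
    known = table[table["mt_clade"].isin(["F", "S"])]
    counts = known.groupby("locale").size()
    s_counts = known[known["mt_clade"] == "S"].groupby("locale").size()
    props = (s_counts.reindex(counts.index, fill_value=0) / counts).astype(float)
    return props.reindex(sorted(table["locale"].unique())).rename("s_clade_proportion")


def locale_summaries(
    table: pd.DataFrame, locale_q: pd.DataFrame, savanna_col: str = "q_2"
) -> pd.DataFrame:
    """Join clade frequencies with mean nuclear cluster membership.

    ``locale_q`` is the per-locale Q-mean table (from
    :func:`strmix.admixture.mean_cluster_by_locale`); ``savanna_col``
    names the Q column of the savanna-like cluster.  Returns one row per
    locale: habitat, n, s_clade_proportion, mean_savanna_q,
    s_clade_present.
    """
    props = clade_frequencies(table)
    hab = table.groupby("locale")["habitat"].agg(
        lambda s: s.mode().iloc[0]
    )
    n = table.groupby("locale").size().rename("n")
    q = locale_q.set_index("locale")[savanna_col].rename("mean_savanna_q")
    out = pd.concat([hab, n, props, q], axis=1).reset_index()
    missing_q = out["mean_savanna_q"].isna()
    if missing_q.any():
        raise ValueError(
            f"locales missing from Q table: {list(out.loc[missing_q, 'locale'])}"
        )
    out["s_clade_present"] = out["s_clade_proportion"].fillna(0.0) > 0.0
    return out


def concordance_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Deviation of nuclear ancestry from the clade-proportion diagonal.

    Under strict mito-nuclear concordance a locale's mean savanna nuclear
    membership would equal its S-clade proportion (the diagonal).  The
    deviation mean_savanna_q - s_clade_proportion is the discordance
    signature: savanna locales fixed for introgressed F-clade mtDNA sit
    near deviation +1.
    """
    required = {"locale", "s_clade_proportion", "mean_savanna_q"}
    if not required <= set(summaries.columns):
        raise ValueError(f"summaries must carry columns {sorted(required)}")
    out = summaries.copy()
    out["deviation"] = out["mean_savanna_q"] - out["s_clade_proportion"]
    return out


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact test of a 2x2 table [[a, b], [c, d]].

    Enumerates all tables with the observed margins; the two-tailed p is
    the total probability of tables whose hypergeometric probability does
    not exceed the observed table's (within 1e-12 relative slack).
    Log-gamma arithmetic keeps the enumeration exact at realistic N.
    """
    for x in (a, b, c, d):
        if not float(x).is_integer() or x < 0:
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("a zero row or column margin makes the test undefined")

    def log_p(x: int) -> float:
        # P(X = x) for X hypergeometric with margins (r1, r2 | c1, c2)
        return (
            gammaln(r1 + 1)
            - gammaln(x + 1)
            - gammaln(r1 - x + 1)
            + gammaln(r2 + 1)
            - gammaln(c1 - x + 1)
            - gammaln(r2 - c1 + x + 1)
            - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    lp_obs = log_p(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_p(x)
        if lp <= lp_obs + 1e-12 * abs(lp_obs) + 1e-12:
            total += float(np.exp(lp))
    return min(1.0, total)


def habitat_association(summaries: pd.DataFrame):
    """Exact test of S-clade presence against habitat class.

    Rows: S clade present / not detected; columns: tropical forest /
    other-or-mixed (mixed-habitat locales group with non-forest).  A
    locale counts as S-present if at least one classified individual
    carries S.  Returns ``(table, p)`` with table a 2x2 int array.
    """
    required = {"locale", "habitat", "s_clade_present"}
    if not required <= set(summaries.columns):
        raise ValueError(f"summaries must carry columns {sorted(required)}")
    forest = summaries["habitat"] == "forest"
    present = summaries["s_clade_present"].astype(bool)
    if forest.all() or (~forest).all():
        raise ValueError("need locales on both habitat sides")
    table = np.array(
        [
            [int((present & forest).sum()), int((present & ~forest).sum())],
            [int((~present & forest).sum()), int((~present & ~forest).sum())],
        ]
    )
    p = fisher_exact_2x2(*table.ravel())
    return table, p
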