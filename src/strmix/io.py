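"""Genotype containers and text-format readers/writers for STR data.

The two dialects supported are the plain-text layouts consumed by the
classic microsatellite toolchain: the STRUCTURE input format (two rows per
individual, or two columns per locus) and GenePop 4.x.  Allele calls are
integer codes (typically fragment sizes in base pairs); the missing
sentinel is -9 internally, following the STRUCTURE convention, and 00/000
in GenePop files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -9

HABITAT_CLASSES = ("forest", "savanna", "mixed")


class ParseError(ValueError):
    """Raised when an input file violates its dialect; names the line."""


@dataclass
class GenotypeMatrix:
    """Diploid multi-allelic genotypes: individuals x loci x 2 allele codes.

    ``calls`` has shape (n_individuals, n_loci, 2) with positive integer
    allele codes, or both entries equal to :data:`MISSING` for a missing
    call.  Allele pairs are stored unordered (sorted ascending): phase is
    never used downstream.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.individual_ids), len(self.locus_ids)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} individuals x {L} loci x 2"
            )
        a, b = self.calls[..., 0], self.calls[..., 1]
        half_missing = (a == MISSING) ^ (b == MISSING)
        if half_missing.any():
            raise ValueError("a call must have both alleles present or both missing")
        valid = self.calls[self.calls != MISSING]
        if valid.size and (valid <= 0).any():
            raise ValueError("allele codes must be positive integers")
        # canonical unordered storage
        self.calls = np.sort(self.calls, axis=2)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) mask of missing calls."""
        return self.calls[..., 0] == MISSING

    def locus_index(self, locus_id: str) -> int:
        try:
            return self.locus_ids.index(locus_id)
        except ValueError:
            raise KeyError(f"locus {locus_id!r} not in matrix") from None

    def locus_calls(self, locus_id: str) -> np.ndarray:
        """Non-missing allele pairs (m, 2) at one locus."""
        j = self.locus_index(locus_id)
        col = self.calls[:, j, :]
        return col[col[:, 0] != MISSING]

    def subset_loci(self, locus_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.locus_index(l) for l in locus_ids]
        return GenotypeMatrix(
            list(self.individual_ids), list(locus_ids), self.calls[:, idx, :]
        )

    def subset_individuals(self, individual_ids: list[str]) -> "GenotypeMatrix":
        pos = {iid: i for i, iid in enumerate(self.individual_ids)}
        idx = [pos[i] for i in individual_ids]
        return GenotypeMatrix(
            list(individual_ids), list(self.locus_ids), self.calls[idx]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls)
        )


def make_sample_table(
    individual_ids,
    locales,
    habitats=None,
    regions=None,
    mt_clades=None,
) -> pd.DataFrame:
    """Assemble the per-individual metadata table.

    Columns: individual_id, locale, habitat (forest/savanna/mixed or
    unknown), region, mt_clade (F/S/unknown).
    """
    n = len(individual_ids)

    def col(x, default):
        return list(x) if x is not None else [default] * n

    table = pd.DataFrame(
        {
            "individual_id": list(individual_ids),
            "locale": list(locales),
            "habitat": col(habitats, "unknown"),
            "region": col(regions, "unknown"),
            "mt_clade": col(mt_clades, "unknown"),
        }
    )
    bad = set(table["habitat"]) - set(HABITAT_CLASSES) - {"unknown"}
    if bad:
        raise ValueError(f"unknown habitat classes: {sorted(bad)}")
    bad = set(table["mt_clade"]) - {"F", "S", "unknown"}
    if bad:
        raise ValueError(f"unknown mtDNA clade labels: {sorted(bad)}")
    return table


@dataclass
class LocusSummary:
    locus_id: str
    n_typed: int
    allele_codes: list[int] = field(repr=False)
    allele_freqs: np.ndarray = field(repr=False)
    n_alleles: int = 0
    ho: float = 0.0
    he: float = 0.0


def allele_frequencies(matrix: GenotypeMatrix, locus_id: str) -> pd.Series:
    """Allele frequencies at one locus from non-missing calls."""
    pairs = matrix.locus_calls(locus_id)
    if pairs.size == 0:
        raise ValueError(f"locus {locus_id!r} has no non-missing calls")
    codes, counts = np.unique(pairs.ravel(), return_counts=True)
    return pd.Series(counts / counts.sum(), index=codes, name=locus_id)


def summarize_locus(matrix: GenotypeMatrix, locus_id: str) -> LocusSummary:
    """Allele count/frequencies, observed and expected heterozygosity.

    He = 1 - sum(p_i^2); Ho = fraction heterozygous among non-missing calls.
    """
    pairs = matrix.locus_calls(locus_id)
    if pairs.size == 0:
        raise ValueError(f"locus {locus_id!r} has no non-missing calls")
    freqs = allele_frequencies(matrix, locus_id)
    he = float(1.0 - np.sum(freqs.values**2))
    ho = float(np.mean(pairs[:, 0] != pairs[:, 1]))
    return LocusSummary(
        locus_id=locus_id,
        n_typed=len(pairs),
        allele_codes=[int(c) for c in freqs.index],
        allele_freqs=freqs.values.copy(),
        n_alleles=len(freqs),
        ho=ho,
        he=he,
    )


# ---------------------------------------------------------------------------
# STRUCTURE format
# ---------------------------------------------------------------------------


def write_structure(
    matrix: GenotypeMatrix,
    path,
    table: pd.DataFrame | None = None,
    layout: str = "two-row",
) -> None:
    """Write a STRUCTURE input file.

    ``two-row`` layout: header of locus names, then two lines per
    individual (one allele per locus per line).  ``two-column`` layout: one
    line per individual with 2 columns per locus.  When ``table`` is given,
    a numeric population column (locale rank) follows the individual label.
    """
    if layout not in ("two-row", "two-column"):
        raise ValueError(f"unknown layout {layout!r}")
    pop_codes = None
    if table is not None:
        t = table.set_index("individual_id")
        locales = sorted(t["locale"].unique())
        rank = {loc: i + 1 for i, loc in enumerate(locales)}
        pop_codes = {iid: rank[t.at[iid, "locale"]] for iid in matrix.individual_ids}
    lines = ["\t".join(matrix.locus_ids)]
    for i, iid in enumerate(matrix.individual_ids):
        lead = [iid] + ([str(pop_codes[iid])] if pop_codes else [])
        if layout == "two-row":
            for c in (0, 1):
                lines.append("\t".join(lead + [str(a) for a in matrix.calls[i, :, c]]))
        else:
            flat = matrix.calls[i].reshape(-1)
            lines.append("\t".join(lead + [str(a) for a in flat]))
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_structure(path, layout: str = "two-row"):
    """Read a STRUCTURE input file written in either supported layout.

    Returns ``(GenotypeMatrix, SampleTable)``; the table carries locale
    codes only when the file has a population column, otherwise 'unknown'.
    """
    if layout not in ("two-row", "two-column"):
        raise ValueError(f"unknown layout {layout!r}")
    with open(path) as fh:
        raw = [ln.rstrip("\n") for ln in fh]
    rows = [(k + 1, ln.split()) for k, ln in enumerate(raw) if ln.strip()]
    if len(rows) < 2:
        raise ParseError("file has no data rows")
    locus_ids = rows[0][1]
    L = len(locus_ids)
    data_rows = rows[1:]
    per_ind = 2 if layout == "two-row" else 1
    if len(data_rows) % per_ind:
        raise ParseError(
            f"line {data_rows[-1][0]}: odd row count for two-row layout"
        )
    n_alleles = L if layout == "two-row" else 2 * L
    first_width = len(data_rows[0][1])
    has_pop = first_width == n_alleles + 2
    if not has_pop and first_width != n_alleles + 1:
        raise ParseError(
            f"line {data_rows[0][0]}: expected {n_alleles + 1} or "
            f"{n_alleles + 2} fields, found {first_width}"
        )
    ids: list[str] = []
    pops: list[str] = []
    calls = []
    for g in range(0, len(data_rows), per_ind):
        group = data_rows[g : g + per_ind]
        lineno0, tok0 = group[0]
        for lineno, tok in group:
            if len(tok) != first_width:
                raise ParseError(f"line {lineno}: ragged row ({len(tok)} fields)")
        iid = tok0[0]
        for lineno, tok in group[1:]:
            if tok[0] != iid:
                raise ParseError(
                    f"line {lineno}: individual label {tok[0]!r} does not pair "
                    f"with {iid!r}"
                )
        if iid in ids:
            raise ParseError(f"line {lineno0}: individual {iid!r} appears more "
                             "than twice")
        ids.append(iid)
        pops.append(tok0[1] if has_pop else "unknown")
        off = 2 if has_pop else 1
        try:
            if layout == "two-row":
                a = [int(x) for x in group[0][1][off:]]
                b = [int(x) for x in group[1][1][off:]]
                pair = np.stack([a, b], axis=1)
            else:
                flat = [int(x) for x in tok0[off:]]
                pair = np.asarray(flat).reshape(L, 2)
        except ValueError as exc:
            raise ParseError(f"line {lineno0}: non-integer allele token ({exc})")
        calls.append(pair)
    matrix = GenotypeMatrix(ids, list(locus_ids), np.stack(calls))
    table = make_sample_table(ids, pops)
    return matrix, table


# ---------------------------------------------------------------------------
# GenePop format
# ---------------------------------------------------------------------------


def write_genepop(
    matrix: GenotypeMatrix,
    table: pd.DataFrame,
    path,
    digits: int = 3,
    title: str = "strmix export",
) -> None:
    """Write GenePop 4.x text: title, locus list, Pop blocks by locale."""
    if digits not in (2, 3):
        raise ValueError("GenePop allele codes are 2 or 3 digits wide")
    limit = 10**digits - 1
    valid = matrix.calls[matrix.calls != MISSING]
    if valid.size and valid.max() > limit:
        raise ValueError(
            f"allele code {valid.max()} exceeds {digits}-digit GenePop width"
        )
    t = table.set_index("individual_id")
    lines = [title]
    lines.extend(matrix.locus_ids)
    by_locale: dict[str, list[int]] = {}
    for i, iid in enumerate(matrix.individual_ids):
        by_locale.setdefault(str(t.at[iid, "locale"]), []).append(i)
    for locale in by_locale:
        lines.append("Pop")
        for i in by_locale[locale]:
            genos = []
            for j in range(matrix.n_loci):
                a, b = matrix.calls[i, j]
                if a == MISSING:
                    a = b = 0
                genos.append(f"{a:0{digits}d}{b:0{digits}d}")
            lines.append(f"{matrix.individual_ids[i]} ,  " + " ".join(genos))
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_genepop(path):
    """Read GenePop text; Pop blocks become locales POP1, POP2, ...

    Returns ``(GenotypeMatrix, SampleTable)``.
    """
    with open(path) as fh:
        raw = [ln.rstrip("\n") for ln in fh]
    if not raw:
        raise ParseError("empty GenePop file")
    lines = [(k, ln) for k, ln in enumerate(raw[1:], start=2) if ln.strip()]
    locus_ids: list[str] = []
    i = 0
    while i < len(lines) and lines[i][1].strip().lower() != "pop":
        # locus names may also be comma-separated on one line
        locus_ids.extend(
            s.strip() for s in lines[i][1].split(",") if s.strip()
        )
        i += 1
    if i == len(lines):
        raise ParseError("no 'Pop' separator found")
    L = len(locus_ids)
    ids, locales, calls = [], [], []
    pop = 0
    while i < len(lines):
        lineno, ln = lines[i]
        if ln.strip().lower() == "pop":
            pop += 1
            i += 1
            continue
        if "," not in ln:
            raise ParseError(f"line {lineno}: missing ',' after individual label")
        label, geno_part = ln.split(",", 1)
        tokens = geno_part.split()
        if len(tokens) != L:
            raise ParseError(
                f"line {lineno}: expected {L} genotypes, found {len(tokens)}"
            )
        width = len(tokens[0])
        if width not in (4, 6):
            raise ParseError(
                f"line {lineno}: genotype token {tokens[0]!r} is not 4 or 6 "
                "digits"
            )
        digits = width // 2
        pair = np.empty((L, 2), dtype=np.int64)
        for j, tok in enumerate(tokens):
            if len(tok) != width or not tok.isdigit():
                raise ParseError(f"line {lineno}: bad genotype token {tok!r}")
            a, b = int(tok[:digits]), int(tok[digits:])
            if a == 0 or b == 0:
                a = b = MISSING
            pair[j] = (a, b)
        ids.append(label.strip())
        locales.append(f"POP{pop}")
        calls.append(pair)
        i += 1
    if not ids:
        raise ParseError("no individuals found")
    matrix = GenotypeMatrix(ids, locus_ids, np.stack(calls))
    return matrix, make_sample_table(ids, locales)


def write_sample_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_sample_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual_id", "locale"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"sample table lacks columns: {sorted(missing)}")
    for col in ("habitat", "region", "mt_clade"):
        if col not in table.columns:
            table[col] = "unknown"
    return table


# ---------------------------------------------------------------------------
# Fragment-size binning
# ---------------------------------------------------------------------------


def bin_alleles(raw_sizes, motif_length: int):
    """Cluster raw fragment sizes onto an integer allele ladder.

    Sizes are assigned to the rungs of a ladder with spacing
    ``motif_length``; the ladder offset is chosen on a 0.1-base grid over
    [0, motif_length) to minimise the total absolute deviation of sizes
    from their assigned rungs.  Returns ``(codes, unbinnable)`` where codes
    are rung centers rounded to integers and unbinnable flags sizes
    farther than motif_length/2 from every rung after fitting (reported,
    coded as :data:`MISSING`).
    """
    sizes = np.asarray(raw_sizes, dtype=float)
    if sizes.ndim != 1 or sizes.size == 0:
        raise ValueError("raw_sizes must be a non-empty 1-D sequence")
    if (sizes <= 0).any():
        raise ValueError("fragment sizes must be positive")
    if motif_length not in (2, 3, 4, 5, 6):
        raise ValueError("motif_length must be in {2,3,4,5,6}")
    m = motif_length
    offsets = np.arange(0.0, m, 0.1)
    # residual of each size from its nearest rung at each candidate offset
    resid = sizes[None, :] - offsets[:, None]
    dev = np.abs(resid - np.round(resid / m) * m)
    totals = dev.sum(axis=1)
    best = int(np.argmin(totals))
    offset = offsets[best]
    rungs = np.round((sizes - offset) / m) * m + offset
    deviation = np.abs(sizes - rungs)
    unbinnable = deviation > m / 2
    codes = np.rint(rungs).astype(np.int64)
    codes[unbinnable] = MISSING
    return codes, unbinnable
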