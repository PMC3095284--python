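"""Data model and I/O for multilocus codominant diploid genotypes.

The central container is :class:`GenotypeMatrix`: *n* accessions scored at
*L* codominant loci (microsatellites in the motivating use case), each cell
holding an unordered pair of integer allele codes.  Allele codes are opaque
labels -- SSR fragment sizes or arbitrary integers -- no numeric meaning is
ever assumed.  A cell is either wholly typed or wholly missing (sentinel
``-9`` for both copies); half-calls are rejected because codominant SSR
scoring produces none.

Two on-disk dialects are supported:

* ``csv`` -- header ``accession,group,<LOCUS>.1,<LOCUS>.2,...`` with the
  ``group`` column optional; read and write.
* ``structure`` -- the classic two-columns-per-locus, one-row-per-individual
  layout with an optional population column; read only.
"""

from __future__ import annotations

import csv as _csv
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING = -9
"""Missing-data sentinel used for both allele copies of an untyped cell."""


class ParseError(ValueError):
    """Malformed genotype/phenotype input; carries file and line context."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


def _as_id_list(ids: Iterable, what: str) -> list[str]:
    out = [str(x) for x in ids]
    if len(set(out)) != len(out):
        dupes = sorted({x for x in out if out.count(x) > 1})
        raise ValueError(f"duplicate {what}: {dupes[:5]}")
    return out


@dataclass(eq=False)
class GenotypeMatrix:
    """Diploid multilocus genotypes for an ordered set of accessions.

    Parameters
    ----------
    accession_ids
        Unique accession identifiers, in input order.
    locus_names
        Unique locus names, in input order.
    calls
        Integer array of shape ``(n, L, 2)``.  Non-missing entries are
        allele codes ``>= 0``; missing cells carry :data:`MISSING` in both
        positions.
    """

    accession_ids: list[str]
    locus_names: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.accession_ids = _as_id_list(self.accession_ids, "accession id")
        self.locus_names = _as_id_list(self.locus_names, "locus name")
        calls = np.asarray(self.calls)
        if calls.ndim != 3 or calls.shape[2] != 2:
            raise ValueError(
                f"calls must have shape (n, L, 2); got {calls.shape} -- "
                "only diploid data are supported"
            )
        if calls.shape[0] != len(self.accession_ids):
            raise ValueError("calls row count does not match accession_ids")
        if calls.shape[1] != len(self.locus_names):
            raise ValueError("calls locus count does not match locus_names")
        if not np.issubdtype(calls.dtype, np.integer):
            if not np.all(calls == np.round(calls)):
                raise ValueError("allele codes must be integers")
            calls = calls.astype(np.int32)
        self.calls = np.ascontiguousarray(calls, dtype=np.int32)
        a, b = self.calls[..., 0], self.calls[..., 1]
        half = (a == MISSING) ^ (b == MISSING)
        if half.any():
            i, l = np.argwhere(half)[0]
            raise ValueError(
                f"half-missing call at accession {self.accession_ids[i]!r}, "
                f"locus {self.locus_names[l]!r}: a cell is wholly typed or wholly missing"
            )
        bad = (self.calls < 0) & (self.calls != MISSING)
        if bad.any():
            raise ValueError("allele codes must be >= 0 (missing sentinel -9)")
        self._index = {aid: i for i, aid in enumerate(self.accession_ids)}
        self._locus_index = {name: j for j, name in enumerate(self.locus_names)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def index_of(self, accession: str | int) -> int:
        if isinstance(accession, (int, np.integer)):
            i = int(accession)
            if not 0 <= i < self.n_accessions:
                raise KeyError(f"accession index {i} out of range")
            return i
        try:
            return self._index[str(accession)]
        except KeyError:
            raise KeyError(f"unknown accession {accession!r}") from None

    def locus_index(self, locus: str | int) -> int:
        if isinstance(locus, (int, np.integer)):
            j = int(locus)
            if not 0 <= j < self.n_loci:
                raise KeyError(f"locus index {j} out of range")
            return j
        try:
            return self._locus_index[str(locus)]
        except KeyError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def typed_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` array: True where the cell is typed."""
        return self.calls[..., 0] != MISSING

    def subset(self, accessions: Iterable[str | int]) -> "GenotypeMatrix":
        """New matrix restricted to the given accessions, keeping this
        matrix's ordering."""
        idx = sorted({self.index_of(a) for a in accessions})
        if not idx:
            raise ValueError("empty accession subset")
        return GenotypeMatrix(
            [self.accession_ids[i] for i in idx],
            list(self.locus_names),
            self.calls[idx].copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Equality up to within-cell allele order."""
        if (
            self.accession_ids != other.accession_ids
            or self.locus_names != other.locus_names
        ):
            return False
        return bool(
            np.array_equal(np.sort(self.calls, axis=2), np.sort(other.calls, axis=2))
        )


@dataclass
class GroupAssignment:
    """A-priori stratification: mapping accession id -> group label."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}

    def labels(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for v in self.mapping.values():
            seen.setdefault(v, None)
        return list(seen)

    def members(self, label: str) -> list[str]:
        return [a for a, g in self.mapping.items() if g == str(label)]

    def validate_against(self, G: GenotypeMatrix) -> None:
        unknown = [a for a in self.mapping if a not in G._index]
        if unknown:
            raise ValueError(f"group assignment references unknown accessions: {unknown[:5]}")


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele counts and frequencies over a set of accessions.

    ``counts[l]`` maps allele code -> number of allele copies observed at
    locus ``l``; ``n[l]`` is the number of accessions typed at that locus,
    so each count is out of ``2 * n[l]`` copies.
    """

    locus_names: list[str]
    counts: list[dict[int, int]]
    n: np.ndarray  # typed accessions per locus

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)
        if len(self.counts) != len(self.locus_names) or len(self.n) != len(self.locus_names):
            raise ValueError("counts/n length must match locus_names")

    def locus_index(self, locus: str | int) -> int:
        if isinstance(locus, (int, np.integer)):
            return int(locus)
        return self.locus_names.index(str(locus))

    def frequencies(self, locus: str | int) -> dict[int, float]:
        l = self.locus_index(locus)
        tot = 2 * self.n[l]
        return {a: c / tot for a, c in self.counts[l].items()}

    def frequency(self, locus: str | int, allele: int) -> float:
        return self.frequencies(locus).get(int(allele), 0.0)

    def allele_count(self, locus: str | int) -> int:
        return len(self.counts[self.locus_index(locus)])

    @property
    def total_alleles(self) -> int:
        return sum(len(c) for c in self.counts)


@dataclass
class PhenotypeTable:
    """Replicated quantitative trait values keyed by accession id."""

    values: dict[str, list[float]]

    def __post_init__(self) -> None:
        clean: dict[str, list[float]] = {}
        for k, v in self.values.items():
            vals = [float(x) for x in v]
            if not vals:
                raise ValueError(f"accession {k!r} has no replicate values")
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite trait value for accession {k!r}")
            clean[str(k)] = vals
        self.values = clean

    def pooled(self) -> np.ndarray:
        return np.concatenate([np.asarray(v) for v in self.values.values()])

    def accession_means(self) -> dict[str, float]:
        return {k: float(np.mean(v)) for k, v in self.values.items()}


# ---------------------------------------------------------------------------
# Frequency bookkeeping
# ---------------------------------------------------------------------------

def _resolve_subset(G: GenotypeMatrix, subset) -> list[int]:
    if subset is None:
        return list(range(G.n_accessions))
    idx = sorted({G.index_of(a) for a in subset})
    if not idx:
        raise ValueError("empty accession subset")
    return idx


def allele_frequencies(G: GenotypeMatrix, subset=None) -> AlleleFrequencyTable:
    """Pool both allele copies per typed cell into per-locus counts.

    Missing cells are excluded from that locus's denominator (per-locus
    pairwise deletion).  A locus entirely untyped within the subset is an
    error because its frequencies are undefined.
    """
    idx = _resolve_subset(G, subset)
    calls = G.calls[idx]
    typed = calls[..., 0] != MISSING
    counts: list[dict[int, int]] = []
    n_l = typed.sum(axis=0)
    for l, name in enumerate(G.locus_names):
        if n_l[l] == 0:
            raise ValueError(f"locus {name!r} has no typed accessions in subset")
        cell = calls[typed[:, l], l, :]
        alleles, c = np.unique(cell, return_counts=True)
        counts.append({int(a): int(k) for a, k in zip(alleles, c)})
    return AlleleFrequencyTable(list(G.locus_names), counts, n_l)


def count_distinct_alleles(G: GenotypeMatrix, subset=None) -> tuple[int, dict[str, int]]:
    """Total and per-locus numbers of distinct observed alleles."""
    table = allele_frequencies(G, subset)
    per_locus = {name: len(c) for name, c in zip(table.locus_names, table.counts)}
    return table.total_alleles, per_locus


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_allele(token: str, path: str, line: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(f"allele code {token!r} is not an integer", path, line) from None


def _read_csv_dialect(path: str) -> tuple[GenotypeMatrix, GroupAssignment | None]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = _csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file", path, 1) from None
        header = [h.strip() for h in header]
        if not header or header[0] != "accession":
            raise ParseError("first header column must be 'accession'", path, 1)
        has_group = len(header) > 1 and header[1] == "group"
        first_locus_col = 2 if has_group else 1
        locus_cols = header[first_locus_col:]
        if len(locus_cols) == 0 or len(locus_cols) % 2 != 0:
            raise ParseError(
                "locus columns must come in '<LOCUS>.1,<LOCUS>.2' pairs "
                f"(got {len(locus_cols)} locus columns)",
                path,
                1,
            )
        locus_names: list[str] = []
        for j in range(0, len(locus_cols), 2):
            c1, c2 = locus_cols[j], locus_cols[j + 1]
            if not (c1.endswith(".1") and c2.endswith(".2") and c1[:-2] == c2[:-2]):
                raise ParseError(
                    f"locus column pair {c1!r},{c2!r} must be '<LOCUS>.1','<LOCUS>.2'",
                    path,
                    1,
                )
            locus_names.append(c1[:-2])

        ids: list[str] = []
        groups: dict[str, str] = {}
        rows: list[list[int]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"expected {len(header)} fields, found {len(row)}", path, lineno
                )
            aid = row[0].strip()
            if aid in set(ids):
                raise ParseError(f"duplicate accession id {aid!r}", path, lineno)
            ids.append(aid)
            if has_group:
                groups[aid] = row[1].strip()
            alleles = [
                _parse_allele(tok.strip(), path, lineno) for tok in row[first_locus_col:]
            ]
            rows.append(alleles)
        if not ids:
            raise ParseError("no accessions (header only)", path, 1)
    calls = np.asarray(rows, dtype=np.int32).reshape(len(ids), len(locus_names), 2)
    G = GenotypeMatrix(ids, locus_names, calls)
    return G, (GroupAssignment(groups) if has_group else None)


def _read_structure_dialect(path: str) -> tuple[GenotypeMatrix, GroupAssignment | None]:
    with open(path, encoding="utf-8") as fh:
        raw = [ln.rstrip("\n") for ln in fh]
    lines = [(i + 1, ln.split()) for i, ln in enumerate(raw) if ln.strip()]
    if not lines:
        raise ParseError("empty file", path, 1)

    def _is_int(tok: str) -> bool:
        try:
            int(tok)
            return True
        except ValueError:
            return False

    locus_names: list[str] | None = None
    first = lines[0][1]
    # A header line of locus names contains non-integer tokens only.
    if not any(_is_int(t) for t in first):
        locus_names = first
        lines = lines[1:]
        if not lines:
            raise ParseError("no accessions (header only)", path, 1)

    ncols = len(lines[0][1])
    # label + [pop] + 2L allele columns: total parity decides the pop column.
    has_pop = ncols % 2 == 0
    n_allele_cols = ncols - (2 if has_pop else 1)
    if n_allele_cols <= 0 or n_allele_cols % 2 != 0:
        raise ParseError(
            f"cannot infer loci from {ncols} columns (need label, optional "
            "population, then two columns per locus)",
            path,
            lines[0][0],
        )
    L = n_allele_cols // 2
    if locus_names is None:
        locus_names = [f"L{j + 1}" for j in range(L)]
    elif len(locus_names) != L:
        raise ParseError(
            f"header names {len(locus_names)} loci but rows carry {L}", path, 1
        )

    ids: list[str] = []
    groups: dict[str, str] = {}
    rows: list[list[int]] = []
    for lineno, toks in lines:
        if len(toks) != ncols:
            raise ParseError(
                f"expected {ncols} columns, found {len(toks)}", path, lineno
            )
        aid = toks[0]
        if aid in set(ids):
            raise ParseError(f"duplicate accession id {aid!r}", path, lineno)
        ids.append(aid)
        body = toks[1:]
        if has_pop:
            groups[aid] = body[0]
            body = body[1:]
        rows.append([_parse_allele(t, path, lineno) for t in body])
    calls = np.asarray(rows, dtype=np.int32).reshape(len(ids), L, 2)
    G = GenotypeMatrix(ids, locus_names, calls)
    return G, (GroupAssignment(groups) if has_pop else None)


def read_genotype_table(
    path: str, dialect: str = "csv"
) -> tuple[GenotypeMatrix, GroupAssignment | None]:
    """Read a genotype table.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"csv"`` for the native dialect, ``"structure"`` for the
        two-column-per-locus layout (read only).

    Returns
    -------
    (GenotypeMatrix, GroupAssignment or None)
        Group labels are returned when the file carries a group/population
        column.
    """
    if dialect == "csv":
        return _read_csv_dialect(path)
    if dialect == "structure":
        return _read_structure_dialect(path)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'csv' or 'structure')")


def write_genotype_table(
    G: GenotypeMatrix,
    path: str,
    dialect: str = "csv",
    groups: GroupAssignment | None = None,
) -> None:
    """Write ``G`` in the native CSV dialect (byte-stable for a fixed input)."""
    if dialect != "csv":
        raise ValueError("only the 'csv' dialect is writable")
    if groups is not None:
        groups.validate_against(G)
    header = ["accession"]
    if groups is not None:
        header.append("group")
    for name in G.locus_names:
        header += [f"{name}.1", f"{name}.2"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = _csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for i, aid in enumerate(G.accession_ids):
            row: list = [aid]
            if groups is not None:
                row.append(groups.mapping.get(aid, ""))
            row += [int(x) for x in G.calls[i].reshape(-1)]
            writer.writerow(row)


def read_phenotype_table(path: str) -> PhenotypeTable:
    """Read a long-format phenotype CSV: ``accession,replicate,value``."""
    values: dict[str, list[float]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = _csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file", path, 1) from None
        if [h.strip() for h in header[:3]] != ["accession", "replicate", "value"]:
            raise ParseError("header must be 'accession,replicate,value'", path, 1)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise ParseError("expected 3 fields", path, lineno)
            try:
                val = float(row[2])
            except ValueError:
                raise ParseError(f"bad value {row[2]!r}", path, lineno) from None
            values.setdefault(row[0].strip(), []).append(val)
    if not values:
        raise ParseError("no accessions (header only)", path, 1)
    return PhenotypeTable(values)


def write_phenotype_table(table: PhenotypeTable, path: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = _csv.writer(fh, lineterminator="\n")
        writer.writerow(["accession", "replicate", "value"])
        for aid, vals in table.values.items():
            for r, v in enumerate(vals, start=1):
                writer.writerow([aid, r, repr(float(v))])
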