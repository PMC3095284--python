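"""Shared-allele genetic distance between diploid accessions.

For a pair of accessions the proportion of shared alleles is

    Ps = sum_l s_l / (2 * L')

where ``s_l`` is the number of allele copies the two accessions share at
locus ``l`` (the sum over alleles of the minimum copy count in each
accession: 0, 1 or 2) and ``L'`` is the number of loci typed in both
accessions (pairwise deletion).  Two distance transforms are provided:

* ``one_minus_ps`` -- ``1 - Ps``, bounded in [0, 1]; e.g. two accessions
  sharing 6 of 10 allele copies over 5 loci are at distance 1 - 6/10 = 0.4.
* ``neg_log_ps`` -- ``-ln(Ps)``, with ``Ps = 0`` mapped to a finite cap so
  that maximally distant pairs stay ranked first.

The two transforms are strictly monotone in each other, so any selection
procedure driven by the ranking of pairwise distances is invariant to the
choice.
"""

from __future__ import annotations

import csv as _csv
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .genotypes import MISSING, GenotypeMatrix

TRANSFORMS = ("one_minus_ps", "neg_log_ps")


def _check_transform(transform: str) -> None:
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; expected one of {TRANSFORMS}")


def default_log_cap(G: GenotypeMatrix) -> float:
    """Finite stand-in for -ln(0): -ln(eps) with eps = 1/(4 L n)."""
    eps = 1.0 / (4.0 * G.n_loci * G.n_accessions)
    return float(-np.log(eps))


@dataclass(eq=False)
class DistanceMatrix:
    """Symmetric pairwise genetic distances with a transform tag."""

    accession_ids: list[str]
    values: np.ndarray
    transform: str = "one_minus_ps"

    def __post_init__(self) -> None:
        _check_transform(self.transform)
        self.accession_ids = [str(a) for a in self.accession_ids]
        v = np.asarray(self.values, dtype=float)
        n = len(self.accession_ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = v
        self._index = {a: i for i, a in enumerate(self.accession_ids)}

    @property
    def n(self) -> int:
        return len(self.accession_ids)

    @property
    def n_pairs(self) -> int:
        """Number of unordered accession pairs, n(n-1)/2."""
        return self.n * (self.n - 1) // 2

    def pair(self, i: str | int, j: str | int) -> float:
        ii = i if isinstance(i, (int, np.integer)) else self._index[str(i)]
        jj = j if isinstance(j, (int, np.integer)) else self._index[str(j)]
        return float(self.values[ii, jj])

    def condensed(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(i_idx, j_idx, d) arrays over the upper triangle."""
        iu, ju = np.triu_indices(self.n, k=1)
        return iu, ju, self.values[iu, ju]


def shared_allele_proportion(G: GenotypeMatrix, i, j) -> float:
    """Proportion of allele copies shared by accessions *i* and *j*.

    Loci missing in either accession are dropped from both numerator and
    denominator; a pair with no commonly typed locus is an error.
    """
    ii, jj = G.index_of(i), G.index_of(j)
    if ii == jj:
        raise ValueError("shared_allele_proportion requires two distinct accessions")
    shared = 0
    n_loci = 0
    for l in range(G.n_loci):
        a = G.calls[ii, l]
        b = G.calls[jj, l]
        if a[0] == MISSING or b[0] == MISSING:
            continue
        n_loci += 1
        shared += sum((Counter(a.tolist()) & Counter(b.tolist())).values())
    if n_loci == 0:
        raise ValueError(
            f"no comparable loci between accessions "
            f"{G.accession_ids[ii]!r} and {G.accession_ids[jj]!r}"
        )
    return shared / (2.0 * n_loci)


def _apply_transform(ps: np.ndarray | float, transform: str, cap: float) -> np.ndarray | float:
    if transform == "one_minus_ps":
        return 1.0 - ps
    ps_arr = np.asarray(ps, dtype=float)
    out = np.where(ps_arr > 0, -np.log(np.where(ps_arr > 0, ps_arr, 1.0)), cap)
    out = np.minimum(out, cap)
    return float(out) if np.isscalar(ps) else out


def pair_distance(
    G: GenotypeMatrix, i, j, transform: str = "one_minus_ps", cap: float | None = None
) -> float:
    """Distance between two accessions under the chosen transform."""
    _check_transform(transform)
    if cap is None:
        cap = default_log_cap(G)
    ps = shared_allele_proportion(G, i, j)
    return float(_apply_transform(ps, transform, cap))


def _allele_count_matrix(G: GenotypeMatrix) -> np.ndarray:
    """(n, total_alleles) copy-count matrix; missing cells are all-zero."""
    cols: list[np.ndarray] = []
    typed = G.typed_mask()
    for l in range(G.n_loci):
        cell = G.calls[:, l, :]
        alleles = np.unique(cell[typed[:, l]])
        block = np.zeros((G.n_accessions, len(alleles)), dtype=np.float64)
        for k, a in enumerate(alleles):
            block[:, k] = (cell == a).sum(axis=1)
        block[~typed[:, l]] = 0.0
        cols.append(block)
    return np.concatenate(cols, axis=1) if cols else np.zeros((G.n_accessions, 0))

def distance_matrix(
    G: GenotypeMatrix, transform: str = "one_minus_ps", cap: float | None = None
) -> DistanceMatrix:
    """All-pairs shared-allele distances.

    Vectorized via the identity ``sum_a min(c_i, c_j) = (T_i + T_j -
    |c_i - c_j|_1) / 2`` on per-allele copy-count vectors, where ``T_i`` is
    twice the number of typed loci of accession *i*; Manhattan distances are
    delegated to :func:`scipy.spatial.distance.pdist`.
    """
    _check_transform(transform)
    if G.n_accessions < 2:
        raise ValueError("distance matrix requires at least 2 accessions")
    if cap is None:
        cap = default_log_cap(G)
    C = _allele_count_matrix(G)
    typed = G.typed_mask().astype(np.float64)
    both_typed = typed @ typed.T  # L' per pair
    iu, ju = np.triu_indices(G.n_accessions, k=1)
    lboth = both_typed[iu, ju]
    if (lboth == 0).any():
        k = int(np.argmax(lboth == 0))
        raise ValueError(
            "no comparable loci between accessions "
            f"{G.accession_ids[iu[k]]!r} and {G.accession_ids[ju[k]]!r}"
        )
    manhattan = pdist(C, metric="cityblock")
    t = 2.0 * typed.sum(axis=1)
    shared = 0.5 * (t[iu] + t[ju] - manhattan)
    ps = shared / (2.0 * lboth)
    d = _apply_transform(ps, transform, cap)
    mat = squareform(d)
    return DistanceMatrix(list(G.accession_ids), mat, transform)


# ---------------------------------------------------------------------------
# I/O: square CSV with id header row/column (writer), square or
# lower-triangle accepted on read
# ---------------------------------------------------------------------------

def write_distance_matrix(D: DistanceMatrix, path: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# transform: {D.transform}\n")
        writer = _csv.writer(fh, lineterminator="\n")
        writer.writerow([""] + D.accession_ids)
        for i, aid in enumerate(D.accession_ids):
            writer.writerow([aid] + [f"{x:.6f}" for x in D.values[i]])


def read_distance_matrix(path: str) -> DistanceMatrix:
    transform = "one_minus_ps"
    with open(path, newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "transform:" in first:
                transform = first.split("transform:")[1].strip()
            header_line = fh.readline()
        else:
            header_line = first
        header = next(_csv.reader([header_line]))
        ids = [h.strip() for h in header[1:] if h.strip()]
        n = len(ids)
        values = np.zeros((n, n), dtype=float)
        reader = _csv.reader(fh)
        for i, row in enumerate(reader):
            if not row or all(not c.strip() for c in row):
                continue
            if i >= n:
                raise ValueError(f"{path}: more rows than header accessions")
            body = [c for c in row[1:] if c.strip() != ""]
            if len(body) == n:  # full square row
                values[i, :] = [float(x) for x in body]
            elif len(body) == i:  # strict lower-triangle row
                values[i, :i] = [float(x) for x in body]
                values[:i, i] = values[i, :i]
            elif len(body) == i + 1:  # lower triangle including diagonal
                values[i, : i + 1] = [float(x) for x in body]
                values[: i, i] = values[i, :i]
            else:
                raise ValueError(
                    f"{path}: row {i + 2} has {len(body)} values; expected "
                    f"{n} (square) or {i}/{i + 1} (lower triangle)"
                )
    return DistanceMatrix(ids, values, transform)
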