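"""Core-collection extraction strategies.

Three samplers are provided:

* :func:`corex_select` -- maximum-distance ranking.  All unordered
  accession pairs are sorted by genetic distance, descending; the ranked
  list is walked, adding both members of each pair, until the target size
  ``k`` is reached.  Ties between equal distances (common with
  shared-allele distances, which take few discrete values) are shuffled
  independently in every repetition, and the analysis across repetitions
  yields per-accession inclusion frequencies; accessions present in every
  repetition form the *stable set* (100% inclusion).
* :func:`random_select` -- uniform k-subsets without replacement, the
  baseline any deliberate strategy must beat.
* :func:`mstrategy_cover` / :func:`mstrategy_fixed` -- a greedy allele
  maximizer in the spirit of the M (Maximization) strategy: repeatedly add
  the accession contributing the most not-yet-represented alleles, either
  until every allele of the collection is covered (cover mode, variable
  size) or up to a fixed size.  This is a generic greedy implementation;
  no bit-compatibility with any particular M-strategy program is claimed.

All samplers take an explicit seed; per-repetition random streams are
spawned from it by repetition index, so repetitions are order-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .distance import DistanceMatrix
from .genotypes import GenotypeMatrix, allele_frequencies

SeedLike = "int | None | np.random.SeedSequence"


def _seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _seed_repr(seed):
    if isinstance(seed, np.random.SeedSequence):
        e = seed.entropy
        return int(e) if isinstance(e, int) and e < 2**63 else str(e)
    return seed


@dataclass(eq=False)
class CoreSelection:
    """Result of a (possibly repeated) core-extraction run.

    ``selected`` is the reported core: the stable set when more than one
    repetition was run, otherwise the single repetition (for the fixed-size
    M strategy, the best repetition).
    """

    method: str
    k: int | None
    reps: int
    repetitions: list[list[str]]
    inclusion: dict[str, float]
    selected: list[str]
    seed: int | str | None = None

    @property
    def rep_sizes(self) -> list[int]:
        return [len(r) for r in self.repetitions]

    def stable_set(self, threshold: float = 1.0) -> list[str]:
        """Accessions with inclusion frequency >= ``threshold``."""
        if not 0.0 < threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")
        return [a for a, f in self.inclusion.items() if f >= threshold - 1e-12]

    # -- serialization ---------------------------------------------------
    def _ordered_ids(self) -> list[str]:
        return sorted(self.inclusion, key=lambda a: (-self.inclusion[a], a))

    def to_json(self) -> str:
        stable = set(self.stable_set())
        payload = {
            "method": self.method,
            "k": self.k,
            "reps": self.reps,
            "seed": self.seed,
            "selected": list(self.selected),
            "inclusion": {a: self.inclusion[a] for a in self._ordered_ids()},
            "stable_set": [a for a in self._ordered_ids() if a in stable],
            "repetitions": [list(r) for r in self.repetitions],
        }
        return json.dumps(payload, indent=2) + "\n"

    def write_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    def write_csv(self, path: str) -> None:
        stable = set(self.stable_set())
        with open(path, "w", newline="", encoding="utf-8") as fh:
            fh.write("accession,inclusion_frequency,in_stable_set\n")
            for a in self._ordered_ids():
                fh.write(f"{a},{self.inclusion[a]:.6f},{int(a in stable)}\n")


def selection_from_json(path: str) -> CoreSelection:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return CoreSelection(
        method=payload["method"],
        k=payload["k"],
        reps=payload["reps"],
        repetitions=[list(r) for r in payload["repetitions"]],
        inclusion={str(a): float(f) for a, f in payload["inclusion"].items()},
        selected=[str(a) for a in payload["selected"]],
        seed=payload.get("seed"),
    )


def stable_set(sel: CoreSelection, threshold: float = 1.0) -> list[str]:
    """Accessions included in at least ``threshold`` of the repetitions."""
    return sel.stable_set(threshold)


def _finish(
    method: str,
    k: int | None,
    ids: Sequence[str],
    rep_sets: list[np.ndarray],
    seed,
    selected_idx: np.ndarray | None = None,
) -> CoreSelection:
    reps = len(rep_sets)
    counts = np.zeros(len(ids), dtype=np.int64)
    for r in rep_sets:
        counts[r] += 1
    inclusion = {ids[i]: counts[i] / reps for i in range(len(ids)) if counts[i] > 0}
    repetitions = [[ids[i] for i in np.sort(r)] for r in rep_sets]
    if selected_idx is not None:
        selected = [ids[i] for i in np.sort(selected_idx)]
    elif reps > 1:
        stable_idx = np.nonzero(counts == reps)[0]
        selected = [ids[i] for i in stable_idx]
    else:
        selected = repetitions[0]
    return CoreSelection(
        method=method,
        k=k,
        reps=reps,
        repetitions=repetitions,
        inclusion=inclusion,
        selected=selected,
        seed=_seed_repr(seed),
    )


# ---------------------------------------------------------------------------
# Corex: maximum-distance pair ranking
# ---------------------------------------------------------------------------

def _corex_one_rep(
    iu: np.ndarray,
    ju: np.ndarray,
    order: np.ndarray,
    n: int,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    selected = np.zeros(n, dtype=bool)
    count = 0
    for p in order:
        a, b = int(iu[p]), int(ju[p])
        new_a, new_b = not selected[a], not selected[b]
        n_new = new_a + new_b
        if n_new == 0:
            continue
        room = k - count
        if n_new <= room:
            selected[a] = selected[b] = True
            count += n_new
        else:  # two new members, one slot: pick one uniformly at random
            pick = a if rng.integers(2) == 0 else b
            selected[pick] = True
            count += 1
        if count == k:
            break
    return np.nonzero(selected)[0]


def corex_select(D: DistanceMatrix, k: int, reps: int = 100, seed=None) -> CoreSelection:
    """Maximum-distance core extraction with repetitions.

    Per repetition, the full ranked pair list (ties shuffled by that
    repetition's random stream) is walked, adding both members of each
    not-yet-included pair, until exactly ``k`` accessions are accumulated;
    when a full pair would overshoot, one member is chosen uniformly at
    random.  Inclusion frequencies and the stable set are computed across
    repetitions.
    """
    n = D.n
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]; got {k}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    iu, ju, d = D.condensed()
    children = _seed_sequence(seed).spawn(reps)
    rep_sets = []
    for child in children:
        rng = np.random.default_rng(child)
        keys = rng.random(len(d))
        order = np.lexsort((keys, -d))  # distance desc, ties shuffled
        rep_sets.append(_corex_one_rep(iu, ju, order, n, k, rng))
    return _finish("corex", k, D.accession_ids, rep_sets, seed)


# ---------------------------------------------------------------------------
# Random baseline
# ---------------------------------------------------------------------------

def random_select(accessions, k: int, reps: int = 100, seed=None) -> CoreSelection:
    """Uniform k-subsets without replacement (independent repetitions)."""
    if isinstance(accessions, (GenotypeMatrix, DistanceMatrix)):
        ids = list(accessions.accession_ids)
    else:
        ids = [str(a) for a in accessions]
    n = len(ids)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]; got {k}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    children = _seed_sequence(seed).spawn(reps)
    rep_sets = [
        np.random.default_rng(c).choice(n, size=k, replace=False) for c in children
    ]
    return _finish("random", k, ids, rep_sets, seed, selected_idx=rep_sets[0])


# ---------------------------------------------------------------------------
# Greedy M strategy
# ---------------------------------------------------------------------------

def _incidence(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, list[slice]]:
    """Boolean allele-incidence matrix (n, A), copy counts, per-locus
    column slices."""
    from .distance import _allele_count_matrix

    C = _allele_count_matrix(G)
    slices = []
    start = 0
    from .genotypes import MISSING

    typed = G.typed_mask()
    for l in range(G.n_loci):
        cell = G.calls[:, l, :]
        n_alleles = len(np.unique(cell[typed[:, l]]))
        slices.append(slice(start, start + n_alleles))
        start += n_alleles
    return C > 0, C, slices


def _mean_raw_gd(colsum: np.ndarray, slices: list[slice]) -> float:
    vals = []
    for sl in slices:
        c = colsum[sl]
        tot = c.sum()
        if tot > 0:
            p = c / tot
            vals.append(1.0 - np.sum(p**2))
    return float(np.mean(vals)) if vals else 0.0


def _greedy_m(
    A: np.ndarray,
    C: np.ndarray,
    slices: list[slice],
    k: int | None,
    rng: np.random.Generator,
    gd_tiebreak: bool,
) -> np.ndarray:
    n, n_alleles = A.shape
    covered = np.zeros(n_alleles, dtype=bool)
    in_sel = np.zeros(n, dtype=bool)
    colsum = np.zeros(n_alleles)
    order: list[int] = []
    target = n if k is None else k
    while len(order) < target:
        gains = (A[:, ~covered]).sum(axis=1)
        gains[in_sel] = -1
        best = gains.max()
        if k is None and best <= 0:
            break  # cover mode: everything representable is covered
        cand = np.nonzero(gains == best)[0]
        if len(cand) > 1 and gd_tiebreak and best > 0:
            scores = np.array(
                [_mean_raw_gd(colsum + C[i], slices) for i in cand]
            )
            cand = cand[scores == scores.max()]
        pick = int(cand[rng.integers(len(cand))]) if len(cand) > 1 else int(cand[0])
        in_sel[pick] = True
        covered |= A[pick]
        colsum += C[pick]
        order.append(pick)
    return np.asarray(order, dtype=np.int64)


def mstrategy_cover(G: GenotypeMatrix, seed=None) -> CoreSelection:
    """Greedy set cover over alleles: smallest greedy selection that
    represents 100% of the collection's distinct alleles.

    Ties on allele gain are broken toward the candidate giving the higher
    mean (raw) gene diversity, then at random.
    """
    A, C, slices = _incidence(G)
    rng = np.random.default_rng(_seed_sequence(seed))
    sel = _greedy_m(A, C, slices, None, rng, gd_tiebreak=True)
    return _finish("mstrat_cover", None, G.accession_ids, [sel], seed)


def mstrategy_fixed(G: GenotypeMatrix, k: int, reps: int = 10, seed=None) -> CoreSelection:
    """Fixed-size greedy allele maximizer with random tie-breaks.

    Each repetition greedily adds the accession covering the most new
    alleles until ``k`` accessions are chosen; the best repetition
    (most alleles, then highest mean gene diversity) is reported.
    """
    n = G.n_accessions
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]; got {k}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    A, C, slices = _incidence(G)
    children = _seed_sequence(seed).spawn(reps)
    rep_sets = []
    scores = []
    for child in children:
        rng = np.random.default_rng(child)
        sel = _greedy_m(A, C, slices, k, rng, gd_tiebreak=False)
        covered = A[sel].any(axis=0).sum()
        gd = _mean_raw_gd(C[sel].sum(axis=0), slices)
        rep_sets.append(sel)
        scores.append((int(covered), gd))
    best = max(range(reps), key=lambda i: scores[i])
    return _finish(
        "mstrat_fixed", k, G.accession_ids, rep_sets, seed, selected_idx=rep_sets[best]
    )
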