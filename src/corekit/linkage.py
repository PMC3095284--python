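"""Multiallelic linkage disequilibrium between pairs of loci.

Genotypes are unphased, so two-locus haplotype frequencies are estimated
by an EM algorithm over the (collapsed) two-locus genotype classes: only
double heterozygotes are phase-ambiguous, and their expected haplotype
counts are re-weighted each iteration by the current frequency estimates.
From the fitted haplotype frequency matrix ``h`` with marginals ``p`` and
``q``:

    D_ij   = h_ij - p_i q_j
    D'     = sum_ij p_i q_j |D_ij / Dmax_ij|
    r^2    = sum_ij p_i q_j * D_ij^2 / (p_i (1 - p_i) q_j (1 - q_j))

Both coefficients reduce to the classic biallelic definitions.
Significance is assessed by permuting one locus's genotype column across
accessions (which preserves both single-locus genotype distributions while
breaking the between-locus association), with a chi-square approximation
available as a fast alternative.  Pairs where either locus is monomorphic
within the analyzed subset are flagged as undefined rather than raised,
and excluded from summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .genotypes import MISSING, GenotypeMatrix, _resolve_subset

try:  # jitted permutation kernel; the numpy path below is the fallback
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(fn):
            return fn

        return deco

#: p-value cutpoints for the three-class significance map:
#: high p < 1e-4, intermediate 1e-4 <= p < 1e-2, low p >= 1e-2.
DEFAULT_ALPHA_CLASSES = (1e-4, 1e-2)


@dataclass
class HaplotypeFrequencies:
    """EM-fitted two-locus haplotype frequencies."""

    alleles_a: np.ndarray
    alleles_b: np.ndarray
    freqs: np.ndarray  # (nA, nB), sums to 1
    n: int  # accessions used
    loglik_path: list[float]
    n_iter: int
    converged: bool

    def frequency(self, allele_a: int, allele_b: int) -> float:
        ia = int(np.searchsorted(self.alleles_a, allele_a))
        ib = int(np.searchsorted(self.alleles_b, allele_b))
        return float(self.freqs[ia, ib])


def _pair_calls(G, locus_a, locus_b, subset):
    la, lb = G.locus_index(locus_a), G.locus_index(locus_b)
    idx = _resolve_subset(G, subset)
    A = G.calls[idx, la, :]
    B = G.calls[idx, lb, :]
    both = (A[:, 0] != MISSING) & (B[:, 0] != MISSING)
    return A[both], B[both]


def _collapse_classes(A: np.ndarray, B: np.ndarray):
    """Collapse individuals into distinct two-locus genotype classes.

    Returns the per-class phase-1/phase-2 haplotype index pairs, the
    ambiguity flags and class counts, plus the sorted allele arrays.
    """
    ua, inv_a = np.unique(A, return_inverse=True)
    ub, inv_b = np.unique(B, return_inverse=True)
    ia = inv_a.reshape(A.shape)
    ib = inv_b.reshape(B.shape)
    a_lo, a_hi = np.minimum(ia[:, 0], ia[:, 1]), np.maximum(ia[:, 0], ia[:, 1])
    b_lo, b_hi = np.minimum(ib[:, 0], ib[:, 1]), np.maximum(ib[:, 0], ib[:, 1])
    nB = len(ub)
    key = ((a_lo * len(ua) + a_hi) * nB + b_lo) * nB + b_hi
    uk, counts = np.unique(key, return_counts=True)
    kb_hi = uk % nB
    rest = uk // nB
    kb_lo = rest % nB
    rest //= nB
    ka_hi = rest % len(ua)
    ka_lo = rest // len(ua)
    h11 = ka_lo * nB + kb_lo
    h12 = ka_hi * nB + kb_hi
    h21 = ka_lo * nB + kb_hi
    h22 = ka_hi * nB + kb_lo
    amb = (ka_lo != ka_hi) & (kb_lo != kb_hi)
    return ua, ub, h11, h12, h21, h22, amb, counts.astype(float)


def em_haplotype_frequencies(
    G: GenotypeMatrix,
    locus_a,
    locus_b,
    subset=None,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> HaplotypeFrequencies:
    """Maximum-likelihood two-locus haplotype frequencies via EM.

    When no double heterozygotes exist the genotype data carry no phase
    ambiguity and the first M step is already the fixed point.
    """
    A, B = _pair_calls(G, locus_a, locus_b, subset)
    n = len(A)
    if n == 0:
        raise ValueError(
            f"no accessions typed at both loci "
            f"{G.locus_names[G.locus_index(locus_a)]!r} and "
            f"{G.locus_names[G.locus_index(locus_b)]!r}"
        )
    ua, ub, h11, h12, h21, h22, amb, counts = _collapse_classes(A, B)
    nA, nB = len(ua), len(ub)
    # init: product of single-locus allele frequencies
    pa = np.bincount(
        np.searchsorted(ua, A.reshape(-1)), minlength=nA
    ) / (2.0 * n)
    pb = np.bincount(
        np.searchsorted(ub, B.reshape(-1)), minlength=nB
    ) / (2.0 * n)
    f = np.outer(pa, pb).reshape(-1)
    loglik_path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w1 = f[h11] * f[h12]
        w2 = np.where(amb, f[h21] * f[h22], 0.0)
        tot = w1 + w2
        safe = np.where(tot > 0, tot, 1.0)
        loglik_path.append(float(np.sum(counts * np.log(np.where(tot > 0, safe, 1e-300)))))
        r = np.where(amb, np.where(tot > 0, w1 / safe, 0.5), 1.0)
        new = np.zeros_like(f)
        np.add.at(new, h11, counts * r)
        np.add.at(new, h12, counts * r)
        np.add.at(new, h21, counts * (1.0 - r))
        np.add.at(new, h22, counts * (1.0 - r))
        new /= 2.0 * n
        delta = float(np.max(np.abs(new - f)))
        f = new
        if delta < tol:
            converged = True
            break
    return HaplotypeFrequencies(
        alleles_a=ua,
        alleles_b=ub,
        freqs=f.reshape(nA, nB),
        n=n,
        loglik_path=loglik_path,
        n_iter=it,
        converged=converged,
    )


def _dprime_r2(freqs: np.ndarray) -> tuple[float, float]:
    """Multiallelic D' and r^2 from a haplotype frequency matrix."""
    p = freqs.sum(axis=1)
    q = freqs.sum(axis=0)
    D = freqs - np.outer(p, q)
    P, Q = np.meshgrid(p, q, indexing="ij")
    dmax = np.where(
        D < 0, np.minimum(P * Q, (1 - P) * (1 - Q)), np.minimum(P * (1 - Q), (1 - P) * Q)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dmax > 0, np.abs(D) / np.where(dmax > 0, dmax, 1.0), 0.0)
        denom = P * (1 - P) * Q * (1 - Q)
        r2_cell = np.where(denom > 0, D**2 / np.where(denom > 0, denom, 1.0), 0.0)
    w = P * Q
    dprime = float(np.sum(w * ratio))
    r2 = float(np.sum(w * r2_cell))
    return min(dprime, 1.0), min(r2, 1.0)


@dataclass
class LDPair:
    locus_a: str
    locus_b: str
    dprime: float
    r2: float
    p_value: float
    significance_class: str
    defined: bool = True
    note: str = ""


def _classify_p(p: float, alpha_classes=DEFAULT_ALPHA_CLASSES) -> str:
    hi, lo = alpha_classes
    if p < hi:
        return "high"
    if p < lo:
        return "intermediate"
    return "low"


def _stat_r2(A: np.ndarray, B: np.ndarray) -> tuple[float, float, np.ndarray]:
    hap = em_haplotype_frequencies_from_calls(A, B)
    d, r2 = _dprime_r2(hap.freqs)
    return d, r2, hap.freqs


class _PairEngine:
    """Precomputed genotype-category tables for one locus pair.

    Under a permutation of one locus's genotype column only the pairing of
    single-locus genotype categories changes, so the per-permutation work
    reduces to a bincount over joint categories plus an EM on the observed
    classes.  This is what makes a permutation test with an EM fit per
    shuffle affordable.
    """

    def __init__(self, A: np.ndarray, B: np.ndarray):
        self.n = len(A)
        ua, inv_a = np.unique(A, return_inverse=True)
        ub, inv_b = np.unique(B, return_inverse=True)
        ia = inv_a.reshape(A.shape)
        ib = inv_b.reshape(B.shape)
        self.nA, self.nB = len(ua), len(ub)
        aLo, aHi = np.minimum(ia[:, 0], ia[:, 1]), np.maximum(ia[:, 0], ia[:, 1])
        bLo, bHi = np.minimum(ib[:, 0], ib[:, 1]), np.maximum(ib[:, 0], ib[:, 1])
        catA, self.gA = np.unique(aLo * self.nA + aHi, return_inverse=True)
        catB, self.gB = np.unique(bLo * self.nB + bHi, return_inverse=True)
        cALo, cAHi = catA // self.nA, catA % self.nA
        cBLo, cBHi = catB // self.nB, catB % self.nB
        self.nCA, self.nCB = len(catA), len(catB)
        # full cross tables over (genotype category A, genotype category B)
        self.H11 = (cALo[:, None] * self.nB + cBLo[None, :]).ravel()
        self.H12 = (cAHi[:, None] * self.nB + cBHi[None, :]).ravel()
        self.H21 = (cALo[:, None] * self.nB + cBHi[None, :]).ravel()
        self.H22 = (cAHi[:, None] * self.nB + cBLo[None, :]).ravel()
        self.AMB = ((cALo != cAHi)[:, None] & (cBLo != cBHi)[None, :]).ravel()

    def freqs(self, gB: np.ndarray, tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
        joint = self.gA * self.nCB + gB
        counts = np.bincount(joint, minlength=self.nCA * self.nCB)
        nz = np.nonzero(counts)[0]
        c = counts[nz].astype(float)
        h11, h12 = self.H11[nz], self.H12[nz]
        h21, h22 = self.H21[nz], self.H22[nz]
        amb = self.AMB[nz]
        size = self.nA * self.nB
        two_n = 2.0 * self.n
        # product-of-marginals init
        pa = np.bincount(h11 // self.nB, weights=c, minlength=self.nA)
        pa += np.bincount(h12 // self.nB, weights=c, minlength=self.nA)
        pb = np.bincount(h11 % self.nB, weights=c, minlength=self.nB)
        pb += np.bincount(h12 % self.nB, weights=c, minlength=self.nB)
        f = np.outer(pa / two_n, pb / two_n).reshape(-1)
        if not amb.any():
            new = np.zeros(size)
            np.add.at(new, h11, c)
            np.add.at(new, h12, c)
            return (new / two_n).reshape(self.nA, self.nB)
        for _ in range(max_iter):
            w1 = f[h11] * f[h12]
            w2 = np.where(amb, f[h21] * f[h22], 0.0)
            tot = w1 + w2
            safe = np.where(tot > 0, tot, 1.0)
            r = np.where(amb, np.where(tot > 0, w1 / safe, 0.5), 1.0)
            new = np.zeros(size)
            cr = c * r
            c1r = c * (1.0 - r)
            np.add.at(new, h11, cr)
            np.add.at(new, h12, cr)
            np.add.at(new, h21, c1r)
            np.add.at(new, h22, c1r)
            new /= two_n
            delta = float(np.max(np.abs(new - f)))
            f = new
            if delta < tol:
                break
        return f.reshape(self.nA, self.nB)

    def r2(self, gB: np.ndarray) -> float:
        return _dprime_r2(self.freqs(gB))[1]

    def permutation_hits(
        self, perms: np.ndarray, r2_obs: float, tol: float = 1e-10, max_iter: int = 1000
    ) -> int:
        """Number of permutations whose r^2 reaches the observed value.

        ``perms`` holds one permuted copy of the locus-B genotype-category
        vector per row.
        """
        if _HAVE_NUMBA:
            return int(
                _perm_kernel(
                    self.gA.astype(np.int64),
                    perms.astype(np.int64),
                    self.H11.astype(np.int64),
                    self.H12.astype(np.int64),
                    self.H21.astype(np.int64),
                    self.H22.astype(np.int64),
                    self.AMB,
                    self.nCB,
                    self.nA,
                    self.nB,
                    self.n,
                    r2_obs,
                    tol,
                    max_iter,
                )
            )
        hits = 0
        for p in range(perms.shape[0]):
            if self.r2(perms[p]) >= r2_obs - 1e-12:
                hits += 1
        return hits


@_njit(cache=True)
def _perm_kernel(gA, perms, H11, H12, H21, H22, AMB, nCB, nA, nB, n,
                 r2_obs, tol, max_iter):  # pragma: no cover - exercised via tests
    ncat = (gA.max() + 1) * nCB
    nhap = nA * nB
    counts = np.zeros(ncat, np.int64)
    c = np.zeros(n, np.float64)
    h11 = np.zeros(n, np.int64)
    h12 = np.zeros(n, np.int64)
    h21 = np.zeros(n, np.int64)
    h22 = np.zeros(n, np.int64)
    amb = np.zeros(n, np.bool_)
    f = np.zeros(nhap, np.float64)
    new = np.zeros(nhap, np.float64)
    hits = 0
    for p in range(perms.shape[0]):
        counts[:] = 0
        for i in range(n):
            counts[gA[i] * nCB + perms[p, i]] += 1
        m = 0
        any_amb = False
        for j in range(ncat):
            if counts[j] > 0:
                c[m] = counts[j]
                h11[m] = H11[j]
                h12[m] = H12[j]
                h21[m] = H21[j]
                h22[m] = H22[j]
                amb[m] = AMB[j]
                if AMB[j]:
                    any_amb = True
                m += 1
        two_n = 2.0 * n
        f[:] = 0.0
        if not any_amb:
            for j in range(m):
                f[h11[j]] += c[j]
                f[h12[j]] += c[j]
            for q in range(nhap):
                f[q] /= two_n
        else:
            # product-of-marginals init
            pa = np.zeros(nA, np.float64)
            pb = np.zeros(nB, np.float64)
            for j in range(m):
                pa[h11[j] // nB] += c[j]
                pa[h12[j] // nB] += c[j]
                pb[h11[j] % nB] += c[j]
                pb[h12[j] % nB] += c[j]
            for a in range(nA):
                for b in range(nB):
                    f[a * nB + b] = (pa[a] / two_n) * (pb[b] / two_n)
            for _ in range(max_iter):
                new[:] = 0.0
                for j in range(m):
                    if amb[j]:
                        w1 = f[h11[j]] * f[h12[j]]
                        w2 = f[h21[j]] * f[h22[j]]
                        tot = w1 + w2
                        r = 0.5 if tot <= 0.0 else w1 / tot
                    else:
                        r = 1.0
                    cr = c[j] * r
                    c1r = c[j] * (1.0 - r)
                    new[h11[j]] += cr
                    new[h12[j]] += cr
                    new[h21[j]] += c1r
                    new[h22[j]] += c1r
            # normalize and test convergence
                delta = 0.0
                for q in range(nhap):
                    new[q] /= two_n
                    d = abs(new[q] - f[q])
                    if d > delta:
                        delta = d
                    f[q] = new[q]
                if delta < tol:
                    break
        # weighted multiallelic r^2 from f
        pm = np.zeros(nA, np.float64)
        qm = np.zeros(nB, np.float64)
        for a in range(nA):
            for b in range(nB):
                pm[a] += f[a * nB + b]
                qm[b] += f[a * nB + b]
        r2 = 0.0
        for a in range(nA):
            for b in range(nB):
                denom = pm[a] * (1.0 - pm[a]) * qm[b] * (1.0 - qm[b])
                if denom > 0.0:
                    D = f[a * nB + b] - pm[a] * qm[b]
                    r2 += pm[a] * qm[b] * D * D / denom
        if r2 > 1.0:
            r2 = 1.0
        if r2 >= r2_obs - 1e-12:
            hits += 1
    return hits


def em_haplotype_frequencies_from_calls(A: np.ndarray, B: np.ndarray, tol=1e-10, max_iter=1000):
    """EM on raw paired call arrays; used internally and by permutations."""
    n = len(A)
    ua, ub, h11, h12, h21, h22, amb, counts = _collapse_classes(A, B)
    nA, nB = len(ua), len(ub)
    pa = np.bincount(np.searchsorted(ua, A.reshape(-1)), minlength=nA) / (2.0 * n)
    pb = np.bincount(np.searchsorted(ub, B.reshape(-1)), minlength=nB) / (2.0 * n)
    f = np.outer(pa, pb).reshape(-1)
    if not amb.any():
        # no phase ambiguity: haplotype counts are read off the genotypes
        new = np.zeros_like(f)
        np.add.at(new, h11, counts)
        np.add.at(new, h12, counts)
        new /= 2.0 * n
        return HaplotypeFrequencies(ua, ub, new.reshape(nA, nB), n, [], 1, True)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w1 = f[h11] * f[h12]
        w2 = np.where(amb, f[h21] * f[h22], 0.0)
        tot = w1 + w2
        safe = np.where(tot > 0, tot, 1.0)
        r = np.where(amb, np.where(tot > 0, w1 / safe, 0.5), 1.0)
        new = np.zeros_like(f)
        np.add.at(new, h11, counts * r)
        np.add.at(new, h12, counts * r)
        np.add.at(new, h21, counts * (1.0 - r))
        np.add.at(new, h22, counts * (1.0 - r))
        new /= 2.0 * n
        delta = float(np.max(np.abs(new - f)))
        f = new
        if delta < tol:
            converged = True
            break
    return HaplotypeFrequencies(ua, ub, f.reshape(nA, nB), n, [], it, converged)


def ld_pair(
    G: GenotypeMatrix,
    locus_a,
    locus_b,
    subset=None,
    n_permutations: int = 999,
    seed=None,
    method: str = "permutation",
) -> LDPair:
    """D', r^2 and a significance p-value for one locus pair.

    ``method='permutation'`` shuffles one locus's genotype column
    ``n_permutations`` times (p = (1 + #{r2_perm >= r2_obs}) / (1 + B));
    ``method='chisq'`` uses the contingency chi-square approximation
    ``X^2 = 2 n r^2 (nA - 1)(nB - 1)``-style statistic, which is fast but
    fragile for sparse multiallelic tables.
    """
    name_a = G.locus_names[G.locus_index(locus_a)]
    name_b = G.locus_names[G.locus_index(locus_b)]
    A, B = _pair_calls(G, locus_a, locus_b, subset)
    if len(A) < 2:
        raise ValueError(f"loci {name_a!r}/{name_b!r}: fewer than 2 common typed accessions")
    if len(np.unique(A)) < 2 or len(np.unique(B)) < 2:
        return LDPair(
            name_a, name_b, float("nan"), float("nan"), float("nan"),
            "undefined", defined=False, note="monomorphic locus in subset",
        )
    dprime, r2_obs, freqs = _stat_r2(A, B)
    n = len(A)
    if method == "chisq":
        nA, nB = freqs.shape
        p_m = freqs.sum(axis=1)
        q_m = freqs.sum(axis=0)
        D = freqs - np.outer(p_m, q_m)
        x2 = 2.0 * n * float(np.sum(D**2 / np.outer(p_m, q_m)))
        p = float(chi2.sf(x2, (nA - 1) * (nB - 1)))
    elif method == "permutation":
        rng = np.random.default_rng(
            seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        )
        engine = _PairEngine(A, B)
        perms = np.empty((n_permutations, n), dtype=np.int64)
        for b in range(n_permutations):
            perms[b] = engine.gB[rng.permutation(n)]
        hits = engine.permutation_hits(perms, r2_obs)
        p = (1.0 + hits) / (1.0 + n_permutations)
    else:
        raise ValueError(f"unknown method {method!r}")
    return LDPair(name_a, name_b, dprime, r2_obs, p, _classify_p(p))


@dataclass
class LDResult:
    """All-pairs LD summary: long table plus the significant fraction."""

    pairs: list[LDPair]
    alpha: float
    alpha_classes: tuple[float, float]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_defined(self) -> int:
        return sum(p.defined for p in self.pairs)

    @property
    def fraction_significant(self) -> float:
        defined = [p for p in self.pairs if p.defined]
        if not defined:
            return float("nan")
        return sum(p.p_value < self.alpha for p in defined) / len(defined)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locusA": [p.locus_a for p in self.pairs],
                "locusB": [p.locus_b for p in self.pairs],
                "Dprime": [p.dprime for p in self.pairs],
                "r2": [p.r2 for p in self.pairs],
                "pvalue": [p.p_value for p in self.pairs],
                "class": [p.significance_class for p in self.pairs],
            }
        )

    def write_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def ld_significance_matrix(
    G: GenotypeMatrix,
    subset=None,
    n_permutations: int = 999,
    seed=None,
    alpha: float = 0.01,
    alpha_classes=DEFAULT_ALPHA_CLASSES,
    method: str = "permutation",
) -> LDResult:
    """Evaluate every unordered locus pair (L(L-1)/2 of them).

    Per-pair seeds are spawned from the master seed so that pairs are
    independent and order-insensitive.  The summary fraction counts pairs
    with ``p < alpha`` among pairs where LD is defined.
    """
    L = G.n_loci
    if L < 2:
        raise ValueError("need at least 2 loci")
    pairs = []
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_combos = L * (L - 1) // 2
    children = master.spawn(n_combos)
    c = 0
    for i in range(L):
        for j in range(i + 1, L):
            pairs.append(
                ld_pair(
                    G, i, j, subset=subset, n_permutations=n_permutations,
                    seed=children[c], method=method,
                )
            )
            c += 1
    return LDResult(pairs, alpha=alpha, alpha_classes=tuple(alpha_classes))
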