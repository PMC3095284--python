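"""Diversity statistics for codominant marker data.

Per-locus statistics follow the conventions of the standard SSR-analysis
toolchain:

* observed heterozygosity ``Ho`` -- fraction of typed accessions whose two
  allele copies differ;
* gene diversity ``GD`` (expected heterozygosity) -- ``1 - sum_i p_i^2``,
  with the small-sample correction ``(2n / (2n - 1))`` applied
  multiplicatively (the unbiased estimator);
* polymorphism information content ``PIC`` (Botstein form) --
  ``1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``;
* inbreeding coefficient ``f`` -- moment estimator ``1 - Ho/He`` with both
  terms averaged over loci before the ratio (ratio of means);
* Wright's fixation indices ``FIS``/``FST``/``FIT`` -- Weir & Cockerham
  variance-component (a, b, c) moment estimators, summed over alleles and
  loci.

Highly autogamous species such as rice sit near ``Ho = 0``, ``f`` close to
1, and gene diversity is then the informative measure of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .genotypes import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeMatrix,
    GroupAssignment,
    _resolve_subset,
    allele_frequencies,
)

# Frequency-class boundaries for lost-allele bookkeeping; boundary values
# fall in the higher class.
RARE_MAX = 0.05
COMMON_MIN = 0.30


def observed_heterozygosity(G: GenotypeMatrix, locus, subset=None) -> float:
    """Fraction of typed accessions heterozygous at ``locus``."""
    l = G.locus_index(locus)
    idx = _resolve_subset(G, subset)
    cell = G.calls[idx, l, :]
    typed = cell[:, 0] != MISSING
    n = int(typed.sum())
    if n == 0:
        raise ValueError(f"locus {G.locus_names[l]!r} has no typed accessions in subset")
    het = int((cell[typed, 0] != cell[typed, 1]).sum())
    return het / n


def gene_diversity(freqs: AlleleFrequencyTable, locus, unbiased: bool = True) -> float:
    """Gene diversity ``1 - sum p^2``, optionally small-sample corrected."""
    l = freqs.locus_index(locus)
    n = int(freqs.n[l])
    if n < 1:
        raise ValueError(f"locus {freqs.locus_names[l]!r} has n = 0")
    p = np.asarray(list(freqs.frequencies(l).values()))
    raw = 1.0 - float(np.sum(p**2))
    if not unbiased:
        return raw
    if 2 * n < 2:
        raise ValueError("unbiased correction requires at least one diploid sample")
    return (2.0 * n / (2.0 * n - 1.0)) * raw


def pic(freqs: AlleleFrequencyTable, locus) -> float:
    """Polymorphism information content (Botstein convention)."""
    p = np.asarray(list(freqs.frequencies(locus).values()))
    p2 = p**2
    cross = float(np.sum(np.outer(p2, p2)) - np.sum(p2**2)) / 2.0
    return 1.0 - float(np.sum(p2)) - 2.0 * cross


def inbreeding_f(G: GenotypeMatrix, subset=None) -> float:
    """Moment estimator of the inbreeding (endogamy) coefficient.

    ``f = 1 - mean_l(Ho_l) / mean_l(He_l)`` with ``He`` the unbiased gene
    diversity; undefined (error) when every locus is monomorphic.
    """
    freqs = allele_frequencies(G, subset)
    ho = np.array([observed_heterozygosity(G, l, subset) for l in range(G.n_loci)])
    he = np.array([gene_diversity(freqs, l, unbiased=True) for l in range(G.n_loci)])
    he_mean = float(np.mean(he))
    if he_mean <= 0.0:
        raise ValueError("f undefined: all loci monomorphic (mean He = 0)")
    return 1.0 - float(np.mean(ho)) / he_mean


@dataclass
class DiversitySummary:
    """Per-locus diversity table with across-locus arithmetic means."""

    locus_names: list[str]
    n: np.ndarray
    allele_counts: np.ndarray
    ho: np.ndarray
    gd_raw: np.ndarray
    gd: np.ndarray
    pic: np.ndarray
    f: float

    @property
    def mean_ho(self) -> float:
        return float(np.mean(self.ho))

    @property
    def mean_gd(self) -> float:
        return float(np.mean(self.gd))

    @property
    def mean_pic(self) -> float:
        return float(np.mean(self.pic))

    @property
    def total_alleles(self) -> int:
        return int(np.sum(self.allele_counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": self.locus_names,
                "n": self.n,
                "alleles": self.allele_counts,
                "Ho": self.ho,
                "GD": self.gd,
                "PIC": self.pic,
            }
        )


def diversity_summary(G: GenotypeMatrix, subset=None) -> DiversitySummary:
    """Compute the per-locus Ho/GD/PIC table plus the inbreeding f."""
    freqs = allele_frequencies(G, subset)
    L = G.n_loci
    ho = np.array([observed_heterozygosity(G, l, subset) for l in range(L)])
    gd_raw = np.array([gene_diversity(freqs, l, unbiased=False) for l in range(L)])
    gd = np.array([gene_diversity(freqs, l, unbiased=True) for l in range(L)])
    pic_ = np.array([pic(freqs, l) for l in range(L)])
    try:
        f = inbreeding_f(G, subset)
    except ValueError:
        f = float("nan")
    return DiversitySummary(
        list(G.locus_names),
        freqs.n.copy(),
        np.array([len(c) for c in freqs.counts]),
        ho,
        gd_raw,
        gd,
        pic_,
        f,
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham F-statistics
# ---------------------------------------------------------------------------

@dataclass
class FStatistics:
    fis: float
    fst: float
    fit: float
    pairwise_fst: dict[tuple[str, str], float] = field(default_factory=dict)


def _wc_components(
    G: GenotypeMatrix, group_indices: dict[str, list[int]]
) -> tuple[float, float, float]:
    """Summed Weir–Cockerham variance components (a, b, c) over alleles and
    loci for the given populations."""
    sum_a = sum_b = sum_c = 0.0
    calls = G.calls
    for l in range(G.n_loci):
        pops = []
        for label, idx in group_indices.items():
            cell = calls[idx, l, :]
            typed = cell[:, 0] != MISSING
            if typed.sum() >= 1:
                pops.append(cell[typed])
        r = len(pops)
        if r < 2:
            continue
        sizes = np.array([len(p) for p in pops], dtype=float)
        nbar = sizes.mean()
        if nbar <= 1.0:
            continue
        nsum = sizes.sum()
        nc = (nsum - np.sum(sizes**2) / nsum) / (r - 1)
        if nc <= 0:
            continue
        alleles = np.unique(np.concatenate([p.reshape(-1) for p in pops]))
        if len(alleles) < 2:
            continue
        for a in alleles:
            p_i = np.array([np.mean(pop == a) for pop in pops])
            h_i = np.array(
                [np.mean((pop[:, 0] != pop[:, 1]) & ((pop == a).any(axis=1))) for pop in pops]
            )
            pbar = float(np.sum(sizes * p_i) / nsum)
            s2 = float(np.sum(sizes * (p_i - pbar) ** 2) / ((r - 1) * nbar))
            hbar = float(np.sum(sizes * h_i) / nsum)
            term = pbar * (1 - pbar) - (r - 1) / r * s2
            a_comp = (nbar / nc) * (s2 - (term - hbar / 4.0) / (nbar - 1.0))
            b_comp = (nbar / (nbar - 1.0)) * (
                term - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
            )
            c_comp = hbar / 2.0
            sum_a += a_comp
            sum_b += b_comp
            sum_c += c_comp
    return sum_a, sum_b, sum_c


def f_statistics(G: GenotypeMatrix, groups: GroupAssignment) -> FStatistics:
    """Multiallelic, multilocus FIS/FST/FIT plus per-group-pair FST.

    Components are summed over alleles and loci before the ratios are
    formed, so ``(1 - FIT) = (1 - FIS)(1 - FST)`` holds by construction.
    """
    groups.validate_against(G)
    labels = groups.labels()
    if len(labels) < 2:
        raise ValueError("f_statistics requires at least 2 groups")
    gidx = {lab: [G.index_of(a) for a in groups.members(lab)] for lab in labels}
    for lab, idx in gidx.items():
        if not idx:
            raise ValueError(f"group {lab!r} has no accessions")
    a, b, c = _wc_components(G, gidx)
    denom = a + b + c
    if denom == 0:
        raise ValueError("F-statistics undefined: no polymorphic locus across groups")
    fst = a / denom
    fit = 1.0 - c / denom
    fis = 1.0 - c / (b + c) if (b + c) != 0 else float("nan")
    pairwise: dict[tuple[str, str], float] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pa, pb, pc = _wc_components(
                G, {labels[i]: gidx[labels[i]], labels[j]: gidx[labels[j]]}
            )
            tot = pa + pb + pc
            pairwise[(labels[i], labels[j])] = pa / tot if tot != 0 else float("nan")
    return FStatistics(fis=fis, fst=fst, fit=fit, pairwise_fst=pairwise)


# ---------------------------------------------------------------------------
# Allele-level bookkeeping
# ---------------------------------------------------------------------------

def allele_richness(subset_alleles: int, reference_alleles: int) -> float:
    """Percentage of the reference collection's alleles retained:
    ``100 * subset / reference``."""
    if reference_alleles < 1:
        raise ValueError("reference allele count must be >= 1")
    if not 0 <= subset_alleles <= reference_alleles:
        raise ValueError("subset allele count must be in [0, reference]")
    return 100.0 * subset_alleles / reference_alleles


@dataclass
class AlleleClassification:
    """Frequency and locality class of every allele in a reference
    collection: ``(locus, allele) -> (freq_class, locality)`` with
    freq_class in {rare, intermediate, common} and locality in
    {exclusive, shared}."""

    freq_class: dict[tuple[str, int], str]
    locality: dict[tuple[str, int], str]
    exclusive_group: dict[tuple[str, int], str]

    def of(self, locus: str, allele: int) -> tuple[str, str]:
        key = (str(locus), int(allele))
        return self.freq_class[key], self.locality[key]


def classify_alleles(
    G: GenotypeMatrix,
    groups: GroupAssignment,
    freqs: AlleleFrequencyTable | None = None,
) -> AlleleClassification:
    """Classify every allele of the reference collection by frequency
    (rare < 0.05 <= intermediate < 0.30 <= common) and by whether its
    carriers all belong to a single a-priori group (exclusive)."""
    groups.validate_against(G)
    if freqs is None:
        freqs = allele_frequencies(G)
    freq_class: dict[tuple[str, int], str] = {}
    locality: dict[tuple[str, int], str] = {}
    exclusive_group: dict[tuple[str, int], str] = {}
    label_of = groups.mapping
    for l, name in enumerate(G.locus_names):
        cell = G.calls[:, l, :]
        for allele, f in freqs.frequencies(l).items():
            key = (name, int(allele))
            if f < RARE_MAX:
                freq_class[key] = "rare"
            elif f < COMMON_MIN:
                freq_class[key] = "intermediate"
            else:
                freq_class[key] = "common"
            carriers = np.nonzero((cell == allele).any(axis=1))[0]
            carrier_groups = {
                label_of[G.accession_ids[i]]
                for i in carriers
                if G.accession_ids[i] in label_of
            }
            if len(carrier_groups) == 1:
                locality[key] = "exclusive"
                exclusive_group[key] = next(iter(carrier_groups))
            else:
                locality[key] = "shared"
    return AlleleClassification(freq_class, locality, exclusive_group)


def write_stats_report(summary: DiversitySummary, path: str, fmt: str = "csv") -> None:
    """Per-locus table plus a summary row (CSV) or a JSON bundle."""
    frame = summary.to_frame()
    if fmt == "csv":
        mean_row = pd.DataFrame(
            {
                "locus": ["MEAN"],
                "n": [float(np.mean(summary.n))],
                "alleles": [float(np.mean(summary.allele_counts))],
                "Ho": [summary.mean_ho],
                "GD": [summary.mean_gd],
                "PIC": [summary.mean_pic],
            }
        )
        pd.concat([frame, mean_row], ignore_index=True).to_csv(path, index=False)
    elif fmt == "json":
        import json

        payload = {
            "per_locus": frame.to_dict(orient="records"),
            "means": {
                "Ho": summary.mean_ho,
                "GD": summary.mean_gd,
                "PIC": summary.mean_pic,
            },
            "total_alleles": summary.total_alleles,
            "f": summary.f,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
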