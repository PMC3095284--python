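"""Retention curves, core-size selection and cross-method comparison.

The size of a core collection is chosen from a *retention curve*: for a
sweep of nominal sizes, the sampler is run with repetitions, the stable
set (100% inclusion) is formed, and its allele richness against the full
collection is recorded.  The chosen size is the smallest whose stable set
retains at least a threshold percentage (80% by convention) of the
reference alleles.

Selections produced by different strategies are compared on: retained and
lost alleles (with the lost alleles cross-classified by frequency class and
group exclusivity), mean gene diversity (computed from the selection's own
allele frequencies and its own sample size), and accession overlap
percentages over the distinct union of all selected accessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .distance import DistanceMatrix
from .genotypes import GenotypeMatrix, GroupAssignment, allele_frequencies
from .popgen import allele_richness, classify_alleles, diversity_summary
from .samplers import CoreSelection, corex_select, random_select


@dataclass
class RetentionCurve:
    """Stable-set allele retention as a function of nominal core size."""

    sizes: list[int]
    stable_sizes: list[int]
    retained_alleles: list[int]
    retention_pct: list[float]
    mean_gd: list[float]
    reference_total: int
    method: str = "corex"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.sizes,
                "stable_size": self.stable_sizes,
                "retained_alleles": self.retained_alleles,
                "retention_pct": self.retention_pct,
                "mean_GD": self.mean_gd,
            }
        )

    def write_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def _selection_alleles(G: GenotypeMatrix, members: Sequence[str]) -> set[tuple[str, int]]:
    sub = allele_frequencies(G, members)
    out: set[tuple[str, int]] = set()
    for name, counts in zip(sub.locus_names, sub.counts):
        out.update((name, a) for a in counts)
    return out


def _mean_gd(G: GenotypeMatrix, members: Sequence[str]) -> float:
    if len(members) == 0:
        return float("nan")
    return diversity_summary(G, members).mean_gd


def retention_curve(
    G: GenotypeMatrix,
    D: DistanceMatrix | None,
    sizes: Iterable[int],
    reps: int = 100,
    seed=None,
    method: str = "corex",
) -> RetentionCurve:
    """Run the sampler at each size and record stable-set retention.

    ``mean_GD`` is the unbiased gene diversity averaged over loci, computed
    from the stable set's own allele frequencies (NaN when the stable set
    is empty).
    """
    sizes = sorted(int(k) for k in sizes)
    total, _ = _reference_totals(G)
    master = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    children = master.spawn(len(sizes))
    stable_sizes, retained, pct, gds = [], [], [], []
    for k, child in zip(sizes, children):
        if method == "corex":
            if D is None:
                raise ValueError("corex retention curve requires a distance matrix")
            sel = corex_select(D, k, reps=reps, seed=child)
        elif method == "random":
            sel = random_select(G, k, reps=reps, seed=child)
        else:
            raise ValueError(f"unknown method {method!r}")
        stable = sel.stable_set()
        stable_sizes.append(len(stable))
        if stable:
            alleles = len(_selection_alleles(G, stable))
        else:
            alleles = 0
        retained.append(alleles)
        pct.append(allele_richness(alleles, total))
        gds.append(_mean_gd(G, stable))
    return RetentionCurve(sizes, stable_sizes, retained, pct, gds, total, method)


def choose_core_size(curve: RetentionCurve, threshold: float = 80.0) -> int:
    """Smallest evaluated size whose stable set retains >= ``threshold`` %."""
    if not curve.sizes:
        raise ValueError("empty retention curve")
    for k, p in zip(curve.sizes, curve.retention_pct):
        if p >= threshold:
            return int(k)
    raise ValueError(
        f"no evaluated size reaches {threshold}% retention "
        f"(max {max(curve.retention_pct):.1f}%); increase size range"
    )


def _reference_totals(G: GenotypeMatrix) -> tuple[int, set[tuple[str, int]]]:
    ref = _selection_alleles(G, G.accession_ids)
    return len(ref), ref


@dataclass
class MethodReport:
    name: str
    size: int
    members: list[str]
    retained: list[tuple[str, int]]
    lost: list[tuple[str, int]]
    retention_pct: float
    mean_gd: float


@dataclass
class ComparisonReport:
    """Cross-method comparison over a shared reference collection."""

    methods: dict[str, MethodReport]
    reference_total: int
    reference_n: int
    union_size: int
    all_common_pct: float
    pairwise_pct: dict[tuple[str, str], float]
    unique_counts: dict[str, int]
    lost_crosstab: pd.DataFrame

    def table1(self) -> pd.DataFrame:
        """Summary with the field's usual rounding (retention 1 d.p.,
        size % 2 d.p., GD 3 d.p.)."""
        rows = []
        for name, m in self.methods.items():
            rows.append(
                {
                    "collection": name,
                    "alleles": len(m.retained),
                    "retention_pct": round(m.retention_pct, 1),
                    "size_pct": round(100.0 * m.size / self.reference_n, 2),
                    "n": m.size,
                    "GD": round(m.mean_gd, 3),
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "reference_total_alleles": self.reference_total,
            "reference_n": self.reference_n,
            "union_size": self.union_size,
            "all_common_pct": self.all_common_pct,
            "pairwise_pct": {f"{a}|{b}": v for (a, b), v in self.pairwise_pct.items()},
            "unique_counts": self.unique_counts,
            "methods": {
                name: {
                    "size": m.size,
                    "retained_alleles": len(m.retained),
                    "lost_alleles": len(m.lost),
                    "retention_pct": m.retention_pct,
                    "mean_GD": m.mean_gd,
                    "members": m.members,
                }
                for name, m in self.methods.items()
            },
            "lost_crosstab": (
                self.lost_crosstab.reset_index().to_dict(orient="records")
                if not self.lost_crosstab.empty
                else []
            ),
        }
        return json.dumps(payload, indent=2) + "\n"


def _normalize_selections(selections) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    if isinstance(selections, dict):
        items = selections.items()
    else:
        items = []
        for sel in selections:
            if isinstance(sel, CoreSelection):
                name = sel.method
                i = 2
                while name in dict(items):
                    name = f"{sel.method}_{i}"
                    i += 1
                items.append((name, sel.selected))
            else:
                raise TypeError("selections must be CoreSelection objects or a dict")
    for name, members in items:
        members = [str(m) for m in (members.selected if isinstance(members, CoreSelection) else members)]
        if not members:
            raise ValueError(f"selection {name!r} is empty")
        out[str(name)] = members
    return out


def compare_selections(
    G: GenotypeMatrix,
    groups: GroupAssignment | None,
    selections,
) -> ComparisonReport:
    """Compare named selections drawn from the same collection ``G``.

    Overlap percentages use the distinct-accession union of all selections
    as the denominator.  Lost alleles are cross-classified by frequency
    class x exclusivity when group labels are available.
    """
    named = _normalize_selections(selections)
    total, ref = _reference_totals(G)
    classification = classify_alleles(G, groups) if groups is not None else None

    methods: dict[str, MethodReport] = {}
    rows = []
    for name, members in named.items():
        for m in members:
            G.index_of(m)  # raises on unknown accession
        got = _selection_alleles(G, members)
        lost = sorted(ref - got)
        methods[name] = MethodReport(
            name=name,
            size=len(members),
            members=list(members),
            retained=sorted(got),
            lost=lost,
            retention_pct=allele_richness(len(got), total),
            mean_gd=_mean_gd(G, members),
        )
        if classification is not None:
            for key in lost:
                fc, loc = classification.of(*key)
                rows.append({"method": name, "freq_class": fc, "locality": loc})
    if rows:
        df = pd.DataFrame(rows)
        crosstab = df.groupby(["method", "freq_class", "locality"]).size().unstack(
            fill_value=0
        )
    else:
        crosstab = pd.DataFrame()

    sets = {name: set(m.members) for name, m in methods.items()}
    union = set().union(*sets.values())
    common = set.intersection(*sets.values()) if sets else set()
    names = list(sets)
    pairwise = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            inter = sets[names[i]] & sets[names[j]]
            pairwise[(names[i], names[j])] = 100.0 * len(inter) / len(union)
    unique_counts = {}
    for name in names:
        others = set().union(*(sets[o] for o in names if o != name)) if len(names) > 1 else set()
        unique_counts[name] = len(sets[name] - others)
    return ComparisonReport(
        methods=methods,
        reference_total=total,
        reference_n=G.n_accessions,
        union_size=len(union),
        all_common_pct=100.0 * len(common) / len(union),
        pairwise_pct=pairwise,
        unique_counts=unique_counts,
        lost_crosstab=crosstab,
    )


# ---------------------------------------------------------------------------
# Statistical comparisons
# ---------------------------------------------------------------------------

@dataclass
class GDTestResult:
    t_statistic: float
    t_p: float
    wilcoxon_statistic: float
    wilcoxon_p: float
    degenerate: bool = False  # all per-locus differences zero


def gd_comparison_tests(perlocus_gd_a, perlocus_gd_b) -> GDTestResult:
    """Paired two-sided Student's t and Wilcoxon signed-rank tests on
    per-locus gene-diversity vectors.

    With identical vectors both tests are undefined; by convention p = 1 is
    reported with the ``degenerate`` flag set.  The signed-rank test is
    exact for up to 25 loci, normal-approximated above.
    """
    a = np.asarray(perlocus_gd_a, dtype=float)
    b = np.asarray(perlocus_gd_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need equal-length 1-D paired vectors")
    if len(a) < 5:
        raise ValueError("need at least 5 paired loci")
    diffs = a - b
    if np.all(diffs == 0):
        return GDTestResult(0.0, 1.0, 0.0, 1.0, degenerate=True)
    t_stat, t_p = _st.ttest_rel(a, b)
    method = "exact" if len(a) <= 25 else "approx"
    try:
        w_stat, w_p = _st.wilcoxon(a, b, method=method)
    except ValueError:
        w_stat, w_p = _st.wilcoxon(a, b, method="approx")
    return GDTestResult(float(t_stat), float(t_p), float(w_stat), float(w_p))


def bartlett_test(samples: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Bartlett's chi-square test of variance homogeneity across groups."""
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    for i, arr in enumerate(arrays):
        if len(arr) < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
        if np.var(arr, ddof=1) == 0:
            raise ValueError(f"group {i} has zero variance; statistic undefined")
    stat, p = _st.bartlett(*arrays)
    return float(stat), float(p)


def write_table2(
    phenotypes_by_method: dict[str, Sequence[float]],
    gd_by_method: dict[str, float],
    path: str,
) -> None:
    """Table-2-style CSV: per collection, mean GD plus trait mean and SD."""
    rows = []
    for name, vals in phenotypes_by_method.items():
        arr = np.asarray(vals, dtype=float)
        rows.append(
            {
                "collection": name,
                "GD": round(gd_by_method.get(name, float("nan")), 3),
                "mean": round(float(arr.mean()), 2),
                "sd": round(float(arr.std(ddof=1)), 2),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
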