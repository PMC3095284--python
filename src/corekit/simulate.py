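"""Synthetic structured, partially selfing SSR populations.

The generator emulates the statistical signature of a large autogamous
germplasm collection genotyped at microsatellite loci: a few hundred
accessions in a small number of a-priori groups, ~14 alleles per locus,
moderate between-group differentiation and near-complete inbreeding.

Model
-----
* Ancestral allele frequencies per locus follow the shape SSR loci show
  in practice: a handful (2-4) of common alleles carrying most of the
  frequency mass, plus a long near-uniform tail of rare alleles (each at
  roughly 0.005-0.015).  The common weights are Dirichlet-distributed;
  the tail's total mass is drawn per locus.  This joint shape is what
  lets a 16-locus collection carry ~220 distinct alleles while its mean
  gene diversity stays near 0.67.
* Group frequencies: Balding–Nichols -- Dirichlet with concentration
  ``p * (1 - F) / F``, whose dispersion parameter ``F`` equals the
  expected FST (the closed-form recovery target).
* Individuals: partial selfing at rate ``s`` gives an equilibrium
  inbreeding coefficient ``f_eq = s / (2 - s)``; each locus is
  homozygous-by-descent with probability ``f_eq``, otherwise two
  independent draws from the group's frequencies.  Loci are realized
  independently (adequate for unlinked markers).
* Rare group-exclusive alleles: injected per locus per group with a
  configurable rate, at frequencies below a ceiling, so that the
  exclusive/rare classification machinery has true positives.
* Missing data: cells masked uniformly at a configurable rate.

Defaults mirror a ~500-accession, 16-locus, 2-group upland-rice-like
collection: divergence F = 0.15, selfing rate 0.98 (``f_eq ~ 0.96``).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, GroupAssignment, PhenotypeTable


@dataclass
class SimulationConfig:
    """Generator parameters; all rates are probabilities in [0, 1]."""

    n_accessions: int = 500
    n_groups: int = 2
    group_proportions: tuple[float, ...] | None = None  # equal if None
    n_loci: int = 16
    allele_pool_mean: float = 34.0  # alleles drawn per locus (mean)
    allele_pool_sd: float = 3.0  # dispersion of the pool size
    common_alleles_max: int = 4  # 2..max common alleles per locus
    common_dirichlet_alpha: float = 1.0
    rare_tail_mass: tuple[float, float] = (0.20, 0.32)  # per-locus range
    divergence_f: float = 0.15  # Balding–Nichols F, the expected FST
    selfing_rate: float = 0.98
    rare_allele_rate: float = 0.4  # per locus per group injection probability
    rare_freq_ceiling: float = 0.05
    missing_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.n_accessions < self.n_groups:
            raise ValueError("need n_accessions >= n_groups >= 1")
        if self.n_loci < 1:
            raise ValueError("need at least one locus")
        for name in ("divergence_f", "selfing_rate", "rare_allele_rate",
                     "rare_freq_ceiling", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]; got {v}")
        if self.allele_pool_mean < 2:
            raise ValueError("allele_pool_mean must be >= 2")
        if self.common_alleles_max < 2:
            raise ValueError("common_alleles_max must be >= 2")
        lo, hi = self.rare_tail_mass
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("rare_tail_mass must be a range inside [0, 1)")
        if self.group_proportions is not None:
            props = tuple(float(p) for p in self.group_proportions)
            if len(props) != self.n_groups or any(p <= 0 for p in props):
                raise ValueError("group_proportions must be positive, one per group")
            total = sum(props)
            self.group_proportions = tuple(p / total for p in props)

    @property
    def equilibrium_inbreeding(self) -> float:
        """f at the partial-selfing equilibrium, s / (2 - s)."""
        s = self.selfing_rate
        return s / (2.0 - s)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2) + "\n"


def _group_sizes(cfg: SimulationConfig) -> list[int]:
    props = cfg.group_proportions or tuple(1.0 / cfg.n_groups for _ in range(cfg.n_groups))
    sizes = [int(np.floor(p * cfg.n_accessions)) for p in props]
    i = 0
    while sum(sizes) < cfg.n_accessions:
        sizes[i % cfg.n_groups] += 1
        i += 1
    if any(s < 1 for s in sizes):
        raise ValueError("group proportions leave a group empty")
    return sizes


def simulate_structured_population(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, GroupAssignment]:
    """Draw a genotype matrix plus group labels under the model above."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    sizes = _group_sizes(cfg)
    n, L, K_groups = cfg.n_accessions, cfg.n_loci, cfg.n_groups
    f_eq = cfg.equilibrium_inbreeding
    group_of = np.repeat(np.arange(K_groups), sizes)

    calls = np.empty((n, L, 2), dtype=np.int32)
    next_code = 0
    for l in range(L):
        k = int(np.clip(np.rint(rng.normal(cfg.allele_pool_mean,
                                           cfg.allele_pool_sd)),
                        max(4, cfg.common_alleles_max), 80))
        m_common = int(rng.integers(2, cfg.common_alleles_max + 1))
        w = np.sort(rng.dirichlet(np.full(m_common, cfg.common_dirichlet_alpha)))[::-1]
        tail = rng.uniform(*cfg.rare_tail_mass)
        m_rare = k - m_common
        if m_rare == 0:
            base = w.copy()
        else:
            base = np.concatenate([w * (1.0 - tail), np.full(m_rare, tail / m_rare)])
        rng.shuffle(base)
        codes = np.arange(next_code, next_code + k)
        next_code += k
        group_freqs = []
        for g in range(K_groups):
            if cfg.divergence_f <= 0:
                q = base.copy()
            else:
                conc = base * (1.0 - cfg.divergence_f) / cfg.divergence_f
                # Dirichlet needs strictly positive concentrations
                q = rng.dirichlet(np.maximum(conc, 1e-8))
            group_freqs.append([codes.copy(), q])
        # rare group-exclusive injections
        for g in range(K_groups):
            if rng.random() < cfg.rare_allele_rate:
                u = rng.uniform(0.001, max(cfg.rare_freq_ceiling, 0.0011))
                gcodes, q = group_freqs[g]
                group_freqs[g] = [
                    np.append(gcodes, next_code),
                    np.append(q * (1.0 - u), u),
                ]
                next_code += 1
        start = 0
        for g, sz in enumerate(sizes):
            gcodes, q = group_freqs[g]
            rows = slice(start, start + sz)
            hom = rng.random(sz) < f_eq
            draw1 = gcodes[rng.choice(len(q), size=sz, p=q)]
            draw2 = gcodes[rng.choice(len(q), size=sz, p=q)]
            calls[rows, l, 0] = draw1
            calls[rows, l, 1] = np.where(hom, draw1, draw2)
            start += sz
    if cfg.missing_rate > 0:
        mask = rng.random((n, L)) < cfg.missing_rate
        # keep at least one typed accession per locus
        for l in range(L):
            if mask[:, l].all():
                mask[rng.integers(n), l] = False
        calls[mask] = MISSING

    ids = [f"ACC{i + 1:04d}" for i in range(n)]
    groups = GroupAssignment({ids[i]: f"G{group_of[i] + 1}" for i in range(n)})
    return GenotypeMatrix(ids, [f"SSR{l + 1:02d}" for l in range(L)], calls), groups


def simulate_phenotypes(
    assignment: GroupAssignment,
    group_means: dict[str, float] | float = 2.89,
    group_sds: dict[str, float] | float = 0.57,
    replicate_sd: float = 0.125,
    n_replicates: int = 3,
    seed: int | None = None,
) -> PhenotypeTable:
    """Replicated normal trait values (e.g. 100-grain weight in grams).

    Each accession's true mean is drawn from its group's normal
    distribution; replicates add within-plot noise with SD
    ``replicate_sd``.  Scalar means/SDs apply to every group.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    labels = assignment.labels()
    if isinstance(group_means, (int, float)):
        group_means = {lab: float(group_means) for lab in labels}
    if isinstance(group_sds, (int, float)):
        group_sds = {lab: float(group_sds) for lab in labels}
    for lab in labels:
        if group_sds[lab] < 0 or replicate_sd < 0:
            raise ValueError("standard deviations must be >= 0")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    values: dict[str, list[float]] = {}
    for aid, lab in assignment.mapping.items():
        mu = rng.normal(group_means[lab], group_sds[lab])
        values[aid] = [float(rng.normal(mu, replicate_sd)) for _ in range(n_replicates)]
    return PhenotypeTable(values)
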