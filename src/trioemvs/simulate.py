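"""Synthetic case-parent trio data with an admixed haplotype pool.

The pool is parametric: each bi-allelic site has one allele frequency
per subpopulation, and the "weighted MAF" of a site is the
admixture-weighted average of the subpopulation frequencies, folded to
<= 0.5.  The default pool emulates a two-subpopulation 25%/75% admixture
over 12 gene regions of 2.7 kb, with a handful of common sites and a
spectrum of rare sites per region, including one region-1 rare site
pinned at weighted MAF 0.026.

Disease is generated by a logistic model on the child's causal
genotypes, logit P(y = 1) = a0 + sum_i beta_i G_i with a0 = -2.2; trios
are ascertained on the affected child by rejection sampling with the
exact logistic acceptance probability.  Causal common variants have
effects +/-0.9; causal rare effects scale with rarity as
+/- 0.4 |log10 MAF|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import HaplotypePair, TrioFamily

DEFAULT_INTERCEPT = -2.2
DEFAULT_COMMON_EFFECT = 0.9
DEFAULT_EFFECT_SCALE = 0.4


@dataclass(frozen=True)
class PoolConfig:
    """Parameters of the parametric haplotype pool."""

    n_regions: int = 12
    region_length: int = 2700
    admixture: tuple[float, ...] = (0.25, 0.75)
    common_per_region: int = 4
    common_maf_range: tuple[float, float] = (0.05, 0.5)
    #: weighted-MAF bins of the rare spectrum and sites drawn per region from each
    rare_bins: tuple[tuple[float, float], ...] = ((1e-4, 1e-3), (1e-3, 1e-2), (1e-2, 5e-2))
    rare_per_region: tuple[int, ...] = (3, 3, 2)
    #: pin one region-1 rare site at exactly this weighted MAF (None to disable)
    anchor_maf: float | None = 0.026
    #: relative spread of subpopulation frequencies around the weighted MAF
    divergence: float = 0.5
    #: copy whole region segments from this many founder haplotypes with
    #: probability ``ld_weight`` (0 founders = independent sites, no LD)
    ld_founders: int = 0
    ld_weight: float = 0.5


@dataclass
class PopulationPool:
    """Per-subpopulation allele frequencies over a set of sites.

    ``freqs`` has shape (n_subpops, n_sites) and stores the frequency of
    the allele coded 1.  ``weights`` are the admixture proportions.
    """

    freqs: np.ndarray
    weights: np.ndarray
    positions: np.ndarray
    region_ids: np.ndarray
    variant_ids: tuple[str, ...]
    anchor_id: str | None = None
    ld_founders: dict[int, np.ndarray] = field(default_factory=dict)  # subpop -> (K, n_sites)
    ld_weight: float = 0.0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.freqs < 0) or np.any(self.freqs > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("admixture weights must be non-negative and sum to 1")

    @property
    def n_sites(self) -> int:
        return self.freqs.shape[1]

    @property
    def weighted_freq(self) -> np.ndarray:
        """Admixture-weighted frequency of the allele coded 1."""
        return self.weights @ self.freqs

    @property
    def weighted_maf(self) -> np.ndarray:
        """Weighted minor allele frequency (folded to <= 0.5)."""
        w = self.weighted_freq
        return np.minimum(w, 1.0 - w)

    def draw_haplotypes(self, subpop: int, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n haplotypes (0/1 arrays) from one subpopulation."""
        hap = (rng.random((n, self.n_sites)) < self.freqs[subpop]).astype(np.int8)
        if self.ld_founders and self.ld_weight > 0:
            founders = self.ld_founders[subpop]
            for r in np.unique(self.region_ids):
                cols = np.flatnonzero(self.region_ids == r)
                copy = rng.random(n) < self.ld_weight
                if copy.any():
                    pick = rng.integers(founders.shape[0], size=int(copy.sum()))
                    hap[np.ix_(copy, cols)] = founders[np.ix_(pick, cols)]
        return hap


def _subpop_freqs(w: np.ndarray, weights: np.ndarray, divergence: float, rng) -> np.ndarray:
    """Spread a target weighted frequency across subpopulations.

    The first subpopulation gets a multiplicative perturbation; the last
    absorbs the remainder so the weighted average stays exactly w.
    """
    n_pop = len(weights)
    freqs = np.tile(w, (n_pop, 1))
    if n_pop >= 2 and divergence > 0:
        m = rng.uniform(1.0 - divergence, 1.0 + divergence, size=w.shape)
        f0 = np.clip(w * m, 0.0, 1.0)
        rest = (w - weights[0] * f0) / weights[1:].sum()
        freqs[0] = f0
        freqs[1:] = np.clip(rest, 0.0, 1.0)
    return freqs


def build_pool(config: PoolConfig = PoolConfig(), seed: int = 0) -> PopulationPool:
    """Construct a reproducible pool realizing the configured spectrum."""
    rng = np.random.default_rng(seed)
    weights = np.asarray(config.admixture, dtype=float)
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("admixture weights must be non-negative and sum to 1")
    if len(config.rare_per_region) != len(config.rare_bins):
        raise ValueError("rare_per_region must match rare_bins")
    mafs, regions, kinds = [], [], []
    anchor_index = None
    for r in range(1, config.n_regions + 1):
        lo, hi = config.common_maf_range
        for _ in range(config.common_per_region):
            mafs.append(rng.uniform(lo, hi))
            regions.append(r)
            kinds.append("common")
        for (blo, bhi), count in zip(config.rare_bins, config.rare_per_region):
            draws = np.exp(rng.uniform(np.log(blo), np.log(bhi), size=count))
            for m in draws:
                mafs.append(float(m))
                regions.append(r)
                kinds.append("rare")
        if r == 1 and config.anchor_maf is not None:
            anchor_index = len(mafs)
            mafs.append(float(config.anchor_maf))
            regions.append(1)
            kinds.append("rare")
    mafs = np.array(mafs)
    regions = np.array(regions)
    # evenly spaced positions within each region, in region order
    order = np.argsort(regions, kind="stable")
    positions = np.empty(len(mafs), dtype=int)
    for r in range(1, config.n_regions + 1):
        cols = order[regions[order] == r]
        start = (r - 1) * config.region_length
        positions[cols] = start + np.linspace(
            1, config.region_length, num=len(cols), dtype=int, endpoint=False
        )
    ids = tuple(f"V{i + 1:04d}" for i in range(len(mafs)))
    freqs = _subpop_freqs(mafs, weights, config.divergence, rng)
    pool = PopulationPool(
        freqs=freqs,
        weights=weights,
        positions=positions,
        region_ids=regions,
        variant_ids=ids,
        anchor_id=ids[anchor_index] if anchor_index is not None else None,
        ld_weight=config.ld_weight if config.ld_founders else 0.0,
    )
    if config.ld_founders:
        pool.ld_founders = {
            k: (rng.random((config.ld_founders, pool.n_sites)) < freqs[k]).astype(np.int8)
            for k in range(len(weights))
        }
    return pool


@dataclass(frozen=True)
class CausalModel:
    """Generating disease model: which variants are causal and how strongly."""

    intercept: float = DEFAULT_INTERCEPT
    #: region -> effect of that region's first common site
    common_effects: tuple[tuple[int, float], ...] = (
        (3, DEFAULT_COMMON_EFFECT),
        (6, -DEFAULT_COMMON_EFFECT),
    )
    #: regions eligible to harbor causal rare variants
    causal_regions: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    #: "per_region": fixed number of causal rare sites drawn per causal region;
    #: "fraction": a fraction of all eligible rare sites drawn pool-wide
    rare_scheme: str = "per_region"
    rare_per_region: int = 2
    rare_fraction: float = 0.05
    rare_maf_max: float = 0.03
    effect_scale: float = DEFAULT_EFFECT_SCALE
    #: give the pinned anchor site a risk-increasing causal effect
    anchor_causal: bool = True


@dataclass
class SimTruth:
    """The generating model of a synthetic dataset, for the metrics module."""

    table: pd.DataFrame  # variant_id, region_id, position, weighted_maf, effect, causal
    intercept: float

    @property
    def causal_ids(self) -> set[str]:
        return set(self.table.loc[self.table["causal"], "variant_id"])

    @property
    def associated_regions(self) -> set[int]:
        return set(self.table.loc[self.table["causal"], "region_id"].astype(int))

    def effects(self) -> np.ndarray:
        return self.table["effect"].to_numpy(dtype=float)


def rare_effect_magnitude(weighted_maf: np.ndarray, scale: float = DEFAULT_EFFECT_SCALE) -> np.ndarray:
    """Effect magnitude scale * |log10 MAF|: rarer variants act more strongly."""
    return scale * np.abs(np.log10(weighted_maf))


def assign_effects(pool: PopulationPool, model: CausalModel = CausalModel(), seed: int = 0) -> SimTruth:
    """Choose causal variants and assign effects under the generating model.

    Causal rare variants receive magnitude ``effect_scale * |log10 MAF|``
    with signs split equally between risk and protection (a seeded coin
    breaks odd counts).  The anchor site, when present and requested, is
    always causal and risk-increasing.
    """
    rng = np.random.default_rng(seed)
    maf = pool.weighted_maf
    n = pool.n_sites
    effects = np.zeros(n)
    is_common = maf >= 0.05
    for region, eff in model.common_effects:
        cols = np.flatnonzero((pool.region_ids == region) & is_common)
        if len(cols) == 0:
            raise ValueError(f"no common site available in region {region}")
        # the region's most common site: the design wants unambiguously
        # common causal variants (ascertainment shifts the sample MAF of a
        # causal site, so a near-threshold site could be reclassified rare)
        effects[cols[np.argmax(maf[cols])]] = eff
    anchor_col = None
    if pool.anchor_id is not None and model.anchor_causal:
        anchor_col = pool.variant_ids.index(pool.anchor_id)
        effects[anchor_col] = rare_effect_magnitude(maf[anchor_col], model.effect_scale)
    eligible = np.flatnonzero(
        ~is_common & (maf < model.rare_maf_max) & np.isin(pool.region_ids, model.causal_regions)
    )
    eligible = eligible[eligible != anchor_col]
    if len(eligible) == 0 and anchor_col is None:
        raise ValueError("no rare sites eligible to be causal")
    if model.rare_scheme == "per_region":
        chosen = []
        for r in model.causal_regions:
            in_r = eligible[pool.region_ids[eligible] == r]
            take = min(model.rare_per_region, len(in_r))
            chosen.extend(rng.choice(in_r, size=take, replace=False))
        chosen = np.array(sorted(chosen), dtype=int)
    elif model.rare_scheme == "fraction":
        k = int(round(model.rare_fraction * len(eligible)))
        chosen = np.sort(rng.choice(eligible, size=k, replace=False))
    else:
        raise ValueError(f"unknown rare_scheme {model.rare_scheme!r}")
    signs = np.ones(len(chosen))
    signs[len(chosen) // 2 :] = -1.0
    if len(chosen) % 2:
        signs[len(chosen) // 2] = rng.choice([-1.0, 1.0])
    rng.shuffle(signs)
    effects[chosen] = signs * rare_effect_magnitude(maf[chosen], model.effect_scale)
    table = pd.DataFrame(
        {
            "variant_id": list(pool.variant_ids),
            "region_id": pool.region_ids,
            "position": pool.positions,
            "weighted_maf": maf,
            "effect": effects,
            "causal": effects != 0.0,
        }
    )
    return SimTruth(table=table, intercept=model.intercept)


@dataclass
class SimulatedTrio:
    """A sampled trio with full phased haplotypes."""

    family: TrioFamily
    mother: HaplotypePair
    father: HaplotypePair
    child: HaplotypePair
    subpop: int


def sample_case_trio(
    pool: PopulationPool,
    truth: SimTruth,
    rng: np.random.Generator,
    batch: int = 32,
    max_batches: int = 100000,
) -> SimulatedTrio:
    """Rejection-sample one trio ascertained on an affected child.

    Parents are drawn as two individuals from a single subpopulation
    (admixture acts at the family level); one haplotype of each parent
    is transmitted; the candidate child is accepted with its exact
    logistic disease probability.
    """
    effects = truth.effects()
    causal = np.flatnonzero(effects != 0.0)
    subpop = int(rng.choice(len(pool.weights), p=pool.weights))
    for _ in range(max_batches):
        haps = pool.draw_haplotypes(subpop, 4 * batch, rng).reshape(batch, 4, -1)
        pick = rng.integers(2, size=(batch, 2))
        rows = np.arange(batch)
        tm = haps[rows, pick[:, 0]]
        tf = haps[rows, 2 + pick[:, 1]]
        geno_causal = (tm[:, causal] + tf[:, causal]).astype(float)
        logit = truth.intercept + geno_causal @ effects[causal]
        p_dis = 1.0 / (1.0 + np.exp(-logit))
        accept = rng.random(batch) < p_dis
        if accept.any():
            i = int(np.flatnonzero(accept)[0])
            mother = HaplotypePair(maternal=haps[i, pick[i, 0]], paternal=haps[i, 1 - pick[i, 0]])
            father = HaplotypePair(maternal=haps[i, 2 + pick[i, 1]], paternal=haps[i, 3 - pick[i, 1]])
            child = HaplotypePair(maternal=mother.maternal, paternal=father.maternal)
            um, uf = mother.paternal, father.paternal
            case = child.genotype
            sibs = np.stack([um + child.paternal, child.maternal + uf, um + uf])
            fam = TrioFamily(family_id="", case_genotype=case, pseudo_siblings=sibs)
            return SimulatedTrio(family=fam, mother=mother, father=father, child=child, subpop=subpop)
    raise RuntimeError("acceptance probability is (numerically) zero everywhere")


def acceptance_rate(
    pool: PopulationPool, truth: SimTruth, n_draws: int, seed: int = 0
) -> float:
    """Fraction of candidate trios accepted by the ascertainment step.

    Draws candidate children exactly as the rejection sampler does and
    returns the empirical acceptance fraction.  Under a null model
    (no causal effects) this estimates the disease prevalence
    1 / (1 + exp(-intercept)).
    """
    rng = np.random.default_rng(seed)
    effects = truth.effects()
    causal = np.flatnonzero(effects != 0.0)
    subpops = rng.choice(len(pool.weights), size=n_draws, p=pool.weights)
    accepted = 0
    for s in np.unique(subpops):
        n = int((subpops == s).sum())
        haps = pool.draw_haplotypes(int(s), 4 * n, rng).reshape(n, 4, -1)
        pick = rng.integers(2, size=(n, 2))
        rows = np.arange(n)
        geno = haps[rows, pick[:, 0]][:, causal] + haps[rows, 2 + pick[:, 1]][:, causal]
        logit = truth.intercept + geno.astype(float) @ effects[causal]
        accepted += int((rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).sum())
    return accepted / n_draws


@dataclass
class SimulatedDataset:
    """A replicate dataset of ascertained trios plus its generating truth."""

    trios: list[SimulatedTrio]
    pool: PopulationPool
    truth: SimTruth
    seed: int
    sample_maf: np.ndarray = field(default=None)  # parental-haplotype MAF per site
    polymorphic: np.ndarray = field(default=None)

    @property
    def families(self) -> list[TrioFamily]:
        return [t.family for t in self.trios]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": list(self.pool.variant_ids),
                "sample_maf": self.sample_maf,
                "polymorphic": self.polymorphic,
            }
        )


def simulate_dataset(
    pool: PopulationPool,
    truth: SimTruth,
    n_families: int,
    seed: int = 0,
) -> SimulatedDataset:
    """Generate a replicate of ascertained trios.

    A master seed spawns one independent stream per family, so datasets
    are reproducible and family sampling is order-independent.  Sample
    MAFs and polymorphism flags are computed from the 4N parental
    haplotypes (the alt allele is folded if it is the major one).
    """
    streams = np.random.SeedSequence(seed).spawn(n_families)
    trios = []
    for i, ss in enumerate(streams):
        trio = sample_case_trio(pool, truth, np.random.default_rng(ss))
        trio.family.family_id = f"F{i + 1:05d}"
        trios.append(trio)
    n_hap = 4 * n_families
    if n_families:
        counts = np.zeros(pool.n_sites, dtype=int)
        for t in trios:
            counts += t.mother.genotype + t.father.genotype
        freq = counts / n_hap
        sample_maf = np.minimum(freq, 1.0 - freq)
        polymorphic = (counts > 0) & (counts < n_hap)
    else:
        sample_maf = np.zeros(pool.n_sites)
        polymorphic = np.zeros(pool.n_sites, dtype=bool)
    return SimulatedDataset(
        trios=trios, pool=pool, truth=truth, seed=seed, sample_maf=sample_maf, polymorphic=polymorphic
    )
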