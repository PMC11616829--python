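"""Replicate simulation studies: simulate, classify, tune once, fit each.

This mirrors the evaluation protocol of the simulation experiments: a
single haplotype pool and causal model are fixed; replicate trio
datasets are drawn from them; variants are classified common/rare by
the *median* sample MAF across the replicates (so the model layout is
identical in every replicate); the exclusion variances are tuned on the
first replicate and reused; each replicate is then fit and thresholded,
and the replicate outcomes feed the region- and variant-level metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .em import SelectionResult, final_selection, run_daem
from .likelihood import ContrastMatrix, build_contrasts
from .metrics import ReplicateOutcome
from .priors import AnnealingSchedule, ConvergenceSpec, PriorSpec
from .simulate import (
    CausalModel,
    PoolConfig,
    PopulationPool,
    SimTruth,
    assign_effects,
    build_pool,
    simulate_dataset,
)
from .tuning import TuneResult, TuningGrid, tune
from .variants import ModelLayout, Variant, build_layout, classify_variants

log = logging.getLogger(__name__)


@dataclass
class ReplicateFit:
    dataset: int
    selection: SelectionResult
    converged: bool
    outcome: ReplicateOutcome


@dataclass
class StudyResult:
    pool: PopulationPool
    truth: SimTruth
    variants: list[Variant]
    layout: ModelLayout
    median_maf: np.ndarray
    prior: PriorSpec
    tuning: TuneResult | None
    fits: list[ReplicateFit] = field(default_factory=list)

    @property
    def outcomes(self) -> list[ReplicateOutcome]:
        return [f.outcome for f in self.fits]

    def selection_rate(self, variant_id: str) -> float:
        """Fraction of replicates in which a variant was selected."""
        return float(np.mean([variant_id in f.selection.selected_variants for f in self.fits]))


def default_study_inputs(seed: int = 0) -> tuple[PopulationPool, SimTruth]:
    """The default pool and causal architecture used by the replicate studies."""
    pool = build_pool(PoolConfig(), seed=seed)
    truth = assign_effects(pool, CausalModel(), seed=seed + 1)
    return pool, truth


def outcome_from_selection(
    dataset: int,
    selection: SelectionResult,
    truth: SimTruth,
    polymorphic_ids: set[str],
    all_regions: set[int],
) -> ReplicateOutcome:
    return ReplicateOutcome(
        dataset=dataset,
        selected_variants=selection.selected_variants,
        selected_regions=selection.selected_regions,
        associated_variants=truth.causal_ids,
        associated_regions=truth.associated_regions,
        all_regions=all_regions,
        polymorphic=polymorphic_ids,
    )


def run_study(
    pool: PopulationPool,
    truth: SimTruth,
    n_families: int,
    n_replicates: int,
    seed: int = 0,
    prior: PriorSpec | None = None,
    tune_first: bool = True,
    maf_threshold: float = 0.05,
    threshold: float = 0.5,
    conv: ConvergenceSpec = ConvergenceSpec(),
    anneal: AnnealingSchedule = AnnealingSchedule(),
    solver: str = "newton",
) -> StudyResult:
    """Simulate ``n_replicates`` datasets of ``n_families`` trios and fit each.

    When ``prior`` is None and ``tune_first`` is True, the exclusion
    variances are tuned on the first replicate via the two-stage
    regularization path and the tuned prior is reused for every
    replicate; otherwise the given (or default) prior is used directly.
    """
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_replicates)]
    datasets = [
        simulate_dataset(pool, truth, n_families, seed=rs) for rs in rep_seeds
    ]
    # classify by median sample MAF across replicates -> one shared layout
    maf_matrix = np.stack([d.sample_maf for d in datasets])
    median_maf = np.median(maf_matrix, axis=0)
    base_variants = [
        Variant(id=v, position=int(pool.positions[i]), region_id=int(pool.region_ids[i]), maf=0.0)
        for i, v in enumerate(pool.variant_ids)
    ]
    variants = classify_variants(base_variants, maf=median_maf, threshold=maf_threshold)
    layout = build_layout(variants)
    all_regions = {int(r) for r in np.unique(pool.region_ids)}

    def contrasts_for(d) -> ContrastMatrix:
        return build_contrasts(d.families).reorder_columns(layout.column_order)

    tuning_result = None
    if prior is None:
        prior = PriorSpec()
        if tune_first:
            log.info("tuning exclusion variances on replicate 1 (%d trios)", n_families)
            tuning_result = tune(
                contrasts_for(datasets[0]),
                layout,
                variants,
                prior_template=prior,
                grid1=TuningGrid(stage=1),
                grid2=TuningGrid(stage=2),
                conv=conv,
                anneal=anneal,
                threshold=threshold,
                solver=solver,
            )
            prior = tuning_result.prior
            log.info("tuned prior: v0=%g v2=%g", prior.v0, prior.v2)
    fits = []
    for d_idx, d in enumerate(datasets):
        state = run_daem(
            contrasts_for(d),
            layout,
            prior,
            conv=conv,
            anneal=anneal,
            solver=solver,
            keep_trace=False,
        )
        sel = final_selection(state, layout, variants, threshold=threshold)
        poly_ids = {pool.variant_ids[i] for i in np.flatnonzero(d.polymorphic)}
        fits.append(
            ReplicateFit(
                dataset=d_idx,
                selection=sel,
                converged=state.converged,
                outcome=outcome_from_selection(d_idx, sel, truth, poly_ids, all_regions),
            )
        )
        log.info(
            "replicate %d/%d: %d variants, %d regions selected%s",
            d_idx + 1,
            n_replicates,
            len(sel.selected_variants),
            len(sel.selected_regions),
            "" if state.converged else " (not converged)",
        )
    return StudyResult(
        pool=pool,
        truth=truth,
        variants=variants,
        layout=layout,
        median_maf=median_maf,
        prior=prior,
        tuning=tuning_result,
        fits=fits,
    )
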