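"""Replicate-level evaluation metrics for region and variant selection.

Two summaries are used across replicate analyses of simulated data:

* the weighted average correct association percentage (WACAP) at the
  region level — the mean of region-level sensitivity and specificity,
  each averaged over regions and replicates;
* average true/false positive rates (ATPR/AFPR) at the variant level,
  whose per-replicate denominators count only variants polymorphic in
  that replicate (or only variants polymorphic in *every* replicate,
  for the cross-dataset summary convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ReplicateOutcome:
    """Selection outcome of one replicate against its generating truth."""

    dataset: int
    selected_variants: set[str]
    selected_regions: set[int]
    associated_variants: set[str]
    associated_regions: set[int]
    all_regions: set[int]
    polymorphic: set[str]  # variant ids polymorphic in this replicate
    analyzed_variants: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.analyzed_variants:
            self.analyzed_variants = set(self.polymorphic)
        extra = self.selected_regions - self.all_regions
        if extra:
            raise ValueError(f"replicate {self.dataset}: selected unknown regions {sorted(extra)}")


def wacap(outcomes: list[ReplicateOutcome]) -> float:
    """Weighted average correct association percentage, as a fraction.

    (1/2) [ sum_r P(selected | associated) / #associated regions
          + sum_r P(unselected | unassociated) / #unassociated regions ],
    with the per-region probabilities estimated across replicates.
    """
    if not outcomes:
        raise ValueError("no replicates given")
    assoc = sorted(outcomes[0].associated_regions)
    unassoc = sorted(outcomes[0].all_regions - outcomes[0].associated_regions)
    if not assoc or not unassoc:
        raise ValueError("need at least one associated and one unassociated region")
    sens = np.mean([[r in o.selected_regions for o in outcomes] for r in assoc], axis=1)
    spec = np.mean([[r not in o.selected_regions for o in outcomes] for r in unassoc], axis=1)
    return float(0.5 * (sens.mean() + spec.mean()))


def atpr_afpr(
    outcomes: list[ReplicateOutcome],
    restrict: str = "per-dataset",
    variant_subset: set[str] | None = None,
) -> tuple[float, float]:
    """Average true and false positive rates of individual-variant selection.

    For each replicate d the TPR is N_d(selected | associated) over the
    number of associated variants polymorphic in d, and likewise for the
    FPR over unassociated variants; the rates are averaged over
    replicates.  ``restrict="all-polymorphic"`` limits the universe to
    variants polymorphic in every replicate.  Replicates with an empty
    denominator are skipped for the affected rate with a warning.
    """
    if restrict not in ("per-dataset", "all-polymorphic"):
        raise ValueError(f"unknown restrict mode {restrict!r}")
    universe = None
    if restrict == "all-polymorphic":
        universe = set.intersection(*(o.polymorphic for o in outcomes))
    tprs, fprs = [], []
    for o in outcomes:
        pool = o.polymorphic if universe is None else universe
        if variant_subset is not None:
            pool = pool & variant_subset
        assoc = pool & o.associated_variants
        unassoc = pool - o.associated_variants
        if assoc:
            tprs.append(len(o.selected_variants & assoc) / len(assoc))
        else:
            warnings.warn(f"replicate {o.dataset}: no polymorphic associated variants; skipped for ATPR")
        if unassoc:
            fprs.append(len(o.selected_variants & unassoc) / len(unassoc))
        else:
            warnings.warn(f"replicate {o.dataset}: no polymorphic unassociated variants; skipped for AFPR")
    atpr = float(np.mean(tprs)) if tprs else 0.0
    afpr = float(np.mean(fprs)) if fprs else 0.0
    return atpr, afpr


def maf_stratified_report(
    outcomes: list[ReplicateOutcome],
    maf: dict[str, float],
    bins: tuple[float, ...] = (0.0, 0.01, 0.05, np.inf),
    restrict: str = "all-polymorphic",
) -> pd.DataFrame:
    """ATPR/AFPR and variant counts per median-MAF bin.

    ``maf`` maps variant id to its (median) MAF.  Bins are half-open
    [lo, hi); empty bins report NaN rates.
    """
    rows = []
    universe = set(maf)
    if restrict == "all-polymorphic":
        universe &= set.intersection(*(o.polymorphic for o in outcomes))
    assoc_all = outcomes[0].associated_variants
    for lo, hi in zip(bins[:-1], bins[1:]):
        subset = {v for v in universe if lo <= maf[v] < hi}
        n_assoc = len(subset & assoc_all)
        n_unassoc = len(subset - assoc_all)
        if subset:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                atpr, afpr = atpr_afpr(outcomes, restrict=restrict, variant_subset=subset)
            atpr = atpr if n_assoc else np.nan
            afpr = afpr if n_unassoc else np.nan
        else:
            atpr = afpr = np.nan
        rows.append((lo, hi, n_assoc, n_unassoc, atpr, afpr))
    return pd.DataFrame(
        rows, columns=["maf_lo", "maf_hi", "n_associated", "n_unassociated", "atpr", "afpr"]
    )
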