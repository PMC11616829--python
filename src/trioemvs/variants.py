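"""Variant metadata and the common/rare model layout.

The joint model orders its coefficient vector as the S common variants
first, followed by the L rare variants grouped contiguously by region.
:class:`ModelLayout` freezes that ordering and the per-region group
boundaries so the E-step can aggregate rare-variant densities with a
single ``reduceat``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Default minor-allele-frequency threshold separating common from rare.
DEFAULT_MAF_THRESHOLD = 0.05


@dataclass
class Variant:
    """A single bi-allelic site.

    ``maf`` is a minor-allele frequency in [0, 1]; ``is_common`` mirrors
    ``maf >= threshold`` as set by :func:`classify_variants`.  ``region_id``
    is a 1-based region/gene label; every rare variant must carry one.
    """

    id: str
    position: int
    region_id: int
    maf: float
    is_common: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"variant {self.id}: maf {self.maf} outside [0, 1]")


def classify_variants(
    variants: list[Variant],
    maf: np.ndarray | None = None,
    threshold: float = DEFAULT_MAF_THRESHOLD,
) -> list[Variant]:
    """Partition variants into common (maf >= threshold) and rare (maf < threshold).

    When ``maf`` is given (e.g. the median sample MAF across replicate
    datasets) it overrides each variant's stored ``maf``.  Returns new
    ``Variant`` objects with ``is_common`` set; the input list is untouched.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    out = []
    for i, v in enumerate(variants):
        m = float(maf[i]) if maf is not None else v.maf
        out.append(replace(v, maf=m, is_common=m >= threshold))
    for v in out:
        if not v.is_common and v.region_id <= 0:
            raise ValueError(f"rare variant {v.id} has no region assignment")
    return out


@dataclass(frozen=True)
class ModelLayout:
    """Column layout of the joint coefficient vector (common first, then
    rare grouped by region).

    Attributes
    ----------
    common_cols, rare_cols
        Indices into the *original* variant ordering for each model column.
    rare_regions
        Region id of each rare model column (non-decreasing).
    region_ids
        The distinct regions that contain rare variants, in order.
    group_starts
        Offsets into the rare block where each region's group begins
        (suitable for ``np.add.reduceat``).
    """

    common_cols: np.ndarray
    rare_cols: np.ndarray
    rare_regions: np.ndarray
    region_ids: np.ndarray
    group_starts: np.ndarray
    variant_ids: tuple[str, ...] = field(default=())

    @property
    def S(self) -> int:
        return len(self.common_cols)

    @property
    def L(self) -> int:
        return len(self.rare_cols)

    @property
    def R(self) -> int:
        return len(self.region_ids)

    @property
    def p(self) -> int:
        return self.S + self.L

    @property
    def J(self) -> np.ndarray:
        """Number of rare variants per region (length R)."""
        ends = np.append(self.group_starts[1:], self.L)
        return ends - self.group_starts

    @property
    def column_order(self) -> np.ndarray:
        """Original-variant index of each model column."""
        return np.concatenate([self.common_cols, self.rare_cols]).astype(int)

    def region_of_rare(self, j: int) -> int:
        return int(self.rare_regions[j])


def build_layout(variants: list[Variant]) -> ModelLayout:
    """Derive the model column layout from classified variants.

    Rare variants are sorted by (region_id, original index); common
    variants keep their original order.
    """
    is_common = np.array([v.is_common for v in variants], dtype=bool)
    idx = np.arange(len(variants))
    common_cols = idx[is_common]
    rare_idx = idx[~is_common]
    regions = np.array([variants[i].region_id for i in rare_idx])
    order = np.lexsort((rare_idx, regions))
    rare_cols = rare_idx[order]
    rare_regions = regions[order]
    region_ids, group_starts = np.unique(rare_regions, return_index=True)
    # np.unique sorts, and rare_regions is sorted, so starts are increasing
    return ModelLayout(
        common_cols=common_cols,
        rare_cols=rare_cols,
        rare_regions=rare_regions,
        region_ids=region_ids,
        group_starts=group_starts,
        variant_ids=tuple(v.id for v in variants),
    )
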