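import numpy as np
import pytest

from trioemvs.likelihood import ContrastMatrix, TrioFamily, build_contrasts
from trioemvs.variants import ModelLayout, Variant, build_layout, classify_variants


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_families(rng: np.random.Generator, n_families: int, p: int) -> list[TrioFamily]:
    """Random valid trios: per variant, draw parental haplotypes and a
    transmission, then derive the case and its 3 pseudo-siblings."""
    fams = []
    for n in range(n_families):
        haps = rng.integers(0, 2, size=(4, p)).astype(np.int8)  # m1 m2 f1 f2
        tm, um = (haps[0], haps[1]) if rng.random() < 0.5 else (haps[1], haps[0])
        tf, uf = (haps[2], haps[3]) if rng.random() < 0.5 else (haps[3], haps[2])
        fams.append(
            TrioFamily(
                family_id=f"F{n}",
                case_genotype=tm + tf,
                pseudo_siblings=np.stack([um + tf, tm + uf, um + uf]),
            )
        )
    return fams


def contrasts_from_rows(rows: np.ndarray) -> ContrastMatrix:
    """Wrap raw contrast rows (3N, p) in a ContrastMatrix."""
    rows = np.asarray(rows, dtype=np.int8)
    n = rows.shape[0] // 3
    return ContrastMatrix(
        X=rows,
        family_ids=tuple(f"F{i}" for i in range(n)),
        monomorphic=np.zeros(rows.shape[1], dtype=bool),
    )


def toy_panel(S: int, region_sizes: list[int]) -> tuple[list[Variant], ModelLayout]:
    """A variant panel with S common variants and the given rare-region sizes."""
    variants = []
    k = 0
    for s in range(S):
        variants.append(Variant(id=f"C{s}", position=k + 1, region_id=s % max(len(region_sizes), 1) + 1, maf=0.3))
        k += 1
    for r, J in enumerate(region_sizes, start=1):
        for j in range(J):
            variants.append(Variant(id=f"R{r}_{j}", position=k + 1, region_id=r, maf=0.01))
            k += 1
    variants = classify_variants(variants)
    return variants, build_layout(variants)


@pytest.fixture
def small_instance(rng):
    """A small random model instance: 3 common + 2 regions of (2, 3) rare."""
    variants, layout = toy_panel(3, [2, 3])
    fams = random_families(rng, 40, layout.p)
    contrasts = build_contrasts(fams).reorder_columns(layout.column_order)
    return contrasts, layout, variants
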