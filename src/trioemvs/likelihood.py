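"""Pseudo-sibling construction and the conditional logistic trio likelihood.

A phased case-parent trio determines four equally likely child genotypes:
the observed case plus the three "pseudo-siblings" formed from the
untransmitted parental haplotypes.  Conditioning the logistic disease
model on this 1:3 matched set eliminates population-stratification
nuisance parameters, leaving

    P(case | parents) = exp(g_0 . w) / sum_{i=0..3} exp(g_i . w)

which depends on the data only through the per-family contrast vectors
x_i = g_0 - g_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp


class MendelianError(ValueError):
    """A child haplotype cannot be matched to the parental haplotypes."""

    def __init__(self, family_id: str, parent: str, bad_sites: np.ndarray):
        self.family_id = family_id
        self.bad_sites = np.asarray(bad_sites)
        sites = ", ".join(str(int(s)) for s in self.bad_sites[:10])
        more = "" if len(self.bad_sites) <= 10 else f" (+{len(self.bad_sites) - 10} more)"
        super().__init__(
            f"family {family_id}: child {parent} haplotype inconsistent with "
            f"{parent}'s haplotypes at variant index(es) {sites}{more}"
        )


@dataclass
class HaplotypePair:
    """Two phased haplotypes (0/1 allele vectors) of one individual."""

    maternal: np.ndarray
    paternal: np.ndarray

    def __post_init__(self) -> None:
        self.maternal = np.asarray(self.maternal, dtype=np.int8)
        self.paternal = np.asarray(self.paternal, dtype=np.int8)
        if self.maternal.shape != self.paternal.shape:
            raise ValueError("haplotypes of one individual differ in length")

    @property
    def genotype(self) -> np.ndarray:
        """Additive minor-allele count (0/1/2)."""
        return self.maternal + self.paternal


@dataclass
class TrioFamily:
    """One trio reduced to the case genotype plus its 3 pseudo-siblings."""

    family_id: str
    case_genotype: np.ndarray
    pseudo_siblings: np.ndarray  # (3, p)

    def __post_init__(self) -> None:
        self.case_genotype = np.asarray(self.case_genotype, dtype=np.int8)
        self.pseudo_siblings = np.asarray(self.pseudo_siblings, dtype=np.int8)
        if self.pseudo_siblings.shape != (3, self.case_genotype.shape[0]):
            raise ValueError(
                f"family {self.family_id}: expected 3 pseudo-siblings of length "
                f"{self.case_genotype.shape[0]}, got shape {self.pseudo_siblings.shape}"
            )


def _match_transmitted(
    child_hap: np.ndarray, parent: HaplotypePair, family_id: str, label: str
) -> tuple[np.ndarray, np.ndarray]:
    """Return (transmitted, untransmitted) parental haplotypes for one parent."""
    mism1 = child_hap != parent.maternal
    if not mism1.any():
        return parent.maternal, parent.paternal
    mism2 = child_hap != parent.paternal
    if not mism2.any():
        return parent.paternal, parent.maternal
    # neither matches: report the sites of the better assignment
    bad = mism1 if mism1.sum() <= mism2.sum() else mism2
    raise MendelianError(family_id, label, np.flatnonzero(bad))


def enumerate_pseudo_siblings(
    mother: HaplotypePair,
    father: HaplotypePair,
    child: HaplotypePair,
    family_id: str = "",
) -> TrioFamily:
    """Build the case genotype and the 3 pseudo-sibling genotypes.

    The child's maternal (paternal) haplotype must equal one of the
    mother's (father's) haplotypes; otherwise :class:`MendelianError` is
    raised naming the offending variants.  Pseudo-siblings are the three
    alternative transmissions, in the fixed order (untransmitted-maternal
    x transmitted-paternal, transmitted-maternal x untransmitted-paternal,
    untransmitted x untransmitted).
    """
    tm, um = _match_transmitted(child.maternal, mother, family_id, "maternal")
    tf, uf = _match_transmitted(child.paternal, father, family_id, "paternal")
    case = tm + tf
    sibs = np.stack([um + tf, tm + uf, um + uf])
    return TrioFamily(family_id=family_id, case_genotype=case, pseudo_siblings=sibs)


@dataclass
class ContrastMatrix:
    """Stacked per-family contrasts x_in = g_case - g_pseudo-sib,i.

    ``X`` has shape (3N, p) with family n occupying rows 3n..3n+2;
    entries lie in {-2,...,2}.  ``monomorphic`` flags columns whose
    contrasts are all zero *and* whose allele count is zero everywhere
    (the variant is absent from the data, not merely uninformative).
    """

    X: np.ndarray
    family_ids: tuple[str, ...]
    monomorphic: np.ndarray

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def reorder_columns(self, order: np.ndarray) -> "ContrastMatrix":
        return ContrastMatrix(
            X=np.ascontiguousarray(self.X[:, order]),
            family_ids=self.family_ids,
            monomorphic=self.monomorphic[order],
        )


def build_contrasts(families: list[TrioFamily], n_variants: int | None = None) -> ContrastMatrix:
    """Assemble the (3N, p) contrast matrix from trio families."""
    if not families:
        p = n_variants or 0
        return ContrastMatrix(
            X=np.zeros((0, p), dtype=np.int8), family_ids=(), monomorphic=np.ones(p, dtype=bool)
        )
    p = families[0].case_genotype.shape[0]
    if n_variants is not None and n_variants != p:
        raise ValueError(f"family {families[0].family_id}: expected {n_variants} variants, found {p}")
    rows = []
    any_allele = np.zeros(p, dtype=bool)
    for fam in families:
        if fam.case_genotype.shape[0] != p:
            raise ValueError(
                f"family {fam.family_id}: genotype length {fam.case_genotype.shape[0]} != {p}"
            )
        rows.append(fam.case_genotype[None, :] - fam.pseudo_siblings)
        any_allele |= fam.case_genotype > 0
        any_allele |= fam.pseudo_siblings.any(axis=0)
    X = np.concatenate(rows).astype(np.int8)
    mono = (~X.any(axis=0)) & ~any_allele
    return ContrastMatrix(X=X, family_ids=tuple(f.family_id for f in families), monomorphic=mono)


def _linear_scores(contrasts: ContrastMatrix, omega: np.ndarray) -> np.ndarray:
    """Per-family pseudo-sibling scores z_in = x_in . omega, shape (N, 3)."""
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (contrasts.p,):
        raise ValueError(f"omega has length {omega.shape}, expected ({contrasts.p},)")
    if not np.all(np.isfinite(omega)):
        raise ValueError("omega contains non-finite entries")
    return (contrasts.X @ omega).reshape(-1, 3)


def conditional_log_likelihood(contrasts: ContrastMatrix, omega: np.ndarray) -> float:
    """Conditional logistic log-likelihood of the case transmissions.

    Equals -sum_n log(1 + sum_i exp(-x_in . omega)); computed with a
    stable log-sum-exp so it is finite for any finite omega.  At
    omega = 0 the value is -N log 4 (uniform over the 4 configurations).
    """
    Z = _linear_scores(contrasts, omega)
    A = np.concatenate([np.zeros((Z.shape[0], 1)), -Z], axis=1)
    return float(-logsumexp(A, axis=1).sum())


def softmax_weights(contrasts: ContrastMatrix, omega: np.ndarray) -> np.ndarray:
    """Posterior configuration weights u_in of the 3 pseudo-siblings, (N, 3).

    u_in = exp(-z_in) / (1 + sum_j exp(-z_jn)); the case weight is
    1 - sum_i u_in.
    """
    Z = _linear_scores(contrasts, omega)
    A = np.concatenate([np.zeros((Z.shape[0], 1)), -Z], axis=1)
    A -= A.max(axis=1, keepdims=True)
    E = np.exp(A)
    return E[:, 1:] / E.sum(axis=1, keepdims=True)


def conditional_log_likelihood_grad(contrasts: ContrastMatrix, omega: np.ndarray) -> np.ndarray:
    """Gradient of :func:`conditional_log_likelihood` with respect to omega."""
    U = softmax_weights(contrasts, omega)
    return contrasts.X.T.astype(float) @ U.reshape(-1)
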