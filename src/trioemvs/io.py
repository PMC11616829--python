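"""Format adapters: phased VCF + PED trios, region maps, result tables.

Conventions: VCF positions are 1-based and genotypes must be phased
("|" separator) for all trio members; BED region maps are 0-based
half-open and are converted at read time.  The minor allele is defined
per dataset from the parental haplotypes (4 independent haplotypes per
family), with a tie at frequency 0.5 broken toward the VCF ALT allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .em import SelectionResult
from .likelihood import (
    HaplotypePair,
    MendelianError,
    TrioFamily,
    enumerate_pseudo_siblings,
)
from .simulate import SimulatedDataset
from .variants import Variant, classify_variants

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# writing simulated datasets

_VCF_HEADER = """##fileformat=VCFv4.2
##source=trioemvs
##contig=<ID={chrom}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path, chrom: str = "1") -> dict[str, Path]:
    """Write a simulated dataset as phased VCF + PED + region map + truth.

    Sample order per family is child, mother, father; parental genotypes
    are written transmitted-haplotype first so a read round-trip
    reproduces the pseudo-sibling ordering exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pool, truth = dataset.pool, dataset.truth
    samples, ped_rows = [], []
    for trio in dataset.trios:
        fid = trio.family.family_id
        child, mother, father = f"{fid}_c", f"{fid}_m", f"{fid}_f"
        samples.extend([child, mother, father])
        ped_rows.append((fid, father, "0", "0", "1", "1"))
        ped_rows.append((fid, mother, "0", "0", "2", "1"))
        ped_rows.append((fid, child, father, mother, "0", "2"))
    vcf_path = out / "trios.vcf"
    with open(vcf_path, "w") as fh:
        fh.write(_VCF_HEADER.format(chrom=chrom))
        cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        fh.write(cols + ("\tFORMAT\t" + "\t".join(samples) if samples else "") + "\n")
        for i in range(pool.n_sites):
            gts = []
            for trio in dataset.trios:
                c, m, f = trio.child, trio.mother, trio.father
                gts.append(f"{c.maternal[i]}|{c.paternal[i]}")
                gts.append(f"{m.maternal[i]}|{m.paternal[i]}")
                gts.append(f"{f.maternal[i]}|{f.paternal[i]}")
            row = f"{chrom}\t{pool.positions[i]}\t{pool.variant_ids[i]}\tA\tT\t.\tPASS\t."
            fh.write(row + ("\tGT\t" + "\t".join(gts) if gts else "") + "\n")
    ped_path = out / "trios.ped"
    with open(ped_path, "w") as fh:
        fh.write("#family_id\tindividual_id\tfather_id\tmother_id\tsex\tphenotype\n")
        for row in ped_rows:
            fh.write("\t".join(row) + "\n")
    region_path = out / "regions.tsv"
    pd.DataFrame({"variant_id": list(pool.variant_ids), "region_id": pool.region_ids}).to_csv(
        region_path, sep="\t", index=False
    )
    truth_path = out / "truth.tsv"
    truth.table.to_csv(truth_path, sep="\t", index=False)
    summary_path = out / "summary.tsv"
    dataset.summary_frame().to_csv(summary_path, sep="\t", index=False)
    return {
        "vcf": vcf_path,
        "ped": ped_path,
        "regions": region_path,
        "truth": truth_path,
        "summary": summary_path,
    }


# ---------------------------------------------------------------------------
# region maps


def read_region_map(path: str | Path) -> "RegionMap":
    """Read a variant->region map: 2-column TSV or 4-column BED.

    TSV columns: variant_id, region_id.  BED columns: chrom, start, end,
    region_id with 0-based half-open intervals mapped onto 1-based VCF
    positions.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] >= 4:
        return RegionMap(
            intervals=[
                (row[0], int(row[1]), int(row[2]), int(row[3])) for row in df.itertuples(index=False)
            ]
        )
    if df.shape[1] == 2:
        first = df.iloc[0]
        if first[0] == "variant_id":  # header present
            df = df.iloc[1:]
        return RegionMap(by_id={vid: int(r) for vid, r in df.itertuples(index=False)})
    raise ValueError(f"region map {path}: expected 2 (TSV) or >=4 (BED) columns, got {df.shape[1]}")


@dataclass
class RegionMap:
    by_id: dict[str, int] | None = None
    intervals: list[tuple[str, int, int, int]] | None = None

    def region_of(self, variant_id: str, chrom: str, pos: int) -> int | None:
        """Region of a variant; ``pos`` is 1-based."""
        if self.by_id is not None:
            return self.by_id.get(variant_id)
        for c, start, end, region in self.intervals:
            if c == chrom and start < pos <= end:  # BED half-open, 0-based
                return region
        return None


# ---------------------------------------------------------------------------
# reading trios


def read_trios(
    vcf_path: str | Path,
    ped_path: str | Path,
    region_map: RegionMap | str | Path | None = None,
    maf_threshold: float = 0.05,
    min_mac: int = 0,
) -> tuple[list[TrioFamily], list[Variant]]:
    """Load phased trios from a VCF + PED pair.

    Children are PED rows with both parents set; families with missing
    members, unphased genotypes, or Mendelian inconsistencies are
    dropped with a warning.  Variants are classified common/rare by
    parental-haplotype MAF against ``maf_threshold``; sites with
    parental minor-allele count below ``min_mac`` are excluded.
    """
    from cyvcf2 import VCF

    if region_map is not None and not isinstance(region_map, RegionMap):
        region_map = read_region_map(region_map)
    ped = pd.read_csv(
        ped_path,
        sep=r"\s+",
        comment="#",
        header=None,
        dtype=str,
        names=["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"],
        usecols=range(6),
    )
    vcf = VCF(str(vcf_path))
    sample_idx = {s: i for i, s in enumerate(vcf.samples)}
    chroms, positions, ids = [], [], []
    haps = []  # per variant: (n_samples, 2) int8
    phased_ok = None
    for var in vcf:
        g = np.asarray(var.genotype.array())  # (n_samples, 3): a, b, phased
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
        haps.append(g[:, :2].astype(np.int8))
        ph = g[:, 2].astype(bool)
        phased_ok = ph if phased_ok is None else (phased_ok & ph)
    if not ids:
        raise ValueError(f"{vcf_path}: no variants")
    H = np.stack(haps, axis=0)  # (n_variants, n_samples, 2)
    trios = ped[(ped["father_id"] != "0") & (ped["mother_id"] != "0")]
    families: list[TrioFamily] = []
    parent_rows = []
    n_skipped = 0
    for row in trios.itertuples(index=False):
        members = (row.individual_id, row.mother_id, row.father_id)
        if any(m not in sample_idx for m in members):
            log.warning("family %s: member(s) missing from VCF; skipped", row.family_id)
            n_skipped += 1
            continue
        ci, mi, fi = (sample_idx[m] for m in members)
        if not (phased_ok[ci] and phased_ok[mi] and phased_ok[fi]):
            log.warning("family %s: unphased genotype(s); skipped", row.family_id)
            n_skipped += 1
            continue
        child = HaplotypePair(maternal=H[:, ci, 0], paternal=H[:, ci, 1])
        mother = HaplotypePair(maternal=H[:, mi, 0], paternal=H[:, mi, 1])
        father = HaplotypePair(maternal=H[:, fi, 0], paternal=H[:, fi, 1])
        try:
            fam = enumerate_pseudo_siblings(mother, father, child, family_id=row.family_id)
        except MendelianError as exc:
            log.warning("family dropped: %s", exc)
            n_skipped += 1
            continue
        families.append(fam)
        parent_rows.append((mi, fi))
    if n_skipped:
        log.info("skipped %d of %d candidate families", n_skipped, len(trios))
    if not families:
        raise ValueError("no usable trios found")
    # minor-allele orientation and MAF from parental haplotypes
    n_hap = 4 * len(families)
    alt_counts = np.zeros(len(ids), dtype=int)
    for mi, fi in parent_rows:
        alt_counts += H[:, mi, :].sum(axis=1) + H[:, fi, :].sum(axis=1)
    alt_freq = alt_counts / n_hap
    flip = alt_freq > 0.5  # ties at 0.5 stay on the ALT allele
    maf = np.where(flip, 1.0 - alt_freq, alt_freq)
    if flip.any():
        for fam in families:
            fam.case_genotype[flip] = 2 - fam.case_genotype[flip]
            fam.pseudo_siblings[:, flip] = 2 - fam.pseudo_siblings[:, flip]
    mac = np.minimum(alt_counts, n_hap - alt_counts)
    keep = mac >= min_mac
    variants = []
    for i in np.flatnonzero(keep):
        region = region_map.region_of(ids[i], chroms[i], positions[i]) if region_map else None
        variants.append(
            Variant(id=ids[i], position=int(positions[i]), region_id=int(region or 0), maf=float(maf[i]))
        )
    if not keep.all():
        cols = np.flatnonzero(keep)
        for fam in families:
            fam.case_genotype = fam.case_genotype[cols]
            fam.pseudo_siblings = fam.pseudo_siblings[:, cols]
        log.info("excluded %d variant(s) with minor allele count < %d", int((~keep).sum()), min_mac)
    variants = classify_variants(variants, threshold=maf_threshold)
    return families, variants


def read_contrast_table(path: str | Path) -> tuple[list[TrioFamily], list[str]]:
    """Read a pre-built per-family contrast table.

    TSV columns: family_id, role in {case, sib1, sib2, sib3}, then one
    0/1/2 genotype column per variant.
    """
    df = pd.read_csv(path, sep="\t")
    variant_cols = [c for c in df.columns if c not in ("family_id", "role")]
    families = []
    for fid, grp in df.groupby("family_id", sort=False):
        grp = grp.set_index("role")
        missing = {"case", "sib1", "sib2", "sib3"} - set(grp.index)
        if missing:
            raise ValueError(f"family {fid}: missing roles {sorted(missing)}")
        case = grp.loc["case", variant_cols].to_numpy(dtype=np.int8)
        sibs = np.stack([grp.loc[r, variant_cols].to_numpy(dtype=np.int8) for r in ("sib1", "sib2", "sib3")])
        families.append(TrioFamily(family_id=str(fid), case_genotype=case, pseudo_siblings=sibs))
    return families, variant_cols


# ---------------------------------------------------------------------------
# result tables


def write_selection(result: SelectionResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the per-variant and per-region selection TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vpath = out / "variants.tsv"
    rpath = out / "region_selection.tsv"
    result.variants.to_csv(vpath, sep="\t", index=False)
    result.regions.to_csv(rpath, sep="\t", index=False)
    return {"variants": vpath, "regions": rpath}


def read_selection(out_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    out = Path(out_dir)
    return (
        pd.read_csv(out / "variants.tsv", sep="\t"),
        pd.read_csv(out / "region_selection.tsv", sep="\t"),
    )
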