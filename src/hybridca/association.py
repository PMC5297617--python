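"""Single-marker association between parental SNPs and combining ability.

For every SNP site the F1 crosses of the factorial are partitioned by the
zygosity the cross inherits from its two homozygous parents: crosses whose
parents carry different alleles form the heterozygous group, crosses whose
parents carry the same allele the homozygous group (a cross with a missing
parental call is excluded at that site).  A two-sample t-test on the
per-cross trait means decides, at alpha = 0.01 by default, whether the
heterozygous group performs significantly better (a favorable locus) or
worse (unfavorable) than the homozygous group.  The marker's share of
phenotypic variance is the squared point-biserial correlation between the
group indicator and the trait value, and the locus-level heterosis is

    100 * (mean_het - mean_hom) / mean_hom .

The scan follows the Model / Results idiom::

    res = SingleMarkerScan(matrix, pheno).fit(alpha=0.01)
    res.frame; res.per_trait_summary(); res.per_parent_counts()
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from hybridca.io import HOM_ALT, MISSING, ParentGenotypeMatrix, PhenotypeTable, Zygosity, derive_f1_zygosity
from hybridca.snp_summary import (
    EFFECT_MISSENSE,
    EFFECT_NONSENSE,
    EFFECT_SYNONYMOUS,
    REGION_SPLICE,
    SnpAnnotation,
)

logger = logging.getLogger(__name__)

FAVORABLE = "favorable"
UNFAVORABLE = "unfavorable"
NONE = "none"


@dataclass
class LocusPartition:
    """Heterozygous / homozygous / excluded crosses at one site."""

    site_id: str
    het_crosses: list[tuple[str, str]]
    hom_crosses: list[tuple[str, str]]
    excluded_crosses: list[tuple[str, str]]

    @property
    def n_het(self) -> int:
        return len(self.het_crosses)

    @property
    def n_hom(self) -> int:
        return len(self.hom_crosses)

    def testable(self, min_group: int = 5) -> bool:
        return self.n_het >= min_group and self.n_hom >= min_group


def partition_crosses(
    matrix: ParentGenotypeMatrix,
    design: list[tuple[str, str]],
    site_id: str,
) -> LocusPartition:
    """Assign every design cross to the het/hom/excluded set at one site."""
    j = matrix.site_index(site_id)
    het, hom, excl = [], [], []
    for f, m in design:
        zyg = derive_f1_zygosity(
            int(matrix.calls[matrix.parent_index(f), j]),
            int(matrix.calls[matrix.parent_index(m), j]),
        )
        (het if zyg is Zygosity.HET else hom if zyg is Zygosity.HOM else excl).append((f, m))
    return LocusPartition(site_id, het, hom, excl)


def heterosis_percent(mean_het: float, mean_hom: float) -> float:
    """Percent heterosis of the heterozygous-locus group:
    100 * (mean_het - mean_hom) / mean_hom."""
    if mean_hom == 0:
        raise ValueError("undefined heterosis: homozygous-group mean is zero")
    return 100.0 * (mean_het - mean_hom) / mean_hom


@dataclass
class AssociationRecord:
    """One locus x trait association test."""

    site_id: str
    trait: str
    n_het: int
    n_hom: int
    mean_het: float = np.nan
    mean_hom: float = np.nan
    delta: float = np.nan
    t_stat: float = np.nan
    df: float = np.nan
    p_value: float = np.nan
    r_squared: float = np.nan
    heterosis_pct: float = np.nan
    significant: bool = False
    sign_class: str = NONE
    testable: bool = True
    chrom: str = ""
    pos: int = 0
    p_adjusted: float = field(default=np.nan)


def sma_test(
    partition: LocusPartition,
    trait_means,
    trait: str = "trait",
    alpha: float = 0.01,
    variant: str = "welch",
    min_group: int = 5,
) -> AssociationRecord:
    """Two-sided t-test of heterozygous vs homozygous cross means.

    ``trait_means`` maps (female, male) to the cross's phenotype mean.
    ``variant`` selects Welch (default) or pooled-variance t.  A locus
    with fewer than ``min_group`` crosses in either group is returned as
    non-testable with undefined statistics.  If both groups have zero
    variance and equal means the test degenerates to t = 0, p = 1.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    rec = AssociationRecord(partition.site_id, trait, partition.n_het, partition.n_hom)
    if not partition.testable(min_group):
        rec.testable = False
        return rec
    het = np.asarray([trait_means[c] for c in partition.het_crosses], dtype=float)
    hom = np.asarray([trait_means[c] for c in partition.hom_crosses], dtype=float)
    rec.mean_het, rec.mean_hom = float(het.mean()), float(hom.mean())
    rec.delta = rec.mean_het - rec.mean_hom
    if het.var(ddof=1) == 0 and hom.var(ddof=1) == 0 and rec.delta == 0:
        rec.t_stat, rec.p_value = 0.0, 1.0
        rec.df = float(len(het) + len(hom) - 2)
        rec.r_squared = 0.0
    else:
        t, p = stats.ttest_ind(het, hom, equal_var=(variant == "pooled"))
        rec.t_stat, rec.p_value = float(t), float(p)
        if variant == "pooled":
            rec.df = float(len(het) + len(hom) - 2)
        else:
            v1, v2 = het.var(ddof=1) / len(het), hom.var(ddof=1) / len(hom)
            if v1 + v2 == 0:
                rec.df = float(len(het) + len(hom) - 2)
            else:
                rec.df = float(
                    (v1 + v2) ** 2 / (v1**2 / (len(het) - 1) + v2**2 / (len(hom) - 1))
                )
        indicator = np.r_[np.ones(len(het)), np.zeros(len(hom))]
        values = np.r_[het, hom]
        if values.std() == 0:
            rec.r_squared = 0.0
        else:
            rec.r_squared = float(np.corrcoef(indicator, values)[0, 1] ** 2)
    if rec.mean_hom != 0:
        rec.heterosis_pct = heterosis_percent(rec.mean_het, rec.mean_hom)
    rec.significant = bool(rec.p_value < alpha)
    if rec.significant:
        rec.sign_class = FAVORABLE if rec.delta > 0 else UNFAVORABLE if rec.delta < 0 else NONE
    return rec


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------

class ScanResults:
    """Results of a genome-wide single-marker scan."""

    def __init__(
        self,
        records: list[AssociationRecord],
        matrix: ParentGenotypeMatrix,
        design: list[tuple[str, str]],
        alpha: float,
        n_nontestable: int,
    ):
        self.records = records
        self.matrix = matrix
        self.design = design
        self.alpha = alpha
        self.n_nontestable = n_nontestable

    @property
    def frame(self) -> pd.DataFrame:
        cols = [
            "site_id", "chrom", "pos", "trait", "n_het", "n_hom", "mean_het", "mean_hom",
            "delta", "t_stat", "df", "p_value", "p_adjusted", "r_squared", "heterosis_pct",
            "significant", "sign_class",
        ]
        return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in self.records], columns=cols)

    def significant_records(self) -> list[AssociationRecord]:
        return [r for r in self.records if r.significant]

    # -- report tables ---------------------------------------------------
    def per_trait_summary(self) -> pd.DataFrame:
        return per_trait_summary(self.records)

    def per_parent_counts(self) -> pd.DataFrame:
        return per_parent_counts(self.records, self.matrix)

    def filter_functional(self, annotations: dict[str, SnpAnnotation]) -> "ScanResults":
        kept = filter_functional(self.records, annotations)
        return ScanResults(kept, self.matrix, self.design, self.alpha, self.n_nontestable)

    def summary(self) -> str:
        n_sig = len(self.significant_records())
        traits = sorted({r.trait for r in self.records})
        lines = [
            "Single-marker CA scan",
            f"  {len(self.records)} locus-trait tests on {len(self.design)} crosses; "
            f"{self.n_nontestable} non-testable site-trait pairs skipped",
            f"  {n_sig} significant at alpha={self.alpha}",
            "",
            self.per_trait_summary().to_string(float_format=lambda v: f"{v:.3g}"),
        ]
        return "\n".join(lines)


class SingleMarkerScan:
    """Genome-wide single-marker scan of SNPs against F1 performance.

    Parameters
    ----------
    matrix
        Parental genotypes.
    pheno
        Balanced F1 phenotype table; its crosses must equal the design.
    design
        Cross list; defaults to all female x male pairs of ``pheno``.
    """

    def __init__(
        self,
        matrix: ParentGenotypeMatrix,
        pheno: PhenotypeTable,
        design: list[tuple[str, str]] | None = None,
    ):
        self.matrix = matrix
        self.pheno = pheno
        self.design = design if design is not None else pheno.crosses
        known = set(matrix.parents)
        for f, m in self.design:
            if f not in known or m not in known:
                raise ValueError(f"design cross ({f}, {m}) references unknown parent")

    def fit(
        self,
        traits: list[str] | None = None,
        alpha: float = 0.01,
        variant: str = "welch",
        correction: str = "none",
        min_group: int = 5,
    ) -> ScanResults:
        if correction not in ("none", "bh"):
            raise ValueError(f"unknown correction {correction!r}")
        traits = traits if traits is not None else self.pheno.traits
        means = {t: dict(self.pheno.cross_mean_series(t)) for t in traits}
        records: list[AssociationRecord] = []
        n_nontestable = 0
        site_lookup = {s.site_id: s for s in self.matrix.sites}
        for site in self.matrix.sites:
            part = partition_crosses(self.matrix, self.design, site.site_id)
            if not part.testable(min_group):
                n_nontestable += len(traits)
                continue
            for t in traits:
                rec = sma_test(part, means[t], trait=t, alpha=alpha, variant=variant, min_group=min_group)
                rec.chrom, rec.pos = site.chrom, site_lookup[site.site_id].pos
                records.append(rec)
        if not records:
            logger.warning("no testable site: empty scan result")
        if correction == "bh" and records:
            from statsmodels.stats.multitest import multipletests

            pvals = np.array([r.p_value for r in records])
            reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
            for r, rej, pa in zip(records, reject, p_adj):
                r.p_adjusted = float(pa)
                r.significant = bool(rej)
                r.sign_class = (
                    (FAVORABLE if r.delta > 0 else UNFAVORABLE if r.delta < 0 else NONE)
                    if r.significant
                    else NONE
                )
        if n_nontestable:
            logger.info("%d non-testable site-trait pairs skipped", n_nontestable)
        return ScanResults(records, self.matrix, self.design, alpha, n_nontestable)


def genome_scan(
    matrix: ParentGenotypeMatrix,
    design: list[tuple[str, str]] | None,
    pheno: PhenotypeTable,
    traits: list[str] | None = None,
    alpha: float = 0.01,
    variant: str = "welch",
    correction: str = "none",
    min_group: int = 5,
) -> ScanResults:
    """Functional wrapper around :class:`SingleMarkerScan`."""
    return SingleMarkerScan(matrix, pheno, design).fit(
        traits=traits, alpha=alpha, variant=variant, correction=correction, min_group=min_group
    )


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def per_trait_summary(records: list[AssociationRecord]) -> pd.DataFrame:
    """Per-trait summary of significant loci (survey-table layout).

    For each trait: number of significant loci; total het/hom crosses
    over those loci; cross-count-weighted pooled group means; the average
    percent heterosis both as (i) the mean of per-locus heterosis and
    (ii) the heterosis formula applied to the pooled means; counts of
    favorable (positive) and unfavorable (negative) loci with their mean
    absolute heterosis.
    """
    rows = []
    traits = list(dict.fromkeys(r.trait for r in records))
    for t in traits:
        sig = [r for r in records if r.trait == t and r.significant]
        n_het = sum(r.n_het for r in sig)
        n_hom = sum(r.n_hom for r in sig)
        het_mean = (
            sum(r.mean_het * r.n_het for r in sig) / n_het if n_het else np.nan
        )
        hom_mean = (
            sum(r.mean_hom * r.n_hom for r in sig) / n_hom if n_hom else np.nan
        )
        pos = [r for r in sig if r.sign_class == FAVORABLE]
        neg = [r for r in sig if r.sign_class == UNFAVORABLE]
        rows.append(
            {
                "trait": t,
                "n_loci": len(sig),
                "n_het_crosses": n_het,
                "het_mean": het_mean,
                "n_hom_crosses": n_hom,
                "hom_mean": hom_mean,
                "heterosis_pct_per_locus": float(np.mean([r.heterosis_pct for r in sig])) if sig else np.nan,
                "heterosis_pct_pooled": (
                    heterosis_percent(het_mean, hom_mean) if n_het and n_hom and hom_mean != 0 else np.nan
                ),
                "n_positive": len(pos),
                "n_negative": len(neg),
                "mean_abs_heterosis_positive": (
                    float(np.mean([abs(r.heterosis_pct) for r in pos])) if pos else np.nan
                ),
                "mean_abs_heterosis_negative": (
                    float(np.mean([abs(r.heterosis_pct) for r in neg])) if neg else np.nan
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trait", "n_loci", "n_het_crosses", "het_mean", "n_hom_crosses", "hom_mean",
            "heterosis_pct_per_locus", "heterosis_pct_pooled", "n_positive", "n_negative",
            "mean_abs_heterosis_positive", "mean_abs_heterosis_negative",
        ],
    )


def per_parent_counts(
    records: list[AssociationRecord],
    matrix: ParentGenotypeMatrix,
) -> pd.DataFrame:
    """Per parent x trait: significant loci at which the parent carries
    the alternate allele, split by favorable/unfavorable sign."""
    rows = []
    traits = list(dict.fromkeys(r.trait for r in records))
    sig = [r for r in records if r.significant]
    for parent in matrix.parents:
        i = matrix.parent_index(parent)
        for t in traits:
            pos = neg = 0
            for r in sig:
                if r.trait != t:
                    continue
                if matrix.calls[i, matrix.site_index(r.site_id)] == HOM_ALT:
                    if r.sign_class == FAVORABLE:
                        pos += 1
                    elif r.sign_class == UNFAVORABLE:
                        neg += 1
            rows.append(
                {
                    "parent": parent,
                    "role": matrix.roles[i],
                    "trait": t,
                    "positive": pos,
                    "negative": neg,
                    "total": pos + neg,
                }
            )
    return pd.DataFrame(rows)


def filter_functional(
    records: list[AssociationRecord],
    annotations: dict[str, SnpAnnotation],
) -> list[AssociationRecord]:
    """Keep loci in coding regions (synonymous / missense / nonsense) or
    at splice sites."""
    keep_effects = {EFFECT_SYNONYMOUS, EFFECT_MISSENSE, EFFECT_NONSENSE}
    out = []
    for r in records:
        ann = annotations.get(r.site_id)
        if ann is None:
            raise ValueError(f"unannotated site {r.site_id}")
        if ann.coding_effect in keep_effects or ann.region_class == REGION_SPLICE:
            out.append(r)
    return out
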