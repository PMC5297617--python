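"""Descriptive SNP layer: substitution classes, window densities, hotspots,
and genic-effect annotation of parental SNPs.

The annotation is a deliberately small coding-effect classifier: region
class by precedence exon > splice site > intron > intergenic across
overlapping gene models, and for CDS positions the standard codon table
applied to the mutated codon (strand-aware).  It covers the classes a
GBS SNP survey tabulates (intergenic / splice site / intron / exon with
synonymous / missense / nonsense) and nothing more.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from hybridca.io import HOM_ALT, BASES, GeneModel, ParentGenotypeMatrix, SnpSite

logger = logging.getLogger(__name__)

TRANSITION = "transition"
TRANSVERSION = "transversion"

REGION_INTERGENIC = "intergenic"
REGION_SPLICE = "splice_site"
REGION_INTRON = "intron"
REGION_EXON = "exon"
#: precedence of region classes, most severe first
_REGION_RANK = {REGION_EXON: 0, REGION_SPLICE: 1, REGION_INTRON: 2, REGION_INTERGENIC: 3}

EFFECT_SYNONYMOUS = "synonymous"
EFFECT_MISSENSE = "missense"
EFFECT_NONSENSE = "nonsense"
EFFECT_NA = "not_applicable"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass(frozen=True)
class SnpAnnotation:
    """Classification of one SNP site."""

    site_id: str
    substitution_class: str
    region_class: str
    coding_effect: str = EFFECT_NA


def classify_substitution(ref: str, alt: str) -> str:
    """Transition (purine<->purine or pyrimidine<->pyrimidine: C/T, G/A)
    versus transversion (all other base exchanges)."""
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"bases must be in {BASES}: {ref}/{alt}")
    if ref == alt:
        raise ValueError(f"not a polymorphism: {ref}>{alt}")
    pair = {ref, alt}
    return TRANSITION if pair <= _PURINES or pair <= _PYRIMIDINES else TRANSVERSION


def ts_tv_ratio(annotations) -> float:
    """count(transitions) / count(transversions)."""
    n_ts = sum(1 for a in annotations if a.substitution_class == TRANSITION)
    n_tv = sum(1 for a in annotations if a.substitution_class == TRANSVERSION)
    if n_tv == 0:
        raise ValueError("undefined ratio: zero transversions")
    return n_ts / n_tv


# ---------------------------------------------------------------------------
# window densities
# ---------------------------------------------------------------------------

def window_density(
    matrix: ParentGenotypeMatrix,
    chrom_lengths: dict[str, int],
    window_bp: int = 200_000,
    group: list[str] | None = None,
    group_label: str = "",
) -> pd.DataFrame:
    """SNP counts in non-overlapping genomic windows.

    Windows are 0-based half-open ``[k*w, (k+1)*w)``; a 1-based site at
    position p falls in window ``floor((p-1)/w)``.  A site counts if at
    least one parent of ``group`` (default: all parents) is homozygous-
    alternate there.  Per-chromosome window counts sum to the chromosome's
    SNP-site total by construction.
    """
    if group is None:
        group = matrix.parents
    rows = [matrix.parent_index(p) for p in group]
    variant = (
        (matrix.calls[rows] == HOM_ALT).any(axis=0)
        if rows
        else np.zeros(matrix.n_sites, dtype=bool)
    )
    for s in matrix.sites:
        if s.chrom not in chrom_lengths:
            raise ValueError(f"no chromosome length for {s.chrom}")
        if s.pos > chrom_lengths[s.chrom]:
            raise ValueError(f"site {s.site_id} beyond chromosome length {chrom_lengths[s.chrom]}")
    counts: dict[tuple[str, int], int] = {}
    for s, v in zip(matrix.sites, variant):
        if v:
            k = (s.pos - 1) // window_bp
            counts[(s.chrom, k)] = counts.get((s.chrom, k), 0) + 1
    recs = []
    for chrom, length in chrom_lengths.items():
        n_win = max(1, math.ceil(length / window_bp))
        for k in range(n_win):
            recs.append(
                {
                    "chrom": chrom,
                    "window_start": k * window_bp,
                    "window_end": min((k + 1) * window_bp, length),
                    "snp_count": counts.get((chrom, k), 0),
                    "parent_group": group_label,
                }
            )
    return pd.DataFrame(recs)


def mean_window_density(table: pd.DataFrame) -> pd.Series:
    """Mean SNPs per window for each chromosome."""
    return table.groupby("chrom", sort=False)["snp_count"].mean()


def high_density_windows(table: pd.DataFrame, threshold: int = 30) -> pd.DataFrame:
    """Windows with snp_count strictly greater than ``threshold`` (the
    hotspot definition), sorted by count descending then position."""
    hot = table[table["snp_count"] > threshold]
    return hot.sort_values(
        ["snp_count", "chrom", "window_start"], ascending=[False, True, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# genic annotation
# ---------------------------------------------------------------------------

def _region_in_model(model: GeneModel, pos: int, splice_margin: int) -> str | None:
    lo, hi = model.span
    if pos < lo or pos > hi:
        return None
    for a, b in model.exons:
        if a <= pos <= b:
            return REGION_EXON
    for a, b in model.introns():
        if a <= pos <= b:
            if pos - a < splice_margin or b - pos < splice_margin:
                return REGION_SPLICE
            return REGION_INTRON
    return None


def _coding_effect(model: GeneModel, seq: str, site: SnpSite) -> str:
    """Effect of the alternate allele on the protein, for a site inside
    the model's CDS; EFFECT_NA when the position is exonic but non-coding
    (UTR)."""
    # index of the position along the spliced CDS, in translation order
    offset = 0
    cds_index = None
    for a, b in model.cds:
        if a <= site.pos <= b:
            cds_index = offset + (site.pos - a if model.strand == "+" else b - site.pos)
            break
        offset += b - a + 1
    if cds_index is None:
        return EFFECT_NA
    codon_i, within = divmod(cds_index, 3)
    # rebuild the reference codon from the genome
    cds_seq = []
    for a, b in model.cds:
        chunk = seq[a - 1 : b]
        cds_seq.append(chunk if model.strand == "+" else str(Seq(chunk).reverse_complement()))
    cds_seq = "".join(cds_seq)
    codon = cds_seq[3 * codon_i : 3 * codon_i + 3]
    alt_base = site.alt if model.strand == "+" else _COMPLEMENT[site.alt]
    mutated = codon[:within] + alt_base + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    if aa_alt == aa_ref:
        return EFFECT_SYNONYMOUS
    if aa_alt == "*":
        return EFFECT_NONSENSE
    return EFFECT_MISSENSE


def annotate_site(
    site: SnpSite,
    models: list[GeneModel],
    seqs: dict[str, str],
    splice_margin: int = 2,
) -> SnpAnnotation:
    """Annotate one SNP site against gene models and the reference.

    Region precedence across overlapping models is exon > splice site >
    intron > intergenic; splice sites are the first/last ``splice_margin``
    bases of an intron.  Coding effects are computed only for CDS
    positions; exonic positions outside CDS (UTR) get ``not_applicable``.
    """
    seq = seqs.get(site.chrom)
    if seq is None:
        raise ValueError(f"chromosome {site.chrom!r} absent from reference")
    if site.pos > len(seq):
        raise ValueError(f"position {site.pos} beyond {site.chrom} length {len(seq)}")
    if seq[site.pos - 1] != site.ref:
        logger.warning(
            "reference mismatch at %s: FASTA %s, site ref %s",
            site.site_id,
            seq[site.pos - 1],
            site.ref,
        )
    best = REGION_INTERGENIC
    best_model = None
    for model in models:
        if model.chrom != site.chrom:
            continue
        region = _region_in_model(model, site.pos, splice_margin)
        if region is not None and _REGION_RANK[region] < _REGION_RANK[best]:
            best, best_model = region, model
    effect = EFFECT_NA
    if best == REGION_EXON:
        # among models placing the site in an exon, take the most severe
        # coding effect (mirrors most-severe region precedence)
        severity = {EFFECT_NONSENSE: 0, EFFECT_MISSENSE: 1, EFFECT_SYNONYMOUS: 2, EFFECT_NA: 3}
        for model in models:
            if model.chrom != site.chrom:
                continue
            if _region_in_model(model, site.pos, splice_margin) == REGION_EXON:
                e = _coding_effect(model, seq, site)
                if severity[e] < severity[effect]:
                    effect = e
    return SnpAnnotation(
        site_id=site.site_id,
        substitution_class=classify_substitution(site.ref, site.alt),
        region_class=best,
        coding_effect=effect,
    )


def annotate_matrix(
    matrix: ParentGenotypeMatrix,
    models: list[GeneModel],
    seqs: dict[str, str],
    splice_margin: int = 2,
) -> dict[str, SnpAnnotation]:
    """Annotate every site of the matrix; returns site_id -> annotation."""
    return {s.site_id: annotate_site(s, models, seqs, splice_margin) for s in matrix.sites}


_CLASS_COLUMNS = [
    "Total",
    "Intergenic",
    "Splice site",
    "Intron",
    "Exon",
    "Synonymous",
    "Missense",
    "Nonsense",
]


def tabulate_annotations(
    matrix: ParentGenotypeMatrix,
    annotations: dict[str, SnpAnnotation],
) -> pd.DataFrame:
    """Per-parent SNP class counts in survey-table layout.

    Total counts a parent's homozygous-alternate calls; region columns
    partition Total; Synonymous + Missense + Nonsense <= Exon (UTR SNPs
    carry no coding effect).  Group rows (females, males, all) are
    appended.
    """
    missing = [s for s in matrix.site_ids if s not in annotations]
    if missing:
        raise ValueError(f"unannotated sites (first: {missing[0]})")
    region_of = np.array([annotations[s].region_class for s in matrix.site_ids])
    effect_of = np.array([annotations[s].coding_effect for s in matrix.site_ids])
    rows = {}
    for i, parent in enumerate(matrix.parents):
        carries = matrix.calls[i] == HOM_ALT
        if not carries.any():
            logger.warning("parent %s carries no alternate alleles", parent)
        rows[parent] = {
            "Total": int(carries.sum()),
            "Intergenic": int((carries & (region_of == REGION_INTERGENIC)).sum()),
            "Splice site": int((carries & (region_of == REGION_SPLICE)).sum()),
            "Intron": int((carries & (region_of == REGION_INTRON)).sum()),
            "Exon": int((carries & (region_of == REGION_EXON)).sum()),
            "Synonymous": int((carries & (effect_of == EFFECT_SYNONYMOUS)).sum()),
            "Missense": int((carries & (effect_of == EFFECT_MISSENSE)).sum()),
            "Nonsense": int((carries & (effect_of == EFFECT_NONSENSE)).sum()),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")[_CLASS_COLUMNS]
    females, males = matrix.females, matrix.males
    if females:
        table.loc["All females"] = table.loc[females].sum()
    if males:
        table.loc["All males"] = table.loc[males].sum()
    table.loc["All parents"] = table.loc[matrix.parents].sum()
    return table
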