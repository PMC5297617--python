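"""Core containers and readers/writers for factorial hybrid-trial data.

The pipeline works on three kinds of input:

* genotype calls for the inbred parents of the factorial (VCF, or the
  package's plain TSV dialect) coded homozygous-reference / homozygous-
  alternate / missing,
* replicated F1 phenotypes from the randomized-complete-block trial
  (one row per cross x replicate, one column per trait),
* gene models (GFF3 + reference FASTA) for the lightweight coding-effect
  annotator.

All genomic coordinates are 1-based inclusive on input (VCF/GFF3
conventions); window arithmetic elsewhere in the package is 0-based
half-open.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: genotype call codes for inbred (homozygous) parents
HOM_REF = 0
HOM_ALT = 2
MISSING = -1

VALID_CALLS = (HOM_REF, HOM_ALT, MISSING)
BASES = ("A", "C", "G", "T")

FEMALE = "female"
MALE = "male"


class Zygosity(enum.Enum):
    """Zygosity of an F1 at one SNP site, derived from its two parents."""

    HET = "HET"
    HOM = "HOM"
    MISSING = "MISSING"


def _chrom_key(chrom: str):
    """Natural sort key so that chr2 sorts before chr10."""
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass(frozen=True)
class SnpSite:
    """A biallelic SNP position on the reference genome.

    One matrix column corresponds to one (chrom, pos); several parents may
    carry the alternate allele there, which is how a survey can report more
    parent-level SNPs than chromosomal sites.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    site_id: str = ""

    def __post_init__(self):
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"bases must be one of {BASES}: {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"not a polymorphism: {self.ref}>{self.alt} at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"positions are 1-based; got {self.pos}")
        if not self.site_id:
            object.__setattr__(self, "site_id", f"{self.chrom}:{self.pos}")


@dataclass
class ParentGenotypeMatrix:
    """Inbred parents x SNP sites, with calls in {0, 2, MISSING}.

    Parameters
    ----------
    parents
        Parent identifiers, females (CMS lines) and males (restorers).
    roles
        Role tag per parent, ``"female"`` or ``"male"``, same order.
    sites
        Sites sorted by (chrom, pos), unique.
    calls
        int8 array of shape (n_parents, n_sites).
    """

    parents: list[str]
    roles: list[str]
    sites: list[SnpSite]
    calls: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(self.parents) != len(set(self.parents)):
            raise ValueError("duplicate parent identifiers")
        if len(self.roles) != len(self.parents):
            raise ValueError("roles must match parents")
        bad_roles = set(self.roles) - {FEMALE, MALE}
        if bad_roles:
            raise ValueError(f"unknown roles: {bad_roles}")
        if self.calls.shape != (len(self.parents), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.parents)}, {len(self.sites)})"
            )
        if not np.isin(self.calls, VALID_CALLS).all():
            raise ValueError("calls must be in {0, 2, MISSING}")
        keys = [(_chrom_key(s.chrom), s.pos) for s in self.sites]
        if any(keys[i] >= keys[i + 1] for i in range(len(keys) - 1)):
            raise ValueError("sites must be sorted by (chrom, pos) and unique")
        if self.n_sites and (self.calls == MISSING).all(axis=0).any():
            raise ValueError("every site needs at least one non-missing call")
        self._index = {s.site_id: j for j, s in enumerate(self.sites)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_parents(self) -> int:
        return len(self.parents)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def females(self) -> list[str]:
        return [p for p, r in zip(self.parents, self.roles) if r == FEMALE]

    @property
    def males(self) -> list[str]:
        return [p for p, r in zip(self.parents, self.roles) if r == MALE]

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    def site_index(self, site_id: str) -> int:
        try:
            return self._index[site_id]
        except KeyError:
            raise KeyError(f"unknown site {site_id!r}") from None

    def parent_index(self, parent: str) -> int:
        try:
            return self.parents.index(parent)
        except ValueError:
            raise KeyError(f"unknown parent {parent!r}") from None

    def call(self, parent: str, site_id: str) -> int:
        return int(self.calls[self.parent_index(parent), self.site_index(site_id)])

    def monomorphic_reference_mask(self) -> np.ndarray:
        """Sites where no non-missing parent carries the alternate allele."""
        return ~(self.calls == HOM_ALT).any(axis=0)

    def variant_counts(self) -> pd.Series:
        """Per-parent count of homozygous-alternate calls.

        This is the parent-level "SNP" accounting: summing it over parents
        can exceed the number of sites because parents share sites.
        """
        return pd.Series((self.calls == HOM_ALT).sum(axis=1), index=self.parents, name="n_snps")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.sites],
                "pos": [s.pos for s in self.sites],
                "ref": [s.ref for s in self.sites],
                "alt": [s.alt for s in self.sites],
            }
        )
        for i, p in enumerate(self.parents):
            df[p] = self.calls[i]
        return df


def _sort_sites(sites, calls):
    order = sorted(range(len(sites)), key=lambda j: (_chrom_key(sites[j].chrom), sites[j].pos))
    return [sites[j] for j in order], calls[:, order]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_genotypes(
    path,
    inbred_policy: str = "het_to_missing",
    roles: dict[str, str] | None = None,
) -> ParentGenotypeMatrix:
    """Read homozygous-coded parent genotypes from a VCF.

    Only biallelic SNP records are retained; indels and multi-allelic
    records are skipped with a logged count.  Residual heterozygous calls
    (GBS inbreds are not perfectly homozygous) are handled per
    ``inbred_policy``:

    * ``"het_to_missing"`` (default) — the cell becomes MISSING;
    * ``"drop_het"`` — the whole site is dropped.

    ``roles`` maps sample name to ``"female"``/``"male"``; samples without
    an entry default to ``"female"``.
    """
    from cyvcf2 import VCF

    if inbred_policy not in ("het_to_missing", "drop_het"):
        raise ValueError(f"unknown inbred_policy {inbred_policy!r}")
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError("VCF contains no samples")
    if len(samples) != len(set(samples)):
        raise ValueError("duplicate sample names in VCF")

    sites: list[SnpSite] = []
    cols: list[np.ndarray] = []
    skipped = {"non_snp": 0, "het_site": 0, "all_missing": 0}
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped["non_snp"] += 1
            continue
        if v.REF not in BASES or v.ALT[0] not in BASES:
            skipped["non_snp"] += 1
            continue
        gt = np.asarray(v.gt_types)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        col = np.full(len(samples), MISSING, dtype=np.int8)
        col[gt == 0] = HOM_REF
        col[gt == 2] = HOM_ALT
        if (gt == 1).any():
            if inbred_policy == "drop_het":
                skipped["het_site"] += 1
                continue
            # het_to_missing: cells already MISSING
        if (col == MISSING).all():
            skipped["all_missing"] += 1
            continue
        sites.append(SnpSite(v.CHROM, v.POS, v.REF, v.ALT[0]))
        cols.append(col)
    if not sites:
        raise ValueError("zero retained sites")
    calls = np.stack(cols, axis=1)
    sites, calls = _sort_sites(sites, calls)
    role_list = [(roles or {}).get(s, FEMALE) for s in samples]
    n_skipped = sum(skipped.values())
    logger.info("read %d sites from %s (%d records skipped: %s)", len(sites), path, n_skipped, skipped)
    return ParentGenotypeMatrix(samples, role_list, sites, calls, meta={"skipped": skipped})


def write_vcf(matrix: ParentGenotypeMatrix, path) -> None:
    """Write the matrix as a minimal VCF 4.2 with GT-only genotypes."""
    from hybridca import __version__

    gt_map = {HOM_REF: "0/0", HOM_ALT: "1/1", MISSING: "./."}
    chroms = []
    for s in matrix.sites:
        if s.chrom not in chroms:
            chroms.append(s.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=hybridca {__version__}\n")
        for c in chroms:
            length = max(s.pos for s in matrix.sites if s.chrom == c)
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.parents) + "\n")
        for j, s in enumerate(matrix.sites):
            gts = "\t".join(gt_map[int(c)] for c in matrix.calls[:, j])
            fh.write(f"{s.chrom}\t{s.pos}\t{s.site_id}\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# genotype TSV dialect
# ---------------------------------------------------------------------------

def write_genotype_tsv(matrix: ParentGenotypeMatrix, path) -> None:
    """Write the TSV genotype dialect: commented version + roles lines, a
    header row of parent ids after chrom/pos/ref/alt, MISSING as '.'."""
    from hybridca import __version__

    with open(path, "w") as fh:
        fh.write(f"# hybridca {__version__} genotype matrix\n")
        fh.write("# roles:\t" + "\t".join(matrix.roles) + "\n")
        fh.write("chrom\tpos\tref\talt\t" + "\t".join(matrix.parents) + "\n")
        for j, s in enumerate(matrix.sites):
            codes = "\t".join("." if c == MISSING else str(int(c)) for c in matrix.calls[:, j])
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{codes}\n")


def read_genotype_tsv(path) -> ParentGenotypeMatrix:
    roles_line = None
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for ln in lines:
        if ln.startswith("# roles:"):
            roles_line = ln.rstrip("\n").split("\t")[1:]
        elif ln.startswith("#"):
            continue
        else:
            body.append(ln.rstrip("\n"))
    if not body:
        raise ValueError("empty genotype TSV")
    header = body[0].split("\t")
    if header[:4] != ["chrom", "pos", "ref", "alt"]:
        raise ValueError("genotype TSV must start with chrom, pos, ref, alt columns")
    parents = header[4:]
    roles = roles_line if roles_line is not None else [FEMALE] * len(parents)
    sites, cols = [], []
    for ln in body[1:]:
        fields = ln.split("\t")
        chrom, pos, ref, alt = fields[:4]
        sites.append(SnpSite(chrom, int(pos), ref, alt))
        cols.append([MISSING if c == "." else int(c) for c in fields[4:]])
    calls = np.asarray(cols, dtype=np.int8).T
    return ParentGenotypeMatrix(parents, roles, sites, calls)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Replicated F1 phenotypes from a balanced factorial RCBD trial.

    ``data`` has columns female, male, replicate, then one column per
    trait; one row per cross x replicate (plot means).
    """

    data: pd.DataFrame
    traits: list[str]

    def __post_init__(self):
        required = ["female", "male", "replicate"]
        for col in required:
            if col not in self.data.columns:
                raise ValueError(f"phenotype table needs a {col!r} column")
        self.data = self.data.reset_index(drop=True)
        for t in self.traits:
            vals = self.data[t]
            if not np.issubdtype(vals.dtype, np.number):
                raise ValueError(f"trait {t!r} has non-numeric values")
            if not np.isfinite(vals.to_numpy(dtype=float)).all():
                bad = int(np.flatnonzero(~np.isfinite(vals.to_numpy(dtype=float)))[0])
                raise ValueError(f"non-finite value for trait {t!r} at row {bad}")
        self._check_balance()

    def _check_balance(self):
        reps = sorted(self.data["replicate"].unique())
        seen = set(zip(self.data["female"], self.data["male"], self.data["replicate"]))
        if len(seen) != len(self.data):
            raise ValueError("duplicate (female, male, replicate) rows")
        for f in self.females:
            for m in self.males:
                for r in reps:
                    if (f, m, r) not in seen:
                        raise ValueError(
                            f"unbalanced design: missing cell (female={f}, male={m}, replicate={r})"
                        )

    @property
    def females(self) -> list[str]:
        return list(dict.fromkeys(self.data["female"]))

    @property
    def males(self) -> list[str]:
        return list(dict.fromkeys(self.data["male"]))

    @property
    def crosses(self) -> list[tuple[str, str]]:
        return [(f, m) for f in self.females for m in self.males]

    @property
    def n_replicates(self) -> int:
        return self.data["replicate"].nunique()

    def grand_mean(self, trait: str) -> float:
        return float(self.data[trait].mean())

    def cross_means(self, trait: str) -> pd.DataFrame:
        """Per-cross means over replicates as a female x male table."""
        piv = self.data.pivot_table(index="female", columns="male", values=trait, aggfunc="mean")
        return piv.reindex(index=self.females, columns=self.males)

    def cross_mean_series(self, trait: str) -> pd.Series:
        """Per-cross means keyed by (female, male)."""
        g = self.data.groupby(["female", "male"], sort=False)[trait].mean()
        return g.reindex(pd.MultiIndex.from_tuples(self.crosses, names=["female", "male"]))


def read_phenotypes(path) -> PhenotypeTable:
    """Read the phenotype TSV (columns female, male, replicate, traits...).

    Raises with the offending row/cell named on non-numeric values or a
    missing cross x replicate combination.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"female": str, "male": str})
    for col in ("female", "male", "replicate"):
        if col not in df.columns:
            raise ValueError(f"phenotype file {path} lacks column {col!r}")
    traits = [c for c in df.columns if c not in ("female", "male", "replicate")]
    if not traits:
        raise ValueError("phenotype file has no trait columns")
    for t in traits:
        coerced = pd.to_numeric(df[t], errors="coerce")
        bad = df.index[coerced.isna() & df[t].notna()]
        if len(bad) or coerced.isna().any():
            row = int(bad[0]) if len(bad) else int(df.index[coerced.isna()][0])
            # +2: header line plus 1-based numbering
            raise ValueError(f"non-numeric value for trait {t!r} at file row {row + 2}")
        df[t] = coerced
    return PhenotypeTable(df, traits)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    from hybridca import __version__

    with open(path, "w") as fh:
        fh.write(f"# hybridca {__version__} phenotypes\n")
        pheno.data.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# F1 zygosity
# ---------------------------------------------------------------------------

def derive_f1_zygosity(female_code: int, male_code: int) -> Zygosity:
    """Zygosity of the F1 from two homozygous parental calls.

    HET iff both calls are non-missing and differ (e.g. ref x alt);
    HOM iff both are non-missing and equal; MISSING otherwise.  Symmetric
    in its arguments.
    """
    if female_code not in VALID_CALLS or male_code not in VALID_CALLS:
        raise ValueError(f"invalid call codes ({female_code}, {male_code})")
    if female_code == MISSING or male_code == MISSING:
        return Zygosity.MISSING
    return Zygosity.HET if female_code != male_code else Zygosity.HOM


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One mRNA: exon intervals (ascending) and CDS intervals in
    translation order (descending start for minus-strand models).
    Intervals are 1-based inclusive."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -: {self.strand}")
        if any(a > b for a, b in self.exons) or any(a > b for a, b in self.cds):
            raise ValueError("malformed interval")

    @property
    def span(self) -> tuple[int, int]:
        return min(a for a, _ in self.exons), max(b for _, b in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (a1, b1), (a2, b2) in zip(self.exons, self.exons[1:]):
            if a2 > b1 + 1:
                out.append((b1 + 1, a2 - 1))
        return out


def read_gene_models(gff_path, fasta_path) -> tuple[list[GeneModel], dict[str, str]]:
    """Parse GFF3 mRNA/exon/CDS features plus the reference FASTA.

    Models whose total CDS length is not divisible by 3 are skipped with a
    warning; a GFF seqid absent from the FASTA is a hard error.
    """
    import gffutils

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        if mrna.seqid not in seqs:
            raise ValueError(f"GFF seqid {mrna.seqid!r} absent from FASTA")
        exons = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted((f.start, f.end) for f in db.children(mrna, featuretype="CDS"))
        if not exons:
            exons = list(cds)
        model = GeneModel(
            gene_id=mrna.id,
            chrom=mrna.seqid,
            strand=mrna.strand,
            exons=exons,
            cds=cds if mrna.strand == "+" else cds[::-1],
        )
        if model.cds and model.cds_length % 3 != 0:
            logger.warning(
                "skipping model %s: CDS length %d not divisible by 3", model.gene_id, model.cds_length
            )
            continue
        models.append(model)
    return models, seqs
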