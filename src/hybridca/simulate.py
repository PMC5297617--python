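"""Synthetic factorial-trial generator with known ground truth.

Emulates the data a 9 CMS x 9 restorer genotyping-by-sequencing study
produces without any sequencing: homozygous parental genotypes at SNP
sites spread over 12 rice-sized chromosomes with density hotspots and
configurable missingness, toy genomes + gene models for the annotator,
and replicated F1 phenotypes built from

    y_fmk = mu + g_f + g_m + s_fm + sum_l beta_l * 1[F1 het at l] + b_k + e_fmk

with Gaussian effects of configurable scale.  Every draw is reproducible
from the config seed, and a truth ledger records the generating effects
so estimator-recovery tests have an exact reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from hybridca.io import (
    BASES,
    FEMALE,
    HOM_ALT,
    HOM_REF,
    MALE,
    MISSING,
    ParentGenotypeMatrix,
    PhenotypeTable,
    SnpSite,
    Zygosity,
    derive_f1_zygosity,
)

logger = logging.getLogger(__name__)

#: approximate sizes of the 12 rice chromosomes (IRGSP-1.0, rounded)
RICE_CHROM_LENGTHS = {
    "chr01": 43_300_000,
    "chr02": 35_900_000,
    "chr03": 36_400_000,
    "chr04": 35_500_000,
    "chr05": 29_900_000,
    "chr06": 31_200_000,
    "chr07": 29_700_000,
    "chr08": 28_400_000,
    "chr09": 23_000_000,
    "chr10": 23_200_000,
    "chr11": 29_000_000,
    "chr12": 27_500_000,
}

_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class TraitParams:
    """Effect scales for one trait (trait units).

    Defaults below put the residual CV of the trial in the realistic
    5-15% band for field trials of yield components.
    """

    mean: float
    sigma_gca_f: float
    sigma_gca_m: float
    sigma_sca: float
    sigma_block: float
    sigma_error: float

    def __post_init__(self):
        for name in ("sigma_gca_f", "sigma_gca_m", "sigma_sca", "sigma_block", "sigma_error"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _default_trait(mean: float) -> TraitParams:
    return TraitParams(
        mean=mean,
        sigma_gca_f=0.04 * abs(mean),
        sigma_gca_m=0.04 * abs(mean),
        sigma_sca=0.02 * abs(mean),
        sigma_block=0.02 * abs(mean),
        sigma_error=0.06 * abs(mean),
    )


#: the 12 yield-related traits of a japonica hybrid trial, with typical means
DEFAULT_TRAITS: dict[str, TraitParams] = {
    "plant_height": _default_trait(110.0),
    "grain_width": _default_trait(2.1),
    "grain_length": _default_trait(8.2),
    "grain_thickness": _default_trait(3.5),
    "thousand_grain_weight": _default_trait(25.5),
    "grain_yield_per_plot": _default_trait(31.0),
    "days_to_heading": _default_trait(105.0),
    "panicle_length": _default_trait(22.4),
    "panicles_per_plant": _default_trait(9.6),
    "spikelets_per_panicle": _default_trait(282.0),
    "filled_grains_per_panicle": _default_trait(222.0),
    "seed_setting_rate": _default_trait(0.8),
}


@dataclass(frozen=True)
class PlantedLocus:
    """A locus with a real effect beta added to heterozygous F1s."""

    site_id: str
    trait: str
    beta: float


@dataclass
class SimulationConfig:
    """Study-design parameters of the simulated trial.

    Defaults reproduce the design of the motivating trial: 9 females x
    9 males, 4 replicates, 11,085 SNP sites on 12 rice-sized
    chromosomes, a transition fraction giving Ts/Tv ~ 1.4, and 10%
    missing genotype calls (GBS-like).
    """

    n_female: int = 9
    n_male: int = 9
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(RICE_CHROM_LENGTHS))
    n_sites: int = 11_085
    alt_freq_beta: tuple[float, float] = (1.2, 3.5)
    alt_freq_fixed: float | None = None
    hotspot_window_fraction: float = 0.03
    hotspot_intensity: float = 15.0
    hotspot_window_bp: int = 200_000
    transition_fraction: float = 1.4 / 2.4
    missing_rate: float = 0.10
    n_replicates: int = 4
    traits: dict[str, TraitParams] = field(default_factory=lambda: dict(DEFAULT_TRAITS))
    planted_loci: list[PlantedLocus] = field(default_factory=list)
    seed: int = 0

    def with_traits(self, **traits: TraitParams) -> "SimulationConfig":
        return replace(self, traits=dict(traits))


@dataclass
class TruthLedger:
    """Generating values behind one simulated trial."""

    mu: pd.Series  # per trait
    gca_female: pd.DataFrame  # female x trait
    gca_male: pd.DataFrame  # male x trait
    sca: dict[str, pd.DataFrame]  # trait -> female x male
    block: pd.DataFrame  # replicate x trait
    planted: list[PlantedLocus]
    planted_zygosity: pd.DataFrame  # cross x planted site_id, values HET/HOM

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# hybridca truth ledger\n")
            fh.write("## mu\n")
            self.mu.rename_axis("trait").to_frame("mu").to_csv(fh, sep="\t")
            fh.write("## gca_female\n")
            self.gca_female.rename_axis("parent").to_csv(fh, sep="\t")
            fh.write("## gca_male\n")
            self.gca_male.rename_axis("parent").to_csv(fh, sep="\t")
            fh.write("## planted\n")
            pd.DataFrame([vars(p) for p in self.planted]).to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _draw_positions(config: SimulationConfig, rng: np.random.Generator) -> list[tuple[str, int]]:
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    total_positions = int(lengths.sum())
    if config.n_sites > total_positions:
        raise ValueError("n_sites exceeds available positions")
    per_chrom = rng.multinomial(config.n_sites, lengths / lengths.sum())
    out: list[tuple[str, int]] = []
    w = config.hotspot_window_bp
    for chrom, n in zip(chroms, per_chrom):
        length = config.chrom_lengths[chrom]
        n_win = max(1, math.ceil(length / w))
        n_hot = int(round(config.hotspot_window_fraction * n_win))
        hot = rng.choice(n_win, size=n_hot, replace=False) if n_hot else np.array([], dtype=int)
        weights = np.ones(n_win)
        weights[hot] = config.hotspot_intensity
        weights /= weights.sum()
        taken: set[int] = set()
        while len(taken) < n:
            need = n - len(taken)
            ks = rng.choice(n_win, size=need, p=weights)
            los = ks * w
            his = np.minimum((ks + 1) * w, length)
            pos = rng.integers(los + 1, his + 1)  # 1-based
            taken.update(int(p) for p in pos)
        out.extend((chrom, p) for p in sorted(taken))
    return out


def simulate_parent_genotypes(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    seqs: dict[str, str] | None = None,
) -> ParentGenotypeMatrix:
    """Draw homozygous parental genotypes per the config.

    Site positions cluster in enriched windows (hotspots); per-site
    alternate-allele frequencies come from a Beta distribution (or a
    fixed value); missingness is i.i.d.  Sites that happen to come out
    monomorphic-reference remain in the matrix and are flagged by
    :meth:`~hybridca.io.ParentGenotypeMatrix.monomorphic_reference_mask`.
    The complete (pre-missingness) calls are kept in ``meta["true_calls"]``.

    With ``seqs`` (a toy reference, chrom -> sequence) the chromosome
    lengths come from the sequences and each site's reference base is the
    genome base, so downstream annotation sees a consistent reference.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if seqs is not None:
        config = replace(config, chrom_lengths={c: len(s) for c, s in seqs.items()})
    females = [f"CMS{i + 1}" for i in range(config.n_female)]
    males = [f"R{i + 1}" for i in range(config.n_male)]
    parents = females + males
    roles = [FEMALE] * len(females) + [MALE] * len(males)

    positions = _draw_positions(config, rng)
    sites = []
    for chrom, pos in positions:
        ref = seqs[chrom][pos - 1] if seqs is not None else BASES[rng.integers(4)]
        if rng.random() < config.transition_fraction:
            alt = _TRANSITION_OF[ref]
        else:
            alt = rng.choice([b for b in BASES if b != ref and b != _TRANSITION_OF[ref]])
        sites.append(SnpSite(chrom, pos, ref, str(alt)))

    n_p, n_s = len(parents), len(sites)
    if config.alt_freq_fixed is not None:
        freqs = np.full(n_s, config.alt_freq_fixed)
    else:
        freqs = rng.beta(*config.alt_freq_beta, size=n_s)
    true_calls = np.where(rng.random((n_p, n_s)) < freqs[None, :], HOM_ALT, HOM_REF).astype(np.int8)

    calls = true_calls.copy()
    if config.missing_rate > 0:
        miss = rng.random((n_p, n_s)) < config.missing_rate
        # keep at least one observed call per site
        all_missing = miss.all(axis=0)
        if all_missing.any():
            keep_rows = rng.integers(0, n_p, size=int(all_missing.sum()))
            miss[keep_rows, np.flatnonzero(all_missing)] = False
        calls[miss] = MISSING

    matrix = ParentGenotypeMatrix(parents, roles, sites, calls, meta={"true_calls": true_calls})
    n_mono = int(matrix.monomorphic_reference_mask().sum())
    if n_mono:
        logger.info("%d of %d simulated sites are monomorphic-reference", n_mono, n_s)
    return matrix


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean()


def _double_center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + x.mean()


def simulate_phenotypes(
    matrix: ParentGenotypeMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PhenotypeTable, TruthLedger]:
    """Replicated F1 phenotypes for every female x male cross.

    GCA/SCA draws are centred (double-centred for SCA) so the ledger
    satisfies the estimator's zero-sum convention exactly.  Planted locus
    effects apply to crosses whose F1 is heterozygous under the
    generator's complete calls (missingness is observational only).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    females, males = matrix.females, matrix.males
    f, m, r = len(females), len(males), config.n_replicates
    crosses = [(a, b) for a in females for b in males]

    true_calls = matrix.meta.get("true_calls", matrix.calls)
    zyg_cols = {}
    for locus in config.planted_loci:
        j = matrix.site_index(locus.site_id)
        col = {}
        for a, b in crosses:
            z = derive_f1_zygosity(
                int(true_calls[matrix.parent_index(a), j]),
                int(true_calls[matrix.parent_index(b), j]),
            )
            col[(a, b)] = z.value
        zyg_cols[locus.site_id] = col
        if len({v for v in col.values()}) == 1:
            logger.warning("planted locus %s is monomorphic across crosses; effect inert", locus.site_id)

    mu = pd.Series({t: tp.mean for t, tp in config.traits.items()}, name="mu")
    gca_f = pd.DataFrame(index=females, columns=list(config.traits), dtype=float)
    gca_m = pd.DataFrame(index=males, columns=list(config.traits), dtype=float)
    sca: dict[str, pd.DataFrame] = {}
    block = pd.DataFrame(index=range(1, r + 1), columns=list(config.traits), dtype=float)

    rows = {"female": [], "male": [], "replicate": []}
    values: dict[str, list[float]] = {t: [] for t in config.traits}
    for a, b in crosses:
        for k in range(1, r + 1):
            rows["female"].append(a)
            rows["male"].append(b)
            rows["replicate"].append(k)

    for trait, tp in config.traits.items():
        g_f = _center(rng.normal(0.0, tp.sigma_gca_f, f)) if tp.sigma_gca_f else np.zeros(f)
        g_m = _center(rng.normal(0.0, tp.sigma_gca_m, m)) if tp.sigma_gca_m else np.zeros(m)
        s = _double_center(rng.normal(0.0, tp.sigma_sca, (f, m))) if tp.sigma_sca else np.zeros((f, m))
        b_k = rng.normal(0.0, tp.sigma_block, r) if tp.sigma_block else np.zeros(r)
        gca_f[trait] = g_f
        gca_m[trait] = g_m
        sca[trait] = pd.DataFrame(s, index=females, columns=males)
        block[trait] = b_k
        locus_effect = {c: 0.0 for c in crosses}
        for locus in config.planted_loci:
            if locus.trait != trait:
                continue
            for c in crosses:
                if zyg_cols[locus.site_id][c] == Zygosity.HET.value:
                    locus_effect[c] += locus.beta
        for i, a in enumerate(females):
            for j2, b in enumerate(males):
                base = tp.mean + g_f[i] + g_m[j2] + s[i, j2] + locus_effect[(a, b)]
                eps = rng.normal(0.0, tp.sigma_error, r) if tp.sigma_error else np.zeros(r)
                for k in range(r):
                    values[trait].append(base + b_k[k] + eps[k])

    data = pd.DataFrame({**rows, **values})
    pheno = PhenotypeTable(data, list(config.traits))
    zyg_frame = pd.DataFrame(
        zyg_cols,
        index=pd.MultiIndex.from_tuples(crosses, names=["female", "male"]),
    )
    ledger = TruthLedger(
        mu=mu,
        gca_female=gca_f,
        gca_male=gca_m,
        sca=sca,
        block=block,
        planted=list(config.planted_loci),
        planted_zygosity=zyg_frame,
    )
    return pheno, ledger


def simulate_trial(
    config: SimulationConfig,
) -> tuple[ParentGenotypeMatrix, PhenotypeTable, TruthLedger]:
    """Genotypes + phenotypes + truth ledger from one seeded config."""
    rng = np.random.default_rng(config.seed)
    matrix = simulate_parent_genotypes(config, rng)
    pheno, ledger = simulate_phenotypes(matrix, config, rng)
    return matrix, pheno, ledger


# ---------------------------------------------------------------------------
# toy genomes + gene models
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in _STOPS and a + b + c != "ATG"
]
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(s))


def simulate_gene_models(
    fasta_path,
    gff_path,
    chrom_lengths: dict[str, int] | None = None,
    n_genes: int = 10,
    seed: int = 0,
    rng: np.random.Generator | None = None,
):
    """Write a toy reference FASTA and GFF3 with valid random gene models.

    Genes are non-overlapping, on both strands, with multi-exon CDS of
    length divisible by 3 that starts with ATG and ends at a stop codon;
    short UTRs keep the exon/CDS distinction exercised.  Returns the list
    of (gene_id, chrom, strand, exons, cds-in-translation-order) written.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    rng = rng if rng is not None else np.random.default_rng(seed)
    chrom_lengths = chrom_lengths or {"chrA": 60_000, "chrB": 60_000}
    seqs = {
        c: list(rng.choice(list(BASES), size=n)) for c, n in chrom_lengths.items()
    }

    genes = []
    chroms = list(chrom_lengths)
    cursor = {c: 1 for c in chroms}
    for gi in range(n_genes):
        chrom = chroms[gi % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        n_codons = int(rng.integers(12, 60))
        n_exons = int(rng.integers(1, 4))
        # split coding length into exon-resident chunks of >= 3 bp
        cds_len = 3 * n_codons
        cuts = sorted(rng.choice(range(3, cds_len - 2), size=n_exons - 1, replace=False)) if n_exons > 1 else []
        chunk_lens = np.diff([0, *cuts, cds_len]).tolist()
        utr5, utr3 = int(rng.integers(0, 30)), int(rng.integers(0, 30))
        introns = [int(rng.integers(30, 150)) for _ in range(n_exons - 1)]

        start = cursor[chrom] + int(rng.integers(50, 300))
        exons, cds = [], []
        pos = start
        for e in range(n_exons):
            e_start = pos
            lead = utr5 if e == 0 else 0
            tail = utr3 if e == n_exons - 1 else 0
            c_start = e_start + lead
            c_end = c_start + chunk_lens[e] - 1
            e_end = c_end + tail
            exons.append((e_start, e_end))
            cds.append((c_start, c_end))
            pos = e_end + 1 + (introns[e] if e < n_exons - 1 else 0)
        gene_end = exons[-1][1]
        if gene_end > chrom_lengths[chrom]:
            raise ValueError("gene density too high for the chromosome lengths")
        cursor[chrom] = gene_end + 1

        # coding sequence: ATG + sense codons + stop
        body = [str(rng.choice(_SENSE_CODONS)) for _ in range(n_codons - 2)]
        cds_seq = "ATG" + "".join(body) + str(rng.choice(list(_STOPS)))
        # paste into the genome in translation order
        t_order = cds if strand == "+" else cds[::-1]
        off = 0
        for a, b in t_order:
            seg = cds_seq[off : off + (b - a + 1)]
            frag = seg if strand == "+" else _revcomp(seg)
            seqs[chrom][a - 1 : b] = list(frag)
            off += b - a + 1
        genes.append((f"gene{gi + 1}", chrom, strand, exons, t_order))

    records = [SeqRecord(Seq("".join(s)), id=c, description="") for c, s in seqs.items()]
    SeqIO.write(records, str(fasta_path), "fasta")

    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, chrom, strand, exons, t_order in genes:
            lo = min(a for a, _ in exons)
            hi = max(b for _, b in exons)
            fh.write(f"{chrom}\thybridca\tgene\t{lo}\t{hi}\t.\t{strand}\t.\tID={gene_id}\n")
            fh.write(
                f"{chrom}\thybridca\tmRNA\t{lo}\t{hi}\t.\t{strand}\t.\tID={gene_id}.1;Parent={gene_id}\n"
            )
            for a, b in exons:
                fh.write(
                    f"{chrom}\thybridca\texon\t{a}\t{b}\t.\t{strand}\t.\tParent={gene_id}.1\n"
                )
            off = 0
            for a, b in t_order:
                phase = (3 - off % 3) % 3
                fh.write(
                    f"{chrom}\thybridca\tCDS\t{a}\t{b}\t.\t{strand}\t{phase}\tParent={gene_id}.1\n"
                )
                off += b - a + 1
    return genes
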