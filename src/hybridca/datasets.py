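"""Published reference tabulations from the motivating GBS survey.

A genotyping-by-sequencing survey of nine japonica CMS lines and nine
restorer lines against the Nipponbare reference reported per-line SNP
annotation class counts and, after the combining-ability association
scan, per-trait counts of significant loci.  Those printed tables are
packaged here so report aggregation can be checked against the survey's
grand totals (13,186 CMS SNPs, 25,815 restorer SNPs, 39,001 overall)
without any sequence data.

Note the survey's own per-line rows are not internally consistent
(region columns do not always sum to the Total column, and the CMS
nonsense column sums to 26 while the survey's prose says 27); the values
here are the printed ones, and :func:`aggregate_annotation_counts` simply
sums them.
"""

from __future__ import annotations

import io as _io

import pandas as pd

_ANNOTATION_COLUMNS = [
    "line", "Total", "Intergenic", "Splice site", "Intron", "Exon",
    "Synonymous", "Missense", "Nonsense",
]

_CMS_ROWS = """\
95122A	1378	793	13	357	276	119	139	0
90167A	1305	770	19	328	265	121	110	2
863A	1273	700	18	271	308	130	132	3
A171	1206	702	12	277	259	120	116	3
Aizhixiang A	365	219	1	84	67	30	29	1
18A	888	516	27	213	169	80	73	2
Zhe 04A	1785	1026	20	399	362	167	158	6
Chunjiang 19A	1574	884	21	430	288	118	149	1
Chunjiang 18A	3412	1972	49	853	655	270	308	8
"""

_RESTORER_ROWS = """\
R4179	1508	850	16	342	355	142	174	1
LC64	2970	1774	40	639	622	276	303	3
LC109	1527	904	14	338	300	130	137	1
Yanhui R50	2623	1516	27	604	538	205	369	3
Yanhui R8	3483	2057	37	856	696	291	334	4
LR5	5397	3080	63	1372	1118	441	529	4
LR27	4128	2364	44	1058	828	318	420	1
Shenhui 254	2145	1288	21	479	454	195	205	4
C4115	2034	1137	20	538	466	191	218	1
"""

# per-trait association summary: significant loci, het/hom cross totals,
# pooled group means, and the survey's printed average percent heterosis
_ASSOCIATION_ROWS = """\
trait	n_loci	n_het_crosses	het_mean	n_hom_crosses	hom_mean	printed_avg_heterosis
plant_height	53	871	107.4	3422	110	-4.9
grain_width	44	593	2.2	2971	2.1	4.9
grain_length	27	544	8.3	1643	8.2	-0.2
grain_thickness	10	189	3.7	621	3.5	6.1
thousand_grain_weight	19	413	26.2	1121	25.5	2.8
grain_yield_per_plot	6	84	25.5	321	31	-16.7
days_to_heading	27	808	110.6	1379	105.4	10.2
panicle_length	110	1849	23.6	7061	22.4	5.9
panicles_per_plant	5	68	11.4	337	9.6	19.2
spikelets_per_panicle	53	914	229	3379	281.9	-17.7
filled_grains_per_panicle	7	114	177.4	453	222	-25.2
seed_setting_rate	1	10	0.65	71	0.8	-19.1
"""


def _parse(rows: str) -> pd.DataFrame:
    df = pd.read_csv(
        _io.StringIO(rows), sep="\t", header=None, names=_ANNOTATION_COLUMNS
    )
    return df.set_index("line")


def cms_annotation_counts() -> pd.DataFrame:
    """Per-line SNP annotation counts for the nine CMS (female) lines."""
    return _parse(_CMS_ROWS)


def restorer_annotation_counts() -> pd.DataFrame:
    """Per-line SNP annotation counts for the nine restorer (male) lines."""
    return _parse(_RESTORER_ROWS)


def association_trait_counts() -> pd.DataFrame:
    """Per-trait counts of significant CA-associated loci with het/hom
    cross totals and pooled group means."""
    return pd.read_csv(_io.StringIO(_ASSOCIATION_ROWS), sep="\t").set_index("trait")


def aggregate_annotation_counts(table: pd.DataFrame) -> pd.Series:
    """Column sums of a per-line annotation table (the report aggregator
    used for group and grand totals)."""
    return table.sum(axis=0)
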