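"""General and specific combining ability from a balanced factorial trial.

The model for a female x male factorial (NCII mating design, no selfs or
reciprocals) with randomized-complete-block replication is

    y_fmk = mu + g_f + g_m + s_fm + b_k + e_fmk

with zero-sum constraints sum_f g_f = sum_m g_m = 0 and every row/column
sum of the SCA matrix s zero.  On balanced data the least-squares
solution is the classical moment one:

    g_f = ybar_f.. - mu,   g_m = ybar_.m. - mu,
    s_fm = ybar_fm. - ybar_f.. - ybar_.m. + mu

so mu + g_f + g_m + s_fm reproduces each cross mean exactly.  The ANOVA
is the standard two-factor-with-blocks partition; parent means are
compared with an LSD test rendered as compact letter groups, and the
trial's residual coefficient of variation CV% = 100*sqrt(MSe)/grand mean.

Usage follows the Model / Results idiom::

    res = CombiningAbilityModel(pheno, "plant_height").fit()
    res.gca_female; res.sca; res.anova; print(res.summary())
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from hybridca.io import PhenotypeTable


def _response_array(pheno: PhenotypeTable, trait: str) -> np.ndarray:
    """(f, m, r) array of observations, ordered by table parent order."""
    if trait not in pheno.traits:
        raise KeyError(f"unknown trait {trait!r}")
    females, males = pheno.females, pheno.males
    reps = sorted(pheno.data["replicate"].unique())
    idx = {
        (f, m, r): v
        for f, m, r, v in zip(
            pheno.data["female"], pheno.data["male"], pheno.data["replicate"], pheno.data[trait]
        )
    }
    arr = np.empty((len(females), len(males), len(reps)))
    for i, f in enumerate(females):
        for j, m in enumerate(males):
            for k, r in enumerate(reps):
                arr[i, j, k] = idx[(f, m, r)]
    return arr


def anova_ca(pheno: PhenotypeTable, trait: str) -> pd.DataFrame:
    """Balanced two-factor-with-blocks ANOVA.

    Rows: blocks, crosses, female (GCA), male (GCA), female x male (SCA),
    error.  SS(crosses) = SS(female) + SS(male) + SS(female x male); F for
    every systematic row is taken against the error mean square.
    """
    y = _response_array(pheno, trait)
    f, m, r = y.shape
    if r < 2:
        raise ValueError("ANOVA needs at least 2 replicates (no error df with 1)")
    mu = y.mean()
    ss_total = float(((y - mu) ** 2).sum())
    ss_blocks = float(f * m * ((y.mean(axis=(0, 1)) - mu) ** 2).sum())
    ss_female = float(m * r * ((y.mean(axis=(1, 2)) - mu) ** 2).sum())
    ss_male = float(f * r * ((y.mean(axis=(0, 2)) - mu) ** 2).sum())
    cross_dev = y.mean(axis=2) - y.mean(axis=(1, 2))[:, None] - y.mean(axis=(0, 2))[None, :] + mu
    ss_fm = float(r * (cross_dev**2).sum())
    ss_crosses = ss_female + ss_male + ss_fm
    ss_error = ss_total - ss_blocks - ss_crosses
    ss_error = max(ss_error, 0.0)  # guard tiny negative rounding

    df_blocks, df_female, df_male = r - 1, f - 1, m - 1
    df_fm = (f - 1) * (m - 1)
    df_crosses = f * m - 1
    df_error = (f * m - 1) * (r - 1)

    rows = {
        "blocks": (df_blocks, ss_blocks),
        "crosses": (df_crosses, ss_crosses),
        "female": (df_female, ss_female),
        "male": (df_male, ss_male),
        "female_x_male": (df_fm, ss_fm),
        "error": (df_error, ss_error),
    }
    ms_error = ss_error / df_error
    out = []
    for name, (df_, ss) in rows.items():
        ms = ss / df_ if df_ else np.nan
        if name == "error" or ms_error == 0:
            F = p = np.nan
        else:
            F = ms / ms_error
            p = float(stats.f.sf(F, df_, df_error))
        out.append({"source": name, "df": df_, "sum_sq": ss, "mean_sq": ms, "F": F, "p": p})
    return pd.DataFrame(out).set_index("source")


def lsd_letters(
    means: pd.Series,
    ms_error: float,
    df_error: int,
    n_per_mean: int,
    alpha: float = 0.01,
) -> pd.Series:
    """Compact letter display from an LSD test.

    LSD = t(1 - alpha/2, df_error) * sqrt(2 * MSe / n_per_mean); means are
    sorted descending and letters assigned greedily over maximal runs of
    means whose pairwise differences fall below the LSD, so 'a' marks the
    highest group.
    """
    if n_per_mean <= 0:
        raise ValueError("n_per_mean must be positive")
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    lsd = float(stats.t.ppf(1 - alpha / 2, df_error) * np.sqrt(2 * ms_error / n_per_mean))
    order = means.sort_values(ascending=False, kind="stable")
    vals = order.to_numpy(dtype=float)
    n = len(vals)
    runs: list[tuple[int, int]] = []
    for i in range(n):
        j = i
        while j + 1 < n and vals[i] - vals[j + 1] < lsd:
            j += 1
        if runs and runs[-1][0] <= i and j <= runs[-1][1]:
            continue  # contained in the previous run; no new letter
        runs.append((i, j))
    letters = {name: "" for name in order.index}
    alphabet = string.ascii_lowercase
    for r_i, (a, b) in enumerate(runs):
        tag = alphabet[r_i % 26] * (r_i // 26 + 1)
        for k in range(a, b + 1):
            letters[order.index[k]] += tag
    return pd.Series(letters).reindex(means.index)


def cv_percent(pheno: PhenotypeTable, trait: str, ms_error: float) -> float:
    """Residual coefficient of variation, 100*sqrt(MSe)/grand mean."""
    gm = pheno.grand_mean(trait)
    if gm == 0:
        raise ValueError("undefined CV: zero grand mean")
    return 100.0 * float(np.sqrt(ms_error)) / gm


@dataclass
class CombiningAbilityResults:
    """Estimates and diagnostics from a fitted combining-ability model."""

    trait: str
    grand_mean: float
    gca_female: pd.Series
    gca_male: pd.Series
    sca: pd.DataFrame
    anova: pd.DataFrame
    letters_female: pd.Series
    letters_male: pd.Series
    cv_percent: float
    alpha: float
    n_replicates: int
    model: "CombiningAbilityModel" = field(repr=False, default=None)

    @property
    def ms_error(self) -> float:
        return float(self.anova.loc["error", "mean_sq"])

    def fitted_cross_means(self) -> pd.DataFrame:
        """mu + g_f + g_m + s_fm; equals the observed cross means exactly
        on balanced data."""
        return (
            self.grand_mean
            + self.gca_female.to_numpy()[:, None]
            + self.gca_male.to_numpy()[None, :]
            + self.sca
        )

    def effects_table(self) -> pd.DataFrame:
        """Per-parent GCA effect with its LSD letter group (report layout)."""
        rows = [
            {"parent": p, "role": "female", "gca": self.gca_female[p], "letters": self.letters_female[p]}
            for p in self.gca_female.index
        ] + [
            {"parent": p, "role": "male", "gca": self.gca_male[p], "letters": self.letters_male[p]}
            for p in self.gca_male.index
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Combining-ability analysis: {self.trait}",
            f"  grand mean {self.grand_mean:.4f}   CV% {self.cv_percent:.2f}   "
            f"replicates {self.n_replicates}   LSD alpha {self.alpha}",
            "",
            "  ANOVA",
        ]
        lines.append(self.anova.to_string(float_format=lambda v: f"{v:.4g}"))
        lines.append("")
        lines.append("  GCA effects (letter groups share no significant difference)")
        tab = self.effects_table()
        for _, row in tab.iterrows():
            lines.append(f"    {row['parent']:>14s} ({row['role']}): {row['gca']:+.4f} {row['letters']}")
        return "\n".join(lines)


class CombiningAbilityModel:
    """Combining-ability model for one trait of a balanced factorial trial.

    Parameters
    ----------
    pheno
        Balanced :class:`~hybridca.io.PhenotypeTable`.
    trait
        Trait column to analyse.
    """

    def __init__(self, pheno: PhenotypeTable, trait: str):
        if trait not in pheno.traits:
            raise KeyError(f"unknown trait {trait!r}")
        self.pheno = pheno
        self.trait = trait

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, trait: str) -> "CombiningAbilityModel":
        traits = [c for c in df.columns if c not in ("female", "male", "replicate")]
        return cls(PhenotypeTable(df, traits), trait)

    def fit(self, alpha: float = 0.01) -> CombiningAbilityResults:
        pheno = self.pheno
        y = _response_array(pheno, self.trait)
        f, m, r = y.shape
        mu = float(y.mean())
        cross = y.mean(axis=2)
        g_f = cross.mean(axis=1) - mu
        g_m = cross.mean(axis=0) - mu
        s = cross - g_f[:, None] - g_m[None, :] - mu
        gca_female = pd.Series(g_f, index=pheno.females, name="gca")
        gca_male = pd.Series(g_m, index=pheno.males, name="gca")
        sca = pd.DataFrame(s, index=pheno.females, columns=pheno.males)
        anova = anova_ca(pheno, self.trait)
        ms_e = float(anova.loc["error", "mean_sq"])
        df_e = int(anova.loc["error", "df"])
        letters_f = lsd_letters(
            pd.Series(cross.mean(axis=1), index=pheno.females), ms_e, df_e, n_per_mean=r * m, alpha=alpha
        )
        letters_m = lsd_letters(
            pd.Series(cross.mean(axis=0), index=pheno.males), ms_e, df_e, n_per_mean=r * f, alpha=alpha
        )
        return CombiningAbilityResults(
            trait=self.trait,
            grand_mean=mu,
            gca_female=gca_female,
            gca_male=gca_male,
            sca=sca,
            anova=anova,
            letters_female=letters_f,
            letters_male=letters_m,
            cv_percent=cv_percent(pheno, self.trait, ms_e),
            alpha=alpha,
            n_replicates=r,
            model=self,
        )


def estimate_gca_sca(pheno: PhenotypeTable, trait: str, alpha: float = 0.01) -> CombiningAbilityResults:
    """Functional wrapper: fit the combining-ability model for one trait."""
    return CombiningAbilityModel(pheno, trait).fit(alpha=alpha)


def fit_all_traits(pheno: PhenotypeTable, alpha: float = 0.01) -> dict[str, CombiningAbilityResults]:
    return {t: CombiningAbilityModel(pheno, t).fit(alpha=alpha) for t in pheno.traits}
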