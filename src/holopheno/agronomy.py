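"""Yield, harvest-index, emergence and flowering statistics.

Yield components are analysed with a full-factorial three-way ANOVA
(genotype x irrigation regime x inoculation, all interactions) on per-plant
values, preceded by Shapiro-Wilk normality and Levene homogeneity
diagnostics, with Tukey HSD compact-letter groups for significant terms.
Type-II sums of squares are used: robust to the mild imbalance left by
removed plants and identical to the classical table when balanced.
Phenology (emergence, anthesis, silking, the anthesis-silking interval) is
compared between inoculation arms per hybrid with unpaired t-tests, and an
inoculation effect on flowering is flagged when the flowering proportion
differs between arms by more than a configurable margin (10 percentage
points by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "harvest_index",
    "YieldModel",
    "YieldResults",
    "yield_stats",
    "phenology_summary",
    "read_yield_table",
]

_FACTORS = ("hybrid", "regime", "inoculated")
_TERMS = (
    "hybrid",
    "regime",
    "inoculated",
    "hybrid:regime",
    "hybrid:inoculated",
    "regime:inoculated",
    "hybrid:regime:inoculated",
)


def harvest_index(grain_g: float, biomass_g: float) -> float:
    """Harvest index in percent: 100 x mean grain yield / mean aboveground
    biomass (both in grams)."""
    if biomass_g <= 0:
        raise ValueError("biomass must be positive")
    if grain_g < 0:
        raise ValueError("grain yield must be non-negative")
    return 100.0 * grain_g / biomass_g


def read_yield_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"plant_id", "hybrid", "inoculated", "regime"} - set(df.columns)
    if missing:
        raise ValueError(f"yield table missing columns: {sorted(missing)}")
    return df


def _compact_letters(groups: list[str], reject: dict[frozenset, bool]) -> dict[str, str]:
    """Compact letter display from pairwise rejections (insert-and-absorb)."""
    letters: list[set[str]] = [set(groups)]
    for pair, rej in reject.items():
        if not rej:
            continue
        a, b = tuple(pair)
        for s in list(letters):
            if a in s and b in s:
                letters.remove(s)
                sa, sb = s - {b}, s - {a}
                if not any(sa <= t for t in letters):
                    letters.append(sa)
                if not any(sb <= t for t in letters):
                    letters.append(sb)
    letters.sort(key=lambda s: sorted(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, s in enumerate(letters):
        for g in sorted(s):
            out[g] += alphabet[i % len(alphabet)]
    return out


@dataclass
class YieldResults:
    """Fitted yield analysis: diagnostics, ANOVA table, post-hoc groups."""

    response: str
    anova_table: pd.DataFrame
    shapiro_p: float
    levene_p: float
    tukey: dict = field(default_factory=dict)
    letters: dict = field(default_factory=dict)
    alpha: float = 0.05

    @property
    def significant_terms(self) -> list[str]:
        p = self.anova_table["PR(>F)"]
        return [t for t in _TERMS if t in p.index and p[t] <= self.alpha]

    def summary(self) -> str:
        lines = [
            f"Three-way ANOVA on {self.response} (type II SS)",
            f"  Shapiro-Wilk residual normality p = {self.shapiro_p:.4f}",
            f"  Levene homogeneity p = {self.levene_p:.4f}",
            "",
            self.anova_table.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        if self.letters:
            lines.append("")
            lines.append("Tukey HSD groups (significant terms):")
            for term, groups in self.letters.items():
                pretty = ", ".join(f"{g}: {l}" for g, l in groups.items())
                lines.append(f"  {term}: {pretty}")
        return "\n".join(lines)


class YieldModel:
    """Three-way factorial model of a yield component.

    Parameters
    ----------
    table
        Per-plant records with columns ``hybrid``, ``regime``,
        ``inoculated`` (0/1) and the response.
    response
        Column to analyse (e.g. ``yield_g``, ``kernels``).

    :meth:`fit` runs the Shapiro-Wilk and Levene diagnostics, the
    full-factorial OLS ANOVA (7 effect terms + residual, type-II SS) and
    Tukey HSD comparisons for each term significant at ``alpha``,
    returning a :class:`YieldResults`.
    """

    def __init__(self, table: pd.DataFrame, response: str):
        if response not in table.columns:
            raise ValueError(f"response column {response!r} not in table")
        df = table.dropna(subset=[response]).copy()
        for f in _FACTORS:
            df[f] = df[f].astype(str)
        sizes = df.groupby(list(_FACTORS), observed=True).size()
        n_cells = df["hybrid"].nunique() * df["regime"].nunique() * df["inoculated"].nunique()
        if len(sizes) < n_cells or (sizes < 2).any():
            raise ValueError("every design cell needs at least two observations")
        self.data = df
        self.response = response

    def fit(self, alpha: float = 0.05, posthoc: bool = True) -> YieldResults:
        df = self.data.rename(columns={self.response: "_y"})
        model = smf.ols(
            "_y ~ C(hybrid) * C(regime) * C(inoculated)", data=df
        ).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        anova.index = [_clean_term(t) for t in anova.index]
        shapiro_p = float(stats.shapiro(model.resid).pvalue)
        cells = [
            g[1]["_y"].to_numpy()
            for g in df.groupby(list(_FACTORS), observed=True)
        ]
        levene_p = float(stats.levene(*cells).pvalue)
        res = YieldResults(
            response=self.response,
            anova_table=anova,
            shapiro_p=shapiro_p,
            levene_p=levene_p,
            alpha=alpha,
        )
        if not posthoc:
            return res
        for term in res.significant_terms:
            factors = term.split(":")
            labels = df[factors].agg("/".join, axis=1) if len(factors) > 1 else df[factors[0]]
            if labels.nunique() < 2:
                continue
            hsd = pairwise_tukeyhsd(df["_y"].to_numpy(), labels.to_numpy(), alpha=alpha)
            res.tukey[term] = pd.DataFrame(
                hsd.summary().data[1:], columns=hsd.summary().data[0]
            )
            reject = {}
            for row, rej in zip(hsd.summary().data[1:], hsd.reject):
                reject[frozenset((str(row[0]), str(row[1])))] = bool(rej)
            res.letters[term] = _compact_letters(
                sorted(labels.unique()), reject
            )
        return res


def _clean_term(term: str) -> str:
    return (
        term.replace("C(hybrid)", "hybrid")
        .replace("C(regime)", "regime")
        .replace("C(inoculated)", "inoculated")
    )


def yield_stats(
    table: pd.DataFrame, response: str, alpha: float = 0.05, posthoc: bool = True
) -> YieldResults:
    """Functional wrapper: ``YieldModel(table, response).fit(alpha)``.

    ``posthoc=False`` skips the Tukey HSD comparisons (useful for
    simulation studies that only inspect the ANOVA table).
    """
    return YieldModel(table, response).fit(alpha=alpha, posthoc=posthoc)


def _arm_ttest(a: np.ndarray, b: np.ndarray) -> float:
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return np.nan
    if np.ptp(np.concatenate([a, b])) == 0.0:
        return 1.0
    return float(stats.ttest_ind(a, b).pvalue)


def phenology_summary(
    table: pd.DataFrame, flowering_margin_pp: float = 10.0
) -> pd.DataFrame:
    """Per-hybrid emergence and flowering comparison between inoculation arms.

    Unpaired t-tests on emergence, anthesis and silking DAS; the
    anthesis-silking interval (ASI) is computed per plant where both dates
    exist.  Plants lacking either flowering date are *flowerless*: excluded
    from ASI but counted in the flowering proportion.  An inoculation effect
    on flowering is flagged when the proportion of flowering plants differs
    between arms by more than ``flowering_margin_pp`` percentage points.
    Arms with fewer than two observations are reported untestable (missing
    p-values), never raised.
    """
    df = table.copy()
    df["asi"] = df["silking_das"] - df["anthesis_das"]
    df["flowering"] = df["anthesis_das"].notna() & df["silking_das"].notna()
    rows = []
    for (hybrid, regime), sub in df.groupby(["hybrid", "regime"], observed=True):
        arm_i = sub[sub["inoculated"] == 1]
        arm_u = sub[sub["inoculated"] == 0]
        row = {"hybrid": hybrid, "regime": regime,
               "n_inoculated": len(arm_i), "n_uninoculated": len(arm_u)}
        for col in ("emergence_das", "anthesis_das", "silking_das", "asi"):
            row[f"p_{col}"] = _arm_ttest(
                arm_i[col].to_numpy(dtype=float), arm_u[col].to_numpy(dtype=float)
            )
        prop_i = arm_i["flowering"].mean() if len(arm_i) else np.nan
        prop_u = arm_u["flowering"].mean() if len(arm_u) else np.nan
        row["flowering_pct_inoculated"] = 100.0 * prop_i
        row["flowering_pct_uninoculated"] = 100.0 * prop_u
        diff = 100.0 * (prop_i - prop_u)
        row["flowering_effect"] = (
            bool(abs(diff) > flowering_margin_pp) if np.isfinite(diff) else False
        )
        rows.append(row)
    return pd.DataFrame(rows)
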