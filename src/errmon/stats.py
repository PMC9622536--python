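"""Repeated-measures group inference.

Thin, contract-level wrappers producing the report shape used throughout
the pipeline: F, uncorrected df, Greenhouse-Geisser epsilon (applied when
Mauchly's test rejects sphericity at 0.05), corrected p, partial eta
squared, and pairwise post-hoc p values (within-subject Tukey HSD or
Bonferroni-corrected t tests, optionally one-tailed).

The ANOVA machinery delegates to pingouin; the within-subject Tukey HSD
uses the studentized-range distribution on the rm-ANOVA error term.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA_SPHERICITY = 0.05


@dataclass
class RmAnovaResult:
    levels: list[str]
    F: float
    df1: float
    df2: float
    eps: float
    p: float                 # GG-corrected when sphericity was rejected
    p_uncorrected: float
    partial_eta_sq: float
    sphericity_p: float
    gg_applied: bool
    posthoc: pd.DataFrame | None = field(default=None, repr=False)

    def report(self) -> str:
        df1, df2 = (self.df1 * self.eps, self.df2 * self.eps) if self.gg_applied \
            else (self.df1, self.df2)
        s = (f"F({df1:.2f}, {df2:.2f}) = {self.F:.2f}, p = {self.p:.3g}, "
             f"eta_p^2 = {self.partial_eta_sq:.2f}")
        if self.gg_applied:
            s += f", eps = {self.eps:.2f}"
        return s

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "posthoc"}
        if self.posthoc is not None:
            d["posthoc"] = self.posthoc.to_dict(orient="records")
        return d


def _as_wide(values: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    wide = pd.DataFrame(values)
    if wide.isna().any().any():
        raise ValueError("complete participant x level matrix required "
                         "(apply the minimum-trial filter upstream)")
    return wide


def rm_anova(values: pd.DataFrame | np.ndarray) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on a participant x level matrix."""
    import pingouin as pg

    wide = _as_wide(values)
    n, k = wide.shape
    if n < 3:
        raise ValueError("repeated-measures ANOVA needs at least 3 participants")
    long = wide.reset_index(names="subject").melt(
        id_vars="subject", var_name="level", value_name="y"
    )
    aov = pg.rm_anova(
        data=long, dv="y", within="level", subject="subject",
        correction=True, effsize="np2", detailed=False,
    ).iloc[0]
    if "F" not in aov.index or not np.isfinite(aov.get("F", np.nan)):
        # degenerate input (zero effect and zero error variance)
        return RmAnovaResult(
            levels=[str(c) for c in wide.columns],
            F=0.0, df1=float(k - 1), df2=float((n - 1) * (k - 1)),
            eps=1.0, p=1.0, p_uncorrected=1.0, partial_eta_sq=0.0,
            sphericity_p=1.0, gg_applied=False,
        )
    if k > 2:
        spher_p = float(aov["p_spher"])
        eps = float(aov["eps"])
    else:
        spher_p, eps = 1.0, 1.0
    gg = spher_p < ALPHA_SPHERICITY and k > 2
    p_unc = float(aov["p_unc"])
    p = float(aov["p_GG_corr"]) if gg else p_unc
    return RmAnovaResult(
        levels=[str(c) for c in wide.columns],
        F=float(aov["F"]), df1=float(aov["ddof1"]), df2=float(aov["ddof2"]),
        eps=eps, p=p, p_uncorrected=p_unc,
        partial_eta_sq=float(aov["np2"]), sphericity_p=spher_p, gg_applied=gg,
    )


def rm_anova_2x2(
    values: pd.DataFrame, factor_a: str = "A", factor_b: str = "B"
) -> pd.DataFrame:
    """2x2 within-subject ANOVA; columns must be tuples (a_level, b_level).

    Returns the pingouin two-way rm-ANOVA table (both factors have two
    levels, so sphericity holds by construction and eps = 1).
    """
    import pingouin as pg

    wide = _as_wide(values)
    if wide.shape[1] != 4:
        raise ValueError("expect 4 columns: (a1,b1),(a1,b2),(a2,b1),(a2,b2)")
    rows = []
    for s, (_, row) in enumerate(wide.iterrows()):
        for col in wide.columns:
            rows.append({"subject": s, factor_a: col[0], factor_b: col[1],
                         "y": float(row[col])})
    long = pd.DataFrame(rows)
    return pg.rm_anova(
        data=long, dv="y", within=[factor_a, factor_b], subject="subject",
        effsize="np2",
    )


# --------------------------------------------------------------------------
# post-hoc tests
# --------------------------------------------------------------------------
def _rm_error_ms(wide: pd.DataFrame) -> tuple[float, float]:
    """Mean-square error (subject x level interaction) of the one-way
    rm-ANOVA, with its degrees of freedom."""
    x = wide.to_numpy(float)
    n, k = x.shape
    grand = x.mean()
    resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + grand
    df = (n - 1) * (k - 1)
    return float((resid**2).sum() / df), float(df)


def pairwise_posthoc(
    values: pd.DataFrame | np.ndarray,
    method: str = "tukey_hsd",
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Pairwise within-subject comparisons of all level pairs.

    ``tukey_hsd``: studentized-range test on the rm-ANOVA error term.
    ``bonferroni_t``: paired t tests, p multiplied by the number of pairs.
    ``one_tailed_bonferroni_t``: as above with ``alternative`` applied to
    (level_i − level_j).
    """
    wide = _as_wide(values)
    k = wide.shape[1]
    n = wide.shape[0]
    pairs = list(itertools.combinations(range(k), 2))
    rows = []
    if method == "tukey_hsd":
        ms_err, df_err = _rm_error_ms(wide)
        se = np.sqrt(ms_err / n)
        for i, j in pairs:
            q = abs(wide.iloc[:, i].mean() - wide.iloc[:, j].mean()) / se
            p = float(sps.studentized_range.sf(q, k, df_err))
            rows.append((wide.columns[i], wide.columns[j], q, min(1.0, p)))
        cols = ["level_a", "level_b", "q", "p"]
    elif method in ("bonferroni_t", "one_tailed_bonferroni_t"):
        alt = alternative if method == "one_tailed_bonferroni_t" else "two-sided"
        m = len(pairs)
        for i, j in pairs:
            t, p = sps.ttest_rel(wide.iloc[:, i], wide.iloc[:, j], alternative=alt)
            rows.append((wide.columns[i], wide.columns[j], float(t),
                         min(1.0, float(p) * m)))
        cols = ["level_a", "level_b", "t", "p"]
    else:
        raise ValueError(f"unknown post-hoc method {method!r}")
    return pd.DataFrame(rows, columns=cols)


def rm_anova_with_posthoc(
    values: pd.DataFrame | np.ndarray, method: str = "tukey_hsd"
) -> RmAnovaResult:
    res = rm_anova(values)
    res.posthoc = pairwise_posthoc(values, method=method)
    return res
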