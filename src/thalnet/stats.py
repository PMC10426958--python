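"""Group-level statistics on working-point metrics.

Two-way repeated-measures ANOVA (with Greenhouse-Geisser sphericity
correction and generalized eta squared), paired Wilcoxon signed-rank tests
with Benjamini-Hochberg FDR correction, and paired Cohen's d. The ANOVA is
computed by pingouin; Wilcoxon by scipy; the BH adjustment by statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = ["RMAnovaResult", "rm_anova_2way", "paired_wilcoxon_fdr",
           "cohens_d_paired", "bh_adjust"]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values for one comparison family."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


@dataclass
class RMAnovaResult:
    """Two-way within-subject ANOVA table plus assumption diagnostics.

    ``table`` has one row per effect (A, B, A*B) with F, df1, df2,
    generalized eta squared (ng2), Greenhouse-Geisser epsilon, the
    uncorrected and GG-corrected p-values, and the reported ``p`` — GG
    whenever Mauchly's test rejects sphericity (eps is printed always).
    ``normality`` holds Shapiro-Wilk p per design cell; ``sphericity``
    Mauchly's W and p per multi-level effect.
    """

    table: pd.DataFrame
    normality: pd.DataFrame
    sphericity: pd.DataFrame


def rm_anova_2way(values, subject_ids, factor_a, factor_b) -> RMAnovaResult:
    """Two-way repeated-measures ANOVA on a complete balanced design.

    Parameters are parallel sequences: one observation per (subject, a, b)
    cell. Raises on unbalanced/incomplete designs and on fewer than three
    subjects.
    """
    df = pd.DataFrame(
        {"subject": list(subject_ids), "a": list(factor_a),
         "b": list(factor_b), "value": np.asarray(values, dtype=float)}
    )
    n_subj = df["subject"].nunique()
    if n_subj < 3:
        raise ValueError("need at least 3 subjects")
    counts = df.groupby(["subject", "a", "b"]).size()
    n_a, n_b = df["a"].nunique(), df["b"].nunique()
    if (counts != 1).any() or len(counts) != n_subj * n_a * n_b:
        raise ValueError("design must be complete and balanced (one value per cell)")

    res = pg.rm_anova(data=df, dv="value", within=["a", "b"], subject="subject",
                      detailed=True, effsize="ng2")
    normality = (
        df.groupby(["a", "b"])["value"]
        .apply(lambda x: sstats.shapiro(x).pvalue if x.nunique() > 1 else np.nan)
        .rename("shapiro_p")
        .reset_index()
    )
    sph_rows = []
    for effect, col in (("a", "a"), ("b", "b")):
        if df[col].nunique() < 3:
            # sphericity is trivially satisfied with two levels
            sph_rows.append({"effect": effect, "W": np.nan, "p": np.nan, "spherical": True})
            continue
        sph = pg.sphericity(df, dv="value", within=col, subject="subject")
        sph_rows.append({"effect": effect, "W": float(sph.W), "p": float(sph.pval),
                         "spherical": bool(sph.spher)})
    sphericity = pd.DataFrame(sph_rows)

    table = res.rename(columns={"Source": "effect", "ddof1": "df1", "ddof2": "df2",
                                "p_unc": "p_uncorrected", "p_GG_corr": "p_gg"})
    spher_by_effect = {row["effect"]: row["spherical"] for _, row in sphericity.iterrows()}
    reported = []
    for _, row in table.iterrows():
        eff = row["effect"]
        # the interaction inherits a correction if either factor violates
        needs_gg = not all(
            spher_by_effect.get(part.strip(), True) for part in str(eff).split("*")
        )
        reported.append(row["p_gg"] if needs_gg and np.isfinite(row["p_gg"]) else row["p_uncorrected"])
    table = table.assign(p=reported)[
        ["effect", "F", "df1", "df2", "ng2", "eps", "p_uncorrected", "p_gg", "p"]
    ]
    return RMAnovaResult(table=table, normality=normality, sphericity=sphericity)


def cohens_d_paired(x, y) -> float:
    """Paired Cohen's d: mean of differences / sd of differences (ddof=1)."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            raise ValueError("zero-variance differences: effect size undefined")
        return float(np.sign(d.mean()) * np.inf)  # constant nonzero shift
    return float(d.mean() / sd)


def paired_wilcoxon_fdr(pairs_list) -> pd.DataFrame:
    """Wilcoxon signed-rank family with BH-FDR adjusted p-values.

    ``pairs_list`` is a sequence of ``(name, x, y)`` paired samples. Each
    comparison yields the signed-rank statistic W, paired Cohen's d, raw p
    and the Benjamini-Hochberg adjusted p across the family. All-zero
    difference sets are flagged degenerate (NaN statistics) but stay in the
    table; they are excluded from the adjustment family.
    """
    rows = []
    for name, x, y in pairs_list:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError(f"{name}: paired samples differ in length")
        if x.size < 5:
            raise ValueError(f"{name}: need n >= 5 pairs")
        diff = x - y
        if np.all(diff == 0):
            rows.append({"comparison": name, "W": np.nan, "cohens_d": np.nan,
                         "p_raw": np.nan, "degenerate": True})
            continue
        stat = sstats.wilcoxon(x, y)
        rows.append({"comparison": name, "W": float(stat.statistic),
                     "cohens_d": cohens_d_paired(x, y),
                     "p_raw": float(stat.pvalue), "degenerate": False})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    ok = ~out["degenerate"]
    if ok.any():
        out.loc[ok, "p_adjusted"] = bh_adjust(out.loc[ok, "p_raw"])
    return out
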