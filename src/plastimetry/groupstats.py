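"""Group-comparison statistics on tidy measurement tables.

The decision tree mirrors common practice in in-vivo plasticity studies:
a per-group Shapiro-Wilk normality gate routes each endpoint to either the
parametric branch (one-way ANOVA with Tukey's HSD post-hoc, or two-way ANOVA
for factorial designs) or the nonparametric branch (Kruskal-Wallis with
Dunn's z-based post-hoc). qPCR relative expression uses the delta-delta-Ct
method with fold change 2^(-ddCt) against a housekeeping reference gene
(Gapdh by default) and a control group.

Tidy tables have columns ``unit_id, group, value`` (plus ``factor_level``
for factorial designs); Ct tables have ``sample_id, group, gene, ct``.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .datatypes import GroupComparisonResult
from .errors import (
    DataError,
    DesignError,
    InsufficientDataError,
    UndefinedStatisticError,
)

logger = logging.getLogger(__name__)


def _groups(data: pd.DataFrame, value_col: str = "value",
            group_col: str = "group") -> dict[str, np.ndarray]:
    if group_col not in data or value_col not in data:
        raise DataError(f"table needs columns {group_col!r} and {value_col!r}")
    vals = data[value_col].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise DataError("values contain NaN or infinities")
    out = {g: sub[value_col].to_numpy(dtype=float)
           for g, sub in data.groupby(group_col, sort=True)}
    if len(out) < 2:
        raise InsufficientDataError("need >= 2 groups")
    return out


def normality_gate(data: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Shapiro-Wilk per group; all groups normal -> parametric branch.

    A constant-valued group makes the test undefined and routes the endpoint
    to the nonparametric branch with a logged warning. Returns a dict with
    the chosen ``branch``, per-group p values, and the gate alpha.
    """
    groups = _groups(data)
    per_group_p: dict[str, float] = {}
    branch = "parametric"
    for g, v in groups.items():
        if v.size < 3:
            raise InsufficientDataError(
                f"group {g!r} has {v.size} values; normality needs >= 3")
        if np.ptp(v) == 0:
            logger.warning(
                "group %s is constant; Shapiro-Wilk undefined -> "
                "nonparametric branch", g)
            per_group_p[g] = float("nan")
            branch = "nonparametric"
            continue
        p = float(sps.shapiro(v).pvalue)
        per_group_p[g] = p
        if p < alpha:
            branch = "nonparametric"
    return {"branch": branch, "per_group_p": per_group_p, "alpha": alpha}


def one_way_anova_tukey(data: pd.DataFrame,
                        posthoc_alpha: float = 0.05,
                        posthoc: bool = True) -> GroupComparisonResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons for k > 2 groups.

    ``posthoc=False`` skips the pairwise table (omnibus only), which is much
    faster in calibration loops."""
    groups = _groups(data)
    arrays = list(groups.values())
    names = list(groups.keys())
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ssb = sum(a.size * (a.mean() - grand.mean()) ** 2 for a in arrays)
    if ssw == 0 and ssb == 0:
        raise UndefinedStatisticError(
            "F undefined: zero within-group variance and equal means")
    if ssw == 0 and ssb > 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat, p = sps.f_oneway(*arrays)
        f_stat, p = float(f_stat), float(p)
    posthoc_rows: list[dict] = []
    if k > 2 and posthoc:
        tk = pairwise_tukeyhsd(
            endog=grand,
            groups=np.concatenate([[n] * a.size
                                   for n, a in zip(names, arrays)]),
            alpha=posthoc_alpha,
        )
        res = tk.summary().data[1:]
        for row in res:
            posthoc_rows.append({"pair": f"{row[0]} vs {row[1]}",
                                 "p": float(row[3])})
    return GroupComparisonResult(
        test_name="one_way_anova_tukey",
        statistic=f_stat,
        df=(k - 1, n_total - k),
        p_value=p,
        posthoc=posthoc_rows,
    )


def two_way_anova(data: pd.DataFrame,
                  factor_col: str = "factor_level") -> GroupComparisonResult:
    """Two-way fixed-effects ANOVA on a group x within-factor design.

    Uses type-II sums of squares (identical to the classical balanced
    decomposition when the design is balanced; a note is recorded when it is
    not). The group-factor F is the headline ``statistic``; the level and
    interaction effects are carried in ``posthoc``.
    """
    for col in ("group", factor_col, "value"):
        if col not in data:
            raise DataError(f"table needs column {col!r}")
    cells = data.groupby(["group", factor_col], observed=True).size()
    g_levels = data["group"].nunique()
    f_levels = data[factor_col].nunique()
    if len(cells) < g_levels * f_levels:
        raise DesignError("incomplete design: at least one empty cell")
    notes = []
    if cells.nunique() > 1:
        notes.append("unbalanced design: type-II sums of squares used")
        logger.warning(notes[-1])
    df = data.rename(columns={factor_col: "flevel"})
    model = smf.ols("value ~ C(group) * C(flevel)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    fg = tab.loc["C(group)"]
    extras = []
    for label, name in (("C(flevel)", "factor"),
                        ("C(group):C(flevel)", "interaction")):
        row = tab.loc[label]
        extras.append({"pair": name, "F": float(row["F"]),
                       "df": (float(row["df"]),
                              float(tab.loc["Residual", "df"])),
                       "p": float(row["PR(>F)"])})
    return GroupComparisonResult(
        test_name="two_way_anova",
        statistic=float(fg["F"]),
        df=(float(fg["df"]), float(tab.loc["Residual", "df"])),
        p_value=float(fg["PR(>F)"]),
        posthoc=extras,
        notes=notes + ["within-factor treated as crossed fixed effect"],
    )


def _dunn_pairwise(groups: dict[str, np.ndarray],
                   adjust: str | None) -> list[dict]:
    """Dunn's z-based pairwise comparisons with tie correction."""
    names = list(groups.keys())
    all_vals = np.concatenate([groups[n] for n in names])
    n_total = all_vals.size
    ranks = sps.rankdata(all_vals)
    offsets = np.cumsum([0] + [groups[n].size for n in names])
    mean_ranks = {n: ranks[offsets[i]:offsets[i + 1]].mean()
                  for i, n in enumerate(names)}
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())
                     / (12.0 * (n_total - 1))) if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    raw = []
    for a, b in itertools.combinations(names, 2):
        na, nb = groups[a].size, groups[b].size
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        raw.append({"pair": f"{a} vs {b}", "z": float(z), "p": float(p)})
    if adjust:
        adj = multipletests([r["p"] for r in raw], method=adjust)[1]
        for r, pa in zip(raw, adj):
            r["p_adjusted"] = float(pa)
    return raw


def kruskal_dunn(data: pd.DataFrame,
                 adjust: str | None = None,
                 posthoc: bool = True) -> GroupComparisonResult:
    """Kruskal-Wallis H (tie-corrected) with Dunn's post-hoc for k > 2.

    Dunn p values are unadjusted by default; pass ``adjust="holm"`` or
    ``"bonferroni"`` for family-wise correction (reported in an extra
    ``p_adjusted`` column).
    """
    groups = _groups(data)
    arrays = list(groups.values())
    if np.ptp(np.concatenate(arrays)) == 0:
        raise UndefinedStatisticError("H undefined: all values identical")
    h_stat, p = sps.kruskal(*arrays)
    pairwise = _dunn_pairwise(groups, adjust) \
        if len(arrays) > 2 and posthoc else []
    return GroupComparisonResult(
        test_name="kruskal_wallis_dunn",
        statistic=float(h_stat),
        df=(len(arrays) - 1,),
        p_value=float(p),
        posthoc=pairwise,
    )


def auto_compare(data: pd.DataFrame, alpha: float = 0.05,
                 adjust: str | None = None) -> GroupComparisonResult:
    """Full decision tree: normality gate, then ANOVA/Tukey or KW/Dunn."""
    decision = normality_gate(data, alpha=alpha)
    if decision["branch"] == "parametric":
        res = one_way_anova_tukey(data)
    else:
        res = kruskal_dunn(data, adjust=adjust)
    res.normality_decision = decision
    return res


# ---------------------------------------------------------------------------
# qPCR relative expression
# ---------------------------------------------------------------------------

def relative_expression(expr: pd.DataFrame, control_group: str,
                        reference_gene: str = "Gapdh") -> pd.DataFrame:
    """Delta-delta-Ct fold changes per sample and gene.

    dCt = Ct_gene - Ct_reference per sample; ddCt = dCt - mean(dCt over the
    control group); fold = 2^(-ddCt). The control group's geometric-mean fold
    is 1 per gene by construction.
    """
    for col in ("sample_id", "group", "gene", "ct"):
        if col not in expr:
            raise DataError(f"Ct table needs column {col!r}")
    if control_group not in set(expr["group"]):
        raise DataError(f"control group {control_group!r} not in table")
    ref = expr[expr["gene"] == reference_gene].set_index("sample_id")["ct"]
    rows = []
    for (sample, gene), sub in expr[expr["gene"] != reference_gene].groupby(
            ["sample_id", "gene"], sort=True):
        if sample not in ref.index:
            raise DataError(
                f"sample {sample!r} lacks a {reference_gene} reference Ct")
        dct = float(sub["ct"].iloc[0]) - float(ref.loc[sample])
        rows.append({"sample_id": sample, "group": sub["group"].iloc[0],
                     "gene": gene, "delta_ct": dct})
    out = pd.DataFrame(rows)
    control_means = out[out["group"] == control_group] \
        .groupby("gene")["delta_ct"].mean()
    missing = set(out["gene"]) - set(control_means.index)
    if missing:
        raise DataError(f"genes missing in control group: {sorted(missing)}")
    out["ddct"] = out["delta_ct"] - out["gene"].map(control_means)
    out["fold"] = 2.0 ** (-out["ddct"])
    return out


def per_gene_tests(fold_table: pd.DataFrame,
                   contrasts: list[tuple[str, str]],
                   value_col: str = "fold",
                   equal_var: bool = True,
                   fdr: bool = False) -> pd.DataFrame:
    """Unpaired two-sample t-test per gene for each named (a, b) contrast.

    Degenerate inputs are handled explicitly: identical zero-variance groups
    give t = 0, p = 1; separated zero-variance groups give p = 0.
    """
    rows = []
    for a, b in contrasts:
        for gene, sub in fold_table.groupby("gene", sort=True):
            va = sub.loc[sub["group"] == a, value_col].to_numpy(dtype=float)
            vb = sub.loc[sub["group"] == b, value_col].to_numpy(dtype=float)
            if va.size == 0 or vb.size == 0:
                raise DataError(
                    f"gene {gene!r}: missing values for contrast {a} vs {b}")
            if np.ptp(va) == 0 and np.ptp(vb) == 0:
                if va[0] == vb[0]:
                    t, p = 0.0, 1.0
                else:
                    t, p = float("inf"), 0.0
            else:
                t, p = sps.ttest_ind(va, vb, equal_var=equal_var)
            rows.append({"contrast": f"{a} vs {b}", "gene": gene,
                         "t": float(t), "p": float(p),
                         "n_a": va.size, "n_b": vb.size})
    out = pd.DataFrame(rows)
    if fdr and len(out):
        out["p_fdr"] = np.nan
        for contrast, idx in out.groupby("contrast").groups.items():
            out.loc[idx, "p_fdr"] = multipletests(
                out.loc[idx, "p"], method="fdr_bh")[1]
    return out
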