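"""Group-comparison statistics for laterality values.

The omnibus policy mirrors standard practice for small unbalanced cohorts:
Shapiro-Wilk normality per group and Levene (median-centred) homogeneity at
alpha = 0.05 select among one-way ANOVA + Tukey (normal, homoscedastic),
Welch ANOVA + Games-Howell (normal, heteroscedastic) and Kruskal-Wallis +
Dunn-Holm (non-normal).  A two-way ANOVA assesses a recording-device
confound, and multiple regression with a variance-inflation-factor screen
assesses clinical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ALPHA_ASSUMPTION = 0.05


@dataclass
class GroupTestResult:
    test: str  # "one-way ANOVA" | "Welch ANOVA" | "Kruskal-Wallis" | "two-way ANOVA"
    statistic: float
    df: tuple  # (df1, df2); df2 may be fractional (Welch) or None (KW)
    p_value: float
    posthoc: pd.DataFrame | None = None  # columns: group_a, group_b, statistic, p_value
    assumption_notes: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")

    def posthoc_p(self, a: str, b: str) -> float:
        ph = self.posthoc
        row = ph[((ph.group_a == a) & (ph.group_b == b)) | ((ph.group_a == b) & (ph.group_b == a))]
        if row.empty:
            raise KeyError((a, b))
        return float(row.p_value.iloc[0])


def _groups(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    names = [g for g in pd.unique(labels)]
    samples = [values[labels == g] for g in names]
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for g, s in zip(names, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    return names, samples, values, labels


def welch_anova(values, labels) -> tuple[float, float, float, float]:
    """Welch's heteroscedasticity-robust one-way ANOVA.

    Returns (F, df1, df2, p)."""
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": np.asarray(labels)})
    res = pg.welch_anova(data=df, dv="value", between="group")
    return (
        float(res["F"].iloc[0]),
        float(res["ddof1"].iloc[0]),
        float(res["ddof2"].iloc[0]),
        float(res["p_unc"].iloc[0]),
    )


def games_howell(values, labels) -> pd.DataFrame:
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": np.asarray(labels)})
    res = pg.pairwise_gameshowell(data=df, dv="value", between="group")
    return pd.DataFrame(
        {
            "group_a": res["A"],
            "group_b": res["B"],
            "statistic": res["T"],
            "p_value": res["pval"],
        }
    )


def dunn_holm(values, labels) -> pd.DataFrame:
    """Dunn's rank-based pairwise test with Holm correction.

    z_ab = (Rbar_a - Rbar_b) / sqrt( (N(N+1)/12 - T) (1/n_a + 1/n_b) ),
    where Rbar are mean ranks over the pooled sample and T is the tie
    correction sum(t^3 - t) / (12 (N - 1)).
    """
    names, samples, values, labels = _groups(values, labels)
    n_total = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_rank = {g: ranks[labels == g].mean() for g in names}
    n = {g: int((labels == g).sum()) for g in names}

    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / n[a] + 1.0 / n[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "statistic": z, "p_value": p})
    out = pd.DataFrame(rows)
    # Holm step-down correction
    order = np.argsort(out.p_value.to_numpy())
    m = len(out)
    adj = np.empty(m)
    running = 0.0
    for rank_i, idx in enumerate(order):
        running = max(running, (m - rank_i) * out.p_value.iloc[idx])
        adj[idx] = min(1.0, running)
    out["p_value"] = adj
    return out


def _tukey(values, labels) -> pd.DataFrame:
    res = pairwise_tukeyhsd(values, labels, alpha=0.05)
    tbl = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return pd.DataFrame(
        {
            "group_a": tbl["group1"],
            "group_b": tbl["group2"],
            "statistic": tbl["meandiff"].astype(float),
            "p_value": tbl["p-adj"].astype(float),
        }
    )


def omnibus_group_test(
    values, labels, alpha: float = ALPHA_ASSUMPTION, include_posthoc: bool = True
) -> GroupTestResult:
    """Assumption-gated omnibus comparison of >= 2 groups.

    Normal + homoscedastic -> one-way ANOVA with Tukey post hoc;
    normal + heteroscedastic -> Welch ANOVA with Games-Howell;
    non-normal -> Kruskal-Wallis with Dunn-Holm.

    ``include_posthoc=False`` skips the pairwise table (cheaper, e.g. for
    calibration simulations).
    """
    names, samples, values, labels = _groups(values, labels)
    k = len(names)

    degenerate = all(np.ptp(s) == 0 for s in samples) and np.ptp(values) == 0
    if degenerate:
        return GroupTestResult(
            "one-way ANOVA",
            0.0,
            (k - 1, len(values) - k),
            1.0,
            _tukey(values, labels),
            {"note": "all values identical"},
        )

    shapiro_p = {}
    for g, s in zip(names, samples):
        shapiro_p[g] = float(stats.shapiro(s).pvalue) if np.ptp(s) > 0 and len(s) >= 3 else 0.0
    normal = all(p > alpha for p in shapiro_p.values())
    levene_p = float(stats.levene(*samples, center="median").pvalue)
    homogeneous = levene_p > alpha
    notes = {"shapiro_p": shapiro_p, "levene_p": levene_p}

    if not normal:
        stat, p = stats.kruskal(*samples)
        ph = dunn_holm(values, labels) if include_posthoc else None
        return GroupTestResult("Kruskal-Wallis", float(stat), (k - 1, None), float(p), ph, notes)
    if homogeneous:
        stat, p = stats.f_oneway(*samples)
        ph = _tukey(values, labels) if include_posthoc else None
        return GroupTestResult(
            "one-way ANOVA", float(stat), (k - 1, len(values) - k), float(p), ph, notes
        )
    f, df1, df2, p = welch_anova(values, labels)
    ph = games_howell(values, labels) if include_posthoc else None
    return GroupTestResult("Welch ANOVA", f, (df1, df2), p, ph, notes)


def two_way_anova(values, group, device) -> GroupTestResult:
    """Two-way ANOVA (type-II sums of squares) with group and device factors.

    Unbalanced designs are handled by model-comparison sums of squares; if
    empty group x device cells make the interaction inestimable, or a
    factor is constant, the model degrades gracefully (interaction dropped /
    one-way ANOVA) with a note.
    """
    df = pd.DataFrame(
        {"value": np.asarray(values, dtype=float), "group": np.asarray(group), "device": np.asarray(device)}
    )
    notes: dict = {}
    if df.group.nunique() < 2:
        raise ValueError("group factor needs >= 2 levels")
    if df.device.nunique() < 2:
        res = omnibus_group_test(df.value, df.group)
        res.assumption_notes["note"] = "single-device cohort; reduces to one-way comparison"
        return res

    cells = df.groupby(["group", "device"]).size().unstack(fill_value=0)
    full_cells = (cells > 0).all(axis=None)
    formula = "value ~ C(group) * C(device)" if full_cells else "value ~ C(group) + C(device)"
    if not full_cells:
        notes["note"] = "empty group x device cells: interaction dropped"
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    notes["anova_table"] = table
    row = table.loc["C(group)"]
    resid = table.loc["Residual"]
    return GroupTestResult(
        "two-way ANOVA",
        float(row["F"]),
        (float(row["df"]), float(resid["df"])),
        float(row["PR(>F)"]),
        _tukey(df.value.to_numpy(), df.group.to_numpy()),
        notes,
    )


@dataclass
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    p_values: pd.Series
    vif: pd.Series
    n: int

    def __post_init__(self):
        if (self.vif < 1.0 - 1e-9).any():
            raise ValueError("VIF must be >= 1 for every factor")

    @property
    def high_vif(self) -> list[str]:
        return list(self.vif.index[self.vif > 10.0])


def _vif_from_design(X: pd.DataFrame) -> pd.Series:
    """VIF per regressor as the diagonal of the inverse correlation matrix.

    Exactly 1 for mutually uncorrelated regressors; infinite (reported, then
    rejected upstream) under perfect collinearity.
    """
    R = np.corrcoef(X.to_numpy(), rowvar=False)
    try:
        inv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        return pd.Series(np.inf, index=X.columns)
    return pd.Series(np.diag(inv), index=X.columns)


def laterality_regression(values, covariates: pd.DataFrame) -> RegressionResult:
    """OLS of a laterality value on clinical covariates with a VIF screen.

    ``covariates`` columns are used as given; non-numeric columns are dummy
    coded (first level dropped).  Raises on perfect collinearity, naming the
    factors involved.
    """
    y = np.asarray(values, dtype=float)
    X = pd.get_dummies(covariates, drop_first=True).astype(float)
    if len(y) <= X.shape[1] + 2:
        raise ValueError("too few observations for the number of factors")
    const = [c for c in X.columns if X[c].nunique() == 1]
    if const:
        raise ValueError(f"constant factor(s): {const}")

    # identify perfectly collinear factors before fitting
    mat = X.to_numpy()
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), mat])) < mat.shape[1] + 1:
        corr = np.corrcoef(mat, rowvar=False)
        pairs = [
            (X.columns[i], X.columns[j])
            for i in range(len(X.columns))
            for j in range(i + 1, len(X.columns))
            if abs(corr[i, j]) > 1 - 1e-9
        ]
        raise ValueError(f"perfectly collinear factors: {pairs or list(X.columns)}")

    vif = _vif_from_design(X)
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return RegressionResult(
        params=model.params.drop("const"),
        bse=model.bse.drop("const"),
        p_values=model.pvalues.drop("const"),
        vif=vif,
        n=len(y),
    )
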