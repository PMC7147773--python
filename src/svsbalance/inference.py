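"""Three-way mixed-model ANOVA, Tukey post-hoc tests, and outlier screening.

Each outcome measure is analyzed with a three-way ANOVA — stimulation
condition × balance condition × threshold technique, all 2-level — with
participant as a random effect. Trials are first averaged to participant ×
cell means, so a balanced 13-participant design has 13 × 8 = 104
observations and every fixed-effect F is tested on (1, 84) degrees of
freedom (104 − 1 − 7 fixed-effect df − 12 participant df = 84).

On balanced cell means the random-intercept model is the classical mixed
ANOVA: participant enters as a block factor and each fixed effect is tested
against the residual mean square. Significant interactions gate Tukey HSD
pairwise comparisons among the four interaction cell means; observations
with large externally studentized residuals are flagged and the model is
refitted without them for comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.outliers_influence import OLSInfluence

from .errors import DesignError, InvalidArgumentError

logger = logging.getLogger(__name__)

FACTORS = ("technique", "balance", "stimulation")

EFFECT_ORDER = (
    "technique",
    "balance",
    "stimulation",
    "technique:balance",
    "technique:stimulation",
    "balance:stimulation",
    "technique:balance:stimulation",
)

_FORMULA = (
    "value ~ C(participant) + C(technique) * C(balance) * C(stimulation)"
)


@dataclass
class AnovaReport:
    """Fixed-effect F tests and auxiliary diagnostics for one measure."""

    measure: str
    effects: pd.DataFrame  # effect, F, df_num, df_den, p
    participant_variance: float
    residual_variance: float
    n_obs: int
    n_participants: int
    alpha: float = 0.05
    outlier_flags: pd.DataFrame | None = None
    refit_without_outliers: "AnovaReport | None" = None
    posthoc: pd.DataFrame | None = None
    data: pd.DataFrame | None = field(default=None, repr=False)
    model: object = field(default=None, repr=False)

    def effect(self, name: str) -> pd.Series:
        return self.effects.set_index("effect").loc[name]

    def significant_interactions(self) -> list:
        mask = self.effects["effect"].str.contains(":") & (
            self.effects["p"] < self.alpha
        )
        return self.effects.loc[mask, "effect"].tolist()


def aggregate_trials(measures: pd.DataFrame) -> pd.DataFrame:
    """Average the per-cell trials to participant × cell means.

    Expects a long table with columns ``participant, task, balance,
    stimulation, technique, trial, measure, value``; returns one row per
    participant × cell × measure. Missing cells are logged and left absent.
    """
    if measures is None or len(measures) == 0:
        raise InvalidArgumentError("empty measures table")
    keys = ["participant", "task", "balance", "stimulation", "technique", "measure"]
    cells = (
        measures.dropna(subset=["value"])
        .groupby(keys, as_index=False)["value"]
        .mean()
    )
    for measure, group in cells.groupby("measure"):
        expected = (
            group["participant"].nunique()
            * group["balance"].nunique()
            * group["stimulation"].nunique()
            * group["technique"].nunique()
        )
        if len(group) != expected:
            logger.warning(
                "measure %s: %d of %d expected participant x cell means present",
                measure,
                len(group),
                expected,
            )
    return cells


def fit_mixed_anova(
    cells: pd.DataFrame, measure_name: str, alpha: float = 0.05
) -> AnovaReport:
    """Fit the three-way mixed ANOVA for one measure on cell means."""
    df = cells[cells["measure"] == measure_name].copy()
    if df.empty:
        raise InvalidArgumentError(f"no rows for measure {measure_name!r}")
    if df["participant"].nunique() < 3:
        raise DesignError("need at least 3 participants")
    for factor in FACTORS:
        if df[factor].nunique() < 2:
            raise DesignError(f"factor {factor!r} has fewer than 2 levels")
    return _fit(df, measure_name, alpha)


def _fit(df: pd.DataFrame, measure_name: str, alpha: float) -> AnovaReport:
    model = smf.ols(_FORMULA, data=df).fit()
    table = anova_lm(model, typ=2)
    rows = []
    for effect in EFFECT_ORDER:
        label = ":".join(f"C({f})" for f in effect.split(":"))
        rows.append(
            {
                "effect": effect,
                "F": float(table.loc[label, "F"]),
                "df_num": int(table.loc[label, "df"]),
                "df_den": int(model.df_resid),
                "p": float(table.loc[label, "PR(>F)"]),
            }
        )
    ms_resid = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
    ms_part = float(
        table.loc["C(participant)", "sum_sq"] / table.loc["C(participant)", "df"]
    )
    n_part = df["participant"].nunique()
    cells_per_part = len(df) / n_part
    sigma2_p = max(0.0, (ms_part - ms_resid) / cells_per_part)
    return AnovaReport(
        measure=measure_name,
        effects=pd.DataFrame(rows),
        participant_variance=sigma2_p,
        residual_variance=ms_resid,
        n_obs=len(df),
        n_participants=n_part,
        alpha=alpha,
        data=df.reset_index(drop=True),
        model=model,
    )


def tukey_posthoc(report: AnovaReport, interaction=("balance", "stimulation")) -> pd.DataFrame:
    """Tukey HSD comparisons among the four cell means of a 2×2 interaction.

    Uses the model's residual mean square and degrees of freedom
    (Tukey–Kramer standard errors under imbalance). The sham-vs-SVS
    contrasts within each balance level — the planned reading of a balance ×
    stimulation interaction — are flagged in ``marked``.
    """
    fa, fb = interaction
    name = f"{fa}:{fb}"
    alt = f"{fb}:{fa}"
    if name not in set(EFFECT_ORDER) and alt not in set(EFFECT_ORDER):
        raise InvalidArgumentError(f"interaction {name!r} is not a fitted effect")
    df = report.data
    mse = report.residual_variance
    df_resid = int(report.model.df_resid)
    groups = df.groupby([fa, fb])["value"]
    means = groups.mean()
    counts = groups.count()
    labels = list(means.index)
    k = len(labels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            diff = float(means[a] - means[b])
            se_q = np.sqrt(mse / 2 * (1 / counts[a] + 1 / counts[b]))
            q = abs(diff) / se_q
            p_adj = float(stats.studentized_range.sf(q, k, df_resid))
            se_t = np.sqrt(mse * (1 / counts[a] + 1 / counts[b]))
            p_unadj = float(2 * stats.t.sf(abs(diff) / se_t, df_resid))
            rows.append(
                {
                    "cell_1": f"{a[0]}:{a[1]}",
                    "cell_2": f"{b[0]}:{b[1]}",
                    "mean_diff": diff,
                    "q": float(q),
                    "p_adj": min(1.0, p_adj),
                    "p_unadj": p_unadj,
                    "significant": p_adj < report.alpha,
                    "marked": a[0] == b[0],  # same first-factor level
                }
            )
    return pd.DataFrame(rows)


def screen_outliers(
    report: AnovaReport, threshold: float = 4.0, refit: bool = True
):
    """Flag rows with |externally studentized residual| ≥ ``threshold``.

    Returns ``(flags, refit_report)``; the refit excludes the flagged rows
    (``None`` when nothing is flagged or ``refit`` is False). A threshold
    that flags more than 10% of the rows triggers a warning.
    """
    resid = np.asarray(OLSInfluence(report.model).resid_studentized_external)
    mask = np.abs(resid) >= threshold
    flags = report.data.loc[mask].copy()
    flags["studentized_residual"] = resid[mask]
    if mask.mean() > 0.10:
        warnings.warn(
            f"outlier threshold {threshold} flags {mask.mean():.0%} of rows; "
            "likely misconfigured",
            stacklevel=2,
        )
    refit_report = None
    if refit and mask.any():
        refit_report = _fit(
            report.data.loc[~mask].reset_index(drop=True), report.measure, report.alpha
        )
    report.outlier_flags = flags
    report.refit_without_outliers = refit_report
    return flags, refit_report


def analyze_measures(
    measures: pd.DataFrame,
    alpha: float = 0.05,
    outlier_threshold: float = 4.0,
    posthoc_interaction=("balance", "stimulation"),
) -> dict:
    """Full inference stage: aggregate, fit per measure, screen, post-hoc.

    Returns ``{(task, measure): AnovaReport}``. Tukey tests run only when the
    requested interaction is significant at ``alpha`` (interactions gate the
    post-hoc tests).
    """
    cells = aggregate_trials(measures)
    reports = {}
    for (task, measure), sub in cells.groupby(["task", "measure"]):
        report = fit_mixed_anova(sub, measure, alpha)
        screen_outliers(report, outlier_threshold)
        name = ":".join(posthoc_interaction)
        if name in report.significant_interactions():
            report.posthoc = tukey_posthoc(report, posthoc_interaction)
        reports[(task, measure)] = report
    return reports


def format_p(p: float) -> str:
    """Report style: three decimals, '< 0.0001' below that."""
    return "< 0.0001" if p < 1e-4 else f"{p:.3f}"


def build_report(reports: dict, alpha: float = 0.05):
    """Per-task summary tables of F(df1, df2) and p for every effect.

    Returns ``(tables, text)``: a dict of per-task DataFrames (one row per
    measure, main effects then interactions) and a human-readable rendering
    with significance marks at ``alpha``.
    """
    if not reports:
        raise InvalidArgumentError("no reports to summarize")
    tables = {}
    lines = []
    for task in sorted({t for t, _ in reports}):
        rows = []
        for (t, measure), rep in sorted(reports.items()):
            if t != task:
                continue
            row = {"measure": measure}
            for _, e in rep.effects.iterrows():
                base = e["effect"]
                row[f"{base}_F"] = e["F"]
                row[f"{base}_df"] = f"({e['df_num']}, {e['df_den']})"
                row[f"{base}_p"] = e["p"]
            rows.append(row)
        tables[task] = pd.DataFrame(rows)
        lines.append(f"=== {task} ===")
        for (t, measure), rep in sorted(reports.items()):
            if t != task:
                continue
            lines.append(f"{measure}:")
            for _, e in rep.effects.iterrows():
                star = " *" if e["p"] < alpha else ""
                lines.append(
                    f"  {e['effect']}: F({e['df_num']}, {e['df_den']}) = "
                    f"{e['F']:.2f}, p = {format_p(e['p'])}{star}"
                )
            if rep.outlier_flags is not None and len(rep.outlier_flags):
                lines.append(f"  outliers flagged: {len(rep.outlier_flags)}")
            if rep.posthoc is not None:
                sig = rep.posthoc[rep.posthoc["significant"]]
                lines.append(
                    f"  Tukey post-hoc: {len(sig)} of {len(rep.posthoc)} pairs "
                    f"significant at alpha = {alpha}"
                )
        lines.append("")
    return tables, "\n".join(lines)
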