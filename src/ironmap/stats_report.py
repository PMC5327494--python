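"""Cohort-level statistics and report generation.

The statistical workflow is deliberately plain: Kolmogorov-Smirnov
normality check per group, one-way ANOVA across groups, and Holm-Sidak
step-down adjustment of the pairwise contrasts, with significance at
alpha = 0.05.  Results are presented as mean +/- standard error.

The KS test is run against a normal with parameters estimated from the
sample, which makes it conservative (Lilliefors caveat); the flag is
reported for audit, not used to switch tests.
"""
from __future__ import annotations

import itertools
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05

GROUP_ORDER = ("humanized_control", "thal_control", "thal_iron_loaded")


def summarize(records: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per-group n, mean and SEM for one metric column."""
    if metric not in records.columns:
        raise KeyError(f"metric {metric!r} not in records")
    rows = []
    for group, sub in records.groupby("group", sort=False):
        vals = sub[metric].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            warnings.warn(f"group {group!r} has no values for {metric!r}; omitted")
            continue
        sem = float(sps.sem(vals)) if vals.size > 1 else np.nan
        rows.append({"group": group, "metric": metric, "n": vals.size,
                     "mean": float(vals.mean()), "sem": sem})
    out = pd.DataFrame(rows)
    order = [g for g in GROUP_ORDER if g in set(out.get("group", []))]
    if order:
        out = out.set_index("group").loc[order].reset_index()
    return out


def holm_sidak_adjust(pvalues) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values.

    For sorted raw p-values p_(1) <= ... <= p_(m), the i-th adjusted value
    is 1 - (1 - p_(i))^(m - i + 1), made monotone non-decreasing.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, alpha=ALPHA, method="holm-sidak")[1]


def compare_groups(records: pd.DataFrame, metric: str, alpha: float = ALPHA) -> dict:
    """KS normality per group, one-way ANOVA, Holm-Sidak-adjusted pairwise
    t contrasts.

    Returns a dict with keys ``normality`` (group -> KS p), ``anova``
    (F, p), and ``contrasts`` (DataFrame with raw and adjusted p and a
    significance flag at ``alpha``).
    """
    groups = {g: sub[metric].dropna().to_numpy(dtype=float)
              for g, sub in records.groupby("group", sort=False)}
    groups = {g: v for g, v in groups.items() if v.size > 0}
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups to compare")
    names = [g for g in GROUP_ORDER if g in groups] + [g for g in groups if g not in GROUP_ORDER]

    normality = {}
    for g in names:
        v = groups[g]
        if v.size >= 3 and np.std(v) > 0:
            ks = sps.kstest(v, "norm", args=(v.mean(), v.std(ddof=1)))
            normality[g] = {"ks_p": float(ks.pvalue), "normal": bool(ks.pvalue > alpha)}
        else:
            normality[g] = {"ks_p": np.nan, "normal": True}

    if all(np.std(groups[g]) == 0 for g in names) and len({groups[g][0] for g in names}) == 1:
        f_stat, p_anova = 0.0, 1.0
    else:
        f_stat, p_anova = (float(x) for x in sps.f_oneway(*(groups[g] for g in names)))

    pairs = list(itertools.combinations(names, 2))
    raw = []
    for ga, gb in pairs:
        if np.std(groups[ga]) == 0 and np.std(groups[gb]) == 0 and groups[ga][0] == groups[gb][0]:
            raw.append(1.0)
        else:
            raw.append(float(sps.ttest_ind(groups[ga], groups[gb]).pvalue))
    adj = holm_sidak_adjust(raw)
    contrasts = pd.DataFrame({
        "group_a": [p[0] for p in pairs],
        "group_b": [p[1] for p in pairs],
        "p_raw": raw,
        "p_adj": adj,
        "significant": adj < alpha,
    })
    return {"metric": metric, "normality": normality,
            "anova": {"F": f_stat, "p": p_anova}, "contrasts": contrasts}


# ---------------------------------------------------------------------------
# report generation

_DEFAULT_METRICS = (
    "myocardium_t2", "myocardium_t2star", "myocardium_t1",
    "liver_t2", "liver_t2star", "liver_t1",
    "spleen_t2", "spleen_t2star",
    "spleen_ratio", "edv", "esv", "sv", "ef", "co",
)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < ALPHA:
        return "*"
    return ""


def build_report(records: pd.DataFrame, out_dir, metrics=None, calibration=None,
                 make_figures: bool = True) -> dict:
    """Summary tables (CSV) and group bar figures with significance stars.

    Returns a dict of output paths; empty cohort yields an empty report
    with a warning rather than an error.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    if records.empty:
        warnings.warn("empty cohort: writing empty report")
        pd.DataFrame().to_csv(out_dir / "summary.csv", index=False)
        outputs["summary"] = str(out_dir / "summary.csv")
        return outputs
    if metrics is None:
        metrics = [m for m in _DEFAULT_METRICS if m in records.columns]

    summaries, all_contrasts = [], []
    comparisons = {}
    for metric in metrics:
        summaries.append(summarize(records, metric))
        if records["group"].nunique() >= 2:
            cmp_res = compare_groups(records, metric)
            comparisons[metric] = cmp_res
            ct = cmp_res["contrasts"].copy()
            ct.insert(0, "metric", metric)
            ct["anova_F"] = cmp_res["anova"]["F"]
            ct["anova_p"] = cmp_res["anova"]["p"]
            all_contrasts.append(ct)
    summary = pd.concat(summaries, ignore_index=True)
    summary.to_csv(out_dir / "summary.csv", index=False)
    outputs["summary"] = str(out_dir / "summary.csv")
    if all_contrasts:
        contrasts = pd.concat(all_contrasts, ignore_index=True)
        contrasts.to_csv(out_dir / "comparisons.csv", index=False)
        outputs["comparisons"] = str(out_dir / "comparisons.csv")

    if make_figures:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for metric in metrics:
            s = summary[summary["metric"] == metric]
            fig, ax = plt.subplots(figsize=(4, 3))
            x = np.arange(len(s))
            ax.bar(x, s["mean"], yerr=s["sem"].fillna(0), capsize=4, color="0.7",
                   edgecolor="k")
            ax.set_xticks(x)
            ax.set_xticklabels(s["group"], rotation=30, ha="right", fontsize=8)
            ax.set_ylabel(metric)
            if metric in comparisons:
                ct = comparisons[metric]["contrasts"]
                gpos = {g: i for i, g in enumerate(s["group"])}
                ymax = float((s["mean"] + s["sem"].fillna(0)).max())
                step = 0.08 * ymax if ymax else 1.0
                level = ymax + step
                for _, row in ct.iterrows():
                    mark = _stars(row["p_adj"])
                    if mark and row["group_a"] in gpos and row["group_b"] in gpos:
                        xa, xb = gpos[row["group_a"]], gpos[row["group_b"]]
                        ax.plot([xa, xa, xb, xb],
                                [level, level + step / 4, level + step / 4, level], c="k", lw=0.8)
                        ax.text((xa + xb) / 2, level + step / 3, mark, ha="center", fontsize=9)
                        level += step
            fig.tight_layout()
            fig.savefig(out_dir / f"{metric}.png", dpi=110)
            plt.close(fig)
            outputs[f"fig_{metric}"] = str(out_dir / f"{metric}.png")

        if calibration is not None:
            from .iron import predict_iron

            fig, ax = plt.subplots(figsize=(4, 3))
            if calibration.fit_pairs:
                taus = [p[0] for p in calibration.fit_pairs]
                fes = [p[1] for p in calibration.fit_pairs]
                ax.plot(taus, fes, "ko", ms=4, label="animals")
            grid = np.linspace(0.3, calibration.tau0, 200)
            ax.plot(grid, predict_iron(calibration, grid), "r-", label="calibration")
            ax.set_xlabel(f"{calibration.mode} (ms)")
            ax.set_ylabel("iron (mg/g dry)")
            ax.legend(fontsize=8)
            fig.tight_layout()
            fig.savefig(out_dir / "calibration.png", dpi=110)
            plt.close(fig)
            outputs["fig_calibration"] = str(out_dir / "calibration.png")
    return outputs
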