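"""Group-level inference on the per-channel activation magnitudes.

Per-channel one-sample t-tests across subjects with Benjamini-Hochberg
FDR correction give the activation maps; ROI means feed a 2x2
repeated-measures ANOVA (task x hand, both within-subject) with partial
eta squared and Bonferroni-corrected paired post hocs.  With both
factors at two levels every effect has one numerator degree of freedom,
so no sphericity correction applies and each main-effect F equals the
square of the corresponding paired t.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError
from .probe_geometry import ProbeLayout


def one_sample_t(values, popmean: float = 0.0, tail: str = "two-sided"):
    """Student one-sample t-test: t = mean / (sd / sqrt(n)), df = n - 1."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ParameterError("need at least two observations")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ParameterError("zero variance across subjects")
    n = x.size
    t = (x.mean() - popmean) / (sd / np.sqrt(n))
    df = n - 1
    if tail == "two-sided":
        p = 2.0 * sps.t.sf(abs(t), df)
    elif tail == "greater":
        p = sps.t.sf(t, df)
    elif tail == "less":
        p = sps.t.cdf(t, df)
    else:
        raise ParameterError(f"unknown tail {tail!r}")
    return float(t), int(df), float(p)


def fdr_bh(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up across a family of p-values.

    Returns ``(p_adjusted, reject)``.  Adjusted p-values are the usual
    monotone cumulative minima p_(i) * m / i; ``reject`` is the step-up
    rejection set at level q (equivalently adjusted p <= q).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    p_adj = np.empty(m)
    p_adj[order] = adj_sorted
    return p_adj, p_adj <= q


def group_activation(
    mean_betas: pd.DataFrame,
    q: float = 0.05,
    tail: str = "two-sided",
    require_positive_t: bool = True,
) -> pd.DataFrame:
    """Per (condition, channel) t/p/FDR table from per-subject mean betas.

    ``mean_betas`` needs columns subject, condition, channel, mean_beta.
    The FDR family is the set of channels within each condition.  The
    ``significant`` flag additionally requires t > 0 (activation =
    increase) unless ``require_positive_t`` is false.
    """
    required = {"subject", "condition", "channel", "mean_beta"}
    if not required.issubset(mean_betas.columns):
        raise ParameterError(f"mean_betas must have columns {sorted(required)}")
    out_rows = []
    for cond, sub in mean_betas.groupby("condition"):
        stats = []
        for ch, vals in sub.groupby("channel"):
            t, df, p = one_sample_t(vals["mean_beta"].to_numpy(), tail=tail)
            stats.append((ch, t, df, p))
        p_adj, reject = fdr_bh([s[3] for s in stats], q=q)
        for (ch, t, df, p), pa, rej in zip(stats, p_adj, reject):
            sig = bool(rej) and (t > 0 if require_positive_t else True)
            out_rows.append(
                {
                    "condition": cond,
                    "channel": ch,
                    "t": t,
                    "df": df,
                    "p_raw": p,
                    "p_fdr": pa,
                    "significant": sig,
                }
            )
    return pd.DataFrame(out_rows)


def roi_means(mean_betas: pd.DataFrame, layout: ProbeLayout) -> pd.DataFrame:
    """Per (subject, condition, roi, hemisphere) mean of channel betas."""
    roi_rows = [
        {"channel": ch.id, "roi": ch.roi, "hemisphere": ch.hemisphere}
        for ch in layout.channels
        if ch.roi != "none"
    ]
    roi_map = pd.DataFrame(roi_rows)
    if roi_map.empty:
        raise ParameterError("layout has no ROI labels; run assign_rois first")
    merged = mean_betas.merge(roi_map, on="channel")
    return (
        merged.groupby(["subject", "condition", "roi", "hemisphere"], as_index=False)[
            "mean_beta"
        ]
        .mean()
        .rename(columns={"mean_beta": "roi_beta"})
    )


def repeated_anova_2x2(cells: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """2x2 fully-within ANOVA via orthogonal contrasts.

    ``cells`` needs columns subject, task, hand, ``value`` with exactly
    two levels of task and hand and one observation per cell per subject.
    Returns one row per effect (task, hand, interaction) with F(1, n-1),
    p, and partial eta squared = SS_effect / (SS_effect + SS_error).
    """
    for col in ("subject", "task", "hand", value):
        if col not in cells.columns:
            raise ParameterError(f"missing column {col!r}")
    tasks = sorted(cells["task"].unique())
    hands = sorted(cells["hand"].unique())
    if len(tasks) != 2 or len(hands) != 2:
        raise ParameterError("both factors must have exactly two levels")
    wide = cells.pivot_table(
        index="subject", columns=["task", "hand"], values=value, aggfunc="mean"
    )
    if wide.isna().any().any() or wide.shape[1] != 4:
        raise ParameterError("incomplete 2x2 within-subject table")
    n = wide.shape[0]
    if n < 2:
        raise ParameterError("need at least two subjects")
    y = {
        (tk, hd): wide[(tk, hd)].to_numpy()
        for tk in tasks
        for hd in hands
    }
    contrasts = {
        "task": (y[(tasks[0], hands[0])] + y[(tasks[0], hands[1])]
                 - y[(tasks[1], hands[0])] - y[(tasks[1], hands[1])]) / 2.0,
        "hand": (y[(tasks[0], hands[0])] - y[(tasks[0], hands[1])]
                 + y[(tasks[1], hands[0])] - y[(tasks[1], hands[1])]) / 2.0,
        "interaction": (y[(tasks[0], hands[0])] - y[(tasks[0], hands[1])]
                        - y[(tasks[1], hands[0])] + y[(tasks[1], hands[1])]) / 2.0,
    }
    rows = []
    for effect, c in contrasts.items():
        ss_effect = n * c.mean() ** 2
        ss_error = float(((c - c.mean()) ** 2).sum())
        if ss_error == 0.0:
            F = np.inf if ss_effect > 0 else 0.0
            p = 0.0 if ss_effect > 0 else 1.0
            eta = 1.0 if ss_effect > 0 else 0.0
        else:
            F = ss_effect / (ss_error / (n - 1))
            p = float(sps.f.sf(F, 1, n - 1))
            eta = ss_effect / (ss_effect + ss_error)
        rows.append(
            {
                "effect": effect,
                "F": float(F),
                "df1": 1,
                "df2": n - 1,
                "p": p,
                "partial_eta_sq": float(eta),
            }
        )
    return pd.DataFrame(rows)


def posthoc_paired(comparisons: list[tuple[str, np.ndarray, np.ndarray]]) -> pd.DataFrame:
    """Paired t-tests with Bonferroni correction over the family.

    Each comparison is (label, a, b) with a and b aligned by subject.
    MD is the mean within-subject difference a - b; adjusted p is raw p
    times the number of comparisons, clipped at 1.
    """
    m = len(comparisons)
    if m == 0:
        raise ParameterError("no comparisons given")
    rows = []
    for label, a, b in comparisons:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape or a.size < 2:
            raise ParameterError(f"comparison {label!r}: need paired n >= 2")
        diff = a - b
        md = float(diff.mean())
        if diff.std(ddof=1) == 0.0:
            t, p = (0.0, 1.0) if md == 0.0 else (np.inf, 0.0)
        else:
            t, p = sps.ttest_rel(a, b)
        rows.append(
            {
                "comparison": label,
                "mean_difference": md,
                "t": float(t),
                "p_raw": float(p),
                "p_bonferroni": float(min(1.0, p * m)),
            }
        )
    return pd.DataFrame(rows)


def anova_by_roi(roi_beta: pd.DataFrame) -> pd.DataFrame:
    """Run the 2x2 ANOVA in every (roi, hemisphere), conditions coded
    '<task>_<hand>' (e.g. ME_left)."""
    parts = roi_beta["condition"].str.rsplit("_", n=1, expand=True)
    df = roi_beta.assign(task=parts[0], hand=parts[1])
    out = []
    for (roi, hemi), sub in df.groupby(["roi", "hemisphere"]):
        table = repeated_anova_2x2(sub.rename(columns={"roi_beta": "value"}))
        table.insert(0, "roi", roi)
        table.insert(1, "hemisphere", hemi)
        out.append(table)
    return pd.concat(out, ignore_index=True)


def make_tmap(activation: pd.DataFrame, layout: ProbeLayout, path=None) -> pd.DataFrame:
    """Per-channel map table (+ optional probe-plane heat-map figure)."""
    pos = {ch.id: ch.midpoint for ch in layout.channels}
    table = activation.copy()
    table["x_cm"] = table["channel"].map(lambda c: pos[c][0])
    table["y_cm"] = table["channel"].map(lambda c: pos[c][1])
    if path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        conds = table["condition"].unique()
        fig, axes = plt.subplots(1, len(conds), figsize=(4.2 * len(conds), 4), squeeze=False)
        lim = max(1.0, float(np.abs(table["t"]).max()))
        for ax, cond in zip(axes[0], conds):
            sub = table[table["condition"] == cond]
            scat = ax.scatter(
                sub["x_cm"], sub["y_cm"], c=sub["t"], s=260,
                cmap="RdBu_r", vmin=-lim, vmax=lim, edgecolors="k",
            )
            for row in sub.itertuples():
                marker = "*" if row.significant else ""
                ax.annotate(
                    f"{row.channel}{marker}", (row.x_cm, row.y_cm),
                    ha="center", va="center", fontsize=7,
                )
            ax.invert_yaxis()
            ax.set_title(cond)
            ax.set_aspect("equal")
        fig.colorbar(scat, ax=axes.ravel().tolist(), shrink=0.8, label="t")
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return table
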