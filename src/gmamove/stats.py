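"""Group comparison of autocorrelation features between GM classes.

Subjects' per-(joint, lag) autocorrelation values are compared between
the normal and cramped-synchronized cohorts cell by cell with an
independent two-sample t-test (pooled-variance Student t by default,
df = n1 + n2 - 2; Welch available by flag).  The signed t is reported as
first group minus second group, so with the default group order
(normal, cramped_synchronized) a negative t means the CS cohort has the
higher autocorrelation.  An omnibus one-way MANOVA (Wilks' lambda)
across the eight joints at a single lag is available as a multivariate
complement to the per-cell grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CohortFeatures",
    "GroupComparisonTable",
    "InsufficientDataError",
    "DegeneracyError",
    "ttest_by_joint_lag",
    "two_sided_p_from_t",
    "manova_across_joints",
    "summarize_comparison",
    "format_cell",
]


class InsufficientDataError(ValueError):
    """A group has too few observations for the requested test."""


class DegeneracyError(ValueError):
    """Singular covariance (or similar degeneracy) blocks the test."""


@dataclass
class CohortFeatures:
    """Subjects-by-(joint, lag) feature matrix with group labels.

    ``data`` is indexed by subject with a two-level column MultiIndex
    (joint, lag_s); ``labels`` maps each subject to its GM class string.
    """

    data: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.data.columns, pd.MultiIndex):
            raise ValueError("data columns must be a (joint, lag_s) MultiIndex")
        self.labels = self.labels.reindex(self.data.index)
        if self.labels.isna().any():
            missing = self.labels[self.labels.isna()].index.tolist()
            raise ValueError(f"subjects without labels: {missing}")

    @classmethod
    def from_tidy(cls, df: pd.DataFrame) -> "CohortFeatures":
        """Build from a tidy table with columns subject, label, joint, lag_s, r."""
        required = {"subject", "label", "joint", "lag_s", "r"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"tidy feature table missing columns {sorted(missing)}")
        wide = df.pivot_table(
            index="subject", columns=["joint", "lag_s"], values="r"
        )
        labels = df.drop_duplicates("subject").set_index("subject")["label"]
        return cls(data=wide, labels=labels)

    def group_sizes(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()

    def group_matrix(self, label: str) -> pd.DataFrame:
        return self.data.loc[self.labels == label]


@dataclass
class GroupComparisonTable:
    """t statistic and two-sided p per (joint, lag) cell."""

    table: pd.DataFrame  # index (joint, lag_s); columns t, p, df, significant
    alpha: float
    group_order: tuple[str, str]
    n_groups: dict[str, int] = field(default_factory=dict)

    def significant_cells(self) -> list[tuple[str, float]]:
        sig = self.table[self.table["significant"]]
        return [tuple(ix) for ix in sig.index]


def two_sided_p_from_t(t: float, df: float) -> float:
    """Two-sided p value of a t statistic: 2 * (1 - F_t(|t|; df))."""
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    return float(2.0 * sps.t.sf(abs(t), df))


def _two_sample_t(a: np.ndarray, b: np.ndarray, variant: str) -> tuple[float, float, float]:
    """(t, p, df) for first-minus-second group ordering."""
    n1, n2 = len(a), len(b)
    if variant == "pooled":
        df = n1 + n2 - 2.0
        sp2 = ((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1)) / df
        if sp2 == 0.0:
            if np.mean(a) == np.mean(b):
                return 0.0, 1.0, df
            # zero pooled variance with unequal means: infinite-t sentinel
            t = np.inf if np.mean(a) > np.mean(b) else -np.inf
            return float(t), 0.0, df
        t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        return float(t), two_sided_p_from_t(t, df), df
    elif variant == "welch":
        res = sps.ttest_ind(a, b, equal_var=False)
        v1, v2 = np.var(a, ddof=1) / n1, np.var(b, ddof=1) / n2
        if v1 + v2 == 0.0:
            if np.mean(a) == np.mean(b):
                return 0.0, 1.0, float(n1 + n2 - 2)
            t = np.inf if np.mean(a) > np.mean(b) else -np.inf
            return float(t), 0.0, float(n1 + n2 - 2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        return float(res.statistic), float(res.pvalue), float(df)
    raise ValueError(f"unknown t-test variant {variant!r}")


def ttest_by_joint_lag(
    features: CohortFeatures,
    alpha: float = 0.05,
    variant: str = "pooled",
    group_order: tuple[str, str] = ("normal", "cramped_synchronized"),
    holm: bool = False,
) -> GroupComparisonTable:
    """Independent two-sample t-test per (joint, lag) cell.

    ``holm`` applies a Holm step-down correction to the significance
    flags (the raw p values are always reported uncorrected).
    """
    g1 = features.group_matrix(group_order[0])
    g2 = features.group_matrix(group_order[1])
    if len(g1) < 2 or len(g2) < 2:
        raise InsufficientDataError(
            f"need >= 2 subjects per group, have "
            f"{group_order[0]}={len(g1)}, {group_order[1]}={len(g2)}"
        )
    rows = []
    for col in features.data.columns:
        a = g1[col].dropna().to_numpy()
        b = g2[col].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise InsufficientDataError(
                f"cell {col}: fewer than 2 observations in a group"
            )
        t, p, df = _two_sample_t(a, b, variant)
        rows.append({"joint": col[0], "lag_s": col[1], "t": t, "p": p, "df": df})
    table = pd.DataFrame(rows).set_index(["joint", "lag_s"])
    if holm:
        order = np.argsort(table["p"].to_numpy())
        m = len(table)
        sig = np.zeros(m, dtype=bool)
        for rank, idx in enumerate(order):
            if table["p"].iloc[idx] < alpha / (m - rank):
                sig[idx] = True
            else:
                break
        table["significant"] = sig
    else:
        table["significant"] = table["p"] < alpha
    return GroupComparisonTable(
        table=table,
        alpha=alpha,
        group_order=group_order,
        n_groups={group_order[0]: len(g1), group_order[1]: len(g2)},
    )


def manova_across_joints(
    features: CohortFeatures,
    lag_s: float,
    group_order: tuple[str, str] = ("normal", "cramped_synchronized"),
) -> float:
    """One-way MANOVA (Wilks' lambda) on all joints' r values at one lag.

    Returns the omnibus p value of the group effect.  Requires more
    subjects than response columns; a singular within-group covariance
    raises :class:`DegeneracyError` with a suggestion to prune columns.
    """
    from statsmodels.multivariate.manova import MANOVA

    cols = [c for c in features.data.columns if np.isclose(c[1], lag_s)]
    if not cols:
        raise ValueError(f"no feature columns at lag {lag_s} s")
    sub = features.data[cols].dropna()
    labels = features.labels.reindex(sub.index)
    counts = labels.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise InsufficientDataError("MANOVA needs >= 2 groups with >= 2 subjects")
    if len(sub) <= len(cols):
        raise DegeneracyError(
            f"{len(sub)} subjects for {len(cols)} response columns; "
            "prune columns or add subjects"
        )
    endog = sub.to_numpy()
    group = (labels == group_order[1]).astype(float).to_numpy()
    exog = np.column_stack([np.ones(len(sub)), group])
    # identical group means: Wilks' lambda is exactly 1 and the F
    # machinery degenerates, so short-circuit to p = 1
    if np.allclose(endog[group == 1].mean(axis=0), endog[group == 0].mean(axis=0)):
        return 1.0
    try:
        mv = MANOVA(endog, exog)
        res = mv.mv_test(
            hypotheses=[("group", np.array([[0.0, 1.0]]), None)]
        )
        stat = res.results["group"]["stat"]
        return float(stat.loc["Wilks' lambda", "Pr > F"])
    except np.linalg.LinAlgError as exc:
        raise DegeneracyError(
            f"singular within-group covariance ({exc}); prune columns"
        ) from exc


def format_cell(t: float, p: float) -> str:
    """Render one grid cell as ``"t (p)"`` with 2-decimal rounding."""
    return f"{t:.2f} ({p:.2f})"


def summarize_comparison(result: GroupComparisonTable) -> tuple[pd.DataFrame, str]:
    """Lags-by-joints grid of ``"t (p)"`` cells plus a text summary.

    The grid rows are lags (seconds) and the columns joints, mirroring
    the usual presentation of the group comparison; the text lists the
    cells significant at the table's alpha.
    """
    if result.table.empty:
        raise ValueError("empty comparison table")
    tab = result.table.reset_index()
    joints = list(dict.fromkeys(tab["joint"]))
    lags = sorted(tab["lag_s"].unique())
    grid = pd.DataFrame(index=pd.Index(lags, name="lag_s"), columns=joints, dtype=object)
    for _, row in tab.iterrows():
        grid.loc[row["lag_s"], row["joint"]] = format_cell(row["t"], row["p"])
    sig = result.significant_cells()
    lines = [
        f"groups: {result.group_order[0]} (n={result.n_groups.get(result.group_order[0], '?')}) "
        f"vs {result.group_order[1]} (n={result.n_groups.get(result.group_order[1], '?')})",
        f"significant cells at alpha={result.alpha:g}: {len(sig)}",
    ]
    for joint, lag in sig:
        cell = result.table.loc[(joint, lag)]
        lines.append(
            f"  {joint} @ {lag:g} s: t={cell['t']:.2f}, p={cell['p']:.4f}"
        )
    return grid, "\n".join(lines)
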