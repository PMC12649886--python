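"""The study's statistical layer, written out from first principles.

Student's and Welch's t-tests, the 2-factor ANOVA with interaction used for
the condition x PMD design, Fisher's LSD post hoc comparisons with compact
letter display, and 2^-ddCt relative expression. Sums of squares, mean
squares and test statistics are computed explicitly; only the t and F
distribution tail areas come from scipy.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import InputError


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def t_test(group_a, group_b, variant: str = "student") -> tuple[float, float, float]:
    """Two-sided two-sample t-test; returns (t, df, p).

    ``student`` pools the variances (the study's two-group comparison);
    ``welch`` uses the Satterthwaite approximation. Zero-variance input with
    equal means yields (0, df, 1); with unequal means the difference is
    infinitely many standard errors, so p -> 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each group needs at least 2 values")
    na, nb = len(a), len(b)
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if variant == "student":
        df = na + nb - 2.0
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    elif variant == "welch":
        se = np.sqrt(va / na + vb / nb)
        if va == 0 and vb == 0:
            df = na + nb - 2.0
        else:
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        raise StatsError(f"unknown variant {variant!r}")
    if se == 0:
        if ma == mb:
            return 0.0, float(df), 1.0
        return float(np.sign(ma - mb) * np.inf), float(df), 0.0
    t = (ma - mb) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


# ---------------------------------------------------------------------------
# two-factor ANOVA with interaction
# ---------------------------------------------------------------------------

@dataclass
class AnovaTable:
    """Sums of squares, F statistics and p-values per source."""

    sources: dict = field(default_factory=dict)  # name -> dict(ss, df, ms, F, p)
    degenerate: bool = False

    def __getitem__(self, source: str) -> dict:
        return self.sources[source]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"source": k, **v} for k, v in self.sources.items()])


def _cell_map(values, a_labels, b_labels):
    values = np.asarray(values, dtype=float)
    a_labels = np.asarray(a_labels)
    b_labels = np.asarray(b_labels)
    if not (len(values) == len(a_labels) == len(b_labels)):
        raise StatsError("values and factor labels must have equal length")
    a_levels = sorted(pd.unique(a_labels).tolist())
    b_levels = sorted(pd.unique(b_labels).tolist())
    cells = {}
    for ai in a_levels:
        for bj in b_levels:
            sel = values[(a_labels == ai) & (b_labels == bj)]
            if len(sel) < 2:
                raise StatsError(f"design cell {ai!r} x {bj!r} needs >= 2 observations")
            cells[(ai, bj)] = sel
    return values, a_labels, b_labels, a_levels, b_levels, cells


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def anova_2x2(values, a_labels, b_labels,
              a_name: str = "condition", b_name: str = "pmd") -> AnovaTable:
    """Two-factor ANOVA with interaction.

    Balanced designs use the classical marginal-means decomposition (which
    satisfies SS_A + SS_B + SS_AB + SS_err = SS_total); unbalanced designs
    fall back to Type-II sums of squares computed from nested least-squares
    fits. An error sum of squares of zero (all cells constant) flags the
    table as degenerate with undefined F ratios.
    """
    values, a_labels, b_labels, a_levels, b_levels, cells = _cell_map(
        values, a_labels, b_labels)
    n_total = len(values)
    grand = float(np.mean(values))
    ns = {k: len(v) for k, v in cells.items()}
    balanced = len(set(ns.values())) == 1
    ss_err = float(sum(np.sum((v - np.mean(v)) ** 2) for v in cells.values()))
    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_err = n_total - len(a_levels) * len(b_levels)

    if balanced:
        n_cell = next(iter(ns.values()))
        a_means = {ai: np.mean([np.mean(cells[(ai, bj)]) for bj in b_levels])
                   for ai in a_levels}
        b_means = {bj: np.mean([np.mean(cells[(ai, bj)]) for ai in a_levels])
                   for bj in b_levels}
        ss_a = n_cell * len(b_levels) * sum((a_means[ai] - grand) ** 2 for ai in a_levels)
        ss_b = n_cell * len(a_levels) * sum((b_means[bj] - grand) ** 2 for bj in b_levels)
        ss_cells = n_cell * sum((np.mean(cells[(ai, bj)]) - grand) ** 2
                                for ai in a_levels for bj in b_levels)
        ss_ab = ss_cells - ss_a - ss_b
    else:
        # Type-II via residual sums of squares of nested models
        def dummies(labels, levels):
            cols = [(labels == lv).astype(float) for lv in levels[1:]]
            return (np.column_stack(cols) if cols
                    else np.empty((n_total, 0)))

        Xa = dummies(a_labels, a_levels)
        Xb = dummies(b_labels, b_levels)
        ones = np.ones((n_total, 1))
        prods = [Xa[:, i] * Xb[:, j]
                 for i in range(Xa.shape[1]) for j in range(Xb.shape[1])]
        Xab = np.column_stack(prods) if prods else np.empty((n_total, 0))
        y = values
        rss_ab_full = _rss(y, np.hstack([ones, Xa, Xb]))
        ss_a = _rss(y, np.hstack([ones, Xb])) - rss_ab_full
        ss_b = _rss(y, np.hstack([ones, Xa])) - rss_ab_full
        ss_ab = rss_ab_full - _rss(y, np.hstack([ones, Xa, Xb, Xab]))

    table = AnovaTable()
    ms_err = ss_err / df_err if df_err > 0 else float("nan")
    degenerate = not (ms_err > 0)
    for name, ss, df in ((a_name, ss_a, df_a), (b_name, ss_b, df_b),
                         (f"{a_name}:{b_name}", ss_ab, df_ab)):
        ms = ss / df if df > 0 else float("nan")
        if degenerate or df == 0:
            F, p = float("nan"), float("nan")
        else:
            F = ms / ms_err
            p = float(sps.f.sf(F, df, df_err))
        table.sources[name] = {"ss": float(ss), "df": int(df), "ms": float(ms),
                               "F": float(F), "p": p}
    table.sources["error"] = {"ss": ss_err, "df": int(df_err), "ms": float(ms_err),
                              "F": float("nan"), "p": float("nan")}
    table.degenerate = degenerate
    return table


# ---------------------------------------------------------------------------
# Fisher's LSD post hoc comparisons
# ---------------------------------------------------------------------------

def fisher_lsd(anova: AnovaTable, cell_means: dict, cell_ns: dict,
               alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Pairwise LSD tests using the ANOVA error mean square, plus letters.

    Pairwise t statistics are ``(m_i - m_j) / sqrt(MSE (1/n_i + 1/n_j))``
    with the error degrees of freedom. Groups are then merged greedily into
    letter sets (means descending, label as tie-break), so groups sharing a
    letter are not significantly different at ``alpha``.
    """
    err = anova.sources.get("error")
    if err is None or not np.isfinite(err["ms"]) or err["df"] <= 0:
        raise StatsError("ANOVA table lacks a usable error term")
    mse, df_err = err["ms"], err["df"]
    groups = sorted(cell_means, key=lambda g: (-cell_means[g], str(g)))
    rows = []
    pmat = {}
    for i, gi in enumerate(groups):
        for gj in groups[i + 1:]:
            se = np.sqrt(mse * (1.0 / cell_ns[gi] + 1.0 / cell_ns[gj]))
            if se == 0:
                t = 0.0 if cell_means[gi] == cell_means[gj] else np.inf
                p = 1.0 if t == 0.0 else 0.0
            else:
                t = (cell_means[gi] - cell_means[gj]) / se
                p = 2.0 * float(sps.t.sf(abs(t), df_err))
            rows.append({"group_a": str(gi), "group_b": str(gj),
                         "t": float(t), "df": float(df_err), "p": p})
            pmat[(gi, gj)] = pmat[(gj, gi)] = p
    letter_sets: list[list] = []
    for g in groups:
        placed = False
        for members in letter_sets:
            if all(pmat[(g, m)] > alpha for m in members):
                members.append(g)
                placed = True
        if not placed:
            letter_sets.append([g])
    letters = {g: "" for g in groups}
    for k, members in enumerate(letter_sets):
        for g in members:
            letters[g] += chr(ord("a") + k)
    return pd.DataFrame(rows, columns=["group_a", "group_b", "t", "df", "p"]), letters


# ---------------------------------------------------------------------------
# comparative threshold cycle (2^-ddCt)
# ---------------------------------------------------------------------------

def ddct(ct_table: pd.DataFrame, housekeeping: str = "18S",
         reference: str = "control") -> pd.DataFrame:
    """Per-sample dCt, ddCt and fold (2^-ddCt) relative quantification.

    dCt = target Ct - housekeeping Ct within a sample; ddCt references each
    sample's dCt to the mean dCt of the reference condition for that gene;
    group statistics should be run on ddCt values, not folds.
    """
    required = {"sample", "condition", "gene", "ct"}
    if not required.issubset(ct_table.columns):
        raise InputError(f"ct table must have columns {sorted(required)}")
    hk = ct_table[ct_table["gene"] == housekeeping].set_index("sample")["ct"]
    targets = ct_table[ct_table["gene"] != housekeeping]
    missing = sorted(set(targets["sample"]) - set(hk.index))
    if missing:
        raise InputError(f"missing housekeeping Ct for sample(s): {missing}")
    out = targets.copy()
    out["delta_ct"] = out["ct"].to_numpy() - hk.loc[out["sample"]].to_numpy()
    parts = []
    for gene, sub in out.groupby("gene", sort=True):
        ref = sub[sub["condition"] == reference]
        if len(ref) == 0:
            raise InputError(f"no reference-condition samples for gene {gene!r}")
        ref_mean = float(ref["delta_ct"].mean())
        sub = sub.copy()
        sub["delta_delta_ct"] = sub["delta_ct"] - ref_mean
        sub["fold"] = 2.0 ** (-sub["delta_delta_ct"])
        parts.append(sub)
    return pd.concat(parts, ignore_index=True)


def ddct_condition_tests(ddct_table: pd.DataFrame, reference: str = "control",
                         variant: str = "student") -> pd.DataFrame:
    """Per-gene two-group t-tests on ddCt values (reference vs. other)."""
    rows = []
    for gene, sub in ddct_table.groupby("gene", sort=True):
        ref = sub[sub["condition"] == reference]["delta_delta_ct"].to_numpy()
        alt = sub[sub["condition"] != reference]
        for cond, other in alt.groupby("condition", sort=True):
            t, df, p = t_test(other["delta_delta_ct"].to_numpy(), ref, variant)
            rows.append({"gene": gene, "comparison": f"{cond} vs {reference}",
                         "mean_fold": float(other["fold"].mean()),
                         "geo_mean_fold": float(
                             2.0 ** (-other["delta_delta_ct"].mean())),
                         "t": t, "df": df, "p": p})
    return pd.DataFrame(rows)
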