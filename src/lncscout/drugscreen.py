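"""Expression-ranked drug-sensitivity screen.

Cell lines are ranked by a biomarker's expression; per compound, the screen
computes the ratio of geometric-mean IC50 between the top-k and bottom-k
expressing lines (ratio < cutoff flags high-expressor sensitivity), a Welch
t-test on log10 IC50 of the top/bottom k_test lines, and the Pearson
correlation of expression with log10 IC50 over all measured lines. Hits are
compounds that pass the ratio filter with a negative correlation whose BH q
(adjusted across ratio-passing compounds) falls below the configured level;
an optional group-test gate can additionally require the Welch p.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .survival import bh_adjust

__all__ = [
    "validate_drug_table",
    "rank_cell_lines",
    "ic50_ratio",
    "group_difference_test",
    "expression_ic50_correlation",
    "run_drug_screen",
]


def validate_drug_table(responses: pd.DataFrame) -> pd.DataFrame:
    """Check (cell_line, compound, ic50_uM) structure; add log10_ic50."""
    required = {"cell_line", "compound", "ic50_uM"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"drug table missing columns {sorted(missing)}")
    if (responses["ic50_uM"] <= 0).any():
        raise ValueError("IC50 values must be positive")
    dup = responses.duplicated(["cell_line", "compound"])
    if dup.any():
        pair = responses.loc[dup.idxmax(), ["cell_line", "compound"]].tolist()
        raise ValueError(f"duplicate (cell_line, compound) pair {pair}")
    out = responses.copy()
    out["log10_ic50"] = np.log10(out["ic50_uM"])
    return out


def rank_cell_lines(expression: pd.Series) -> list:
    """Cell-line ids by descending expression; ties broken by id."""
    expression = pd.Series(expression)
    if len(expression) < 2:
        raise ValueError("need at least 2 cell lines to rank")
    return sorted(expression.index, key=lambda c: (-expression[c], str(c)))


def _compound_logs(responses: pd.DataFrame, compound: str) -> pd.Series:
    sub = responses[responses["compound"] == compound]
    return pd.Series(sub["log10_ic50"].to_numpy(), index=sub["cell_line"].to_numpy())


def ic50_ratio(high_lines, low_lines, responses: pd.DataFrame, compound: str) -> float | None:
    """Geometric-mean IC50 of high-expressing over low-expressing lines.

    Equals 10^(mean log10 IC50 high - mean log10 IC50 low); ratio < 1 means
    high expressors are more sensitive. Returns None (with a warning) if
    either group has fewer than 2 measured lines.
    """
    logs = _compound_logs(responses, compound)
    hi = logs.reindex([l for l in high_lines if l in logs.index]).dropna()
    lo = logs.reindex([l for l in low_lines if l in logs.index]).dropna()
    if len(hi) < 2 or len(lo) < 2:
        warnings.warn(f"compound {compound!r}: fewer than 2 measured lines per group; skipped")
        return None
    return float(10.0 ** (hi.mean() - lo.mean()))


def group_difference_test(high_lines, low_lines, responses: pd.DataFrame, compound: str) -> float:
    """Two-sided Welch t-test p on log10 IC50 between the two line groups."""
    logs = _compound_logs(responses, compound)
    hi = logs.reindex([l for l in high_lines if l in logs.index]).dropna()
    lo = logs.reindex([l for l in low_lines if l in logs.index]).dropna()
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError(f"compound {compound!r}: insufficient group size for Welch test")
    if hi.std(ddof=1) == 0 and lo.std(ddof=1) == 0:
        return 1.0 if hi.mean() == lo.mean() else 0.0
    t, p = stats.ttest_ind(hi, lo, equal_var=False)
    return float(p)


def expression_ic50_correlation(
    expression: pd.Series, responses: pd.DataFrame, compound: str
) -> tuple[float, float]:
    """Pearson r and two-sided p of expression vs log10 IC50 over all lines.

    Uses every line with both values; constant inputs give (nan, nan) with a
    warning.
    """
    logs = _compound_logs(responses, compound)
    common = [l for l in expression.index if l in logs.index]
    if len(common) < 3:
        raise ValueError(f"compound {compound!r}: fewer than 3 paired observations")
    x = expression.reindex(common).to_numpy(dtype=float)
    y = logs.reindex(common).to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn(f"compound {compound!r}: constant input; correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def run_drug_screen(
    expression: pd.Series,
    responses: pd.DataFrame,
    k_rank: int = 4,
    k_test: int = 6,
    ratio_cutoff: float = 0.25,
    hit_q: float = 0.10,
    group_alpha: float | None = None,
) -> pd.DataFrame:
    """Full screen cascade over every compound.

    Per compound: top/bottom ``k_rank`` geometric-mean IC50 ratio (strict <
    ``ratio_cutoff`` passes), Welch test on the top/bottom ``k_test`` lines,
    Pearson correlation over all lines, and BH adjustment of the correlation p
    across the compounds passing the ratio filter. ``hit`` requires ratio pass,
    negative correlation, bh_q <= hit_q and, when ``group_alpha`` is set, a
    group-test p below it. Every compound is reported with its stage of exit.
    """
    expression = pd.Series(expression)
    responses = validate_drug_table(responses)
    n_needed = 2 * max(k_rank, k_test)
    if len(expression) < n_needed:
        raise ValueError(
            f"insufficient cell lines: need >= {n_needed} for k_rank={k_rank}, k_test={k_test}"
        )
    ranked = rank_cell_lines(expression)
    hi_r, lo_r = ranked[:k_rank], ranked[-k_rank:]
    hi_t, lo_t = ranked[:k_test], ranked[-k_test:]

    rows = []
    for compound in sorted(responses["compound"].unique()):
        logs = _compound_logs(responses, compound)
        ratio = ic50_ratio(hi_r, lo_r, responses, compound)
        if ratio is None:
            rows.append(
                dict(compound=compound, n_lines_used=len(logs), ic50_ratio=np.nan,
                     mean_log_ic50_high=np.nan, mean_log_ic50_low=np.nan,
                     group_test_p=np.nan, pearson_r=np.nan, pearson_p=np.nan,
                     stage_of_exit="insufficient_data")
            )
            continue
        hi_mean = logs.reindex([l for l in hi_r if l in logs.index]).mean()
        lo_mean = logs.reindex([l for l in lo_r if l in logs.index]).mean()
        try:
            group_p = group_difference_test(hi_t, lo_t, responses, compound)
        except ValueError:
            group_p = np.nan
        r, p = expression_ic50_correlation(expression, responses, compound)
        ratio_pass = ratio < ratio_cutoff
        stage = "ratio_filter" if not ratio_pass else "passed"
        rows.append(
            dict(compound=compound, n_lines_used=len(logs), ic50_ratio=ratio,
                 mean_log_ic50_high=float(hi_mean), mean_log_ic50_low=float(lo_mean),
                 group_test_p=group_p, pearson_r=r, pearson_p=p, stage_of_exit=stage)
        )
    table = pd.DataFrame(rows).set_index("compound")

    table["ratio_pass"] = ((table["ic50_ratio"] < ratio_cutoff) & table["ic50_ratio"].notna()).astype(int)
    table["bh_q"] = np.nan
    passers = table.index[table["ratio_pass"] == 1]
    valid = [c for c in passers if np.isfinite(table.loc[c, "pearson_p"])]
    if valid:
        table.loc[valid, "bh_q"] = bh_adjust(table.loc[valid, "pearson_p"])

    hit = (
        (table["ratio_pass"] == 1)
        & (table["pearson_r"] < 0)
        & (table["bh_q"] <= hit_q)
    )
    if group_alpha is not None:
        hit &= table["group_test_p"] < group_alpha
    table["hit"] = hit.fillna(False).astype(int)
    exit_update = table.index[(table["ratio_pass"] == 1) & (table["hit"] == 0)]
    table.loc[exit_update, "stage_of_exit"] = "correlation"
    table.loc[table["hit"] == 1, "stage_of_exit"] = "hit"
    return table
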