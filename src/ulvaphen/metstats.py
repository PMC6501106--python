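"""Diurnal metabolite statistics and the growth-biomarker screen.

Turnover is the signed end-of-day minus end-of-night difference
(positive = consumed overnight). The night-consumption screen ranks
metabolites by log2(mean EOD / mean EON) across strains and keeps those
above a fold-change threshold (default log2FC > 1). Associations with
growth are Spearman rank correlations (average ranks, two-sided p from
the t approximation) corrected for multiple testing per family with
Benjamini-Hochberg q-values by default, or a Storey pi0-estimating
variant behind a flag. Because everything is rank-based, screen
decisions are invariant under strictly monotone transforms of the
abundances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "turnover",
    "turnover_table",
    "night_consumption_screen",
    "spearman",
    "spearman_matrix",
    "adjust_fdr",
    "biomarker_screen",
    "significance_tier",
]


class MetstatsError(ValueError):
    """Raised for invalid statistical inputs."""


# ---------------------------------------------------------------------------
# turnover


def turnover(eod, eon):
    """Signed overnight turnover eod - eon (positive = consumed).

    Antisymmetric in its arguments: turnover(a, b) == -turnover(b, a).
    """
    out = np.asarray(eod, dtype=float) - np.asarray(eon, dtype=float)
    return out.item() if out.ndim == 0 else out


def _pivot(matrix: pd.DataFrame) -> pd.DataFrame:
    """Long (strain_id, metabolite, timepoint, value) -> wide table."""
    required = {"strain_id", "metabolite", "timepoint", "value"}
    if not required.issubset(matrix.columns):
        raise MetstatsError(f"matrix needs columns {sorted(required)}")
    if (matrix["value"].dropna() < 0).any():
        raise MetstatsError("abundances must be non-negative")
    return matrix.pivot_table(
        index="strain_id", columns=["metabolite", "timepoint"], values="value", aggfunc="mean"
    )


def turnover_table(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-strain, per-metabolite overnight turnover (EOD - EON).

    (strain, metabolite) pairs lacking either timepoint are excluded;
    their names are returned as notes.
    """
    wide = _pivot(matrix)
    notes = []
    rows = {}
    for met in wide.columns.get_level_values(0).unique():
        sub = wide[met]
        if "EOD" not in sub.columns or "EON" not in sub.columns:
            notes.append(f"{met}: missing timepoint, excluded")
            continue
        diff = sub["EOD"] - sub["EON"]
        missing = diff.isna()
        if missing.any():
            notes.append(f"{met}: {int(missing.sum())} strain(s) missing a pair, excluded")
        rows[met] = diff
    return pd.DataFrame(rows), notes


# ---------------------------------------------------------------------------
# night-consumption screen


def night_consumption_screen(
    matrix: pd.DataFrame, threshold_log2fc: float = 1.0
) -> tuple[pd.DataFrame, list[str]]:
    """Metabolites consumed overnight by more than a fold-change cutoff.

    Per metabolite the statistic is log2(mean EOD / mean EON) across
    strains; metabolites with log2FC > ``threshold_log2fc`` are marked
    consumed. Zero means are offset by half the smallest nonzero value
    of that metabolite so the ratio stays defined; all-zero metabolites
    are excluded with a note.
    """
    wide = _pivot(matrix)
    rows, notes = [], []
    for met in wide.columns.get_level_values(0).unique():
        sub = wide[met]
        if "EOD" not in sub.columns or "EON" not in sub.columns:
            notes.append(f"{met}: missing timepoint, excluded")
            continue
        mean_eod = sub["EOD"].mean()
        mean_eon = sub["EON"].mean()
        values = pd.concat([sub["EOD"], sub["EON"]]).to_numpy()
        nonzero = values[values > 0]
        if nonzero.size == 0:
            notes.append(f"{met}: all-zero abundances, excluded")
            continue
        offset = 0.5 * nonzero.min()
        if mean_eod == 0:
            mean_eod = offset
        if mean_eon == 0:
            mean_eon = offset
        log2fc = float(np.log2(mean_eod / mean_eon))
        rows.append(
            {
                "metabolite": met,
                "log2fc": log2fc,
                "consumed": log2fc > threshold_log2fc,
            }
        )
    return pd.DataFrame(rows), notes


# ---------------------------------------------------------------------------
# Spearman correlation and FDR


def spearman(x, y, *, min_n: int = 4) -> tuple[float, float, int]:
    """Spearman rho and two-sided p on pairwise-complete observations.

    Rho is the Pearson correlation of average-ranked data; p uses the
    t approximation. Returns (rho, p, n); rho is NaN for constant
    variables or fewer than ``min_n`` complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < min_n or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan"), n
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), n


def adjust_fdr(pvalues, method: str = "bh") -> np.ndarray:
    """q-values for one family of p-values.

    ``"bh"`` (default) is the Benjamini-Hochberg step-up (monotone in
    p, <= 1, invariant to input order). ``"storey"`` scales the BH
    values by an estimate of pi0, the null proportion, obtained from a
    cubic smoother of pi0(lambda) over a lambda grid, evaluated at the
    largest lambda. NaN p-values propagate to NaN q-values.
    """
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise MetstatsError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if ok.sum() == 0:
        return q
    bh = multipletests(p[ok], method="fdr_bh")[1]
    if method == "bh":
        q[ok] = bh
        return q
    if method != "storey":
        raise MetstatsError(f"unknown FDR method {method!r}")
    pv = p[ok]
    lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_raw = np.array([np.mean(pv > lam) / (1.0 - lam) for lam in lambdas])
    if len(pv) < 8 or np.all(pi0_raw == 0):
        pi0 = 1.0
    else:
        coeffs = np.polyfit(lambdas, pi0_raw, 3)
        pi0 = float(np.polyval(coeffs, lambdas.max()))
        pi0 = min(max(pi0, 1.0 / len(pv)), 1.0)
    q[ok] = np.minimum(bh * pi0, 1.0)
    return q


def significance_tier(q: float) -> str:
    """Asterisk tier for a q-value: *, **, *** below 0.05/0.01/0.001."""
    if np.isnan(q):
        return ""
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return ""


def spearman_matrix(
    table: pd.DataFrame, *, fdr: str = "bh", min_n: int = 4
) -> pd.DataFrame:
    """All pairwise Spearman correlations among the columns of a table.

    ``table`` is observations (strains) x variables. Missing values are
    handled pairwise-complete. All unordered pairs are emitted with
    rho, p, q (one multiple-testing family per matrix) and an asterisk
    tier; constant variables yield undefined (NaN) rho reported as
    such.
    """
    cols = list(table.columns)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            rho, p, n = spearman(table[cols[i]], table[cols[j]], min_n=min_n)
            rows.append({"var1": cols[i], "var2": cols[j], "rho": rho, "p": p, "n": n})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = adjust_fdr(out["p"].to_numpy(), method=fdr)
    out["tier"] = [significance_tier(q) for q in out["q"]]
    return out


# ---------------------------------------------------------------------------
# biomarker screen


def biomarker_screen(
    matrix: pd.DataFrame,
    rgr: pd.Series,
    *,
    fdr: str = "bh",
    alpha: float = 0.05,
    min_n: int = 4,
) -> pd.DataFrame:
    """Correlate each metabolite with growth at EOD, EON and overnight
    difference.

    For every metabolite, its end-of-day value, end-of-night value and
    EON - EOD difference are Spearman-correlated against per-strain RGR.
    Each of the three sets is its own multiple-testing family; hits are
    flagged at q < ``alpha``. Returns columns ``metabolite, family,
    rho, p, q, n, significant, tier``.
    """
    wide = _pivot(matrix)
    rgr = pd.Series(rgr)
    rgr = rgr.reindex(wide.index)
    mets = list(wide.columns.get_level_values(0).unique())

    families: dict[str, list[dict]] = {"EOD": [], "EON": [], "diff": []}
    for met in mets:
        sub = wide[met]
        for fam in ("EOD", "EON", "diff"):
            if fam == "diff":
                if "EOD" not in sub.columns or "EON" not in sub.columns:
                    continue
                vals = sub["EON"] - sub["EOD"]
            else:
                if fam not in sub.columns:
                    continue
                vals = sub[fam]
            rho, p, n = spearman(vals.to_numpy(), rgr.to_numpy(), min_n=min_n)
            families[fam].append({"metabolite": met, "family": fam, "rho": rho, "p": p, "n": n})

    parts = []
    for fam, rows in families.items():
        if not rows:
            continue
        df = pd.DataFrame(rows)
        df["q"] = adjust_fdr(df["p"].to_numpy(), method=fdr)
        parts.append(df)
    out = pd.concat(parts, ignore_index=True)
    out["significant"] = out["q"] < alpha
    out["tier"] = [significance_tier(q) for q in out["q"]]
    return out
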