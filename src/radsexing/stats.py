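"""Sex-ratio inference: exact binomial tests, median splits, correlations.

The central question — are males and females produced in equal numbers? —
is answered with the exact two-sided binomial test under the
point-probability convention: the two-sided p-value sums P(X = i) over all
outcomes i whose point probability does not exceed that of the observed
count (up to a 1 + 1e-7 relative tolerance), with X ~ Binomial(n, p0).
This is the convention of R's ``binom.test`` and reproduces its printed
p-values exactly, including boundary cases where the observed count sits at
the mode and the p-value is 1.

Helpers cover grouped sex-ratio tables, median splits of continuous
covariates (ties at the median go to the "low" group), Pearson correlation
tests via the t transform, and per-sex trait summaries for testing sexual
dimorphism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp

__all__ = [
    "BinomialTestResult",
    "binom_test_two_sided",
    "proportion_female",
    "group_sexratio_report",
    "median_split",
    "pearson_test",
    "p_from_r",
    "seed_dimorphism_summary",
]

_REL_TOL = 1e-7  # relative tolerance when comparing point probabilities


@dataclass(frozen=True)
class BinomialTestResult:
    k: int
    n: int
    p0: float
    proportion: float
    p_value: float
    ci_low: float   # 95 % Clopper-Pearson (extension; not part of the core output)
    ci_high: float


def binom_test_two_sided(k: int, n: int, p0: float = 0.5) -> BinomialTestResult:
    """Exact two-sided binomial test, point-probability method.

    p = Σ_i P(X = i) over all i with P(X = i) <= P(X = k) · (1 + 1e-7),
    X ~ Binomial(n, p0); computed in log space so n of 10⁴ and beyond are
    exact to floating precision; capped at 1.
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise TypeError("k and n must be integers")
    if n < 1 or not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n and n >= 1")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")

    i = np.arange(n + 1)
    logpmf = sps.binom.logpmf(i, n, p0)
    keep = logpmf <= logpmf[k] + np.log1p(_REL_TOL)
    if keep.all():  # the observed outcome is (one of) the modes
        p = 1.0
    else:
        p = min(float(np.exp(logsumexp(logpmf[keep]))), 1.0)

    # 95 % Clopper-Pearson interval
    alpha = 0.05
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return BinomialTestResult(int(k), int(n), float(p0), k / n, p, lo, hi)


def proportion_female(records: pd.DataFrame | None = None,
                      k_female: int | None = None,
                      n: int | None = None,
                      sex_col: str = "sex") -> float:
    """Proportion of females, from a records table or from explicit counts."""
    if records is not None:
        n = len(records)
        k_female = int((records[sex_col] == "F").sum())
    if n is None or k_female is None or n < 1:
        raise ValueError("need a non-empty records table or explicit counts with n >= 1")
    return k_female / n


def group_sexratio_report(records: pd.DataFrame, grouping: str,
                          p0: float = 0.5, sex_col: str = "sex") -> pd.DataFrame:
    """Per-group sex-ratio table with exact two-sided binomial p-values.

    One row per group: group, n_female, n_male, total, prop_female, p_value.
    Groups ordered by first appearance so tables print in input order.
    """
    if grouping not in records.columns:
        raise ValueError(f"grouping key {grouping!r} missing from records")
    rows = []
    for g in records[grouping].drop_duplicates():
        grp = records[records[grouping] == g]
        n_f = int((grp[sex_col] == "F").sum())
        n_m = int((grp[sex_col] == "M").sum())
        res = binom_test_two_sided(n_f, n_f + n_m, p0)
        rows.append({
            "group": g, "n_female": n_f, "n_male": n_m, "total": n_f + n_m,
            "prop_female": res.proportion, "p_value": res.p_value,
        })
    return pd.DataFrame(rows)


def median_split(records: pd.DataFrame, field: str,
                 label_col: str | None = None) -> pd.DataFrame:
    """Split records at the median of ``field``: value <= median → 'low',
    value > median → 'high' (ties at the median fall in 'low').

    Records missing the field are dropped.  All-identical values are
    rejected — no informative split exists.
    """
    sub = records.dropna(subset=[field]).copy()
    if len(sub) < 2:
        raise ValueError("need >= 2 records with the field present")
    values = sub[field].to_numpy(dtype=float)
    if np.all(values == values[0]):
        raise ValueError(f"all values of {field!r} identical: no median split possible")
    med = float(np.median(values))
    sub[label_col or f"{field}_split"] = np.where(values <= med, "low", "high")
    sub.attrs["median"] = med
    return sub


def p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation from its summary statistics,
    via t = r·√(n−2)/√(1−r²) on n−2 degrees of freedom."""
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 < r < 1.0:
        return 0.0 if abs(r) == 1.0 else float("nan")
    df = n - 2
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), df))


def pearson_test(x, y) -> tuple[float, int, float]:
    """Pearson correlation with its two-sided t-test: returns (r, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate (zero-variance) input")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, n - 2, p_from_r(r, n)


def seed_dimorphism_summary(records: pd.DataFrame, trait: str,
                            sex_col: str = "sex") -> pd.DataFrame:
    """Per-sex mean ± SE of a seed trait plus a point-biserial test of
    trait against sex (sex coded 0 = male, 1 = female).

    Returns a two-row table (one per sex) with columns sex, n, mean, se;
    the correlation test lives in ``.attrs``: r, df, p_value.
    """
    sub = records.dropna(subset=[trait])
    counts = sub[sex_col].value_counts()
    if set(counts.index) != {"M", "F"} or (counts < 2).any():
        raise ValueError("need >= 2 records of each sex with the trait present")
    rows = []
    for sex in ("F", "M"):
        vals = sub.loc[sub[sex_col] == sex, trait].to_numpy(dtype=float)
        rows.append({
            "sex": sex, "n": len(vals), "mean": float(vals.mean()),
            "se": float(vals.std(ddof=1) / np.sqrt(len(vals))),
        })
    out = pd.DataFrame(rows)
    if sub[trait].nunique() > 1:
        r, df, p = pearson_test(sub[trait], (sub[sex_col] == "F").astype(float))
    else:
        r, df, p = 0.0, len(sub) - 2, 1.0
    out.attrs.update({"r": r, "df": df, "p_value": p})
    return out
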