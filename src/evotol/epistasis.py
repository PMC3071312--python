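"""Epistasis decomposition against a multiplicative fitness null.

Under the multiplicative null, the relative fitness of a combination mutant
equals the product of its constituent single-mutant relative fitnesses:
w_S = prod_{i in S} w_i.  The total epistatic interaction of a subset S is

    epsilon_S = w_S / prod_{i in S} w_i,

reported as log10(epsilon): positive log-epistasis means the combination is
fitter than the multiplicative expectation (synergy), negative means
antagonism.  Significance is assessed from a confidence interval for
log10(epsilon) -- delta-method by default, percentile bootstrap when
replicate-level fitness values are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MutationSet",
    "EpistasisResult",
    "multiplicative_expectation",
    "epistasis",
    "epistasis_ci",
    "landscape_scan",
]

_LN10 = math.log(10.0)


def MutationSet(labels) -> tuple[str, ...]:
    """Canonical (sorted, deduplicated, nonempty) tuple of mutation labels."""
    s = tuple(sorted(set(map(str, labels))))
    if not s:
        raise ValueError("a mutation set must be nonempty")
    return s


@dataclass(frozen=True)
class EpistasisResult:
    subset: tuple[str, ...]
    w: float
    expected_w: float
    epsilon: float
    log_epsilon: float
    ci: tuple[float, float]
    significant: bool
    missing_singles: tuple[str, ...] = ()


def multiplicative_expectation(singles: dict[str, tuple[float, float]]) -> tuple[float, float]:
    """Expected combination fitness under the multiplicative null.

    ``singles`` maps label -> (w_i, SE_i).  Returns (prod w_i, SE) with the
    SE propagated to first order on the log scale:
    Var(ln prod) = sum (SE_i / w_i)^2.  The empty product is 1 with SE 0.
    """
    if not singles:
        return 1.0, 0.0
    ws = np.array([v[0] for v in singles.values()], dtype=float)
    ses = np.array([v[1] for v in singles.values()], dtype=float)
    if np.any(ws <= 0):
        raise ValueError("all single-mutant fitness values must be positive")
    prod = float(np.prod(ws))
    var_log = float(np.sum((ses / ws) ** 2))
    return prod, prod * math.sqrt(var_log)


def _delta_ci(w: float, se_w: float, singles: dict[str, tuple[float, float]],
              level: float, df: float | None = None) -> tuple[float, float]:
    """Normal (or t, if df given) interval for log10(epsilon) by the delta method."""
    var = (se_w / w) ** 2 / _LN10 ** 2
    for wi, sei in singles.values():
        var += (sei / wi) ** 2 / _LN10 ** 2
    point = math.log10(w) - sum(math.log10(wi) for wi, _ in singles.values())
    if df is not None:
        q = float(stats.t.ppf(0.5 + level / 2.0, df))
    else:
        q = float(stats.norm.ppf(0.5 + level / 2.0))
    half = q * math.sqrt(var)
    return (point - half, point + half)


def epistasis_ci(w_combo: tuple[float, float],
                 singles: dict[str, tuple[float, float]], *,
                 method: str = "delta", level: float = 0.95,
                 df: float | None = None,
                 combo_reps=None, single_reps: dict | None = None,
                 n_boot: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Confidence interval for log10(epsilon).

    ``method="delta"``: interval on the log scale with variance
    sum (SE_i/w_i)^2 / ln(10)^2 + (SE_w/w)^2 / ln(10)^2; normal quantile, or
    Student t with ``df`` degrees of freedom when SEs come from few
    replicates.  ``method="bootstrap"``: seeded percentile interval over
    resampled replicate means; requires per-replicate fitness values for the
    combination (``combo_reps``) and each single (``single_reps``).
    """
    w, se_w = w_combo
    if w <= 0:
        raise ValueError("combination fitness must be positive")
    if method == "delta":
        return _delta_ci(w, se_w, singles, level, df)
    if method == "bootstrap":
        if combo_reps is None or single_reps is None:
            raise ValueError("bootstrap requires replicate-level fitness values")
        rng = np.random.default_rng(seed)
        combo_reps = np.asarray(combo_reps, dtype=float)
        sreps = {k: np.asarray(v, dtype=float) for k, v in single_reps.items()}
        vals = np.empty(n_boot)
        for b in range(n_boot):
            wb = np.mean(rng.choice(combo_reps, size=len(combo_reps)))
            tot = math.log10(wb)
            for arr in sreps.values():
                tot -= math.log10(np.mean(rng.choice(arr, size=len(arr))))
            vals[b] = tot
        lo, hi = np.percentile(vals, [100 * (0.5 - level / 2), 100 * (0.5 + level / 2)])
        return (float(lo), float(hi))
    raise ValueError(f"unknown CI method {method!r}")


def epistasis(w_combo: tuple[float, float],
              singles: dict[str, tuple[float, float]], *,
              method: str = "delta", level: float = 0.95,
              df: float | None = None, **ci_kwargs) -> EpistasisResult:
    """Total epistasis of one combination against the multiplicative null."""
    w, se_w = w_combo
    if w <= 0:
        raise ValueError("combination fitness must be positive")
    expected, _ = multiplicative_expectation(singles)
    eps = w / expected
    log_eps = math.log10(eps)
    ci = epistasis_ci(w_combo, singles, method=method, level=level, df=df, **ci_kwargs)
    significant = not (ci[0] <= 0.0 <= ci[1])
    return EpistasisResult(MutationSet(singles), w, expected, eps, log_eps, ci, significant)


def landscape_scan(fitness_table: pd.DataFrame, *, method: str = "delta",
                   level: float = 0.95, df: float | None = None,
                   include_singletons: bool = False) -> pd.DataFrame:
    """Epistasis decomposition of every non-singleton subset of a fitness table.

    ``fitness_table`` columns: subset (semicolon-joined labels), w, se.  All
    singletons referenced by a subset must be present; subsets referencing a
    missing singleton are flagged (``missing=True``) and skipped rather than
    imputed.  A table containing only singletons yields an empty scan;
    with ``include_singletons=True`` singletons are appended with
    epsilon = 1 (their own fitness is the reference).  The result is sorted
    by |log_epsilon| descending.
    """
    singles = {}
    for rec in fitness_table.itertuples(index=False):
        labels = MutationSet(rec.subset.split(";"))
        if len(labels) == 1:
            singles[labels[0]] = (float(rec.w), float(rec.se))
    rows = []
    for rec in fitness_table.itertuples(index=False):
        labels = MutationSet(rec.subset.split(";"))
        if len(labels) == 1:
            rows.append({"subset": ";".join(labels), "w": rec.w, "expected_w": rec.w,
                         "epsilon": 1.0, "log_epsilon": 0.0, "ci_lo": float("nan"),
                         "ci_hi": float("nan"), "significant": False, "missing": False})
            continue
        missing = [m for m in labels if m not in singles]
        if missing:
            rows.append({"subset": ";".join(labels), "w": rec.w, "expected_w": float("nan"),
                         "epsilon": float("nan"), "log_epsilon": float("nan"),
                         "ci_lo": float("nan"), "ci_hi": float("nan"),
                         "significant": False, "missing": True})
            continue
        sub_singles = {m: singles[m] for m in labels}
        res = epistasis((float(rec.w), float(rec.se)), sub_singles,
                        method=method, level=level, df=df)
        rows.append({"subset": ";".join(labels), "w": res.w, "expected_w": res.expected_w,
                     "epsilon": res.epsilon, "log_epsilon": res.log_epsilon,
                     "ci_lo": res.ci[0], "ci_hi": res.ci[1],
                     "significant": res.significant, "missing": False})
    out = pd.DataFrame(rows, columns=["subset", "w", "expected_w", "epsilon",
                                      "log_epsilon", "ci_lo", "ci_hi",
                                      "significant", "missing"])
    nonsingle = out[out["subset"].str.contains(";")]
    singles_df = out[~out["subset"].str.contains(";")]
    nonsingle = nonsingle.reindex(
        nonsingle["log_epsilon"].abs().sort_values(ascending=False, kind="stable").index)
    if include_singletons:
        return pd.concat([nonsingle, singles_df], ignore_index=True)
    return nonsingle.reset_index(drop=True)
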