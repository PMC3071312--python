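"""Microarray preprocessing and moderated-t differential expression.

The preprocessing cascade mirrors a spotted-oligo two-condition design:
background subtraction, variance-stabilizing generalized-log transform,
unweighted quantile normalization, technical-replicate medians with a
biological-replicate acceptance rule, one probe chosen per gene by minimum
replicate variation, an intensity + IQR gene filter, and finally
empirical-Bayes moderated two-sample t statistics with Benjamini-Hochberg
FDR control.

The three standard contrasts of a 2 x 2 strain-by-treatment design are
supported: treatment effect within the reference strain, treatment effect
within the mutant strain, and the strain difference in treatment response
(difference of differences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ArrayLayout",
    "layout_spot_count",
    "background_adjust",
    "glog",
    "quantile_normalize",
    "normalize",
    "collapse_replicates",
    "select_probe_per_gene",
    "filter_genes",
    "estimate_variance_prior",
    "moderated_t_test",
    "adjust_bh",
    "CONTRASTS",
]

CONTRASTS = ("ref_treatment", "mut_treatment", "interaction")


@dataclass(frozen=True)
class ArrayLayout:
    """Array design: probe count, per-probe replication, and design passes.

    ``passes`` is a list of (n_probes, n_cds) tuples, one per probe-design
    pass; their sums must equal ``probe_count`` and ``cds_count``.
    """

    probe_count: int
    replicates_per_probe: int
    cds_count: int
    passes: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.probe_count <= 0 or self.replicates_per_probe <= 0:
            raise ValueError("counts must be positive")
        if self.passes:
            p_sum = sum(p for p, _ in self.passes)
            c_sum = sum(c for _, c in self.passes)
            if p_sum != self.probe_count or c_sum != self.cds_count:
                raise ValueError(
                    f"pass sums ({p_sum} probes, {c_sum} CDSs) disagree with layout "
                    f"({self.probe_count}, {self.cds_count})")


def layout_spot_count(layout: ArrayLayout) -> dict:
    """Total spot count and design summary for an array layout."""
    return {
        "spots": layout.probe_count * layout.replicates_per_probe,
        "probes": layout.probe_count,
        "replicates_per_probe": layout.replicates_per_probe,
        "cds_targeted": layout.cds_count,
    }


def background_adjust(spots: pd.DataFrame) -> pd.DataFrame:
    """Subtract background directly from foreground per spot.

    Adds an ``adjusted`` column (fg - bg); negative values are retained and
    handled downstream by the variance-stabilizing transform.
    """
    out = spots.copy()
    out["adjusted"] = out["fg"] - out["bg"]
    return out


def glog(x: np.ndarray, lam: float | None = None, x0: float = 0.0) -> np.ndarray:
    """Generalized-log (asinh-based) variance-stabilizing transform.

    glog(x) = asinh((x - x0) / lam) / ln(2), which behaves like log2(2x/lam)
    for large x and stays linear (and finite) through zero and negative
    values.  When ``lam`` is None it is chosen from the data as a robust
    scale of the values at or below zero (their MAD about 0, scaled to a
    normal SD), falling back to 1.0 when no such values exist -- a stand-in
    calibration for a full variance-stabilizing-normalization fit.
    """
    x = np.asarray(x, dtype=float)
    if lam is None:
        neg = x[x <= 0]
        lam = 1.4826 * float(np.median(np.abs(neg))) if len(neg) else 1.0
        lam = max(lam, 1e-8)
    if lam <= 0:
        raise ValueError("lam must be positive")
    return np.arcsinh((x - x0) / lam) / math.log(2.0)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Unweighted quantile normalization across sample columns.

    After normalization every column's sorted value vector is identical:
    each value is replaced by the mean across columns of the values sharing
    its rank; ties within a column receive the average of the ranks they
    span.  A single-column input is returned unchanged (the transform is the
    identity in that case).
    """
    if matrix.shape[1] < 2:
        import warnings

        warnings.warn("quantile normalization of a single sample is the identity")
        return matrix.copy()
    vals = matrix.to_numpy(dtype=float)
    order = np.argsort(vals, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(vals, order, axis=0)
    mean_quantiles = sorted_vals.mean(axis=1)
    out = np.empty_like(vals)
    n = vals.shape[0]
    for j in range(vals.shape[1]):
        ranks = stats.rankdata(vals[:, j], method="average") - 1.0  # 0-based, ties averaged
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        frac = ranks - lo
        out[:, j] = (1 - frac) * mean_quantiles[lo] + frac * mean_quantiles[np.minimum(hi, n - 1)]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def normalize(adjusted: pd.DataFrame, lam: float | None = None) -> pd.DataFrame:
    """Two-stage normalization: generalized-log transform, then quantile normalization.

    ``adjusted`` is a probes/genes x samples matrix of background-adjusted
    intensities.
    """
    transformed = pd.DataFrame(glog(adjusted.to_numpy(), lam=lam),
                               index=adjusted.index, columns=adjusted.columns)
    return quantile_normalize(transformed)


def collapse_replicates(spots: pd.DataFrame, design: pd.DataFrame, *,
                        value_col: str = "adjusted",
                        min_acceptable_bio: int = 2,
                        acceptance_min: float = -np.inf) -> pd.DataFrame:
    """Collapse spot-level values to a probe x sample matrix with acceptance rules.

    Per array (sample), a probe's value is the median of its technical
    replicate spots.  A probe x sample cell is "acceptable" when its median
    exceeds ``acceptance_min`` and at least one technical spot is
    non-missing.  Within each condition (strain x treatment cell of
    ``design``; columns sample, condition), a probe must be acceptable in at
    least ``min_acceptable_bio`` biological replicates or its values in that
    condition are set missing; probes failing the rule in every condition
    are dropped.
    """
    medians = (spots.pivot_table(index="probe", columns="sample", values=value_col,
                                 aggfunc="median"))
    cond_of = design.set_index("sample")["condition"]
    acceptable = medians.notna() & (medians > acceptance_min)
    keep_any = pd.Series(False, index=medians.index)
    out = medians.copy()
    for cond, samples in cond_of.groupby(cond_of):
        cols = [s for s in samples.index if s in medians.columns]
        ok = acceptable[cols].sum(axis=1) >= min_acceptable_bio
        out.loc[~ok, cols] = np.nan
        keep_any |= ok
    dropped = medians.index[~keep_any]
    if len(dropped):
        import logging

        logging.getLogger(__name__).info(
            "dropped %d probes with <%d acceptable biological replicates in every condition",
            len(dropped), min_acceptable_bio)
    return out.loc[keep_any]


def select_probe_per_gene(probe_matrix: pd.DataFrame, probe_to_gene: pd.Series,
                          design: pd.DataFrame) -> pd.DataFrame:
    """Represent each gene by its most reproducible probe.

    For each gene, the probe minimizing the sum over conditions of the
    replicate standard deviation is kept; ties break lexicographically by
    probe id.  Returns a gene x sample matrix.
    """
    cond_of = design.set_index("sample")["condition"]
    sd_sum = pd.Series(0.0, index=probe_matrix.index)
    for cond, samples in cond_of.groupby(cond_of):
        cols = [s for s in samples.index if s in probe_matrix.columns]
        sd_sum += probe_matrix[cols].std(axis=1, ddof=1).fillna(np.inf)
    rows = []
    for gene, probes in probe_to_gene.groupby(probe_to_gene):
        cand = [p for p in probes.index if p in probe_matrix.index]
        if not cand:
            continue
        best = min(sorted(cand), key=lambda p: (sd_sum[p], p))
        row = probe_matrix.loc[best].copy()
        row.name = gene
        rows.append(row)
    return pd.DataFrame(rows)


def filter_genes(gene_matrix: pd.DataFrame, *, intensity_min: float = 100.0,
                 min_fraction: float = 0.25, iqr_min: float = 0.5) -> pd.DataFrame:
    """Keep genes with notable expression changes.

    A gene passes when (i) its value exceeds ``intensity_min`` in at least
    ceil(min_fraction * n_samples) samples, and (ii) its interquartile range
    (linear-interpolation quartiles) exceeds ``iqr_min``.
    """
    n = gene_matrix.shape[1]
    need = math.ceil(min_fraction * n)
    vals = gene_matrix.to_numpy(dtype=float)
    count_high = (vals > intensity_min).sum(axis=1)
    q75, q25 = np.nanpercentile(vals, [75, 25], axis=1)
    keep = (count_high >= need) & ((q75 - q25) > iqr_min)
    return gene_matrix.loc[keep]


# --- moderated t -----------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0."""
    if x <= 0:
        return float("inf")
    # trigamma is decreasing; bracket and solve
    lo, hi = 1e-8, 1e8
    return brentq(lambda y: special.polygamma(1, y) - x, lo, hi, xtol=1e-12)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled inverse-chi-square prior to gene variances.

    Given per-gene sample variances ``s2`` on ``df`` degrees of freedom,
    returns (d0, s0_squared): the prior degrees of freedom and prior
    variance such that s2/s0^2 ~ F(df, d0) across genes.  ``d0`` may be
    ``inf`` when the observed log-variance spread is no wider than expected
    from chi-square sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if np.all(s2 <= 0):
        raise ValueError("all gene variances are zero; cannot estimate a variance prior")
    eps = 1e-300
    z = np.log(np.maximum(s2, eps))
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) * (len(e) / (len(e) - 1.0)) if len(e) > 1 else 0.0
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = float("inf")
        s0_2 = math.exp(e_mean)
    else:
        half_d0 = _trigamma_inverse(excess)
        d0 = 2.0 * half_d0
        s0_2 = math.exp(e_mean + special.digamma(half_d0) - math.log(half_d0))
    return d0, s0_2


def _cell_stats(matrix: np.ndarray, cols: np.ndarray):
    sub = matrix[:, cols]
    n = sub.shape[1]
    mean = np.nanmean(sub, axis=1)
    var = np.nanvar(sub, axis=1, ddof=1)
    return mean, var, n


def moderated_t_test(gene_matrix: pd.DataFrame, design: pd.DataFrame,
                     contrast: str, *, prior_df: float | None = None,
                     fdr_cutoff: float = 0.001) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t-test for one contrast.

    ``design`` columns: sample, strain (two levels: reference first
    alphabetically is taken as 'ref'), treated (bool or 0/1).  Contrasts:

    - ``"ref_treatment"``: treated vs untreated within the reference strain;
    - ``"mut_treatment"``: treated vs untreated within the mutant strain;
    - ``"interaction"``: (mut treated - mut untreated) - (ref treated - ref
      untreated), the strain difference in treatment response.

    Per gene, within-group variances are pooled and shrunk toward a prior
    variance s0^2 with prior degrees of freedom d0, both estimated from the
    ensemble of gene variances by method of moments
    (:func:`estimate_variance_prior`); the moderated t uses the shrunk
    variance and df + d0 degrees of freedom.  ``prior_df`` overrides the
    estimated d0 (0 recovers the ordinary Student t).  P-values are
    two-sided; BH-adjusted p-values and flags at ``fdr_cutoff`` are included.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    strains = sorted(design["strain"].unique())
    if len(strains) != 2:
        raise ValueError("the design must have exactly two strains")
    ref, mut = strains
    samples = list(gene_matrix.columns)
    d = design.set_index("sample").loc[samples]
    treated = d["treated"].astype(bool).to_numpy()
    strain = d["strain"].to_numpy()
    vals = gene_matrix.to_numpy(dtype=float)

    def cols(st, tr):
        return np.nonzero((strain == st) & (treated == tr))[0]

    groups = {(st, tr): cols(st, tr) for st in (ref, mut) for tr in (False, True)}
    if contrast == "ref_treatment":
        used = [(ref, True), (ref, False)]
        signs = [1.0, -1.0]
    elif contrast == "mut_treatment":
        used = [(mut, True), (mut, False)]
        signs = [1.0, -1.0]
    else:
        used = [(mut, True), (mut, False), (ref, True), (ref, False)]
        signs = [1.0, -1.0, -1.0, 1.0]
    for key in used:
        if len(groups[key]) < 2:
            raise ValueError(f"group {key} has fewer than 2 samples")

    effect = np.zeros(vals.shape[0])
    pooled_ss = np.zeros(vals.shape[0])
    inv_n = 0.0
    df_total = 0.0
    for key, sign in zip(used, signs):
        mean, var, n = _cell_stats(vals, groups[key])
        effect += sign * mean
        pooled_ss += var * (n - 1)
        inv_n += 1.0 / n
        df_total += n - 1
    s2 = pooled_ss / df_total

    if prior_df is None:
        d0, s0_2 = estimate_variance_prior(s2, df_total)
    elif prior_df == 0:
        d0, s0_2 = 0.0, 0.0
    else:
        d0, s0_2 = float(prior_df), float(np.median(s2))
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_post = np.inf
    else:
        s2_post = (d0 * s0_2 + df_total * s2) / (d0 + df_total)
        df_post = df_total + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(s2_post * inv_n)
    if math.isinf(df_post):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_post)

    keep = np.isfinite(p)
    result = pd.DataFrame({
        "gene": gene_matrix.index,
        "contrast": contrast,
        "effect": effect,
        "t": t,
        "p": p,
    })
    adj = np.full(len(result), np.nan)
    sig = np.zeros(len(result), dtype=bool)
    if keep.any():
        adj_vals, sig_vals = adjust_bh(p[keep], cutoff=fdr_cutoff)
        adj[keep] = adj_vals
        sig[keep] = sig_vals
    result["p_adj"] = adj
    result["significant"] = sig
    return result


def adjust_bh(p_values, cutoff: float = 0.001) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment with significance flags.

    Returns (adjusted p-values, flags at adjusted p < cutoff).  Input p
    outside [0, 1] is rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj, adj < cutoff
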