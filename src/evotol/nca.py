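"""Network Component Analysis: TF activities from expression via known connectivity.

NCA models a genes x samples log-expression matrix E as a bilinear product

    E ~ A @ P

where P (TFs x samples) holds latent transcription-factor activities and the
loadings A (genes x TFs) are constrained to the support of a known binary
connectivity matrix Z: A[i, j] can be nonzero only where Z[i, j] = 1.  Under
the classical identifiability conditions (full-rank A given its support,
full-rank reduced matrices after deleting any TF and its regulon, and at
least as many samples as TFs) the decomposition is unique up to a per-TF
scale and sign.

This module implements the decomposition by alternating least squares (ALS),
an identifiability checker, and a consensus procedure that runs NCA over
many small TF subsets (needed when the number of conditions limits how many
TFs one decomposition can resolve) and retains only TFs whose
condition-contrast is consistent in sign across subsets and significant
against a permutation null.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IdentifiabilityReport",
    "NCADecomposition",
    "ConsensusReport",
    "check_identifiability",
    "decompose",
    "subset_consensus",
    "activity_ci",
]


@dataclass(frozen=True)
class IdentifiabilityReport:
    """Pass/fail of the three NCA identifiability criteria."""

    full_column_rank: bool
    reduced_rank_ok: bool
    enough_conditions: bool
    failing_tfs: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return self.full_column_rank and self.reduced_rank_ok and self.enough_conditions


@dataclass(frozen=True)
class NCADecomposition:
    """Result of one constrained ALS decomposition.

    ``A`` has support within Z and unit-norm columns with the
    largest-magnitude loading positive; ``P`` is rescaled inversely.
    ``residuals`` is the Frobenius residual-norm trajectory per iteration
    (nonincreasing).
    """

    A: pd.DataFrame
    P: pd.DataFrame
    residuals: np.ndarray
    converged: bool
    seed: int


@dataclass(frozen=True)
class ConsensusReport:
    """Per-TF consensus over subset decompositions."""

    table: pd.DataFrame  # tf, mean contrast, sign_consistency, p_perm, retained, n_subsets
    retained: tuple[str, ...]
    activities: pd.DataFrame  # long: tf, subset_id, replicate, condition, activity


def _generic_fill(Z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random matrix with support exactly on Z (for generic-rank tests)."""
    return np.where(Z != 0, rng.uniform(0.5, 1.5, size=Z.shape), 0.0)


def check_identifiability(Z: pd.DataFrame, n_conditions: int, *,
                          seed: int = 0) -> IdentifiabilityReport:
    """Verify the NCA identifiability conditions for a connectivity matrix.

    (i) A is generically full column rank given support Z; (ii) for each TF,
    deleting its column and all genes it regulates leaves a matrix of full
    column rank; (iii) the number of samples is at least the number of TFs.
    Generic rank is evaluated on a random filling of the support.
    """
    Zv = (Z.to_numpy() != 0).astype(float)
    n_genes, n_tfs = Zv.shape
    rng = np.random.default_rng(seed)
    filled = _generic_fill(Zv, rng)
    crit1 = np.linalg.matrix_rank(filled) == n_tfs
    failing = []
    for j, tf in enumerate(Z.columns):
        keep_genes = Zv[:, j] == 0
        keep_tfs = np.arange(n_tfs) != j
        reduced = filled[np.ix_(keep_genes, keep_tfs)]
        if reduced.shape[1] == 0:
            continue  # single-TF network: the reduced-rank condition is vacuous
        if reduced.shape[0] == 0 or np.linalg.matrix_rank(reduced) < n_tfs - 1:
            failing.append(str(tf))
    crit2 = not failing
    crit3 = n_conditions >= n_tfs
    return IdentifiabilityReport(bool(crit1), crit2, bool(crit3), tuple(failing))


def _solve_P(A: np.ndarray, E: np.ndarray, ridge: float) -> np.ndarray:
    AtA = A.T @ A
    try:
        return np.linalg.solve(AtA, A.T @ E)
    except np.linalg.LinAlgError:
        return np.linalg.solve(AtA + ridge * np.eye(AtA.shape[0]), A.T @ E)


def _solve_A(P: np.ndarray, E: np.ndarray, support: dict[tuple[int, ...], np.ndarray],
             ridge: float) -> np.ndarray:
    # genes sharing a support pattern share the Gram matrix, so solve once
    # per pattern with all their right-hand sides
    A = np.zeros((E.shape[0], P.shape[0]))
    for pattern, gene_idx in support.items():
        idx = np.asarray(pattern)
        Psub = P[idx]  # k x samples
        G = Psub @ Psub.T
        B = Psub @ E[gene_idx].T  # k x n_pattern_genes
        try:
            sol = np.linalg.solve(G, B)
        except np.linalg.LinAlgError:
            sol = np.linalg.solve(G + ridge * np.eye(len(idx)), B)
        A[np.ix_(gene_idx, idx)] = sol.T
    return A


def _support_patterns(Zv: np.ndarray) -> dict[tuple[int, ...], np.ndarray]:
    patterns: dict[tuple[int, ...], list[int]] = {}
    for i in range(Zv.shape[0]):
        patterns.setdefault(tuple(np.nonzero(Zv[i])[0]), []).append(i)
    return {k: np.asarray(v) for k, v in patterns.items()}


def _als_run(Ev: np.ndarray, support: dict[tuple[int, ...], np.ndarray],
             A0: np.ndarray, tol: float, max_iter: int, ridge: float):
    A = A0
    residuals = []
    prev = None
    converged = False
    for _ in range(max_iter):
        P = _solve_P(A, Ev, ridge)
        A = _solve_A(P, Ev, support, ridge)
        r = float(np.linalg.norm(Ev - A @ P))
        residuals.append(r)
        if prev is not None and prev - r <= tol * max(prev, 1e-300):
            converged = True
            break
        prev = r
    P = _solve_P(A, Ev, ridge)
    return A, P, np.asarray(residuals), converged


def decompose(E: pd.DataFrame, Z: pd.DataFrame, *, seed: int = 0,
              tol: float = 1e-10, max_iter: int = 2000, ridge: float = 1e-8,
              n_restarts: int = 3, check: bool = True) -> NCADecomposition:
    """Constrained alternating least squares for E ~ A @ P with support(A) in Z.

    Alternates an unconstrained least-squares P-step with per-gene restricted
    A-steps, stopping when the relative improvement of the Frobenius residual
    falls below ``tol`` or after ``max_iter`` iterations.  ALS has local
    minima under random starts, so the first start sets A to ones on the
    support (empirically it reaches the global optimum on identifiable
    noiseless problems) followed by ``n_restarts`` seeded random starts; the
    run with the lowest final residual is kept.  At exit, each column of A is
    scaled to unit Euclidean norm with its largest-magnitude entry positive
    and P is rescaled inversely.  Rank-deficient subproblems fall back to a
    small ridge.

    Gene rows of ``E`` and ``Z`` must match.  With ``check=True`` a failed
    identifiability check raises; pass ``check=False`` to proceed with a
    warning (exploratory use with more TFs than samples).
    """
    if list(E.index) != list(Z.index):
        raise ValueError("gene rows of E and Z must match")
    report = check_identifiability(Z, E.shape[1], seed=seed)
    if not report.ok:
        msg = f"connectivity fails identifiability: {report}"
        if check:
            raise ValueError(msg)
        warnings.warn(msg)
    Ev = E.to_numpy(dtype=float)
    Zv = (Z.to_numpy() != 0)
    support = _support_patterns(Zv)
    rng = np.random.default_rng(seed)
    starts = [Zv.astype(float)]
    starts += [np.where(Zv, rng.standard_normal(Zv.shape), 0.0)
               for _ in range(n_restarts)]
    best = None
    for A0 in starts:
        run = _als_run(Ev, support, A0, tol, max_iter, ridge)
        if best is None or run[2][-1] < best[2][-1]:
            best = run
    A, P, residuals, converged = best
    if not converged:
        warnings.warn("ALS did not converge within max_iter")

    # normalization convention: unit-norm A columns, majority of loadings
    # positive (majority sign is stable across gene subsets; the single
    # largest loading is not) with largest-magnitude tie-break
    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0] = 1.0
    signs = np.empty(A.shape[1])
    for j in range(A.shape[1]):
        s = np.sign(np.sign(A[:, j]).sum())
        if s == 0:
            s = np.sign(A[np.argmax(np.abs(A[:, j])), j]) or 1.0
        signs[j] = s
    scale = norms * signs
    A = A / scale
    P = P * scale[:, None]
    return NCADecomposition(
        pd.DataFrame(A, index=E.index, columns=Z.columns),
        pd.DataFrame(P, index=Z.columns, columns=E.columns),
        np.asarray(residuals), converged, seed)


def _subset_iter(tfs: list[str], subset_size: int, cap: int,
                 rng: np.random.Generator):
    """All TF subsets when few enough, else a seeded random sample of ``cap``."""
    n_total = math.comb(len(tfs), subset_size)
    if n_total <= cap:
        yield from itertools.combinations(sorted(tfs), subset_size)
        return
    seen = set()
    while len(seen) < cap:
        pick = tuple(sorted(rng.choice(len(tfs), size=subset_size, replace=False)))
        if pick not in seen:
            seen.add(pick)
    tfs_sorted = sorted(tfs)
    for pick in sorted(seen):
        yield tuple(tfs_sorted[i] for i in pick)


def subset_consensus(E: pd.DataFrame, Z_full: pd.DataFrame, design: pd.DataFrame,
                     contrast: dict[str, float], *, subset_size: int = 3,
                     max_subsets: int = 60, consistency_min: float = 0.8,
                     alpha: float = 0.05, t_alpha: float = 0.01,
                     n_permutations: int = 999,
                     enforce_identifiability: bool = True,
                     seed: int = 0) -> ConsensusReport:
    """Consensus TF-activity changes over many small-subset NCA runs.

    ``E`` is genes x samples; ``design`` (columns sample, condition,
    replicate) maps samples to conditions and biological replicates; each
    replicate's genes x conditions matrix is decomposed separately.
    ``contrast`` maps condition -> weight (e.g. the strain effect of a 2 x 2
    design); for each decomposition, each member TF contributes the weighted
    sum of its activities multiplied by the root-mean-square of its loadings
    on its anchor genes (genes it regulates alone in the full network).  The
    loading-activity product is invariant to the per-TF scale/sign
    indeterminacy, so this statistic is comparable across subsets; it also
    collapses to ~0 for a constant-activity TF that merely absorbs a
    co-regulated changing TF's pattern, because such leak solutions put
    near-zero loadings on the anchor genes.  Signs are aligned per TF by the
    dot product of its anchor-gene loadings with the first decomposition's
    estimate (stable because anchor genes recur in every subset).

    For every identifiable ``subset_size``-subset of TFs (exhaustive when
    there are at most ``max_subsets``, else a seeded random sample), the
    genes regulated exclusively by member TFs are decomposed; genes with any
    regulator outside the subset are excluded because their expression
    violates the subset model and would contaminate the activities.
    Replicate contrasts are averaged per subset; a TF is retained when
    (i) the fraction of its subset-level contrasts sharing the majority
    sign is >= ``consistency_min`` and (ii) its median subset-level
    |contrast| exceeds a seeded permutation null at family-wise level
    ``alpha``.  The null shuffles condition labels once per biological
    replicate per iteration and applies the same shuffle to every subset's
    activities from that replicate: subsets reuse the same replicate data,
    so they are not independent evidence, and replicates are the
    exchangeable units.  The permutation test runs per TF at level ``alpha``
    without a multiplicity correction, because the permutation group is too
    small to reach Bonferroni-corrected levels (with r replicates of c
    conditions the smallest achievable p-value is bounded by the group
    size, e.g. ~1/108 for r=3, c=4).  Family-wise error over the TF panel
    is instead controlled by a third condition, a replicate t-test:
    biological replicates are the independent units, and the per-replicate
    mean contrast must differ from zero at family-wise level ``t_alpha``
    (Bonferroni over the TF panel, r - 1 degrees of freedom).  True
    activity changes give huge t values because the effect is shared by
    every replicate; chance alignments do not.  TFs appearing in no identifiable subset are
    reported unevaluable (retained = False, n_subsets = 0).

    Each gene row is centered across conditions before decomposition, which
    removes any per-gene baseline exactly but costs one rank: with ``c``
    conditions, at most ``c - 1`` TFs are resolvable per decomposition, so
    ``subset_size`` must be at most ``c - 1`` and ``contrast`` weights should
    sum to zero.  With ``enforce_identifiability=False`` larger subsets (up
    to 6) run anyway with a warning, for exploratory comparisons; their
    decompositions are not unique and the report should be read as
    descriptive only.
    """
    if subset_size > design["condition"].nunique() - 1:
        msg = ("subset size exceeds n_conditions - 1 (row-centering absorbs "
               "the per-gene baseline and removes one rank); activities are "
               "not uniquely determined")
        if enforce_identifiability or subset_size > 6:
            raise ValueError(msg)
        warnings.warn(msg)
    tfs = [str(c) for c in Z_full.columns]
    conditions = sorted(design["condition"].unique())
    cvec = np.array([contrast.get(c, 0.0) for c in conditions])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5ca1ab1e]))

    # per-replicate condition matrices
    rep_matrices = {}
    for rep, grp in design.groupby("replicate"):
        cols = grp.set_index("condition")["sample"]
        mat = E[[cols[c] for c in conditions]].set_axis(conditions, axis=1)
        rep_matrices[rep] = mat.sub(mat.mean(axis=1), axis=0)

    # anchor genes: regulated by exactly one TF in the full network; they
    # pass the exclusivity filter of every subset containing their TF
    n_reg_total = (Z_full != 0).sum(axis=1)
    anchors = {tf: Z_full.index[(Z_full[tf] != 0) & (n_reg_total == 1)]
               for tf in tfs}

    # sign-aligned loading-scaled activity vectors per (tf, subset, replicate)
    vectors: dict[str, list[tuple[int, object, np.ndarray]]] = {tf: [] for tf in tfs}
    refs: dict[str, pd.Series] = {}
    act_rows = []
    subset_id = 0
    for subset in _subset_iter(tfs, subset_size, max_subsets, rng):
        Zs = Z_full[list(subset)]
        exclusive = ((Zs != 0).any(axis=1)
                     & ((Zs != 0).sum(axis=1) == n_reg_total))
        genes = Zs.index[exclusive]
        Zs = Zs.loc[genes]
        if not check_identifiability(Zs, len(conditions) - 1, seed=seed).ok:
            if enforce_identifiability:
                continue
        for rep, mat in rep_matrices.items():
            with warnings.catch_warnings():
                # with noise, small subset decompositions routinely use all
                # iterations without meeting the strict tolerance; that is
                # expected here and not a per-subset concern
                warnings.filterwarnings("ignore", message="ALS did not converge")
                dec = decompose(mat.loc[genes], Zs, seed=seed + subset_id + 1,
                                check=False, n_restarts=1, tol=1e-9, max_iter=300)
            for tf in subset:
                anchor = anchors[tf]
                if len(anchor) == 0:  # fall back to all its genes in the subset
                    anchor = genes[Zs[tf] != 0]
                a = dec.A.loc[anchor, tf]
                if tf in refs:
                    common = refs[tf].index.intersection(a.index)
                    s = float(np.sign(refs[tf][common] @ a[common])) or 1.0
                else:
                    refs[tf] = a
                    s = 1.0
                amp = float(np.sqrt(np.mean(a.to_numpy() ** 2)))
                vec = s * amp * dec.P.loc[tf].to_numpy()
                vectors[tf].append((subset_id, rep, vec))
                for ci, cond in enumerate(conditions):
                    act_rows.append({"tf": tf, "subset_id": subset_id, "replicate": rep,
                                     "condition": cond, "activity": float(vec[ci])})
        subset_id += 1

    n_cond = len(conditions)
    rep_levels = sorted({rep for entry in vectors.values() for _, rep, _ in entry},
                        key=str)
    # shared permutations: one label shuffle per replicate per iteration,
    # applied identically to every TF and subset (Westfall-Young max-T)
    idx_rep = rng.permuted(
        np.broadcast_to(np.arange(n_cond),
                        (n_permutations, len(rep_levels), n_cond)).copy(), axis=2)

    stats_by_tf = {}
    for tf in tfs:
        entries = vectors[tf]
        if not entries:
            continue
        sids = np.array([sid for sid, _, _ in entries])
        rep_code = np.array([rep_levels.index(rep) for _, rep, _ in entries])
        av = np.vstack([vec for _, _, vec in entries])  # rows x conditions
        # averaging matrix: subsets x rows, each row weighted 1/(replicates in subset)
        uniq, inv = np.unique(sids, return_inverse=True)
        M = np.zeros((len(uniq), len(sids)))
        M[inv, np.arange(len(sids))] = 1.0
        M /= M.sum(axis=1, keepdims=True)
        subset_vals = M @ (av @ cvec)  # subset-level mean contrast
        idx = idx_rep[:, rep_code, :]  # n_perm x rows x conditions
        permuted = np.take_along_axis(
            np.broadcast_to(av, (n_permutations, *av.shape)), idx, axis=2)
        null = np.median(np.abs((permuted @ cvec) @ M.T), axis=1)
        # replicate-level means of the contrast (independent units)
        row_vals = av @ cvec
        rep_means = np.array([row_vals[rep_code == k].mean()
                              for k in np.unique(rep_code)])
        stats_by_tf[tf] = (subset_vals, len(uniq), null, rep_means)

    n_tfs_eval = max(len(stats_by_tf), 1)
    rows = []
    retained = []
    for tf in tfs:
        if tf not in stats_by_tf:
            rows.append({"tf": tf, "mean_contrast": float("nan"),
                         "sign_consistency": float("nan"), "p_perm": float("nan"),
                         "t_rep": float("nan"), "n_subsets": 0, "retained": False,
                         "unevaluable": True})
            continue
        subset_vals, n_subsets, null, rep_means = stats_by_tf[tf]
        signs = np.sign(subset_vals)
        frac = max((signs > 0).mean(), (signs < 0).mean())
        observed = float(np.median(np.abs(subset_vals)))
        p_perm = (1.0 + np.sum(null >= observed)) / (n_permutations + 1.0)
        r = len(rep_means)
        if r >= 2:
            se = float(np.std(rep_means, ddof=1)) / math.sqrt(r)
            m = float(np.mean(rep_means))
            t_rep = m / se if se > 0 else (math.inf if m != 0 else 0.0)
            t_crit = float(stats.t.ppf(1.0 - t_alpha / (2.0 * n_tfs_eval), r - 1))
            t_ok = abs(t_rep) >= t_crit
        else:  # single replicate: no scatter estimate, skip the t criterion
            t_rep = float("nan")
            t_ok = True
        keep = (frac >= consistency_min) and (p_perm <= alpha) and t_ok
        rows.append({"tf": tf, "mean_contrast": float(np.mean(subset_vals)),
                     "sign_consistency": float(frac), "p_perm": float(p_perm),
                     "t_rep": float(t_rep), "n_subsets": int(n_subsets),
                     "retained": bool(keep), "unevaluable": False})
        if keep:
            retained.append(tf)
    table = pd.DataFrame(rows)
    return ConsensusReport(table, tuple(retained), pd.DataFrame(act_rows))


def activity_ci(per_replicate: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Mean and t-based confidence interval of TF activity across replicates.

    ``per_replicate`` columns: tf, condition, replicate, activity.  With a
    single replicate the CI is undefined (NaN bounds, flagged).
    """
    rows = []
    for (tf, cond), grp in per_replicate.groupby(["tf", "condition"], sort=True):
        vals = grp["activity"].to_numpy(dtype=float)
        n = len(vals)
        mean = float(np.mean(vals))
        if n >= 2:
            se = float(np.std(vals, ddof=1) / math.sqrt(n))
            q = float(stats.t.ppf(0.5 + level / 2.0, n - 1))
            lo, hi = mean - q * se, mean + q * se
            flagged = False
        else:
            lo = hi = float("nan")
            flagged = True
        rows.append({"tf": tf, "condition": cond, "mean": mean,
                     "ci_lo": lo, "ci_hi": hi, "n": n, "single_replicate": flagged})
    return pd.DataFrame(rows)
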