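"""Seeded end-to-end recovery studies against planted ground truth.

Each study generates synthetic data with :mod:`evotol.synth`, runs the
corresponding estimator, and returns summary statistics (recovery error,
false-positive rate, oracle agreement, ...).  The studies back both the
acceptance test suite and the standalone acceptance script, so the numbers
they report are computed from scratch on every run.

All studies are pure functions of an integer seed.
"""

from __future__ import annotations

import math
import re

import numpy as np
import pandas as pd
from scipy import stats

from evotol import epistasis, expression, genotype, growth, nca, qpcr, synth

__all__ = [
    "growth_recovery_study",
    "growth_window_oracle",
    "epistasis_null_study",
    "epistasis_noiseless_study",
    "nca_recovery_study",
    "consensus_case",
    "consensus_study",
    "fdr_null_study",
    "mak2_recovery_study",
    "triage_study",
]


# --- growth ----------------------------------------------------------------------

def growth_window_oracle(curve: growth.GrowthCurve, cfg: growth.GrowthFitConfig,
                         blank: float = 0.0):
    """Exhaustive log-phase window search by direct per-window regression.

    Independent re-implementation of the window-selection rule of
    :func:`evotol.growth.fit_mu_max` using per-window statistics computed
    from sliding views (no rolling-sum shortcuts).  Returns the selected
    (first_index, last_index) window in original-point coordinates, or None
    when no window qualifies.
    """
    y = curve.od600 - blank
    sigma = cfg.noise_sd if cfg.noise_sd is not None else growth._estimate_noise_sd(curve.od600)
    floor = max(cfg.floor, 3.0 * sigma)
    idx = np.nonzero(y > floor)[0]
    if len(idx) < cfg.min_points:
        return None
    t = curve.time_h[idx]
    ln_y = np.log(y[idx])
    w = 1.0 / (y[idx] ** 2)
    n = len(t)
    candidates = []  # (score, L, start)
    from numpy.lib.stride_tricks import sliding_window_view as swv
    for L in range(cfg.min_points, n + 1):
        T, Y, W = swv(t, L), swv(ln_y, L), swv(w, L)
        tbar = T.mean(axis=1)
        ybar = Y.mean(axis=1)
        dt = T - tbar[:, None]
        sxx = (dt * dt).sum(axis=1)
        sxy = (dt * (Y - ybar[:, None])).sum(axis=1)
        syy = ((Y - ybar[:, None]) ** 2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = sxy / sxx
            r2 = np.where(syy > 0, 1.0 - np.maximum(syy - sxy ** 2 / sxx, 0.0) / syy, 1.0)
            var_unit = ((dt / sxx[:, None]) ** 2 * W).sum(axis=1)
        se = sigma * np.sqrt(np.maximum(var_unit, 0.0))
        span = T[:, -1] - T[:, 0]
        ok = (r2 >= cfg.r2_min) & (slope * span >= cfg.min_ln_range)
        if cfg.selection == "lcb":
            score = slope - cfg.z * se
        else:
            score = slope
        for s in np.nonzero(ok)[0]:
            candidates.append((float(score[s]), L, int(s)))
    if not candidates:
        return None
    top = max(c[0] for c in candidates)
    near = [c for c in candidates if c[0] >= top - 1e-15]
    _, L, s = max(near, key=lambda c: (c[1], -c[2]))
    return (int(idx[s]), int(idx[s + L - 1]))


def growth_recovery_study(seed: int = 0, n_wells: int = 100,
                          noise_sd: float = 0.002) -> dict:
    """Recovery of planted mu_max on a noisy synthetic plate.

    Plants ``n_wells`` three-phase curves (289 points each) with mu uniform
    in [0.2, 0.8] and additive OD noise ``noise_sd``, fits every well, and
    compares against the planted rates and the exhaustive window oracle.
    Returns mean/max relative |error| and the fraction of wells whose
    selected window equals the oracle's.
    """
    rng = synth.substream(seed, "growth_study")
    truth = pd.DataFrame({
        "well": [f"W{i:03d}" for i in range(n_wells)],
        "mu": rng.uniform(0.2, 0.8, n_wells),
        "lag_h": rng.uniform(1.0, 4.0, n_wells),
        "od0": rng.uniform(0.003, 0.01, n_wells),
        "capacity": rng.uniform(1.0, 1.4, n_wells),
    })
    plate, plate_map = synth.gen_growth_plate(
        truth, synth.SimConfig(seed=seed, noise_sd=noise_sd))
    cfg = growth.GrowthFitConfig(noise_sd=noise_sd)
    blank_wells = set(plate_map.loc[plate_map["blank"], "well"])
    blank = float(plate.loc[plate["well"].isin(blank_wells), "od600"].median())
    errs = []
    agree = 0
    for rec in truth.itertuples(index=False):
        grp = plate[plate["well"] == rec.well]
        curve = growth.GrowthCurve(rec.well, grp["time_h"].to_numpy(),
                                   grp["od600"].to_numpy())
        fit = growth.fit_mu_max(curve, cfg, blank=blank)
        errs.append(abs(fit.mu_max - rec.mu) / rec.mu)
        if fit.window == growth_window_oracle(curve, cfg, blank=blank):
            agree += 1
    errs = np.asarray(errs)
    return {"mean_rel_error": float(errs.mean()),
            "max_rel_error": float(errs.max()),
            "oracle_agreement": agree / n_wells,
            "n_wells": n_wells}


# --- epistasis -------------------------------------------------------------------

def epistasis_null_study(seed: int = 0, n_landscapes: int = 1000, K: int = 5,
                         noise_sd: float = 0.05) -> dict:
    """95%-CI false-positive rate on multiplicative-null fitness landscapes.

    Generates ``n_landscapes`` K-mutation landscapes with lognormal noise
    and no planted epistasis, scans every non-singleton subset, and reports
    the fraction flagged significant (nominally 5%).
    """
    rng = synth.substream(seed, "epistasis_null")
    n_sig = 0
    n_tests = 0
    for i in range(n_landscapes):
        singles = {f"m{j}": float(rng.uniform(0.7, 1.3)) for j in range(K)}
        table, _ = synth.gen_fitness_landscape(
            singles, None, synth.SimConfig(seed=int(rng.integers(2**31)),
                                           noise_sd=noise_sd))
        scan = epistasis.landscape_scan(table)
        n_sig += int(scan["significant"].sum())
        n_tests += len(scan)
    return {"fp_rate": n_sig / n_tests, "n_tests": n_tests}


def epistasis_noiseless_study(seed: int = 0) -> dict:
    """Exactness of epsilon recovery on a noiseless planted landscape."""
    singles = {"a": 1.10, "b": 0.90, "c": 1.05, "d": 1.20}
    planted = {("a", "b"): 1.5, ("a", "b", "c"): 0.8, ("c", "d"): 1.25}
    table, truth = synth.gen_fitness_landscape(singles, planted,
                                               synth.SimConfig(seed=seed, noise_sd=0.0))
    scan = epistasis.landscape_scan(table).set_index("subset")
    truth = truth.set_index("subset")
    err = 0.0
    for subset, row in scan.iterrows():
        err = max(err, abs(row["epsilon"] - truth.loc[subset, "eps"]))
    return {"max_eps_error": float(err), "n_subsets": len(scan)}


# --- NCA -------------------------------------------------------------------------

def _tf_correlations(P_est: pd.DataFrame, P_true: pd.DataFrame) -> np.ndarray:
    """Per-TF |correlation| between estimated and planted activities."""
    rs = []
    for tf in P_true.index:
        a = P_est.loc[tf].to_numpy(dtype=float)
        b = P_true.loc[tf].to_numpy(dtype=float)
        rs.append(abs(float(np.corrcoef(a, b)[0, 1])))
    return np.asarray(rs)


def nca_recovery_study(seed: int = 0, n_instances: int = 5, n_genes: int = 200,
                       noise_frac: float = 0.0) -> dict:
    """Activity recovery of constrained ALS on identifiable instances.

    Generates ``n_instances`` identifiable ``n_genes`` x 4-TF connectivities
    with planted activities over 4 conditions, adds Gaussian noise of SD
    ``noise_frac`` times the expression SD, decomposes, and reports the
    worst per-TF |correlation| with the planted activities (scale/sign
    invariant).
    """
    rng = synth.substream(seed, "nca_recovery")
    tfs = ["TF1", "TF2", "TF3", "TF4"]
    worst = 1.0
    for i in range(n_instances):
        s = int(rng.integers(2**31))
        Z = synth.sample_connectivity(n_genes, tfs, seed=s, identifiable=True,
                                      n_conditions=4)
        r2 = np.random.default_rng(s + 1)
        A = np.where(Z.to_numpy() != 0,
                     r2.uniform(0.5, 1.5, Z.shape) * r2.choice([-1.0, 1.0], Z.shape), 0.0)
        P = pd.DataFrame(r2.standard_normal((4, 4)), index=tfs,
                         columns=[f"c{j}" for j in range(4)])
        E = pd.DataFrame(A @ P.to_numpy(), index=Z.index, columns=P.columns)
        if noise_frac > 0:
            E = E + noise_frac * float(E.to_numpy().std()) * r2.standard_normal(E.shape)
        dec = nca.decompose(E, Z, seed=s)
        worst = min(worst, float(_tf_correlations(dec.P, P).min()))
    return {"min_abs_corr": worst, "n_instances": n_instances}


def consensus_case(seed: int, planted: bool, *, n_genes: int = 320,
                   n_tfs: int = 16, n_changing: int = 4, delta: float = 1.0,
                   noise_sd: float = 0.05):
    """One synthetic consensus instance: 16 TFs, 2x2 design, 3 replicates.

    Four planted TFs (the first ``n_changing``) differ in activity between
    the two strains by ``delta``; the rest are constant across conditions.
    With ``planted=False`` all TFs are constant (null data).  Returns
    (E, Z, design, contrast, changing_tfs).
    """
    tfs = [f"TF{i:02d}" for i in range(n_tfs)]
    Z = synth.sample_connectivity(n_genes, tfs, seed=seed)
    rng = synth.substream(seed, "consensus_case")
    A = np.where(Z.to_numpy() != 0,
                 rng.uniform(0.5, 1.5, Z.shape) * rng.choice([-1.0, 1.0], Z.shape), 0.0)
    conditions = ["mut_ctl", "mut_trt", "ref_ctl", "ref_trt"]
    P = np.tile(rng.uniform(-1.0, 1.0, (n_tfs, 1)), (1, 4))  # constant activities
    changing = tuple(tfs[:n_changing]) if planted else ()
    if planted:
        for i in range(n_changing):
            P[i, :2] += delta / 2.0   # mut conditions up
            P[i, 2:] -= delta / 2.0   # ref conditions down
    baseline = rng.uniform(6.0, 10.0, n_genes)
    rows, cols = [], {}
    design_rows = []
    for cond_i, cond in enumerate(conditions):
        for rep in (1, 2, 3):
            sample = f"{cond}_rep{rep}"
            cols[sample] = (baseline + A @ P[:, cond_i]
                            + rng.normal(0.0, noise_sd, n_genes))
            design_rows.append({"sample": sample, "condition": cond, "replicate": rep})
    E = pd.DataFrame(cols, index=Z.index)
    design = pd.DataFrame(design_rows)
    contrast = {"mut_ctl": 0.5, "mut_trt": 0.5, "ref_ctl": -0.5, "ref_trt": -0.5}
    return E, Z, design, contrast, changing


def consensus_study(seed: int = 0, n_runs: int = 50, planted: bool = True,
                    n_permutations: int = 499) -> dict:
    """Fraction of consensus runs with exactly the right retained set.

    With ``planted=True``: fraction of runs retaining exactly the 4 planted
    changing TFs.  With ``planted=False``: fraction of runs retaining
    nothing on null data.
    """
    rng = synth.substream(seed, "consensus_study")
    hits = 0
    for i in range(n_runs):
        s = int(rng.integers(2**31))
        E, Z, design, contrast, changing = consensus_case(s, planted)
        rep = nca.subset_consensus(E, Z, design, contrast, seed=s,
                                   n_permutations=n_permutations)
        if tuple(sorted(rep.retained)) == tuple(sorted(changing)):
            hits += 1
    return {"exact_fraction": hits / n_runs, "n_runs": n_runs}


# --- expression ------------------------------------------------------------------

def fdr_null_study(seed: int = 0, n_runs: int = 200, n_genes: int = 2000,
                   q: float = 0.05) -> dict:
    """Empirical FDR of the moderated-t + BH pipeline on complete-null data.

    Each run draws a 2000-gene x 12-sample null matrix (2 strains x 2
    treatments x 3 replicates), tests the interaction contrast, and counts
    discoveries at BH level ``q``.  Under a complete null the false
    discovery proportion is 1 whenever anything is discovered, so the
    empirical FDR is the fraction of runs with at least one discovery.
    """
    design = pd.DataFrame(
        [{"sample": f"{st}_{tr}_{r}", "strain": st, "treated": tr == "t"}
         for st in ("mut", "ref") for tr in ("t", "u") for r in (1, 2, 3)])
    rng = synth.substream(seed, "fdr_null")
    false_runs = 0
    for i in range(n_runs):
        vals = rng.normal(0.0, 1.0, (n_genes, 12))
        mat = pd.DataFrame(vals, index=[f"g{j}" for j in range(n_genes)],
                           columns=design["sample"])
        res = expression.moderated_t_test(mat, design, "interaction", fdr_cutoff=q)
        if res["significant"].any():
            false_runs += 1
    return {"empirical_fdr": false_runs / n_runs, "n_runs": n_runs}


# --- qPCR ------------------------------------------------------------------------

def mak2_recovery_study(seed: int = 0) -> dict:
    """Noiseless MAK2 parameter recovery and the one-cycle recurrence value."""
    d0, k = 1e-6, 2.0
    f = qpcr.mak2_forward(d0, k, 45)
    curve = qpcr.AmplificationCurve("w1", np.arange(1, 46), f)
    fit = qpcr.fit_mak2(curve)
    f1 = qpcr.mak2_forward(1.0, 1.0, 1)[0]
    return {"d0_rel_error": abs(fit.d0 - d0) / d0,
            "k_rel_error": abs(fit.k - k) / k,
            "f1_error": abs(f1 - (1.0 + math.log(2.0)))}


# --- variant triage --------------------------------------------------------------

def triage_study(seed: int = 0) -> dict:
    """Exact separation of planted variants, gap detection, homopolymer oracle."""
    gap = (1_000_000, 1_009_900)  # 9,900 bp planted deletion
    cands, truth_coords, coverage, reads = synth.gen_variant_candidates(
        n_true_snps=6, n_decoy_snps=6, n_true_indels=4, n_decoy_indels=4,
        cfg=synth.SimConfig(seed=seed), gap_intervals=[gap],
        n_reads=40, n_homopolymer_reads=12)
    kept = genotype.filter_variants(cands)
    separation = set(kept["coordinate"]) == truth_coords
    track = genotype.CoverageTrack(coverage, 4_600_000)
    gaps = genotype.detect_coverage_gaps(track, min_length=1000)
    gap_exact = gaps == [gap]
    oracle = [(rid, s) for rid, s in reads if not re.search(r"(.)\1{10,}", s)]
    homopolymer_match = genotype.homopolymer_filter(reads, max_run=10) == oracle
    return {"separation_exact": bool(separation),
            "gap_exact": bool(gap_exact),
            "gap_length": int(gaps[0][1] - gaps[0][0]) if gaps else 0,
            "homopolymer_match": bool(homopolymer_match),
            "n_candidates": len(cands)}
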