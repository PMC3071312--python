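"""Synthetic-data generators with planted ground truth.

Every pipeline input can be generated here with the statistical structure the
downstream analyses assume, so each estimator is testable against a known
truth without external data:

- microplate OD600 time courses (48 h at 10-minute intervals, three-phase
  lag / exponential / logistic-saturation curves, additive Gaussian noise);
- fitness landscapes over mutation subsets with a multiplicative null and
  planted epistasis, multiplicative lognormal noise;
- spot-level microarray intensity tables generated as loadings x planted TF
  activities through a sparse gene-TF connectivity;
- per-generation allele states with staggered fixation;
- MAK2 forward qPCR amplification curves;
- resequencing variant-candidate tables with planted true/decoy variants,
  coverage tracks with planted gaps, and reads with planted homopolymer runs.

All generators are pure functions of their parameters and an integer seed;
the seed is split into independent substreams by fixed string labels.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from evotol.qpcr import mak2_forward

__all__ = [
    "SimConfig",
    "substream",
    "three_phase_od",
    "gen_growth_plate",
    "gen_fitness_landscape",
    "sample_connectivity",
    "gen_expression_dataset",
    "gen_allele_trajectories",
    "gen_amplification_curves",
    "gen_variant_candidates",
]


@dataclass(frozen=True)
class SimConfig:
    """Common simulation settings: one global seed plus a per-generator noise SD.

    ``noise_sd`` is interpreted in the units of each generator (absolute OD
    for growth plates, SD of log fitness for landscapes, SD on the log
    expression scale for arrays, fluorescence units for qPCR).
    """

    seed: int = 0
    noise_sd: float = 0.0
    n_bio_replicates: int = 3
    n_tech_replicates: int = 6


def substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-generator random substream of a global integer seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


# --- growth plates ---------------------------------------------------------------

def three_phase_od(t: np.ndarray, mu: float, lag_h: float, od0: float,
                   capacity: float) -> np.ndarray:
    """Noiseless three-phase growth curve.

    Flat at ``od0`` until ``lag_h``; exact exponential at rate ``mu`` until
    half capacity; logistic saturation thereafter, C1-continuous at the
    switch.  The exact exponential segment gives an exact in-window ln-slope
    for testing the regression-based mu_max estimator.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if capacity <= od0:
        raise ValueError("capacity must exceed the inoculum OD")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    x_switch = capacity / 2.0
    t_switch = lag_h + np.log(x_switch / od0) / mu
    od = np.where(t <= lag_h, od0, od0 * np.exp(mu * np.clip(t - lag_h, 0, None)))
    r = mu / (1.0 - x_switch / capacity)  # logistic rate matching slope at switch
    c = (capacity - x_switch) / x_switch
    logistic = capacity / (1.0 + c * np.exp(-r * (t - t_switch)))
    return np.where(t <= t_switch, od, logistic)


def gen_growth_plate(truth: pd.DataFrame, cfg: SimConfig = SimConfig(), *,
                     duration_h: float = 48.0, interval_min: float = 10.0,
                     blank_value: float = 0.05, n_blank_wells: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a plate of growth curves from planted per-well parameters.

    ``truth`` columns: well, mu (h^-1, > 0), lag_h, od0, capacity.  Returns
    (plate, plate_map): ``plate`` is long-format (well, time_h, od600) with
    289 time points per well for the default 48 h / 10-minute design,
    including ``n_blank_wells`` blank wells; ``od600`` = curve + blank offset
    + additive Gaussian noise.  ``plate_map`` marks blank wells and carries
    strain/condition annotations if present in ``truth``.
    """
    if (truth["mu"] <= 0).any():
        raise ValueError("all planted mu must be positive")
    if (truth["capacity"] <= truth["od0"]).any():
        raise ValueError("capacity must exceed inoculum OD")
    rng = substream(cfg.seed, "growth_plate")
    t = np.arange(0.0, duration_h + 1e-9, interval_min / 60.0)
    rows = []
    map_rows = []
    for rec in truth.itertuples(index=False):
        od = three_phase_od(t, rec.mu, rec.lag_h, rec.od0, rec.capacity)
        noisy = od + blank_value + rng.normal(0.0, cfg.noise_sd, size=od.shape)
        rows.append(pd.DataFrame({"well": rec.well, "time_h": t, "od600": noisy}))
        map_rows.append({"well": rec.well,
                         "strain": getattr(rec, "strain", ""),
                         "condition": getattr(rec, "condition", ""),
                         "blank": False})
    for i in range(n_blank_wells):
        well = f"BLANK{i + 1}"
        noisy = blank_value + rng.normal(0.0, cfg.noise_sd, size=t.shape)
        rows.append(pd.DataFrame({"well": well, "time_h": t, "od600": noisy}))
        map_rows.append({"well": well, "strain": "", "condition": "", "blank": True})
    return pd.concat(rows, ignore_index=True), pd.DataFrame(map_rows)


# --- fitness landscapes ----------------------------------------------------------

def _canonical(subset) -> tuple[str, ...]:
    return tuple(sorted(set(map(str, subset))))


def gen_fitness_landscape(singles: dict[str, float],
                          planted_eps: dict | None = None,
                          cfg: SimConfig = SimConfig(), *,
                          n_replicates: int = 1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate relative-fitness measurements for all nonempty mutation subsets.

    The fitness of subset S is ``eps_S * prod_{i in S} w_i`` perturbed by
    multiplicative lognormal noise with log-SD ``cfg.noise_sd``.  Unlisted
    subsets have eps = 1 (the multiplicative null).  With ``n_replicates=1``
    the reported SE is the analytic delta-method value ``w * noise_sd``;
    with more replicates the sample mean and SE over replicates are
    reported and per-replicate values are included as columns rep1..repN.

    Returns (table, truth): table columns subset (semicolon-joined), w, se
    [, rep columns]; truth columns subset, w_true, eps.
    """
    K = len(singles)
    if K > 12:
        raise ValueError("landscapes above K=12 mutations are not supported")
    if any(w <= 0 for w in singles.values()):
        raise ValueError("all single-mutant fitness values must be positive")
    planted = { _canonical(k): float(v) for k, v in (planted_eps or {}).items() }
    if any(e <= 0 for e in planted.values()):
        raise ValueError("planted epsilon values must be positive")
    rng = substream(cfg.seed, "fitness_landscape")
    labels = sorted(singles)
    rows, truth_rows = [], []
    for r in range(1, K + 1):
        for combo in itertools.combinations(labels, r):
            subset = _canonical(combo)
            eps = planted.get(subset, 1.0) if len(subset) > 1 else 1.0
            w_true = eps * float(np.prod([singles[m] for m in subset]))
            reps = w_true * np.exp(rng.normal(0.0, cfg.noise_sd, size=n_replicates))
            row = {"subset": ";".join(subset)}
            if n_replicates == 1:
                row["w"] = float(reps[0])
                row["se"] = float(reps[0] * cfg.noise_sd)
            else:
                row["w"] = float(np.mean(reps))
                row["se"] = float(np.std(reps, ddof=1) / np.sqrt(n_replicates))
                for j, v in enumerate(reps, 1):
                    row[f"rep{j}"] = float(v)
            rows.append(row)
            truth_rows.append({"subset": ";".join(subset), "w_true": w_true, "eps": eps})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# --- expression datasets ---------------------------------------------------------

def _regulator_count_pmf(max_reg: int = 5, mean_reg: float = 1.5) -> np.ndarray:
    """Truncated-geometric pmf on {1..max_reg} with the requested mean."""
    from scipy.optimize import brentq

    ks = np.arange(1, max_reg + 1)

    def mean_of(q):
        w = q ** (ks - 1)
        return float((ks * w).sum() / w.sum())

    if abs(mean_of(1e-12) - mean_reg) < 1e-9:
        q = 1e-12
    else:
        q = brentq(lambda q: mean_of(q) - mean_reg, 1e-12, 0.999999)
    w = q ** (ks - 1)
    return w / w.sum()


def sample_connectivity(n_genes: int, tf_labels: list[str], seed: int = 0, *,
                        max_reg: int = 5, mean_reg: float = 1.5,
                        identifiable: bool = False, n_conditions: int | None = None,
                        max_tries: int = 200) -> pd.DataFrame:
    """Sample a sparse binary gene x TF connectivity matrix.

    Per-gene regulator counts follow a truncated geometric distribution on
    {1..max_reg} with the requested mean (default 1.5).  With
    ``identifiable=True``, draws are rejected until the matrix passes the
    network-component-analysis identifiability criteria for
    ``n_conditions`` conditions (see :func:`evotol.nca.check_identifiability`).
    """
    from evotol import nca as _nca

    rng = substream(seed, "connectivity")
    pmf = _regulator_count_pmf(max_reg, mean_reg)
    n_tfs = len(tf_labels)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    for _ in range(max_tries):
        Z = np.zeros((n_genes, n_tfs), dtype=int)
        counts = rng.choice(np.arange(1, max_reg + 1), size=n_genes, p=pmf)
        for g, c in enumerate(counts):
            Z[g, rng.choice(n_tfs, size=min(c, n_tfs), replace=False)] = 1
        zdf = pd.DataFrame(Z, index=genes, columns=tf_labels)
        if (zdf.sum(axis=0) == 0).any():
            continue
        if not identifiable:
            return zdf
        report = _nca.check_identifiability(zdf, n_conditions or n_tfs)
        if report.ok:
            return zdf
    raise RuntimeError("failed to sample an identifiable connectivity matrix")


def gen_expression_dataset(Z: pd.DataFrame, P: pd.DataFrame,
                           cfg: SimConfig = SimConfig(), *,
                           background_mean: float = 2.0, background_sd: float = 0.0,
                           loading_low: float = 0.5, loading_high: float = 1.5,
                           baseline: float = 8.0) -> tuple[pd.DataFrame, dict]:
    """Generate a spot-level intensity table from planted TF activities.

    ``Z`` is binary genes x TFs; ``P`` is TFs x conditions (planted
    activities).  Loadings A are drawn with support exactly on Z's nonzeros,
    uniform magnitude in [loading_low, loading_high] with random sign.  The
    log-scale expression is ``E = baseline + A @ P`` plus per-(gene, sample)
    Gaussian noise of SD ``cfg.noise_sd``; each gene has one probe expanded
    to ``cfg.n_bio_replicates`` biological replicates per condition and
    ``cfg.n_tech_replicates`` technical spots per array, each spot carrying a
    background offset so foreground = expression + background.

    Returns (spots, truth): spots columns spot, probe, sample, fg, bg; truth
    holds A, P, the sample sheet and the noiseless gene-level matrix.
    """
    if (Z.sum(axis=1) == 0).any():
        raise ValueError("connectivity has an all-zero gene row")
    if list(Z.columns) != list(P.index):
        raise ValueError("Z columns and P rows must list the same TFs in order")
    rng = substream(cfg.seed, "expression")
    genes = list(Z.index)
    conditions = list(P.columns)
    A = rng.uniform(loading_low, loading_high, size=Z.shape) * rng.choice([-1.0, 1.0], size=Z.shape)
    A = A * Z.to_numpy()
    E0 = baseline + A @ P.to_numpy()  # genes x conditions, noiseless
    sample_rows = []
    spot_rows = []
    spot_id = 0
    for ci, cond in enumerate(conditions):
        for b in range(1, cfg.n_bio_replicates + 1):
            sample = f"{cond}_rep{b}"
            sample_rows.append({"sample": sample, "condition": cond, "replicate": b})
            expr = E0[:, ci] + rng.normal(0.0, cfg.noise_sd, size=len(genes))
            for gi, gene in enumerate(genes):
                bg = background_mean + (rng.normal(0.0, background_sd, size=cfg.n_tech_replicates)
                                        if background_sd > 0 else np.zeros(cfg.n_tech_replicates))
                for tr in range(cfg.n_tech_replicates):
                    spot_rows.append((f"s{spot_id:07d}", f"{gene}_p1", sample,
                                      expr[gi] + bg[tr], bg[tr]))
                    spot_id += 1
    spots = pd.DataFrame(spot_rows, columns=["spot", "probe", "sample", "fg", "bg"])
    truth = {
        "A": pd.DataFrame(A, index=genes, columns=Z.columns),
        "P": P.copy(),
        "samples": pd.DataFrame(sample_rows),
        "E": pd.DataFrame(E0, index=genes, columns=conditions),
        "baseline": baseline,
    }
    return spots, truth


# --- allele trajectories ---------------------------------------------------------

def gen_allele_trajectories(loci: pd.DataFrame, sampled_generations) -> pd.DataFrame:
    """Per-generation allele states for loci sweeping to fixation.

    ``loci`` columns: locus, fixation_generation, sweep_width (generations).
    A locus is WT before ``fixation_generation - sweep_width``, Mixed from
    there until fixation, and Mut from ``fixation_generation`` on, evaluated
    at exactly the sampled generations (which must be increasing).
    """
    gens = np.asarray(list(sampled_generations))
    if np.any(np.diff(gens) <= 0):
        raise ValueError("sampled generations must be increasing")
    rows = []
    for rec in loci.itertuples(index=False):
        start = rec.fixation_generation - rec.sweep_width
        for g in gens:
            if g >= rec.fixation_generation:
                state = "Mut"
            elif g >= start:
                state = "Mixed"
            else:
                state = "WT"
            rows.append({"locus": rec.locus, "generation": int(g), "state": state})
    return pd.DataFrame(rows)


# --- qPCR curves -----------------------------------------------------------------

def gen_amplification_curves(true_params: pd.DataFrame, cfg: SimConfig = SimConfig(), *,
                             n_cycles: int = 45) -> pd.DataFrame:
    """Forward-MAK2 amplification curves with plateau clamp and additive noise.

    ``true_params`` columns: well, d0 (>= 0), k (> 0), plateau.  Returns a
    long table (well, cycle, fluorescence).
    """
    if (true_params["k"] <= 0).any():
        raise ValueError("all k must be positive")
    if (true_params["d0"] < 0).any():
        raise ValueError("d0 must be nonnegative")
    rng = substream(cfg.seed, "qpcr")
    rows = []
    for rec in true_params.itertuples(index=False):
        f = np.minimum(mak2_forward(rec.d0, rec.k, n_cycles), rec.plateau)
        f = f + rng.normal(0.0, cfg.noise_sd, size=f.shape)
        rows.append(pd.DataFrame({"well": rec.well,
                                  "cycle": np.arange(1, n_cycles + 1), "fluorescence": f}))
    return pd.concat(rows, ignore_index=True)


# --- variant candidates / coverage / reads ---------------------------------------

_BASES = np.array(list("ACGT"))


def gen_variant_candidates(n_true_snps: int = 5, n_decoy_snps: int = 5,
                           n_true_indels: int = 0, n_decoy_indels: int = 0,
                           cfg: SimConfig = SimConfig(), *,
                           genome_length: int = 4_600_000,
                           gap_intervals: list[tuple[int, int]] | None = None,
                           uniform_depth: int = 100,
                           n_reads: int = 10, n_homopolymer_reads: int = 3,
                           read_length: int = 36, homopolymer_run: int = 15,
                           snp_quality_min: int = 150, indel_freq_min: float = 0.4):
    """Planted variant candidates, a coverage track, and reads.

    True variants get quality/frequency at or above the triage thresholds,
    decoys strictly below.  The coverage track is uniform at
    ``uniform_depth`` except for the planted zero-coverage ``gap_intervals``
    (0-based half-open; must not overlap).  Reads are random sequences of
    ``read_length`` bases; ``n_homopolymer_reads`` of them carry a planted
    single-base run of ``homopolymer_run`` bases.

    Returns (candidates, truth_coordinates, coverage, reads): candidates is
    a DataFrame (coordinate, class, quality, frequency, is_true only in the
    returned truth set), coverage a bedGraph-like DataFrame (seq, start,
    end, depth), reads a list of (read_id, sequence).
    """
    gaps = sorted(gap_intervals or [])
    for (s1, e1), (s2, e2) in zip(gaps, gaps[1:]):
        if e1 > s2:
            raise ValueError("planted deletion intervals must not overlap")
    for s, e in gaps:
        if not (0 <= s < e <= genome_length):
            raise ValueError("gap interval outside the genome")
    rng = substream(cfg.seed, "variants")

    n_total = n_true_snps + n_decoy_snps + n_true_indels + n_decoy_indels
    coords = rng.choice(genome_length - 1, size=n_total, replace=False) + 1  # 1-based
    rows = []
    i = 0
    for _ in range(n_true_snps):
        rows.append({"coordinate": int(coords[i]), "class": "SNP",
                     "quality": int(rng.integers(snp_quality_min, 256)),
                     "frequency": float(rng.uniform(0.8, 1.0)), "is_true": True}); i += 1
    for _ in range(n_decoy_snps):
        rows.append({"coordinate": int(coords[i]), "class": "SNP",
                     "quality": int(rng.integers(10, snp_quality_min)),
                     "frequency": float(rng.uniform(0.05, 1.0)), "is_true": False}); i += 1
    for _ in range(n_true_indels):
        rows.append({"coordinate": int(coords[i]), "class": "indel",
                     "quality": int(rng.integers(30, 256)),
                     "frequency": float(rng.uniform(indel_freq_min, 1.0)), "is_true": True}); i += 1
    for _ in range(n_decoy_indels):
        rows.append({"coordinate": int(coords[i]), "class": "indel",
                     "quality": int(rng.integers(30, 256)),
                     "frequency": float(rng.uniform(0.02, indel_freq_min - 0.01)),
                     "is_true": False}); i += 1
    candidates = pd.DataFrame(rows).sort_values("coordinate").reset_index(drop=True)
    truth_coords = set(candidates.loc[candidates["is_true"], "coordinate"])

    cov_rows = []
    pos = 0
    for s, e in gaps:
        if pos < s:
            cov_rows.append(("chr", pos, s, uniform_depth))
        cov_rows.append(("chr", s, e, 0))
        pos = e
    if pos < genome_length:
        cov_rows.append(("chr", pos, genome_length, uniform_depth))
    coverage = pd.DataFrame(cov_rows, columns=["seq", "start", "end", "depth"])

    reads = []
    for j in range(n_reads):
        seq = "".join(rng.choice(_BASES, size=read_length))
        if j < n_homopolymer_reads:
            base = str(rng.choice(_BASES))
            run = base * homopolymer_run
            start = int(rng.integers(0, read_length - homopolymer_run + 1))
            seq = seq[:start] + run + seq[start + homopolymer_run:]
        reads.append((f"read{j:03d}", seq))

    return candidates.drop(columns="is_true"), truth_coords, coverage, reads
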