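"""Mutation catalogs, parallel evolution, allele trajectories, and resequencing triage.

Covers the bookkeeping half of a resequencing study: loading mutation
catalogs (clone x locus tables), tallying parallel genotypic adaptation
across independently evolved populations, ordering mutations by their first
detected generation, and the bespoke triage filters applied to raw variant
candidates -- quality/frequency cutoffs, coverage-gap detection for large
deletions, and homopolymer filtering of unmapped reads.

Coordinate conventions: mutation catalogs are 1-based (as printed in the
source tables); coverage intervals are 0-based half-open (bedGraph).
Converters :func:`to_zero_based` / :func:`to_one_based` translate.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MutationRecord",
    "GenotypeCall",
    "VariantCandidate",
    "CoverageTrack",
    "MUTATION_CLASSES",
    "GENOTYPE_STATES",
    "load_mutation_table",
    "load_table1",
    "load_table2",
    "load_class_totals",
    "load_x3_trajectory",
    "count_mutations",
    "total_mutations",
    "parallel_evolution_tally",
    "allele_frequency",
    "mutation_order",
    "trajectory_join",
    "filter_variants",
    "detect_coverage_gaps",
    "homopolymer_filter",
    "to_zero_based",
    "to_one_based",
]

MUTATION_CLASSES = ("SNP", "short-indel", "SV")
GENOTYPE_STATES = ("WT", "Mut", "Mixed", "NT")

# Sanger-verification preset (candidates with consensus quality > 200);
# the default discard thresholds (150 / 0.4) follow the catalog's own rule.
TRIAGE_DEFAULT = {"snp_quality_min": 150, "indel_freq_min": 0.4}
TRIAGE_VERIFICATION = {"snp_quality_min": 201, "indel_freq_min": 0.4}


@dataclass(frozen=True)
class MutationRecord:
    carrier: str
    gene: str
    coordinate: int | None
    mutation_class: str
    nt_change: str
    protein_change: str
    allele_frequency: float | None = None

    def __post_init__(self):
        if self.mutation_class not in MUTATION_CLASSES:
            raise ValueError(f"unknown mutation class {self.mutation_class!r}")
        if self.coordinate is not None and self.coordinate < 1:
            raise ValueError("coordinates are 1-based (>= 1)")


@dataclass(frozen=True)
class GenotypeCall:
    locus: str
    generation: int
    state: str

    def __post_init__(self):
        if self.state not in GENOTYPE_STATES:
            raise ValueError(f"unknown genotype state {self.state!r}")


@dataclass(frozen=True)
class VariantCandidate:
    coordinate: int
    variant_class: str  # SNP | indel
    quality: int
    frequency: float

    def __post_init__(self):
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must be in [0, 1]")
        if self.quality < 0:
            raise ValueError("quality must be nonnegative")


@dataclass(frozen=True)
class CoverageTrack:
    """Sorted, non-overlapping 0-based half-open intervals covering a genome."""

    intervals: pd.DataFrame  # columns: seq, start, end, depth
    genome_length: int

    def __post_init__(self):
        df = self.intervals
        if list(df.columns[:4]) != ["seq", "start", "end", "depth"]:
            raise ValueError("coverage track needs columns seq, start, end, depth")
        if (df["end"] <= df["start"]).any():
            raise ValueError("intervals must have positive length")
        starts, ends = df["start"].to_numpy(), df["end"].to_numpy()
        if np.any(starts[1:] != ends[:-1]) or starts[0] != 0 or ends[-1] != self.genome_length:
            raise ValueError("intervals must tile the genome contiguously")


# --- fixture loading -------------------------------------------------------------

def load_mutation_table(path) -> list[MutationRecord]:
    """Load a mutation-catalog TSV into records.

    Expected columns: carrier, gene, coordinate, class, nt_change,
    protein_change [, allele_frequency].  Lines starting with ``#`` are
    comments.  An unknown class token is a hard error naming the row.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"carrier", "gene", "coordinate", "class", "nt_change", "protein_change"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    df = df.rename(columns={"class": "mutation_class"})
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        cls = row.mutation_class
        if cls not in MUTATION_CLASSES:
            raise ValueError(f"row {lineno}: unknown mutation class {cls!r}")
        coord = row.coordinate
        coord = int(coord) if coord not in (None, "", "-") and not pd.isna(coord) else None
        freq = getattr(row, "allele_frequency", None)
        freq = float(freq) if freq not in (None, "", "-") and not pd.isna(freq) else None
        records.append(MutationRecord(row.carrier, row.gene, coord, cls,
                                      row.nt_change, row.protein_change, freq))
    return records


def _fixture(name: str):
    return importlib.resources.files("evotol.data").joinpath(name)


def load_table1() -> list[MutationRecord]:
    """Packaged transcription of the clone resequencing mutation catalog."""
    return load_mutation_table(_fixture("table1_mutations.tsv"))


def load_table2() -> pd.DataFrame:
    """Packaged transcription of the endpoint-population parallel-evolution table.

    One row per (population, gene) mutation; columns population, gene,
    coordinate, change.
    """
    return pd.read_csv(_fixture("table2_parallel.tsv"), sep="\t", comment="#")


def load_class_totals() -> pd.DataFrame:
    """Packaged totals of discovered mutations by class across all sequenced clones."""
    return pd.read_csv(_fixture("mutation_class_totals.tsv"), sep="\t", comment="#")


def load_x3_trajectory() -> pd.DataFrame:
    """Packaged allele-state trajectory of the X3 lineage (locus, generation, state).

    Only the generations 180 and 266 are anchored by published observations; the
    remaining first-detection generations are synthetic placeholders that
    encode ordinal structure only (see the fixture's header comment).
    """
    return pd.read_csv(_fixture("x3_allele_trajectory.tsv"), sep="\t", comment="#")


# --- catalog statistics ----------------------------------------------------------

def count_mutations(records: list[MutationRecord], by: str = "carrier") -> dict[str, int]:
    """Tally records per carrier or per mutation class."""
    if by not in ("carrier", "class"):
        raise ValueError("by must be 'carrier' or 'class'")
    out: dict[str, int] = {}
    for rec in records:
        key = rec.carrier if by == "carrier" else rec.mutation_class
        out[key] = out.get(key, 0) + 1
    return out


def total_mutations(class_totals: pd.DataFrame) -> int:
    """Sum of per-class mutation counts (columns: class, count)."""
    return int(class_totals["count"].sum())


def parallel_evolution_tally(population_records: pd.DataFrame, locus: str, *,
                             merge_acrAB: bool = False) -> int:
    """Number of distinct populations carrying >= 1 mutation at a locus.

    ``population_records`` columns: population, gene.  With
    ``merge_acrAB=True``, the locus ``"acrAB"`` counts populations with a
    mutation in either acrA or acrB.  An unknown locus returns 0.
    """
    genes = population_records["gene"]
    if merge_acrAB and locus == "acrAB":
        mask = genes.isin(["acrA", "acrB"])
    else:
        mask = genes == locus
    return int(population_records.loc[mask, "population"].nunique())


def allele_frequency(n_mutant_clones: int, n_total_clones: int) -> float:
    """Allele frequency in percent from clone counts."""
    if n_total_clones <= 0:
        raise ValueError("total clone count must be positive")
    if not 0 <= n_mutant_clones <= n_total_clones:
        raise ValueError("mutant clone count out of range")
    return 100.0 * n_mutant_clones / n_total_clones


# --- allele trajectories ---------------------------------------------------------

def mutation_order(calls: pd.DataFrame) -> pd.DataFrame:
    """First detected generation per locus, in order of appearance.

    ``calls`` columns: locus, generation, state.  Mixed states count as
    detection (whole-population screening); NT generations are skipped.
    Returns (locus, first_detected, rank) sorted by generation then locus;
    ties share a rank (a mutation cluster).  Loci never observed non-WT are
    returned with first_detected = NaN and rank = NaN ("not detected").
    """
    rows = []
    for locus, grp in calls.groupby("locus", sort=True):
        det = grp[grp["state"].isin(["Mut", "Mixed"])]
        first = int(det["generation"].min()) if len(det) else None
        rows.append({"locus": locus, "first_detected": first})
    df = pd.DataFrame(rows)
    detected = df[df["first_detected"].notna()].sort_values(
        ["first_detected", "locus"]).reset_index(drop=True)
    detected["rank"] = detected["first_detected"].rank(method="dense").astype(int)
    undetected = df[df["first_detected"].isna()].copy()
    undetected["rank"] = np.nan
    return pd.concat([detected, undetected], ignore_index=True)


def trajectory_join(order: pd.DataFrame, fitness_by_generation: pd.DataFrame) -> pd.DataFrame:
    """Attribute growth-rate changes between genotyped generations to new loci.

    ``order`` is the output of :func:`mutation_order`;
    ``fitness_by_generation`` has columns generation, condition, mu.  For
    each interval between consecutive genotyped generations, lists the loci
    first detected in that interval and the per-condition change in mu
    across it.  Purely descriptive -- no causal attribution is implied.
    Intervals lacking fitness data at either end are flagged.
    """
    gens = sorted(fitness_by_generation["generation"].unique())
    detected = order[order["first_detected"].notna()]
    rows = []
    fit = fitness_by_generation.set_index(["generation", "condition"])["mu"]
    conditions = sorted(fitness_by_generation["condition"].unique())
    for g0, g1 in zip(gens, gens[1:]):
        loci = detected.loc[(detected["first_detected"] > g0)
                            & (detected["first_detected"] <= g1), "locus"]
        for cond in conditions:
            try:
                dmu = float(fit.loc[(g1, cond)] - fit.loc[(g0, cond)])
                flagged = False
            except KeyError:
                dmu, flagged = float("nan"), True
            rows.append({"generation_from": g0, "generation_to": g1,
                         "condition": cond, "new_loci": ";".join(loci),
                         "delta_mu": dmu, "missing_fitness": flagged})
    return pd.DataFrame(rows)


# --- resequencing triage ---------------------------------------------------------

def filter_variants(candidates: pd.DataFrame, snp_quality_min: int = 150,
                    indel_freq_min: float = 0.4) -> pd.DataFrame:
    """Variant-candidate triage by consensus quality and supporting-read frequency.

    SNPs are kept iff quality >= ``snp_quality_min``; indels iff frequency >=
    ``indel_freq_min`` (boundary values kept).  ``candidates`` columns:
    coordinate, class (SNP|indel), quality, frequency.
    """
    if snp_quality_min < 0 or indel_freq_min < 0:
        raise ValueError("thresholds must be nonnegative")
    is_snp = candidates["class"] == "SNP"
    keep = np.where(is_snp,
                    candidates["quality"] >= snp_quality_min,
                    candidates["frequency"] >= indel_freq_min)
    return candidates[keep].reset_index(drop=True)


def detect_coverage_gaps(track: CoverageTrack, min_length: int = 1000,
                         max_depth: int = 0) -> list[tuple[int, int]]:
    """Maximal low-coverage runs (candidate large deletions).

    Returns 0-based half-open intervals where depth <= ``max_depth``
    throughout and total length >= ``min_length``; adjacent sub-threshold
    intervals are merged into one maximal run.
    """
    gaps = []
    cur = None
    for rec in track.intervals.itertuples(index=False):
        if rec.depth <= max_depth:
            if cur is not None and cur[1] == rec.start:
                cur = (cur[0], rec.end)
            else:
                if cur is not None and cur[1] - cur[0] >= min_length:
                    gaps.append(cur)
                cur = (rec.start, rec.end)
        else:
            if cur is not None and cur[1] - cur[0] >= min_length:
                gaps.append(cur)
            cur = None
    if cur is not None and cur[1] - cur[0] >= min_length:
        gaps.append(cur)
    return gaps


def _longest_run(seq: str) -> int:
    best = run = 0
    prev = ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        best = max(best, run)
    return best


def homopolymer_filter(reads: list[tuple[str, str]], max_run: int = 10) -> list[tuple[str, str]]:
    """Discard reads containing a single-base run strictly longer than ``max_run``.

    Runs of N count as runs.  Empty reads are kept (vacuously run-free).
    ``reads`` is a list of (read_id, sequence) pairs.
    """
    allowed = set("ACGTN")
    kept = []
    for rid, seq in reads:
        if set(seq) - allowed:
            raise ValueError(f"read {rid} contains non-ACGTN characters")
        if _longest_run(seq) <= max_run:
            kept.append((rid, seq))
    return kept


# --- coordinate conversion -------------------------------------------------------

def to_zero_based(coordinate_1based: int) -> int:
    """1-based catalog coordinate -> 0-based position."""
    if coordinate_1based < 1:
        raise ValueError("1-based coordinates start at 1")
    return coordinate_1based - 1


def to_one_based(position_0based: int) -> int:
    """0-based position -> 1-based catalog coordinate."""
    if position_0based < 0:
        raise ValueError("0-based positions start at 0")
    return position_0based + 1
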