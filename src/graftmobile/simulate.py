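"""Labelled synthetic count data: binomial read simulator and dataset blending.

Two generators are provided. The cohort simulator draws per-read error
outcomes at a fixed rate ``q`` to produce homograft reference tables and a
balanced heterograft table with known mobile/non-mobile labels. The blender
titrates one real-or-synthetic homograft count table into another at
proportion ``p`` to create labelled pseudo-heterograft data.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import SnpCounts

__all__ = [
    "SimulationConfig",
    "BlendConfig",
    "Cohort",
    "simulate_homograft_snp",
    "simulate_heterograft_snp",
    "simulate_cohort",
    "blend_datasets",
    "bin_by_depth",
]

logger = logging.getLogger(__name__)

COLUMNS = [
    "transcript_id",
    "snp_id",
    "replicate_id",
    "tissue",
    "genotype_sampled",
    "total_reads",
    "distal_reads",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated homograft/heterograft cohort."""

    error_rate: float = 0.01
    homograft_depth: int = 100
    heterograft_depth: int = 100
    mobile_reads: int = 5
    snps_per_transcript: int = 1
    replicates: int = 3
    n_transcripts: int = 2
    seed: int = 0
    tissue: str = "scion"
    local_genotype: str = "A"
    distal_genotype: str = "B"
    mobile_read_errors: bool = False  # apply the distal error rate to added reads

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError(f"error_rate must be in [0, 1], got {self.error_rate}")
        for name in (
            "homograft_depth",
            "heterograft_depth",
            "mobile_reads",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("snps_per_transcript", "replicates", "n_transcripts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class BlendConfig:
    """Parameters for titrating a distal count table into a local one."""

    blend_proportion: float = 0.1
    depth_comparability_tolerance: float = 2.0  # max/min depth ratio kept
    n_bins: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.blend_proportion <= 1.0:
            raise ValueError(f"blend_proportion must be in [0, 1], got {self.blend_proportion}")
        if self.depth_comparability_tolerance < 1.0:
            raise ValueError("depth_comparability_tolerance is a ratio and must be >= 1")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


@dataclass(frozen=True)
class Cohort:
    """A simulated labelled cohort: two homograft reference tables, one heterograft table."""

    homograft_local: pd.DataFrame
    homograft_distal: pd.DataFrame
    heterograft: pd.DataFrame
    labels: pd.DataFrame  # transcript_id, label, n2
    config: SimulationConfig


def simulate_homograft_snp(
    N: int,
    q: float,
    rng: np.random.Generator,
    *,
    snp_id: str = "snp",
    replicate_id: str = "r1",
) -> SnpCounts:
    """Simulate one homograft SNP: each of N reads is misassigned with probability q.

    One uniform draw per read; a read lands on the distal genotype when its
    draw falls at or below ``q``, so ``n ~ Binomial(N, q)``.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    n = int(np.count_nonzero(rng.random(N) <= q))
    return SnpCounts(snp_id=snp_id, replicate_id=replicate_id, total_reads=N, distal_reads=n)


def simulate_heterograft_snp(
    N: int,
    q: float,
    N2: int,
    rng: np.random.Generator,
    *,
    distal_error_rate: float | None = None,
    snp_id: str = "snp",
    replicate_id: str = "r1",
) -> SnpCounts:
    """Simulate one heterograft SNP: homograft process plus N2 genuinely distal reads.

    By default the added reads are observed as distal (error-free). When
    ``distal_error_rate`` is given, each added read is instead misread as
    local with that probability, matching the two-error-rate inference model.
    """
    if N2 < 0:
        raise ValueError(f"N2 must be >= 0, got {N2}")
    base = simulate_homograft_snp(N, q, rng, snp_id=snp_id, replicate_id=replicate_id)
    mobile_observed_distal = N2
    if distal_error_rate is not None:
        if not 0.0 <= distal_error_rate <= 1.0:
            raise ValueError(f"distal_error_rate must be in [0, 1], got {distal_error_rate}")
        mobile_observed_distal = N2 - int(np.count_nonzero(rng.random(N2) <= distal_error_rate))
    return SnpCounts(
        snp_id=snp_id,
        replicate_id=replicate_id,
        total_reads=N + N2,
        distal_reads=base.distal_reads + mobile_observed_distal,
    )


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate a balanced labelled cohort.

    Exactly half the transcripts receive ``mobile_reads`` added distal reads
    at every SNP/replicate (label ``mobile``); the other half receive none.
    Homograft tables for both genotypes are generated independently with the
    same per-SNP error rate. Identical seeds give byte-identical tables.
    """
    if config.n_transcripts % 2 != 0:
        raise ValueError(
            f"n_transcripts must be even for a balanced cohort, got {config.n_transcripts}"
        )
    if config.mobile_reads < 1:
        raise ValueError("mobile_reads must be >= 1 so the mobile arm differs from the null arm")
    rng = np.random.default_rng(config.seed)
    q = config.error_rate
    hom_local_rows, hom_distal_rows, het_rows, label_rows = [], [], [], []
    n_mobile = config.n_transcripts // 2
    for i in range(config.n_transcripts):
        transcript_id = f"t{i:05d}"
        mobile = i < n_mobile
        n2 = config.mobile_reads if mobile else 0
        label_rows.append(
            {"transcript_id": transcript_id, "label": "mobile" if mobile else "non-mobile", "n2": n2}
        )
        for s in range(config.snps_per_transcript):
            snp_id = f"{transcript_id}_s{s}"
            for r in range(config.replicates):
                replicate_id = f"r{r + 1}"
                hom_a = simulate_homograft_snp(
                    config.homograft_depth, q, rng, snp_id=snp_id, replicate_id=replicate_id
                )
                hom_b = simulate_homograft_snp(
                    config.homograft_depth, q, rng, snp_id=snp_id, replicate_id=replicate_id
                )
                het = simulate_heterograft_snp(
                    config.heterograft_depth,
                    q,
                    n2,
                    rng,
                    distal_error_rate=q if config.mobile_read_errors else None,
                    snp_id=snp_id,
                    replicate_id=replicate_id,
                )
                hom_local_rows.append(
                    (transcript_id, snp_id, replicate_id, config.tissue,
                     config.local_genotype, hom_a.total_reads, hom_a.distal_reads)
                )
                hom_distal_rows.append(
                    (transcript_id, snp_id, replicate_id, config.tissue,
                     config.distal_genotype, hom_b.total_reads, hom_b.distal_reads)
                )
                het_rows.append(
                    (transcript_id, snp_id, replicate_id, config.tissue,
                     config.local_genotype, het.total_reads, het.distal_reads)
                )

    def _frame(rows):
        return pd.DataFrame(rows, columns=COLUMNS)

    return Cohort(
        homograft_local=_frame(hom_local_rows),
        homograft_distal=_frame(hom_distal_rows),
        heterograft=_frame(het_rows),
        labels=pd.DataFrame(label_rows),
        config=config,
    )


def _round_half_away(x: float) -> int:
    """Nearest-integer rounding with ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def blend_datasets(
    local_table: pd.DataFrame,
    distal_table: pd.DataFrame,
    config: BlendConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Titrate the distal table into the local one at proportion ``p``.

    Only SNP observations present in both tables (matched on transcript, SNP
    and replicate) with total depths within the comparability tolerance are
    kept. For each kept observation the local reads are down-sampled to
    ``round((1-p) * N_local)`` (hypergeometric subsampling of its distal
    reads) and ``round(p * distal_reads_of_distal_table)`` distal-genotype
    reads are added. A transcript is labelled mobile when any of its SNPs
    received at least one added read.

    Returns ``(blended_table, labels)``; the blended table carries an
    ``added_distal_reads`` column recording the spiked-in reads per row.
    """
    p = config.blend_proportion
    rng = np.random.default_rng(config.seed)
    key = ["transcript_id", "snp_id", "replicate_id"]
    merged = local_table.merge(distal_table, on=key, suffixes=("_local", "_distal"))
    if merged.empty:
        raise ValueError(
            "no shared (transcript_id, snp_id, replicate_id) observations between the two tables"
        )
    depths = merged[["total_reads_local", "total_reads_distal"]].to_numpy(dtype=float)
    lo = depths.min(axis=1)
    hi = depths.max(axis=1)
    comparable = np.where(lo > 0, hi / np.maximum(lo, 1e-300), np.where(hi == 0, 1.0, np.inf))
    kept = merged[comparable <= config.depth_comparability_tolerance]
    if kept.empty:
        raise ValueError(
            "no SNP observations with comparable read depth between the two tables "
            f"(tolerance factor {config.depth_comparability_tolerance})"
        )
    dropped = len(merged) - len(kept)
    if dropped:
        logger.info("dropped %d shared SNP observations outside the depth tolerance", dropped)

    out_rows = []
    for row in kept.itertuples(index=False):
        n_local_total = int(row.total_reads_local)
        n_local_distal = int(row.distal_reads_local)
        new_total_local = _round_half_away((1.0 - p) * n_local_total)
        if new_total_local < n_local_total and n_local_total > 0:
            kept_distal = int(
                rng.hypergeometric(
                    ngood=n_local_distal,
                    nbad=n_local_total - n_local_distal,
                    nsample=new_total_local,
                )
            )
        else:
            kept_distal = n_local_distal
        added = _round_half_away(p * int(row.distal_reads_distal))
        out_rows.append(
            {
                "transcript_id": row.transcript_id,
                "snp_id": row.snp_id,
                "replicate_id": row.replicate_id,
                "tissue": getattr(row, "tissue_local", "scion"),
                "genotype_sampled": getattr(row, "genotype_sampled_local", "A"),
                "total_reads": new_total_local + added,
                "distal_reads": kept_distal + added,
                "added_distal_reads": added,
            }
        )
    blended = pd.DataFrame(out_rows).sort_values(key, kind="stable").reset_index(drop=True)
    labels = (
        blended.groupby("transcript_id", sort=True)["added_distal_reads"]
        .agg(["sum", "max"])
        .reset_index()
    )
    labels["label"] = np.where(labels["max"] >= 1, "mobile", "non-mobile")
    labels = labels.rename(columns={"sum": "n2"})[["transcript_id", "label", "n2"]]
    return blended, labels


def bin_by_depth(rows, n_bins: int) -> np.ndarray:
    """Assign quantile-based depth bins of approximately equal size.

    ``rows`` is a count table (uses its ``total_reads`` column) or a 1-D
    array of depths. Tied depths are always placed in the same bin, so with
    heavy ties bin sizes can deviate from equality; with distinct depths the
    sizes differ by at most one.
    """
    if isinstance(rows, pd.DataFrame):
        depths = rows["total_reads"].to_numpy()
    else:
        depths = np.asarray(rows)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    n = len(depths)
    n_distinct = len(np.unique(depths))
    if n_bins > n_distinct:
        raise ValueError(
            f"n_bins={n_bins} exceeds the number of distinct depths ({n_distinct})"
        )
    order = np.argsort(depths, kind="stable")
    provisional = (np.arange(n) * n_bins) // n
    bins_sorted = np.empty(n, dtype=int)
    start = 0
    while start < n:
        end = start
        while end < n and depths[order[end]] == depths[order[start]]:
            end += 1
        bins_sorted[start:end] = provisional[start]  # whole tie group goes together
        start = end
    out = np.empty(n, dtype=int)
    out[order] = bins_sorted
    return out
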