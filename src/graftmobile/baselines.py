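"""Threshold-based reference classifiers (Methods A and B).

Method A calls a SNP in a replicate when its distal read count exceeds a
fixed threshold, calls the SNP mobile when enough replicates agree, and calls
the transcript mobile when any SNP is mobile. Method B first discards every
SNP that shows any distal reads in the homograft reference and then applies
Method A to the survivors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = [
    "ThresholdConfig",
    "method_a",
    "method_b",
    "classify_table_method_a",
    "classify_table_method_b",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdConfig:
    read_threshold: int = 3
    min_replicates: int = 2
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if not 1 <= self.min_replicates <= self.n_replicates:
            raise ValueError(
                f"require 1 <= min_replicates <= n_replicates, got "
                f"({self.min_replicates}, {self.n_replicates})"
            )
        if self.read_threshold < 0:
            raise ValueError("read_threshold must be >= 0")


def _snp_qualifies(rep_counts: Mapping[str, int], config: ThresholdConfig) -> bool:
    # missing replicates are non-qualifying
    hits = sum(1 for c in rep_counts.values() if c > config.read_threshold)
    if len(rep_counts) < config.n_replicates:
        logger.debug(
            "SNP has %d of %d replicates; missing ones treated as non-qualifying",
            len(rep_counts),
            config.n_replicates,
        )
    return hits >= config.min_replicates


def method_a(
    het_counts_per_replicate: Mapping[str, Mapping[str, int]],
    config: ThresholdConfig | None = None,
    *,
    aggregate: str = "any",
    per: str = "snp",
) -> str:
    """Classify one transcript by the replicate-threshold rule.

    ``het_counts_per_replicate`` maps ``snp_id -> {replicate_id: distal_reads}``.
    ``per='transcript'`` sums counts across SNPs within each replicate before
    thresholding; ``aggregate`` chooses whether any or all SNPs must qualify.
    """
    config = config or ThresholdConfig()
    if aggregate not in ("any", "all"):
        raise ValueError(f"aggregate must be 'any' or 'all', got {aggregate!r}")
    if per not in ("snp", "transcript"):
        raise ValueError(f"per must be 'snp' or 'transcript', got {per!r}")
    if not het_counts_per_replicate:
        return "non-mobile"
    if per == "transcript":
        pooled: dict[str, int] = {}
        for rep_counts in het_counts_per_replicate.values():
            for rep, c in rep_counts.items():
                pooled[rep] = pooled.get(rep, 0) + c
        het_counts_per_replicate = {"__pooled__": pooled}
    verdicts = [
        _snp_qualifies(rep_counts, config) for rep_counts in het_counts_per_replicate.values()
    ]
    mobile = any(verdicts) if aggregate == "any" else all(verdicts)
    return "mobile" if mobile else "non-mobile"


def method_b(
    hom_counts: Mapping[str, int],
    het_counts_per_replicate: Mapping[str, Mapping[str, int]],
    config: ThresholdConfig | None = None,
    *,
    aggregate: str = "any",
    per: str = "snp",
) -> str:
    """Method A restricted to SNPs without any homograft distal reads.

    ``hom_counts`` maps ``snp_id`` to pooled distal reads across homograft
    replicates; SNPs with a positive pooled count are filtered out. SNPs
    present in the heterograft but absent from the homograft table are
    excluded (and logged) rather than trusted.
    """
    config = config or ThresholdConfig()
    surviving: dict[str, Mapping[str, int]] = {}
    for snp_id, rep_counts in het_counts_per_replicate.items():
        if snp_id not in hom_counts:
            logger.info("SNP %s absent from homograft table; excluded from Method B", snp_id)
            continue
        if hom_counts[snp_id] > 0:
            continue
        surviving[snp_id] = rep_counts
    if not surviving:
        return "non-mobile"
    return method_a(surviving, config, aggregate=aggregate, per=per)


# ---------------------------------------------------------------------------
# Table-level wrappers
# ---------------------------------------------------------------------------


def _nested_counts(het_table: pd.DataFrame) -> dict:
    """transcript_id -> snp_id -> replicate_id -> distal_reads."""
    nested: dict = {}
    for row in het_table.itertuples(index=False):
        nested.setdefault(row.transcript_id, {}).setdefault(row.snp_id, {})[
            str(row.replicate_id)
        ] = int(row.distal_reads)
    return nested


def classify_table_method_a(
    het_table: pd.DataFrame,
    config: ThresholdConfig | None = None,
    *,
    aggregate: str = "any",
    per: str = "snp",
) -> pd.DataFrame:
    """Per-transcript Method A labels for a heterograft count table."""
    rows = [
        {"transcript_id": tx, "label": method_a(snps, config, aggregate=aggregate, per=per),
         "method": "method_a"}
        for tx, snps in sorted(_nested_counts(het_table).items())
    ]
    return pd.DataFrame(rows)


def classify_table_method_b(
    hom_table: pd.DataFrame,
    het_table: pd.DataFrame,
    config: ThresholdConfig | None = None,
    *,
    aggregate: str = "any",
    per: str = "snp",
) -> pd.DataFrame:
    """Per-transcript Method B labels; homograft replicates are pooled for the filter."""
    hom_counts = hom_table.groupby("snp_id")["distal_reads"].sum().to_dict()
    rows = [
        {
            "transcript_id": tx,
            "label": method_b(hom_counts, snps, config, aggregate=aggregate, per=per),
            "method": "method_b",
        }
        for tx, snps in sorted(_nested_counts(het_table).items())
    ]
    return pd.DataFrame(rows)
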