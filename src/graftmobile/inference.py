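"""Exact Bayesian evidence computation for distal-origin reads at SNP positions.

Given per-SNP read counts (``N`` total reads, ``n`` reads matching the distal
genotype), this module infers SNP-specific error-rate posteriors from homograft
reference data, derives the discrete posterior over the number of genuinely
distal reads ``N2``, and turns it into per-SNP and per-transcript log10 Bayes
factors comparing the two-genotype hypothesis against the errors-only
hypothesis.

All probability arithmetic is carried out in log space via log-gamma
identities; no Monte Carlo approximation is involved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln, logsumexp

__all__ = [
    "SnpCounts",
    "PriorHyperparameters",
    "ErrorPosterior",
    "MobilePosterior",
    "TranscriptEvidence",
    "fit_error_posterior",
    "log_beta_binomial",
    "posterior_over_n2",
    "snp_log_bf",
    "transcript_log_bf",
    "classify_heterograft",
    "DEFAULT_LOG_BF_THRESHOLD",
]

logger = logging.getLogger(__name__)

LN10 = np.log(10.0)

#: Default decision threshold on the per-transcript log10 Bayes factor
#: ("substantial" support on the conventional interpretive scale).
DEFAULT_LOG_BF_THRESHOLD = 1.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpCounts:
    """One SNP's observation in one replicate.

    Parameters
    ----------
    snp_id : str
        Opaque SNP key.
    replicate_id : str
        Opaque replicate key.
    total_reads : int
        Total reads ``N`` covering the SNP.
    distal_reads : int
        Reads ``n`` whose base matches the distal genotype, ``0 <= n <= N``.
    """

    snp_id: str
    replicate_id: str
    total_reads: int
    distal_reads: int

    def __post_init__(self) -> None:
        if self.total_reads < 0:
            raise ValueError(
                f"total_reads must be >= 0, got {self.total_reads} "
                f"(snp={self.snp_id!r}, replicate={self.replicate_id!r})"
            )
        if not 0 <= self.distal_reads <= self.total_reads:
            raise ValueError(
                f"distal_reads must satisfy 0 <= n <= N, got n={self.distal_reads}, "
                f"N={self.total_reads} (snp={self.snp_id!r}, "
                f"replicate={self.replicate_id!r})"
            )


@dataclass(frozen=True)
class PriorHyperparameters:
    """Beta prior hyperparameters for the per-SNP error rate."""

    u1: float = 1.0
    u2: float = 1.0

    def __post_init__(self) -> None:
        if not (self.u1 > 0 and self.u2 > 0):
            raise ValueError(f"prior hyperparameters must be > 0, got ({self.u1}, {self.u2})")


@dataclass(frozen=True)
class ErrorPosterior:
    """Beta(alpha, beta) posterior over one SNP's error rate.

    ``tissue`` and ``genotype`` identify which homograft the posterior was
    fitted from; they are optional metadata used for pairing sanity checks.
    """

    alpha: float
    beta: float
    snp_id: str | None = None
    tissue: str | None = None
    genotype: str | None = None
    prior: PriorHyperparameters = field(default_factory=PriorHyperparameters)

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(f"shape parameters must be > 0, got ({self.alpha}, {self.beta})")
        if self.alpha < self.prior.u1 or self.beta < self.prior.u2:
            raise ValueError("posterior shape parameters cannot be below the prior's (counts only add)")

    @property
    def mean(self) -> float:
        """Posterior mean error rate ``alpha / (alpha + beta)``."""
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class MobilePosterior:
    """Discrete posterior over the number of genuinely distal reads ``N2``.

    ``probabilities[k]`` is ``P(N2 = k | D)`` for ``k`` in ``0..N``;
    ``log_probabilities`` holds the same cells in natural log (kept to avoid
    underflow when forming Bayes-factor ratios).
    """

    probabilities: np.ndarray
    log_probabilities: np.ndarray
    expected_n2: float
    ratio_r2: float
    snp_id: str | None = None

    @property
    def total_reads(self) -> int:
        return len(self.probabilities) - 1


@dataclass(frozen=True)
class TranscriptEvidence:
    """Per-SNP/per-replicate log10 Bayes factors and their sum for one transcript."""

    transcript_id: str
    contributions: dict
    total_log_bf: float
    label: str  # "mobile" | "non-mobile"
    confident_non_mobile: bool = False
    threshold: float = DEFAULT_LOG_BF_THRESHOLD


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def fit_error_posterior(
    homograft_counts: Iterable[SnpCounts],
    prior: PriorHyperparameters | None = None,
    *,
    tissue: str | None = None,
    genotype: str | None = None,
) -> ErrorPosterior:
    """Conjugate Beta update of the error-rate prior with homograft counts.

    All counts must refer to the same SNP; replicates are pooled, so the
    result is invariant to how the data are split across replicates and to
    their order. An empty collection returns the prior unchanged (with a
    low-information warning).
    """
    prior = prior or PriorHyperparameters()
    counts = list(homograft_counts)
    if not counts:
        warnings.warn(
            "no homograft observations supplied; posterior equals the prior (low information)",
            UserWarning,
            stacklevel=2,
        )
        return ErrorPosterior(
            alpha=prior.u1, beta=prior.u2, tissue=tissue, genotype=genotype, prior=prior
        )
    snp_ids = {c.snp_id for c in counts}
    if len(snp_ids) != 1:
        raise ValueError(f"counts must all share one snp_id, got {sorted(snp_ids)}")
    n_sum = sum(c.distal_reads for c in counts)
    correct_sum = sum(c.total_reads - c.distal_reads for c in counts)
    return ErrorPosterior(
        alpha=prior.u1 + n_sum,
        beta=prior.u2 + correct_sum,
        snp_id=counts[0].snp_id,
        tissue=tissue,
        genotype=genotype,
        prior=prior,
    )


def log_beta_binomial(k, m, alpha: float, beta: float):
    """Natural-log beta-binomial pmf: ``log P(k | m, alpha, beta)``.

    This is the marginal of ``Binomial(m, theta)`` with ``theta ~
    Beta(alpha, beta)``:

        C(m, k) * B(k + alpha, m - k + beta) / B(alpha, beta)

    ``k`` and ``m`` may be scalars or broadcastable integer arrays.
    """
    if not (alpha > 0 and beta > 0):
        raise ValueError(f"alpha and beta must be > 0, got ({alpha}, {beta})")
    k_arr = np.asarray(k)
    m_arr = np.asarray(m)
    if np.any(k_arr < 0) or np.any(k_arr > m_arr) or np.any(m_arr < 0):
        raise ValueError("require 0 <= k <= m")
    out = (
        gammaln(m_arr + 1.0)
        - gammaln(k_arr + 1.0)
        - gammaln(m_arr - k_arr + 1.0)
        + betaln(k_arr + alpha, m_arr - k_arr + beta)
        - betaln(alpha, beta)
    )
    if np.isscalar(k) and np.isscalar(m):
        return float(out)
    return out


def _single_rate_log_likelihood(N: int, n: int, alpha: float, beta: float) -> np.ndarray:
    """log P(n | N2) over N2 in 0..N when distal reads are always observed as distal.

    N2 genuinely distal reads contribute n - ... exactly, so the n observed
    distal reads decompose as N2 mobile plus n - N2 errors among the N - N2
    local reads; N2 > n is impossible.
    """
    loglik = np.full(N + 1, -np.inf)
    n2 = np.arange(n + 1)
    loglik[: n + 1] = log_beta_binomial(n - n2, N - n2, alpha, beta)
    return loglik


def _two_rate_log_likelihood(
    N: int, n: int, a_loc: float, b_loc: float, a_dist: float, b_dist: float
) -> np.ndarray:
    """log P(n | N2) over N2 in 0..N with errors on both read populations.

    Likelihood is a convolution of two beta-binomials: j errors among the
    N - N2 local reads (rate theta1 ~ Beta(a_loc, b_loc), observed as distal)
    and n - j of the N2 distal reads observed correctly (each distal with
    probability 1 - theta2, theta2 ~ Beta(a_dist, b_dist), i.e. a
    beta-binomial with swapped shape parameters).

    Implemented with precomputed log-gamma lookup tables so the whole scan
    over N2 costs O(N * n) array operations rather than repeated gammaln
    evaluations.
    """
    x = np.arange(N + 1)
    gl_fact = gammaln(x + 1.0)
    gA1 = gammaln(x + a_loc)
    gB1 = gammaln(x + b_loc)
    gAB1 = gammaln(x + a_loc + b_loc)
    gA2 = gammaln(x + a_dist)
    gB2 = gammaln(x + b_dist)
    gAB2 = gammaln(x + a_dist + b_dist)
    c1 = betaln(a_loc, b_loc)
    c2 = betaln(a_dist, b_dist)

    n2 = x[None, :]  # columns: candidate N2
    j = np.arange(n + 1)[:, None]  # rows: errors among local reads
    m1 = N - n2  # local trials
    k2 = n - j  # distal reads observed as distal
    valid = (j <= m1) & (k2 <= n2)

    m1j = np.clip(m1 - j, 0, N)
    rem2 = np.clip(n2 - k2, 0, N)
    t_local = gl_fact[m1] - gl_fact[j] - gl_fact[m1j] + gA1[j] + gB1[m1j] - gAB1[m1] - c1
    # swapped shapes: distal read observed distal with prob 1 - theta2
    t_dist = gl_fact[n2] - gl_fact[k2] - gl_fact[rem2] + gB2[k2] + gA2[rem2] - gAB2[n2] - c2
    total = np.where(valid, t_local + t_dist, -np.inf)
    return logsumexp(total, axis=0)


def _check_pairing(het: SnpCounts, local_error: ErrorPosterior, distal_error: ErrorPosterior | None) -> None:
    for role, err in (("local", local_error), ("distal", distal_error)):
        if err is None:
            continue
        if err.snp_id is not None and err.snp_id != het.snp_id:
            raise ValueError(
                f"{role} error posterior is for snp {err.snp_id!r}, heterograft counts for {het.snp_id!r}"
            )
    if distal_error is not None:
        if (
            local_error.tissue is not None
            and distal_error.tissue is not None
            and local_error.tissue != distal_error.tissue
        ):
            raise ValueError(
                f"tissue mismatch between homograft posteriors: "
                f"{local_error.tissue!r} vs {distal_error.tissue!r}"
            )
        if (
            local_error.genotype is not None
            and distal_error.genotype is not None
            and local_error.genotype == distal_error.genotype
        ):
            raise ValueError(
                f"local and distal posteriors must come from different genotypes, "
                f"both are {local_error.genotype!r}"
            )


def posterior_over_n2(
    het: SnpCounts,
    local_error: ErrorPosterior,
    distal_error: ErrorPosterior | None = None,
) -> MobilePosterior:
    """Posterior ``P(N2 | D)`` over the number of genuinely distal reads.

    A uniform prior over ``N2 in {0..N}`` is combined with the (beta-binomial)
    likelihood of observing ``n`` distal-matching reads. When ``distal_error``
    is omitted, genuinely distal reads are taken to be observed as distal with
    certainty (single-error-rate model); otherwise they may themselves be
    misread at the distal genotype's error rate (two-error-rate model).
    """
    _check_pairing(het, local_error, distal_error)
    N, n = het.total_reads, het.distal_reads
    if N == 0:
        warnings.warn(
            f"SNP {het.snp_id!r} has zero reads; returning degenerate posterior P(N2=0)=1",
            UserWarning,
            stacklevel=2,
        )
        return MobilePosterior(
            probabilities=np.array([1.0]),
            log_probabilities=np.array([0.0]),
            expected_n2=0.0,
            ratio_r2=0.0,
            snp_id=het.snp_id,
        )
    if distal_error is None:
        loglik = _single_rate_log_likelihood(N, n, local_error.alpha, local_error.beta)
    else:
        loglik = _two_rate_log_likelihood(
            N, n, local_error.alpha, local_error.beta, distal_error.alpha, distal_error.beta
        )
    # uniform prior over N2 cancels in the normalisation
    log_post = loglik - logsumexp(loglik)
    probs = np.exp(log_post)
    n2 = np.arange(N + 1)
    expected = float(np.dot(n2, probs))
    return MobilePosterior(
        probabilities=probs,
        log_probabilities=log_post,
        expected_n2=expected,
        ratio_r2=expected / N,
        snp_id=het.snp_id,
    )


def snp_log_bf(post: MobilePosterior) -> float:
    """Per-SNP log10 Bayes factor: ``log10(max_{N2>0} P(N2|D) / P(N2=0|D))``.

    The maximum is taken over all positive ``N2`` by exhaustive scan. A
    degenerate posterior (zero reads) carries no evidence and returns 0, as
    does an exact tie between the best positive ``N2`` and ``N2 = 0``.
    """
    lp = post.log_probabilities
    if lp.size == 1:
        return 0.0
    if not np.isfinite(lp[0]):
        raise ValueError("posterior must assign non-zero probability to N2=0")
    best_positive = float(np.max(lp[1:]))
    return (best_positive - float(lp[0])) / LN10


def transcript_log_bf(
    per_snp_per_replicate: Mapping,
    threshold: float = DEFAULT_LOG_BF_THRESHOLD,
    *,
    transcript_id: str = "",
) -> TranscriptEvidence:
    """Sum per-SNP/per-replicate log10 Bayes factors into transcript-level evidence.

    Labels the transcript ``mobile`` when the summed evidence reaches
    ``threshold``; additionally flags confident non-mobility when the total is
    at or below ``-threshold``. An empty contribution map is rejected: a
    transcript with no SNP data is unclassifiable, not non-mobile.
    """
    contributions = dict(per_snp_per_replicate)
    if not contributions:
        raise ValueError(f"transcript {transcript_id!r} has no SNP contributions; cannot classify")
    total = float(sum(contributions.values()))
    label = "mobile" if total >= threshold else "non-mobile"
    return TranscriptEvidence(
        transcript_id=transcript_id,
        contributions=contributions,
        total_log_bf=total,
        label=label,
        confident_non_mobile=total <= -threshold,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Table-level driver
# ---------------------------------------------------------------------------


def _fit_posterior_map(
    hom_table: pd.DataFrame, prior: PriorHyperparameters, genotype_role: str
) -> dict:
    """Fit one pooled-replicate ErrorPosterior per (snp_id, tissue)."""
    posteriors: dict = {}
    for (snp_id, tissue), grp in hom_table.groupby(["snp_id", "tissue"], sort=False):
        n_sum = int(grp["distal_reads"].sum())
        total = int(grp["total_reads"].sum())
        posteriors[(snp_id, tissue)] = ErrorPosterior(
            alpha=prior.u1 + n_sum,
            beta=prior.u2 + (total - n_sum),
            snp_id=snp_id,
            tissue=tissue,
            genotype=str(grp["genotype_sampled"].iloc[0]) if "genotype_sampled" in grp else None,
            prior=prior,
        )
    logger.debug("fitted %d %s error posteriors", len(posteriors), genotype_role)
    return posteriors


def classify_heterograft(
    het_table: pd.DataFrame,
    local_homograft: pd.DataFrame,
    distal_homograft: pd.DataFrame | None = None,
    *,
    prior: PriorHyperparameters | None = None,
    threshold: float = DEFAULT_LOG_BF_THRESHOLD,
    pool_replicates: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full Bayes-factor pipeline on count tables.

    Parameters
    ----------
    het_table, local_homograft, distal_homograft
        Count tables in the standard schema (see :mod:`graftmobile.io`). The
        local homograft must match the sampled genotype of the heterograft;
        passing ``distal_homograft`` enables the two-error-rate model,
        otherwise the single-error-rate model is used with a warning.
    pool_replicates
        If true, heterograft replicates are summed into one count per SNP
        before scoring instead of contributing additive Bayes factors.

    Returns
    -------
    (per_transcript, per_snp)
        ``per_transcript`` has one row per transcript with the summed log10
        Bayes factor, the across-SNP mean of ``<N2>`` and ``r2``, and the
        binary label; ``per_snp`` holds the per-(SNP, replicate) detail.
        Both are sorted deterministically.
    """
    prior = prior or PriorHyperparameters()
    local_post = _fit_posterior_map(local_homograft, prior, "local")
    distal_post = None
    if distal_homograft is not None:
        distal_post = _fit_posterior_map(distal_homograft, prior, "distal")
    else:
        warnings.warn(
            "no distal homograft table supplied; falling back to the "
            "single-error-rate model (distal reads observed as distal)",
            UserWarning,
            stacklevel=2,
        )

    het = het_table.copy()
    if pool_replicates:
        het = (
            het.groupby(["transcript_id", "snp_id", "tissue"], sort=False, as_index=False)
            .agg(total_reads=("total_reads", "sum"), distal_reads=("distal_reads", "sum"))
            .assign(replicate_id="pooled")
        )

    snp_rows = []
    for row in het.itertuples(index=False):
        key = (row.snp_id, row.tissue)
        loc = local_post.get(key)
        if loc is None:
            warnings.warn(
                f"no local homograft data for SNP {row.snp_id!r} (tissue {row.tissue!r}); "
                "using the prior as error posterior",
                UserWarning,
                stacklevel=2,
            )
            loc = ErrorPosterior(alpha=prior.u1, beta=prior.u2, snp_id=row.snp_id, prior=prior)
        dist = distal_post.get(key) if distal_post is not None else None
        counts = SnpCounts(
            snp_id=row.snp_id,
            replicate_id=str(row.replicate_id),
            total_reads=int(row.total_reads),
            distal_reads=int(row.distal_reads),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # N=0 degenerate handled below
            post = posterior_over_n2(counts, loc, dist)
        if counts.total_reads == 0:
            logger.info(
                "SNP %s replicate %s has zero reads; contributes log BF 0",
                row.snp_id,
                row.replicate_id,
            )
        snp_rows.append(
            {
                "transcript_id": row.transcript_id,
                "snp_id": row.snp_id,
                "replicate_id": str(row.replicate_id),
                "total_reads": counts.total_reads,
                "distal_reads": counts.distal_reads,
                "log10_bf": snp_log_bf(post),
                "expected_n2": post.expected_n2,
                "ratio_r2": post.ratio_r2,
            }
        )
    per_snp = pd.DataFrame(snp_rows).sort_values(
        ["transcript_id", "snp_id", "replicate_id"], kind="stable"
    )

    tx_rows = []
    for transcript_id, grp in per_snp.groupby("transcript_id", sort=True):
        contributions = {
            (r.snp_id, r.replicate_id): r.log10_bf for r in grp.itertuples(index=False)
        }
        ev = transcript_log_bf(contributions, threshold, transcript_id=transcript_id)
        tx_rows.append(
            {
                "transcript_id": transcript_id,
                "n_snps": grp["snp_id"].nunique(),
                "n_observations": len(grp),
                "total_log10_bf": ev.total_log_bf,
                "mean_expected_n2": grp["expected_n2"].mean(),
                "mean_ratio_r2": grp["ratio_r2"].mean(),
                "label": ev.label,
                "confident_non_mobile": ev.confident_non_mobile,
            }
        )
    per_transcript = pd.DataFrame(tx_rows).sort_values("transcript_id", kind="stable")
    return per_transcript.reset_index(drop=True), per_snp.reset_index(drop=True)
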