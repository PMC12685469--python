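"""Targeted-panel CNV calling and absolute copy number.

The workflow mirrors a matched tumor/normal panel analysis: per-probe
coverage ratios are aggregated into robust segment means, gene-level
amplification/loss calls use fixed ratio cutoffs (amplification at ratio
>= 2.0, loss below 0.6), and the absolute copy number (ACN) corrects the
observed ratio for normal-cell dilution:

    ACN = (2 * ratio - 2 * (1 - TF)) / TF

Tumor fraction (TF) is estimated from heterozygous-SNP allele balance by a
grid search maximising a folded-binomial likelihood over candidate integer
copy states per segment — a deliberately compact allele-specific estimator
in the spirit of FACETS-style admixture fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "SegmentProfile",
    "TfEstimate",
    "TfUnidentifiableError",
    "segment_mean",
    "build_segment_profile",
    "call_gene_cnv",
    "compute_acn",
    "classify_deletion_zygosity",
    "estimate_tumor_fraction",
    "tumor_content_qc",
]

AMPLIFICATION_RATIO = 2.0   # inclusive
LOSS_RATIO = 0.6            # exclusive (loss strictly below)
HOMOZYGOUS_DEL_ACN = 0.5    # ACN <= 0.5 -> homozygous deletion
HETEROZYGOUS_DEL_ACN = 1.5  # 0.5 < ACN <= 1.5 -> heterozygous deletion
MIN_TUMOR_CONTENT = 0.20    # sample-level QC gate (HRD analyses need 0.30)
# Exon-level rearrangement positivity threshold retained as a documented
# constant; read-level LGR calling itself is outside this package.
LGR_MIN_VAF = 0.25


class TfUnidentifiableError(ValueError):
    """No segment shows allelic imbalance, so TF carries no signal."""


@dataclass
class TfEstimate:
    tf: float
    ci_low: float
    ci_high: float
    n_segments_used: int
    loglik: float


@dataclass
class SegmentProfile:
    """Per-region segment-mean ratios plus sample-level tumor fraction.

    ``segments`` columns: region, chrom, start, end, segment_mean_ratio and,
    once :meth:`annotate_calls` has run, acn and cnv_call.
    """

    segments: pd.DataFrame
    tumor_fraction: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.segments["segment_mean_ratio"] <= 0).any():
            raise ValueError("segment_mean_ratio must be positive")
        if self.tumor_fraction is not None and not 0 < self.tumor_fraction <= 1:
            raise ValueError("tumor_fraction must lie in (0, 1]")

    def annotate_calls(self) -> pd.DataFrame:
        """Add cnv_call, ACN and deletion-zygosity columns in place."""
        seg = self.segments
        seg["cnv_call"] = seg["segment_mean_ratio"].map(call_gene_cnv)
        if self.tumor_fraction is not None:
            seg["acn"] = [
                compute_acn(r, self.tumor_fraction) for r in seg["segment_mean_ratio"]
            ]
            seg["zygosity"] = seg["acn"].map(classify_deletion_zygosity)
        return seg


def segment_mean(probe_ratios: pd.DataFrame, region: str,
                 method: str = "median") -> float:
    """Aggregate per-probe ratios of one region into a segment mean.

    The default is the median — robust to single outlier probes, which are
    common in FFPE material.  ``method='mean'`` is available.
    """
    sub = probe_ratios.loc[probe_ratios["gene"] == region, "ratio"]
    if sub.empty:
        raise ValueError(f"no probes in region {region!r}")
    if method == "median":
        return float(sub.median())
    if method == "mean":
        return float(sub.mean())
    raise ValueError(f"unknown aggregation method {method!r}")


def build_segment_profile(probe_ratios: pd.DataFrame,
                          tumor_fraction: float | None = None,
                          method: str = "median") -> SegmentProfile:
    """Collapse a probe-ratio table into one segment per gene region."""
    rows = []
    for gene, sub in probe_ratios.groupby("gene", sort=False):
        rows.append((
            gene, sub["chrom"].iloc[0], int(sub["start"].min()),
            int(sub["end"].max()), segment_mean(probe_ratios, gene, method),
        ))
    seg = pd.DataFrame(
        rows, columns=["region", "chrom", "start", "end", "segment_mean_ratio"]
    )
    return SegmentProfile(segments=seg, tumor_fraction=tumor_fraction)


def call_gene_cnv(segment_mean_ratio: float) -> str:
    """Gene-level call: amplification at ratio >= 2.0, loss below 0.6."""
    if segment_mean_ratio <= 0:
        raise ValueError("segment mean ratio must be positive")
    if segment_mean_ratio >= AMPLIFICATION_RATIO:
        return "amplification"
    if segment_mean_ratio < LOSS_RATIO:
        return "loss"
    return "neutral"


def compute_acn(ratio: float, tf: float) -> float:
    """Absolute copy number from a coverage ratio and tumor fraction.

    ACN = (2*ratio - 2*(1 - tf)) / tf, clamped at 0 (low ratios at low TF
    can drive the raw value negative; a warning is emitted).
    """
    if not 0 < tf <= 1:
        raise ValueError("tf must lie in (0, 1]")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    raw = (2.0 * ratio - 2.0 * (1.0 - tf)) / tf
    if raw < 0:
        warnings.warn(
            f"ACN formula returned {raw:.3f} < 0 (ratio={ratio}, tf={tf}); clamping to 0",
            stacklevel=2,
        )
        return 0.0
    return raw


def classify_deletion_zygosity(acn: float) -> str:
    """Deletion zygosity from ACN: <=0.5 homozygous, <=1.5 heterozygous."""
    if acn < 0:
        raise ValueError("acn must be >= 0")
    if acn <= HOMOZYGOUS_DEL_ACN:
        return "homozygous_deletion"
    if acn <= HETEROZYGOUS_DEL_ACN:
        return "heterozygous_deletion"
    return "none"


def tumor_content_qc(tf: float, hrd: bool = False) -> bool:
    """Sample-level tumor-content gate: >= 20% (>= 30% for HRD analyses)."""
    return tf >= (0.30 if hrd else MIN_TUMOR_CONTENT)


# ---------------------------------------------------------------------------
# Tumor-fraction estimation from heterozygous SNPs
# ---------------------------------------------------------------------------

def _folded_binom_loglik_grid(alt: np.ndarray, dp: np.ndarray,
                              p: np.ndarray) -> np.ndarray:
    """Log-likelihood of het-SNP alt counts under a symmetric BAF mixture,
    evaluated for every candidate allele fraction in ``p`` at once.

    The alt allele sits on either haplotype with probability 1/2, so the
    observed alt count is a 50/50 mixture of Binomial(dp, p) and
    Binomial(dp, 1-p).  Returns an array shaped like ``p``.
    """
    p = np.clip(np.atleast_1d(np.asarray(p, dtype=float)), 1e-3, 1 - 1e-3)
    log_c = (gammaln(dp + 1) - gammaln(alt + 1) - gammaln(dp - alt + 1)).sum()
    lp = np.log(p)[:, None]
    l1p = np.log1p(-p)[:, None]
    a = alt[None, :] * lp + (dp - alt)[None, :] * l1p
    b = alt[None, :] * l1p + (dp - alt)[None, :] * lp
    return log_c + np.logaddexp(a, b).sum(axis=1) - len(alt) * np.log(2.0)


def _folded_binom_loglik(alt: np.ndarray, dp: np.ndarray, p: float) -> float:
    return float(_folded_binom_loglik_grid(alt, dp, np.array([p]))[0])


def _segment_imbalance_lrt(alt: np.ndarray, dp: np.ndarray) -> float:
    """LRT statistic for allelic imbalance of one segment (H0: BAF = 0.5)."""
    null = _folded_binom_loglik(alt, dp, 0.5)
    best = _folded_binom_loglik_grid(alt, dp, np.linspace(0.5, 0.99, 50)).max()
    return 2.0 * (best - null)


def _candidate_states(max_total: int = 8):
    states = [(0, 0)]
    for total in range(1, max_total + 1):
        for minor in range(0, total // 2 + 1):
            states.append((total, minor))
    return states


def estimate_tumor_fraction(
    snps: pd.DataFrame,
    segments: SegmentProfile,
    min_snps: int = 10,
    imbalance_lrt_cutoff: float = 10.0,
    grid: np.ndarray | None = None,
    ratio_sd: float = 0.05,
) -> TfEstimate:
    """Estimate tumor fraction from het-SNP allele balance and segment ratios.

    For each candidate TF on a grid over (0.05, 1.0], every segment is
    assigned the integer (total, minor) copy state that maximises the joint
    likelihood of its folded-binomial BAFs and its Gaussian segment-ratio
    deviation from the admixture expectation
    ``(tf*total + 2*(1-tf)) / 2``.  The TF maximising the summed profile
    likelihood is returned with a profile-likelihood 95% interval.

    Raises
    ------
    TfUnidentifiableError
        When no segment with >= ``min_snps`` informative SNPs shows allelic
        imbalance beyond sampling noise; the caller must supply TF manually.
    """
    if (snps[["ref_count", "alt_count"]] < 0).any().any():
        raise ValueError("allele counts must be non-negative")
    if grid is None:
        grid = np.arange(0.05, 1.0001, 0.005)

    per_segment = []
    any_aberrant = False
    for _, row in segments.segments.iterrows():
        sub = snps[snps["region"] == row["region"]]
        dp = (sub["ref_count"] + sub["alt_count"]).to_numpy()
        keep = dp > 0
        alt = sub["alt_count"].to_numpy()[keep]
        dp = dp[keep]
        if len(dp) < min_snps:
            continue
        aberrant = _segment_imbalance_lrt(alt, dp) > imbalance_lrt_cutoff
        any_aberrant = any_aberrant or aberrant
        per_segment.append((row["segment_mean_ratio"], alt, dp))

    if not any_aberrant:
        raise TfUnidentifiableError(
            "no segment shows allelic imbalance; tumor fraction is "
            "unidentifiable from this sample — supply TF manually"
        )

    states = np.array(_candidate_states(), dtype=float)  # (S, 2)
    totals, minors = states[:, 0], states[:, 1]
    tf_grid = grid[:, None]                               # (G, 1)
    tumor_cov = tf_grid * totals + 2.0 * (1.0 - tf_grid)  # (G, S)
    valid = tumor_cov > 1e-9
    exp_ratio = tumor_cov / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        baf = np.where(valid, (tf_grid * minors + (1.0 - tf_grid)) / tumor_cov, 0.5)

    logliks = np.zeros(len(grid))
    for ratio, alt, dp in per_segment:
        ll = stats.norm.logpdf(ratio, exp_ratio, ratio_sd)
        ll += _folded_binom_loglik_grid(alt, dp, baf.ravel()).reshape(baf.shape)
        ll[~valid] = -np.inf
        logliks += ll.max(axis=1)

    best_i = int(np.argmax(logliks))
    in_ci = logliks >= logliks[best_i] - 1.92  # chi2_1 95% profile interval
    return TfEstimate(
        tf=float(grid[best_i]),
        ci_low=float(grid[in_ci].min()),
        ci_high=float(grid[in_ci].max()),
        n_segments_used=len(per_segment),
        loglik=float(logliks[best_i]),
    )
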