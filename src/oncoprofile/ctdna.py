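"""Plasma ctDNA monitoring: mutation positivity, the hierarchical
tumor-fraction estimator, dilution-series LOD, molecular response, and the
survival statistics used to relate response to outcome.

Tumor fraction (TF) per plasma draw follows a strict three-tier hierarchy:

1. mutations — when any tracked/hotspot mutation is positive, TF is the
   mean VAF of all positive mutations;
2. copy number — otherwise, the ichorCNA-style scalar when it is positive;
3. fragment length — otherwise, a calibrated linear regression converts the
   fragment-length signal to a TF, clamped at 0, with predictions inside
   the model's own noise floor treated as undetectable.

Mutation positivity at ultra-deep amplicon depth uses a one-sided binomial
tail against the per-read background error rate (p < 1e-3) plus a 3-read
floor; at 100,000x with a 5e-5 error rate this supports detection down to
0.01% TF.  A molecular responder is a patient whose on-treatment ctDNA TF
drops by strictly more than 50% from a positive baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "PlasmaTimepoint",
    "MolecularResponse",
    "LodResult",
    "FragmentModel",
    "call_plasma_mutation",
    "annotate_mutations",
    "estimate_plasma_tf",
    "fit_fragment_model",
    "evaluate_dilution",
    "compute_lod",
    "classify_molecular_response",
    "km_curve",
    "cox_hr",
]

MUTATION_TAIL_P = 1e-3
MUTATION_MIN_ALT = 3
RESPONSE_DECREASE_PCT = 50.0  # responder strictly above 50% decrease


@dataclass
class PlasmaTimepoint:
    """One plasma draw: tracked-mutation reads plus scalar ctDNA signals.

    ``mutations`` columns: site, depth, alt_reads, origin
    ('tumor_informed' | 'hotspot'); after annotation also vaf and positive.
    ``cn_signal`` is an ichorCNA-style TF (0 / None when no aberration is
    detected); ``fragment_signal`` is the raw fragment-length score.
    """

    timepoint: float
    mutations: pd.DataFrame
    cn_signal: float | None = None
    fragment_signal: float | None = None
    tf: float | None = None
    tf_tier: str | None = None     # 'mutation' | 'copy_number' | 'fragment'
    ctdna_status: str | None = None


@dataclass
class MolecularResponse:
    baseline_tf: float
    on_treatment_tf: float
    percent_change: float
    classification: str  # 'responder' | 'non_responder'


@dataclass
class LodResult:
    hit_rates: pd.Series          # per dilution level, descending levels
    lod90: float | None
    confidence: float
    status: str                   # 'fitted' | 'empirical' | 'above_tested_range'
    model: object = None


def call_plasma_mutation(alt_reads: int, depth: int,
                         error_rate: float) -> tuple[bool, float]:
    """Positivity of one amplicon site against the background error rate.

    Positive iff the one-sided binomial tail P(X >= alt | depth, error) is
    below 1e-3 and at least 3 alt reads support the call.  Returns
    (positive, vaf).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if alt_reads > depth:
        raise ValueError("alt_reads cannot exceed depth")
    if alt_reads < 0:
        raise ValueError("alt_reads must be >= 0")
    vaf = alt_reads / depth
    if alt_reads < MUTATION_MIN_ALT:
        return False, vaf
    tail = stats.binom.sf(alt_reads - 1, depth, error_rate)
    return bool(tail < MUTATION_TAIL_P), vaf


def annotate_mutations(tp: PlasmaTimepoint, error_rate: float) -> pd.DataFrame:
    """Add vaf and positive columns to a timepoint's mutation table.

    Vectorised equivalent of :func:`call_plasma_mutation` applied per row.
    """
    muts = tp.mutations
    depth = muts["depth"].to_numpy(dtype=np.int64)
    alt = muts["alt_reads"].to_numpy(dtype=np.int64)
    if (depth <= 0).any():
        raise ValueError("depth must be positive")
    if (alt < 0).any() or (alt > depth).any():
        raise ValueError("alt_reads must lie in [0, depth]")
    vaf = alt / depth
    tail = stats.binom.sf(alt - 1, depth, error_rate)
    positive = (tail < MUTATION_TAIL_P) & (alt >= MUTATION_MIN_ALT)
    muts = muts.assign(vaf=vaf, positive=positive)
    tp.mutations = muts
    return muts


@dataclass
class FragmentModel:
    """Linear conversion of the fragment-length signal to a TF."""

    slope: float
    intercept: float
    stderr_slope: float
    stderr_intercept: float
    residual_sd: float
    n: int
    detection_floor: float = 0.0   # predictions at/below this count as 0

    def predict(self, signal: float) -> float:
        tf = self.slope * signal + self.intercept
        if tf <= self.detection_floor:
            return 0.0
        return float(tf)


def fit_fragment_model(calibration: pd.DataFrame,
                       floor_multiplier: float = 2.0) -> FragmentModel:
    """Ordinary least squares of known TF on fragment signal.

    ``calibration`` columns: fragment_signal, tf.  The detection floor is
    ``floor_multiplier`` times the residual standard deviation: predicted
    TFs inside the model's own noise are reported as 0 rather than as
    spurious positives.
    """
    if len(calibration) < 3:
        raise ValueError("need at least 3 calibration points")
    x = calibration["fragment_signal"].to_numpy(dtype=float)
    y = calibration["tf"].to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("fragment signal is constant; cannot calibrate")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    rsd = float(np.std(resid, ddof=2))
    return FragmentModel(
        slope=float(res.slope), intercept=float(res.intercept),
        stderr_slope=float(res.stderr), stderr_intercept=float(res.intercept_stderr),
        residual_sd=rsd, n=len(x), detection_floor=floor_multiplier * rsd,
    )


def estimate_plasma_tf(tp: PlasmaTimepoint, error_rate: float,
                       fragment_model: FragmentModel | None = None) -> float:
    """Hierarchical TF: mean positive-mutation VAF, else CN, else fragment.

    Exactly one tier fires; the tier used and the resulting ctDNA status
    (positive iff TF > 0) are recorded on the timepoint.
    """
    muts = annotate_mutations(tp, error_rate)
    positive = muts[muts["positive"]]
    if len(positive) > 0:
        tf = float(positive["vaf"].mean())
        tier = "mutation"
    elif tp.cn_signal is not None and tp.cn_signal > 0:
        tf = float(tp.cn_signal)
        tier = "copy_number"
    elif tp.fragment_signal is not None and fragment_model is not None:
        tf = max(0.0, fragment_model.predict(tp.fragment_signal))
        tier = "fragment"
    elif tp.cn_signal is not None:
        # CN assessed but negative, no fragment tier available
        tf, tier = 0.0, "copy_number"
    else:
        raise ValueError("no signal tier available for this timepoint")
    tp.tf = tf
    tp.tf_tier = tier
    tp.ctdna_status = "positive" if tf > 0 else "negative"
    return tf


def evaluate_dilution(samples, error_rate: float,
                      fragment_model: FragmentModel | None = None) -> pd.DataFrame:
    """Run the TF hierarchy on dilution replicates; returns detection flags.

    ``samples`` is an iterable with level / replicate / timepoint fields
    (as produced by a dilution-series generator).  Detection means a
    positive ctDNA status after the hierarchy.
    """
    rows = []
    for s in samples:
        tf = estimate_plasma_tf(s.timepoint, error_rate, fragment_model)
        rows.append((s.level, s.replicate, tf, tf > 0))
    return pd.DataFrame(rows, columns=["level", "replicate", "tf", "detected"])


def compute_lod(detection: pd.DataFrame, confidence: float = 0.90) -> LodResult:
    """LOD at the given confidence from per-level detection flags.

    Fits a probit of detection probability on log10(level) and inverts it
    at ``confidence``.  Degenerate inputs fall back to the lowest level
    whose empirical hit rate reaches the confidence (e.g. everything
    detected everywhere); no detections at all puts the LOD above the
    tested range.
    """
    if detection["level"].nunique() < 2:
        raise ValueError("need at least 2 dilution levels")
    rates = (
        detection.groupby("level")["detected"].mean()
        .sort_index(ascending=False)
    )
    rates.name = "hit_rate"

    if not detection["detected"].any():
        return LodResult(hit_rates=rates, lod90=None, confidence=confidence,
                         status="above_tested_range")

    def _empirical() -> LodResult:
        ok = rates[rates >= confidence]
        if ok.empty:
            return LodResult(hit_rates=rates, lod90=None, confidence=confidence,
                             status="above_tested_range")
        return LodResult(hit_rates=rates, lod90=float(ok.index.min()),
                         confidence=confidence, status="empirical")

    per_level = detection.groupby("level")["detected"].agg(["sum", "count"])
    if detection["detected"].all():
        return _empirical()

    x = sm.add_constant(np.log10(per_level.index.to_numpy(dtype=float)))
    endog = np.column_stack([
        per_level["sum"].to_numpy(dtype=float),
        (per_level["count"] - per_level["sum"]).to_numpy(dtype=float),
    ])
    try:
        with np.errstate(all="ignore"):
            fit = sm.GLM(
                endog, x,
                family=sm.families.Binomial(link=sm.families.links.Probit()),
            ).fit()
        b0, b1 = fit.params
        if not np.isfinite([b0, b1]).all() or b1 <= 0:
            return _empirical()
        z = stats.norm.ppf(confidence)
        lod = 10 ** ((z - b0) / b1)
    except Exception:
        return _empirical()
    return LodResult(hit_rates=rates, lod90=float(lod), confidence=confidence,
                     status="fitted", model=fit)


def classify_molecular_response(baseline_tf: float,
                                on_tx_tf: float) -> MolecularResponse:
    """Responder iff ctDNA decreased by strictly more than 50% from baseline.

    An exact 50% decrease is a non-responder; a ctDNA-negative baseline is
    not classifiable.
    """
    if baseline_tf <= 0:
        raise ValueError("baseline ctDNA-negative, not classifiable")
    if on_tx_tf < 0:
        raise ValueError("on-treatment TF must be >= 0")
    pct = (on_tx_tf - baseline_tf) / baseline_tf * 100.0
    responder = -pct > RESPONSE_DECREASE_PCT
    return MolecularResponse(
        baseline_tf=baseline_tf, on_treatment_tf=on_tx_tf,
        percent_change=pct,
        classification="responder" if responder else "non_responder",
    )


# ---------------------------------------------------------------------------
# Survival statistics
# ---------------------------------------------------------------------------

@dataclass
class KmCurve:
    fitter: KaplanMeierFitter
    median: float

    def survival_at(self, t: float) -> float:
        return float(self.fitter.predict(t))


def km_curve(times, events) -> KmCurve:
    """Kaplan-Meier product-limit estimate with right censoring."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    return KmCurve(fitter=kmf, median=float(kmf.median_survival_time_))


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p_logrank: float
    p_wald: float


def cox_hr(times, events, groups) -> CoxResult:
    """Cox proportional-hazards HR of group 1 vs group 0 (Efron ties),
    with a two-sided log-rank test."""
    df = pd.DataFrame({
        "time": np.asarray(times, dtype=float),
        "event": np.asarray(events, dtype=int),
        "group": np.asarray(groups, dtype=int),
    })
    if df["group"].nunique() != 2:
        raise ValueError("need exactly two groups")
    if df.groupby("group")["event"].sum().eq(0).all():
        raise ValueError("no events in either group")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")  # Efron tie handling
    summary = cph.summary.loc["group"]
    lr = logrank_test(
        df.loc[df["group"] == 1, "time"], df.loc[df["group"] == 0, "time"],
        df.loc[df["group"] == 1, "event"], df.loc[df["group"] == 0, "event"],
    )
    return CoxResult(
        hr=float(summary["exp(coef)"]),
        ci_low=float(summary["exp(coef) lower 95%"]),
        ci_high=float(summary["exp(coef) upper 95%"]),
        p_logrank=float(lr.p_value),
        p_wald=float(summary["p"]),
    )
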