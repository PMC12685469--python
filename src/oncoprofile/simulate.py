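"""Synthetic-data generators with recorded ground truth.

Every input table the pipeline consumes can be produced here: targeted-panel
probe coverage ratios and heterozygous-SNP allele counts for a tumor of
known tumor fraction (TF) and copy-number events, shallow-WGS bin counts
with chromosome/arm-level gains and losses, RNA/DNA fusion evidence tables,
multi-class expression cohorts with class-informative genes, and serial
plasma draws (tracked-mutation read counts plus copy-number and
fragment-length scalar signals).  Each generator returns a
:class:`TruthRecord` so downstream estimates can be scored against the
simulated truth.

Model conventions
-----------------
* Coverage ratio of a region at true total copy number ``c`` and tumor
  fraction ``tf``: ``E[ratio] = (tf*c + 2*(1-tf)) / 2`` (diploid normal
  admixture; 1.0 = diploid).
* Heterozygous-SNP alt counts are binomial around the allele balance implied
  by the event's (total, minor) copy configuration and ``tf``.
* Counts (sWGS bins, amplicon depths) are gamma-scaled Poisson, i.e.
  negative binomial with variance ``mu + dispersion * mu**2``.
* Expression is log-normal per gene, with informative genes shifted by a
  fixed log2 fold change in exactly one class, then Poisson-sampled.
* Tracked plasma mutations follow the operational convention that the
  expected VAF equals the tumor fraction (``vaf_equals_tf=True``); the
  heterozygous-mutation convention ``VAF = TF/2`` is available via the
  switch.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .ctdna import PlasmaTimepoint
from .too import ExpressionCohort

__all__ = [
    "CnvEvent",
    "TruthRecord",
    "DilutionSample",
    "gen_tumor_coverage",
    "gen_swgs_bins",
    "gen_expression_cohort",
    "bayes_oracle_predictions",
    "gen_fusion_tables",
    "gen_plasma_series",
    "gen_dilution_series",
]

# Cancer-type vocabulary for simulated tissue-of-origin cohorts (TCGA codes).
TISSUE_CLASSES = [
    "LUAD", "BRCA", "COAD", "PRAD", "STAD", "LIHC", "KIRC", "THCA",
    "BLCA", "HNSC", "OV", "PAAD", "GBM", "SKCM", "UCEC", "ESCA",
    "CESC", "SARC", "LGG", "LAML", "READ", "TGCT", "THYM", "KIRP",
    "LUSC", "MESO", "UVM", "ACC", "KICH", "UCS", "DLBC", "CHOL",
]


def _check_seed(seed: int) -> np.random.Generator:
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    return np.random.default_rng(int(seed))


def _nbinom(rng: np.random.Generator, mean, dispersion: float):
    """Negative-binomial draws with var = mean + dispersion*mean**2.

    dispersion = 0 degrades gracefully to Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


@dataclass(frozen=True)
class CnvEvent:
    """A copy-number event on a named panel gene region.

    ``minor_cn`` is the copy number of the less abundant haplotype; when
    omitted it defaults to the maximally informative configuration: 0 when
    total_cn <= 1 and 1 otherwise (single-haplotype gains/losses).
    """

    region: str
    total_cn: int
    minor_cn: int | None = None

    def __post_init__(self) -> None:
        if self.total_cn < 0:
            raise ValueError("total_cn must be >= 0")
        minor = self.resolved_minor
        if minor < 0 or minor > self.total_cn - minor:
            raise ValueError("minor_cn must satisfy 0 <= minor <= total - minor")

    @property
    def resolved_minor(self) -> int:
        if self.minor_cn is not None:
            return self.minor_cn
        return 0 if self.total_cn <= 1 else 1


@dataclass
class TruthRecord:
    """Ground truth carried alongside every generated dataset."""

    tumor_fraction: float | None = None
    cnv_events: list = field(default_factory=list)
    sv_events: list = field(default_factory=list)
    fusions: list = field(default_factory=list)
    tissue_label: object = None
    informative_genes: dict = field(default_factory=dict)
    plasma_tf_trajectory: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tumor_fraction is not None and not 0 <= self.tumor_fraction <= 1:
            raise ValueError("tumor_fraction must lie in [0, 1]")
        for _, tf in self.plasma_tf_trajectory:
            if not 0 <= tf <= 1:
                raise ValueError("trajectory TFs must lie in [0, 1]")


def expected_ratio(total_cn: float, tf: float) -> float:
    """Expected tumor/normal coverage ratio of a region at copy ``total_cn``."""
    return (tf * total_cn + 2.0 * (1.0 - tf)) / 2.0


# ---------------------------------------------------------------------------
# Targeted-panel coverage + heterozygous SNPs
# ---------------------------------------------------------------------------

def gen_tumor_coverage(
    spec: GenomeSpec,
    tf: float,
    cnv_events: Sequence[CnvEvent] = (),
    depth: float = 150.0,
    noise_cv: float = 0.08,
    n_snps_per_region: int = 50,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Simulate per-probe coverage ratios and het-SNP allele counts.

    Parameters
    ----------
    tf
        Tumor fraction in (0, 1].
    cnv_events
        Non-overlapping :class:`CnvEvent` entries on panel genes.
    depth
        Mean read depth at a diploid heterozygous SNP; SNP depth scales
        with the local coverage ratio.
    noise_cv
        Coefficient of variation of the multiplicative (gamma) probe noise.

    Returns
    -------
    (probe_ratios, snp_alleles, truth)
        ``probe_ratios``: probe, gene, chrom, start, end, ratio.
        ``snp_alleles``: site, region, ref_count, alt_count.
    """
    if not 0 < tf <= 1:
        raise ValueError("tf must lie in (0, 1]")
    events = list(cnv_events)
    seen: set[str] = set()
    for ev in events:
        if ev.region not in spec.gene_regions:
            raise ValueError(f"event region {ev.region!r} is not a panel gene")
        if ev.region in seen:
            raise ValueError(f"overlapping/duplicate events on {ev.region!r}")
        seen.add(ev.region)
    rng = _check_seed(seed)
    cn_by_gene = {ev.region: ev for ev in events}

    probe_rows = []
    snp_rows = []
    for gene, region in spec.gene_regions.items():
        ev = cn_by_gene.get(gene)
        total = ev.total_cn if ev is not None else 2
        minor = ev.resolved_minor if ev is not None else 1
        r = expected_ratio(total, tf)

        # Probe ratios: gamma multiplicative noise, mean r, CV = noise_cv.
        n_probes = region.probe_count
        positions = np.linspace(region.start, region.end, n_probes, dtype=int)
        if noise_cv > 0 and r > 0:
            shape = 1.0 / noise_cv**2
            ratios = rng.gamma(shape, r / shape, size=n_probes)
        else:
            ratios = np.full(n_probes, r)
        for i in range(n_probes):
            probe_rows.append(
                (f"{gene}_p{i}", gene, region.chrom, int(positions[i]),
                 int(positions[i]) + 120, float(ratios[i]))
            )

        # Het SNPs: depth follows the coverage ratio, alt fraction follows
        # the allele balance implied by (total, minor, tf).  The alt allele
        # sits on either haplotype with equal probability.
        tumor_cov = tf * total + 2.0 * (1.0 - tf)
        snp_depths = rng.poisson(depth * r, size=n_snps_per_region)
        alt_on_minor = rng.random(n_snps_per_region) < 0.5
        for j in range(n_snps_per_region):
            d = int(snp_depths[j])
            if d == 0:
                continue
            alt_copies = minor if alt_on_minor[j] else total - minor
            p_alt = (tf * alt_copies + (1.0 - tf)) / tumor_cov if tumor_cov > 0 else 0.5
            alt = int(rng.binomial(d, p_alt))
            snp_rows.append((f"{gene}_s{j}", gene, d - alt, alt))

    probes = pd.DataFrame(
        probe_rows, columns=["probe", "gene", "chrom", "start", "end", "ratio"]
    )
    snps = pd.DataFrame(snp_rows, columns=["site", "region", "ref_count", "alt_count"])
    truth = TruthRecord(
        tumor_fraction=tf,
        cnv_events=[(ev.region, ev.total_cn) for ev in events],
        extras={"events": events},
    )
    return probes, snps, truth


# ---------------------------------------------------------------------------
# Shallow-WGS bins
# ---------------------------------------------------------------------------

_SV_COPY = {"gain": 3, "loss": 1}


def _arm_mask(spec: GenomeSpec, chrom: str, n_bins: int, arm: str | None) -> slice:
    # Toy chromosomes carry no centromere annotation; the p arm is taken as
    # the first 40% of bins, the q arm the remainder.
    if arm is None:
        return slice(0, n_bins)
    split = max(1, int(round(0.4 * n_bins)))
    return slice(0, split) if arm == "p" else slice(split, n_bins)


def gen_swgs_bins(
    spec: GenomeSpec,
    chrom_events: Sequence[tuple[str, str]] = (),
    depth: float = 100.0,
    dispersion: float = 0.02,
    tf: float = 1.0,
    seed: int = 0,
    sex: str = "female",
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate genome-ordered sWGS bin counts with chromosome/arm events.

    ``chrom_events`` entries are ``(target, kind)`` where target is a
    chromosome name optionally suffixed with an arm ('chr10', 'chr9p') and
    kind is 'gain' (3 copies) or 'loss' (1 copy).  Counts are negative
    binomial around ``depth`` scaled by the admixed copy state.
    """
    if not 0 < tf <= 1:
        raise ValueError("tf must lie in (0, 1]")
    rng = _check_seed(seed)

    parsed = []
    for target, kind in chrom_events:
        if kind not in _SV_COPY:
            raise ValueError(f"unknown event kind {kind!r}")
        arm = None
        chrom = target
        if target.endswith(("p", "q")) and target not in spec.chromosomes:
            chrom, arm = target[:-1], target[-1]
        if chrom not in spec.chromosomes:
            raise ValueError(f"unknown chromosome {target!r}")
        parsed.append((chrom, arm, kind))

    rows = []
    for chrom, length in spec.chromosomes.items():
        n = spec.n_bins(chrom)
        mult = np.ones(n)
        if sex == "male" and chrom in spec.sex_chromosomes:
            mult[:] = 0.5
        elif sex == "female" and chrom == "chrY":
            mult[:] = 0.02  # mismapped background only
        for echrom, arm, kind in parsed:
            if echrom == chrom:
                mult[_arm_mask(spec, chrom, n, arm)] = expected_ratio(_SV_COPY[kind], tf)
        counts = _nbinom(rng, depth * mult, dispersion)
        for i in range(n):
            rows.append((chrom, i * spec.bin_size, (i + 1) * spec.bin_size, int(counts[i])))

    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
    truth = TruthRecord(
        tumor_fraction=tf,
        sv_events=[(f"{c}{a or ''}", k) for c, a, k in parsed],
    )
    return bins, truth


# ---------------------------------------------------------------------------
# Expression cohorts for tissue-of-origin
# ---------------------------------------------------------------------------

def gen_expression_cohort(
    n_classes: int = 5,
    n_per_class: int = 50,
    n_genes: int = 200,
    n_informative: int = 40,
    effect_log2fc: float = 4.0,
    seed: int = 0,
    base_log2_range: tuple[float, float] = (3.0, 9.0),
    sigma_log2: float = 0.7,
) -> tuple[ExpressionCohort, TruthRecord]:
    """Simulate a gene x sample count matrix with class-informative genes.

    Each informative gene is up-shifted by ``effect_log2fc`` in exactly one
    class (assigned round-robin); all other genes are class-independent.
    Per-gene log2 means are uniform over ``base_log2_range`` and per-sample
    log2 expression is normal with sd ``sigma_log2`` before Poisson count
    sampling.  Gene lengths (500-5000 bp) are recorded for FPKM.
    """
    if n_informative > n_genes:
        raise ValueError("n_informative must not exceed n_genes")
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    if not 2 <= n_classes <= len(TISSUE_CLASSES):
        raise ValueError(f"n_classes must lie in [2, {len(TISSUE_CLASSES)}]")
    rng = _check_seed(seed)

    classes = TISSUE_CLASSES[:n_classes]
    labels = np.repeat(classes, n_per_class)
    n_samples = n_classes * n_per_class

    genes = [f"gene_{g:04d}" for g in range(n_genes)]
    base = rng.uniform(*base_log2_range, size=n_genes)
    lengths = rng.integers(500, 5001, size=n_genes)

    info_class = {}
    mu = np.tile(base[:, None], (1, n_samples))
    if effect_log2fc != 0:
        for g in range(n_informative):
            cls = classes[g % n_classes]
            info_class[genes[g]] = cls
            mu[g, labels == cls] += effect_log2fc

    log2_expr = rng.normal(mu, sigma_log2)
    counts = rng.poisson(np.exp2(log2_expr))

    samples = [f"S{i:04d}" for i in range(n_samples)]
    cohort = ExpressionCohort(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        gene_lengths=pd.Series(lengths, index=genes, name="length"),
        labels=pd.Series(labels, index=samples, name="label"),
    )
    truth = TruthRecord(
        tissue_label=pd.Series(labels, index=samples),
        informative_genes=info_class,
        extras={"base_log2": dict(zip(genes, base)), "sigma_log2": sigma_log2,
                "effect_log2fc": effect_log2fc},
    )
    return cohort, truth


def bayes_oracle_predictions(cohort: ExpressionCohort, truth: TruthRecord) -> pd.Series:
    """Bayes-rule class assignment using the generator's own parameters.

    Scores each sample under the true Gaussian log2-expression model of
    every class (known per-gene means, shifts and sigma) and returns the
    argmax class.  This is the separability oracle for a simulated cohort:
    no trained classifier can systematically beat it.
    """
    sigma = truth.extras["sigma_log2"]
    effect = truth.extras["effect_log2fc"]
    base = pd.Series(truth.extras["base_log2"])
    classes = sorted(set(truth.tissue_label))
    x = np.log2(cohort.counts.clip(lower=1)).T  # samples x genes
    base_vec = base[cohort.counts.index].to_numpy()

    scores = {}
    for cls in classes:
        mu = np.tile(base_vec, (x.shape[0], 1))
        for gene, g_cls in truth.informative_genes.items():
            if g_cls == cls:
                mu[:, cohort.counts.index.get_loc(gene)] += effect
        scores[cls] = -(((x.to_numpy() - mu) / sigma) ** 2).sum(axis=1)
    score_df = pd.DataFrame(scores, index=x.index)
    return score_df.idxmax(axis=1)


# ---------------------------------------------------------------------------
# Fusion evidence tables
# ---------------------------------------------------------------------------

_FUSION_PARTNERS = [
    ("EML4", "ALK"), ("KIF5B", "RET"), ("CD74", "ROS1"), ("SDC4", "ROS1"),
    ("TPM3", "NTRK1"), ("ETV6", "NTRK3"), ("FGFR3", "TACC3"), ("MET", "MET"),
    ("SLC34A2", "ROS1"), ("CCDC6", "RET"),
]


def gen_fusion_tables(
    n_events: int = 8,
    prevalence: float = 0.5,
    coverage_rate: float = 0.8,
    rna_mean_reads: float = 40.0,
    dna_mean_reads: float = 8.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Simulate paired RNA junction and DNA breakpoint read tables.

    Each candidate event is truly present with probability ``prevalence``;
    present events draw negative-binomial supporting reads in both assays,
    absent events draw sparse Poisson background (mean 0.2).  A fraction
    ``coverage_rate`` of breakpoints falls inside the DNA panel design.
    """
    if not 1 <= n_events <= len(_FUSION_PARTNERS):
        raise ValueError(f"n_events must lie in [1, {len(_FUSION_PARTNERS)}]")
    rng = _check_seed(seed)
    rows_rna, rows_dna, fusions = [], [], []
    for i in range(n_events):
        g5, g3 = _FUSION_PARTNERS[i]
        present = bool(rng.random() < prevalence)
        covered = bool(rng.random() < coverage_rate)
        rna_reads = int(_nbinom(rng, rna_mean_reads, 0.3)) if present else int(rng.poisson(0.2))
        dna_reads = int(_nbinom(rng, dna_mean_reads, 0.3)) if present else int(rng.poisson(0.2))
        rows_rna.append((g5, g3, 100 + i, 200 + i, rna_reads))
        rows_dna.append((g5, g3, 100 + i, 200 + i, dna_reads, covered))
        fusions.append((g5, g3, present))
    rna = pd.DataFrame(rows_rna, columns=["gene5", "gene3", "breakpoint5", "breakpoint3", "reads"])
    dna = pd.DataFrame(
        rows_dna,
        columns=["gene5", "gene3", "breakpoint5", "breakpoint3", "reads", "panel_covered"],
    )
    return rna, dna, TruthRecord(fusions=fusions)


# ---------------------------------------------------------------------------
# Plasma ctDNA series and dilutions
# ---------------------------------------------------------------------------

def gen_plasma_series(
    truth_tf: Sequence[tuple[float, float]],
    n_tracked_mutations: int = 8,
    depth: float = 100_000,
    error_rate: float = 5e-5,
    seed: int = 0,
    vaf_equals_tf: bool = True,
    cn_detection_limit: float = 0.03,
    cn_noise_sd: float = 0.005,
    frag_slope: float = 2.0,
    frag_intercept: float = 0.01,
    frag_noise_sd: float = 0.002,
) -> tuple[list[PlasmaTimepoint], TruthRecord]:
    """Simulate serial plasma draws for a known TF trajectory.

    Per tracked site, alt reads are binomial with success probability
    ``TF + error_rate`` (or ``TF/2 + error_rate`` when ``vaf_equals_tf`` is
    off) at Poisson-jittered amplicon depth.  The copy-number scalar mimics
    an ichorCNA readout: TF plus noise, reported as 0 below its detection
    limit.  The fragment-length scalar is linear in TF with Gaussian noise.
    """
    if not 4 <= n_tracked_mutations <= 10:
        raise ValueError("n_tracked_mutations must lie in [4, 10]")
    if not 0 <= error_rate < 1e-3:
        raise ValueError("error_rate must lie in [0, 1e-3)")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = _check_seed(seed)

    series = []
    for timepoint, tf in truth_tf:
        if not 0 <= tf <= 1:
            raise ValueError("trajectory TFs must lie in [0, 1]")
        p = min(1.0, (tf if vaf_equals_tf else tf / 2.0) + error_rate)
        depths = np.maximum(1, rng.poisson(depth, size=n_tracked_mutations))
        alts = rng.binomial(depths, p)
        muts = pd.DataFrame({
            "site": [f"mut_{i}" for i in range(n_tracked_mutations)],
            "depth": depths.astype(int),
            "alt_reads": alts.astype(int),
            "origin": "tumor_informed",
        })
        cn_raw = tf + rng.normal(0.0, cn_noise_sd)
        cn_signal = float(cn_raw) if cn_raw >= cn_detection_limit else 0.0
        frag = float(frag_slope * tf + frag_intercept + rng.normal(0.0, frag_noise_sd))
        series.append(PlasmaTimepoint(
            timepoint=timepoint, mutations=muts,
            cn_signal=cn_signal, fragment_signal=frag,
        ))
    truth = TruthRecord(
        plasma_tf_trajectory=list(truth_tf),
        extras={
            "error_rate": error_rate, "depth": depth,
            "vaf_equals_tf": vaf_equals_tf,
            "frag_slope": frag_slope, "frag_intercept": frag_intercept,
        },
    )
    return series, truth


@dataclass
class DilutionSample:
    level: float
    replicate: int
    timepoint: PlasmaTimepoint


def gen_dilution_series(
    base_tf: float = 0.005,
    levels: Sequence[float] = (0.001, 0.0005, 0.00025, 0.0001),
    replicates: int = 3,
    depth: float = 100_000,
    error_rate: float = 5e-5,
    seed: int = 0,
    **plasma_kwargs,
) -> tuple[list[DilutionSample], TruthRecord]:
    """Serially dilute a base sample and simulate each replicate.

    Defaults mirror a 0.5% TF sample diluted to 0.1%, 0.05%, 0.025% and
    0.01%, analysed in triplicate (4 levels x 3 replicates = 12 draws).
    """
    levels = list(levels)
    if not levels:
        raise ValueError("levels must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if any(lv > base_tf for lv in levels):
        raise ValueError("dilution levels must not exceed base_tf")
    if any(b >= a for a, b in zip(levels, levels[1:])):
        raise ValueError("levels must be strictly descending")

    rng = _check_seed(seed)
    samples = []
    for level in levels:
        for rep in range(replicates):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            (tp,), _ = gen_plasma_series(
                [(0.0, level)], depth=depth, error_rate=error_rate,
                seed=sub_seed, **plasma_kwargs,
            )
            samples.append(DilutionSample(level=level, replicate=rep, timepoint=tp))
    truth = TruthRecord(extras={"base_tf": base_tf, "levels": levels,
                                "replicates": replicates})
    return samples, truth
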