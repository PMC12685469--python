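"""Fusion calling from RNA junction reads and DNA breakpoint reads.

RNA calls require >= 5 junction-supporting reads for inter-gene fusions and
strictly more than 10 reads for intra-gene exon-skipping events (gene5 ==
gene3, e.g. MET exon 14).  DNA calls require >= 2 reads at a breakpoint that
the panel design actually covers; breakpoints outside the design are *not
assessable* rather than negative.  RNA samples are gated by library QC
(total reads, insert size, coverage uniformity); DV200 is recorded for
reporting but is deliberately not a gate.  Integration is a union with
provenance: an event is positive when positive in any assessable source,
which is what makes the combined assay strictly at least as sensitive as
either alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "RnaQc",
    "FusionEvidence",
    "QcFailedError",
    "rna_sample_qc",
    "call_fusions_rna",
    "call_fusions_dna",
    "combine_fusion_results",
]

RNA_FUSION_MIN_READS = 5        # inclusive
EXON_SKIP_MIN_READS = 10        # exclusive: positive strictly above 10
DNA_FUSION_MIN_READS = 2        # inclusive
QC_MIN_TOTAL_READS = 30_000_000  # fail at <= 30 M (inclusive)
QC_MIN_MEDIAN_INSERT = 100       # fail strictly below 100 bp
QC_MAX_COVERAGE_CV = 1.0         # fail strictly above 1


class QcFailedError(RuntimeError):
    """RNA fusion calling refused on a QC-failed library."""


@dataclass
class RnaQc:
    total_reads: int
    median_insert: float
    coverage_cv: float
    dv200: float | None = None   # reported, never a gate
    verdict: str = "pass"

    def __post_init__(self) -> None:
        if min(self.total_reads, self.median_insert, self.coverage_cv) < 0:
            raise ValueError("QC metrics must be non-negative")


@dataclass
class FusionEvidence:
    gene5: str
    gene3: str
    junction_reads: int
    source: str                     # 'RNA' | 'DNA' | 'RNA+DNA'
    call: str                       # 'positive' | 'negative' | 'not_assessable'
    panel_covered: bool | None = None  # DNA only
    intragenic: bool = False
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.junction_reads < 0:
            raise ValueError("junction_reads must be >= 0")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)


def rna_sample_qc(total_reads: int, median_insert: float, coverage_cv: float,
                  dv200: float | None = None) -> RnaQc:
    """QC verdict: fail iff reads <= 30 M, insert < 100 bp, or CV > 1."""
    qc = RnaQc(total_reads=total_reads, median_insert=median_insert,
               coverage_cv=coverage_cv, dv200=dv200)
    failed = (
        total_reads <= QC_MIN_TOTAL_READS
        or median_insert < QC_MIN_MEDIAN_INSERT
        or coverage_cv > QC_MAX_COVERAGE_CV
    )
    qc.verdict = "fail" if failed else "pass"
    return qc


def call_fusions_rna(junctions: pd.DataFrame, qc: RnaQc) -> list[FusionEvidence]:
    """Call fusions from an RNA junction table (gene5, gene3, reads).

    Refuses to run on a QC-failed sample: degraded libraries produce
    unreliable junction counts in both directions.
    """
    if qc.verdict != "pass":
        raise QcFailedError("RNA sample failed QC; fusion calls would be unreliable")
    out = []
    for _, row in junctions.iterrows():
        intra = row["gene5"] == row["gene3"]
        reads = int(row["reads"])
        if intra:
            positive = reads > EXON_SKIP_MIN_READS
        else:
            positive = reads >= RNA_FUSION_MIN_READS
        out.append(FusionEvidence(
            gene5=row["gene5"], gene3=row["gene3"], junction_reads=reads,
            source="RNA", call="positive" if positive else "negative",
            intragenic=intra,
        ))
    return out


def call_fusions_dna(breakpoints: pd.DataFrame,
                     panel: set[tuple[str, str]] | None = None) -> list[FusionEvidence]:
    """Call fusions from a DNA breakpoint table.

    Coverage comes either from a ``panel_covered`` column or from a set of
    covered (gene5, gene3) pairs.  Uncovered breakpoints are not assessable
    regardless of read support.
    """
    out = []
    for _, row in breakpoints.iterrows():
        if "panel_covered" in row.index:
            covered = bool(row["panel_covered"])
        elif panel is not None:
            covered = (row["gene5"], row["gene3"]) in panel
        else:
            raise ValueError("no panel coverage information provided")
        reads = int(row["reads"])
        if not covered:
            call = "not_assessable"
        else:
            call = "positive" if reads >= DNA_FUSION_MIN_READS else "negative"
        out.append(FusionEvidence(
            gene5=row["gene5"], gene3=row["gene3"], junction_reads=reads,
            source="DNA", call=call, panel_covered=covered,
            intragenic=row["gene5"] == row["gene3"],
        ))
    return out


def combine_fusion_results(
    dna: list[FusionEvidence],
    rna: list[FusionEvidence],
    rna_qc: RnaQc | None = None,
) -> list[FusionEvidence]:
    """Union-with-provenance integration of DNA and RNA fusion calls.

    An event is positive when positive in either assessable source; the
    reporting source records where the evidence came from.  When the RNA
    library failed QC the result is DNA-only and every event carries an
    'RNA not assessable' flag.
    """
    rna_usable = rna_qc is None or rna_qc.verdict == "pass"
    merged: dict[tuple[str, str], FusionEvidence] = {}
    for ev in dna:
        merged[ev.key] = FusionEvidence(
            gene5=ev.gene5, gene3=ev.gene3, junction_reads=ev.junction_reads,
            source="DNA", call=ev.call, panel_covered=ev.panel_covered,
            intragenic=ev.intragenic, flags=list(ev.flags),
        )
    if rna_usable:
        for ev in rna:
            if ev.key in merged:
                cur = merged[ev.key]
                if ev.call == "positive":
                    if cur.call == "positive":
                        cur.source = "RNA+DNA"
                    else:
                        cur.call = "positive"
                        cur.source = "RNA"
                cur.junction_reads = max(cur.junction_reads, ev.junction_reads)
            else:
                merged[ev.key] = FusionEvidence(
                    gene5=ev.gene5, gene3=ev.gene3,
                    junction_reads=ev.junction_reads, source="RNA",
                    call=ev.call, intragenic=ev.intragenic, flags=list(ev.flags),
                )
    else:
        for ev in merged.values():
            ev.flags.append("RNA not assessable")
    return list(merged.values())
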