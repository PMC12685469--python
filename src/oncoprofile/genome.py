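"""Genome layout shared by the simulators and callers.

A :class:`GenomeSpec` describes the coordinate system everything else works
in: ordered chromosomes, a fixed bin tiling for shallow whole-genome
sequencing (sWGS), and the gene regions covered by the targeted panel.  The
default :func:`toy_genome` is a 1/1000-scale replica of hg38 so that
full-genome simulations run in well under a second while keeping realistic
relative chromosome sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["GeneRegion", "GenomeSpec", "toy_genome"]

# hg38 chromosome lengths in bp (GRCh38.p14 primary assembly).
_HG38_LENGTHS = {
    "chr1": 248_956_422,
    "chr2": 242_193_529,
    "chr3": 198_295_559,
    "chr4": 190_214_555,
    "chr5": 181_538_259,
    "chr6": 170_805_979,
    "chr7": 159_345_973,
    "chr8": 145_138_636,
    "chr9": 138_394_717,
    "chr10": 133_797_422,
    "chr11": 135_086_622,
    "chr12": 133_275_309,
    "chr13": 114_364_328,
    "chr14": 107_043_718,
    "chr15": 101_991_189,
    "chr16": 90_338_345,
    "chr17": 83_257_441,
    "chr18": 80_373_285,
    "chr19": 58_617_616,
    "chr20": 64_444_167,
    "chr21": 46_709_983,
    "chr22": 50_818_468,
    "chrX": 156_040_895,
    "chrY": 57_227_415,
}

# Approximate hg38 start coordinates of a small panel of cancer genes that
# matter for the worked examples (amplification targets, MTAP-CDKN2A
# deletion, BRCA1/2, fusion partners).  Scaled along with the genome.
_PANEL_GENES = {
    # gene: (chrom, start, end)
    "ALK": ("chr2", 29_190_000, 29_920_000),
    "EGFR": ("chr7", 55_020_000, 55_210_000),
    "MET": ("chr7", 116_670_000, 116_800_000),
    "MYC": ("chr8", 127_730_000, 127_740_000),
    "MTAP": ("chr9", 21_800_000, 21_940_000),
    "CDKN2A": ("chr9", 21_960_000, 21_995_000),
    "PTEN": ("chr10", 87_860_000, 87_970_000),
    "KRAS": ("chr12", 25_200_000, 25_250_000),
    "BRCA2": ("chr13", 32_310_000, 32_400_000),
    "TP53": ("chr17", 7_660_000, 7_690_000),
    "ERBB2": ("chr17", 39_680_000, 39_730_000),
    "BRCA1": ("chr17", 43_040_000, 43_130_000),
}


@dataclass(frozen=True)
class GeneRegion:
    """A targeted-panel gene region with its probe density."""

    chrom: str
    start: int
    end: int
    probe_count: int = 30

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("gene region end must exceed start")
        if self.probe_count < 1:
            raise ValueError("probe_count must be >= 1")


@dataclass
class GenomeSpec:
    """Ordered chromosomes, sWGS bin tiling and targeted gene regions.

    Parameters
    ----------
    chromosomes
        Ordered mapping chromosome name -> length in bp.
    bin_size
        sWGS bin width in bp; bins tile each chromosome, the last
        (partial) bin of a chromosome is dropped.
    gene_regions
        Mapping gene name -> :class:`GeneRegion`; regions must lie within
        their chromosome.
    sex_chromosomes
        Names excluded from genome-median normalisation.
    scale
        Linear scale relative to the full human genome (1.0 = full size).
        Length-based rules elsewhere (e.g. the 10 Mb segment floor of the
        instability score) are multiplied by this.
    """

    chromosomes: dict[str, int]
    bin_size: int = 1_000_000
    gene_regions: dict[str, GeneRegion] = field(default_factory=dict)
    sex_chromosomes: frozenset[str] = frozenset({"chrX", "chrY"})
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be positive")
        for name, region in self.gene_regions.items():
            if region.chrom not in self.chromosomes:
                raise ValueError(f"gene {name} on unknown chromosome {region.chrom}")
            if region.end > self.chromosomes[region.chrom]:
                raise ValueError(f"gene {name} extends past the end of {region.chrom}")

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chromosomes if c not in self.sex_chromosomes]

    def n_bins(self, chrom: str) -> int:
        return self.chromosomes[chrom] // self.bin_size

    def bins(self, include_sex: bool = True):
        """Yield (chrom, start, end) for every full bin, genome order."""
        for chrom, length in self.chromosomes.items():
            if not include_sex and chrom in self.sex_chromosomes:
                continue
            for i in range(length // self.bin_size):
                yield chrom, i * self.bin_size, (i + 1) * self.bin_size


def toy_genome(bin_size: int = 2_000, probe_count: int = 30) -> GenomeSpec:
    """A 1/1000-scale hg38: 22 autosomes + X/Y with proportional lengths.

    With the default 2 kb bins the genome holds ~1,550 bins (roughly the
    resolution of 2 Mb bins on the real genome), so arm-level events span
    tens of bins and Monte-Carlo loops over hundreds of genomes stay cheap.
    """
    scale = 1 / 1000
    chroms = {name: int(length * scale) for name, length in _HG38_LENGTHS.items()}
    genes = {
        name: GeneRegion(chrom, int(s * scale), int(e * scale), probe_count)
        for name, (chrom, s, e) in _PANEL_GENES.items()
    }
    return GenomeSpec(
        chromosomes=chroms,
        bin_size=bin_size,
        gene_regions=genes,
        scale=scale,
    )
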