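"""Synthetic inputs with known ground truth for every stage of the pipeline.

Three generators:

* windowed depth tracks over a diploid genome carrying duplicated segments at
  the copy number implied by a chosen genotype (Poisson counts by default,
  negative binomial when overdispersion is requested);
* haplotype sequences with primer annealing sites planted at spacings chosen
  to yield configured amplicon sizes, as templates for in-silico PCR;
* Hardy–Weinberg population samples at given allele frequencies, with
  optional dominant-marker masking (hom/het collapsed to "positive") the way
  a presence/absence band assay reports them.

Coverage structure emulates ~26X short-read data summarised in 10 kbp
windows.  GC/mappability bias is deliberately not simulated: standardization
by the median window depth removes global scale anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .depth_genotyper import WindowDepthTrack
from .genome_model import (
    WILDTYPE,
    DiploidGenotype,
    GenomicRegion,
    TranslocationAlleleModel,
    expected_depth_ratio,
)

__all__ = [
    "DepthSimConfig",
    "PopulationSimConfig",
    "PrimerPlant",
    "simulate_depth_track",
    "simulate_haplotype",
    "simulate_population",
    "fixture_primer_pairs",
    "make_allele_templates",
]

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class DepthSimConfig:
    """Parameters of the window-count simulator.

    ``mean_depth`` is the per-window expected count at diploid copy number
    (the study animals average 26X); ``dispersion`` is the negative-binomial
    overdispersion ``alpha`` in ``var = m + alpha * m**2`` (0 = Poisson).
    ``n_background_windows`` diploid windows on a separate background contig
    anchor the genome-wide median.
    """

    window_size: int = 10_000
    mean_depth: float = 26.0
    dispersion: float = 0.0
    n_background_windows: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_background_windows <= 0:
            raise ValueError(
                "need at least one background window (median undefined otherwise)"
            )


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    if dispersion == 0:
        return rng.poisson(mean).astype(float)
    # NB2 parameterisation: var = m + alpha m^2; gamma-Poisson mixture
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam).astype(float)


def simulate_depth_track(
    genotype: DiploidGenotype,
    models: list[TranslocationAlleleModel],
    regions: list[GenomicRegion],
    config: DepthSimConfig = DepthSimConfig(),
) -> WindowDepthTrack:
    """Simulate a windowed depth track for one animal of known genotype.

    Windows tiling each region of interest draw counts with mean
    ``mean_depth × expected_depth_ratio``; background windows use ratio 1.0.
    Identical genotype/config/seed give bit-identical tracks.
    """
    rng = np.random.default_rng(config.seed)
    frames: list[pd.DataFrame] = []

    bg_start = np.arange(config.n_background_windows) * config.window_size
    frames.append(
        pd.DataFrame(
            {
                "chrom": "background",
                "start": bg_start,
                "end": bg_start + config.window_size,
                "mean": config.mean_depth,
            }
        )
    )
    for region in regions:
        ratio = expected_depth_ratio(genotype, region, models)
        starts = np.arange(region.start, region.end, config.window_size)
        ends = np.minimum(starts + config.window_size, region.end)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": region.chrom,
                    "start": starts,
                    "end": ends,
                    "mean": config.mean_depth * ratio,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df["depth"] = _draw_counts(rng, df.pop("mean").to_numpy(), config.dispersion)
    return WindowDepthTrack(df)


@dataclass(frozen=True)
class PrimerPlant:
    """A primer pair to embed in a synthetic haplotype.

    The forward primer sequence is planted verbatim at ``offset``; the
    reverse complement of the reverse primer is planted so the amplicon
    (5' end of forward through 5' end of reverse, inclusive) has length
    ``product_size``.
    """

    forward: str
    reverse: str
    offset: int
    product_size: int

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("plant offset must be >= 0")
        if self.product_size < len(self.forward) + len(self.reverse):
            raise ValueError("product_size smaller than the two primer footprints")

    @property
    def footprints(self) -> list[tuple[int, int]]:
        rev_end = self.offset + self.product_size
        return [
            (self.offset, self.offset + len(self.forward)),
            (rev_end - len(self.reverse), rev_end),
        ]


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def simulate_haplotype(
    plants: list[PrimerPlant],
    base_length: int = 2_000,
    seed: int = 0,
    mismatches: int = 0,
) -> str:
    """Random uniform-composition DNA with primer sites planted exactly.

    Raises if any footprint runs past ``base_length`` or two footprints
    overlap.  ``mismatches`` > 0 substitutes that many internal (non-3')
    bases of each planted forward site, for mismatch-tolerant matcher tests.
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(BASES, size=base_length)

    occupied: list[tuple[int, int]] = []
    for plant in plants:
        for lo, hi in plant.footprints:
            if hi > base_length:
                raise ValueError(
                    f"primer footprint [{lo}, {hi}) exceeds base_length {base_length}"
                )
            for plo, phi in occupied:
                if lo < phi and hi > plo:
                    raise ValueError(
                        f"primer footprints overlap: [{lo},{hi}) vs [{plo},{phi})"
                    )
            occupied.append((lo, hi))

    for plant in plants:
        fwd = list(plant.forward.upper())
        if mismatches:
            # never touch the 3'-terminal base: annealing requires it to match
            positions = rng.choice(len(fwd) - 1, size=mismatches, replace=False)
            for p in positions:
                others = [b for b in "ACGT" if b != fwd[p]]
                fwd[p] = others[rng.integers(len(others))]
        seq[plant.offset : plant.offset + len(fwd)] = list("".join(fwd))
        rc = _revcomp(plant.reverse.upper())
        rev_end = plant.offset + plant.product_size
        seq[rev_end - len(rc) : rev_end] = list(rc)
    return "".join(seq)


@dataclass(frozen=True)
class PopulationSimConfig:
    """Hardy–Weinberg population sample parameters.

    ``allele_freqs`` gives non-wildtype allele frequencies (remainder is
    wildtype); alleles in ``dominant_alleles`` are reported only as
    positive/negative on the observed record, the way a presence/absence
    breakpoint-PCR band reads out.
    """

    n_animals: int
    allele_freqs: dict[str, float] = field(default_factory=dict)
    dominant_alleles: frozenset[str] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals <= 0:
            raise ValueError("n_animals must be positive")
        if any(f < 0 for f in self.allele_freqs.values()):
            raise ValueError("allele frequencies must be >= 0")
        if sum(self.allele_freqs.values()) > 1 + 1e-12:
            raise ValueError("allele frequencies sum above 1")
        object.__setattr__(self, "dominant_alleles", frozenset(self.dominant_alleles))


def simulate_population(config: PopulationSimConfig) -> pd.DataFrame:
    """Draw a random-mating population sample with known true genotypes.

    Each animal's two alleles are drawn i.i.d. from the allele frequency
    vector (wildtype takes the remaining mass).  Returns one row per animal
    with the true alleles plus observed columns: ``Cs29_genotype``-style
    codominant class (hom / het / non-carrier) for each codominant allele and
    ``positive`` / ``negative`` for dominant ones.  Masking never alters the
    true allele columns, only what the observed columns reveal.
    """
    rng = np.random.default_rng(config.seed)
    names = sorted(config.allele_freqs)
    freqs = np.array([config.allele_freqs[n] for n in names])
    wt_freq = 1.0 - freqs.sum()
    choices = names + [WILDTYPE]
    probs = np.append(freqs, wt_freq)
    draws = rng.choice(len(choices), size=(config.n_animals, 2), p=probs)

    rows = []
    for i, (a, b) in enumerate(draws):
        allele_a, allele_b = choices[a], choices[b]
        genotype = DiploidGenotype.from_alleles(allele_a, allele_b)
        row: dict[str, object] = {
            "animal": f"sim{i:04d}",
            "allele_a": allele_a,
            "allele_b": allele_b,
            "true_genotype": genotype.name,
        }
        for name in names:
            count = genotype.count(name)
            if name in config.dominant_alleles:
                row[f"{name}_status"] = "positive" if count > 0 else "negative"
            else:
                row[f"{name}_genotype"] = {0: "non-carrier", 1: "het", 2: "hom"}[count]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic breakpoint-PCR fixtures
#
# The real breakpoint primer nucleotide sequences are published elsewhere and
# not bundled here; these are synthetic stand-in primers whose amplicons on
# the synthetic haplotypes below reproduce the diagnostic multiplex sizes:
# 318 bp (Cs29 junction, pair "A-E"), 394 bp (wildtype chromosome 29, pair
# "alpha-beta") and 525 bp (Cs6 junction, pair "gamma-B").


def fixture_primer_pairs() -> list["PrimerPair"]:
    """Synthetic primer pairs for the three-pair informative multiplex."""
    from .insilico_pcr import PrimerPair

    return [
        PrimerPair(
            "A-E",
            forward="ACGGTCATTGAACCTGGACT",
            reverse="TGACCAGTTCGGATACCTCA",
            expected_size=318,
            marker_for="Cs29",
        ),
        PrimerPair(
            "alpha-beta",
            forward="CCATGGTACGTTAGCCTGAT",
            reverse="GTTCACGGATTCAGCCATGA",
            expected_size=394,
            marker_for=WILDTYPE,
        ),
        PrimerPair(
            "gamma-B",
            forward="TGCCAATCGGTCATAGGACT",
            reverse="CAGTTGGCATCCGTATGACA",
            expected_size=525,
            marker_for="Cs6",
        ),
    ]


def make_allele_templates(
    seed: int = 0, base_length: int = 2_000
) -> dict[str, str]:
    """Synthetic haplotype templates per allele for in-silico PCR.

    * ``wt``   — wildtype chromosome 29: the alpha-beta site pair (394 bp).
    * ``Cs29`` — rearranged chromosome 29 with the Cs29 junction: the A-E
      site pair (318 bp); the wildtype alpha-beta spacing is disrupted.
    * ``Cs6``  — Cs6 haplotype: its own junction (gamma-B, 525 bp) plus an
      intact wildtype chromosome-29 configuration (alpha-beta, 394 bp) —
      which is what makes the Cs6 marker dominant: carriers of one or two
      Cs6 alleles show the same 394 + 525 pattern.
    """
    pairs = {p.name: p for p in fixture_primer_pairs()}
    ae, ab, gb = pairs["A-E"], pairs["alpha-beta"], pairs["gamma-B"]
    templates = {
        "wt": simulate_haplotype(
            [PrimerPlant(ab.forward, ab.reverse, 100, 394)],
            base_length=base_length,
            seed=seed + 1,
        ),
        "Cs29": simulate_haplotype(
            [PrimerPlant(ae.forward, ae.reverse, 100, 318)],
            base_length=base_length,
            seed=seed + 2,
        ),
        "Cs6": simulate_haplotype(
            [
                PrimerPlant(ab.forward, ab.reverse, 100, 394),
                PrimerPlant(gb.forward, gb.reverse, 700, 525),
            ],
            base_length=base_length,
            seed=seed + 3,
        ),
    }
    return templates


def study_allele_models(
    n_region_windows: int = 150, window_size: int = 10_000
) -> tuple[list[TranslocationAlleleModel], list[GenomicRegion]]:
    """Allele models with regions sized for simulation studies.

    Each scored region spans exactly ``n_region_windows`` windows (the
    plotted regions of interest are 1.5 Mbp, i.e. 150 windows of 10 kbp), so
    simulated tracks have a known number of in-region windows.  Region
    coordinates are arbitrary; only labels and sizes matter downstream.
    """
    from .genome_model import RegionGain

    span = n_region_windows * window_size
    kit = GenomicRegion("6", 0, span, label="chr6_KIT")
    cs6 = GenomicRegion("29", 0, span, label="chr29_Cs6")
    models = [
        TranslocationAlleleModel("Cs29", (RegionGain(kit, 1),)),
        TranslocationAlleleModel("Cs6", (RegionGain(kit, 1), RegionGain(cs6, 1))),
        TranslocationAlleleModel(WILDTYPE),
    ]
    return models, [kit, cs6]
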