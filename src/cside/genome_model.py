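"""Domain model for translocation alleles and their copy-number consequences.

The colour-sidedness alleles of cattle are structural variants: ``Cs29`` is a
translocation of a ~500 kbp chromosome-6 segment (containing *KIT*) onto
chromosome 29, so each Cs29 allele carried adds one extra copy of that
segment.  ``Cs6`` arose from the Cs29 configuration by a further translocation
back to chromosome 6 and elevates copy number of both the chromosome-6 *KIT*
segment and a chromosome-29 segment.  Against a diploid background (2 copies),
a heterozygous carrier therefore has 3 copies of a gained segment and a
homozygote 4, i.e. standardized read-depth ratios of 1.5 and 2.0.

Coordinates are 0-based half-open (BED convention) throughout; use
:meth:`GenomicRegion.display` / :meth:`GenomicRegion.from_display` for 1-based
inclusive strings.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

WILDTYPE = "wt"

__all__ = [
    "WILDTYPE",
    "GenomicRegion",
    "RegionGain",
    "TranslocationAlleleModel",
    "DiploidGenotype",
    "expected_depth_ratio",
    "copy_number_profile",
    "enumerate_genotypes",
    "default_allele_models",
    "default_regions",
]


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"region start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"region end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def key(self) -> tuple[str, int, int]:
        """Identity used to match regions between models and observations."""
        return (self.chrom, self.start, self.end)

    def contains(self, chrom: str, start: int, end: int) -> bool:
        """True if ``[start, end)`` on ``chrom`` lies fully inside this region."""
        return chrom == self.chrom and start >= self.start and end <= self.end

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and start < self.end and end > self.start

    def display(self) -> str:
        """1-based inclusive display string, e.g. ``chr6:71600001-72100000``."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    @classmethod
    def from_display(cls, text: str, label: str = "") -> "GenomicRegion":
        """Parse a 1-based inclusive ``chrom:start-end`` string."""
        m = re.fullmatch(r"([^:]+):([\d,]+)-([\d,]+)", text.strip())
        if m is None:
            raise ValueError(f"cannot parse region string {text!r}")
        start1 = int(m.group(2).replace(",", ""))
        end1 = int(m.group(3).replace(",", ""))
        return cls(m.group(1), start1 - 1, end1, label=label)


@dataclass(frozen=True)
class RegionGain:
    """Extra copies of ``region`` contributed per allele carried."""

    region: GenomicRegion
    copies_added: int = 1

    def __post_init__(self) -> None:
        if self.copies_added < 0:
            raise ValueError("copies_added must be >= 0")


@dataclass(frozen=True)
class TranslocationAlleleModel:
    """A named structural allele and the regions whose copy number it elevates.

    The wildtype allele is any model (or absent model) with no gains; by
    convention it is named :data:`WILDTYPE`.
    """

    name: str
    gained_regions: tuple[RegionGain, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("allele name must be non-empty")
        object.__setattr__(self, "gained_regions", tuple(self.gained_regions))
        if self.name == WILDTYPE and any(
            g.copies_added > 0 for g in self.gained_regions
        ):
            raise ValueError("the wildtype allele cannot gain copies")

    def copies_added_at(self, region: GenomicRegion) -> int:
        """Extra copies contributed per carried allele over ``region``.

        Regions are identified by label when both carry one (so regions read
        from a BED file join against configured allele models by name), and
        by exact coordinates otherwise.
        """
        return sum(
            g.copies_added
            for g in self.gained_regions
            if (
                g.region.label == region.label
                if g.region.label and region.label
                else g.region.key() == region.key()
            )
        )


@dataclass(frozen=True)
class DiploidGenotype:
    """An unordered pair of alleles at the colour-sidedness locus."""

    allele_counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        counts = dict(self.allele_counts)
        if any(c < 0 for c in counts.values()):
            raise ValueError("allele counts must be >= 0")
        total = sum(counts.values())
        if total != 2:
            raise ValueError(f"a diploid genotype needs 2 alleles, got {total}")
        # canonical order so equal genotypes compare equal
        object.__setattr__(
            self,
            "allele_counts",
            tuple(sorted((a, c) for a, c in counts.items() if c > 0)),
        )

    @classmethod
    def from_alleles(cls, a: str, b: str) -> "DiploidGenotype":
        counts: dict[str, int] = {}
        for allele in (a, b):
            counts[allele] = counts.get(allele, 0) + 1
        return cls(tuple(counts.items()))

    @property
    def alleles(self) -> tuple[str, str]:
        out: list[str] = []
        for name, count in self.allele_counts:
            out.extend([name] * count)
        return (out[0], out[1])

    def count(self, allele: str) -> int:
        return dict(self.allele_counts).get(allele, 0)

    @property
    def name(self) -> str:
        """Conventional slash form with non-wildtype alleles first, e.g. ``Cs29/wt``."""
        a, b = self.alleles
        ordered = sorted((a, b), key=lambda x: (x == WILDTYPE, x))
        return f"{ordered[0]}/{ordered[1]}"

    @classmethod
    def from_name(cls, name: str) -> "DiploidGenotype":
        parts = name.strip().split("/")
        if len(parts) != 2:
            raise ValueError(f"genotype name must be 'a/b', got {name!r}")
        return cls.from_alleles(parts[0], parts[1])

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def _model_index(
    models: list[TranslocationAlleleModel] | tuple[TranslocationAlleleModel, ...],
) -> dict[str, TranslocationAlleleModel]:
    index = {m.name: m for m in models}
    index.setdefault(WILDTYPE, TranslocationAlleleModel(WILDTYPE))
    return index


def expected_depth_ratio(
    genotype: DiploidGenotype,
    region: GenomicRegion,
    models: list[TranslocationAlleleModel] | tuple[TranslocationAlleleModel, ...],
) -> float:
    """Expected standardized depth-of-coverage ratio over ``region``.

    The diploid background contributes 2 copies; every carried allele adds its
    model's ``copies_added`` over the region.  The standardized ratio is total
    copies over the diploid median, ``(2 + extra) / 2``: 1.0 for non-carriers,
    1.5 for a single-gain heterozygote, 2.0 for a homozygote.
    """
    index = _model_index(models)
    extra = 0
    for allele, count in genotype.allele_counts:
        if allele not in index:
            raise KeyError(f"unknown allele {allele!r}: no model provided")
        extra += count * index[allele].copies_added_at(region)
    return (2 + extra) / 2


def copy_number_profile(
    genotype: DiploidGenotype,
    models: list[TranslocationAlleleModel] | tuple[TranslocationAlleleModel, ...],
    regions: list[GenomicRegion],
) -> dict[str, int]:
    """Total copy number per region label, ``2 + Σ count × copies_added``."""
    profile: dict[str, int] = {}
    for region in regions:
        ratio = expected_depth_ratio(genotype, region, models)
        profile[region.label or region.display()] = round(2 * ratio)
    return profile


def enumerate_genotypes(allele_names: list[str] | None = None) -> list[DiploidGenotype]:
    """All unordered diploid genotypes over an allele set (wildtype included).

    With the default Cs29/Cs6 locus this is the six-genotype space
    wt/wt, Cs29/wt, Cs29/Cs29, Cs6/wt, Cs6/Cs6, Cs29/Cs6.
    """
    names = list(allele_names) if allele_names is not None else ["Cs29", "Cs6"]
    if WILDTYPE not in names:
        names.append(WILDTYPE)
    return [
        DiploidGenotype.from_alleles(a, b)
        for a, b in itertools.combinations_with_replacement(sorted(names), 2)
    ]


# Placeholder coordinates: the ~500 kbp KIT segment on chromosome 6 and the
# chromosome-29 segment elevated by Cs6.  The published analysis obtained its
# region boundaries by lifting earlier assemblies over to ARS-UCD1.2 and does
# not print them; coordinates here are editable configuration centred on KIT
# (chr6, ~71.8 Mbp in ARS-UCD1.2) and are placeholders, not assertions.
_KIT_SEGMENT = GenomicRegion("6", 71_600_000, 72_100_000, label="chr6_KIT")
_CS6_SEGMENT = GenomicRegion("29", 38_700_000, 39_200_000, label="chr29_Cs6")


def default_regions() -> list[GenomicRegion]:
    """The two scored regions: the chr6 KIT segment and the chr29 Cs6 segment."""
    return [_KIT_SEGMENT, _CS6_SEGMENT]


def default_allele_models() -> list[TranslocationAlleleModel]:
    """Cs29/Cs6 allele models with placeholder region coordinates.

    Cs29 adds one copy of the chr6 KIT segment per allele; Cs6 adds one copy
    of the chr6 KIT segment and one copy of a chr29 segment per allele.
    """
    return [
        TranslocationAlleleModel("Cs29", (RegionGain(_KIT_SEGMENT, 1),)),
        TranslocationAlleleModel(
            "Cs6", (RegionGain(_KIT_SEGMENT, 1), RegionGain(_CS6_SEGMENT, 1))
        ),
        TranslocationAlleleModel(WILDTYPE),
    ]
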