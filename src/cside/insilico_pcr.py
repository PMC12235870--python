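"""In-silico breakpoint PCR: primer-site scanning, amplicon prediction, and
multiplex band-pattern interpretation.

Breakpoint PCR genotypes a structural variant with primer pairs that span
translocation junctions, so a product forms only from the rearranged (or,
for the wildtype pair, the unrearranged) haplotype.  The informative
three-pair multiplex for the cattle colour-sidedness locus produces a 318 bp
band from the Cs29 junction, a 394 bp band from the wildtype chromosome 29,
and a 525 bp band from the Cs6 junction.  The 318/394 pair of bands reads
out the Cs29 genotype codominantly; the 525 band is a dominant
presence/absence marker for Cs6 (heterozygotes and homozygotes are
indistinguishable because the Cs6 haplotype also yields the 394 band).

Primer matching is a direct scan with IUPAC-aware mismatch counting; the
3'-terminal base must always match, since polymerase extension requires a
paired 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_model import WILDTYPE, DiploidGenotype

__all__ = [
    "PrimerPair",
    "AmpliconPrediction",
    "BandPattern",
    "MarkerBand",
    "MarkerMap",
    "BandCall",
    "reverse_complement",
    "find_primer_sites",
    "predict_amplicons",
    "multiplex_pattern",
    "interpret_bands",
    "DEFAULT_MARKER_MAP",
]

# IUPAC nucleotide codes as base bitmasks (A=1, C=2, G=4, T=8)
_IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}
_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN"
)


def _encode(seq: str, what: str) -> np.ndarray:
    seq = seq.upper()
    try:
        return np.array([_IUPAC_BITS[b] for b in seq], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC character {exc.args[0]!r} in {what}") from exc


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair and the allele its product indicates."""

    name: str
    forward: str
    reverse: str
    expected_size: int | None = None
    marker_for: str = WILDTYPE

    def __post_init__(self) -> None:
        for seq, which in ((self.forward, "forward"), (self.reverse, "reverse")):
            if not seq:
                raise ValueError(f"{which} primer of {self.name} is empty")
            _encode(seq, f"{which} primer {self.name}")
        if self.expected_size is not None and self.expected_size <= max(
            len(self.forward), len(self.reverse)
        ):
            raise ValueError(
                f"expected product size of {self.name} not larger than the primers"
            )


@dataclass(frozen=True)
class AmpliconPrediction:
    """A predicted PCR product: ``[start, end)`` on the template, ``length = end - start``."""

    template: str
    pair: str
    start: int
    end: int
    forward_strand: str = "+"
    reverse_strand: str = "-"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BandPattern:
    """The set of band sizes observed (or predicted) for one animal."""

    animal: str
    sizes: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sizes", frozenset(int(s) for s in self.sizes))
        if any(s <= 0 for s in self.sizes):
            raise ValueError("band sizes must be positive")


@dataclass(frozen=True)
class MarkerBand:
    size: int
    allele: str
    dominance: str = "codominant"  # "codominant" | "dominant-presence"

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("nominal band size must be positive")
        if self.dominance not in ("codominant", "dominant-presence"):
            raise ValueError(f"unknown dominance {self.dominance!r}")


@dataclass(frozen=True)
class MarkerMap:
    """Nominal multiplex band sizes and the alleles they indicate."""

    bands: tuple[MarkerBand, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))

    def validate_separation(self, tolerance: float) -> None:
        """Nominal sizes must stay distinguishable at the matching tolerance."""
        sizes = sorted(b.size for b in self.bands)
        for a, b in zip(sizes[:-1], sizes[1:]):
            if b - a <= tolerance * (a + b):
                raise ValueError(
                    f"marker bands {a} and {b} bp collide at tolerance {tolerance}"
                )

    def match(self, observed: int, tolerance: float) -> MarkerBand | None:
        best = None
        for band in self.bands:
            if abs(observed - band.size) <= tolerance * band.size:
                if best is None or abs(observed - band.size) < abs(
                    observed - best.size
                ):
                    best = band
        return best


# The informative multiplex: Cs29 junction 318 bp, wildtype chr29 394 bp,
# Cs6 junction 525 bp (dominant presence marker).
DEFAULT_MARKER_MAP = MarkerMap(
    (
        MarkerBand(318, "Cs29", "codominant"),
        MarkerBand(394, WILDTYPE, "codominant"),
        MarkerBand(525, "Cs6", "dominant-presence"),
    )
)


def find_primer_sites(
    template: str, primer: str, max_mismatches: int = 0
) -> list[tuple[int, str]]:
    """All annealing sites of ``primer`` on either strand of ``template``.

    Returns ``(position, strand)`` tuples where ``position`` is the 0-based
    start of the primer footprint on the plus strand of the template.  A site
    matches when at most ``max_mismatches`` positions disagree AND the
    3'-terminal base pairs exactly (IUPAC codes match on base-set
    intersection).  A primer longer than the template simply has no sites.
    """
    tmpl = _encode(template, "template")
    prim = _encode(primer, "primer")
    m = len(prim)
    if m > len(tmpl):
        return []

    sites: list[tuple[int, str]] = []
    windows = np.lib.stride_tricks.sliding_window_view(tmpl, m)
    for strand, pbits, three_prime_idx in (
        ("+", prim, m - 1),
        ("-", _encode(reverse_complement(primer), "primer"), 0),
    ):
        matched = (windows & pbits) != 0
        mism = (~matched).sum(axis=1)
        ok = (mism <= max_mismatches) & matched[:, three_prime_idx]
        for pos in np.nonzero(ok)[0]:
            sites.append((int(pos), strand))
    sites.sort()
    return sites


def predict_amplicons(
    template: str,
    pair: PrimerPair,
    max_product: int = 2_000,
    max_mismatches: int = 0,
    template_id: str = "",
) -> list[AmpliconPrediction]:
    """All products of ``pair`` on ``template`` up to ``max_product`` bp.

    A product forms from every convergent combination of a plus-strand site
    of one primer and a downstream minus-strand site of the other.  Product
    length runs from the 5' end of the forward-facing primer through the 5'
    end of the reverse-facing primer, inclusive — the convention in which
    assay product sizes are reported.
    """
    fwd_sites = find_primer_sites(template, pair.forward, max_mismatches)
    rev_sites = find_primer_sites(template, pair.reverse, max_mismatches)
    out: list[AmpliconPrediction] = []
    for left_primer, right_primer, left_sites, right_sites in (
        (pair.forward, pair.reverse, fwd_sites, rev_sites),
        (pair.reverse, pair.forward, rev_sites, fwd_sites),
    ):
        plus = [p for p, s in left_sites if s == "+"]
        minus = [p for p, s in right_sites if s == "-"]
        for p in plus:
            for q in minus:
                end = q + len(right_primer)
                length = end - p
                if q >= p + len(left_primer) and length <= max_product:
                    out.append(
                        AmpliconPrediction(
                            template=template_id, pair=pair.name, start=p, end=end
                        )
                    )
    # a palindromic pairing could be found from both orderings; deduplicate
    return sorted(set(out), key=lambda a: (a.start, a.end))


def multiplex_pattern(
    genotype: DiploidGenotype,
    templates: dict[str, str],
    pairs: list[PrimerPair],
    animal: str = "",
    max_product: int = 2_000,
) -> BandPattern:
    """Band sizes a multiplex produces for a genotype.

    ``templates`` maps each allele name to its haplotype sequence.  The
    pattern is the union of product sizes over the alleles present — band
    intensity (dosage) is not modelled, which is exactly why a marker whose
    band appears on both carrier classes behaves dominantly.
    """
    sizes: set[int] = set()
    for allele, count in genotype.allele_counts:
        if count == 0:
            continue
        if allele not in templates:
            raise KeyError(f"no haplotype template for allele {allele!r}")
        for pair in pairs:
            for amp in predict_amplicons(
                templates[allele], pair, max_product=max_product, template_id=allele
            ):
                sizes.add(amp.length)
    return BandPattern(animal=animal, sizes=frozenset(sizes))


@dataclass(frozen=True)
class BandCall:
    """Decoded multiplex pattern for one animal.

    ``cs29_genotype`` is the codominant class (hom / het / non-carrier) of
    the translocation read from the junction and wildtype bands;
    ``cs6_status`` is positive/negative only.  ``status`` is ``"failed"``
    when neither the junction-class nor the wildtype-class band is present
    (no chromosome-29 product at all signals PCR failure, not a genotype).
    """

    animal: str
    status: str  # "ok" | "failed"
    cs29_genotype: str | None
    cs6_status: str | None
    notes: tuple[str, ...] = ()
    unassigned: tuple[int, ...] = ()

    def compatible_genotypes(self) -> tuple[str, ...]:
        """Diploid genotypes consistent with the call (Cs6 dosage may be ambiguous)."""
        if self.status != "ok":
            return ()
        if self.cs29_genotype == "hom":
            return ("Cs29/Cs29",)
        if self.cs29_genotype == "het":
            return ("Cs29/Cs6",) if self.cs6_status == "positive" else ("Cs29/wt",)
        if self.cs6_status == "positive":
            return ("Cs6/wt", "Cs6/Cs6")
        return ("wt/wt",)


def interpret_bands(
    pattern: BandPattern,
    marker_map: MarkerMap = DEFAULT_MARKER_MAP,
    size_tolerance: float = 0.03,
) -> BandCall:
    """Decode an observed band pattern into a translocation genotype call.

    Bands are assigned to the nearest nominal marker within
    ``size_tolerance`` (a fraction of the nominal size; electrophoresis
    sizing error).  The junction band plus wildtype band read the codominant
    genotype; each dominant-presence marker is reported positive/negative
    with the het-or-hom ambiguity noted.  Bands matching no marker are
    listed as unassigned.
    """
    marker_map.validate_separation(size_tolerance)
    present: set[tuple[str, str]] = set()
    unassigned: list[int] = []
    for size in sorted(pattern.sizes):
        band = marker_map.match(size, size_tolerance)
        if band is None:
            unassigned.append(size)
        else:
            present.add((band.allele, band.dominance))

    codominant = {a for a, d in present if d == "codominant"}
    trans_band = codominant - {WILDTYPE}
    wt_band = WILDTYPE in codominant
    notes: list[str] = []

    if not codominant:
        notes.append("no junction-class or wildtype-class band: PCR failure")
        return BandCall(
            animal=pattern.animal,
            status="failed",
            cs29_genotype=None,
            cs6_status=None,
            notes=tuple(notes),
            unassigned=tuple(unassigned),
        )

    if trans_band and wt_band:
        cs29 = "het"
    elif trans_band:
        cs29 = "hom"
    else:
        cs29 = "non-carrier"

    dominant_positive = {a for a, d in present if d == "dominant-presence"}
    has_dominant_marker = any(
        b.dominance == "dominant-presence" for b in marker_map.bands
    )
    cs6 = None
    if has_dominant_marker:
        cs6 = "positive" if dominant_positive else "negative"
        if dominant_positive:
            notes.append("Cs6 dosage: het or hom indistinguishable (dominant marker)")

    return BandCall(
        animal=pattern.animal,
        status="ok",
        cs29_genotype=cs29,
        cs6_status=cs6,
        notes=tuple(notes),
        unassigned=tuple(unassigned),
    )
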