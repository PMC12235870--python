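"""Readers and writers for the plain-text formats the pipeline consumes.

bedGraph and BED for depth and regions, FASTA (via Biopython) for haplotype
templates, TSV for primer tables, CSV for cohort genotype records, YAML for
allele-model configuration.  Parsers validate eagerly and report the
offending line number; writes round-trip through the matching reader.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .depth_genotyper import WindowDepthTrack
from .genome_model import GenomicRegion, RegionGain, TranslocationAlleleModel
from .insilico_pcr import BandPattern, PrimerPair

__all__ = [
    "read_bedgraph",
    "read_bed_regions",
    "read_window_track",
    "write_window_track",
    "read_fasta",
    "write_fasta",
    "read_primer_table",
    "write_primer_table",
    "read_band_patterns",
    "read_allele_models",
    "write_allele_models",
    "read_cohort_csv",
]


class FormatError(ValueError):
    """Malformed input file; the message names the file and line."""


def _fail(path, lineno: int, msg: str) -> None:
    raise FormatError(f"{path}:{lineno}: {msg}")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """4-column bedGraph (chrom, start, end, depth) as a DataFrame."""
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                _fail(path, lineno, f"expected 4 tab-separated columns, got {len(parts)}")
            try:
                start, end, depth = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                _fail(path, lineno, f"non-numeric coordinates or depth: {line!r}")
            if end <= start:
                _fail(path, lineno, f"interval end {end} not beyond start {start}")
            rows.append((parts[0], start, end, depth))
    if not rows:
        raise FormatError(f"{path}: no data lines")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "depth"])


def read_bed_regions(path: str | Path) -> list[GenomicRegion]:
    """BED intervals (3+ columns; column 4, if present, becomes the label)."""
    regions = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                _fail(path, lineno, "expected at least 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                _fail(path, lineno, f"non-integer coordinates: {line!r}")
            if end <= start:
                _fail(path, lineno, f"start {start} not before end {end}")
            label = parts[3] if len(parts) > 3 else ""
            regions.append(GenomicRegion(parts[0], start, end, label=label))
    if not regions:
        raise FormatError(f"{path}: no regions")
    return regions


def write_window_track(track: WindowDepthTrack, path: str | Path) -> None:
    track.windows.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_window_track(path: str | Path) -> WindowDepthTrack:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return WindowDepthTrack(df)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id, normalized to uppercase."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


PRIMER_COLUMNS = ["name", "forward", "reverse", "expected_size", "marker_for"]


def read_primer_table(path: str | Path) -> list[PrimerPair]:
    """TSV primer table: name, forward, reverse, expected_size, marker_for."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PRIMER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing primer columns {missing}")
    pairs = []
    for lineno, row in enumerate(df.itertuples(index=False), 2):
        size = None if pd.isna(row.expected_size) else int(row.expected_size)
        try:
            pairs.append(
                PrimerPair(
                    name=str(row.name),
                    forward=str(row.forward),
                    reverse=str(row.reverse),
                    expected_size=size,
                    marker_for=str(row.marker_for),
                )
            )
        except ValueError as exc:
            _fail(path, lineno, str(exc))
    return pairs


def write_primer_table(pairs: list[PrimerPair], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "name": p.name,
                "forward": p.forward,
                "reverse": p.reverse,
                "expected_size": p.expected_size,
                "marker_for": p.marker_for,
            }
            for p in pairs
        ]
    ).to_csv(path, sep="\t", index=False)


def read_band_patterns(path: str | Path) -> list[BandPattern]:
    """CSV of observed patterns: columns ``animal`` and ``bands``
    (semicolon-separated sizes; empty = no product)."""
    df = pd.read_csv(path, dtype={"bands": str})
    for col in ("animal", "bands"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    patterns = []
    for lineno, row in enumerate(df.itertuples(index=False), 2):
        raw = "" if pd.isna(row.bands) else str(row.bands).strip()
        try:
            sizes = frozenset(int(s) for s in raw.split(";") if s.strip())
        except ValueError:
            _fail(path, lineno, f"non-integer band size in {raw!r}")
        patterns.append(BandPattern(animal=str(row.animal), sizes=sizes))
    return patterns


def read_allele_models(path: str | Path) -> list[TranslocationAlleleModel]:
    """YAML allele-model config.

    Schema::

        alleles:
          - name: Cs29
            gains:
              - {chrom: "6", start: 71600000, end: 72100000,
                 label: chr6_KIT, copies_added: 1}
    """
    with open(path) as handle:
        doc = yaml.safe_load(handle)
    if not isinstance(doc, dict) or "alleles" not in doc:
        raise FormatError(f"{path}: expected a top-level 'alleles' list")
    models = []
    for entry in doc["alleles"]:
        gains = tuple(
            RegionGain(
                GenomicRegion(
                    str(g["chrom"]), int(g["start"]), int(g["end"]),
                    label=str(g.get("label", "")),
                ),
                copies_added=int(g.get("copies_added", 1)),
            )
            for g in entry.get("gains", [])
        )
        models.append(TranslocationAlleleModel(str(entry["name"]), gains))
    return models


def write_allele_models(
    models: list[TranslocationAlleleModel], path: str | Path
) -> None:
    doc = {
        "alleles": [
            {
                "name": m.name,
                "gains": [
                    {
                        "chrom": g.region.chrom,
                        "start": g.region.start,
                        "end": g.region.end,
                        "label": g.region.label,
                        "copies_added": g.copies_added,
                    }
                    for g in m.gained_regions
                ],
            }
            for m in models
        ]
    }
    with open(path, "w") as handle:
        yaml.safe_dump(doc, handle, sort_keys=False)


COHORT_COLUMNS = ["cohort", "breed", "animal", "Cs29_genotype", "Cs6_status"]


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Per-animal cohort genotype records.

    Columns: cohort, breed, animal, Cs29_genotype (hom/het/non-carrier),
    Cs6_status (positive/negative) — the schema the population simulator
    emits and band interpretation produces.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing cohort columns {missing}")
    bad = ~df["Cs29_genotype"].isin(["hom", "het", "non-carrier"])
    if bad.any():
        lineno = int(df.index[bad][0]) + 2
        _fail(path, lineno, f"invalid Cs29_genotype {df.loc[bad, 'Cs29_genotype'].iloc[0]!r}")
    bad = ~df["Cs6_status"].isin(["positive", "negative"])
    if bad.any():
        lineno = int(df.index[bad][0]) + 2
        _fail(path, lineno, f"invalid Cs6_status {df.loc[bad, 'Cs6_status'].iloc[0]!r}")
    return df
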