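"""Gene/region annotation of seed hits and per-miRNA hit tables.

Each hit is assigned one primary mitochondrial gene area plus the full list of
overlapping features. Precedence when several features overlap a hit: gene
features (protein-coding, tRNA, rRNA) outrank non-coding regions; among gene
features the one covering more bases of the hit wins, exact ties go to the
earlier start and flag the row as ambiguous; among non-coding regions the
narrowest wins, so a hypervariable region outranks the enclosing control
region. A hit overlapping nothing is annotated ``intergenic`` (rare: the
mitochondrial genome has essentially no intergenic sequence) and flagged.

Strand naming in summaries follows the mitochondrial convention: forward
(reference-strand) hits sit on the light strand, reverse hits on the heavy
strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import pandas as pd

from .mtgenome import FeatureMap, GENE_CLASSES, MitoGenome, MtFeature, features_overlapping
from .seedscan import MiRNA, Seed, SeedHit, SeedSpec, extract_seed, scan

__all__ = [
    "AnnotatedHit",
    "HitTable",
    "HitSummary",
    "annotate_hit",
    "build_hit_table",
    "summarize_hits",
    "hit_table_to_frame",
    "write_table2_report",
    "write_bed6",
]


@dataclass(frozen=True)
class AnnotatedHit:
    hit: SeedHit
    mt_gene_area: str
    functional_area: str  # "coding" | "non_coding"
    transcript: str
    all_overlaps: tuple
    ambiguous: bool = False

    @property
    def mirna_id(self) -> str:
        return self.hit.mirna_id


@dataclass
class HitTable:
    """Annotated hits grouped by miRNA, with per-miRNA site counts."""

    rows: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    genome_length: int = 0

    def rows_for(self, mirna_id: str) -> list:
        return [r for r in self.rows if r.mirna_id == mirna_id]


@dataclass
class HitSummary:
    n_mirnas_with_sites: int
    n_mirnas_without_sites: int
    total_sites: int
    light_strand_sites: int
    heavy_strand_sites: int
    light_strand_fraction: Optional[float]  # None when the table is empty
    per_region: dict = field(default_factory=dict)


def annotate_hit(hit: SeedHit, fm: FeatureMap) -> AnnotatedHit:
    """Attach the primary gene area and all overlapping features to a hit."""
    overlaps = features_overlapping(fm, hit.start, hit.end)
    if not overlaps:
        return AnnotatedHit(
            hit=hit,
            mt_gene_area="intergenic",
            functional_area="non_coding",
            transcript="",
            all_overlaps=(),
            ambiguous=True,
        )
    L = fm.genome_length
    hit_len = hit.length(L)

    def overlap_bases(f: MtFeature) -> int:
        qsegs = (
            [(hit.start, L), (1, hit.end)]
            if hit.end < hit.start
            else [(hit.start, hit.end)]
        )
        total = 0
        for qs, qe in qsegs:
            for fs, fe in f.segments(L):
                lo, hi = max(qs, fs), min(qe, fe)
                if lo <= hi:
                    total += hi - lo + 1
        return min(total, hit_len)

    genes = [f for f in overlaps if f.feature_class in GENE_CLASSES]
    ambiguous = False
    if genes:
        scored = sorted(genes, key=lambda f: (-overlap_bases(f), f.start, f.name))
        primary = scored[0]
        if len(scored) > 1 and overlap_bases(scored[1]) == overlap_bases(primary):
            ambiguous = True
        functional = "coding"
    else:
        # among non-coding regions the narrowest wins (HVR over control region)
        primary = sorted(overlaps, key=lambda f: (f.span(L), f.start, f.name))[0]
        functional = "non_coding"
    return AnnotatedHit(
        hit=hit,
        mt_gene_area=primary.name,
        functional_area=functional,
        transcript=primary.description,
        all_overlaps=tuple(f.name for f in overlaps),
        ambiguous=ambiguous,
    )


def build_hit_table(
    mirnas: Sequence[MiRNA],
    genome: MitoGenome,
    fm: FeatureMap,
    spec: SeedSpec = SeedSpec(),
    overrides: Optional[Mapping[str, SeedSpec]] = None,
) -> HitTable:
    """Scan and annotate every miRNA; miRNAs with no sites keep count 0.

    ``overrides`` maps miRNA ids to per-miRNA seed conventions (as produced
    by convention calibration); all other miRNAs use ``spec``.
    """
    if not mirnas:
        raise ValueError("empty miRNA list")
    overrides = dict(overrides or {})
    rows: List[AnnotatedHit] = []
    counts: Dict[str, int] = {}
    for mir in mirnas:
        sp = overrides.get(mir.id, spec)
        seed = extract_seed(mir, sp)
        hits = scan(genome, seed)
        counts[mir.id] = len(hits)
        rows.extend(annotate_hit(h, fm) for h in hits)
    return HitTable(rows=rows, counts=counts, genome_length=genome.length)


def summarize_hits(table: HitTable) -> HitSummary:
    """Strand balance and per-region tallies of an annotated hit table."""
    with_sites = sum(1 for n in table.counts.values() if n > 0)
    without = len(table.counts) - with_sites
    fwd = sum(1 for r in table.rows if r.hit.strand == "forward")
    rev = len(table.rows) - fwd
    total = len(table.rows)
    per_region: Dict[str, int] = {}
    for r in table.rows:
        per_region[r.mt_gene_area] = per_region.get(r.mt_gene_area, 0) + 1
    return HitSummary(
        n_mirnas_with_sites=with_sites,
        n_mirnas_without_sites=without,
        total_sites=total,
        light_strand_sites=fwd,
        heavy_strand_sites=rev,
        light_strand_fraction=(fwd / total) if total else None,
        per_region=per_region,
    )


def hit_table_to_frame(table: HitTable) -> pd.DataFrame:
    """Flat DataFrame view (one row per annotated site)."""
    recs = []
    for r in table.rows:
        recs.append(
            {
                "mirna_id": r.mirna_id,
                "start": r.hit.start,
                "end": r.hit.end,
                "strand": r.hit.strand,
                "display_range": r.hit.display_range(),
                "mt_gene_area": r.mt_gene_area,
                "functional_area": r.functional_area,
                "transcript": r.transcript,
                "all_overlaps": ";".join(r.all_overlaps),
                "ambiguous": r.ambiguous,
            }
        )
    cols = [
        "mirna_id", "start", "end", "strand", "display_range",
        "mt_gene_area", "functional_area", "transcript", "all_overlaps", "ambiguous",
    ]
    return pd.DataFrame(recs, columns=cols)


def write_table2_report(table: HitTable, path: Union[str, Path]) -> None:
    """Per-miRNA report in the published table layout: one block per miRNA
    with its total site count ('nos') and one row per site."""
    lines = ["mirna_id\tnos\tdisplay_range\tmt_gene_area\tfunctional_area\ttranscript"]
    for mid, n in table.counts.items():
        rows = table.rows_for(mid)
        if not rows:
            lines.append(f"{mid}\t0\t\t\t\t")
        for r in rows:
            lines.append(
                f"{mid}\t{n}\t{r.hit.display_range()}\t{r.mt_gene_area}\t"
                f"{r.functional_area}\t{r.transcript}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed6(table: HitTable, path: Union[str, Path], chrom: str = "chrM") -> None:
    """BED6 export: 0-based half-open, strand +/- for forward/reverse;
    origin-wrapping hits are split into two lines sharing a name suffix."""
    L = table.genome_length
    lines = []
    for i, r in enumerate(table.rows):
        h = r.hit
        strand = "+" if h.strand == "forward" else "-"
        name = f"{h.mirna_id}_{i}"
        if h.end >= h.start:
            lines.append(f"{chrom}\t{h.start - 1}\t{h.end}\t{name}\t0\t{strand}")
        else:
            lines.append(f"{chrom}\t{h.start - 1}\t{L}\t{name}_wrapA\t0\t{strand}")
            lines.append(f"{chrom}\t0\t{h.end}\t{name}_wrapB\t0\t{strand}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
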