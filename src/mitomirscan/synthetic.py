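"""Synthetic inputs with known ground truth.

Random circular genomes (i.i.d. bases at a chosen GC fraction, default 0.44,
roughly mitochondrial-like), seed sites planted at known coordinates, and
synthetic target/IMPI tables with a known number of mitochondrial genes.
Everything is deterministic under a fixed seed and emits its parameters in a
manifest, so planted-site recovery and filter behaviour can be verified
exactly. Planting overwrites bases in place (no insertion), preserving genome
length and coordinate comparability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .mtgenome import MitoGenome, reverse_complement
from .proteome import TargetRecord
from .seedscan import Seed, SeedHit

__all__ = [
    "PlantSpec",
    "TruthSet",
    "TargetTableSpec",
    "generate_genome",
    "plant_sites",
    "generate_target_table",
]


@dataclass(frozen=True)
class PlantSpec:
    """How many seed sites to plant, or exactly where.

    ``positions`` (1-based start, strand) overrides the random counts when
    given. With ``avoid_overlap`` planted intervals are pairwise disjoint
    under circular arithmetic.
    """

    mirna_id: str
    n_forward: int = 0
    n_reverse: int = 0
    positions: Optional[tuple] = None
    avoid_overlap: bool = True


@dataclass
class TruthSet:
    """Ground truth for a planted genome: the planted hits and the expected
    number of incidental background matches (2 L / 4^k for a k-mer)."""

    planted: list
    background_expected: float
    manifest: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TargetTableSpec:
    """Shape of a synthetic target table: ``n_genes`` records of which
    ``frac_mito`` draw IMPI from ``impi_high_range`` and the rest from
    ``impi_low_range``; prediction scores uniform on ``score_range``."""

    n_genes: int
    frac_mito: float = 0.2
    impi_high_range: tuple = (0.75, 1.0)
    impi_low_range: tuple = (0.0, 0.65)
    score_range: tuple = (50.0, 100.0)
    rng_seed: int = 0
    mirna_id: str = "miR-SYN"

    def __post_init__(self):
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if not (0 <= self.frac_mito <= 1):
            raise ValueError("frac_mito must be in [0, 1]")
        for name, (lo, hi) in (
            ("impi_high_range", self.impi_high_range),
            ("impi_low_range", self.impi_low_range),
        ):
            if not (0 <= lo <= hi <= 1):
                raise ValueError(f"{name} must be an ordered subrange of [0, 1]")
        lo, hi = self.score_range
        if not (50 <= lo <= hi <= 100):
            raise ValueError("score_range must be an ordered subrange of [50, 100]")


def generate_genome(
    length: int, gc_fraction: float = 0.44, rng_seed: int = 0, circular: bool = True
) -> MitoGenome:
    """Random genome with i.i.d. bases; P(G)+P(C) = ``gc_fraction`` split
    evenly. Reproducible under ``rng_seed``."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if not (0 <= gc_fraction <= 1):
        raise ValueError(f"gc_fraction {gc_fraction} outside [0, 1]")
    rng = np.random.default_rng(rng_seed)
    p_gc = gc_fraction / 2
    p_at = (1 - gc_fraction) / 2
    bases = rng.choice(np.array(list("ACGT")), size=length, p=[p_at, p_gc, p_gc, p_at])
    return MitoGenome(
        accession=f"SYN_{length}_{rng_seed}",
        sequence="".join(bases),
        circular=circular,
    )


def _interval_positions(start0: int, k: int, L: int) -> set:
    return {(start0 + j) % L for j in range(k)}


def plant_sites(
    genome: MitoGenome,
    seed: Seed,
    spec: PlantSpec,
    rng_seed: int = 0,
) -> Tuple[MitoGenome, TruthSet]:
    """Overwrite the genome with seed sites at known positions.

    A forward site writes the seed's first search pattern; a reverse site
    writes its reverse complement. Explicit ``positions`` may wrap the origin
    on circular genomes. Returns the modified genome and the truth set; the
    scanner must recover every planted site (extras are incidental background
    matches, verifiable against the oracle).
    """
    if not seed.patterns:
        raise ValueError("seed has no patterns to plant")
    pattern = seed.patterns[0]
    k = len(pattern)
    L = genome.length
    if k > L:
        raise ValueError(f"pattern length {k} exceeds genome length {L}")
    rng = np.random.default_rng(rng_seed)

    if spec.positions is not None:
        chosen = [(int(s), strand) for s, strand in spec.positions]
    else:
        n_total = spec.n_forward + spec.n_reverse
        strands = ["forward"] * spec.n_forward + ["reverse"] * spec.n_reverse
        max_start = L if genome.circular else L - k + 1
        chosen = []
        used: set = set()
        attempts = 0
        while len(chosen) < n_total:
            attempts += 1
            if attempts > 1000 * max(n_total, 1):
                raise ValueError(
                    f"cannot place {n_total} non-overlapping sites of length {k} "
                    f"in a {L} bp genome"
                )
            s0 = int(rng.integers(0, max_start))
            if spec.avoid_overlap:
                cells = _interval_positions(s0, k, L)
                if cells & used:
                    continue
                used |= cells
            chosen.append((s0 + 1, strands[len(chosen)]))

    for start, strand in chosen:
        if not (1 <= start <= L):
            raise ValueError(f"planted position {start} outside genome")
        if not genome.circular and start + k - 1 > L:
            raise ValueError(f"planted site at {start} exceeds linear genome")

    seqlist = list(genome.sequence)
    planted: List[SeedHit] = []
    for start, strand in chosen:
        word = pattern if strand == "forward" else reverse_complement(pattern)
        for j, base in enumerate(word):
            seqlist[(start - 1 + j) % L] = base
        end = (start - 1 + k - 1) % L + 1
        planted.append(
            SeedHit(
                mirna_id=seed.mirna_id,
                start=start,
                end=end,
                strand=strand,
                matched_pattern=pattern if strand == "forward" else word,
            )
        )
    new_genome = MitoGenome(
        accession=genome.accession + "_planted",
        sequence="".join(seqlist),
        circular=genome.circular,
    )
    truth = TruthSet(
        planted=sorted(planted, key=lambda h: (h.start, h.strand)),
        background_expected=2 * L / 4 ** k,
        manifest={
            "genome_length": L,
            "circular": genome.circular,
            "pattern": pattern,
            "mirna_id": seed.mirna_id,
            "n_planted": len(planted),
            "rng_seed": rng_seed,
            "avoid_overlap": spec.avoid_overlap,
        },
    )
    return new_genome, truth


def generate_target_table(spec: TargetTableSpec):
    """Synthetic miRDB/IMPI-style target table with known truth counts.

    Returns ``(records, truth)`` where ``truth`` holds the number of
    mitochondrial genes, a callable-free count of records above any threshold
    separating the two IMPI ranges, and a warning flag when the ranges
    overlap (so a threshold between them cannot be clean).
    """
    rng = np.random.default_rng(spec.rng_seed)
    n_mito = round(spec.frac_mito * spec.n_genes)
    records: List[TargetRecord] = []
    impis = np.concatenate(
        [
            rng.uniform(*spec.impi_high_range, size=n_mito),
            rng.uniform(*spec.impi_low_range, size=spec.n_genes - n_mito),
        ]
    )
    scores = rng.uniform(*spec.score_range, size=spec.n_genes)
    orf_lens = 3 * rng.integers(50, 650, size=spec.n_genes)
    for i in range(spec.n_genes):
        records.append(
            TargetRecord(
                mirna_id=spec.mirna_id,
                gene_id=f"SYNG{i:05d}",
                symbol=f"SYN{i:05d}",
                target_score=float(round(scores[i], 3)),
                impi=float(round(impis[i], 6)),
                orf_length_nt=int(orf_lens[i]),
                mirna_ids=(spec.mirna_id,),
            )
        )
    ranges_overlap = spec.impi_low_range[1] >= spec.impi_high_range[0]
    truth = {
        "n_genes": spec.n_genes,
        "n_mito": n_mito,
        "ranges_overlap_warning": bool(ranges_overlap),
        "rng_seed": spec.rng_seed,
        "impi_high_range": spec.impi_high_range,
        "impi_low_range": spec.impi_low_range,
    }
    return records, truth
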