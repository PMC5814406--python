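"""miRNA seed extraction and seed-complementary site scanning.

A canonical seed is the 5' window of a mature miRNA (nucleotides 2-7 by
default). A *site* is a position of the reference genome whose bases can pair
with the seed. Two pairing geometries are supported:

``antiparallel``
    The standard miRNA:target duplex: the target strand contains the reverse
    complement of the seed. This is how cytosolic target predictors read
    seed matches.
``parallel``
    The target strand contains the base-wise complement of the seed without
    reversal (the seed laid alongside the genome 5'->3' and complemented
    position by position). Published mitochondrial seed-site tables for the
    liver-PNF MitomiR set follow this reading, which is why it is a
    first-class mode here; :mod:`mitomirscan.calibrate` identifies the
    convention from anchor rows rather than guessing.

Hits are reported on both strands: a *forward* hit is an occurrence of the
search pattern on the printed reference strand, a *reverse* hit an occurrence
of its reverse complement (equivalently, a pattern occurrence on the other
strand). For the human mitochondrial reference the printed strand is the
light (L) strand, so forward hits are L-strand sites and reverse hits are
heavy-strand sites (printed with a trailing ``r`` and descending
coordinates). ``orientation="flipped"`` swaps the labels, which together with
the two geometries spans the four conceivable conventions.

Circular genomes are scanned across the origin; overlapping occurrences are
all reported; ``N`` never matches. A brute-force oracle (:func:`scan_oracle`)
provides an independent check used throughout the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

from .mtgenome import (
    MitoGenome,
    SequenceAlphabetError,
    _validate_alphabet,
    NUC_ALPHABET,
    complement,
    interconvert,
    reverse_complement,
)

__all__ = [
    "MiRNA",
    "SeedSpec",
    "Seed",
    "SeedHit",
    "MATCH_MODES",
    "ORIENTATIONS",
    "extract_seed",
    "scan",
    "scan_oracle",
    "load_mirnas",
]

MATCH_MODES = ("antiparallel", "parallel")
ORIENTATIONS = ("reference", "flipped")

#: admissible target base(s) for a G:U wobble, by seed base
_WOBBLE_TARGET = {"G": "T", "U": "G", "T": "G"}


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA: miRBase name, accession, RNA sequence 5'->3'."""

    id: str
    sequence: str
    accession: str = ""
    fold_change: float = 0.0
    p_value: float = 0.5

    def __post_init__(self):
        seq = self.sequence.lower()
        bad = set(seq) - set("acgu")
        if bad:
            raise SequenceAlphabetError(
                f"miRNA {self.id!r}: sequence must be RNA over a/c/g/u, got {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class SeedSpec:
    """How to read a seed out of a mature miRNA and match it to a genome.

    ``window_start``/``window_end`` are 1-based inclusive positions in the
    mature miRNA (default 2..7, the canonical hexamer). ``match_mode`` selects
    the duplex geometry (see module docstring); ``orientation`` selects which
    strand's occurrences are labelled *forward*. ``allow_gu_wobble`` expands
    the pattern set with G:U pairings (off by default; extension hook).
    """

    window_start: int = 2
    window_end: int = 7
    match_mode: str = "antiparallel"
    orientation: str = "reference"
    allow_gu_wobble: bool = False

    def __post_init__(self):
        if self.window_start < 1 or self.window_end < self.window_start:
            raise ValueError(
                f"invalid seed window {self.window_start}..{self.window_end}"
            )
        if not (6 <= self.window_len <= 8):
            raise ValueError(
                f"seed window length {self.window_len} unsupported (must be 6-8)"
            )
        if self.match_mode not in MATCH_MODES:
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def window_len(self) -> int:
        return self.window_end - self.window_start + 1

    @property
    def window(self) -> tuple:
        return (self.window_start, self.window_end)


@dataclass(frozen=True)
class Seed:
    """An extracted seed and the DNA pattern(s) searched on the reference."""

    mirna_id: str
    rna_seed: str
    patterns: tuple
    spec: SeedSpec = field(default_factory=SeedSpec)


@dataclass(frozen=True, order=True)
class SeedHit:
    """One seed-complementary site, 1-based inclusive reference coordinates.

    For origin-wrapping hits on a circular genome ``end < start``; the
    circular-corrected length always equals the pattern length. Display
    follows the published convention: forward hits ascending
    (``start-end``), reverse hits descending with an ``r`` suffix
    (``end-startr``).
    """

    start: int
    strand: str
    mirna_id: str = field(compare=False)
    end: int = field(compare=False)
    matched_pattern: str = field(compare=False)

    def display_range(self) -> str:
        if self.strand == "reverse":
            return f"{self.end}-{self.start}r"
        return f"{self.start}-{self.end}"

    def length(self, genome_length: int) -> int:
        if self.end >= self.start:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end


def _expand_wobble(seed_rna: str, mode: str) -> List[str]:
    """All DNA target patterns admitting G:U pairs, for the given geometry."""
    per_pos = []
    for base in seed_rna.upper():
        target = {complement(base).replace("U", "T")}
        wob = _WOBBLE_TARGET.get(base)
        if wob:
            target.add(wob)
        per_pos.append(sorted(target))
    combos = ["".join(p) for p in product(*per_pos)]
    if mode == "antiparallel":
        combos = [c[::-1] for c in combos]
    return combos


def extract_seed(mirna: MiRNA, spec: SeedSpec = SeedSpec()) -> Seed:
    """Extract the seed window and build the forward-strand search patterns.

    ``antiparallel`` mode searches for the DNA reverse complement of the
    seed; ``parallel`` mode for its non-reversed complement. With
    ``allow_gu_wobble`` the pattern tuple enumerates every wobble-admissible
    target word.
    """
    if len(mirna.sequence) < spec.window_end:
        raise ValueError(
            f"miRNA {mirna.id!r}: sequence length {len(mirna.sequence)} shorter "
            f"than seed window end {spec.window_end}"
        )
    rna_seed = mirna.sequence[spec.window_start - 1 : spec.window_end]
    if spec.allow_gu_wobble:
        patterns = tuple(dict.fromkeys(_expand_wobble(rna_seed, spec.match_mode)))
    else:
        dna = interconvert(rna_seed, "rna_to_dna")
        if spec.match_mode == "antiparallel":
            patterns = (reverse_complement(dna),)
        else:
            patterns = (complement(dna),)
    return Seed(mirna_id=mirna.id, rna_seed=rna_seed, patterns=patterns, spec=spec)


def _pattern_occurrences(genome: MitoGenome, pattern: str) -> List[int]:
    """1-based start positions of ``pattern`` on the printed strand.

    On a circular genome occurrences wrapping the origin are included; every
    start position is reported at most once.
    """
    L = genome.length
    k = len(pattern)
    if k == 0 or (not genome.circular and k > L):
        return []
    if genome.circular and k > L:
        # pattern longer than the genome: check every rotation modularly
        g = genome.sequence
        return [
            s + 1
            for s in range(L)
            if all(g[(s + j) % L] == pattern[j] for j in range(k))
        ]
    text = genome.sequence + (genome.sequence[: k - 1] if genome.circular else "")
    out = []
    i = text.find(pattern)
    while i != -1:
        if i < L:
            out.append(i + 1)
        i = text.find(pattern, i + 1)
    return out


def _hits_for_patterns(genome: MitoGenome, seed: Seed) -> List[SeedHit]:
    L = genome.length
    fwd_label, rev_label = (
        ("forward", "reverse")
        if seed.spec.orientation == "reference"
        else ("reverse", "forward")
    )
    hits = {}
    for pat in seed.patterns:
        p = _validate_alphabet(pat, NUC_ALPHABET, "pattern")
        if "U" in p:
            raise SequenceAlphabetError(f"pattern {pat!r} is not DNA")
        if "N" in p:
            continue  # N never matches
        k = len(p)
        for strand_label, q in ((fwd_label, p), (rev_label, reverse_complement(p))):
            for start in _pattern_occurrences(genome, q):
                end = (start - 1 + k - 1) % L + 1
                key = (seed.mirna_id, start, end, strand_label)
                if key not in hits:
                    hits[key] = SeedHit(
                        mirna_id=seed.mirna_id,
                        start=start,
                        end=end,
                        strand=strand_label,
                        matched_pattern=q,
                    )
    return sorted(hits.values(), key=lambda h: (h.start, h.strand, h.end))


def scan(genome: MitoGenome, seed: Seed) -> List[SeedHit]:
    """Every seed-site on both strands of ``genome``.

    Forward hits are occurrences of a seed pattern on the printed reference
    strand; reverse hits are occurrences on the complementary strand, with
    coordinates mapped back to reference numbering (start = leftmost base).
    On circular genomes sites spanning the origin are found. Overlapping
    occurrences are all reported; hits are unique per
    (miRNA, start, end, strand) and sorted by start position.
    """
    if genome.length == 0:
        raise ValueError("cannot scan an empty genome")
    if not seed.patterns:
        return []
    return _hits_for_patterns(genome, seed)


_ORACLE_MAX = 10_000


def scan_oracle(genome: MitoGenome, seed: Seed) -> List[SeedHit]:
    """Exhaustive per-position rescan of :func:`scan`'s contract.

    Independent implementation: every start position on both orientations is
    compared base by base (on the doubled sequence for circular genomes).
    Restricted to genomes of at most 10 kb to keep the quadratic cost in
    check.
    """
    L = genome.length
    if L > _ORACLE_MAX:
        raise ValueError(f"oracle restricted to genomes <= {_ORACLE_MAX} bp, got {L}")
    fwd_label, rev_label = (
        ("forward", "reverse")
        if seed.spec.orientation == "reference"
        else ("reverse", "forward")
    )
    g = genome.sequence
    hits = set()
    results = []
    for pat in seed.patterns:
        p = pat.upper()
        if "N" in p:
            continue
        k = len(p)
        rc = reverse_complement(p)
        for start0 in range(L):
            limit = L + (k - 1 if genome.circular else 0)
            if start0 + k > limit:
                continue
            word = "".join(g[(start0 + j) % L] for j in range(k))
            for label, q in ((fwd_label, p), (rev_label, rc)):
                if word == q:
                    end = (start0 + k - 1) % L + 1
                    key = (seed.mirna_id, start0 + 1, end, label)
                    if key not in hits:
                        hits.add(key)
                        results.append(
                            SeedHit(
                                mirna_id=seed.mirna_id,
                                start=start0 + 1,
                                end=end,
                                strand=label,
                                matched_pattern=q,
                            )
                        )
    return sorted(results, key=lambda h: (h.start, h.strand, h.end))


# ---------------------------------------------------------------------------
# miRNA input


def load_mirnas(source: Union[str, Path, None] = None) -> List[MiRNA]:
    """Load mature miRNAs from TSV (id, accession, sequence, fold_change,
    p_value) or FASTA (RNA alphabet). With no source, the bundled table of
    the 16 liver-PNF miRNAs is returned."""
    if source is None:
        from importlib import resources

        path = resources.files("mitomirscan") / "data" / "mirnas_liver_pnf.tsv"
        with path.open() as fh:
            return _read_mirna_tsv(fh, "bundled miRNA table")
    path = Path(source)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        return _read_mirna_fasta(text)
    with open(path) as fh:
        return _read_mirna_tsv(fh, str(path))


def _read_mirna_tsv(fh: Iterable, label: str) -> List[MiRNA]:
    out = []
    header = None
    for lineno, raw in enumerate(fh, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = [p.strip() for p in parts]
            if "id" not in header or "sequence" not in header:
                raise ValueError(f"{label}:{lineno}: need at least id and sequence columns")
            continue
        row = dict(zip(header, parts))
        try:
            out.append(
                MiRNA(
                    id=row["id"].strip(),
                    accession=row.get("accession", "").strip(),
                    sequence=row["sequence"].strip(),
                    fold_change=float(row.get("fold_change") or 0.0),
                    p_value=float(row.get("p_value") or 0.5),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{label}:{lineno}: {exc}") from exc
    return out


def _read_mirna_fasta(text: str) -> List[MiRNA]:
    out = []
    name = None
    chunks: List[str] = []
    for line in text.splitlines() + [">"]:
        if line.startswith(">"):
            if name is not None:
                out.append(MiRNA(id=name, sequence="".join(chunks)))
            name = line[1:].split()[0] if len(line) > 1 else None
            chunks = []
        else:
            chunks.append(line.strip())
    return out


def hits_to_tsv(hits: Sequence[SeedHit], path: Union[str, Path]) -> None:
    """Write hits in the package TSV dialect (one row per site)."""
    lines = ["mirna_id\tstart\tend\tstrand\tdisplay_range\tpattern"]
    for h in hits:
        lines.append(
            f"{h.mirna_id}\t{h.start}\t{h.end}\t{h.strand}\t"
            f"{h.display_range()}\t{h.matched_pattern}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
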