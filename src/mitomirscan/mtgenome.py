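"""Circular mitochondrial genome model: sequence, coordinates and feature map.

The human mitochondrial genome is a 16.5 kb circular molecule. All coordinates
in this package are 1-based inclusive on the reference (printed, light-strand)
orientation, matching the convention of the standard human mtDNA annotation.
An interval whose start exceeds its end wraps the sequence origin (the control
region is the canonical example).

The bundled reference fixture is NC_001807.4 (16,571 bp), the public human
mitochondrial genome sequence available to this package offline; the feature
map ships the standard rCRS (NC_012920) annotation coordinates, which differ
from NC_001807.4 numbering by at most 2 bp near three homopolymer indels.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from Bio import SeqIO

__all__ = [
    "MitoGenome",
    "MtFeature",
    "FeatureMap",
    "FEATURE_CLASSES",
    "GENE_CLASSES",
    "load_reference",
    "load_features",
    "subsequence",
    "reverse_complement",
    "interconvert",
    "features_overlapping",
]

DNA_ALPHABET = set("ACGTN")
RNA_ALPHABET = set("ACGUN")
NUC_ALPHABET = set("ACGTUN")

FEATURE_CLASSES = ("protein_coding", "tRNA", "rRNA", "non_coding")
#: feature classes that count as gene features for annotation precedence
GENE_CLASSES = ("protein_coding", "tRNA", "rRNA")

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

_DATA = resources.files("mitomirscan") / "data"
_REFERENCE_FASTA = "human_mt_NC_001807.fasta"
_FEATURES_TSV = "mt_features.tsv"


class SequenceAlphabetError(ValueError):
    """A sequence contains characters outside the nucleotide alphabet."""


def _validate_alphabet(seq: str, allowed: set, context: str = "sequence") -> str:
    s = seq.upper()
    bad = set(s) - allowed
    if bad:
        raise SequenceAlphabetError(
            f"{context} contains non-nucleotide characters: {sorted(bad)}"
        )
    return s


@dataclass(frozen=True)
class MitoGenome:
    """A (possibly circular) reference genome.

    Attributes
    ----------
    accession : str
        Sequence identifier (e.g. ``NC_001807.4``).
    sequence : str
        Upper-case DNA over ``{A,C,G,T,N}``.
    length : int
        Number of bases; always ``len(sequence)``.
    circular : bool
        Whether coordinates may wrap the origin.
    """

    accession: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        _validate_alphabet(self.sequence, DNA_ALPHABET, f"genome {self.accession!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise ValueError(f"genome {self.accession!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def subsequence(self, start: int, end: int) -> str:
        return subsequence(self, start, end)


@dataclass(frozen=True)
class MtFeature:
    """One annotated interval of the mitochondrial genome.

    ``start``/``end`` are 1-based inclusive; ``start > end`` marks an
    origin-wrapping feature (``wraps_origin`` is derived, never stored
    inconsistently). ``strand`` is ``L`` for features read on the printed
    reference strand and ``H`` for heavy-strand (reverse-orientation) genes.
    """

    name: str
    feature_class: str
    start: int
    end: int
    strand: str = "L"
    description: str = ""

    def __post_init__(self):
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"feature {self.name!r}: unknown feature class {self.feature_class!r} "
                f"(expected one of {FEATURE_CLASSES})"
            )
        if self.strand not in ("H", "L"):
            raise ValueError(f"feature {self.name!r}: strand must be 'H' or 'L'")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"feature {self.name!r}: coordinates must be >= 1")

    @property
    def wraps_origin(self) -> bool:
        return self.start > self.end

    def span(self, genome_length: int) -> int:
        """Number of bases covered, under circular arithmetic."""
        if self.wraps_origin:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def segments(self, genome_length: int) -> list:
        """Non-wrapping (start, end) segments covering the feature."""
        if self.wraps_origin:
            return [(self.start, genome_length), (1, self.end)]
        return [(self.start, self.end)]


def _segments_overlap(a: tuple, b: tuple) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


@dataclass
class FeatureMap:
    """Ordered collection of :class:`MtFeature` over one genome length."""

    features: list = field(default_factory=list)
    genome_length: int = 0

    def __post_init__(self):
        for f in self.features:
            if f.start > self.genome_length or f.end > self.genome_length:
                raise ValueError(
                    f"feature {f.name!r} ({f.start}..{f.end}) exceeds genome "
                    f"length {self.genome_length}"
                )

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[MtFeature]:
        return iter(self.features)

    def by_name(self, name: str) -> MtFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def class_counts(self) -> dict:
        counts: dict = {}
        for f in self.features:
            counts[f.feature_class] = counts.get(f.feature_class, 0) + 1
        return counts

    def overlapping(self, start: int, end: int) -> list:
        return features_overlapping(self, start, end)


def features_overlapping(fm: FeatureMap, start: int, end: int) -> list:
    """Features sharing at least one base with ``start..end`` (circular).

    A query with ``start > end`` wraps the origin. The result is ordered by
    feature start position, ties broken by name.
    """
    L = fm.genome_length
    if L == 0:
        return []
    if not (1 <= start <= L and 1 <= end <= L):
        raise ValueError(f"query {start}..{end} outside genome length {L}")
    if start > end:
        qsegs = [(start, L), (1, end)]
    else:
        qsegs = [(start, end)]
    out = []
    for f in fm.features:
        fsegs = f.segments(L)
        if any(_segments_overlap(q, s) for q in qsegs for s in fsegs):
            out.append(f)
    out.sort(key=lambda f: (f.start, f.name))
    return out


# ---------------------------------------------------------------------------
# sequence utilities


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement, DNA or RNA.

    The output alphabet follows the input (a sequence containing U is treated
    as RNA and complemented back into RNA). Applying the function twice
    returns the original sequence.
    """
    s = _validate_alphabet(seq, NUC_ALPHABET)
    if "U" in s and "T" in s:
        raise SequenceAlphabetError("sequence mixes T and U; alphabet is ambiguous")
    is_rna = "U" in s
    rc = s.translate(_COMPLEMENT)[::-1]
    if is_rna:
        rc = rc.replace("T", "U")
    return rc


def complement(seq: str) -> str:
    """Base-wise complement without reversal (parallel-strand reading)."""
    s = _validate_alphabet(seq, NUC_ALPHABET)
    if "U" in s and "T" in s:
        raise SequenceAlphabetError("sequence mixes T and U; alphabet is ambiguous")
    is_rna = "U" in s
    c = s.translate(_COMPLEMENT)
    if is_rna:
        c = c.replace("T", "U")
    return c


def interconvert(seq: str, direction: str) -> str:
    """Convert between RNA and DNA alphabets (U <-> T substitution only).

    ``direction`` is ``"rna_to_dna"`` or ``"dna_to_rna"``. Output is
    normalized to upper case; a round trip is the identity.
    """
    s = _validate_alphabet(seq, NUC_ALPHABET)
    if direction == "rna_to_dna":
        return s.replace("U", "T")
    if direction == "dna_to_rna":
        return s.replace("T", "U")
    raise ValueError(f"unknown direction {direction!r}")


def subsequence(genome: MitoGenome, start: int, end: int) -> str:
    """Bases ``start..end`` read 5'->3' on the reference orientation.

    When ``start > end`` on a circular genome the interval wraps through
    position 1. On a non-circular genome ``start > end`` is an error.
    """
    L = genome.length
    if not (1 <= start <= L and 1 <= end <= L):
        raise ValueError(f"coordinates {start}..{end} outside genome length {L}")
    if start <= end:
        return genome.sequence[start - 1 : end]
    if not genome.circular:
        raise ValueError(
            f"interval {start}..{end} wraps the origin but genome "
            f"{genome.accession!r} is not circular"
        )
    return genome.sequence[start - 1 :] + genome.sequence[:end]


# ---------------------------------------------------------------------------
# loaders


def load_reference(
    source: Optional[Union[str, Path]] = None,
    *,
    record_id: Optional[str] = None,
    circular: bool = True,
) -> MitoGenome:
    """Load a reference genome from FASTA or GenBank.

    With no ``source`` the bundled human mitochondrial reference fixture
    (NC_001807.4, 16,571 bp, circular) is returned. Multi-record files use
    the first record unless ``record_id`` selects one.
    """
    if source is None:
        with (_DATA / _REFERENCE_FASTA).open() as fh:
            return _read_reference(fh, "bundled reference", record_id, circular)
    path = Path(source)
    with open(path) as fh:
        return _read_reference(fh, str(path), record_id, circular)


def _read_reference(fh, label, record_id, circular) -> MitoGenome:
    text = fh.read()
    fmt = "genbank" if text.lstrip()[:5] == "LOCUS" else "fasta"
    try:
        records = list(SeqIO.parse(io.StringIO(text), fmt))
    except ValueError as exc:
        raise ValueError(f"malformed {fmt} in {label}: {exc}") from exc
    if not records:
        raise ValueError(f"no sequence records found in {label}")
    if record_id is not None:
        matches = [r for r in records if r.id == record_id or r.name == record_id]
        if not matches:
            raise ValueError(f"record {record_id!r} not found in {label}")
        rec = matches[0]
    else:
        rec = records[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise ValueError(f"record {rec.id!r} in {label} has an empty sequence")
    accession = rec.id.split()[0]
    return MitoGenome(accession=accession, sequence=seq, circular=circular)


def load_features(
    source: Optional[Union[str, Path]] = None,
    genome: Optional[MitoGenome] = None,
) -> FeatureMap:
    """Load a feature map from a tabular file or GenBank record.

    With no ``source`` the bundled fixture is used: the standard human mtDNA
    annotation (13 protein-coding, 22 tRNA, 2 rRNA genes) plus the control
    region (origin-wrapping, 16024..576) and hypervariable regions HVR1
    (16024..16383), HVR2 (57..372) and HVR3 (438..574).
    """
    if genome is None:
        genome = load_reference()
    if source is None:
        with (_DATA / _FEATURES_TSV).open() as fh:
            return _read_features_tsv(fh, "bundled feature map", genome)
    path = Path(source)
    text = path.read_text()
    if text.lstrip()[:5] == "LOCUS":
        return _read_features_genbank(text, str(path), genome)
    with open(path) as fh:
        return _read_features_tsv(fh, str(path), genome)


def _read_features_tsv(fh: Iterable, label: str, genome: MitoGenome) -> FeatureMap:
    features = []
    header = None
    for lineno, raw in enumerate(fh, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = [p.strip() for p in parts]
            expected = ["name", "class", "start", "end", "strand", "description"]
            if header[: len(expected)] != expected:
                raise ValueError(
                    f"{label}:{lineno}: expected columns {expected}, got {header}"
                )
            continue
        row = dict(zip(header, parts))
        try:
            feat = MtFeature(
                name=row["name"].strip(),
                feature_class=row["class"].strip(),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row.get("strand", "L").strip() or "L",
                description=row.get("description", "").strip(),
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{label}:{lineno}: {exc}") from exc
        features.append(feat)
    return FeatureMap(features=features, genome_length=genome.length)


_GENBANK_CLASSES = {"CDS": "protein_coding", "tRNA": "tRNA", "rRNA": "rRNA",
                    "D-loop": "non_coding"}


def _read_features_genbank(text: str, label: str, genome: MitoGenome) -> FeatureMap:
    try:
        rec = next(SeqIO.parse(io.StringIO(text), "genbank"))
    except (StopIteration, ValueError) as exc:
        raise ValueError(f"malformed GenBank in {label}: {exc}") from exc
    features = []
    for f in rec.features:
        if f.type not in _GENBANK_CLASSES:
            continue
        quals = f.qualifiers
        name = (quals.get("gene") or quals.get("product") or [f.type])[0]
        start = int(f.location.start) + 1
        end = int(f.location.end)
        strand = "H" if f.location.strand == -1 else "L"
        features.append(
            MtFeature(
                name=name,
                feature_class=_GENBANK_CLASSES[f.type],
                start=start,
                end=end,
                strand=strand,
                description=(quals.get("product") or [""])[0],
            )
        )
    return FeatureMap(features=features, genome_length=genome.length)
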