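"""MitomiR classification and mitochondrial-proteome target filtering.

Nuclear gene targets predicted for each miRNA (miRDB-style scores, 50-100)
are joined to a mitochondrial-localization score (IMPI, 0-1); genes above the
IMPI threshold (default 0.7, strict inequality) count as high-confidence
mitochondrial proteins. A separate evidence table records which miRNAs have
been experimentally isolated from mitochondria (MitomiRs). The cross
classification MitomiR x mt-genome sites x mt-proteome targets partitions the
input miRNA panel into eight cells.

ORF protein length follows the standard reading-frame arithmetic: an open
reading frame of ``n`` nucleotides (including the stop codon) encodes
``n/3 - 1`` amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from .annotate import HitTable
from .seedscan import MiRNA

__all__ = [
    "MitomirEvidence",
    "TargetRecord",
    "FilterResult",
    "PartitionReport",
    "UnknownMirnaError",
    "classify_mitomir",
    "filter_mito_targets",
    "orf_protein_length",
    "partition_mirnas",
    "load_evidence",
    "load_targets",
]


class UnknownMirnaError(KeyError):
    """A miRNA id is absent from the evidence table."""


@dataclass(frozen=True)
class MitomirEvidence:
    """Evidence snapshot for one miRNA: mitochondrial isolation flag plus
    display-only database target counts."""

    mirna_id: str
    is_mitomir: bool
    evidence_refs: tuple = ()
    mirdb_targets: Optional[int] = None
    mitominer_targets: Optional[int] = None
    impi_gt07_targets: Optional[int] = None


@dataclass(frozen=True)
class TargetRecord:
    """One predicted gene target with prediction and localization scores.

    ``mirna_ids`` lists every miRNA predicted to target the gene (a shared
    target appears once); ``mirna_id`` is the primary (first) of these.
    """

    mirna_id: str
    gene_id: str
    symbol: str
    target_score: float
    impi: Optional[float] = None
    orf_length_nt: Optional[int] = None
    mirna_ids: tuple = ()

    def __post_init__(self):
        if not self.mirna_ids:
            object.__setattr__(self, "mirna_ids", (self.mirna_id,))

    def validate(self) -> List[str]:
        problems = []
        if not (50 <= self.target_score <= 100):
            problems.append(
                f"{self.symbol}: target_score {self.target_score} outside [50, 100]"
            )
        if self.impi is not None and not (0 <= self.impi <= 1):
            problems.append(f"{self.symbol}: impi {self.impi} outside [0, 1]")
        return problems


@dataclass
class FilterResult:
    surviving: list
    per_mirna_flag: dict
    n_missing_impi: int = 0
    threshold: float = 0.7
    strict: bool = True


@dataclass
class PartitionReport:
    """Eight-cell cross classification of a miRNA panel.

    Cell keys are (is_mitomir, has_mt_genome_sites, targets_mt_proteome).
    The mt-genome-site axis is evaluated for MitomiRs only: seed scanning of
    the organellar genome is meaningful only for miRNAs present in
    mitochondria, so non-MitomiRs are recorded as having no interaction.
    """

    cells: dict = field(default_factory=dict)

    def cell(self, mitomir: bool, sites: bool, proteome: bool) -> list:
        return self.cells.get((mitomir, sites, proteome), [])

    def totals(self) -> dict:
        return {k: len(v) for k, v in self.cells.items()}

    def n_mirnas(self) -> int:
        return sum(len(v) for v in self.cells.values())

    def to_json_dict(self) -> dict:
        def key(k):
            return "mitomir={},mt_sites={},mt_proteome={}".format(
                *("yes" if b else "no" for b in k)
            )

        return {key(k): sorted(v) for k, v in sorted(self.cells.items())}


def classify_mitomir(
    mirna_id: str, evidence: Iterable[MitomirEvidence]
) -> bool:
    """Recorded MitomiR flag for ``mirna_id``.

    An id absent from the evidence table raises :class:`UnknownMirnaError`
    rather than silently returning ``False``.
    """
    for e in evidence:
        if e.mirna_id == mirna_id:
            return e.is_mitomir
    raise UnknownMirnaError(mirna_id)


def filter_mito_targets(
    targets: Sequence[TargetRecord],
    impi_threshold: float = 0.7,
    *,
    strict: bool = True,
    min_target_score: Optional[float] = None,
) -> FilterResult:
    """Retain targets whose IMPI exceeds the threshold.

    ``strict`` selects ``impi > threshold`` (default) versus ``>=``. Records
    lacking an IMPI score never survive but are tallied in
    ``n_missing_impi``. ``min_target_score`` optionally adds a secondary
    filter on the prediction score (off by default). ``per_mirna_flag`` maps
    every miRNA seen in the input to whether at least one of its targets
    survived.
    """
    if not (0 <= impi_threshold <= 1):
        raise ValueError(f"impi_threshold {impi_threshold} outside [0, 1]")
    problems: List[str] = []
    for t in targets:
        problems.extend(t.validate())
    if problems:
        raise ValueError("malformed target records: " + "; ".join(problems))

    flags: Dict[str, bool] = {}
    surviving: List[TargetRecord] = []
    n_missing = 0
    for t in targets:
        for mid in t.mirna_ids:
            flags.setdefault(mid, False)
        if t.impi is None:
            n_missing += 1
            continue
        if min_target_score is not None and t.target_score < min_target_score:
            continue
        keep = t.impi > impi_threshold if strict else t.impi >= impi_threshold
        if keep:
            surviving.append(t)
            for mid in t.mirna_ids:
                flags[mid] = True
    return FilterResult(
        surviving=surviving,
        per_mirna_flag=flags,
        n_missing_impi=n_missing,
        threshold=impi_threshold,
        strict=strict,
    )


def orf_protein_length(orf_length_nt: int) -> int:
    """Amino acids encoded by an ORF of ``orf_length_nt`` nucleotides
    (stop codon excluded)."""
    if orf_length_nt <= 0:
        raise ValueError(f"ORF length must be positive, got {orf_length_nt}")
    if orf_length_nt % 3:
        raise ValueError(f"ORF length {orf_length_nt} nt is not divisible by 3")
    return orf_length_nt // 3 - 1


def partition_mirnas(
    mirnas: Sequence[MiRNA],
    evidence: Sequence[MitomirEvidence],
    filter_result: FilterResult,
    hit_table: HitTable,
) -> PartitionReport:
    """Cross-classify each miRNA by MitomiR status, canonical mt-genome
    sites, and nuclear-encoded mt-proteome targets.

    The hit table must cover the MitomiRs of the panel (ids in the hit table
    that are not in the panel are an error); proteome flags come from the
    filter result; evidence must cover every panel member.
    """
    if not mirnas:
        raise ValueError("empty miRNA list")
    panel = [m.id for m in mirnas]
    unknown_hits = set(hit_table.counts) - set(panel)
    if unknown_hits:
        raise ValueError(f"hit table covers miRNAs outside the panel: {sorted(unknown_hits)}")
    cells: Dict[Tuple[bool, bool, bool], List[str]] = {}
    for mid in panel:
        is_mito = classify_mitomir(mid, evidence)  # raises on unknown id
        sites = bool(is_mito and hit_table.counts.get(mid, 0) > 0)
        proteome = bool(filter_result.per_mirna_flag.get(mid, False))
        cells.setdefault((is_mito, sites, proteome), []).append(mid)
    return PartitionReport(cells=cells)


# ---------------------------------------------------------------------------
# loaders

from importlib import resources

_DATA = resources.files("mitomirscan") / "data"


def _iter_tsv(fh, label: str, required: Sequence[str]):
    header = None
    for lineno, raw in enumerate(fh, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = [p.strip() for p in parts]
            missing = [c for c in required if c not in header]
            if missing:
                raise ValueError(f"{label}: missing columns {missing}")
            continue
        yield lineno, dict(zip(header, parts))


def load_evidence(source: Union[str, Path, None] = None) -> List[MitomirEvidence]:
    """MitomiR evidence table (bundled snapshot when no source given)."""
    if source is None:
        fh = (_DATA / "mitomir_evidence.tsv").open()
        label = "bundled evidence table"
    else:
        fh = open(source)
        label = str(source)
    out = []
    with fh:
        for lineno, row in _iter_tsv(fh, label, ["mirna_id", "is_mitomir"]):
            flag = row["is_mitomir"].strip().upper()
            if flag not in ("Y", "N"):
                raise ValueError(f"{label}:{lineno}: is_mitomir must be Y or N")

            def opt_int(col):
                v = row.get(col, "").strip() if row.get(col) else ""
                return int(v) if v else None

            refs = tuple(
                r for r in (row.get("evidence_refs") or "").strip().split(";") if r
            )
            out.append(
                MitomirEvidence(
                    mirna_id=row["mirna_id"].strip(),
                    is_mitomir=(flag == "Y"),
                    evidence_refs=refs,
                    mirdb_targets=opt_int("mirdb_targets"),
                    mitominer_targets=opt_int("mitominer_targets"),
                    impi_gt07_targets=opt_int("impi_gt07_targets"),
                )
            )
    return out


def load_targets(source: Union[str, Path, None] = None) -> List[TargetRecord]:
    """Per-miRNA gene-target table (bundled 7-record snapshot by default)."""
    if source is None:
        fh = (_DATA / "mito_targets.tsv").open()
        label = "bundled target table"
    else:
        fh = open(source)
        label = str(source)
    out = []
    with fh:
        for lineno, row in _iter_tsv(
            fh, label, ["mirna_id", "gene_id", "symbol", "target_score"]
        ):
            ids = tuple(s.strip() for s in row["mirna_id"].split(";") if s.strip())
            impi_s = (row.get("impi") or "").strip()
            orf_s = (row.get("orf_length_nt") or "").strip()
            try:
                out.append(
                    TargetRecord(
                        mirna_id=ids[0],
                        mirna_ids=ids,
                        gene_id=row["gene_id"].strip(),
                        symbol=row["symbol"].strip(),
                        target_score=float(row["target_score"]),
                        impi=float(impi_s) if impi_s else None,
                        orf_length_nt=int(orf_s) if orf_s else None,
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{label}:{lineno}: {exc}") from exc
    return out


def write_targets(records: Sequence[TargetRecord], path: Union[str, Path]) -> None:
    """Write a target table in the package TSV dialect."""
    lines = ["mirna_id\tgene_id\tsymbol\ttarget_score\timpi\torf_length_nt"]
    for t in records:
        impi = "" if t.impi is None else f"{t.impi:g}"
        orf = "" if t.orf_length_nt is None else str(t.orf_length_nt)
        lines.append(
            f"{';'.join(t.mirna_ids)}\t{t.gene_id}\t{t.symbol}\t"
            f"{t.target_score:g}\t{impi}\t{orf}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
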