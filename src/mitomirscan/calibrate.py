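"""Seed-matching convention calibration against published anchor sites.

Published mitochondrial seed-site tables rarely state their matching
convention precisely: which seed window was taken from the mature miRNA,
whether the site carries the seed's reverse complement (antiparallel, the
canonical duplex) or its non-reversed complement (parallel), and which strand
is labelled forward. Instead of guessing, the calibration procedure
enumerates the candidate conventions (window x geometry x strand labelling),
scores each by how many anchor rows it reproduces exactly, and returns the
best. Anchors that no convention reproduces are reported with a diagnosis of
what actually sits at the anchored interval; miRNAs whose anchors are only
reproduced by a convention other than the global best get a per-miRNA
override. miRNAs with identical effective seeds are flagged as
indistinguishable: no exact-window convention can assign them different hit
sets.

A tie between equally scoring conventions is an error, never a silent pick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .mtgenome import MitoGenome, subsequence
from .seedscan import (
    MATCH_MODES,
    ORIENTATIONS,
    MiRNA,
    SeedSpec,
    extract_seed,
    scan,
)

__all__ = [
    "Anchor",
    "CalibrationReport",
    "CalibrationTieError",
    "CANDIDATE_WINDOWS",
    "calibrate_convention",
    "load_anchors",
]

#: seed windows enumerated during calibration (1-based inclusive)
CANDIDATE_WINDOWS: Tuple[Tuple[int, int], ...] = ((2, 7), (1, 6), (1, 7), (2, 8), (3, 8))


class CalibrationTieError(RuntimeError):
    """Two or more conventions reproduce the anchors equally well."""


@dataclass(frozen=True)
class Anchor:
    """One published seed site: miRNA, 1-based inclusive coordinates, strand."""

    mirna_id: str
    start: int
    end: int
    strand: str  # "forward" | "reverse"
    display_range: str = ""


@dataclass
class CalibrationReport:
    global_spec: Optional[SeedSpec]
    overrides: dict  # mirna_id -> SeedSpec
    candidate_scores: dict  # str(spec) -> n anchors reproduced
    anchor_results: list  # per-anchor dicts
    unresolved_mirnas: list  # miRNAs none of whose anchors any convention matches
    indistinguishable_groups: list  # lists of miRNA ids sharing effective seeds
    failed: bool = False
    notes: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        def spec_str(sp: Optional[SeedSpec]) -> Optional[str]:
            if sp is None:
                return None
            return (
                f"window={sp.window_start}-{sp.window_end},"
                f"mode={sp.match_mode},orientation={sp.orientation}"
            )

        return {
            "failed": self.failed,
            "global_spec": spec_str(self.global_spec),
            "overrides": {m: spec_str(s) for m, s in sorted(self.overrides.items())},
            "candidate_scores": dict(sorted(self.candidate_scores.items())),
            "anchor_results": self.anchor_results,
            "unresolved_mirnas": sorted(self.unresolved_mirnas),
            "indistinguishable_groups": [sorted(g) for g in self.indistinguishable_groups],
            "notes": list(self.notes),
        }


def _spec_key(sp: SeedSpec) -> str:
    return f"window={sp.window_start}-{sp.window_end},mode={sp.match_mode},orientation={sp.orientation}"


def _candidate_specs(windows=CANDIDATE_WINDOWS) -> List[SeedSpec]:
    return [
        SeedSpec(window_start=a, window_end=b, match_mode=m, orientation=o)
        for (a, b) in windows
        for m in MATCH_MODES
        for o in ORIENTATIONS
    ]


def _anchor_reproduced(
    genome: MitoGenome, mirna: MiRNA, anchor: Anchor, spec: SeedSpec
) -> bool:
    if len(mirna.sequence) < spec.window_end:
        return False
    hits = scan(genome, extract_seed(mirna, spec))
    return any(
        h.start == anchor.start and h.end == anchor.end and h.strand == anchor.strand
        for h in hits
    )


def _diagnose_site(
    genome: MitoGenome, anchor: Anchor, mirnas: Sequence[MiRNA]
) -> dict:
    """What actually sits at an anchored interval, and whose pattern it is."""
    word = subsequence(genome, anchor.start, anchor.end)
    matches = []
    for mir in mirnas:
        for sp in _candidate_specs():
            if len(mir.sequence) < sp.window_end:
                continue
            seed = extract_seed(mir, sp)
            k = len(seed.patterns[0])
            if k != len(word):
                continue
            fwd_label = "forward" if sp.orientation == "reference" else "reverse"
            rev_label = "reverse" if sp.orientation == "reference" else "forward"
            from .mtgenome import reverse_complement as _rc

            if word in seed.patterns and anchor.strand == fwd_label:
                matches.append(f"{mir.id}:{_spec_key(sp)}")
            elif _rc(word) in seed.patterns and anchor.strand == rev_label:
                matches.append(f"{mir.id}:{_spec_key(sp)}")
    return {"site_sequence": word, "matching_patterns": sorted(set(matches))}


def calibrate_convention(
    genome: MitoGenome,
    mirnas: Sequence[MiRNA],
    anchors: Sequence[Anchor],
    windows: Sequence[Tuple[int, int]] = CANDIDATE_WINDOWS,
) -> CalibrationReport:
    """Choose the seed-matching convention that reproduces the anchors.

    Returns a report with the best-scoring global convention, per-miRNA
    overrides where a miRNA's anchors demand a different convention, and a
    per-anchor account (including a diagnosis of anchors nothing reproduces).
    Raises :class:`CalibrationTieError` when distinct conventions tie on the
    global score; reports failure (without raising) when no convention
    reproduces any anchor.
    """
    if not anchors:
        raise ValueError("no anchors given")
    by_id = {m.id: m for m in mirnas}
    missing = sorted({a.mirna_id for a in anchors} - set(by_id))
    if missing:
        raise ValueError(f"anchors reference unknown miRNAs: {missing}")

    specs = _candidate_specs(windows)
    # pass matrix: spec -> anchor index -> bool
    passes: Dict[str, List[bool]] = {}
    for sp in specs:
        row = [
            _anchor_reproduced(genome, by_id[a.mirna_id], a, sp) for a in anchors
        ]
        passes[_spec_key(sp)] = row
    scores = {k: sum(v) for k, v in passes.items()}
    best_score = max(scores.values())

    report_scores = dict(scores)
    if best_score == 0:
        diagnoses = [
            {
                "anchor": f"{a.mirna_id}@{a.start}-{a.end}:{a.strand}",
                "reproduced_by_global": False,
                "reproduced_by_override": False,
                **_diagnose_site(genome, a, mirnas),
            }
            for a in anchors
        ]
        return CalibrationReport(
            global_spec=None,
            overrides={},
            candidate_scores=report_scores,
            anchor_results=diagnoses,
            unresolved_mirnas=sorted({a.mirna_id for a in anchors}),
            indistinguishable_groups=[],
            failed=True,
            notes=["no candidate convention reproduces any anchor"],
        )

    top = [sp for sp in specs if scores[_spec_key(sp)] == best_score]
    if len(top) > 1:
        raise CalibrationTieError(
            "conventions tie at score "
            f"{best_score}: {[_spec_key(sp) for sp in top]}"
        )
    global_spec = top[0]
    global_row = passes[_spec_key(global_spec)]

    # per-miRNA overrides: a miRNA whose anchors all fail under the global
    # convention but all pass under exactly one other convention uses that one
    overrides: Dict[str, SeedSpec] = {}
    unresolved: List[str] = []
    notes: List[str] = []
    anchor_idx_by_mirna: Dict[str, List[int]] = {}
    for i, a in enumerate(anchors):
        anchor_idx_by_mirna.setdefault(a.mirna_id, []).append(i)
    for mid, idxs in anchor_idx_by_mirna.items():
        if all(global_row[i] for i in idxs):
            continue
        if any(global_row[i] for i in idxs):
            notes.append(
                f"{mid}: anchors only partially reproduced by the global convention"
            )
            continue
        full = [sp for sp in specs if all(passes[_spec_key(sp)][i] for i in idxs)]
        if not full:
            unresolved.append(mid)
            continue
        # prefer conventions sharing the global geometry and labelling
        full.sort(
            key=lambda sp: (
                sp.match_mode != global_spec.match_mode,
                sp.orientation != global_spec.orientation,
                specs.index(sp),
            )
        )
        overrides[mid] = full[0]
        if len(full) > 1:
            notes.append(
                f"{mid}: override {_spec_key(full[0])} chosen among "
                f"{[_spec_key(sp) for sp in full]}"
            )

    # per-anchor account
    anchor_results = []
    for i, a in enumerate(anchors):
        ov = overrides.get(a.mirna_id)
        entry = {
            "anchor": f"{a.mirna_id}@{a.start}-{a.end}:{a.strand}",
            "display_range": a.display_range,
            "reproduced_by_global": global_row[i],
            "reproduced_by_override": bool(
                ov and passes[_spec_key(ov)][i]
            ),
        }
        if not entry["reproduced_by_global"] and not entry["reproduced_by_override"]:
            entry.update(_diagnose_site(genome, a, mirnas))
        anchor_results.append(entry)

    # miRNAs sharing the effective seed window are indistinguishable
    groups: Dict[tuple, List[str]] = {}
    for mir in mirnas:
        sp = overrides.get(mir.id, global_spec)
        if len(mir.sequence) < sp.window_end:
            continue
        seed = extract_seed(mir, sp)
        groups.setdefault(seed.patterns, []).append(mir.id)
    indist = [g for g in groups.values() if len(g) > 1]
    for g in indist:
        notes.append(
            "identical effective seeds, hit sets cannot differ: " + ", ".join(sorted(g))
        )

    return CalibrationReport(
        global_spec=global_spec,
        overrides=overrides,
        candidate_scores=report_scores,
        anchor_results=anchor_results,
        unresolved_mirnas=unresolved,
        indistinguishable_groups=indist,
        failed=False,
        notes=notes,
    )


def load_anchors(source: Union[str, Path, None] = None) -> List[Anchor]:
    """Anchor rows from TSV (mirna_id, start, end, strand, display_range);
    bundled published-table anchors when no source is given."""
    if source is None:
        fh = (resources.files("mitomirscan") / "data" / "calibration_anchors.tsv").open()
        label = "bundled anchors"
    else:
        fh = open(source)
        label = str(source)
    out = []
    header = None
    with fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = [p.strip() for p in parts]
                continue
            row = dict(zip(header, parts))
            try:
                strand = row["strand"].strip()
                if strand not in ("forward", "reverse"):
                    raise ValueError(f"bad strand {strand!r}")
                out.append(
                    Anchor(
                        mirna_id=row["mirna_id"].strip(),
                        start=int(row["start"]),
                        end=int(row["end"]),
                        strand=strand,
                        display_range=(row.get("display_range") or "").strip(),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{label}:{lineno}: {exc}") from exc
    return out
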