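"""Protein sorting-signal scanner.

Scans protein sequences for the linear internalization/lysosomal sorting
signals relevant to peripheral quality control: tyrosine-based YxxPhi and
acidic dileucine AP-adaptor motifs, caveolin-binding aromatic motifs,
ALIX-binding YPXnL motifs, and KFERQ-related pentapeptides recognized by
chaperone-mediated autophagy. Pattern definitions live in a YAML data file so
they can be amended without touching code; all overlapping matches are
reported with 1-based coordinates. Hits can optionally be restricted to
annotated cytosolic regions, since only cytosolically exposed signals are
accessible to the sorting machinery.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml
from Bio import SeqIO

from .params import ParameterError

__all__ = [
    "ProteinRecord",
    "TopologyAnnotation",
    "MotifHit",
    "MOTIF_CLASSES",
    "scan_motifs",
    "filter_by_topology",
    "read_fasta",
    "read_topology",
]

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ParameterError(f"record {self.id!r}: empty sequence")
        bad = [(i + 1, aa) for i, aa in enumerate(seq) if aa not in STANDARD_RESIDUES]
        if bad:
            pos, aa = bad[0]
            raise ParameterError(
                f"record {self.id!r}: non-standard residue {aa!r} at position {pos}"
                + (f" (+{len(bad) - 1} more)" if len(bad) > 1 else "")
            )


@dataclass(frozen=True)
class TopologyAnnotation:
    """1-based inclusive (start, end) intervals of cytosolic sequence."""

    cytosolic_ranges: tuple

    def __post_init__(self) -> None:
        ranges = tuple(tuple(int(v) for v in r) for r in self.cytosolic_ranges)
        object.__setattr__(self, "cytosolic_ranges", ranges)
        prev_end = 0
        for start, end in ranges:
            if start < 1 or end < start:
                raise ParameterError(f"invalid interval ({start}, {end})")
            if start <= prev_end:
                raise ParameterError("cytosolic intervals must be sorted and non-overlapping")
            prev_end = end

    def contains(self, start: int, end: int) -> bool:
        return any(s <= start and end <= e for s, e in self.cytosolic_ranges)


@dataclass(frozen=True)
class MotifHit:
    record_id: str
    motif_class: str
    start: int  # 1-based
    peptide: str
    in_cytosolic: bool | None = None

    @property
    def end(self) -> int:
        return self.start + len(self.peptide) - 1


def _default_pattern_path() -> Path:
    return Path(resources.files("hergqc").joinpath("data/motifs.yaml"))


@lru_cache(maxsize=4)
def _load_patterns(path_str: str) -> dict:
    raw = yaml.safe_load(Path(path_str).read_text())
    compiled = {name: re.compile(pat) for name, pat in raw["regex"].items()}
    return {"regex": compiled, "kferq_rule": raw["kferq_rule"]}


def _patterns(path: str | Path | None = None) -> dict:
    p = Path(path) if path is not None else _default_pattern_path()
    return _load_patterns(str(p.resolve()))


MOTIF_CLASSES = (
    "tyrosine_YXXphi",
    "dileucine",
    "KFERQ_related",
    "caveolin_binding",
    "ALIX_YPXnL",
)


def _regex_hits(record: ProteinRecord, name: str, pattern: re.Pattern) -> list[MotifHit]:
    hits = []
    pos = 0
    while True:
        m = pattern.search(record.sequence, pos)
        if m is None:
            break
        hits.append(MotifHit(record.id, name, m.start() + 1, m.group(0)))
        pos = m.start() + 1  # overlapping matches at later offsets
    return hits


def _kferq_window_ok(window: str, rule: dict) -> bool:
    """Does any glutamine in the window leave a CMA-competent 4-residue core?"""
    anchor = rule["anchor"]
    b_lo, b_hi = rule["basic_count"]
    h_lo, h_hi = rule["hydrophobic_count"]
    basic, hydrophobic, acidic = set(rule["basic"]), set(rule["hydrophobic"]), set(rule["acidic"])
    for i, aa in enumerate(window):
        if aa != anchor:
            continue
        rest = window[:i] + window[i + 1 :]
        nb = sum(r in basic for r in rest)
        nh = sum(r in hydrophobic for r in rest)
        na = sum(r in acidic for r in rest)
        if b_lo <= nb <= b_hi and h_lo <= nh <= h_hi and na <= rule["acidic_max"]:
            # the four non-anchor residues must be fully accounted for
            if nb + nh + na == len(rest):
                return True
    return False


def _kferq_hits(record: ProteinRecord, rule: dict) -> list[MotifHit]:
    length = int(rule["length"])
    seq = record.sequence
    hits = []
    for i in range(len(seq) - length + 1):
        window = seq[i : i + length]
        if _kferq_window_ok(window, rule):
            hits.append(MotifHit(record.id, "KFERQ_related", i + 1, window))
    return hits


def scan_motifs(
    record: ProteinRecord,
    classes=None,
    pattern_file: str | Path | None = None,
) -> list[MotifHit]:
    """Report all (overlapping) sorting-signal matches in a protein sequence.

    Hits are ordered by (start, motif_class). ``classes`` restricts the scan
    to a subset of :data:`MOTIF_CLASSES`.
    """
    selected = tuple(classes) if classes is not None else MOTIF_CLASSES
    unknown = set(selected) - set(MOTIF_CLASSES)
    if unknown:
        raise ParameterError(f"unknown motif classes {sorted(unknown)}; known: {MOTIF_CLASSES}")
    pats = _patterns(pattern_file)
    hits: list[MotifHit] = []
    for name in selected:
        if name == "KFERQ_related":
            hits.extend(_kferq_hits(record, pats["kferq_rule"]))
        else:
            hits.extend(_regex_hits(record, name, pats["regex"][name]))
    return sorted(hits, key=lambda h: (h.start, h.motif_class))


def filter_by_topology(hits: list[MotifHit], topo: TopologyAnnotation) -> list[MotifHit]:
    """Keep hits whose full peptide lies inside a cytosolic interval.

    Returned hits carry ``in_cytosolic=True``; hits straddling an interval
    boundary are dropped.
    """
    return [
        MotifHit(h.record_id, h.motif_class, h.start, h.peptide, in_cytosolic=True)
        for h in hits
        if topo.contains(h.start, h.end)
    ]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read single- or multi-record protein FASTA."""
    records = [ProteinRecord(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ParameterError(f"no FASTA records in {path}")
    return records


def read_topology(path: str | Path) -> TopologyAnnotation:
    """Read a BED-like TSV of 1-based inclusive cytosolic intervals (start<TAB>end)."""
    ranges = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParameterError(f"topology line needs start<TAB>end: {line!r}")
        ranges.append((int(fields[0]), int(fields[1])))
    return TopologyAnnotation(tuple(ranges))
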