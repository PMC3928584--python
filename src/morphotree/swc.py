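"""Reading, validating and writing SWC reconstructions.

An SWC file is a plain-text format for traced neurons: a header of
``#``-prefixed comment lines followed by one record per line with seven
whitespace-separated fields::

    index  structure_flag  x  y  z  radius  parent_index

Coordinates and radii are in micrometres.  ``parent_index`` is ``-1`` for a
root record; every other record's parent must appear earlier in the file.
Two points joined by a straight line constitute a *segment*, so a single-root
reconstruction with *n* points has *n − 1* segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SwcRecord",
    "Reconstruction",
    "Finding",
    "SwcParseError",
    "SwcValidationError",
    "STRUCTURE_NAMES",
    "read_swc",
    "parse_swc",
    "write_swc",
    "format_swc",
    "validate_reconstruction",
    "renumber",
]

#: Standard SWC structure-flag codes.  The four classes named by tracing
#: conventions; anything else is reported as a warning, not an error.
STRUCTURE_NAMES = {
    1: "soma",
    2: "axon",
    3: "basal dendrite",
    4: "apical dendrite",
}

SOMA_FLAG = 1


class SwcParseError(ValueError):
    """A line of an SWC file could not be parsed."""


class SwcValidationError(ValueError):
    """A reconstruction failed strict validation."""

    def __init__(self, findings: Sequence["Finding"]):
        self.findings = list(findings)
        msg = "; ".join(str(f) for f in self.findings)
        super().__init__(f"reconstruction is not internally consistent: {msg}")


@dataclass(frozen=True)
class SwcRecord:
    """One 7-field SWC row."""

    index: int
    structure_flag: int
    x: float
    y: float
    z: float
    radius: float
    parent_index: int

    @property
    def is_root(self) -> bool:
        return self.parent_index == -1

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class Finding:
    """A single validation finding (data, not an exception)."""

    code: str
    record_index: int
    message: str
    severity: str = "error"  # "error" | "warning"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] record {self.record_index}: {self.message}"


@dataclass
class Reconstruction:
    """An ordered SWC record collection plus its verbatim header."""

    records: list[SwcRecord]
    header: list[str] = field(default_factory=list)
    source_name: str = "<memory>"

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_points(self) -> int:
        return len(self.records)

    @property
    def n_segments(self) -> int:
        """Number of segments = number of non-root records."""
        return sum(1 for r in self.records if not r.is_root)

    @property
    def roots(self) -> list[SwcRecord]:
        return [r for r in self.records if r.is_root]

    def record_by_index(self, index: int) -> SwcRecord:
        return self._index_map()[index]

    def _index_map(self) -> dict[int, SwcRecord]:
        return {r.index: r for r in self.records}

    def children_map(self) -> dict[int, list[SwcRecord]]:
        """Map record index -> list of child records, in file order."""
        out: dict[int, list[SwcRecord]] = {}
        for r in self.records:
            if not r.is_root:
                out.setdefault(r.parent_index, []).append(r)
        return out


def _parse_record(tokens: list[str], lineno: int, source: str) -> SwcRecord:
    if len(tokens) != 7:
        raise SwcParseError(
            f"{source}:{lineno}: expected 7 fields, got {len(tokens)}"
        )
    try:
        idx = int(tokens[0])
        flag = int(tokens[1])
        x, y, z, radius = (float(t) for t in tokens[2:6])
        parent = int(tokens[6])
    except ValueError as exc:
        raise SwcParseError(f"{source}:{lineno}: non-numeric field ({exc})") from None
    if idx <= 0:
        raise SwcParseError(f"{source}:{lineno}: index must be a positive integer")
    # Any negative parent is a root sentinel; normalize to -1.
    if parent < 0:
        parent = -1
    return SwcRecord(idx, flag, x, y, z, radius, parent)


def parse_swc(text: str, source_name: str = "<string>") -> Reconstruction:
    """Parse SWC content from a string (no validation)."""
    header: list[str] = []
    records: list[SwcRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            if not records:
                header.append(line.rstrip("\n"))
            continue
        records.append(_parse_record(stripped.split(), lineno, source_name))
    return Reconstruction(records=records, header=header, source_name=source_name)


def read_swc(path: str | Path, strict: bool = True) -> Reconstruction:
    """Read an SWC file.

    With ``strict=True`` (default) the reconstruction is validated and an
    :class:`SwcValidationError` is raised on any error-level finding; with
    ``strict=False`` the caller is expected to run
    :func:`validate_reconstruction` itself.
    """
    path = Path(path)
    rec = parse_swc(path.read_text(), source_name=str(path))
    if strict:
        findings = [f for f in validate_reconstruction(rec) if f.severity == "error"]
        if findings:
            raise SwcValidationError(findings)
    return rec


def validate_reconstruction(rec: Reconstruction) -> list[Finding]:
    """Check internal consistency; an empty list means consistent.

    Findings cover duplicate indices, dangling or forward parent references,
    zero-length segments (child coordinates equal to the parent's), negative
    radii, missing roots, and unknown structure flags (warning only).
    """
    findings: list[Finding] = []
    seen: dict[int, SwcRecord] = {}
    any_root = False
    for rec_row in rec.records:
        if rec_row.index in seen:
            findings.append(
                Finding("duplicate-index", rec_row.index, "index already used")
            )
        if rec_row.is_root:
            any_root = True
        else:
            parent = seen.get(rec_row.parent_index)
            if parent is None:
                findings.append(
                    Finding(
                        "dangling-parent",
                        rec_row.index,
                        f"parent {rec_row.parent_index} not defined earlier in file",
                    )
                )
            elif parent.xyz == rec_row.xyz:
                findings.append(
                    Finding(
                        "zero-length-segment",
                        rec_row.index,
                        "child coordinates equal parent coordinates",
                    )
                )
        if rec_row.radius < 0:
            findings.append(
                Finding("negative-radius", rec_row.index, f"radius {rec_row.radius}")
            )
        if rec_row.structure_flag not in STRUCTURE_NAMES:
            findings.append(
                Finding(
                    "unknown-structure-flag",
                    rec_row.index,
                    f"flag {rec_row.structure_flag} is not a standard code",
                    severity="warning",
                )
            )
        seen[rec_row.index] = rec_row
    if rec.records and not any_root:
        findings.append(Finding("no-root", rec.records[0].index, "no record with parent -1"))
    return findings


def format_swc(rec: Reconstruction, precision: int = 6) -> str:
    """Render a reconstruction as SWC text (header then records).

    Floats are emitted with ``precision`` significant digits, which exceeds
    the precision of the public archives this format comes from.
    """
    lines: list[str] = []
    for h in rec.header:
        lines.append(h if h.lstrip().startswith("#") else f"# {h}")
    fmt = f"%.{precision}g"
    for r in rec.records:
        lines.append(
            f"{r.index} {r.structure_flag} {fmt % r.x} {fmt % r.y} "
            f"{fmt % r.z} {fmt % r.radius} {r.parent_index}"
        )
    return "\n".join(lines) + "\n"


def write_swc(rec: Reconstruction, path: str | Path, precision: int = 6) -> None:
    """Write a reconstruction to ``path`` as SWC text."""
    Path(path).write_text(format_swc(rec, precision=precision))


def renumber(rec: Reconstruction) -> Reconstruction:
    """Return a copy with contiguous 1-based indices in file order.

    Arbitrary positive indices are legal on read; this produces the
    canonical numbering used when emitting generated neurons.
    """
    mapping = {r.index: i + 1 for i, r in enumerate(rec.records)}
    new_records = [
        replace(
            r,
            index=mapping[r.index],
            parent_index=-1 if r.is_root else mapping[r.parent_index],
        )
        for r in rec.records
    ]
    return Reconstruction(new_records, header=list(rec.header), source_name=rec.source_name)


def segment_length(a: SwcRecord, b: SwcRecord) -> float:
    """Euclidean 3D length of the segment joining two records."""
    return math.dist(a.xyz, b.xyz)


def iter_segments(rec: Reconstruction) -> Iterable[tuple[SwcRecord, SwcRecord]]:
    """Yield (parent_record, child_record) for every segment in file order."""
    index_map = rec._index_map()
    for r in rec.records:
        if not r.is_root:
            yield index_map[r.parent_index], r
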