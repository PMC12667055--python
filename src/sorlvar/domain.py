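"""SORL1 domain architecture: residue-to-domain and residue-to-repeat mapping.

SORL1 (SORLA) is a 2,214-residue multidomain endosomal sorting receptor.
Several of its domains are built from repeated units — eleven ~40-residue
complement-type repeats (CR), six fibronectin type-III (3Fn) domains, the six
blades of the YWTD beta-propeller, and the two ligand-release loops (L1/L2)
of the VPS10p beta-propeller.  Pathogenicity rules for missense variants are
phrased in *within-repeat* coordinates (e.g. "calcium-cage position 37 of a
CR domain"), so the central operation here is mapping a global residue index
to its segment, repeat unit and within-repeat position.

Coordinates are 1-based inclusive throughout, matching HGVS p. notation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Union

import yaml

__all__ = [
    "SEGMENT_NAMES",
    "REPEAT_CLASSES",
    "REPEAT_PARENT_SEGMENT",
    "DomainSegment",
    "RepeatUnit",
    "DomainArchitecture",
    "ResidueContext",
    "ArchitectureError",
    "load_architecture",
    "locate_residue",
]

SEGMENT_NAMES = (
    "signal_peptide",
    "pro",
    "VPS10p",
    "10CC",
    "YWTD",
    "EGF",
    "CR_cluster",
    "3Fn_cassette",
    "TM_tail",
)

REPEAT_CLASSES = ("CR", "3Fn", "YWTD_blade", "L1_loop", "L2_loop")

#: Segment each repeat class nominally lives in.  Repeat units may overhang
#: their parent segment boundary by a small margin (see
#: :data:`MAX_REPEAT_OVERHANG`), reflecting genuinely fuzzy domain edges.
REPEAT_PARENT_SEGMENT: Mapping[str, str] = {
    "CR": "CR_cluster",
    "3Fn": "3Fn_cassette",
    "YWTD_blade": "YWTD",
    "L1_loop": "VPS10p",
    "L2_loop": "VPS10p",
}

#: Repeats may extend at most this many residues beyond their parent segment.
MAX_REPEAT_OVERHANG = 10


class ArchitectureError(ValueError):
    """Raised when a domain architecture config violates its invariants."""


@dataclass(frozen=True)
class DomainSegment:
    """A contiguous residue range forming one named domain segment."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.name not in SEGMENT_NAMES:
            raise ArchitectureError(f"unknown segment name {self.name!r}")
        if not (1 <= self.start <= self.end):
            raise ArchitectureError(
                f"segment {self.name}: invalid range {self.start}..{self.end}"
            )

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class RepeatUnit:
    """One repeat unit (e.g. the 3rd CR domain) inside a repeated segment."""

    repeat_class: str
    index: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise ArchitectureError(f"unknown repeat class {self.repeat_class!r}")
        if self.index < 1:
            raise ArchitectureError(f"repeat index must be >= 1, got {self.index}")
        if not (1 <= self.start <= self.end):
            raise ArchitectureError(
                f"repeat {self.repeat_class}{self.index}: invalid range "
                f"{self.start}..{self.end}"
            )

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    def position_of(self, residue: int) -> int:
        """Within-repeat (1-based) position of a global residue index."""
        if residue not in self:
            raise ValueError(
                f"residue {residue} not in repeat "
                f"{self.repeat_class}{self.index} ({self.start}..{self.end})"
            )
        return residue - self.start + 1


@dataclass(frozen=True)
class ResidueContext:
    """Where a residue sits: segment, and repeat coordinates when applicable."""

    position: int
    segment: str
    repeat_class: Optional[str] = None
    repeat_index: Optional[int] = None
    repeat_position: Optional[int] = None

    def __post_init__(self) -> None:
        fields = (self.repeat_class, self.repeat_index, self.repeat_position)
        if any(f is None for f in fields) != all(f is None for f in fields):
            raise ValueError("repeat fields must be all present or all absent")


@dataclass
class DomainArchitecture:
    """Validated segment + repeat layout of the protein.

    ``reference_sequence`` (one-letter amino acids, length ``protein_length``)
    is optional; it is only required to validate reference residues for the
    cysteine gain/loss rules and by the synthetic variant generator.
    """

    protein_length: int
    segments: list[DomainSegment]
    repeats: list[RepeatUnit] = field(default_factory=list)
    reference_sequence: Optional[str] = None
    name: str = "custom"

    def __post_init__(self) -> None:
        self._validate()

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        if self.protein_length < 1:
            raise ArchitectureError("protein_length must be positive")
        segs = sorted(self.segments, key=lambda s: s.start)
        if not segs:
            raise ArchitectureError("at least one segment required")
        if segs[0].start != 1:
            raise ArchitectureError("segments must start at residue 1")
        for prev, cur in zip(segs, segs[1:]):
            if cur.start <= prev.end:
                raise ArchitectureError(
                    f"segments overlap: {prev.name} ({prev.start}..{prev.end}) "
                    f"and {cur.name} ({cur.start}..{cur.end})"
                )
            if cur.start != prev.end + 1:
                raise ArchitectureError(
                    f"gap between segments {prev.name} (ends {prev.end}) and "
                    f"{cur.name} (starts {cur.start})"
                )
        if segs[-1].end != self.protein_length:
            raise ArchitectureError(
                f"segments end at {segs[-1].end}, expected {self.protein_length}"
            )
        self.segments = segs

        by_name = {s.name: s for s in segs}
        by_class: dict[str, list[RepeatUnit]] = {}
        for rep in self.repeats:
            by_class.setdefault(rep.repeat_class, []).append(rep)
        for cls, reps in by_class.items():
            reps.sort(key=lambda r: r.start)
            indices = [r.index for r in reps]
            if indices != sorted(indices):
                raise ArchitectureError(
                    f"{cls} repeats are not index-ordered along the sequence"
                )
            for prev, cur in zip(reps, reps[1:]):
                if cur.start <= prev.end:
                    raise ArchitectureError(
                        f"{cls} repeats {prev.index} and {cur.index} overlap"
                    )
            parent_name = REPEAT_PARENT_SEGMENT[cls]
            parent = by_name.get(parent_name)
            if parent is None:
                raise ArchitectureError(
                    f"repeat class {cls} requires segment {parent_name}"
                )
            for rep in reps:
                over = max(parent.start - rep.start, 0) + max(
                    rep.end - parent.end, 0
                )
                if over > MAX_REPEAT_OVERHANG:
                    raise ArchitectureError(
                        f"repeat {cls}{rep.index} ({rep.start}..{rep.end}) lies "
                        f"outside parent segment {parent_name} "
                        f"({parent.start}..{parent.end}) by {over} residues"
                    )
                if over > 0:
                    warnings.warn(
                        f"repeat {cls}{rep.index} overhangs its parent segment "
                        f"{parent_name} by {over} residue(s)",
                        stacklevel=3,
                    )
        self.repeats = [r for cls in sorted(by_class) for r in by_class[cls]]

        if self.reference_sequence is not None:
            if len(self.reference_sequence) != self.protein_length:
                raise ArchitectureError(
                    "reference_sequence length "
                    f"{len(self.reference_sequence)} != protein_length "
                    f"{self.protein_length}"
                )

    # -- queries ---------------------------------------------------------

    def segment_at(self, position: int) -> DomainSegment:
        self._check_bounds(position)
        for seg in self.segments:
            if position in seg:
                return seg
        raise AssertionError("unreachable: segments cover 1..protein_length")

    def repeats_at(self, position: int) -> list[RepeatUnit]:
        return [r for r in self.repeats if position in r]

    def repeat(self, repeat_class: str, index: int) -> RepeatUnit:
        for r in self.repeats:
            if r.repeat_class == repeat_class and r.index == index:
                return r
        raise KeyError(f"no repeat {repeat_class}{index}")

    def _check_bounds(self, position: int) -> None:
        if not (1 <= position <= self.protein_length):
            raise IndexError(
                f"residue {position} out of range 1..{self.protein_length}"
            )

    def residue(self, position: int) -> str:
        if self.reference_sequence is None:
            raise ValueError("architecture has no reference sequence")
        self._check_bounds(position)
        return self.reference_sequence[position - 1]


def locate_residue(arch: DomainArchitecture, position: int) -> ResidueContext:
    """Map a global residue index to its segment and repeat coordinates.

    When the residue lies in a repeat unit, ``repeat_position`` is the 1-based
    offset within that repeat (``position - repeat.start + 1``).  If a residue
    falls in more than one repeat (possible near fuzzy boundaries), the repeat
    whose parent segment contains the residue wins.
    """
    seg = arch.segment_at(position)
    candidates = arch.repeats_at(position)
    rep: Optional[RepeatUnit] = None
    if len(candidates) == 1:
        rep = candidates[0]
    elif len(candidates) > 1:
        matching = [
            r for r in candidates if REPEAT_PARENT_SEGMENT[r.repeat_class] == seg.name
        ]
        rep = (matching or candidates)[0]
    if rep is None:
        return ResidueContext(position=position, segment=seg.name)
    return ResidueContext(
        position=position,
        segment=seg.name,
        repeat_class=rep.repeat_class,
        repeat_index=rep.index,
        repeat_position=rep.position_of(position),
    )


# -- config loading ------------------------------------------------------

ConfigSource = Union[str, Mapping, "os.PathLike[str]"]


def _as_config_dict(source: Optional[ConfigSource]) -> dict:
    if source is None:
        text = (
            resources.files("sorlvar").joinpath("data/sorl1_default.yaml").read_text()
        )
        return yaml.safe_load(text)
    if isinstance(source, Mapping):
        return dict(source)
    with open(source) as fh:
        return yaml.safe_load(fh)


def load_architecture(source: Optional[ConfigSource] = None) -> DomainArchitecture:
    """Load and validate a domain architecture from a YAML file or dict.

    With no argument, loads the packaged ``sorl1_default`` architecture.  The
    config has blocks ``segments`` (name/start/end), ``repeats``
    (class/index/start/end) and optional ``anchors``: independently stated
    (residue, repeat_class, repeat_position) facts that the loaded layout must
    reproduce, used to pin repeat boundaries that are otherwise approximate.
    """
    cfg = _as_config_dict(source)
    try:
        segments = [
            DomainSegment(name=s["name"], start=int(s["start"]), end=int(s["end"]))
            for s in cfg["segments"]
        ]
        repeats = [
            RepeatUnit(
                repeat_class=r["class"],
                index=int(r["index"]),
                start=int(r["start"]),
                end=int(r["end"]),
            )
            for r in cfg.get("repeats", [])
        ]
    except KeyError as exc:  # missing required field
        raise ArchitectureError(f"config missing field {exc}") from exc
    arch = DomainArchitecture(
        protein_length=int(cfg["protein_length"]),
        segments=segments,
        repeats=repeats,
        reference_sequence=cfg.get("reference_sequence"),
        name=cfg.get("name", "custom"),
    )
    for anchor in cfg.get("anchors", []):
        ctx = locate_residue(arch, int(anchor["residue"]))
        want_cls = anchor["repeat_class"]
        want_pos = int(anchor["repeat_position"])
        if ctx.repeat_class != want_cls or ctx.repeat_position != want_pos:
            raise ArchitectureError(
                f"anchor violated: residue {anchor['residue']} expected "
                f"{want_cls} position {want_pos}, got "
                f"{ctx.repeat_class} position {ctx.repeat_position}"
            )
    return arch


def iter_repeat_positions(arch: DomainArchitecture) -> Iterable[tuple[RepeatUnit, int, int]]:
    """Yield (repeat, global_residue, within_repeat_position) for all repeats."""
    for rep in arch.repeats:
        for pos in range(rep.start, rep.end + 1):
            yield rep, pos, pos - rep.start + 1
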