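"""FTL 5'-UTR regulatory-element map, construct editing, variant annotation.

Coordinates are 1-based inclusive on the mature 5'-UTR, with +1 at the
annotated transcription start.  The default map carries the two repressive
elements and their landmarks:

* eIF3 PAR-CLIP site: nt 53-76 (24 nt)
* eIF3 repressive element (3RE): nt 58-90 (33 nt; its deletion keeps the
  IRE intact)
* IRE apical-loop IRP contacts: A15, G16, U17; characteristic C bulge C18
* hyperferritinemia SNPs G51C and G52C sit one and two nt upstream of the
  PAR-CLIP site

Reporter constructs additionally carry a cap-to-IRE distance (32 nt native,
70 nt extended; the 38-nt spacer is vector-derived random sequence).  IRP
bound further than 60 nt from the 5' cap can no longer fully block 43S
loading, so constructs are classified sterically as full-block
(distance <= 60) or partial-block (> 60).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "ElementMap",
    "ElementMapError",
    "Deletion",
    "Substitution",
    "FivePrimeInsertion",
    "ConstructSpec",
    "VariantAnnotation",
    "EditResult",
    "element_length",
    "parse_variant",
    "annotate_variant",
    "apply_construct",
    "cap_distance",
    "steric_class",
    "standard_construct",
    "extension_spec",
]

FULL_BLOCK = "full-block"
PARTIAL_BLOCK = "partial-block"


class ElementMapError(KeyError):
    """Unknown element, construct, or malformed variant label."""


@dataclass(frozen=True)
class ElementMap:
    """Named intervals and landmarks on the FTL 5'-UTR (1-based inclusive).

    The IRE interval is only exposed when its start is configured: the UTR
    position of the IRE 3' end (57, five nt into the PAR-CLIP site) is well
    defined, but the 5' start is annotation-dependent and must be supplied.
    """

    intervals: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "PAR": (53, 76),
            "3RE": (58, 90),
            "LOOP": (15, 17),
            "C_BULGE": (18, 18),
        }
    )
    points: dict[str, int] = field(
        default_factory=lambda: {"A15": 15, "G16": 16, "U17": 17, "C18": 18}
    )
    ire_end: int = 57
    ire_start: int | None = None
    cap_distances: dict[str, int] = field(
        default_factory=lambda: {"native": 32, "extended": 70}
    )
    steric_threshold: int = 60

    def __post_init__(self) -> None:
        for name, (start, end) in self.all_intervals().items():
            if start > end:
                raise ValueError(f"element {name}: start {start} > end {end}")
            if start < 1:
                raise ValueError(f"element {name}: coordinates are 1-based (got {start})")

    def all_intervals(self) -> dict[str, tuple[int, int]]:
        out = dict(self.intervals)
        if self.ire_start is not None:
            out["IRE"] = (self.ire_start, self.ire_end)
        return out

    def interval(self, name: str) -> tuple[int, int]:
        table = self.all_intervals()
        key = name.upper()
        if key not in table:
            raise ElementMapError(
                f"unknown element {name!r}; available: {', '.join(sorted(table))}"
            )
        return table[key]


def element_length(emap: ElementMap, name: str) -> int:
    """Length in nt of a named element (1-based inclusive interval)."""
    start, end = emap.interval(name)
    return end - start + 1


_VARIANT_RE = re.compile(r"^([ACGTU])(\d+)([ACGTU])$", re.IGNORECASE)


def parse_variant(label: str) -> tuple[str, int, str]:
    """Parse a variant label like ``G51C`` into (ref, 1-based position, alt)."""
    m = _VARIANT_RE.match(label.strip())
    if not m:
        raise ElementMapError(
            f"malformed variant label {label!r}; expected <ref><pos><alt>, e.g. G51C or A15G"
        )
    ref, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if pos < 1:
        raise ElementMapError(f"variant position must be >= 1, got {pos}")
    return ref, pos, alt


@dataclass(frozen=True)
class VariantAnnotation:
    """Placement of a single-nucleotide variant relative to the element map."""

    label: str
    position: int
    overlapping: tuple[str, ...]
    nearest_element: str | None
    distance_nt: int
    side: str | None  # "upstream" / "downstream" of the nearest element
    steric: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "variant": self.label,
            "position": self.position,
            "overlapping_elements": list(self.overlapping),
            "nearest_element": self.nearest_element,
            "distance_nt": self.distance_nt,
            "side": self.side,
            "steric_class_by_construct": dict(self.steric),
        }


def annotate_variant(label: str, emap: ElementMap | None = None) -> VariantAnnotation:
    """Annotate a variant against the element map.

    Lists every element whose interval contains the position; when none
    does, reports the nearest element and the distance (in nt) to its
    closest boundary, with the side the variant falls on ("upstream" =
    5' of the element start).  G51C, for example, lies 2 nt upstream of
    the PAR-CLIP site and G52C 1 nt upstream.
    """
    emap = emap or ElementMap()
    _ref, pos, _alt = parse_variant(label)
    overlapping = tuple(
        name
        for name, (start, end) in sorted(emap.all_intervals().items())
        if start <= pos <= end
    )
    nearest: str | None = None
    distance = 0
    side: str | None = None
    if not overlapping:
        best = None
        for name, (start, end) in sorted(emap.all_intervals().items()):
            if pos < start:
                d, s = start - pos, "upstream"
            else:
                d, s = pos - end, "downstream"
            if best is None or d < best[0]:
                best = (d, name, s)
        if best is not None:
            distance, nearest, side = best
    steric = {
        construct: steric_class(dist, emap)
        for construct, dist in emap.cap_distances.items()
    }
    return VariantAnnotation(
        label=label,
        position=pos,
        overlapping=overlapping,
        nearest_element=nearest,
        distance_nt=distance,
        side=side,
        steric=steric,
    )


# --- construct editing -----------------------------------------------------


@dataclass(frozen=True)
class Deletion:
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid deletion interval [{self.start}, {self.end}]")

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class Substitution:
    position: int  # 1-based
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("substitution position must be >= 1")

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.position, self.position)


@dataclass(frozen=True)
class FivePrimeInsertion:
    """Sequence prepended at the 5' end (after the cap)."""

    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def footprint(self) -> tuple[int, int]:
        return (0, 0)  # does not consume reference positions


Edit = Union[Deletion, Substitution, FivePrimeInsertion]


@dataclass(frozen=True)
class ConstructSpec:
    """Named, ordered list of non-overlapping edits defining a reporter."""

    name: str
    edits: tuple[Edit, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "edits", tuple(self.edits))
        spans = [e.footprint for e in self.edits if not isinstance(e, FivePrimeInsertion)]
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"construct {self.name}: overlapping edits at [{s1},{e1}] and [{s2},{e2}]"
                )
        n_ins = sum(isinstance(e, FivePrimeInsertion) for e in self.edits)
        if n_ins > 1:
            raise ValueError(f"construct {self.name}: at most one 5' insertion allowed")


@dataclass(frozen=True)
class EditResult:
    """Edited sequence plus the old -> new coordinate lift-over.

    ``liftover[old_pos]`` gives the 1-based position of reference position
    ``old_pos`` in the edited sequence, or ``None`` if it was deleted.
    """

    sequence: str
    liftover: dict[int, int | None]


def _is_rna(seq: str) -> bool:
    up = seq.upper()
    return "U" in up and "T" not in up


def _bases_equal(a: str, b: str) -> bool:
    trans = str.maketrans("Uu", "Tt")
    return a.upper().translate(trans) == b.upper().translate(trans)


def apply_construct(sequence: str, spec: ConstructSpec) -> EditResult:
    """Apply a construct's edits to a reference 5'-UTR sequence.

    Deletions remove their closed interval, substitutions check the
    reference base (U/T equivalent) before replacing it, and a 5'
    insertion is prepended.  The output alphabet (RNA or DNA) follows the
    input.  Returns the edited sequence and a complete lift-over table.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if not re.fullmatch(r"[ACGTUacgtu]+", sequence):
        raise ValueError("sequence must be over the {A, C, G, T, U} alphabet")
    rna = _is_rna(sequence)

    deleted = np.zeros(len(sequence) + 1, dtype=bool)  # 1-based
    replacement: dict[int, str] = {}
    prefix = ""
    for edit in spec.edits:
        if isinstance(edit, FivePrimeInsertion):
            prefix = edit.sequence
        elif isinstance(edit, Deletion):
            if edit.end > len(sequence):
                raise ValueError(
                    f"deletion [{edit.start},{edit.end}] extends past sequence end "
                    f"({len(sequence)} nt)"
                )
            deleted[edit.start : edit.end + 1] = True
        else:
            if edit.position > len(sequence):
                raise ValueError(
                    f"substitution position {edit.position} past sequence end"
                )
            found = sequence[edit.position - 1]
            if not _bases_equal(found, edit.ref_base):
                raise ValueError(
                    f"ref-base mismatch at position {edit.position}: "
                    f"expected {edit.ref_base}, found {found}"
                )
            replacement[edit.position] = edit.alt_base

    def to_alphabet(s: str) -> str:
        if rna:
            return s.upper().replace("T", "U")
        return s.upper().replace("U", "T")

    out: list[str] = list(to_alphabet(prefix))
    liftover: dict[int, int | None] = {}
    for pos in range(1, len(sequence) + 1):
        if deleted[pos]:
            liftover[pos] = None
            continue
        base = replacement.get(pos, sequence[pos - 1])
        out.append(to_alphabet(base) if pos in replacement else base)
        liftover[pos] = len(out)
    return EditResult(sequence="".join(out), liftover=liftover)


def cap_distance(emap: ElementMap, construct: str) -> int:
    """Configured cap-to-IRE (C bulge) distance of a construct, in nt."""
    key = construct.lower()
    if key not in emap.cap_distances:
        raise ElementMapError(
            f"unknown construct {construct!r}; available: "
            f"{', '.join(sorted(emap.cap_distances))}"
        )
    return emap.cap_distances[key]


def steric_class(distance: int, emap: ElementMap | None = None) -> str:
    """Classify IRP steric blockage by cap distance (strict > threshold)."""
    emap = emap or ElementMap()
    return PARTIAL_BLOCK if distance > emap.steric_threshold else FULL_BLOCK


# --- the named reporter constructs ----------------------------------------

_STANDARD: dict[str, tuple[Edit, ...]] = {
    "FTL": (),
    "DPAR": (Deletion(53, 76),),
    "D3RE": (Deletion(58, 90),),
    "LOOP": (Substitution(15, "A", "G"), Substitution(16, "G", "C")),
    "DOUBLE": (
        Substitution(15, "A", "G"),
        Substitution(16, "G", "C"),
        Deletion(58, 90),
    ),
    "G51C": (Substitution(51, "G", "C"),),
    "G52C": (Substitution(52, "G", "C"),),
}


def standard_construct(name: str) -> ConstructSpec:
    """Edit recipe for one of the named reporter constructs.

    FTL (wild type, identity), DPAR (delete nt 53-76), D3RE (delete nt
    58-90), LOOP (A15G/G16C, abolishes IRP binding), DOUBLE (LOOP + D3RE),
    and the hyperferritinemia SNPs G51C and G52C.
    """
    from .occupancy import canonical_construct

    key = canonical_construct(name)
    return ConstructSpec(name=key, edits=_STANDARD[key])


def extension_spec(length: int = 38, seed: int = 2019) -> ConstructSpec:
    """Spacer insertion moving the IRE from 32 to 70 nt from the cap.

    The extension is a random sequence (its composition does not measurably
    affect IRP binding); a fixed seed makes the construct reproducible.
    """
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGU"), size=length))
    return ConstructSpec(name=f"EXT{length}", edits=(FivePrimeInsertion(seq),))
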