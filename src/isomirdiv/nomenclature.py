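"""isomiR naming by signed terminal offsets.

An isomiR is identified by the mature miRNA it derives from plus two signed
integers giving the distance (nt) of its 5' and 3' termini from the archetype
termini annotated on the precursor hairpin.  Positive offsets point downstream
(toward the precursor 3' end), negative upstream.  The canonical text form is
``<name> <offset5>|<offset3>``, e.g. ``miR-455-5p 0|1``; ``0|0`` is the
archetype itself.

Only templated variants are modelled: offsets index into the precursor, so a
sequence can always be reconstructed by slicing the hairpin.  Non-templated 3'
additions are rejected rather than silently mis-sequenced.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "MatureAnnotation",
    "IsomirId",
    "offsets_from_coordinates",
    "format_name",
    "parse_name",
    "isomir_sequence",
    "CoordinateError",
    "NameParseError",
]


class CoordinateError(ValueError):
    """Raised when coordinates or offsets fall outside the precursor."""


class NameParseError(ValueError):
    """Raised when an isomiR name does not match the canonical grammar.

    Attributes
    ----------
    position : int
        0-based index into the input string where parsing failed.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class MatureAnnotation:
    """Archetype mature-arm coordinates on a precursor hairpin.

    ``start``/``end`` are 1-based inclusive positions of the archetype 5' and
    3' termini on the precursor (miRBase hairpin-relative convention).
    """

    precursor_id: str
    mirna_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise CoordinateError(
                f"invalid mature annotation for {self.mirna_name}: "
                f"need 1 <= start <= end, got start={self.start}, end={self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True, order=True)
class IsomirId:
    """A miRNA name plus signed 5'/3' terminal offsets; ``(0, 0)`` is the archetype."""

    mirna_name: str
    offset5: int
    offset3: int

    def __str__(self) -> str:
        return format_name(self)

    @property
    def is_archetype(self) -> bool:
        return self.offset5 == 0 and self.offset3 == 0


def offsets_from_coordinates(
    read_start: int, read_end: int, ann: MatureAnnotation, precursor_length: int | None = None
) -> tuple[int, int]:
    """Convert 1-based read coordinates on the precursor into terminal offsets.

    offset5 = read_start - ann.start and offset3 = read_end - ann.end, so a
    positive offset means the terminus lies downstream of the archetype
    terminus and a negative one upstream.
    """
    if read_start > read_end:
        raise CoordinateError(f"read_start {read_start} > read_end {read_end}")
    if read_start < 1:
        raise CoordinateError(f"read_start {read_start} is before the precursor 5' end")
    if precursor_length is not None and read_end > precursor_length:
        raise CoordinateError(
            f"read_end {read_end} exceeds precursor length {precursor_length}"
        )
    return read_start - ann.start, read_end - ann.end


_NAME_RE = re.compile(r"^(?P<name>\S+) (?P<o5>-?\d+)\|(?P<o3>-?\d+)$")


def format_name(isomir: IsomirId) -> str:
    """Render the canonical text form, e.g. ``miR-455-5p 0|1``.

    No ``+`` sign on positive offsets; ``-`` on negatives.
    """
    return f"{isomir.mirna_name} {isomir.offset5}|{isomir.offset3}"


def parse_name(text: str) -> IsomirId:
    """Parse ``<name> <offset5>|<offset3>`` back into an :class:`IsomirId`.

    Round-trips with :func:`format_name`.  Raises :class:`NameParseError`
    carrying the failure position for malformed input.
    """
    m = _NAME_RE.match(text)
    if m is None:
        # locate the failure point for a useful error message
        sp = text.find(" ")
        if sp < 0:
            raise NameParseError("expected '<name> <o5>|<o3>', no space found", len(text))
        tail = text[sp + 1 :]
        tm = re.match(r"-?\d+\|-?\d+$", tail)
        if tm is None:
            bar = tail.find("|")
            pos = sp + 1 + (bar if bar >= 0 else 0)
            raise NameParseError("malformed offsets, expected '<int>|<int>'", pos)
        raise NameParseError("malformed isomiR name", 0)
    return IsomirId(m["name"], int(m["o5"]), int(m["o3"]))


def isomir_sequence(precursor_seq: str, ann: MatureAnnotation, isomir: IsomirId) -> str:
    """Reconstruct an isomiR sequence by slicing the precursor.

    Returns the precursor subsequence from ``ann.start + offset5`` to
    ``ann.end + offset3`` (1-based inclusive), as uppercase RNA.  The length is
    archetype length - offset5 + offset3.  Offsets that would run off either
    end of the hairpin raise :class:`CoordinateError` — such reads would imply
    non-templated nucleotides, which this model excludes.
    """
    seq = precursor_seq.strip().upper().replace("T", "U")
    start = ann.start + isomir.offset5
    end = ann.end + isomir.offset3
    if ann.end > len(seq):
        raise CoordinateError(
            f"annotation end {ann.end} exceeds precursor length {len(seq)}"
        )
    if start < 1:
        raise CoordinateError(
            f"5' offset {isomir.offset5} extends beyond the precursor 5' end"
        )
    if end > len(seq):
        raise CoordinateError(
            f"3' offset {isomir.offset3} extends beyond the precursor 3' end "
            f"(precursor length {len(seq)})"
        )
    if start > end:
        raise CoordinateError(
            f"offsets ({isomir.offset5}, {isomir.offset3}) leave an empty sequence"
        )
    return seq[start - 1 : end]
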