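"""Domain types and file I/O for CandyCode particle patterns.

A CandyCode is the random arrangement of small colored candy spheres
(nonpareils) on the surface of a pill.  Because the arrangement arises from
an uncontrolled physical process it acts as a physical unclonable function:
easy to produce, effectively impossible to reproduce on demand.  This module
defines the color alphabets, the particle-list container, the string-set
representation produced by the encoder, and plain-text serialization for
both.

Coordinate convention: image frame, ``x`` to the right and ``y`` increasing
downward, matching the pixel coordinates of a photograph.  All angular
("clockwise") logic elsewhere in the package is defined against this frame.
Geometry is unitless.
"""

from __future__ import annotations

import csv
import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "ColorAlphabet",
    "Particle",
    "CandyCode",
    "StringSet",
    "ALPHABETS",
    "get_alphabet",
    "theoretical_bits",
    "read_candycode",
    "write_candycode",
    "read_string_sets",
    "write_string_sets",
]

#: Fixed-point precision used when serializing coordinates.
COORD_DECIMALS = 6


class CandyCodeError(Exception):
    """Base class for errors raised by this package."""


class ParseError(CandyCodeError):
    """A particle file could not be parsed."""


class ValidationError(CandyCodeError):
    """A domain object violates its invariants."""


@dataclass(frozen=True)
class ColorAlphabet:
    """An ordered set of single-letter color labels with sampling probabilities.

    Parameters
    ----------
    letters
        Unique, uppercase, single-character labels, e.g. ``("D", "G", ...)``.
    probabilities
        Per-letter sampling probability; must be nonnegative and sum to 1.
    """

    letters: tuple[str, ...]
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.letters) < 2:
            raise ValidationError("alphabet needs at least 2 letters")
        if len(set(self.letters)) != len(self.letters):
            raise ValidationError("alphabet letters must be unique")
        for c in self.letters:
            if len(c) != 1 or not c.isupper():
                raise ValidationError(f"invalid color letter {c!r}")
        if len(self.probabilities) != len(self.letters):
            raise ValidationError("one probability per letter required")
        if any(p < 0 for p in self.probabilities):
            raise ValidationError("probabilities must be nonnegative")
        if abs(sum(self.probabilities) - 1.0) > 1e-9:
            raise ValidationError("probabilities must sum to 1")

    def __len__(self) -> int:
        return len(self.letters)

    def __contains__(self, letter: str) -> bool:
        return letter in self.letters

    def index(self, letter: str) -> int:
        return self.letters.index(letter)


def _equal_alphabet(letters: str) -> ColorAlphabet:
    n = len(letters)
    return ColorAlphabet(tuple(letters), tuple([1.0 / n] * n))


#: The three built-in alphabets.
#:
#: ``A`` — the eight colors found on commercial chocolate nonpareil candies:
#: dark blue (D), green (G), light blue (L), orange (O), pink (P), red (R),
#: white (W) and yellow (Y), with white five times more probable than each
#: other color (idealized as 5/12 vs 1/12 each).
#: ``B`` — the same eight colors with equal probabilities.
#: ``C`` — fifteen equally probable colors: the eight above plus black (B),
#: dark green / forest (F), dark gray (K), magenta (M), brown (N), light
#: gray / silver (S) and purple / violet (V).
ALPHABETS: Mapping[str, ColorAlphabet] = {
    "A": ColorAlphabet(
        tuple("DGLOPRWY"),
        (1 / 12, 1 / 12, 1 / 12, 1 / 12, 1 / 12, 1 / 12, 5 / 12, 1 / 12),
    ),
    "B": _equal_alphabet("DGLOPRWY"),
    "C": _equal_alphabet("BDFGKLMNOPRSVWY"),
}


def get_alphabet(name: str) -> ColorAlphabet:
    """Return a built-in alphabet by name (``"A"``, ``"B"`` or ``"C"``)."""
    try:
        return ALPHABETS[name.upper()]
    except KeyError:
        raise KeyError(f"unknown alphabet {name!r}; choose from {sorted(ALPHABETS)}")


class Particle(NamedTuple):
    """One nonpareil: position in the image frame plus its color letter."""

    x: float
    y: float
    color: str


@dataclass
class CandyCode:
    """One pill's particle pattern: an id plus a list of colored particles."""

    id: str
    particles: list[Particle]
    alphabet: ColorAlphabet

    def __post_init__(self) -> None:
        seen: set[tuple[float, float]] = set()
        for i, p in enumerate(self.particles):
            if p.color not in self.alphabet:
                raise ValidationError(
                    f"particle {i}: color {p.color!r} not in alphabet"
                )
            key = (p.x, p.y)
            if key in seen:
                raise ValidationError(f"particle {i}: duplicate coordinates {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.particles)

    def coordinates(self) -> np.ndarray:
        """Particle coordinates as an ``(n, 2)`` float array."""
        return np.array([(p.x, p.y) for p in self.particles], dtype=float).reshape(
            -1, 2
        )

    def colors(self) -> list[str]:
        return [p.color for p in self.particles]


@dataclass
class StringSet:
    """The multiset of retained neighborhood strings representing one code.

    Two neighborhoods in one code may canonicalize to the same string; both
    copies are kept, and matching uses multiset-intersection counts.
    """

    code_id: str
    strings: Counter = field(default_factory=Counter)

    @classmethod
    def from_iterable(cls, code_id: str, strings: Iterable[str]) -> "StringSet":
        return cls(code_id, Counter(strings))

    def total(self) -> int:
        """Number of strings, counting multiplicity."""
        return sum(self.strings.values())

    def as_sorted_list(self) -> list[str]:
        out: list[str] = []
        for s in sorted(self.strings):
            out.extend([s] * self.strings[s])
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StringSet):
            return NotImplemented
        return self.code_id == other.code_id and self.strings == other.strings


def theoretical_bits(n_particles: int, n_colors: int) -> float:
    """Information capacity in bits if every particle's color were read exactly.

    A pattern of ``n`` particles, each taking one of ``c`` colors, can encode
    ``n * log2(c)`` bits; e.g. 93 particles with 8 colors give 279 bits, more
    than double the 122 random bits of a version-4 UUID.
    """
    if n_colors < 1:
        raise ValueError("n_colors must be >= 1")
    if n_particles < 0:
        raise ValueError("n_particles must be >= 0")
    return n_particles * math.log2(n_colors)


# ---------------------------------------------------------------------------
# File I/O
#
# CSV dialect: header "x,y,color", one particle per row.  JSON alternative:
# {"id": ..., "particles": [[x, y, "P"], ...]}.  Coordinates are written with
# 6 fractional digits; duplicate detection uses exact equality after parsing.


def _fmt(v: float) -> str:
    return f"{v:.{COORD_DECIMALS}f}"


def read_candycode(
    path: str | Path, alphabet: ColorAlphabet, code_id: str | None = None
) -> CandyCode:
    """Read a particle list (CSV or JSON, chosen by extension) into a CandyCode."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        particles = []
        for i, row in enumerate(doc.get("particles", [])):
            particles.append(_parse_row(row, i, alphabet))
        cid = code_id or doc.get("id") or path.stem
        return CandyCode(cid, particles, alphabet)

    particles = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:3]] != ["x", "y", "color"]:
            raise ParseError(f"{path}: expected header 'x,y,color'")
        for i, row in enumerate(reader):
            if not row or all(not c.strip() for c in row):
                continue
            particles.append(_parse_row(row, i, alphabet))
    return CandyCode(code_id or path.stem, particles, alphabet)


def _parse_row(row: Sequence, index: int, alphabet: ColorAlphabet) -> Particle:
    try:
        x = float(row[0])
        y = float(row[1])
        color = str(row[2]).strip()
    except (ValueError, IndexError, TypeError) as exc:
        raise ParseError(f"row {index}: cannot parse {row!r}") from exc
    if color not in alphabet:
        raise ParseError(f"row {index}: unknown color letter {color!r}")
    return Particle(x, y, color)


def write_candycode(path: str | Path, code: CandyCode) -> None:
    """Write a CandyCode as CSV or JSON, chosen by the path's extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "id": code.id,
            "particles": [
                [float(_fmt(p.x)), float(_fmt(p.y)), p.color] for p in code.particles
            ],
        }
        path.write_text(json.dumps(doc, indent=1))
        return
    lines = ["x,y,color"]
    lines += [f"{_fmt(p.x)},{_fmt(p.y)},{p.color}" for p in code.particles]
    path.write_text("\n".join(lines) + "\n")


def write_string_sets(path: str | Path, sets: Iterable[StringSet]) -> None:
    """Serialize string sets, one line per code: id then sorted strings."""
    with open(path, "w") as fh:
        for s in sets:
            fh.write(s.code_id + "\t" + " ".join(s.as_sorted_list()) + "\n")


def read_string_sets(path: str | Path) -> list[StringSet]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cid, _, rest = line.partition("\t")
            out.append(StringSet.from_iterable(cid, rest.split()))
    return out
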