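"""Data model and I/O for combinatorial modified-histone peptide arrays.

A MODified histone peptide array is a spotted membrane of 19-mer histone
peptides, each carrying zero to four concurrent post-translational
modifications, printed in duplicate subarrays.  Probing the membrane with a
protein (here PARP-1) and reading the spot intensities maps the protein's
binding preference across single marks and mark combinations.

This module holds the static description of such an array: the vocabulary
of modification tags (``H4K20me1``, ``H3S10ph``, ...), the peptide carried
by each spot, and the spot grid, plus set-style queries over spots by the
marks they carry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd

from .errors import FormatError, InvariantError, LayoutError

HISTONES = ("H2A", "H2B", "H3", "H4")
MODTYPES = ("me1", "me2", "me3", "ac", "ph", "cit", "unmod")

#: Control-spot labels; controls are excluded from all statistics by default.
CONTROL_LABELS = ("blank", "positive_control")

PEPTIDE_LENGTH = 19

_TAG_RE = re.compile(
    r"^(H2A|H2B|H3|H4)([A-Z])(\d+)(me1|me2|me3|ac|ph|cit|unmod)$",
    re.IGNORECASE,
)


@dataclass(frozen=True, order=True)
class ModificationTag:
    """One histone mark: histone, residue (letter + 1-based position), type.

    The canonical string form is ``histone + residue + modtype``
    (e.g. ``"H4K20me1"``) and round-trips through :func:`parse_mod_tag`.
    """

    histone: str
    residue: str
    modtype: str

    def __post_init__(self) -> None:
        if self.histone not in HISTONES:
            raise FormatError(f"unknown histone {self.histone!r}")
        if self.modtype not in MODTYPES:
            raise FormatError(f"unknown modification type {self.modtype!r}")
        m = re.match(r"^([A-Z])(\d+)$", self.residue)
        if not m or int(m.group(2)) < 1:
            raise FormatError(f"bad residue {self.residue!r}")

    @property
    def position(self) -> int:
        """1-based residue position within the histone."""
        return int(self.residue[1:])

    def __str__(self) -> str:
        return f"{self.histone}{self.residue}{self.modtype}"


def parse_mod_tag(text: str) -> ModificationTag:
    """Parse a mark name such as ``"H4K20me1"`` (case-insensitive).

    Raises :class:`FormatError` naming the offending token when the text
    does not match the histone+residue+modtype grammar.
    """
    m = _TAG_RE.match(text.strip())
    if not m:
        raise FormatError(f"cannot parse modification tag {text!r}")
    histone, letter, pos, modtype = m.groups()
    return ModificationTag(histone.upper(), f"{letter.upper()}{int(pos)}", modtype.lower())


def as_tag(mark: Union[str, ModificationTag]) -> ModificationTag:
    """Coerce a string or tag to a :class:`ModificationTag`."""
    return mark if isinstance(mark, ModificationTag) else parse_mod_tag(mark)


@dataclass(frozen=True)
class PeptideSpec:
    """A 19-mer peptide spot: id, histone, residue span, set of marks."""

    spot_id: str
    histone: str
    span: tuple[int, int]
    mods: frozenset[ModificationTag] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        start, end = self.span
        if start < 1 or end - start + 1 != PEPTIDE_LENGTH:
            raise InvariantError(
                f"spot {self.spot_id}: span {self.span} is not a 19-residue window"
            )
        if len(self.mods) > 4:
            raise InvariantError(
                f"spot {self.spot_id}: {len(self.mods)} marks exceed the 4-mark maximum"
            )
        for mod in self.mods:
            if mod.histone != self.histone:
                raise InvariantError(
                    f"spot {self.spot_id}: mark {mod} is not on histone {self.histone}"
                )
            if not (start <= mod.position <= end):
                raise InvariantError(
                    f"spot {self.spot_id}: mark {mod} lies outside span {self.span}"
                )


Position = tuple[int, int, int]  # (subarray, row, col), all 1-based


@dataclass
class ArrayLayout:
    """Spot grid of the array: identical subarray duplicates of peptides.

    ``spots`` maps every (subarray, row, col) position either to a
    :class:`PeptideSpec` or to a control label from :data:`CONTROL_LABELS`.
    """

    shape: tuple[int, int]
    n_subarrays: int
    spots: Mapping[Position, Union[PeptideSpec, str]]

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if self.n_subarrays < 1 or rows < 1 or cols < 1:
            raise LayoutError("layout dimensions must be positive")
        expected = {
            (s, r, c)
            for s in range(1, self.n_subarrays + 1)
            for r in range(1, rows + 1)
            for c in range(1, cols + 1)
        }
        got = set(self.spots)
        if got != expected:
            missing = sorted(expected - got)[:3]
            extra = sorted(got - expected)[:3]
            raise LayoutError(
                f"grid positions mismatch (missing {missing}, unexpected {extra})"
            )
        for entry in self.spots.values():
            if isinstance(entry, str) and entry not in CONTROL_LABELS:
                raise LayoutError(f"unknown control label {entry!r}")
        # duplicates: the same peptide (or control) at the same (row, col)
        # in every subarray
        ref = {
            (r, c): v for (s, r, c), v in self.spots.items() if s == 1
        }
        for (s, r, c), v in self.spots.items():
            if ref[(r, c)] != v:
                raise LayoutError(
                    f"position (row {r}, col {c}) differs between subarrays"
                )

    # -- queries -----------------------------------------------------------

    def positions(self) -> list[Position]:
        """All grid positions in deterministic (subarray, row, col) order."""
        return sorted(self.spots)

    def peptide_at(self, pos: Position) -> Union[PeptideSpec, str]:
        return self.spots[pos]

    def is_control(self, pos: Position) -> bool:
        return isinstance(self.spots[pos], str)

    def peptides(self) -> dict[str, PeptideSpec]:
        """Unique peptides keyed by spot_id, in subarray-1 grid order."""
        out: dict[str, PeptideSpec] = {}
        for pos in self.positions():
            entry = self.spots[pos]
            if isinstance(entry, PeptideSpec) and entry.spot_id not in out:
                out[entry.spot_id] = entry
        return out

    def spot_ids(self) -> list[str]:
        """All non-control spot ids in grid order."""
        return list(self.peptides())

    def control_spot_ids(self) -> dict[Position, str]:
        return {p: v for p, v in self.spots.items() if isinstance(v, str)}

    def marks(self) -> set[ModificationTag]:
        """Every mark appearing on at least one peptide."""
        out: set[ModificationTag] = set()
        for spec in self.peptides().values():
            out |= spec.mods
        return out


def spots_with(
    layout: ArrayLayout,
    include: Iterable[Union[str, ModificationTag]] = (),
    exclude: Iterable[Union[str, ModificationTag]] = (),
) -> list[str]:
    """Spot ids of peptides carrying every ``include`` mark and no ``exclude`` mark.

    Controls are never returned.  Order is deterministic grid order
    (subarray, row, col).  ``include`` and ``exclude`` must be disjoint.
    """
    inc = frozenset(as_tag(m) for m in include)
    exc = frozenset(as_tag(m) for m in exclude)
    if inc & exc:
        raise InvariantError(f"include/exclude overlap: {sorted(map(str, inc & exc))}")
    out = []
    for spot_id, spec in layout.peptides().items():
        if spec.mods >= inc and not (spec.mods & exc):
            out.append(spot_id)
    return out


_LAYOUT_COLUMNS = ("subarray", "row", "col", "histone", "span_start", "mods", "control")


def load_array_layout(path: Union[str, Path]) -> ArrayLayout:
    """Read a layout from a headered TSV, one grid position per line.

    Required columns: subarray, row, col, histone, span_start, mods
    (semicolon-separated mark names, empty for unmodified peptides) and
    control (empty, ``blank`` or ``positive_control``).  An optional
    ``spot_id`` column names peptides; otherwise ids are derived from the
    (row, col) position, which guarantees identity across subarrays.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"layout file is missing columns {missing}")

    spots: dict[Position, Union[PeptideSpec, str]] = {}
    for line in df.itertuples(index=False):
        try:
            pos = (int(line.subarray), int(line.row), int(line.col))
        except ValueError as exc:
            raise FormatError(f"non-integer grid position in line {line!r}") from exc
        if pos in spots:
            raise LayoutError(f"position {pos} assigned more than once")
        control = line.control.strip()
        if control:
            if control not in CONTROL_LABELS:
                raise LayoutError(f"unknown control label {control!r} at {pos}")
            spots[pos] = control
            continue
        spot_id = getattr(line, "spot_id", "") or f"r{pos[1]}c{pos[2]}"
        try:
            start = int(line.span_start)
        except ValueError as exc:
            raise FormatError(f"bad span_start at {pos}") from exc
        mods = frozenset(
            parse_mod_tag(tok) for tok in line.mods.split(";") if tok.strip()
        )
        spots[pos] = PeptideSpec(
            spot_id=spot_id,
            histone=line.histone.strip().upper(),
            span=(start, start + PEPTIDE_LENGTH - 1),
            mods=mods,
        )

    if not spots:
        raise LayoutError("empty layout file")
    n_subarrays = max(p[0] for p in spots)
    shape = (max(p[1] for p in spots), max(p[2] for p in spots))
    return ArrayLayout(shape=shape, n_subarrays=n_subarrays, spots=spots)


def write_array_layout(layout: ArrayLayout, path: Union[str, Path]) -> None:
    """Write a layout back to the TSV dialect read by :func:`load_array_layout`."""
    rows = []
    for (s, r, c), entry in sorted(layout.spots.items()):
        if isinstance(entry, str):
            rows.append((s, r, c, "", "", "", "", entry))
        else:
            rows.append(
                (
                    s, r, c, entry.spot_id, entry.histone, entry.span[0],
                    ";".join(sorted(str(m) for m in entry.mods)), "",
                )
            )
    pd.DataFrame(
        rows,
        columns=["subarray", "row", "col", "spot_id", "histone", "span_start", "mods", "control"],
    ).to_csv(path, sep="\t", index=False)
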