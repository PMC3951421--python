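"""Binary character matrices in NEXUS format: reading, writing, filtering, subsetting.

The analysis input is a taxa x characters grid of presence/absence codings
(0/1) with "?" marking features whose state is unknown for a taxon. Cells are
stored as ``int8``: 0, 1, or :data:`MISSING` (-1).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

__all__ = [
    "MISSING",
    "CharacterMatrix",
    "FilterReport",
    "NexusParseError",
    "read_nexus_characters",
    "write_nexus_characters",
    "filter_uninformative",
    "drop_taxa",
]

MISSING: int = -1

_SYMBOL_TO_STATE = {"0": 0, "1": 1, "?": MISSING}


class NexusParseError(ValueError):
    """Raised when a NEXUS character block cannot be read as a binary matrix."""


@dataclass(frozen=True)
class CharacterMatrix:
    """An ordered set of taxa scored for binary characters.

    Parameters
    ----------
    taxa
        Unique, non-empty taxon labels; row order is meaningful.
    states
        ``(n_taxa, n_chars)`` int8 array over ``{0, 1, MISSING}``.
    char_labels
        Optional character names, one per column.
    provenance
        Free-text note on where the matrix came from.
    """

    taxa: tuple[str, ...]
    states: np.ndarray
    char_labels: tuple[str, ...] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.int8)
        if states.ndim != 2:
            raise ValueError("states must be a 2-D taxa x characters grid")
        if states.shape[0] != len(self.taxa):
            raise ValueError(
                f"{len(self.taxa)} taxa but {states.shape[0]} state rows"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon labels must be unique")
        if any(not t for t in self.taxa):
            raise ValueError("taxon labels must be non-empty")
        bad = ~np.isin(states, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid state {states[i, j]} at taxon {self.taxa[i]!r}, column {j}"
            )
        if self.char_labels is not None and len(self.char_labels) != states.shape[1]:
            raise ValueError("char_labels length must equal number of characters")
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "taxa", tuple(self.taxa))
        if self.char_labels is not None:
            object.__setattr__(self, "char_labels", tuple(self.char_labels))

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return int(self.states.shape[1])

    def taxon_index(self, label: str) -> int:
        try:
            return self.taxa.index(label)
        except ValueError:
            raise KeyError(
                f"unknown taxon {label!r}; valid labels: {', '.join(self.taxa)}"
            ) from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.states.shape == other.states.shape
            and bool(np.all(self.states == other.states))
        )

    def __hash__(self) -> int:  # frozen dataclass requires explicit pairing with __eq__
        return hash((self.taxa, self.states.tobytes()))


@dataclass(frozen=True)
class FilterReport:
    """Accounting of a character-filtering pass: every input column is either
    retained or excluded."""

    n_input: int
    n_excluded: int
    n_retained: int
    excluded_indices: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_input != self.n_excluded + self.n_retained:
            raise ValueError("n_input must equal n_excluded + n_retained")
        if len(self.excluded_indices) != self.n_excluded:
            raise ValueError("excluded_indices length must equal n_excluded")


def read_nexus_characters(source: str) -> CharacterMatrix:
    """Read a binary character matrix from NEXUS text or a file path.

    Accepts DATA or CHARACTERS blocks, interleaved or not. "?" is mapped to
    :data:`MISSING`; a gap symbol "-" is also treated as missing, with a
    warning, since presence/absence data has no alignment gaps.
    """
    text = source
    if "\n" not in source and not source.lstrip().startswith("#"):
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    try:
        dm = dendropy.StandardCharacterMatrix.get(
            data=text, schema="nexus", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NexusParseError(f"could not parse NEXUS characters: {exc}") from exc

    taxa: list[str] = []
    rows: list[list[int]] = []
    gap_seen = False
    ncols = None
    for taxon in dm.taxon_namespace:
        seq = dm[taxon]
        row: list[int] = []
        for j, cell in enumerate(seq):
            sym = cell.symbol
            if sym == "-":
                gap_seen = True
                row.append(MISSING)
                continue
            try:
                row.append(_SYMBOL_TO_STATE[sym])
            except KeyError:
                raise NexusParseError(
                    f"unknown state symbol {sym!r} at taxon {taxon.label!r}, "
                    f"character {j + 1}"
                ) from None
        if ncols is None:
            ncols = len(row)
        elif len(row) != ncols:
            raise NexusParseError(
                f"taxon {taxon.label!r} has {len(row)} characters, expected {ncols}"
            )
        taxa.append(taxon.label)
        rows.append(row)
    if gap_seen:
        warnings.warn(
            "gap symbol '-' found in binary matrix; treated as missing",
            stacklevel=2,
        )
    if not taxa:
        raise NexusParseError("no taxa found in NEXUS source")
    states = np.asarray(rows, dtype=np.int8)
    nchar_decl = _declared_nchar(text)
    if nchar_decl is not None and nchar_decl != states.shape[1]:
        raise NexusParseError(
            f"matrix has {states.shape[1]} characters but NCHAR={nchar_decl}"
        )
    return CharacterMatrix(taxa=tuple(taxa), states=states, provenance="nexus input")


def _declared_nchar(text: str) -> int | None:
    m = re.search(r"\bNCHAR\s*=\s*(\d+)", text, flags=re.IGNORECASE)
    return int(m.group(1)) if m else None


def _quote_label(label: str) -> str:
    if re.fullmatch(r"[\w.\-]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_nexus_characters(m: CharacterMatrix) -> str:
    """Serialize a matrix as a non-interleaved NEXUS DATA block.

    Output is conservative: symbols "01", missing "?", labels quoted when they
    contain anything beyond word characters. Round-trips through
    :func:`read_nexus_characters`.
    """
    lines = [
        "#NEXUS",
        "",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_chars};",
        '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;',
        "    MATRIX",
    ]
    width = max((len(_quote_label(t)) for t in m.taxa), default=0) + 2
    for i, taxon in enumerate(m.taxa):
        row = "".join(
            "?" if s == MISSING else str(int(s)) for s in m.states[i]
        )
        lines.append(f"        {_quote_label(taxon):<{width}}{row}")
    lines += ["    ;", "END;", ""]
    return "\n".join(lines)


def filter_uninformative(
    m: CharacterMatrix,
) -> tuple[CharacterMatrix, FilterReport]:
    """Drop characters that are constant among their observed states.

    A character whose non-missing cells are all 0, all 1, or that has no
    observed cell at all, carries no grouping signal and is excluded. Missing
    cells are ignored when judging constancy. Idempotent.
    """
    keep: list[int] = []
    excluded: list[int] = []
    for j in range(m.n_chars):
        col = m.states[:, j]
        obs = col[col != MISSING]
        if obs.size and obs.min() != obs.max():
            keep.append(j)
        else:
            excluded.append(j)
    if not keep:
        warnings.warn("all characters are uninformative; empty matrix returned",
                      stacklevel=2)
    filtered = replace(
        m,
        states=m.states[:, keep],
        char_labels=(
            tuple(m.char_labels[j] for j in keep) if m.char_labels else None
        ),
    )
    report = FilterReport(
        n_input=m.n_chars,
        n_excluded=len(excluded),
        n_retained=len(keep),
        excluded_indices=tuple(excluded),
    )
    return filtered, report


def drop_taxa(m: CharacterMatrix, names: set[str] | frozenset[str]) -> CharacterMatrix:
    """Remove the named taxa; the character set is left untouched.

    Re-filtering for informativeness after dropping taxa is a separate,
    explicit step so the two operations stay auditable.
    """
    names = set(names)
    unknown = names - set(m.taxa)
    if unknown:
        raise KeyError(
            f"unknown taxa {sorted(unknown)}; valid labels: {', '.join(m.taxa)}"
        )
    keep = [i for i, t in enumerate(m.taxa) if t not in names]
    return replace(
        m,
        taxa=tuple(m.taxa[i] for i in keep),
        states=m.states[keep, :],
    )
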