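"""Proteins, site annotations, and lysine-centered sequence windows.

Candidate ubiquitination sites are lysine (K) residues.  Around every K
in a protein a window of ``2n + 1`` residues is extracted (``n`` flanking
residues on each side, default 6, giving 13-mers).  A window is labeled
*positive* when its central lysine is an experimentally validated
ubiquitination site and *negative* otherwise.  Windows that run past a
protein terminus are padded with ``'-'``; pad cells are ignored by every
downstream count-based statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

PAD = "-"
UNKNOWN = "X"

#: integer codes used by :func:`encode_windows`
X_CODE = 20
PAD_CODE = 21

POSITIVE = "positive"
NEGATIVE = "negative"


class ValidationError(ValueError):
    """An input violated one of the documented contracts."""


def canonicalize(sequence: str) -> str:
    """Uppercase a protein sequence and map every non-canonical symbol to 'X'.

    Ambiguity/rare codes (B, Z, U, O, J) and anything else outside the
    20-letter alphabet become 'X'; 'X' never contributes to count-based
    statistics downstream.
    """
    return "".join(
        ch if ch in AA_INDEX else UNKNOWN for ch in sequence.upper()
    )


@dataclass(frozen=True)
class Protein:
    """A protein sequence with its validated ubiquitination sites.

    ``validated_sites`` holds 1-based positions; each must address a 'K'.
    """

    id: str
    sequence: str
    validated_sites: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein id must be non-empty")
        object.__setattr__(self, "sequence", canonicalize(self.sequence))
        object.__setattr__(self, "validated_sites", frozenset(self.validated_sites))
        for pos in self.validated_sites:
            if not 1 <= pos <= len(self.sequence):
                raise ValidationError(
                    f"protein {self.id!r}: annotated position {pos} outside "
                    f"sequence of length {len(self.sequence)}"
                )
            if self.sequence[pos - 1] != "K":
                raise ValidationError(
                    f"protein {self.id!r}: annotated position {pos} is "
                    f"{self.sequence[pos - 1]!r}, not 'K'"
                )

    def lysine_positions(self) -> list[int]:
        """1-based positions of every 'K' in the sequence."""
        return [i + 1 for i, ch in enumerate(self.sequence) if ch == "K"]


@dataclass(frozen=True)
class Fragment:
    """A ``2n + 1`` window centered on a candidate lysine.

    ``site_position`` is the 1-based position of the central K in its
    source protein.  Pads ('-') may appear only as a contiguous prefix
    and/or suffix (terminal truncation).
    """

    window: str
    n: int
    label: str
    protein_id: str
    site_position: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"flank length n must be >= 1, got {self.n}")
        if len(self.window) != 2 * self.n + 1:
            raise ValidationError(
                f"window {self.window!r} has length {len(self.window)}, "
                f"expected {2 * self.n + 1}"
            )
        if self.window[self.n] != "K":
            raise ValidationError(
                f"window {self.window!r} is not centered on 'K'"
            )
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValidationError(f"unknown label {self.label!r}")
        core = self.window.strip(PAD)
        if PAD in core:
            raise ValidationError(
                f"window {self.window!r}: pads must be a contiguous "
                "prefix and/or suffix"
            )
        for ch in core:
            if ch not in AA_INDEX and ch != UNKNOWN:
                raise ValidationError(
                    f"window {self.window!r}: invalid symbol {ch!r}"
                )

    @property
    def pad_left(self) -> int:
        return len(self.window) - len(self.window.lstrip(PAD))

    @property
    def pad_right(self) -> int:
        return len(self.window) - len(self.window.rstrip(PAD))

    @property
    def core(self) -> str:
        """The window with terminal pads stripped."""
        return self.window.strip(PAD)

    @property
    def is_positive(self) -> bool:
        return self.label == POSITIVE


class FragmentSet(Sequence):
    """An ordered collection of fragments sharing one flank length."""

    def __init__(self, fragments: Iterable[Fragment] = ()) -> None:
        self._fragments: list[Fragment] = list(fragments)
        ns = {f.n for f in self._fragments}
        if len(ns) > 1:
            raise ValidationError(f"mixed flank lengths in one set: {sorted(ns)}")
        self._n = ns.pop() if ns else None

    @property
    def n(self) -> int | None:
        """Shared flank length, or None for an empty set."""
        return self._n

    @property
    def window_length(self) -> int | None:
        return None if self._n is None else 2 * self._n + 1

    def __len__(self) -> int:
        return len(self._fragments)

    def __getitem__(self, idx):
        if isinstance(idx, slice):
            return FragmentSet(self._fragments[idx])
        return self._fragments[idx]

    def __iter__(self) -> Iterator[Fragment]:
        return iter(self._fragments)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FragmentSet):
            return NotImplemented
        return self._fragments == other._fragments

    def __repr__(self) -> str:
        return (
            f"FragmentSet({len(self)} fragments, n={self._n}, "
            f"{self.n_positive} positive / {self.n_negative} negative)"
        )

    @property
    def n_positive(self) -> int:
        return sum(1 for f in self._fragments if f.is_positive)

    @property
    def n_negative(self) -> int:
        return len(self) - self.n_positive

    def positives(self) -> "FragmentSet":
        return FragmentSet(f for f in self._fragments if f.is_positive)

    def negatives(self) -> "FragmentSet":
        return FragmentSet(f for f in self._fragments if not f.is_positive)

    def windows(self) -> list[str]:
        return [f.window for f in self._fragments]

    def subset(self, indices: Iterable[int]) -> "FragmentSet":
        return FragmentSet(self._fragments[i] for i in indices)


def encode_windows(fragments: Iterable[Fragment]) -> np.ndarray:
    """Encode windows as an ``(m, 2n+1)`` uint8 matrix of residue codes.

    Codes 0..19 follow alphabetical residue order, 20 is 'X', 21 is the
    terminal pad.  Shared by identity, composition, chi-square and HMM
    counting code.
    """
    frags = list(fragments)
    if not frags:
        return np.zeros((0, 0), dtype=np.uint8)
    length = len(frags[0].window)
    mat = np.empty((len(frags), length), dtype=np.uint8)
    for r, frag in enumerate(frags):
        for c, ch in enumerate(frag.window):
            if ch == PAD:
                mat[r, c] = PAD_CODE
            elif ch == UNKNOWN:
                mat[r, c] = X_CODE
            else:
                mat[r, c] = AA_INDEX[ch]
    return mat


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_site_table(path: str | Path) -> list[tuple[str, int]]:
    """Read the two-column, tab-separated site annotation table.

    Lines starting with '#' are comments.  Returns (protein_id, 1-based
    position) rows in file order.
    """
    rows: list[tuple[str, int]] = []
    with open(path) as handle:
        for ln, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}:{ln}: expected 'protein_id<TAB>position', got {line!r}"
                )
            try:
                pos = int(parts[1])
            except ValueError:
                raise ValidationError(
                    f"{path}:{ln}: position {parts[1]!r} is not an integer"
                ) from None
            rows.append((parts[0], pos))
    return rows


def load_annotated_proteins(
    fasta_path: str | Path, sites_path: str | Path
) -> list[Protein]:
    """Parse a FASTA file and attach validated sites from the annotation table.

    Raises :class:`ValidationError` for duplicate FASTA ids, annotations
    on unknown proteins, out-of-range positions, or positions that do not
    address a lysine.
    """
    records: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in records:
            raise ValidationError(f"duplicate FASTA id {record.id!r}")
        records[record.id] = str(record.seq)
    sites: dict[str, set[int]] = {pid: set() for pid in records}
    for pid, pos in read_site_table(sites_path):
        if pid not in records:
            raise ValidationError(
                f"annotation references unknown protein {pid!r}"
            )
        sites[pid].add(pos)
    return [
        Protein(id=pid, sequence=seq, validated_sites=frozenset(sites[pid]))
        for pid, seq in records.items()
    ]


def extract_fragments(protein: Protein, n: int = 6) -> FragmentSet:
    """Extract one labeled window per lysine in the protein.

    Windows truncated at a terminus are padded with '-'.  A window is
    positive iff its center belongs to ``protein.validated_sites``.
    """
    if n < 1:
        raise ValidationError(f"flank length n must be >= 1, got {n}")
    seq = protein.sequence
    fragments = []
    for pos in protein.lysine_positions():
        left = seq[max(0, pos - 1 - n): pos - 1]
        right = seq[pos: pos + n]
        window = PAD * (n - len(left)) + left + "K" + right + PAD * (n - len(right))
        label = POSITIVE if pos in protein.validated_sites else NEGATIVE
        fragments.append(
            Fragment(
                window=window,
                n=n,
                label=label,
                protein_id=protein.id,
                site_position=pos,
            )
        )
    return FragmentSet(fragments)


def extract_all_fragments(proteins: Iterable[Protein], n: int = 6) -> FragmentSet:
    """Concatenate :func:`extract_fragments` over a protein collection."""
    fragments: list[Fragment] = []
    for protein in proteins:
        fragments.extend(extract_fragments(protein, n))
    return FragmentSet(fragments)


def write_fragment_table(fragments: Iterable[Fragment], path: str | Path) -> None:
    """Write fragments as tab-separated ``protein_id position label window``."""
    with open(path, "w") as handle:
        handle.write("# protein_id\tposition\tlabel\twindow\n")
        for frag in fragments:
            handle.write(
                f"{frag.protein_id}\t{frag.site_position}\t{frag.label}\t{frag.window}\n"
            )


def read_fragment_table(path: str | Path) -> FragmentSet:
    """Read a fragment table written by :func:`write_fragment_table`."""
    fragments = []
    with open(path) as handle:
        for ln, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValidationError(
                    f"{path}:{ln}: expected 4 tab-separated fields, got {len(parts)}"
                )
            pid, pos, label, window = parts
            n = (len(window) - 1) // 2
            fragments.append(
                Fragment(
                    window=window,
                    n=n,
                    label=label,
                    protein_id=pid,
                    site_position=int(pos),
                )
            )
    return FragmentSet(fragments)
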