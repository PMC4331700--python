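"""Synthetic fragments and proteins with planted motif structure.

Every other module is testable without external databases: the
generator draws lysine-centered windows from a background amino-acid
composition and plants group-level biases at chosen flank positions —
for example an aromatic residue enriched at +1 in one subpopulation and
at -1 in another, the kind of substrate-specific signal the MDD/HMM
pipeline is built to detect.  Hidden subpopulation labels are returned
separately (never written into fragment files) so recovery can be
scored without leaking them to any pipeline stage.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .fragment_io import (
    AA_INDEX,
    AMINO_ACIDS,
    Fragment,
    FragmentSet,
    NEGATIVE,
    POSITIVE,
    ValidationError,
)
from .mdd import ResidueGrouping

UNIFORM_BACKGROUND = tuple([1.0 / 20] * 20)


def _enriched_background() -> tuple:
    # flank composition enriched for A, Q, L, S, V, echoing the residues
    # most abundant around real ubiquitination sites
    weights = np.full(20, 0.55 / 15)
    for aa in "AQLSV":
        weights[AA_INDEX[aa]] = 0.45 / 5
    return tuple(weights)


#: named background presets for the generator
BACKGROUNDS: Mapping[str, tuple] = {
    "uniform": UNIFORM_BACKGROUND,
    "ubiquitin-like": _enriched_background(),
}

#: default per-position bias strength for "strong" planted motifs
DEFAULT_BIAS_PROB = 0.9


@dataclass(frozen=True)
class MotifSpec:
    """One subpopulation: its weight, planted biases, and background.

    ``biases`` maps a window offset (non-zero) to ``(group_name,
    probability)``: with that probability the residue is drawn uniformly
    inside the named residue group, otherwise from the background.
    """

    weight: float
    biases: tuple = ()  # tuple of (offset, group_name, probability)
    background: tuple = UNIFORM_BACKGROUND

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValidationError("subpopulation weight must be >= 0")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValidationError("background must be a 20-vector summing to 1")
        grouping = ResidueGrouping.default()
        for offset, group, prob in self.biases:
            if offset == 0:
                raise ValidationError("cannot bias the central lysine")
            if group not in grouping.names:
                raise ValidationError(f"unknown residue group {group!r}")
            if not 0.0 <= prob <= 1.0:
                raise ValidationError(f"bias probability {prob} outside [0, 1]")


def generate_fragments(
    specs: Sequence[MotifSpec],
    n_total: int,
    n: int = 6,
    seed: int = 0,
    label: str = POSITIVE,
    grouping: ResidueGrouping | None = None,
    id_prefix: str = "synth",
) -> tuple[FragmentSet, np.ndarray]:
    """Draw ``n_total`` windows from a mixture of motif subpopulations.

    Returns the fragment set and the hidden per-fragment subpopulation
    indices.  Deterministic for a given seed.
    """
    if n_total < 1:
        raise ValidationError("n_total must be >= 1")
    if not specs:
        raise ValidationError("need at least one MotifSpec")
    grouping = grouping or ResidueGrouping.default()
    weights = np.array([s.weight for s in specs], dtype=float)
    if not np.isclose(weights.sum(), 1.0, atol=1e-9):
        raise ValidationError("subpopulation weights must sum to 1")
    for spec in specs:
        for offset, _, _ in spec.biases:
            if not -n <= offset <= n:
                raise ValidationError(f"bias offset {offset} outside window n={n}")
    rng = np.random.default_rng(seed)
    length = 2 * n + 1
    hidden = rng.choice(len(specs), size=n_total, p=weights)
    codes = np.empty((n_total, length), dtype=np.intp)
    members = {
        name: np.array([AA_INDEX[aa] for aa in residues])
        for name, residues in zip(grouping.names, grouping.members)
    }
    for s, spec in enumerate(specs):
        rows = np.nonzero(hidden == s)[0]
        if rows.size == 0:
            continue
        bg = np.asarray(spec.background, dtype=float)
        codes[rows] = rng.choice(20, size=(rows.size, length), p=bg)
        for offset, group, prob in spec.biases:
            col = offset + n
            biased = rows[rng.random(rows.size) < prob]
            codes[biased, col] = rng.choice(members[group], size=biased.size)
    codes[:, n] = AA_INDEX["K"]
    fragments = [
        Fragment(
            window="".join(AMINO_ACIDS[c] for c in codes[row]),
            n=n,
            label=label,
            protein_id=f"{id_prefix}{row}",
            site_position=n + 1,
        )
        for row in range(n_total)
    ]
    return FragmentSet(fragments), hidden


def two_motif_specs(
    bias_prob: float = DEFAULT_BIAS_PROB, background: tuple = UNIFORM_BACKGROUND
) -> list[MotifSpec]:
    """The two-motif benchmark mixture: aromatic at +1 vs aromatic at -1."""
    return [
        MotifSpec(weight=0.5, biases=((+1, "aromatic", bias_prob),), background=background),
        MotifSpec(weight=0.5, biases=((-1, "aromatic", bias_prob),), background=background),
    ]


def disjoint_motif_specs(background: tuple = UNIFORM_BACKGROUND) -> list[MotifSpec]:
    """Fully disjoint paired biases (aromatic/acidic swapped across +-1).

    With probability-1 biases the subpopulations are separable at either
    position, the regime for exact recovery of planted labels.
    """
    return [
        MotifSpec(
            weight=0.5,
            biases=((+1, "aromatic", 1.0), (-1, "acidic", 1.0)),
            background=background,
        ),
        MotifSpec(
            weight=0.5,
            biases=((-1, "aromatic", 1.0), (+1, "acidic", 1.0)),
            background=background,
        ),
    ]


def benchmark_dataset(
    n_positives: int = 400,
    ratio: float = 2.08,
    n: int = 6,
    seed: int = 0,
    bias_prob: float = DEFAULT_BIAS_PROB,
    background: tuple = UNIFORM_BACKGROUND,
) -> tuple[FragmentSet, FragmentSet, np.ndarray]:
    """Positives from the two-motif mixture plus background negatives.

    Negatives number ``round(n_positives * ratio)`` (default: the
    1:2.08 class ratio) and carry no planted structure.  Returns
    (positives, negatives, hidden positive subpopulation labels).
    """
    positives, hidden = generate_fragments(
        two_motif_specs(bias_prob, background),
        n_total=n_positives,
        n=n,
        seed=seed,
        label=POSITIVE,
        id_prefix="pos",
    )
    negatives, _ = generate_fragments(
        [MotifSpec(weight=1.0, background=background)],
        n_total=round(n_positives * ratio),
        n=n,
        seed=seed + 1,
        label=NEGATIVE,
        id_prefix="neg",
    )
    return positives, negatives, hidden


def generate_annotated_proteins(
    n_proteins: int,
    length: int,
    positive_motif: MotifSpec,
    sites_per_protein: int,
    n: int = 6,
    seed: int = 0,
) -> tuple[str, str]:
    """Background proteins with planted motif windows at annotated lysines.

    Returns (FASTA text, tab-separated site table text); the pair
    round-trips through the fragment-extraction machinery.  Planted
    windows never overlap; lysines arising by chance elsewhere become
    unannotated negatives.
    """
    window = 2 * n + 1
    if length < window:
        raise ValidationError(f"protein length {length} shorter than window {window}")
    if sites_per_protein * window > length:
        raise ValidationError(
            f"cannot place {sites_per_protein} non-overlapping windows of "
            f"{window} residues in a protein of length {length}"
        )
    rng = np.random.default_rng(seed)
    grouping = ResidueGrouping.default()
    members = {
        name: np.array([AA_INDEX[aa] for aa in residues])
        for name, residues in zip(grouping.names, grouping.members)
    }
    bg = np.asarray(positive_motif.background, dtype=float)
    fasta_lines: list[str] = []
    site_lines: list[str] = ["# protein_id\tposition"]
    for p in range(n_proteins):
        codes = rng.choice(20, size=length, p=bg)
        centers: list[int] = []
        for _ in range(200 * max(1, sites_per_protein)):
            if len(centers) == sites_per_protein:
                break
            cand = int(rng.integers(n, length - n))  # 0-based center index
            if all(abs(cand - c) >= window for c in centers):
                centers.append(cand)
        if len(centers) < sites_per_protein:
            raise ValidationError(
                f"could not place {sites_per_protein} sites in length {length}"
            )
        for center in sorted(centers):
            codes[center - n: center + n + 1] = rng.choice(
                20, size=window, p=bg
            )
            for offset, group, prob in positive_motif.biases:
                if rng.random() < prob:
                    codes[center + offset] = rng.choice(members[group])
            codes[center] = AA_INDEX["K"]
            site_lines.append(f"prot{p}\t{center + 1}")
        sequence = "".join(AMINO_ACIDS[c] for c in codes)
        fasta_lines.append(f">prot{p}")
        fasta_lines.extend(textwrap.wrap(sequence, 60))
    return "\n".join(fasta_lines) + "\n", "\n".join(site_lines) + "\n"
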