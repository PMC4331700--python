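"""Amino-acid composition and sequence-logo statistics.

Pooled amino-acid composition (AAC) compares the flanking-residue usage
of positive and negative windows; the position frequency matrix (PFM)
and its per-position information content are the numeric form of a
sequence logo.  Pad cells and 'X' are excluded from every count; the
per-position ``support`` records the effective denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .fragment_io import AMINO_ACIDS, FragmentSet, ValidationError, encode_windows

N_RESIDUES = 20
MAX_BITS = float(np.log2(N_RESIDUES))


@dataclass
class PositionFrequencyMatrix:
    """Per-position residue frequencies of a fragment set.

    ``freq`` is a ``(2n+1, 20)`` matrix whose rows sum to 1 wherever
    ``support`` (the count of non-pad, non-X observations) is positive;
    zero-support rows are all-zero.
    """

    n: int
    freq: np.ndarray
    support: np.ndarray

    @property
    def positions(self) -> list[int]:
        """Window offsets -n..+n (0 is the central lysine)."""
        return list(range(-self.n, self.n + 1))


def _count_matrix(fragment_set: FragmentSet) -> np.ndarray:
    codes = encode_windows(fragment_set)
    length = codes.shape[1]
    counts = np.zeros((length, N_RESIDUES), dtype=np.int64)
    for col in range(length):
        col_codes = codes[:, col]
        valid = col_codes < N_RESIDUES  # drops X and pad
        counts[col] = np.bincount(col_codes[valid], minlength=N_RESIDUES)
    return counts


def amino_acid_composition(fragment_set: FragmentSet) -> np.ndarray:
    """Pooled residue frequencies over all non-pad, non-center flank cells.

    Returns a 20-vector in alphabetical residue order summing to 1.
    """
    if len(fragment_set) == 0:
        raise ValidationError("cannot compute composition of an empty set")
    counts = _count_matrix(fragment_set)
    counts[fragment_set.n] = 0  # the center is 'K' by construction
    pooled = counts.sum(axis=0).astype(float)
    total = pooled.sum()
    if total == 0:
        raise ValidationError("no countable flank cells (all pad or 'X')")
    return pooled / total


def position_frequency_matrix(fragment_set: FragmentSet) -> PositionFrequencyMatrix:
    """Per-position residue frequencies (center column included)."""
    if len(fragment_set) == 0:
        raise ValidationError("cannot compute a PFM of an empty set")
    counts = _count_matrix(fragment_set)
    support = counts.sum(axis=1)
    freq = np.zeros_like(counts, dtype=float)
    nonzero = support > 0
    freq[nonzero] = counts[nonzero] / support[nonzero, None]
    return PositionFrequencyMatrix(n=fragment_set.n, freq=freq, support=support)


def information_content(
    pfm: PositionFrequencyMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Entropy-logo statistics of a PFM.

    Per position, IC = log2(20) - H where H is the Shannon entropy (bits)
    of the residue distribution; letter heights are frequency x IC.  No
    small-sample correction is applied.  Zero-support positions report
    IC = 0.
    """
    freq = pfm.freq
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    entropy = -plogp.sum(axis=1)
    ic = np.where(pfm.support > 0, MAX_BITS - entropy, 0.0)
    ic = np.clip(ic, 0.0, MAX_BITS)
    heights = freq * ic[:, None]
    return ic, heights


def aac_comparison_table(
    positives: FragmentSet, negatives: FragmentSet
) -> dict[str, tuple[float, float, float]]:
    """Per-residue (positive, negative, difference) flank frequencies.

    The numeric form of the positive-vs-negative composition bar plot.
    """
    pos = amino_acid_composition(positives)
    neg = amino_acid_composition(negatives)
    return {
        aa: (float(pos[i]), float(neg[i]), float(pos[i] - neg[i]))
        for i, aa in enumerate(AMINO_ACIDS)
    }


def write_pfm(pfm: PositionFrequencyMatrix, path: str | Path) -> None:
    """Tab-separated PFM: rows are positions -n..+n, columns the 20 residues."""
    with open(path, "w") as handle:
        handle.write("position\t" + "\t".join(AMINO_ACIDS) + "\tsupport\n")
        for row, pos in enumerate(pfm.positions):
            values = "\t".join(f"{v:.6f}" for v in pfm.freq[row])
            handle.write(f"{pos:+d}\t{values}\t{pfm.support[row]}\n")


def write_information_content(
    pfm: PositionFrequencyMatrix, path: str | Path
) -> None:
    ic, _ = information_content(pfm)
    with open(path, "w") as handle:
        handle.write("position\tinformation_bits\n")
        for row, pos in enumerate(pfm.positions):
            handle.write(f"{pos:+d}\t{ic[row]:.6f}\n")
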