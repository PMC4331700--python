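"""Maximal dependence decomposition (MDD) of positive fragment sets.

A single sequence logo of all ubiquitinated windows averages away
substrate-specific signals left by different recognizing enzymes.  MDD
recovers them by recursive partitioning: residues are mapped to a small
number of biochemical groups, the dependence between every pair of
flanking positions is measured with a Pearson chi-square statistic over
the group-by-group contingency table, and the set is split at the
position with the strongest total dependence, on the residue group most
common there.  Recursion continues while a significant dependence
remains and both children stay above a minimum cluster size; the final
never-split remainder is flagged *residual*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .fragment_io import AA_INDEX, FragmentSet, ValidationError, encode_windows

#: upper-tail 0.005 critical value of chi-square at 16 degrees of freedom
#: (the full 5x5 group table) -- the default significance cutoff
DEFAULT_CHI2_CRITICAL = 34.27

DEFAULT_MIN_CLUSTER_SIZE = 80

_DEFAULT_GROUPS: tuple[tuple[str, str], ...] = (
    ("nonpolar", "GAVLIPM"),
    ("aromatic", "FYW"),
    ("polar", "STCNQ"),
    ("acidic", "DE"),
    ("basic", "KRH"),
)


@dataclass(frozen=True)
class ResidueGrouping:
    """A total partition of the 20 residues into contingency categories.

    The default five biochemical groups isolate the aromatics (F, Y, W)
    as their own category, since aromatic enrichment at specific flank
    positions is the dominant substrate signal this decomposition is
    meant to find.  Any alternative total grouping can be injected.
    """

    names: tuple
    members: tuple  # tuple of residue strings, parallel to names

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for gid, residues in enumerate(self.members):
            for aa in residues:
                if aa not in AA_INDEX:
                    raise ValidationError(f"unknown residue {aa!r} in grouping")
                if aa in seen:
                    raise ValidationError(f"residue {aa!r} assigned twice")
                seen[aa] = gid
        if len(seen) != len(AA_INDEX):
            missing = sorted(set(AA_INDEX) - set(seen))
            raise ValidationError(f"grouping is not total; missing {missing}")

    @classmethod
    def default(cls) -> "ResidueGrouping":
        names, members = zip(*_DEFAULT_GROUPS)
        return cls(names=names, members=members)

    @property
    def n_groups(self) -> int:
        return len(self.names)

    def mapping(self) -> Mapping[str, int]:
        return {
            aa: gid for gid, residues in enumerate(self.members) for aa in residues
        }

    def code_vector(self) -> np.ndarray:
        """Residue code (0..21) -> group id; 'X' and pad map to -1."""
        vec = np.full(22, -1, dtype=np.int8)
        for gid, residues in enumerate(self.members):
            for aa in residues:
                vec[AA_INDEX[aa]] = gid
        return vec


@dataclass
class ChiSquareMatrix:
    """All pairwise position-dependence statistics of one fragment set.

    ``positions`` are window offsets excluding the center; ``values`` is
    symmetric with NaN on the diagonal; ``df`` holds the per-pair degrees
    of freedom of the retained contingency table.
    """

    positions: list
    values: np.ndarray
    df: np.ndarray

    def sums(self) -> np.ndarray:
        """S(i) = sum over j != i of chi2(i, j), per position."""
        return np.nansum(self.values, axis=1)


@dataclass
class Split:
    """One recorded MDD split: where, on what group, and how strong."""

    path: tuple
    position: int
    group: str
    chi_sum: float
    size_motif: int
    size_rest: int


@dataclass
class MDDResult:
    """Disjoint motif subgroups plus the trace of splits that made them."""

    clusters: list
    splits: list
    residual: list  # bool per cluster

    @property
    def sizes(self) -> list:
        return [len(c) for c in self.clusters]


def _offset_to_column(offset: int, n: int) -> int:
    if offset == 0 or not -n <= offset <= n:
        raise ValidationError(f"position offset {offset} invalid for n={n}")
    return offset + n


def _chi_square_from_groups(
    gi: np.ndarray, gj: np.ndarray, n_groups: int
) -> tuple[float, int]:
    """Pearson chi-square of the group contingency table, zero-margin
    rows/columns dropped."""
    table = np.zeros((n_groups, n_groups), dtype=np.int64)
    np.add.at(table, (gi, gj), 1)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    r, c = table.shape
    if r <= 1 or c <= 1:
        return 0.0, 0
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return chi2, (r - 1) * (c - 1)


def chi_square(
    fragment_set: FragmentSet,
    i: int,
    j: int,
    grouping: ResidueGrouping | None = None,
) -> tuple[float, int]:
    """Dependence between residue groups at window offsets ``i`` and ``j``.

    Fragments with a pad or 'X' at either position are skipped.  Returns
    (chi2, df) for the retained r x c table; a degenerate table (single
    group at either position) gives (0.0, 0).
    """
    grouping = grouping or ResidueGrouping.default()
    n = fragment_set.n
    if n is None:
        raise ValidationError("empty fragment set")
    if i == j:
        raise ValidationError("positions i and j must differ")
    ci, cj = _offset_to_column(i, n), _offset_to_column(j, n)
    codes = encode_windows(fragment_set)
    vec = grouping.code_vector()
    gi, gj = vec[codes[:, ci]], vec[codes[:, cj]]
    usable = (gi >= 0) & (gj >= 0)
    if int(usable.sum()) < 2:
        raise ValidationError(
            f"fewer than 2 usable fragments for positions {i:+d}/{j:+d}"
        )
    return _chi_square_from_groups(
        gi[usable].astype(np.intp), gj[usable].astype(np.intp), grouping.n_groups
    )


def dependence_profile(
    fragment_set: FragmentSet,
    grouping: ResidueGrouping | None = None,
    strict: bool = True,
) -> ChiSquareMatrix:
    """Chi-square statistics for all unordered flank-position pairs.

    With ``strict=False`` a pair with fewer than two usable fragments
    contributes 0 instead of raising (used internally by the recursion,
    where heavily padded columns may go empty).
    """
    grouping = grouping or ResidueGrouping.default()
    n = fragment_set.n
    if n is None or len(fragment_set) < 2:
        raise ValidationError("need at least 2 fragments")
    positions = [p for p in range(-n, n + 1) if p != 0]
    codes = encode_windows(fragment_set)
    vec = grouping.code_vector()
    groups = vec[codes]  # (m, 2n+1)
    P = len(positions)
    values = np.full((P, P), np.nan)
    df = np.zeros((P, P), dtype=np.int64)
    for a in range(P):
        ca = _offset_to_column(positions[a], n)
        for b in range(a + 1, P):
            cb = _offset_to_column(positions[b], n)
            ga, gb = groups[:, ca], groups[:, cb]
            usable = (ga >= 0) & (gb >= 0)
            if int(usable.sum()) < 2:
                if strict:
                    raise ValidationError(
                        f"fewer than 2 usable fragments for positions "
                        f"{positions[a]:+d}/{positions[b]:+d}"
                    )
                chi2, d = 0.0, 0
            else:
                chi2, d = _chi_square_from_groups(
                    ga[usable].astype(np.intp),
                    gb[usable].astype(np.intp),
                    grouping.n_groups,
                )
            values[a, b] = values[b, a] = chi2
            df[a, b] = df[b, a] = d
    return ChiSquareMatrix(positions=positions, values=values, df=df)


def mdd_partition(
    fragment_set: FragmentSet,
    grouping: ResidueGrouping | None = None,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    chi2_critical: float = DEFAULT_CHI2_CRITICAL,
) -> MDDResult:
    """Recursively partition a fragment set into motif subgroups.

    At each node: stop and emit the set as one cluster if no position
    pair has chi2 > ``chi2_critical`` or no split can produce two
    children of at least ``min_cluster_size``.  Otherwise split at the
    position with the largest dependence sum S(i) (ties: most N-terminal
    offset), peeling off the largest eligible residue group there (ties:
    lowest group id); recurse on both children.  Clusters are emitted in
    discovery order; the terminal node of the pure-remainder path is
    flagged residual.  Deterministic for a given input order.
    """
    grouping = grouping or ResidueGrouping.default()
    if min_cluster_size < 2:
        raise ValidationError("min_cluster_size must be >= 2")
    clusters: list[FragmentSet] = []
    splits: list[Split] = []
    residual: list[bool] = []
    vec = grouping.code_vector()
    n = fragment_set.n

    def emit(frags: FragmentSet, is_residual: bool) -> None:
        clusters.append(frags)
        residual.append(is_residual)

    def recurse(frags: FragmentSet, path: tuple, remainder_chain: bool) -> None:
        if len(frags) < 2 * min_cluster_size or len(frags) < 2:
            emit(frags, remainder_chain)
            return
        profile = dependence_profile(frags, grouping, strict=False)
        if not np.any(np.nan_to_num(profile.values) > chi2_critical):
            emit(frags, remainder_chain)
            return
        sums = profile.sums()
        best = int(np.argmax(sums))  # first occurrence = most N-terminal
        p_star = profile.positions[best]
        codes = encode_windows(frags)
        col = _offset_to_column(p_star, n)
        groups_at = vec[codes[:, col]]
        counts = np.bincount(
            groups_at[groups_at >= 0].astype(np.intp), minlength=grouping.n_groups
        )
        eligible = [
            g
            for g in range(grouping.n_groups)
            if counts[g] >= min_cluster_size
            and len(frags) - counts[g] >= min_cluster_size
        ]
        if not eligible:
            emit(frags, remainder_chain)
            return
        g_star = max(eligible, key=lambda g: (counts[g], -g))
        motif_idx = [k for k in range(len(frags)) if groups_at[k] == g_star]
        rest_idx = [k for k in range(len(frags)) if groups_at[k] != g_star]
        splits.append(
            Split(
                path=path,
                position=p_star,
                group=grouping.names[g_star],
                chi_sum=float(sums[best]),
                size_motif=len(motif_idx),
                size_rest=len(rest_idx),
            )
        )
        recurse(frags.subset(motif_idx), path + ("motif",), False)
        recurse(frags.subset(rest_idx), path + ("rest",), remainder_chain)

    recurse(fragment_set, (), True)
    return MDDResult(clusters=clusters, splits=splits, residual=residual)


def write_split_trace(result: MDDResult, path) -> None:
    """Human-readable split trace plus per-cluster sizes, tab-separated."""
    with open(path, "w") as handle:
        handle.write("# split\tpath\tposition\tgroup\tchi_sum\tsize_motif\tsize_rest\n")
        for k, s in enumerate(result.splits):
            handle.write(
                f"split{k}\t{'/'.join(s.path) or '.'}\t{s.position:+d}\t"
                f"{s.group}\t{s.chi_sum:.3f}\t{s.size_motif}\t{s.size_rest}\n"
            )
        handle.write("# cluster\tsize\tresidual\n")
        for k, (cluster, res) in enumerate(zip(result.clusters, result.residual)):
            handle.write(f"cluster{k}\t{len(cluster)}\t{int(res)}\n")
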