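"""Homology reduction on fixed-length fragments.

Training on near-identical windows overstates cross-validated
performance, so fragment sets are reduced with a greedy single-pass
clustering in the style of CD-HIT: each fragment joins the first
established representative whose pairwise identity strictly exceeds the
threshold, otherwise it founds a new cluster.  Because every window here
has the same length, the exact greedy pass is cheap and fully
deterministic; CD-HIT's short-word pre-filter heuristics are deliberately
not reproduced.

A second, cross-set pass removes every negative window that is exactly
identical to some positive window, so the two classes never share a
fragment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fragment_io import Fragment, FragmentSet, PAD_CODE, ValidationError, encode_windows


@dataclass
class IdentityCluster:
    """A representative fragment and the members it absorbed."""

    representative: Fragment
    members: list
    threshold: float


def fragment_identity(a: Fragment, b: Fragment) -> float:
    """Pairwise identity between two equal-length windows.

    Defined as (# positions where both are non-pad and equal) divided by
    (# positions where both are non-pad).  Symmetric; the shared central
    'K' guarantees a non-zero denominator.
    """
    if len(a.window) != len(b.window):
        raise ValidationError(
            f"window length mismatch: {len(a.window)} vs {len(b.window)}"
        )
    both = matches = 0
    for ca, cb in zip(a.window, b.window):
        if ca != "-" and cb != "-":
            both += 1
            if ca == cb:
                matches += 1
    return matches / both


def cluster_fragments(
    fragment_set: FragmentSet, threshold: float = 0.40
) -> list[IdentityCluster]:
    """Greedy single-pass identity clustering.

    Fragments are visited in canonical order (length descending, then
    input order; all lengths are equal here, so input order).  A fragment
    joins the first representative with identity strictly greater than
    ``threshold``, else founds a new cluster.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    clusters: list[IdentityCluster] = []
    if len(fragment_set) == 0:
        return clusters
    mat = encode_windows(fragment_set)
    nonpad = mat != PAD_CODE
    rep_rows: list[np.ndarray] = []
    rep_nonpad: list[np.ndarray] = []
    for idx, frag in enumerate(fragment_set):
        if rep_rows:
            reps = np.asarray(rep_rows)
            reps_np = np.asarray(rep_nonpad)
            both = reps_np & nonpad[idx]
            match = (reps == mat[idx]) & both
            ident = match.sum(axis=1) / both.sum(axis=1)
            hits = np.nonzero(ident > threshold)[0]
            if hits.size:
                clusters[int(hits[0])].members.append(frag)
                continue
        clusters.append(
            IdentityCluster(representative=frag, members=[frag], threshold=threshold)
        )
        rep_rows.append(mat[idx])
        rep_nonpad.append(nonpad[idx])
    return clusters


def reduce_redundancy(
    fragment_set: FragmentSet, threshold: float = 0.40
) -> FragmentSet:
    """Return the cluster representatives of the greedy identity pass.

    Identity exactly equal to the threshold does not merge; only strictly
    higher identity does.  Output order follows the input; the result is
    a subset of the input and the pass is idempotent.
    """
    return FragmentSet(
        c.representative for c in cluster_fragments(fragment_set, threshold)
    )


def purge_cross_duplicates(
    negatives: FragmentSet, positives: FragmentSet
) -> FragmentSet:
    """Drop every negative whose window exactly equals a positive window.

    Mirrors a cross-set 100%-identity purge; positives are untouched.
    """
    if (
        len(negatives)
        and len(positives)
        and negatives.window_length != positives.window_length
    ):
        raise ValidationError(
            f"window length mismatch across sets: "
            f"{negatives.window_length} vs {positives.window_length}"
        )
    positive_windows = set(positives.windows())
    return FragmentSet(f for f in negatives if f.window not in positive_windows)
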