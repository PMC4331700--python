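"""Profile hidden Markov models over fixed-length lysine windows.

One model is trained per motif subgroup, from positive fragments only.
Because the training windows are gapless and all the same length, the
architecture is simply ``L = 2n + 1`` match states with smoothed
insert/delete mass; emissions are Laplace-smoothed counts and the null
model is the pooled residue composition of the training data.  Scoring
uses the full forward algorithm over match/insert/delete paths and
reports the log-odds of the window under the model versus the null, in
bits.  Windows whose lysine sits near a protein terminus carry pad
cells; pads contribute neither emission nor null mass — the model is
restricted to the match states of the non-pad columns.

A bit-score threshold per model turns scores into decisions: a window is
called positive when its score strictly exceeds the threshold.  The
threshold is chosen by an exhaustive scan over all decision boundaries
that the observed training scores admit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .evaluation import ConfusionCounts, compute_metrics
from .fragment_io import (
    AMINO_ACIDS,
    Fragment,
    FragmentSet,
    ValidationError,
    encode_windows,
)

N_RESIDUES = 20

# default transition mass: match-dominant, with small smoothed
# insert/delete probability so every path has non-zero probability
DEFAULT_TRANSITIONS = {
    "mm": 0.99,
    "mi": 0.005,
    "md": 0.005,
    "im": 0.5,
    "ii": 0.5,
    "dm": 0.5,
    "dd": 0.5,
}

#: emission/null probability assigned to an 'X' cell under every state,
#: so unknown residues contribute ~0 bits
_X_EMISSION = 1.0 / N_RESIDUES


@dataclass(frozen=True)
class ProfileHMM:
    """An L-node match/insert/delete profile with a background null.

    ``match_emissions`` is (L, 20) in alphabetical residue order; insert
    states emit the background.  Transition probabilities are shared
    across nodes (``mm + mi + md = 1``, ``im + ii = 1``, ``dm + dd = 1``).
    """

    match_emissions: np.ndarray
    background: np.ndarray
    pseudocount: float = 1.0
    transitions: dict = field(default_factory=lambda: dict(DEFAULT_TRANSITIONS))

    def __post_init__(self) -> None:
        em = np.asarray(self.match_emissions, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "match_emissions", em)
        object.__setattr__(self, "background", bg)
        if em.ndim != 2 or em.shape[1] != N_RESIDUES:
            raise ValidationError("match_emissions must be (L, 20)")
        if bg.shape != (N_RESIDUES,):
            raise ValidationError("background must be a 20-vector")
        if np.any(em <= 0) or np.any(bg <= 0):
            raise ValidationError("all probabilities must be > 0 (smoothed)")
        if not np.allclose(em.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("emission rows must sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValidationError("background must sum to 1")
        t = self.transitions
        for bundle in (("mm", "mi", "md"), ("im", "ii"), ("dm", "dd")):
            if not np.isclose(sum(t[k] for k in bundle), 1.0, atol=1e-9):
                raise ValidationError(f"transition bundle {bundle} must sum to 1")

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]


@dataclass(frozen=True)
class ThresholdedModel:
    """A profile HMM paired with its decision cutoff (bits)."""

    model: ProfileHMM
    threshold: float
    objective: str = "accuracy"
    objective_value: float = float("nan")
    cluster_id: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValidationError("threshold must be finite")


def smoothed_background(fragment_set: FragmentSet) -> np.ndarray:
    """Laplace-smoothed pooled flank composition, the default null model.

    Falls back to uniform 1/20 when the set has no countable cells.
    """
    if len(fragment_set) == 0:
        return np.full(N_RESIDUES, 1.0 / N_RESIDUES)
    codes = encode_windows(fragment_set)
    center = fragment_set.n
    counts = np.zeros(N_RESIDUES, dtype=np.int64)
    for col in range(codes.shape[1]):
        if col == center:
            continue
        col_codes = codes[:, col]
        valid = col_codes < N_RESIDUES
        counts += np.bincount(col_codes[valid], minlength=N_RESIDUES)
    return (counts + 1.0) / (counts.sum() + N_RESIDUES)


def build_profile_hmm(
    cluster: FragmentSet,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Train a profile HMM from the positive fragments of one cluster.

    Match emission at position p is ``(count + pseudocount) /
    (support(p) + 20 * pseudocount)`` with pad and 'X' cells excluded
    from both count and support.
    """
    if len(cluster) == 0:
        raise ValidationError("cannot build a model from an empty cluster")
    if cluster.n_negative:
        raise ValidationError("training cluster must contain positive fragments only")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    codes = encode_windows(cluster)
    length = codes.shape[1]
    counts = np.zeros((length, N_RESIDUES), dtype=np.int64)
    for col in range(length):
        col_codes = codes[:, col]
        valid = col_codes < N_RESIDUES
        counts[col] = np.bincount(col_codes[valid], minlength=N_RESIDUES)
    support = counts.sum(axis=1, keepdims=True)
    emissions = (counts + pseudocount) / (support + N_RESIDUES * pseudocount)
    if background is None:
        background = smoothed_background(cluster)
    return ProfileHMM(
        match_emissions=emissions,
        background=np.asarray(background, dtype=float),
        pseudocount=pseudocount,
    )


def _forward_batch(
    model: ProfileHMM, obs: np.ndarray, node_start: int, node_end: int
) -> np.ndarray:
    """Forward probability for a batch of depadded observation rows.

    ``obs`` is (B, T) with residue codes 0..19 and 20 for 'X'; the rows
    align to match nodes ``node_start..node_end-1`` (T == node count,
    since pads occur only at termini of full-length windows).
    """
    t = model.transitions
    mm, mi, md = t["mm"], t["mi"], t["md"]
    im, ii = t["im"], t["ii"]
    dm, dd = t["dm"], t["dd"]
    em = np.hstack(
        [
            model.match_emissions[node_start:node_end],
            np.full((node_end - node_start, 1), _X_EMISSION),
        ]
    )
    q = np.append(model.background, _X_EMISSION)
    B, T = obs.shape
    q_obs = q[obs]  # (B, T)
    # prev_* indexed [t, batch]; node 0 is the begin state
    prev_m = np.zeros((T + 1, B))
    prev_m[0] = 1.0
    prev_i = np.zeros((T + 1, B))
    prev_d = np.zeros((T + 1, B))
    for step in range(1, T + 1):
        prev_i[step] = q_obs[:, step - 1] * (
            prev_m[step - 1] * mi + prev_i[step - 1] * ii
        )
    for k in range(1, T + 1):
        e_obs = em[k - 1][obs]  # (B, T)
        cur_m = np.zeros((T + 1, B))
        cur_m[1:] = e_obs.T * (
            prev_m[:-1] * mm + prev_i[:-1] * im + prev_d[:-1] * dm
        )
        cur_d = prev_m * md + prev_d * dd
        cur_i = np.zeros((T + 1, B))
        for step in range(1, T + 1):
            cur_i[step] = q_obs[:, step - 1] * (
                cur_m[step - 1] * mi + cur_i[step - 1] * ii
            )
        prev_m, prev_i, prev_d = cur_m, cur_i, cur_d
    return prev_m[T] * (mm + md) + prev_i[T] * im + prev_d[T] * (dm + dd)


def _transition_mass(transitions: dict, T: int) -> float:
    """Total transition probability of all paths emitting exactly T symbols.

    This is the forward probability with every emission set to 1; the
    null model shares it, so it cancels out of the log-odds ratio.  Kept
    explicit so the null is a proper length-matched state machine.
    """
    mm, mi, md = transitions["mm"], transitions["mi"], transitions["md"]
    im, ii = transitions["im"], transitions["ii"]
    dm, dd = transitions["dm"], transitions["dd"]
    prev_m = np.zeros(T + 1)
    prev_m[0] = 1.0
    prev_i = np.zeros(T + 1)
    prev_d = np.zeros(T + 1)
    for step in range(1, T + 1):
        prev_i[step] = prev_m[step - 1] * mi + prev_i[step - 1] * ii
    for _k in range(1, T + 1):
        cur_m = np.zeros(T + 1)
        cur_m[1:] = prev_m[:-1] * mm + prev_i[:-1] * im + prev_d[:-1] * dm
        cur_d = prev_m * md + prev_d * dd
        cur_i = np.zeros(T + 1)
        for step in range(1, T + 1):
            cur_i[step] = cur_m[step - 1] * mi + cur_i[step - 1] * ii
        prev_m, prev_i, prev_d = cur_m, cur_i, cur_d
    return float(prev_m[T] * (mm + md) + prev_i[T] * im + prev_d[T] * (dm + dd))


def bit_scores(
    model: ProfileHMM, fragments: FragmentSet | Sequence[Fragment]
) -> np.ndarray:
    """Log-odds bit score of each fragment window under the model.

    ``log2(P(window | model) / P(window | background))`` with the forward
    probability summed over all match/insert/delete paths.  Pad cells are
    skipped on both sides of the odds ratio.
    """
    frags = list(fragments)
    if not frags:
        return np.zeros(0)
    for frag in frags:
        if len(frag.window) != model.length:
            raise ValidationError(
                f"window length {len(frag.window)} != model length {model.length}"
            )
    codes = encode_windows(frags)
    scores = np.empty(len(frags))
    q = np.append(model.background, _X_EMISSION)
    # group fragments by pad signature; each group shares one sub-model
    signatures: dict[tuple, list] = {}
    for idx, frag in enumerate(frags):
        signatures.setdefault((frag.pad_left, frag.pad_right), []).append(idx)
    for (pl, pr), indices in signatures.items():
        node_start, node_end = pl, model.length - pr
        obs = codes[indices, node_start:node_end].astype(np.intp)
        fwd = _forward_batch(model, obs, node_start, node_end)
        # length-matched null: the same state machine with background
        # emissions everywhere, i.e. product of background frequencies
        # times the shared transition mass
        null = q[obs].prod(axis=1) * _transition_mass(
            model.transitions, node_end - node_start
        )
        scores[indices] = np.log2(fwd / null)
    return scores


def bit_score(model: ProfileHMM, fragment: Fragment) -> float:
    """Bit score of a single fragment (see :func:`bit_scores`)."""
    return float(bit_scores(model, [fragment])[0])


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])


def select_threshold(
    model: ProfileHMM,
    positives: FragmentSet,
    negatives: FragmentSet,
    objective: str = "accuracy",
) -> ThresholdedModel:
    """Pick the bit-score cutoff maximizing accuracy or MCC.

    Candidates are every midpoint between adjacent distinct observed
    scores plus sentinels below and above all scores; a window is called
    positive when ``score > threshold`` (strict).  Ties are broken toward
    higher MCC, then toward the lower (more sensitive) threshold.
    """
    if objective not in ("accuracy", "mcc"):
        raise ValidationError(f"unknown objective {objective!r}")
    if len(positives) == 0 or len(negatives) == 0:
        raise ValidationError("need non-empty positive and negative sets")
    pos_scores = bit_scores(model, positives)
    neg_scores = bit_scores(model, negatives)
    best_key: tuple | None = None
    best_threshold = 0.0
    best_value = float("nan")
    for tau in _candidate_thresholds(np.concatenate([pos_scores, neg_scores])):
        counts = ConfusionCounts(
            tp=int((pos_scores > tau).sum()),
            fn=int((pos_scores <= tau).sum()),
            tn=int((neg_scores <= tau).sum()),
            fp=int((neg_scores > tau).sum()),
        )
        report = compute_metrics(counts)
        value = report.acc if objective == "accuracy" else report.mcc
        key = (value, report.mcc, -tau)
        if best_key is None or key > best_key:
            best_key, best_threshold, best_value = key, float(tau), float(value)
    return ThresholdedModel(
        model=model,
        threshold=best_threshold,
        objective=objective,
        objective_value=best_value,
    )


# ---------------------------------------------------------------------------
# plain-text serialization (versioned; bit-exact round trip via float repr)
# ---------------------------------------------------------------------------

_FORMAT_TAG = "ubimdd-phmm v1"


def model_to_text(model: ProfileHMM) -> str:
    lines = [_FORMAT_TAG]
    lines.append(f"L {model.length}")
    lines.append(f"pseudocount {model.pseudocount!r}")
    t = model.transitions
    lines.append(
        "transitions "
        + " ".join(f"{k}={t[k]!r}" for k in ("mm", "mi", "md", "im", "ii", "dm", "dd"))
    )
    lines.append("alphabet " + AMINO_ACIDS)
    lines.append("background " + " ".join(repr(float(v)) for v in model.background))
    for row in model.match_emissions:
        lines.append("match " + " ".join(repr(float(v)) for v in row))
    return "\n".join(lines) + "\n"


def model_from_text(text: str) -> ProfileHMM:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if lines[0] != _FORMAT_TAG:
        raise ValidationError(f"unrecognized model format {lines[0]!r}")
    length = int(lines[1].split()[1])
    pseudocount = float(lines[2].split()[1])
    transitions = {
        k: float(v)
        for k, v in (item.split("=") for item in lines[3].split()[1:])
    }
    if lines[4].split()[1] != AMINO_ACIDS:
        raise ValidationError("unexpected alphabet order in model file")
    background = np.array([float(v) for v in lines[5].split()[1:]])
    emissions = np.array(
        [[float(v) for v in ln.split()[1:]] for ln in lines[6: 6 + length]]
    )
    return ProfileHMM(
        match_emissions=emissions,
        background=background,
        pseudocount=pseudocount,
        transitions=transitions,
    )


def save_model(model: ProfileHMM, path: str | Path) -> None:
    Path(path).write_text(model_to_text(model))


def load_model(path: str | Path) -> ProfileHMM:
    return model_from_text(Path(path).read_text())
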