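"""End-to-end training of the combined predictor and protein scanning.

Training pipeline: (optionally) reduce redundancy, partition the
positive windows into motif subgroups by MDD, sample negatives for each
subgroup at the configured ratio, train one profile HMM per subgroup,
and select one bit-score threshold per model.  The combined predictor
calls a lysine positive when *any* model's score strictly exceeds that
model's threshold (decision rule ``union-v1``); the best cluster for a
site is the model with the largest margin ``score - threshold``.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np

from . import phmm
from .evaluation import (
    MetricsReport,
    cross_validate_model,
    macro_average,
    sample_negatives,
)
from .fragment_io import FragmentSet, Protein, ValidationError, extract_fragments
from .mdd import (
    DEFAULT_CHI2_CRITICAL,
    DEFAULT_MIN_CLUSTER_SIZE,
    MDDResult,
    ResidueGrouping,
    mdd_partition,
)
from .redundancy import purge_cross_duplicates, reduce_redundancy

DECISION_RULE = "union-v1"


@dataclass(frozen=True)
class TrainConfig:
    """All knobs of the training pipeline, recorded with the model."""

    n: int = 6
    identity: float = 0.40
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE
    chi2_critical: float = DEFAULT_CHI2_CRITICAL
    ratio: float = 2.08
    pseudocount: float = 1.0
    objective: str = "accuracy"
    seed: int = 0
    reduce_inputs: bool = False


@dataclass
class CombinedPredictor:
    """Ordered per-cluster thresholded models plus the decision rule."""

    models: list
    config: TrainConfig
    rule: str = DECISION_RULE
    cluster_sizes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.models:
            raise ValidationError("a combined predictor needs at least one model")
        lengths = {tm.model.length for tm in self.models}
        if len(lengths) != 1:
            raise ValidationError("all models must share one window length")

    @property
    def window_length(self) -> int:
        return self.models[0].model.length


@dataclass(frozen=True)
class ScoredSite:
    """Per-lysine scan result: scores against every model, one decision."""

    protein_id: str
    position: int
    best_score: float
    best_cluster: int
    scores: tuple
    prediction: bool


def _cluster_seeds(seed: int, count: int) -> list[int]:
    """Per-cluster sampling seeds derived deterministically from one seed."""
    state = np.random.SeedSequence(seed).generate_state(count, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def train_combined(
    positives: FragmentSet,
    negatives: FragmentSet,
    config: TrainConfig = TrainConfig(),
    grouping: ResidueGrouping | None = None,
) -> CombinedPredictor:
    """Train the combined MDD-clustered HMM predictor.

    Deterministic for a given input order, configuration, and seed.  The
    null (background) model is the pooled flank composition of the full
    positive training set and is shared by all cluster models.
    """
    if config.reduce_inputs:
        positives = reduce_redundancy(positives, config.identity)
        negatives = reduce_redundancy(negatives, config.identity)
        negatives = purge_cross_duplicates(negatives, positives)
    if positives.n_negative or negatives.n_positive:
        raise ValidationError("positives/negatives sets carry mislabeled fragments")
    result: MDDResult = mdd_partition(
        positives,
        grouping=grouping,
        min_cluster_size=config.min_cluster_size,
        chi2_critical=config.chi2_critical,
    )
    background = phmm.smoothed_background(positives)
    seeds = _cluster_seeds(config.seed, len(result.clusters))
    models = []
    for cluster_id, cluster in enumerate(result.clusters):
        cluster_negatives = sample_negatives(
            negatives, len(cluster), ratio=config.ratio, seed=seeds[cluster_id]
        )
        model = phmm.build_profile_hmm(
            cluster, pseudocount=config.pseudocount, background=background
        )
        thresholded = phmm.select_threshold(
            model, cluster, cluster_negatives, objective=config.objective
        )
        models.append(
            phmm.ThresholdedModel(
                model=model,
                threshold=thresholded.threshold,
                objective=thresholded.objective,
                objective_value=thresholded.objective_value,
                cluster_id=cluster_id,
            )
        )
    return CombinedPredictor(
        models=models, config=config, cluster_sizes=[len(c) for c in result.clusters]
    )


def score_fragments(
    predictor: CombinedPredictor, fragments: FragmentSet
) -> np.ndarray:
    """(n_fragments, n_models) matrix of bit scores."""
    return np.column_stack(
        [phmm.bit_scores(tm.model, fragments) for tm in predictor.models]
    )


def predict_fragments(
    predictor: CombinedPredictor, fragments: FragmentSet
) -> np.ndarray:
    """Boolean decision per fragment under the union rule."""
    scores = score_fragments(predictor, fragments)
    thresholds = np.array([tm.threshold for tm in predictor.models])
    return (scores > thresholds).any(axis=1)


def predict_sites(
    predictor: CombinedPredictor, protein: Protein
) -> list[ScoredSite]:
    """Scan a protein: one :class:`ScoredSite` per lysine.

    A site is predicted positive iff some model's bit score strictly
    exceeds that model's threshold.
    """
    fragments = extract_fragments(protein, n=predictor.config.n)
    if len(fragments) == 0:
        return []
    scores = score_fragments(predictor, fragments)
    thresholds = np.array([tm.threshold for tm in predictor.models])
    margins = scores - thresholds
    sites = []
    for row, frag in enumerate(fragments):
        best = int(np.argmax(margins[row]))
        sites.append(
            ScoredSite(
                protein_id=protein.id,
                position=frag.site_position,
                best_score=float(scores[row, best]),
                best_cluster=best,
                scores=tuple(float(s) for s in scores[row]),
                prediction=bool((margins[row] > 0).any()),
            )
        )
    return sites


def site_precision(predicted: Iterable[int], validated: Iterable[int]) -> float:
    """Percentage of predicted site positions that are validated."""
    predicted = set(predicted)
    validated = set(validated)
    if not predicted:
        raise ValidationError("no predicted sites; precision is undefined")
    return 100.0 * len(predicted & validated) / len(predicted)


def cross_validate_combined(
    positives: FragmentSet,
    negatives: FragmentSet,
    config: TrainConfig = TrainConfig(),
    k: int = 5,
    grouping: ResidueGrouping | None = None,
) -> tuple[list, MetricsReport]:
    """Per-cluster cross-validation of the MDD-clustered predictor.

    MDD partitions the positives once; each cluster is then evaluated by
    stratified k-fold cross-validation against its own sampled negatives
    and the per-cluster reports are macro-averaged — the evaluation
    protocol behind the per-subgroup performance tables.
    """
    result = mdd_partition(
        positives,
        grouping=grouping,
        min_cluster_size=config.min_cluster_size,
        chi2_critical=config.chi2_critical,
    )
    background = phmm.smoothed_background(positives)
    seeds = _cluster_seeds(config.seed, len(result.clusters))
    reports = []
    for cluster_id, cluster in enumerate(result.clusters):
        cluster_negatives = sample_negatives(
            negatives, len(cluster), ratio=config.ratio, seed=seeds[cluster_id]
        )
        reports.append(
            cross_validate_model(
                cluster,
                cluster_negatives,
                k=k,
                seed=seeds[cluster_id],
                pseudocount=config.pseudocount,
                background=background,
                objective=config.objective,
            )
        )
    return reports, macro_average(reports)


def cross_validate_single(
    positives: FragmentSet,
    negatives: FragmentSet,
    config: TrainConfig = TrainConfig(),
    k: int = 5,
) -> MetricsReport:
    """Cross-validation of one un-clustered HMM on the full training set."""
    background = phmm.smoothed_background(positives)
    seed = _cluster_seeds(config.seed, 1)[0]
    sampled = sample_negatives(
        negatives, len(positives), ratio=config.ratio, seed=seed
    )
    return cross_validate_model(
        positives,
        sampled,
        k=k,
        seed=seed,
        pseudocount=config.pseudocount,
        background=background,
        objective=config.objective,
    )


# ---------------------------------------------------------------------------
# serialization: one plain-text file holding config + all models
# ---------------------------------------------------------------------------

_FORMAT_TAG = "ubimdd-predictor v1"


def predictor_to_text(predictor: CombinedPredictor) -> str:
    lines = [_FORMAT_TAG, f"rule {predictor.rule}"]
    for key, value in asdict(predictor.config).items():
        lines.append(f"config {key}={value!r}")
    lines.append(
        "cluster_sizes " + " ".join(str(s) for s in predictor.cluster_sizes)
    )
    for tm in predictor.models:
        lines.append(
            f"model cluster={tm.cluster_id} threshold={tm.threshold!r} "
            f"objective={tm.objective} objective_value={tm.objective_value!r}"
        )
        lines.append(phmm.model_to_text(tm.model).rstrip("\n"))
        lines.append("end_model")
    return "\n".join(lines) + "\n"


def predictor_from_text(text: str) -> CombinedPredictor:
    lines = text.splitlines()
    if lines[0] != _FORMAT_TAG:
        raise ValidationError(f"unrecognized predictor format {lines[0]!r}")
    rule = lines[1].split(" ", 1)[1]
    config_kwargs: dict = {}
    cluster_sizes: list[int] = []
    models = []
    idx = 2
    while idx < len(lines):
        line = lines[idx]
        if line.startswith("config "):
            key, value = line[len("config "):].split("=", 1)
            config_kwargs[key] = ast.literal_eval(value)
            idx += 1
        elif line.startswith("cluster_sizes"):
            cluster_sizes = [int(v) for v in line.split()[1:]]
            idx += 1
        elif line.startswith("model "):
            attrs = dict(item.split("=", 1) for item in line.split()[1:])
            block = []
            idx += 1
            while lines[idx] != "end_model":
                block.append(lines[idx])
                idx += 1
            idx += 1
            models.append(
                phmm.ThresholdedModel(
                    model=phmm.model_from_text("\n".join(block)),
                    threshold=float(attrs["threshold"]),
                    objective=attrs["objective"],
                    objective_value=float(attrs["objective_value"]),
                    cluster_id=int(attrs["cluster"]),
                )
            )
        else:
            idx += 1
    return CombinedPredictor(
        models=models,
        config=TrainConfig(**config_kwargs),
        rule=rule,
        cluster_sizes=cluster_sizes,
    )


def save_predictor(predictor: CombinedPredictor, path: str | Path) -> None:
    Path(path).write_text(predictor_to_text(predictor))


def load_predictor(path: str | Path) -> CombinedPredictor:
    return predictor_from_text(Path(path).read_text())
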