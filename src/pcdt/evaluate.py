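"""ROC / ROC50 scoring and benchmark orchestration over family splits.

ROC is the normalized area under the full true-positive vs false-positive
curve (trapezoidal, ties averaged).  ROC50 truncates the curve at the 50th
false positive and normalizes by P * min(50, N) so perfect early retrieval
scores 1 and a ranking with no positive before the cutoff scores 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.metrics import roc_curve

from .aaindex import NormalizedIndexSet
from .classify import (
    KernelSpec,
    TrainedModel,
    TrainingError,
    decision_scores,
    select_kernel,
    train_family,
)
from .io import read_fasta, write_fasta
from .pdt import PDTParams, ProteinSequence, feature_annotations, transform_batch

logger = logging.getLogger(__name__)

__all__ = [
    "BenchmarkSplit",
    "EvalResult",
    "BenchmarkSummary",
    "PipelineConfig",
    "UndefinedScoreError",
    "roc_score",
    "roc50_score",
    "run_benchmark",
    "chop_experiment",
    "chop_sequence",
    "load_benchmark_dir",
    "write_benchmark_dir",
    "write_results_tsv",
]

_SPLIT_FILES = ("train_pos", "train_neg", "test_pos", "test_neg")


class UndefinedScoreError(ValueError):
    """Raised when a score list contains only one class."""


def _check_two_classes(labels: np.ndarray) -> tuple[int, int]:
    P = int(np.sum(labels > 0))
    N = int(np.sum(labels <= 0))
    if P == 0 or N == 0:
        raise UndefinedScoreError(
            f"ROC undefined: {P} positives and {N} negatives"
        )
    return P, N


def roc_score(scores: Sequence[float], labels: Sequence[float]) -> float:
    """Normalized area under the full ROC curve (ties averaged)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    _check_two_classes(labels)
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels > 0, scores))


def roc50_score(
    scores: Sequence[float], labels: Sequence[float], max_fp: int = 50
) -> float:
    """ROC area truncated at the ``max_fp``-th false positive.

    Normalized by P * min(max_fp, N); with N <= max_fp this equals the full
    ROC score.  Ties trace diagonal curve segments, matching the averaged
    trapezoid of :func:`roc_score`.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    P, N = _check_two_classes(labels)
    cap = min(max_fp, N)
    fpr, tpr, _ = roc_curve(labels > 0, scores, drop_intermediate=False)
    fp = fpr * N
    tp = tpr * P
    tp_cap = float(np.interp(cap, fp, tp))
    mask = fp <= cap
    xs = np.append(fp[mask], cap)
    ys = np.append(tp[mask], tp_cap)
    area = float(np.trapezoid(ys, xs))
    return area / (P * cap)


@dataclass
class BenchmarkSplit:
    """One family's train/test positive/negative sequence sets."""

    family_id: str
    train_pos: list[ProteinSequence]
    train_neg: list[ProteinSequence]
    test_pos: list[ProteinSequence]
    test_neg: list[ProteinSequence]

    def __post_init__(self) -> None:
        train_ids = {s.id for s in self.train_pos} | {s.id for s in self.train_neg}
        test_ids = {s.id for s in self.test_pos} | {s.id for s in self.test_neg}
        overlap = train_ids & test_ids
        if overlap:
            raise ValueError(
                f"family {self.family_id!r}: ids in both train and test: "
                f"{sorted(overlap)[:5]}"
            )


@dataclass
class EvalResult:
    """Per-family scores plus the ranked decision table (id, score, label)."""

    family_id: str
    roc: float
    roc50: float
    table: list[tuple[str, float, int]] = field(default_factory=list)
    kernel_kind: str = ""


@dataclass
class BenchmarkSummary:
    results: list[EvalResult]
    mean_roc: float
    mean_roc50: float
    failed_families: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end benchmark configuration (transform + SVM + scoring)."""

    params: PDTParams = PDTParams()
    kernels: tuple[KernelSpec, ...] = (KernelSpec(kind="quadratic"),)
    folds: int = 5
    seed: int = 0
    C: float = 10.0
    strict: bool = True


def _fit_family(
    split: BenchmarkSplit, indices: NormalizedIndexSet, config: PipelineConfig
) -> TrainedModel:
    params = config.params
    pos = transform_batch(split.train_pos, indices, params, strict=config.strict)
    neg = transform_batch(split.train_neg, indices, params, strict=config.strict)
    kernel = (
        config.kernels[0]
        if len(config.kernels) == 1
        else select_kernel(
            pos.values, neg.values, config.kernels,
            folds=config.folds, seed=config.seed, C=config.C,
        )
    )
    return train_family(
        pos.values, neg.values, kernel=kernel, seed=config.seed, C=config.C,
        family_id=split.family_id,
        annotations=feature_annotations(indices, params),
    )


def _score_family(
    model: TrainedModel,
    split: BenchmarkSplit,
    indices: NormalizedIndexSet,
    config: PipelineConfig,
    test_pos: Sequence[ProteinSequence] | None = None,
    test_neg: Sequence[ProteinSequence] | None = None,
) -> EvalResult:
    params = config.params
    tp = transform_batch(test_pos if test_pos is not None else split.test_pos,
                         indices, params, strict=config.strict)
    tn = transform_batch(test_neg if test_neg is not None else split.test_neg,
                         indices, params, strict=config.strict)
    scores = decision_scores(model, np.vstack([tp.values, tn.values]))
    labels = np.concatenate([np.ones(len(tp.ids)), -np.ones(len(tn.ids))])
    ids = tp.ids + tn.ids
    order = np.argsort(-scores, kind="stable")
    table = [(ids[i], float(scores[i]), int(labels[i])) for i in order]
    return EvalResult(
        family_id=split.family_id,
        roc=roc_score(scores, labels),
        roc50=roc50_score(scores, labels),
        table=table,
        kernel_kind=model.kernel.kind,
    )


def run_benchmark(
    splits: Sequence[BenchmarkSplit],
    indices: NormalizedIndexSet,
    config: PipelineConfig | None = None,
    model_sink: Callable[[TrainedModel], None] | None = None,
) -> BenchmarkSummary:
    """Train and score every family; summary means are unweighted.

    Families that fail training are recorded, excluded from the means and
    warned about.  Deterministic for a fixed config/seed.
    """
    if config is None:
        config = PipelineConfig()
    results: list[EvalResult] = []
    failed: list[str] = []
    for split in splits:
        try:
            model = _fit_family(split, indices, config)
        except TrainingError as exc:
            logger.warning("run_benchmark: family %s failed: %s", split.family_id, exc)
            failed.append(split.family_id)
            continue
        if model_sink is not None:
            model_sink(model)
        results.append(_score_family(model, split, indices, config))
    mean_roc = float(np.mean([r.roc for r in results])) if results else float("nan")
    mean_roc50 = float(np.mean([r.roc50 for r in results])) if results else float("nan")
    return BenchmarkSummary(
        results=results, mean_roc=mean_roc, mean_roc50=mean_roc50,
        failed_families=failed,
    )


def chop_sequence(
    seq: ProteinSequence, k: int, rng: np.random.Generator, window: int = 20
) -> ProteinSequence:
    """Delete k residues chosen uniformly at random from the first ``window``
    positions of the chain."""
    if k == 0:
        return seq
    w = min(window, len(seq))
    if k > w:
        raise ValueError(f"cannot chop {k} residues from a window of {w}")
    drop = set(rng.choice(w, size=k, replace=False).tolist())
    residues = "".join(c for i, c in enumerate(seq.residues) if i not in drop)
    return ProteinSequence(id=seq.id, residues=residues)


def chop_experiment(
    splits: Sequence[BenchmarkSplit],
    k_values: Iterable[int],
    indices: NormalizedIndexSet,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> list[tuple[int, float]]:
    """Mean benchmark ROC as a function of the number of N-terminal residues
    randomly chopped from each test sequence.

    Models are trained once on unmodified training data; only the test
    sequences are chopped (seeded).
    """
    if config is None:
        config = PipelineConfig()
    models = [(split, _fit_family(split, indices, config)) for split in splits]
    rows: list[tuple[int, float]] = []
    for k in k_values:
        rng = np.random.default_rng(seed + k)
        rocs = []
        for split, model in models:
            test_pos = [chop_sequence(s, k, rng) for s in split.test_pos]
            test_neg = [chop_sequence(s, k, rng) for s in split.test_neg]
            result = _score_family(
                model, split, indices, config, test_pos=test_pos, test_neg=test_neg
            )
            rocs.append(result.roc)
        rows.append((k, float(np.mean(rocs))))
    return rows


def load_benchmark_dir(path: str | Path) -> list[BenchmarkSplit]:
    """Read one subdirectory per family holding train/test pos/neg FASTA files."""
    root = Path(path)
    splits: list[BenchmarkSplit] = []
    for famdir in sorted(p for p in root.iterdir() if p.is_dir()):
        sets = {}
        for name in _SPLIT_FILES:
            fasta = famdir / f"{name}.fasta"
            if not fasta.exists():
                raise FileNotFoundError(f"missing {fasta}")
            sets[name] = read_fasta(fasta)
        splits.append(BenchmarkSplit(family_id=famdir.name, **sets))
    if not splits:
        raise FileNotFoundError(f"no family subdirectories under {root}")
    return splits


def write_benchmark_dir(splits: Iterable[BenchmarkSplit], path: str | Path) -> None:
    root = Path(path)
    for split in splits:
        famdir = root / split.family_id
        famdir.mkdir(parents=True, exist_ok=True)
        for name in _SPLIT_FILES:
            write_fasta(getattr(split, name), famdir / f"{name}.fasta")


def write_results_tsv(
    summary: BenchmarkSummary, path: str | Path, header: dict | None = None
) -> None:
    with open(path, "w") as out:
        for key, val in (header or {}).items():
            out.write(f"# {key}={val}\n")
        out.write("family\tkernel\troc\troc50\n")
        for r in summary.results:
            out.write(f"{r.family_id}\t{r.kernel_kind}\t{r.roc:.6f}\t{r.roc50:.6f}\n")
        out.write(f"MEAN\t-\t{summary.mean_roc:.6f}\t{summary.mean_roc50:.6f}\n")
        for fam in summary.failed_families:
            out.write(f"# failed={fam}\n")
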