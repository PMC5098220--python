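"""End-to-end workflows.

Dataset assembly (negative-class sampling from the physical-PPI universe),
leakage-free k-fold cross-validation, independent testing against held-out
interaction sets, and interactome-wide prediction.

Conventions shared by every workflow:

* pairs are unordered — duplicates and training/test overlaps are resolved
  on the canonical (sorted) accession pair;
* the *others* class is sampled uniformly without replacement from the
  physical-PPI universe minus the labelled training pairs, at a size
  proportional to the activation class (1:1 by default, to limit bias
  toward the dominant class);
* inside cross-validation the GO vocabulary and the label codec are rebuilt
  from the training folds only, and a pair's target and homolog instances
  always travel in the same fold;
* all randomness (sampling, fold assignment) is driven by explicit seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .annotations import AnnotationStore, HomologMap
from .features import (
    ACTIVATION,
    OTHERS,
    FeatureVocabulary,
    Pair,
    build_vocabulary,
    make_instances,
)
from .metrics import LabelMatrix, MultiLabelReport, empty_report, per_class_report
from .multilabel import (
    PredictionRecord,
    TrainedModel,
    fit_codec,
    pool_instances,
    predict_pair,
    train,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pair / edge list I/O

def read_pairs_tsv(path) -> list[Pair]:
    """Read labelled pairs (``protein_a  protein_b  labels``).

    ``labels`` is a comma-separated label list. Duplicate unordered pairs
    are merged by label union (this is exactly how a pair annotated with
    both activation and inhibition becomes multi-label) with a logged count.
    """
    merged: dict[tuple[str, str], set[str]] = {}
    order: list[tuple[str, str]] = []
    n_rows = n_dup = 0
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["protein_a", "protein_b"]:
            raise ValueError(
                f"{path}: expected header 'protein_a<TAB>protein_b<TAB>labels'"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            a, b, labels_field = parts[0], parts[1], parts[2]
            labels = {s for s in labels_field.split(",") if s}
            if not labels:
                raise ValueError(f"{path}:{lineno}: empty label field")
            n_rows += 1
            key = (a, b) if a <= b else (b, a)
            if key in merged:
                n_dup += 1
                merged[key] |= labels
            else:
                merged[key] = labels
                order.append(key)
    if n_dup:
        logger.info("%s: merged %d duplicate pair rows (label union)", path, n_dup)
    return [Pair.make(a, b, merged[(a, b)]) for a, b in order]


def write_pairs_tsv(pairs: Sequence[Pair], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\tlabels\n")
        for p in pairs:
            fh.write(f"{p.a}\t{p.b}\t{','.join(sorted(p.labels))}\n")


def read_edges_tsv(path) -> list[tuple[str, str]]:
    """Read an unlabelled edge list (``protein_a  protein_b``), canonical
    order, duplicates dropped (first occurrence kept)."""
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["protein_a", "protein_b"]:
            raise ValueError(f"{path}: expected header 'protein_a<TAB>protein_b'")
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            a, b = line.split("\t")[:2]
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            edges.append(key)
    if n_dup:
        logger.info("%s: dropped %d duplicate edges", path, n_dup)
    return edges


def write_edges_tsv(edges: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# dataset assembly

@dataclass
class DatasetSpec:
    """Inputs for assembling a training dataset with sampled negatives."""

    train_pairs: list[Pair]
    ppi_universe: list[tuple[str, str]]
    others_ratio: float = 1.0
    seed: int = 0


def sample_others(spec: DatasetSpec) -> list[Pair]:
    """Sample the *others* class from the PPI universe.

    Uniform without replacement from the universe minus the labelled
    training pairs (unordered-pair identity), ``round(others_ratio × #
    activation pairs)`` edges, labelled ``{others}``. Deterministic for a
    fixed seed and input set.
    """
    train_ids = {p.id for p in spec.train_pairs}
    n_act = sum(1 for p in spec.train_pairs if ACTIVATION in p.labels)
    n_wanted = round(spec.others_ratio * n_act)
    candidates = sorted(
        {(a, b) if a <= b else (b, a) for a, b in spec.ppi_universe} - train_ids
    )
    if n_wanted > len(candidates):
        raise ValueError(
            f"cannot sample {n_wanted} 'others' pairs: only {len(candidates)} "
            f"universe edges remain after excluding {len(train_ids)} training pairs"
        )
    rng = np.random.default_rng(spec.seed)
    idx = rng.choice(len(candidates), size=n_wanted, replace=False)
    sampled = [candidates[i] for i in sorted(idx)]
    logger.info(
        "sampled %d 'others' pairs from %d candidates (universe %d, "
        "excluded %d training pairs)",
        n_wanted, len(candidates), len(spec.ppi_universe), len(train_ids),
    )
    return [Pair.make(a, b, {OTHERS}) for a, b in sampled]


def assemble_dataset(spec: DatasetSpec) -> list[Pair]:
    """Training pairs plus the sampled *others* class."""
    return list(spec.train_pairs) + sample_others(spec)


def _report_or_empty(label_order, true_sets, pred_sets) -> MultiLabelReport:
    if not true_sets:
        return empty_report(label_order)
    return per_class_report(
        LabelMatrix.from_label_sets(label_order, true_sets, pred_sets)
    )


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CVPlan:
    """Seeded fold assignment: ``assignment[i]`` is the fold of pair *i*.

    Folds partition the pairs with sizes differing by at most one; a pair's
    target and homolog instances share its fold by construction.
    """

    k: int
    seed: int
    assignment: np.ndarray

    @classmethod
    def make(cls, n_pairs: int, k: int, seed: int) -> "CVPlan":
        if k < 2:
            raise ValueError(f"k must be >= 2, got {k}")
        if k > n_pairs:
            raise ValueError(f"k={k} folds but only {n_pairs} pairs")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n_pairs)
        assignment = np.empty(n_pairs, dtype=int)
        for f, chunk in enumerate(np.array_split(perm, k)):
            assignment[chunk] = f
        return cls(k=k, seed=seed, assignment=assignment)


@dataclass
class CVResult:
    """Pooled-over-folds evaluation, reported separately per instance kind."""

    target: MultiLabelReport
    homolog: MultiLabelReport
    plan: CVPlan
    n_skipped_folds: int
    fold_vocabularies: list[tuple[str, ...]] = field(default_factory=list)
    null_counts: dict[str, int] = field(default_factory=dict)


def cross_validate(
    pairs: Sequence[Pair],
    store: AnnotationStore,
    hmap: HomologMap,
    k: int = 10,
    C: float = 1.0,
    seed: int = 0,
    max_hits: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> CVResult:
    """k-fold cross-validation with per-fold feature construction.

    For each fold the vocabulary and codec are rebuilt from the training
    folds only (no test-fold information leaks into the feature space), the
    model is trained on the pooled non-null target+homolog instances, and
    the held-out pairs' target and homolog instances are scored separately.
    Predictions are pooled across folds into one report per instance kind.
    A fold whose training split holds a single combined class is skipped
    with a warning.
    """
    pairs = list(pairs)
    plan = CVPlan.make(len(pairs), k, seed)
    label_order = tuple(sorted({lab for p in pairs for lab in p.labels}))
    t_true, t_pred = [], []
    h_true, h_pred = [], []
    n_skipped = 0
    fold_vocabs: list[tuple[str, ...]] = []
    null_totals = {"null_target": 0, "null_homolog": 0, "null_both": 0}
    for f in range(k):
        train_pairs = [p for i, p in enumerate(pairs) if plan.assignment[i] != f]
        test_pairs = [p for i, p in enumerate(pairs) if plan.assignment[i] == f]
        codec = fit_codec([p.labels for p in train_pairs])
        if codec.n_classes < 2:
            logger.warning("fold %d: single combined class in training, skipped", f)
            n_skipped += 1
            fold_vocabs.append(())
            continue
        vocab = build_vocabulary(train_pairs, store, hmap, max_hits=max_hits)
        fold_vocabs.append(vocab.terms)
        train_insts, _ = make_instances(train_pairs, store, hmap, vocab, max_hits)
        X, y = pool_instances(train_insts, codec)
        model = train(
            X, y, C=C, tol=tol, max_iter=max_iter, codec=codec, vocab=vocab
        )
        test_insts, counts = make_instances(test_pairs, store, hmap, vocab, max_hits)
        for key in null_totals:
            null_totals[key] += counts[key]
        for inst in test_insts:
            rec = predict_pair(model, inst) if (
                inst.target_vec is not None or inst.homolog_vec is not None
            ) else None
            if rec is None:
                continue
            if rec.target_labels is not None:
                t_true.append(inst.labels)
                t_pred.append(rec.target_labels)
            if rec.homolog_labels is not None:
                h_true.append(inst.labels)
                h_pred.append(rec.homolog_labels)
    if not t_true and not h_true:
        raise ValueError("cross-validation produced no predictions")
    target_report = _report_or_empty(label_order, t_true, t_pred)
    homolog_report = _report_or_empty(label_order, h_true, h_pred)
    return CVResult(
        target=target_report,
        homolog=homolog_report,
        plan=plan,
        n_skipped_folds=n_skipped,
        fold_vocabularies=fold_vocabs,
        null_counts=null_totals,
    )


def permute_labels(pairs: Sequence[Pair], seed: int) -> list[Pair]:
    """Shuffle the label sets across pairs (a chance-level baseline)."""
    rng = np.random.default_rng(seed)
    labels = [p.labels for p in pairs]
    perm = rng.permutation(len(labels))
    return [
        Pair(p.a, p.b, labels[perm[i]]) for i, p in enumerate(pairs)
    ]


# ---------------------------------------------------------------------------
# full-data training, independent test, interactome prediction

def train_full(
    pairs: Sequence[Pair],
    store: AnnotationStore,
    hmap: HomologMap,
    C: float = 1.0,
    max_hits: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> TrainedModel:
    """Fit codec, vocabulary and model on a full labelled dataset."""
    codec = fit_codec([p.labels for p in pairs])
    vocab = build_vocabulary(pairs, store, hmap, max_hits=max_hits)
    insts, _ = make_instances(pairs, store, hmap, vocab, max_hits)
    X, y = pool_instances(insts, codec)
    return train(X, y, C=C, tol=tol, max_iter=max_iter, codec=codec, vocab=vocab)


@dataclass
class TestResult:
    target: MultiLabelReport
    homolog: MultiLabelReport
    records: list[PredictionRecord]
    n_overlap_removed: int

    def correct_pairs(self) -> list[PredictionRecord]:
        """Records whose fused label set equals the true set exactly."""
        return [r for r in self.records if r.fused_labels == r.pair.labels]


def independent_test(
    model: TrainedModel,
    test_pairs: Sequence[Pair],
    store: AnnotationStore,
    hmap: HomologMap,
    train_pairs: Sequence[Pair] | None = None,
    max_hits: int | None = None,
) -> TestResult:
    """Evaluate a trained model on an independent labelled set.

    Pairs that already occur in *train_pairs* are removed first (unordered
    identity, logged); evaluation is restricted to the labels present in
    the test set; a pair with a null target instance is counted only in the
    homolog report (and vice versa).
    """
    test_pairs = list(test_pairs)
    n_removed = 0
    if train_pairs is not None:
        train_ids = {p.id for p in train_pairs}
        kept = [p for p in test_pairs if p.id not in train_ids]
        n_removed = len(test_pairs) - len(kept)
        if n_removed:
            logger.info("removed %d test pairs overlapping the training set", n_removed)
        test_pairs = kept
    if not test_pairs:
        raise ValueError(
            "no test pairs remain after overlap removal "
            f"({n_removed} removed)"
        )
    label_order = tuple(sorted({lab for p in test_pairs for lab in p.labels}))
    insts, _ = make_instances(test_pairs, store, hmap, model.vocab, max_hits)
    records = []
    t_true, t_pred, h_true, h_pred = [], [], [], []
    for inst in insts:
        rec = predict_pair(model, inst)
        records.append(rec)
        if rec.target_labels is not None:
            t_true.append(inst.labels)
            t_pred.append(rec.target_labels)
        if rec.homolog_labels is not None:
            h_true.append(inst.labels)
            h_pred.append(rec.homolog_labels)
    target_report = _report_or_empty(label_order, t_true, t_pred)
    homolog_report = _report_or_empty(label_order, h_true, h_pred)
    return TestResult(
        target=target_report,
        homolog=homolog_report,
        records=records,
        n_overlap_removed=n_removed,
    )


@dataclass
class InteractomeSummary:
    n_edges: int
    n_signed: int          # fused label set contains activation and/or inhibition
    n_activation: int
    n_inhibition: int
    n_others: int
    n_unpredictable: int
    records: list[PredictionRecord]


def _fmt_labels(labels: Optional[frozenset[str]]) -> str:
    return "ABSTAIN" if labels is None else ",".join(sorted(labels))


def _fmt_decision(v: Optional[float]) -> str:
    return "NA" if v is None else f"{v:.6g}"


def predict_interactome(
    model: TrainedModel,
    edge_list: Sequence[tuple[str, str]],
    store: AnnotationStore,
    hmap: HomologMap,
    out_path=None,
    max_hits: int | None = None,
) -> InteractomeSummary:
    """Predict activation/inhibition over an unlabelled edge list.

    Writes (when *out_path* is given) one TSV row per input edge — target,
    homolog and fused label sets, maximum decision values, and flags — and
    returns summary counts. Every input edge appears exactly once in the
    output; edges with both instances null are flagged unpredictable
    rather than dropped.
    """
    pairs = [Pair.make(a, b) for a, b in edge_list]
    insts, _ = make_instances(pairs, store, hmap, model.vocab, max_hits)
    records = []
    n_signed = n_act = n_inh = n_unpred = 0
    out_fh = open(out_path, "w", encoding="utf-8") if out_path else None
    try:
        if out_fh:
            out_fh.write(
                "protein_a\tprotein_b\ttarget_labels\thomolog_labels\t"
                "fused_labels\ttarget_max_decision\thomolog_max_decision\tflags\n"
            )
        for inst in insts:
            rec = predict_pair(model, inst)
            records.append(rec)
            flags = []
            if rec.unpredictable:
                flags.append("unpredictable")
                n_unpred += 1
            else:
                if rec.target_labels is None:
                    flags.append("target_null")
                if rec.homolog_labels is None:
                    flags.append("homolog_null")
                has_act = "activation" in rec.fused_labels
                has_inh = "inhibition" in rec.fused_labels
                if has_act:
                    n_act += 1
                if has_inh:
                    n_inh += 1
                if has_act or has_inh:
                    n_signed += 1
            if out_fh:
                out_fh.write(
                    f"{inst.pair.a}\t{inst.pair.b}\t"
                    f"{_fmt_labels(rec.target_labels)}\t"
                    f"{_fmt_labels(rec.homolog_labels)}\t"
                    f"{_fmt_labels(rec.fused_labels)}\t"
                    f"{_fmt_decision(rec.target_max_decision)}\t"
                    f"{_fmt_decision(rec.homolog_max_decision)}\t"
                    f"{';'.join(flags) or 'ok'}\n"
                )
    finally:
        if out_fh:
            out_fh.close()
    summary = InteractomeSummary(
        n_edges=len(records),
        n_signed=n_signed,
        n_activation=n_act,
        n_inhibition=n_inh,
        n_others=len(records) - n_signed - n_unpred,
        n_unpredictable=n_unpred,
        records=records,
    )
    logger.info(
        "interactome prediction: %d edges, %d signed (%d activation, "
        "%d inhibition), %d others, %d unpredictable",
        summary.n_edges, n_signed, n_act, n_inh, summary.n_others, n_unpred,
    )
    return summary
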