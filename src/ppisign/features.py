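"""GO-term feature encoding for protein pairs.

Each interacting pair is represented by two fixed-length vectors over the
training-set GO term universe ``U``: a *target* vector built from the two
proteins' own annotations and a *homolog* vector built from their homologs'
annotations. A vector component for term ``g`` is

* ``2`` if both proteins carry ``g`` (a shared term),
* ``1`` if exactly one protein carries ``g``,
* ``0`` if neither does.

If either protein's term set is empty the corresponding vector is null
(``None``) and the instance is excluded from training; at prediction time a
null target instance can still be covered by its homolog instance.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .annotations import AnnotationStore, HomologMap, homolog_term_set

logger = logging.getLogger(__name__)

ACTIVATION = "activation"
INHIBITION = "inhibition"
OTHERS = "others"
LABELS = (ACTIVATION, INHIBITION, OTHERS)


@dataclass(frozen=True)
class Pair:
    """An unordered protein pair with an optional label set.

    ``a`` and ``b`` are stored in canonical (lexicographic) order so that a
    pair compares and hashes the same whichever way round it was read.
    """

    a: str
    b: str
    labels: frozenset[str] = frozenset()

    @staticmethod
    def make(a: str, b: str, labels: Iterable[str] = ()) -> "Pair":
        lo, hi = (a, b) if a <= b else (b, a)
        return Pair(lo, hi, frozenset(labels))

    @property
    def id(self) -> tuple[str, str]:
        return (self.a, self.b)

    @property
    def proteins(self) -> tuple[str, str]:
        return (self.a, self.b)


@dataclass(frozen=True)
class FeatureVocabulary:
    """The ordered GO term universe ``U`` fixed by the training set."""

    terms: tuple[str, ...]
    index: dict[str, int] = field(compare=False, hash=False, repr=False, default=None)

    def __post_init__(self):
        object.__setattr__(
            self, "index", {t: i for i, t in enumerate(self.terms)}
        )

    @classmethod
    def from_terms(cls, terms: Iterable[str]) -> "FeatureVocabulary":
        return cls(terms=tuple(sorted(set(terms))))

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index

    def fingerprint(self) -> str:
        """SHA-256 over the ordered term list; guards model/vocab pairing."""
        return hashlib.sha256("\n".join(self.terms).encode()).hexdigest()

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for t in self.terms:
                fh.write(t + "\n")

    @classmethod
    def load(cls, path) -> "FeatureVocabulary":
        with open(path, encoding="utf-8") as fh:
            return cls(terms=tuple(line.strip() for line in fh if line.strip()))


@dataclass
class InstancePair:
    """The target and homolog feature vectors of one protein pair.

    Either vector is ``None`` (null) when at least one protein of the pair
    has an empty corresponding term set.
    """

    pair: Pair
    target_vec: Optional[np.ndarray]
    homolog_vec: Optional[np.ndarray]

    @property
    def labels(self) -> frozenset[str]:
        return self.pair.labels


def build_vocabulary(
    training_pairs: Sequence[Pair],
    store: AnnotationStore,
    hmap: HomologMap,
    max_hits: int | None = None,
) -> FeatureVocabulary:
    """Build ``U``: the union of target and homolog term sets over all
    proteins appearing in the training pairs, in sorted order.

    Terms seen only at prediction time are outside ``U`` and ignored there.
    Raises ``ValueError`` when the union is empty (no usable features).
    """
    if not training_pairs:
        raise ValueError("training_pairs is empty")
    proteins = {p for pair in training_pairs for p in pair.proteins}
    universe: set[str] = set()
    for p in proteins:
        universe |= store.terms(p)
        universe |= homolog_term_set(p, hmap, store, max_hits=max_hits)
    if not universe:
        raise ValueError(
            "empty GO term universe: no training protein has annotations "
            "or annotated homologs"
        )
    vocab = FeatureVocabulary.from_terms(universe)
    logger.info("vocabulary: %d GO terms from %d proteins", len(vocab), len(proteins))
    return vocab


def encode_pair(
    term_set_a: Iterable[str],
    term_set_b: Iterable[str],
    vocab: FeatureVocabulary,
) -> Optional[np.ndarray]:
    """Encode one pair of GO term sets over *vocab*.

    Returns a vector with entries in {0, 1, 2} (see module docstring), or
    ``None`` when either term set is empty — the null-vector rule.
    Out-of-vocabulary terms are dropped (the feature space is fixed by
    training).
    """
    set_a, set_b = set(term_set_a), set(term_set_b)
    if not set_a or not set_b:
        return None
    if len(vocab) == 0:
        raise ValueError("empty vocabulary")
    vec = np.zeros(len(vocab), dtype=np.int8)
    n_oov = 0
    for term in set_a | set_b:
        idx = vocab.index.get(term)
        if idx is None:
            n_oov += 1
            continue
        vec[idx] = 1
    for term in set_a & set_b:
        idx = vocab.index.get(term)
        if idx is not None:
            vec[idx] = 2
    if n_oov:
        logger.debug("encode_pair: %d out-of-vocabulary terms dropped", n_oov)
    return vec


def make_instances(
    pairs: Sequence[Pair],
    store: AnnotationStore,
    hmap: HomologMap,
    vocab: FeatureVocabulary,
    max_hits: int | None = None,
) -> tuple[list[InstancePair], dict[str, int]]:
    """Encode every pair as a target instance and a homolog instance.

    Returns the instances plus counts of pairs whose target, homolog, or
    both vectors are null.
    """
    instances: list[InstancePair] = []
    counts = {"null_target": 0, "null_homolog": 0, "null_both": 0}
    for pair in pairs:
        tv = encode_pair(store.terms(pair.a), store.terms(pair.b), vocab)
        hv = encode_pair(
            homolog_term_set(pair.a, hmap, store, max_hits=max_hits),
            homolog_term_set(pair.b, hmap, store, max_hits=max_hits),
            vocab,
        )
        if tv is None:
            counts["null_target"] += 1
        if hv is None:
            counts["null_homolog"] += 1
        if tv is None and hv is None:
            counts["null_both"] += 1
        instances.append(InstancePair(pair=pair, target_vec=tv, homolog_vec=hv))
    logger.info(
        "encoded %d pairs: %d null target, %d null homolog, %d both null",
        len(pairs), counts["null_target"], counts["null_homolog"], counts["null_both"],
    )
    return instances, counts
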