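"""Self-contained synthetic worlds for the full prediction pipeline.

A world bundles everything the method consumes — a GO vocabulary, sparse
protein annotations, noisy homologs, labelled interactions and an
unlabelled PPI universe — with the statistical structure the method
assumes: class membership of an interacting pair is driven by *planted
class-discriminative GO terms* that the two partners share, GO sparsity is
emulated by annotation dropout (a dropped-out protein has an empty target
term set but still has annotated homologs, exercising the null-vector /
homolog-substitute path), and homolog term sets are noisy copies of the
query's true biology (evolutionary divergence noise).

Generation is a pure function of the configuration (including its seed),
so worlds are exactly reproducible. `world_to_files` serializes a world in
the same file dialects the readers consume; a read-back round-trip
reproduces the in-memory world.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .annotations import AnnotationStore, HomologMap
from .features import ACTIVATION, INHIBITION, LABELS, OTHERS, Pair

logger = logging.getLogger(__name__)


@dataclass
class WorldConfig:
    """Knobs of the synthetic world.

    Defaults describe a moderately sparse, moderately noisy world: a few
    thousand proteins annotated with ~6 of 600 GO terms, 10% of proteins
    unannotated, three homologs per protein whose term sets diverge from
    the query's by 20%, and a 3:1 activation:inhibition imbalance. The
    protein count is deliberately large relative to the pair count so that
    most proteins enter few labelled pairs — as in real curated interaction
    sets — because a protein recurring across many pairs of different
    classes carries every class's signal terms and blurs the planted
    structure.
    """

    n_proteins: int = 2500
    n_terms: int = 600
    terms_per_protein: float = 6.0       # mean annotations per annotated protein
    annotation_dropout: float = 0.1      # P(protein has no GO annotation)
    n_homologs_per_protein: int = 3
    homolog_term_noise: float = 0.2      # P(homolog term replaced by a random one)
    n_activation: int = 300
    n_inhibition: int = 100
    n_others: int = 300
    p_dual: float = 0.05                 # P(activation pair is also inhibition)
    signal_terms_per_class: int = 8      # planted discriminative terms per class
    signal_strength: float = 0.9         # P(pair of class c shares a class-c term)
    n_universe_extra: int = 800          # unlabelled universe edges beyond training
    universe_signed_fraction: float = 0.2  # P(extra edge carries a planted sign)
    e_cutoff: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "annotation_dropout", "homolog_term_noise", "p_dual",
            "signal_strength", "universe_signed_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_proteins", "n_terms", "n_homologs_per_protein",
            "n_activation", "n_inhibition", "n_others", "n_universe_extra",
            "signal_terms_per_class",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if 2 * self.signal_terms_per_class > self.n_terms:
            raise ValueError(
                f"2 x {self.signal_terms_per_class} signal terms exceed the "
                f"{self.n_terms}-term vocabulary"
            )
        if self.terms_per_protein < 1:
            raise ValueError("terms_per_protein must be >= 1")


@dataclass
class World:
    """A generated world plus the ground truth of every planted fact."""

    config: WorldConfig
    store: AnnotationStore
    hmap: HomologMap
    pairs: list[Pair]
    universe: list[tuple[str, str]]
    ground_truth: dict = field(default_factory=dict)


def _draw_true_terms(rng, background, mean):
    # Poisson-like count law truncated at >=1: every annotated protein has
    # at least one term
    n = 1 + rng.poisson(max(mean - 1.0, 0.0))
    n = min(n, len(background))
    return set(rng.choice(background, size=n, replace=False))


def generate_world(cfg: WorldConfig) -> World:
    """Generate a complete synthetic world from *cfg* (deterministically)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    terms = [f"GO:{i:07d}" for i in range(1, cfg.n_terms + 1)]
    shuffled = list(rng.permutation(terms))
    s = cfg.signal_terms_per_class
    # others is a background class (random pairs from the PPI space share no
    # planted signature), so only activation and inhibition get signal terms
    signal = {
        ACTIVATION: shuffled[:s],
        INHIBITION: shuffled[s:2 * s],
        OTHERS: [],
    }
    background = sorted(shuffled[2 * s:])

    proteins = [f"P{i:05d}" for i in range(cfg.n_proteins)]
    true_terms: dict[str, set[str]] = {
        p: _draw_true_terms(rng, background, cfg.terms_per_protein)
        for p in proteins
    }
    dropout = {p for p in proteins if rng.random() < cfg.annotation_dropout}

    # labelled pairs: class membership driven by planted shared signal terms
    used: set[tuple[str, str]] = set()

    def draw_edge() -> tuple[str, str]:
        while True:
            i, j = rng.choice(cfg.n_proteins, size=2, replace=False)
            a, b = sorted((proteins[i], proteins[j]))
            if (a, b) not in used:
                used.add((a, b))
                return a, b

    def plant(a: str, b: str, cls: str) -> None:
        t = signal[cls][rng.integers(len(signal[cls]))]
        true_terms[a].add(t)
        true_terms[b].add(t)

    pairs: list[Pair] = []
    pair_truth: dict[str, str] = {}
    for cls, n in ((ACTIVATION, cfg.n_activation), (INHIBITION, cfg.n_inhibition)):
        for _ in range(n):
            a, b = draw_edge()
            labels = {cls}
            if rng.random() < cfg.signal_strength:
                plant(a, b, cls)
            if cls == ACTIVATION and rng.random() < cfg.p_dual:
                plant(a, b, INHIBITION)
                labels.add(INHIBITION)
            pairs.append(Pair.make(a, b, labels))
            pair_truth[f"{a}--{b}"] = ",".join(sorted(labels))

    # physical-PPI universe beyond the signed training pairs: random edges,
    # a fraction of which carry a planted (but unlabelled) sign
    extras: list[tuple[str, str]] = []
    extra_class: dict[tuple[str, str], str] = {}
    for _ in range(cfg.n_universe_extra + cfg.n_others):
        a, b = draw_edge()
        cls = OTHERS
        if rng.random() < cfg.universe_signed_fraction:
            cls = ACTIVATION if rng.random() < 0.7 else INHIBITION
            if rng.random() < cfg.signal_strength:
                plant(a, b, cls)
        extras.append((a, b))
        extra_class[(a, b)] = cls

    # the *others* training class is sampled from the unsigned part of the
    # universe — negatives come from the same physical-PPI space the model
    # later predicts on, so the "no shared signal" region is calibrated on
    # the right background distribution
    unsigned = [e for e in extras if extra_class[e] == OTHERS]
    if len(unsigned) < cfg.n_others:
        raise ValueError(
            f"universe too small: {len(unsigned)} unsigned edges available "
            f"but n_others={cfg.n_others}; raise n_universe_extra or lower "
            "universe_signed_fraction"
        )
    others_idx = rng.choice(len(unsigned), size=cfg.n_others, replace=False)
    others_edges = {unsigned[i] for i in others_idx}
    for a, b in sorted(others_edges):
        pairs.append(Pair.make(a, b, {OTHERS}))
        pair_truth[f"{a}--{b}"] = OTHERS

    universe = [p.id for p in pairs if p.labels != {OTHERS}]
    extra_truth: dict[str, str] = {}
    for a, b in extras:
        universe.append((a, b))
        if (a, b) not in others_edges:
            extra_truth[f"{a}--{b}"] = extra_class[(a, b)]

    # target annotations: the true biology, minus dropped-out proteins
    store = AnnotationStore()
    for p in proteins:
        if p in dropout:
            continue
        for t in sorted(true_terms[p]):
            store.protein_terms.setdefault(p, set()).add(t)
            store.n_read += 1

    # homologs: noisy copies of the query's true term set; dropped-out
    # proteins keep annotated homologs (the substitute path)
    hits: dict[str, list[tuple[str, float]]] = {}
    for p in proteins:
        entries = []
        for j in range(cfg.n_homologs_per_protein):
            acc = f"H{p}X{j}"
            hterms = {
                t if rng.random() >= cfg.homolog_term_noise
                else terms[rng.integers(cfg.n_terms)]
                for t in true_terms[p]
            }
            for t in sorted(hterms):
                store.protein_terms.setdefault(acc, set()).add(t)
                store.n_read += 1
            evalue = float(rng.uniform(0.0, min(5.0, cfg.e_cutoff)))
            entries.append((acc, evalue))
        entries.sort(key=lambda h: (h[1], h[0]))
        if entries:
            hits[p] = entries
    hmap = HomologMap(hits=hits, e_cutoff=cfg.e_cutoff)

    ground_truth = {
        "config": asdict(cfg),
        "signal_terms": {cls: sorted(signal[cls]) for cls in LABELS},
        "dropout_proteins": sorted(dropout),
        "pair_labels": pair_truth,
        "universe_extra_classes": extra_truth,
        "n_universe_extra_signed": sum(
            1 for c in extra_truth.values() if c != OTHERS
        ),
    }
    logger.info(
        "generated world: %d proteins (%d dropout), %d pairs, universe %d edges",
        cfg.n_proteins, len(dropout), len(pairs), len(universe),
    )
    return World(
        config=cfg,
        store=store,
        hmap=hmap,
        pairs=pairs,
        universe=universe,
        ground_truth=ground_truth,
    )


def world_to_files(world: World, out_dir) -> dict[str, Path]:
    """Write a world as GAF + homolog/pairs/universe TSV + ground-truth JSON.

    The files use exactly the dialects the readers consume, so parsing them
    back reproduces the in-memory world.
    """
    from .pipeline import write_edges_tsv, write_pairs_tsv  # avoid cycle at import

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gaf": out / "annotations.gaf",
        "homologs": out / "homologs.tsv",
        "pairs": out / "train_pairs.tsv",
        "universe": out / "universe.tsv",
        "ground_truth": out / "ground_truth.json",
    }

    with open(paths["gaf"], "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.2\n")
        fh.write("!generated by ppisign.synthetic (synthetic data)\n")
        for protein in sorted(world.store.protein_terms):
            for term in sorted(world.store.protein_terms[protein]):
                fields = [
                    "SYN", protein, protein, "involved_in", term,
                    "SYN:0000001", "IEA", "", "P", protein, "", "protein",
                    "taxon:9606", "20240101", "SYN",
                ]
                fh.write("\t".join(fields) + "\n")

    with open(paths["homologs"], "w", encoding="utf-8") as fh:
        fh.write("query\thomolog\tevalue\n")
        for query in sorted(world.hmap.hits):
            for acc, evalue in world.hmap.hits[query]:
                fh.write(f"{query}\t{acc}\t{evalue!r}\n")

    write_pairs_tsv(world.pairs, paths["pairs"])
    write_edges_tsv(world.universe, paths["universe"])
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(world.ground_truth, fh, indent=2)
    logger.info("wrote world files to %s", out)
    return paths
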