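"""GO annotations and homology relationships.

Reads Gene Ontology annotations from GAF 2.x files and sequence-homology
hit tables (query, homolog, E-value), and derives per-protein GO term sets:
the protein's own annotations (the *target* term set) and the union of its
homologs' annotations (the *homolog* term set). The homolog term set is the
knowledge-transfer device used to enrich sparsely annotated proteins.

Homolog search itself (e.g. PSI-BLAST against SwissProt) is out of scope;
its output enters through :func:`load_homolog_map` as a plain TSV contract.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: A valid GO term identifier: "GO:" followed by exactly seven digits.
GO_TERM_RE = re.compile(r"^GO:\d{7}$")

#: Default E-value cutoff for retaining homolog hits.
DEFAULT_E_CUTOFF = 10.0


@dataclass
class AnnotationStore:
    """Protein accession -> set of GO term IDs.

    Proteins with no annotations are simply absent; :meth:`terms` returns an
    empty set for them. ``n_read``/``n_skipped`` count the annotation records
    accepted and rejected while parsing.
    """

    protein_terms: dict[str, set[str]] = field(default_factory=dict)
    n_read: int = 0
    n_skipped: int = 0

    def terms(self, protein: str) -> frozenset[str]:
        """GO term set of *protein* (empty if unannotated)."""
        return frozenset(self.protein_terms.get(protein, ()))

    def add(self, protein: str, term: str) -> None:
        if not GO_TERM_RE.match(term):
            raise ValueError(f"not a GO term ID: {term!r}")
        self.protein_terms.setdefault(protein, set()).add(term)

    def __len__(self) -> int:
        return len(self.protein_terms)

    def __contains__(self, protein: str) -> bool:
        return protein in self.protein_terms


@dataclass
class HomologMap:
    """Query accession -> homolog hits ``(accession, e_value)``.

    Hit lists are sorted by ascending E-value, ties broken by accession, and
    never contain the query itself. All retained E-values are ``<= e_cutoff``.
    """

    hits: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    e_cutoff: float = DEFAULT_E_CUTOFF

    def homologs(self, protein: str) -> list[tuple[str, float]]:
        return self.hits.get(protein, [])

    def __len__(self) -> int:
        return len(self.hits)


def parse_gaf(path, evidence_filter: set[str] | None = None) -> AnnotationStore:
    """Parse a GAF 2.x annotation file into an :class:`AnnotationStore`.

    Records are keyed by the DB Object ID column (column 2); all three GO
    aspects (BP/CC/MF) are retained. If *evidence_filter* is given, only
    records whose evidence code is in the set are kept; others count as
    skipped. Malformed lines (fewer than 15 tab-separated fields, or an
    invalid GO ID) are skipped with a warning rather than aborting the parse.
    """
    store = AnnotationStore()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < 15:
                logger.warning(
                    "%s:%d: malformed GAF record (%d fields), skipped",
                    path, lineno, len(fields),
                )
                store.n_skipped += 1
                continue
            obj_id, go_id, evidence = fields[1], fields[4], fields[6]
            if not GO_TERM_RE.match(go_id):
                logger.warning(
                    "%s:%d: invalid GO ID %r, skipped", path, lineno, go_id
                )
                store.n_skipped += 1
                continue
            if evidence_filter is not None and evidence not in evidence_filter:
                store.n_skipped += 1
                continue
            store.protein_terms.setdefault(obj_id, set()).add(go_id)
            store.n_read += 1
    logger.info(
        "parsed %s: %d records read, %d skipped, %d proteins",
        path, store.n_read, store.n_skipped, len(store),
    )
    return store


def load_homolog_map(path, e_cutoff: float = DEFAULT_E_CUTOFF) -> HomologMap:
    """Load a homolog hit table (TSV: ``query  homolog  evalue``).

    Rows with E-value above *e_cutoff*, self-hits, and rows with a
    non-numeric E-value are dropped (the last with a warning). Hit lists are
    sorted by (E-value, accession).
    """
    hits: dict[str, list[tuple[str, float]]] = {}
    n_rows = n_bad = 0
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header and not header.rstrip("\n").lower().startswith("query"):
            raise ValueError(
                f"{path}: expected header 'query<TAB>homolog<TAB>evalue', "
                f"got {header.rstrip()!r}"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                logger.warning("%s:%d: fewer than 3 columns, skipped", path, lineno)
                n_bad += 1
                continue
            query, homolog = parts[0], parts[1]
            try:
                evalue = float(parts[2])
            except ValueError:
                logger.warning(
                    "%s:%d: non-numeric E-value %r, skipped", path, lineno, parts[2]
                )
                n_bad += 1
                continue
            n_rows += 1
            if evalue > e_cutoff or query == homolog:
                continue
            hits.setdefault(query, []).append((homolog, evalue))
    for query in hits:
        hits[query].sort(key=lambda h: (h[1], h[0]))
    logger.info(
        "loaded %s: %d rows (%d bad), %d queries with hits at E<=%g",
        path, n_rows, n_bad, len(hits), e_cutoff,
    )
    return HomologMap(hits=hits, e_cutoff=e_cutoff)


def homolog_term_set(
    protein: str,
    hmap: HomologMap,
    store: AnnotationStore,
    max_hits: int | None = None,
) -> frozenset[str]:
    """GO term set of *protein*'s homologs.

    The union of the annotation-store term sets over the first *max_hits*
    homologs (best E-values first; all hits when ``max_hits is None``).
    Empty when the protein has no homologs or no annotated homologs.
    """
    hit_list = hmap.homologs(protein)
    if max_hits is not None:
        hit_list = hit_list[:max_hits]
    out: set[str] = set()
    for accession, _evalue in hit_list:
        out |= store.protein_terms.get(accession, set())
    return frozenset(out)
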