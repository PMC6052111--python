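"""Functional-annotation reference sets (GO or any gene<->term mapping).

The reference is filtered before evaluation: electronically inferred
annotations (IEA evidence) are removed, then terms annotating fewer than
``min_genes`` or more than ``max_genes`` genes are dropped — small terms are
too weakly represented to vote with, very large terms are non-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from coexnet.errors import EmptyAnnotationError, ParseError

#: GAF 2.x column positions (0-based) used here.
_GAF_GENE_COL = 1      # DB Object ID
_GAF_TERM_COL = 4      # GO ID
_GAF_EVIDENCE_COL = 6  # Evidence Code
_GAF_MIN_COLS = 15


@dataclass
class AnnotationSet:
    """Bipartite gene<->term mapping after evidence and size filtering.

    The two mappings are mutual inverses by construction; ``filter_record``
    documents the filtering that produced the set.
    """

    gene_to_terms: dict[str, frozenset[str]]
    term_to_genes: dict[str, frozenset[str]]
    filter_record: dict = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs, *, min_genes: int = 0, max_genes: int = 10**9,
                   filter_record: dict | None = None) -> "AnnotationSet":
        """Build a set from (gene, term) pairs, applying the size filter."""
        term_genes: dict[str, set[str]] = {}
        for gene, term in pairs:
            term_genes.setdefault(term, set()).add(gene)
        term_genes = {
            t: gs for t, gs in term_genes.items()
            if min_genes <= len(gs) <= max_genes
        }
        if not term_genes:
            raise EmptyAnnotationError(
                f"no term with between {min_genes} and {max_genes} genes"
            )
        gene_terms: dict[str, set[str]] = {}
        for term, genes in term_genes.items():
            for g in genes:
                gene_terms.setdefault(g, set()).add(term)
        record = dict(filter_record or {})
        record.setdefault("min_genes", min_genes)
        record.setdefault("max_genes", max_genes)
        return cls(
            gene_to_terms={g: frozenset(ts) for g, ts in gene_terms.items()},
            term_to_genes={t: frozenset(gs) for t, gs in term_genes.items()},
            filter_record=record,
        )

    @property
    def terms(self) -> list[str]:
        return sorted(self.term_to_genes)

    @property
    def genes(self) -> list[str]:
        return sorted(self.gene_to_terms)

    def term_counts(self) -> dict[str, int]:
        return {t: len(gs) for t, gs in self.term_to_genes.items()}

    def share_term(self, gene_a: str, gene_b: str) -> bool:
        """True when the two genes are co-annotated with at least one term."""
        ta = self.gene_to_terms.get(gene_a)
        tb = self.gene_to_terms.get(gene_b)
        return bool(ta and tb and ta & tb)


def read_annotations(path, fmt: str = "two_column", *, min_genes: int = 5,
                     max_genes: int = 100,
                     excluded_evidence: frozenset[str] = frozenset({"IEA"}),
                     ) -> AnnotationSet:
    """Read gene annotations from a GAF 2.x or two-column TSV file.

    Parameters
    ----------
    fmt : {"gaf", "two_column"}
        ``gaf``: standard 17-column GAF with ``!`` comment lines; rows whose
        evidence code is in ``excluded_evidence`` are dropped before the
        size filter. ``two_column``: ``gene_id<TAB>term_id`` with an
        optional header line.
    min_genes, max_genes : int
        Retained terms annotate between ``min_genes`` and ``max_genes``
        genes inclusive, counted after evidence filtering.
    """
    pairs: list[tuple[str, str]] = []
    if fmt == "gaf":
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("!"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < _GAF_MIN_COLS:
                    raise ParseError(
                        f"GAF line with {len(cols)} columns "
                        f"(expected >= {_GAF_MIN_COLS}): {line[:60]!r}"
                    )
                if cols[_GAF_EVIDENCE_COL] in excluded_evidence:
                    continue
                pairs.append((cols[_GAF_GENE_COL], cols[_GAF_TERM_COL]))
    elif fmt == "two_column":
        frame = pd.read_csv(path, sep="\t", header=None, dtype=str,
                            comment="#")
        if frame.shape[1] < 2:
            raise ParseError("two-column annotation file needs 2 columns")
        first = frame.iloc[0]
        if str(first[0]).lower() in {"gene_id", "gene"}:
            frame = frame.iloc[1:]
        pairs = list(
            frame.iloc[:, :2].itertuples(index=False, name=None)
        )
    else:
        raise ParseError(f"unknown annotation format {fmt!r}")
    return AnnotationSet.from_pairs(
        pairs,
        min_genes=min_genes,
        max_genes=max_genes,
        filter_record={
            "min_genes": min_genes,
            "max_genes": max_genes,
            "excluded_evidence": sorted(excluded_evidence),
            "format": fmt,
        },
    )
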