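"""Pathway definitions: guide genes partitioned into sub-pathways.

A :class:`PathwayDefinition` maps each guide gene to exactly one sub-pathway
label, giving the row dimension *n* of the sub-pathway x community
contingency table used by the normalized Chi-squared partition statistic.

Five definitions ship with the package, one per studied pathway
(phenylpropanoids, fatty acid, carbohydrate, terpenes, cytokinin signaling).
The bundled files are synthetic stand-ins: their gene identifiers are
generated, but the gene totals, sub-pathway counts and sub-pathway labels
(KEGG module accessions where applicable) match the published pathway
descriptions — phenylpropanoids 43 genes / 4 sub-pathways, fatty acid 97/6,
carbohydrate 202/8, terpenes 64/6, cytokinin signaling 37 genes over the
five signaling levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from coexnet.errors import AmbiguousAssignmentError, ParseError

#: Names of the bundled synthetic pathway definitions.
BUNDLED_PATHWAYS = (
    "phenylpropanoid",
    "fatty_acid",
    "carbohydrate",
    "terpene",
    "cytokinin",
)


@dataclass
class PathwayDefinition:
    """Guide gene -> sub-pathway partition for one pathway."""

    name: str
    gene_to_subpathway: dict[str, str]

    @property
    def guide_genes(self) -> list[str]:
        return sorted(self.gene_to_subpathway)

    @property
    def subpathways(self) -> list[str]:
        return sorted(set(self.gene_to_subpathway.values()))

    @property
    def n_subpathways(self) -> int:
        return len(set(self.gene_to_subpathway.values()))

    @property
    def n_genes(self) -> int:
        return len(self.gene_to_subpathway)


def read_pathway(path, name: str | None = None) -> PathwayDefinition:
    """Read ``gene_id<TAB>subpathway[<TAB>priority]`` (optional header).

    A gene listed under two labels raises
    :class:`AmbiguousAssignmentError` unless a numeric third column assigns
    priorities, in which case the lowest-priority-value row wins.
    """
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if frame.shape[1] < 2:
        raise ParseError("pathway file needs at least 2 columns")
    if str(frame.iat[0, 0]).lower() in {"gene_id", "gene"}:
        frame = frame.iloc[1:]
    has_priority = frame.shape[1] >= 3 and frame.iloc[:, 2].notna().any()
    mapping: dict[str, str] = {}
    priority: dict[str, float] = {}
    for row in frame.itertuples(index=False):
        gene, label = str(row[0]), str(row[1])
        prio = float(row[2]) if has_priority and pd.notna(row[2]) else 0.0
        if gene in mapping and mapping[gene] != label:
            if not has_priority:
                raise AmbiguousAssignmentError(
                    f"gene {gene!r} listed under {mapping[gene]!r} "
                    f"and {label!r}"
                )
            if prio < priority[gene]:
                mapping[gene], priority[gene] = label, prio
        else:
            mapping[gene] = label
            priority[gene] = prio
    pname = name if name is not None else str(path)
    return PathwayDefinition(name=pname, gene_to_subpathway=mapping)


def bundled_pathway(name: str) -> PathwayDefinition:
    """Load one of the packaged synthetic pathway definitions by name."""
    if name not in BUNDLED_PATHWAYS:
        raise KeyError(
            f"unknown pathway {name!r}; available: {BUNDLED_PATHWAYS}"
        )
    ref = resources.files("coexnet.data") / f"{name}_synthetic.tsv"
    with resources.as_file(ref) as path:
        return read_pathway(path, name=name)
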