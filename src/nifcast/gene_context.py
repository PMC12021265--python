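"""Genomic-context features: nif gene distances, copy numbers, presence.

Distance between two genes is the minimal inter-interval gap over all
copy pairs sharing a contig (0 when intervals overlap or abut),
strand-agnostic; pairs never co-located on a contig yield NaN, left to
the modeling step's median imputation.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from nifcast.records import GeneFeature, StrainRecord, normalize_gene
from nifcast.sequence_features import FeatureVector

#: gene pairs whose genomic distances enter the feature table
DISTANCE_PAIRS: tuple[tuple[str, str], ...] = (
    ("nifD", "nifK"),
    ("nifK", "nifH"),
    ("nifD", "nifH"),
)

#: default nif repertoire tracked for copy numbers (cofactor assembly,
#: maturation and regulation genes seen across diazotroph clusters)
DEFAULT_CLUSTER_GENES: tuple[str, ...] = (
    "nifB", "nifD", "nifE", "nifF", "nifH", "nifK", "nifM", "nifN",
    "nifS", "nifT", "nifU", "nifV", "nifW", "nifX", "nifZ",
)

#: genes whose expression proxies (E/Fop/CAI) enter the feature table;
#: 'lna' follows the source annotation vocabulary, with 'nifa' as the
#: conventional regulator alias
DEFAULT_EXPRESSION_GENES: tuple[str, ...] = (
    "lnA", "nifB", "nifD", "nifH", "nifK", "nifE", "nifN", "nifX",
)


def _gap(a: GeneFeature, b: GeneFeature) -> int:
    # start-minus-end gap: [100,400] vs [1000,1600] -> 600; overlap -> 0
    if a.start > b.start:
        a, b = b, a
    return max(0, b.start - a.end)


def gene_distance(features: Sequence[GeneFeature], a: str, b: str) -> float:
    """Minimal gap in bp between any copy of gene a and of gene b.

    Returns NaN if either gene is absent or the genes never share a
    contig.  Symmetric in (a, b).
    """
    a_n, b_n = normalize_gene(a), normalize_gene(b)
    fa = [f for f in features if f.gene == a_n]
    fb = [f for f in features if f.gene == b_n]
    best = math.inf
    for x in fa:
        for y in fb:
            if x.contig != y.contig:
                continue
            best = min(best, _gap(x, y))
    return float(best) if best < math.inf else float("nan")


def copy_number(features: Sequence[GeneFeature], gene: str) -> int:
    """Number of annotated copies of ``gene`` (0 if absent)."""
    g = normalize_gene(gene)
    return sum(1 for f in features if f.gene == g)


def prevalent_genes(dataset: Sequence[StrainRecord], threshold: float = 0.5) -> list[str]:
    """Genes present in more than ``threshold`` of strains (strict >)."""
    if not dataset:
        raise ValueError("empty dataset")
    n = len(dataset)
    observed: dict[str, int] = {}
    for rec in dataset:
        for g in {f.gene for f in rec.features}:
            observed[g] = observed.get(g, 0) + 1
    return sorted(g for g, k in observed.items() if k / n > threshold)


def strain_context_features(
    strain: StrainRecord,
    cluster_genes: Sequence[str] = DEFAULT_CLUSTER_GENES,
    distance_pairs: Sequence[tuple[str, str]] = DISTANCE_PAIRS,
) -> FeatureVector:
    """Distance and copy-number block for one strain."""
    names: list[str] = []
    values: list[float] = []
    for a, b in distance_pairs:
        names.append(f"dist_{a}_{b}")
        values.append(gene_distance(strain.features, a, b))
    for g in cluster_genes:
        names.append(f"copy_{g}")
        values.append(float(copy_number(strain.features, g)))
    return FeatureVector(names=tuple(names), values=np.asarray(values, dtype=float))
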