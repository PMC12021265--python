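"""End-to-end featurization: StrainRecords -> feature table.

The table is indexed by strain id and partitioned into two blocks:

* the **embedding block** (``emb_0001..emb_1024``): mean-pooled
  per-residue embeddings, averaged over a strain's nitrogenase
  proteins;
* the **auxiliary block**: conjoint-triad (``ct_*``), dipeptide
  (``dpc_*``) and pseudo-amino-acid (``paac_*``) encodings, codon
  statistics (``Average_<gene>_{E,Fop,CAI}``, ``ECD``, ``rscu_*``),
  gene distances (``dist_*``) and copy numbers (``copy_*``).

Missing blocks (a strain without proteins or CDSs) become NaN rows,
handled by the models' median imputation fit on training data.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from nifcast.codon_features import ReferenceSet, strain_codon_features
from nifcast.gene_context import (
    DEFAULT_CLUSTER_GENES,
    DEFAULT_EXPRESSION_GENES,
    DISTANCE_PAIRS,
    strain_context_features,
)
from nifcast.records import StrainRecord
from nifcast.sequence_features import (
    EmbeddingBackend,
    dpc_encode,
    mean_pool,
    paac_encode,
    pool_protein_encodings,
    triad_encode,
)
from nifcast.synthetic import MockEmbedder

logger = logging.getLogger("nifcast")


def _sequence_block(rec: StrainRecord, backend: EmbeddingBackend, lam: int, w: float):
    from nifcast.sequence_features import FeatureVector, embedding_names, dpc_names, paac_names, triad_names

    names = (
        embedding_names(backend.width) + triad_names() + dpc_names() + paac_names(lam)
    )
    if not rec.proteins:
        return names, np.full(len(names), np.nan)
    per_protein = []
    for p in rec.proteins:
        blocks = [
            mean_pool(backend.embed(p)),
            triad_encode(p),
            dpc_encode(p),
            paac_encode(p, lam=lam, w=w),
        ]
        per_protein.append(
            FeatureVector(
                names=tuple(n for b in blocks for n in b.names),
                values=np.concatenate([b.values for b in blocks]),
            )
        )
    pooled = pool_protein_encodings(per_protein)
    return pooled.names, pooled.values


def build_feature_table(
    records: Sequence[StrainRecord],
    backend: EmbeddingBackend | None = None,
    ref: ReferenceSet | None = None,
    expression_genes: Sequence[str] = DEFAULT_EXPRESSION_GENES,
    cluster_genes: Sequence[str] = DEFAULT_CLUSTER_GENES,
    distance_pairs=DISTANCE_PAIRS,
    lam: int = 30,
    w: float = 0.05,
    include_rscu: bool = True,
) -> pd.DataFrame:
    """Featurize a cohort into a samples x features table.

    ``backend`` defaults to the deterministic mock embedder.  ``ref``
    (the highly expressed reference gene set for CAI/Fop) defaults to
    relative adaptiveness derived from the cohort's pooled CDSs — a
    genome-wide fallback; supply ribosomal-protein CDSs for real data.
    """
    if not records:
        raise ValueError("no records to featurize")
    if backend is None:
        backend = MockEmbedder()
    if ref is None:
        all_cds = [c for r in records for c in r.cds]
        if not all_cds:
            raise ValueError("cannot derive a reference set: no CDS in cohort")
        ref = ReferenceSet.from_cds(all_cds)
        logger.info("reference set derived from pooled cohort CDSs")

    rows = []
    index = []
    names_ref: tuple[str, ...] | None = None
    for rec in records:
        seq_names, seq_vals = _sequence_block(rec, backend, lam, w)
        codon = strain_codon_features(rec, ref, expression_genes, include_rscu)
        ctx = strain_context_features(rec, cluster_genes, distance_pairs)
        names = tuple(seq_names) + codon.names + ctx.names
        vals = np.concatenate([seq_vals, codon.values, ctx.values])
        if names_ref is None:
            names_ref = names
        elif names != names_ref:
            raise RuntimeError("inconsistent feature schema across strains")
        rows.append(vals)
        index.append(rec.strain_id)
    return pd.DataFrame(rows, index=pd.Index(index, name="strain_id"), columns=list(names_ref))


def split_blocks(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(embedding block, auxiliary block) views of a feature table."""
    emb_cols = [c for c in X.columns if c.startswith("emb_")]
    aux_cols = [c for c in X.columns if not c.startswith("emb_")]
    return X[emb_cols], X[aux_cols]
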