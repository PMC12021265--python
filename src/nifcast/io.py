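"""Readers/writers for FASTA, GenBank, GFF3 and the activity table.

Identifier convention
---------------------
Multi-strain flat files tie every record to its strain through the id:
``<strain_id>|<name>``.  For coding sequences the part after the bar is
the gene token, optionally suffixed ``_<copy>`` (e.g. ``str1|nifH_2``).
Annotation files use the same prefix on the contig/seqid column.
Per-strain dicts can be passed to :func:`assemble_dataset` instead, in
which case no prefix is needed.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from nifcast.records import (
    CodingSequence,
    GeneFeature,
    ProteinSequence,
    StrainRecord,
    normalize_gene,
    sanitize_nucleotide,
    sanitize_protein,
)

logger = logging.getLogger("nifcast")

_COPY_SUFFIX = re.compile(r"_(\d+)$")


def split_prefixed_id(identifier: str) -> tuple[str, str]:
    """Split ``strain|rest`` -> (strain, rest); ('' , id) if no bar."""
    if "|" in identifier:
        strain, rest = identifier.split("|", 1)
        return strain, rest
    return "", identifier


def gene_from_id(identifier: str) -> str:
    """Gene token from a CDS id (``str1|nifH_2`` -> ``nifh``)."""
    _, rest = split_prefixed_id(identifier)
    return normalize_gene(_COPY_SUFFIX.sub("", rest))


def read_fasta(path, kind: str):
    """Read a FASTA file as proteins or coding sequences.

    Parameters
    ----------
    kind : {'protein', 'nucleotide'}
        Protein records are sanitized to the standard 20-letter
        alphabet; nucleotide records must be A/C/G/T/N and their gene
        token is taken from the record id.
    """
    if kind not in ("protein", "nucleotide"):
        raise ValueError(f"unknown kind {kind!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    out = []
    for rec in records:
        seq = str(rec.seq)
        if kind == "protein":
            out.append(ProteinSequence(id=rec.id, residues=sanitize_protein(seq, rec.id)))
        else:
            out.append(
                CodingSequence(
                    id=rec.id,
                    gene=gene_from_id(rec.id),
                    nucleotides=sanitize_nucleotide(seq, rec.id),
                )
            )
    return out


def write_fasta(path, sequences: Iterable) -> None:
    """Write ProteinSequence or CodingSequence objects as FASTA."""
    recs = []
    for s in sequences:
        body = s.residues if isinstance(s, ProteinSequence) else s.nucleotides
        recs.append(SeqRecord(Seq(body), id=s.id, description=""))
    SeqIO.write(recs, str(path), "fasta")


def _assign_copy_indices(feats: list[GeneFeature]) -> list[GeneFeature]:
    """Number copies 1..k per (strain, gene), in ascending coordinate order."""
    by_gene: dict[tuple[str, str], list[GeneFeature]] = {}
    for f in feats:
        strain = split_prefixed_id(f.contig)[0]
        by_gene.setdefault((strain, f.gene), []).append(f)
    out = []
    for gene_feats in by_gene.values():
        gene_feats.sort(key=lambda f: (f.contig, f.start, f.end))
        for i, f in enumerate(gene_feats, start=1):
            out.append(
                GeneFeature(
                    contig=f.contig, start=f.start, end=f.end,
                    strand=f.strand, gene=f.gene, copy_index=i,
                )
            )
    out.sort(key=lambda f: (f.contig, f.start, f.end, f.gene))
    return out


_GFF_GENE_KEYS = ("gene", "Name", "gene_name", "locus_tag")


def _parse_gff3(path) -> list[GeneFeature]:
    from gffutils.iterators import DataIterator

    feats = []
    for feat in DataIterator(str(path)):
        if feat.featuretype not in ("gene", "CDS"):
            continue
        gene = next(
            (feat.attributes[k][0] for k in _GFF_GENE_KEYS if k in feat.attributes),
            None,
        )
        if gene is None:
            continue
        if feat.start is None or feat.end is None:
            logger.warning("feature without coordinates skipped: %s", gene)
            continue
        feats.append(
            GeneFeature(
                contig=feat.seqid,
                start=int(feat.start),
                end=int(feat.end),
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                gene=normalize_gene(gene),
            )
        )
    # keep gene entries over duplicate CDS entries at identical coordinates
    seen: dict[tuple, GeneFeature] = {}
    for f in feats:
        seen.setdefault((f.contig, f.start, f.end, f.gene), f)
    return list(seen.values())


def _parse_genbank(path) -> list[GeneFeature]:
    feats = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type not in ("gene", "CDS"):
                continue
            gene = None
            for key in ("gene", "locus_tag"):
                if key in feat.qualifiers:
                    gene = feat.qualifiers[key][0]
                    break
            if gene is None or feat.location is None:
                continue
            # Biopython locations are 0-based half-open; convert.
            feats.append(
                GeneFeature(
                    contig=rec.id,
                    start=int(feat.location.start) + 1,
                    end=int(feat.location.end),
                    strand="-" if feat.location.strand == -1 else "+",
                    gene=normalize_gene(gene),
                )
            )
    seen: dict[tuple, GeneFeature] = {}
    for f in feats:
        seen.setdefault((f.contig, f.start, f.end, f.gene), f)
    return list(seen.values())


def read_annotations(path, dialect: str) -> list[GeneFeature]:
    """Read gene/CDS features from a GFF3 or GenBank file.

    Gene names are normalized to lowercase; copies are numbered 1..k per
    gene in coordinate order.
    """
    if dialect == "gff3":
        feats = _parse_gff3(path)
    elif dialect == "genbank":
        feats = _parse_genbank(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return _assign_copy_indices(feats)


def read_activity_table(path) -> pd.DataFrame:
    """Read the strain activity table (CSV/TSV with strain_id, activity)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = {"strain_id", "activity"} - set(df.columns)
    if missing:
        raise ValueError(f"activity table lacks columns {sorted(missing)}")
    df["strain_id"] = df["strain_id"].astype(str)
    return df


def _group_by_strain(items, key) -> dict[str, list]:
    groups: dict[str, list] = {}
    for it in items:
        groups.setdefault(key(it), []).append(it)
    return groups


def assemble_dataset(
    activity_table: pd.DataFrame,
    proteins: Iterable[ProteinSequence] | Mapping[str, list] = (),
    cds: Iterable[CodingSequence] | Mapping[str, list] = (),
    annotations: Iterable[GeneFeature] | Mapping[str, list] = (),
) -> list[StrainRecord]:
    """Join activity rows with sequences and annotations into StrainRecords.

    Sequences may come as flat lists (ids prefixed ``strain|``) or as
    dicts keyed by strain id.  One record per activity row; sequences
    whose strain is absent from the table are reported and dropped.
    """
    if activity_table["strain_id"].duplicated().any():
        dups = activity_table.loc[activity_table["strain_id"].duplicated(), "strain_id"]
        raise ValueError(f"duplicate strain_id(s): {sorted(set(dups))}")
    if (activity_table["activity"] < 0).any():
        raise ValueError("negative activity values in table")

    def as_groups(obj, idkey):
        if isinstance(obj, Mapping):
            return {str(k): list(v) for k, v in obj.items()}
        return _group_by_strain(list(obj), idkey)

    prot_g = as_groups(proteins, lambda p: split_prefixed_id(p.id)[0])
    cds_g = as_groups(cds, lambda c: split_prefixed_id(c.id)[0])
    ann_g = as_groups(annotations, lambda f: split_prefixed_id(f.contig)[0])

    known = set(activity_table["strain_id"])
    for name, groups in (("protein", prot_g), ("CDS", cds_g), ("annotation", ann_g)):
        orphans = set(groups) - known - {""}
        if orphans:
            logger.warning("%s records for unknown strain(s) dropped: %s",
                           name, sorted(orphans))

    records = []
    for row in activity_table.itertuples(index=False):
        sid = str(row.strain_id)
        rec = StrainRecord(
            strain_id=sid,
            activity=float(row.activity),
            proteins=prot_g.get(sid, []),
            cds=cds_g.get(sid, []),
            features=ann_g.get(sid, []),
        )
        if not rec.proteins and not rec.cds:
            logger.warning("strain %r has no sequence data", sid)
        records.append(rec)
    return records
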