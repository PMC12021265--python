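"""Codon-preference statistics: RSCU, ECD, CAI, Fop and the E metric.

All statistics run over the 61 sense codons of the standard genetic
code, excluding the two single-codon families (ATG/Met, TGG/Trp) where
no synonymous choice exists — leaving the 59 codons of degenerate
families.  Codons containing ``N`` are ignored.

* RSCU(c) = observed count of c divided by the mean count within its
  synonymous family (so a family with uniform usage is all ones).
* ECD = Euclidean distance of the RSCU vector from the all-ones
  (no-preference) vector, a scalar genome-level bias strength.
* CAI = geometric mean of per-codon relative adaptiveness w(c) derived
  from a highly expressed reference gene set (Sharp–Li).
* Fop = fraction of a gene's degenerate-family codons that are
  family-optimal (w = 1) under the reference set.
* E = weighted average over families of the total-variation distance
  between the within-family codon frequencies and the uniform
  distribution; an expression proxy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from nifcast.records import CodingSequence, StrainRecord, normalize_gene
from nifcast.sequence_features import FeatureVector

_table = CodonTable.unambiguous_dna_by_id[1]  # standard code

#: amino acid -> tuple of synonymous codons (61 sense codons total)
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_table.forward_table.items()):
    FAMILIES.setdefault(_aa, ())
    FAMILIES[_aa] += (_codon,)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(_table.forward_table))
#: codons in families of size >= 2 (the 59 codons RSCU/ECD run over)
DEGENERATE_CODONS: tuple[str, ...] = tuple(
    c for aa, fam in sorted(FAMILIES.items()) for c in fam if len(fam) >= 2
)
_FAMILY_OF = {c: aa for aa, fam in FAMILIES.items() for c in fam}
STOP_CODONS = tuple(sorted(_table.stop_codons))

W_FLOOR = 0.01  # relative adaptiveness assigned to reference zero-count codons


def count_codons(cds: CodingSequence | Iterable[CodingSequence]) -> Counter:
    """Sense-codon counts; codons with N and stop codons are skipped."""
    if isinstance(cds, CodingSequence):
        cds = [cds]
    counts: Counter = Counter()
    for c in cds:
        for codon in c.codons():
            if codon in _FAMILY_OF:
                counts[codon] += 1
    return counts


@dataclass(frozen=True)
class RSCUProfile:
    """RSCU over the 59 degenerate-family codons.

    Within each family of size k the values sum to k when the family
    was observed; unobserved families are neutral (all ones).
    """

    values: Mapping[str, float]

    def __post_init__(self):
        missing = set(DEGENERATE_CODONS) - set(self.values)
        if missing:
            raise ValueError(f"profile missing codons: {sorted(missing)[:5]} ...")

    def vector(self) -> np.ndarray:
        return np.array([self.values[c] for c in DEGENERATE_CODONS])


def rscu_from_counts(counts: Mapping[str, int]) -> RSCUProfile:
    values: dict[str, float] = {}
    for aa, fam in FAMILIES.items():
        if len(fam) < 2:
            continue
        total = sum(counts.get(c, 0) for c in fam)
        if total == 0:
            for c in fam:
                values[c] = 1.0
        else:
            mean = total / len(fam)
            for c in fam:
                values[c] = counts.get(c, 0) / mean
    return RSCUProfile(values)


def rscu(cds: CodingSequence | Iterable[CodingSequence]) -> RSCUProfile:
    """RSCU profile of one CDS (or pooled over several)."""
    return rscu_from_counts(count_codons(cds))


def ecd(profile: RSCUProfile) -> float:
    """Euclidean distance of the RSCU vector from all-ones."""
    return float(np.sqrt(np.sum((profile.vector() - 1.0) ** 2)))


@dataclass(frozen=True)
class ReferenceSet:
    """Relative adaptiveness w(c) derived from reference (highly
    expressed) genes; per family max w = 1, zero-count codons floored."""

    w: Mapping[str, float] = field(default_factory=dict)

    @classmethod
    def from_cds(cls, reference_cds: Sequence[CodingSequence]) -> "ReferenceSet":
        counts = count_codons(reference_cds)
        w: dict[str, float] = {}
        for aa, fam in FAMILIES.items():
            if len(fam) < 2:
                continue
            fam_counts = [counts.get(c, 0) for c in fam]
            top = max(fam_counts)
            if top == 0:
                for c in fam:
                    w[c] = 1.0  # family unobserved in reference: uninformative
            else:
                for c, x in zip(fam, fam_counts):
                    w[c] = x / top if x > 0 else W_FLOOR
        return cls(w=w)

    def optimal(self, codon: str) -> bool:
        return self.w.get(codon, 0.0) >= 1.0


def _scoreable(cds: CodingSequence) -> list[str]:
    return [c for c in cds.codons() if c in _FAMILY_OF and len(FAMILIES[_FAMILY_OF[c]]) >= 2]


def cai(cds: CodingSequence, ref: ReferenceSet) -> float:
    """Codon adaptation index: geometric mean of w over scoreable codons."""
    codons = _scoreable(cds)
    if not codons:
        raise ValueError(f"CDS {cds.id!r}: no degenerate-family codons to score")
    logs = np.log([ref.w[c] for c in codons])
    return float(np.exp(logs.mean()))


def fop(cds: CodingSequence, ref: ReferenceSet) -> float:
    """Fraction of degenerate-family codons that are family-optimal."""
    codons = _scoreable(cds)
    if not codons:
        raise ValueError(f"CDS {cds.id!r}: no degenerate-family codons to score")
    return sum(ref.optimal(c) for c in codons) / len(codons)


def e_metric(cds: CodingSequence) -> float:
    """Weighted-average deviation of within-family usage from uniform.

    Per family a of size k with within-family frequencies f,
    d_a = 1/2 sum |f_c - 1/k| (total-variation distance to uniform);
    E = sum_a p_a d_a with p_a the family's share of the gene's
    degenerate-family codons.
    """
    counts = count_codons(cds)
    total = sum(counts.get(c, 0) for c in DEGENERATE_CODONS)
    if total == 0:
        return 0.0
    e = 0.0
    for aa, fam in FAMILIES.items():
        k = len(fam)
        if k < 2:
            continue
        fam_total = sum(counts.get(c, 0) for c in fam)
        if fam_total == 0:
            continue
        d = 0.5 * sum(abs(counts.get(c, 0) / fam_total - 1.0 / k) for c in fam)
        e += (fam_total / total) * d
    return float(e)


def genome_ecd(strain: StrainRecord) -> float:
    """Genome-level ECD from codon counts pooled over all CDSs."""
    return ecd(rscu_from_counts(count_codons(strain.cds)))


def strain_codon_features(
    strain: StrainRecord,
    ref: ReferenceSet,
    genes: Sequence[str],
    include_rscu: bool = True,
) -> FeatureVector:
    """Per-strain codon feature block.

    Per gene g in ``genes``: ``Average_g_E``, ``Average_g_Fop``,
    ``Average_g_CAI`` averaged over that gene's CDS copies (NaN when the
    gene is absent, imputed downstream); plus the genome-level ``ECD``
    and, optionally, the 59 genome RSCU values.
    """
    names: list[str] = []
    values: list[float] = []
    by_gene: dict[str, list[CodingSequence]] = {}
    for c in strain.cds:
        by_gene.setdefault(c.gene, []).append(c)

    for gene in genes:
        copies = by_gene.get(normalize_gene(gene), [])
        for stat, fn in (
            ("E", e_metric),
            ("Fop", lambda c: fop(c, ref)),
            ("CAI", lambda c: cai(c, ref)),
        ):
            names.append(f"Average_{gene}_{stat}")
            if copies:
                values.append(float(np.mean([fn(c) for c in copies])))
            else:
                values.append(np.nan)

    names.append("ECD")
    if strain.cds:
        values.append(genome_ecd(strain))
    else:
        values.append(np.nan)

    if include_rscu:
        if strain.cds:
            profile = rscu_from_counts(count_codons(strain.cds))
            vec = profile.vector()
        else:
            vec = np.full(len(DEGENERATE_CODONS), np.nan)
        names.extend(f"rscu_{c}" for c in DEGENERATE_CODONS)
        values.extend(vec)

    return FeatureVector(names=tuple(names), values=np.asarray(values, dtype=float))
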