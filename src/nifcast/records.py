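"""Domain records: sequences, gene features, and per-strain bundles.

Sanitization policy
-------------------
Protein sequences are uppercased and stripped of non-standard residue
codes (``X B Z U J O *``) before any encoding, because every encoder in
:mod:`nifcast.sequence_features` is defined over the 20 standard amino
acids only.  A record losing more than 10% of its residues to
sanitization is rejected rather than silently truncated.

Coordinates are 1-based inclusive throughout (GenBank/GFF3 convention);
0-based sources are converted at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger("nifcast")

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)
#: residue codes removed by sanitization (ambiguity codes, rare residues, stops)
NONSTANDARD_AA = frozenset("XBZUJO*")

MAX_NONSTANDARD_FRACTION = 0.10

_VALID_NT = frozenset("ACGTN")


class SanitizationError(ValueError):
    """Raised when a sequence cannot be reduced to the standard alphabet."""


def sanitize_protein(residues: str, record_id: str = "?") -> str:
    """Uppercase and restrict to the 20 standard residues.

    Raises :class:`SanitizationError` if more than 10% of the residues
    are non-standard, or if nothing remains, or if a character is not a
    recognized amino-acid code at all.
    """
    up = residues.upper().replace(" ", "").replace("\n", "")
    kept = []
    removed = 0
    for ch in up:
        if ch in _STANDARD_SET:
            kept.append(ch)
        elif ch in NONSTANDARD_AA:
            removed += 1
        else:
            raise SanitizationError(
                f"record {record_id!r}: unrecognized residue code {ch!r}"
            )
    if not up:
        raise SanitizationError(f"record {record_id!r}: empty sequence")
    if removed / len(up) > MAX_NONSTANDARD_FRACTION:
        raise SanitizationError(
            f"record {record_id!r}: {removed}/{len(up)} residues are "
            f"non-standard (> {MAX_NONSTANDARD_FRACTION:.0%})"
        )
    if not kept:
        raise SanitizationError(f"record {record_id!r}: no standard residues left")
    return "".join(kept)


def sanitize_nucleotide(nucleotides: str, record_id: str = "?") -> str:
    """Uppercase; error on anything outside A/C/G/T/N."""
    up = nucleotides.upper().replace(" ", "").replace("\n", "")
    bad = set(up) - _VALID_NT
    if bad:
        raise ValueError(
            f"record {record_id!r}: non-ACGTN characters {sorted(bad)!r}"
        )
    return up


def normalize_gene(name: str) -> str:
    """Case-insensitive gene token used for all gene-name matching."""
    return name.strip().lower()


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"protein {self.id!r}: empty residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CodingSequence:
    """A coding sequence; ``gene`` is the normalized gene token ('' if unknown)."""

    id: str
    gene: str
    nucleotides: str

    def __post_init__(self):
        if len(self.nucleotides) % 3 != 0:
            raise ValueError(
                f"CDS {self.id!r}: length {len(self.nucleotides)} not divisible by 3"
            )
        # internal stop codons are suspicious but tolerated (warn only):
        # annotation slippage is common in draft genomes.
        for i in range(0, len(self.nucleotides) - 3, 3):
            if self.nucleotides[i : i + 3] in ("TAA", "TAG", "TGA"):
                logger.warning("CDS %r has internal stop codon at %d", self.id, i + 1)
                break

    def codons(self) -> list[str]:
        nt = self.nucleotides
        return [nt[i : i + 3] for i in range(0, len(nt), 3)]


@dataclass(frozen=True)
class GeneFeature:
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'
    gene: str  # normalized token
    copy_index: int = 1

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"feature {self.gene!r}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.gene!r}: bad strand {self.strand!r}")


@dataclass
class StrainRecord:
    """Everything known about one strain.

    ``activity`` is the acetylene-reduction rate in
    nmol C2H4 / mg protein / hour; ``None`` for unlabeled strains.
    """

    strain_id: str
    activity: float | None = None
    proteins: list[ProteinSequence] = field(default_factory=list)
    cds: list[CodingSequence] = field(default_factory=list)
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        if self.activity is not None and self.activity < 0:
            raise ValueError(
                f"strain {self.strain_id!r}: negative activity {self.activity}"
            )
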