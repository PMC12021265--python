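"""Write a cohort to disk as the flat files the readers consume.

Layout (all plain text): ``proteins.faa``, ``cds.fna``,
``annotations.gff3``, ``activity.csv`` and, for synthetic cohorts,
``ground_truth.csv``.  Record ids follow the ``strain|name`` convention
of :mod:`nifcast.io`, so ``load_cohort`` round-trips the dataset.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from nifcast.io import assemble_dataset, read_activity_table, read_annotations, read_fasta, write_fasta
from nifcast.records import StrainRecord


def write_cohort(records: Sequence[StrainRecord], out_dir, truth: pd.DataFrame | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "proteins.faa", [p for r in records for p in r.proteins])
    write_fasta(out / "cds.fna", [c for r in records for c in r.cds])
    with open(out / "annotations.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            for f in r.features:
                fh.write(
                    "\t".join(
                        [
                            f.contig, "nifcast", "gene", str(f.start), str(f.end),
                            ".", f.strand, ".", f"gene={f.gene}",
                        ]
                    )
                    + "\n"
                )
    pd.DataFrame(
        {"strain_id": [r.strain_id for r in records],
         "activity": [r.activity for r in records]}
    ).to_csv(out / "activity.csv", index=False)
    if truth is not None:
        truth.to_csv(out / "ground_truth.csv", index=False)
    return out


def load_cohort(data_dir) -> list[StrainRecord]:
    d = Path(data_dir)
    table = read_activity_table(d / "activity.csv")
    proteins = read_fasta(d / "proteins.faa", "protein") if (d / "proteins.faa").exists() else []
    cds = read_fasta(d / "cds.fna", "nucleotide") if (d / "cds.fna").exists() else []
    ann = read_annotations(d / "annotations.gff3", "gff3") if (d / "annotations.gff3").exists() else []
    return assemble_dataset(table, proteins, cds, ann)
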