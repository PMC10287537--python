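"""Readers, writers and run configuration.

GFF3 is the only 1-based inclusive surface; everything internal is
0-based half-open. BED fragments are 6-column, 0-based half-open. Contig
sequences are random uniform nucleotides (sequence content never affects
the analysis — only lengths and coordinates do) and regenerate
byte-identically for a given seed.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    GeneCopy,
    ParseError,
    ValidationError,
    fragments_frame,
)

# ---------------------------------------------------------------------------
# GFF3

_REQUIRED_ATTRS = ("ID", "family", "biotype")


def write_gff3(genes: Sequence[GeneCopy], path: Union[str, Path]) -> None:
    """Write the gene catalog as GFF3 (1-based inclusive coordinates)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig_id, g.start, g.copy_id)):
            attrs = f"ID={g.copy_id};family={g.family_id};biotype={g.biotype}"
            fh.write(
                f"{g.contig_id}\tdosagecomp\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: Union[str, Path]) -> List[GeneCopy]:
    """Read a gene catalog from GFF3.

    Requires ``ID``, ``family`` and ``biotype`` attributes on every
    feature; parse failures report the offending line number. Output is
    ordered by (contig, start).
    """
    genes: List[GeneCopy] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"line {lineno}: expected 9 columns, got {len(fields)}")
            contig, _source, _type, start, end, _score, strand, _phase, attrs = fields
            if strand not in ("+", "-"):
                raise ParseError(f"line {lineno}: bad strand {strand!r}")
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer coordinates") from None
            attr_map = {}
            for item in attrs.split(";"):
                if item and "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            for key in _REQUIRED_ATTRS:
                if key not in attr_map:
                    raise ParseError(f"line {lineno}: missing attribute {key!r}")
            try:
                genes.append(
                    GeneCopy(
                        copy_id=attr_map["ID"],
                        family_id=attr_map["family"],
                        contig_id=contig,
                        start=start_i - 1,
                        end=end_i,
                        strand=strand,
                        biotype=attr_map["biotype"],
                    )
                )
            except ValidationError as err:
                raise ParseError(f"line {lineno}: {err}") from None
    genes.sort(key=lambda g: (g.contig_id, g.start, g.copy_id))
    return genes


# ---------------------------------------------------------------------------
# BED fragments

def write_bed(fragments: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write fragments as 6-column BED (0-based half-open)."""
    out = pd.DataFrame(
        {
            "contig": fragments["contig"],
            "start": fragments["start"],
            "end": fragments["end"],
            "name": [f"frag{i}" for i in range(len(fragments))],
            "score": 0,
            "strand": fragments["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: Union[str, Path], source: str = "rna") -> pd.DataFrame:
    """Read 6-column BED into a fragment frame."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["contig", "start", "end", "name", "score", "strand"],
        dtype={"contig": str, "start": np.int64, "end": np.int64, "strand": str},
    )
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ParseError(
            f"line {int(np.flatnonzero(bad.to_numpy())[0]) + 1}: bad strand"
        )
    return fragments_frame(df["contig"], df["start"], df["end"], df["strand"], source)


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(
    contig_lengths: Mapping[str, int], path: Union[str, Path], seed: int = 0
) -> None:
    """Write random uniform-nucleotide contig sequences.

    Each contig's sequence is seeded by ``(seed, crc32(contig))`` so the
    file is byte-identical across regenerations with the same seed.
    """
    records = []
    for contig in sorted(contig_lengths):
        rng = np.random.default_rng([seed, zlib.crc32(contig.encode())])
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, contig_lengths[contig])])
        records.append(SeqRecord(Seq(seq), id=contig, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_fasta_lengths(path: Union[str, Path]) -> Dict[str, int]:
    """Contig lengths from a FASTA file."""
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Count tables (external quantification entry point)

COUNT_TABLE_COLUMNS = ["copy_id", "family_id", "length", "sense", "antisense", "contig"]


def read_count_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read an externally quantified per-copy count table (TSV).

    Expected columns: ``copy_id, family_id, length, sense, antisense,
    contig``. The result is ``copy_id``-indexed with a ``biotype`` column
    defaulting to ``protein`` (external tables are assumed pre-filtered).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"count table missing columns {missing}")
    if "biotype" not in df.columns:
        df["biotype"] = "protein"
    return df.set_index("copy_id")


# ---------------------------------------------------------------------------
# Run configuration

@dataclass
class RunConfig:
    """Full configuration of a simulate-and-analyze run.

    Round-trips losslessly through YAML; every random draw in the pipeline
    is derived from ``seed``.
    """

    n_families: int = 150
    n_lineages: int = 2
    abundances: Union[str, List[float]] = "T_undata"
    reference_families: int = 150
    core_fraction: float = 0.05
    single_lineage_prob: float = 0.3
    scenario: str = "subdivision"
    mu_beta: float = 0.0
    sigma_beta: float = 0.45
    k: float = 4.0
    sigma_d: float = 6.0
    antisense: float = 0.05
    readthrough: float = 0.0
    rrna_multiplier: float = 20.0
    depth_dna: int = 100_000
    depth_rna: int = 200_000
    fragment_length: int = 150
    host_dna_fraction: float = 0.5
    host_rna_fraction: float = 0.3
    host_contig_length: int = 200_000
    alpha: float = 0.05
    theta_over: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.depth_dna is None or self.depth_rna is None:
            raise ValidationError("depths must be set")
        if self.depth_dna < 0 or self.depth_rna < 0:
            raise ValidationError("depths must be >= 0")
        if self.n_families < 1 or self.n_lineages < 1:
            raise ValidationError("need >= 1 family and lineage")
        if self.fragment_length < 1:
            raise ValidationError("fragment_length must be >= 1")

    def to_dict(self) -> Dict[str, object]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**data)  # type: ignore[arg-type]
        cfg.validate()
        return cfg

    def save(self, path: Union[str, Path]) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
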