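"""Domain model for split-endosymbiont dosage analysis.

The objects here describe a bacteriome-style symbiosis: a focal symbiont
whose genome has split into several cell lineages with complementary gene
loss, an unsplit reference symbiont, and a host background. Coordinates are
0-based half-open everywhere inside the package; GFF3 is the only 1-based
surface (see :mod:`dosagecomp.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Errors

class DosagecompError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DosagecompError):
    """A requested configuration cannot be satisfied."""


class ValidationError(DosagecompError):
    """An input value violates its contract."""


class SimulationError(DosagecompError):
    """The simulator was asked to sample from a degenerate distribution."""


class InputError(DosagecompError):
    """Malformed or inconsistent data passed to an operation."""


class UndefinedValueError(DosagecompError):
    """The requested statistic is undefined for this input (e.g. 0/0)."""


class DegenerateInputError(DosagecompError):
    """Statistical input with no variance (or a perfectly collinear control)."""


class ParseError(InputError):
    """A file could not be parsed; message carries the line number."""


# ---------------------------------------------------------------------------
# Gene catalog

VALID_BIOTYPES = ("protein", "rRNA", "tRNA")


@dataclass(frozen=True)
class GeneCopy:
    """One copy of a gene family on one contig.

    ``start``/``end`` are 0-based half-open base-pair coordinates. Protein
    copies enter the TPM universe; rRNA and tRNA copies are annotated but
    excluded from expression quantification.
    """

    copy_id: str
    family_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    biotype: str = "protein"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r} for {self.copy_id}")
        if self.biotype not in VALID_BIOTYPES:
            raise ValidationError(f"bad biotype {self.biotype!r} for {self.copy_id}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"bad coordinates [{self.start}, {self.end}) for {self.copy_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Lineage:
    """A symbiont cell lineage and its relative cell abundance."""

    lineage_id: str
    contig_ids: List[str]
    abundance: float


@dataclass
class SymbiontSystem:
    """A symbiont population: lineages, contigs and the gene catalog.

    ``retention`` maps each protein-coding family to the set of lineages
    that kept a functional copy after splitting; by complementarity the
    union over families covers every ancestral family.
    """

    symbiont_id: str
    lineages: List[Lineage]
    genes: List[GeneCopy]
    retention: Dict[str, Set[str]]
    contig_lengths: Dict[str, int]

    def validate(self) -> None:
        total = sum(l.abundance for l in self.lineages)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"{self.symbiont_id}: lineage abundances sum to {total}, not 1"
            )
        lineage_ids = {l.lineage_id for l in self.lineages}
        for fam, kept in self.retention.items():
            if not kept:
                raise ValidationError(f"family {fam} retained by no lineage")
            if not kept <= lineage_ids:
                raise ValidationError(f"family {fam} retained by unknown lineage")
        for g in self.genes:
            if g.contig_id not in self.contig_lengths:
                raise ValidationError(f"gene {g.copy_id} on unknown contig")
            if g.end > self.contig_lengths[g.contig_id]:
                raise ValidationError(f"gene {g.copy_id} extends past contig end")

    @property
    def lineage_abundance(self) -> Dict[str, float]:
        return {l.lineage_id: l.abundance for l in self.lineages}

    @property
    def contig_lineage(self) -> Dict[str, str]:
        return {c: l.lineage_id for l in self.lineages for c in l.contig_ids}

    def genes_frame(self) -> pd.DataFrame:
        """Gene catalog as a DataFrame (one row per copy)."""
        return genes_to_frame(self.genes)

    def family_dosage(self) -> pd.Series:
        """True relative dosage d_f = summed abundance of retaining lineages."""
        ab = self.lineage_abundance
        return pd.Series(
            {f: sum(ab[l] for l in kept) for f, kept in self.retention.items()},
            name="dosage",
        ).sort_index()

    def with_abundances(self, fractions: Sequence[float]) -> "SymbiontSystem":
        if len(fractions) != len(self.lineages):
            raise ValidationError(
                f"{len(fractions)} fractions for {len(self.lineages)} lineages"
            )
        new = [replace(l, abundance=float(a)) for l, a in zip(self.lineages, fractions)]
        return replace(self, lineages=new)


def genes_to_frame(genes: Sequence[GeneCopy]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "copy_id": [g.copy_id for g in genes],
            "family_id": [g.family_id for g in genes],
            "contig": [g.contig_id for g in genes],
            "start": np.asarray([g.start for g in genes], dtype=np.int64),
            "end": np.asarray([g.end for g in genes], dtype=np.int64),
            "strand": [g.strand for g in genes],
            "biotype": [g.biotype for g in genes],
        }
    )
    df["length"] = df["end"] - df["start"]
    return df


# ---------------------------------------------------------------------------
# Fragments
#
# Sequenced fragments are handled as DataFrames with the columns below: a
# stranded genomic interval already resolved to the transcript strand
# (paired-end flag bookkeeping is treated as solved upstream).

FRAGMENT_COLUMNS = ["contig", "start", "end", "strand", "source"]


def fragments_frame(
    contig: Sequence[str],
    start: Sequence[int],
    end: Sequence[int],
    strand: Sequence[str],
    source: str = "rna",
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "contig": list(contig),
            "start": np.asarray(start, dtype=np.int64),
            "end": np.asarray(end, dtype=np.int64),
            "strand": list(strand),
        }
    )
    df["source"] = source
    if len(df) and not (df["start"] < df["end"]).all():
        raise ValidationError("fragment with start >= end")
    return df


def empty_fragments(source: str = "rna") -> pd.DataFrame:
    return fragments_frame([], [], [], [], source=source)


# ---------------------------------------------------------------------------
# Scenario parameters

SCENARIOS = ("overcompensation", "complementation", "subdivision", "disruption")

#: Defaults for the transcription model. The baseline spread ``sigma_beta``
#: is calibrated so that, under subdivision at a two-lineage 60:40 split,
#: the dosage-expression Kendall tau lands in the empirically observed
#: 0.44-0.58 range; ``sigma_d`` makes disruption noise dominate the dosage
#: ranking (see docs/methods.md).
DEFAULT_MU_BETA = 0.0
DEFAULT_SIGMA_BETA = 0.45
DEFAULT_K_OVER = 4.0
DEFAULT_SIGMA_D = 6.0
DEFAULT_ANTISENSE = 0.05
DEFAULT_RRNA_MULTIPLIER = 20.0


@dataclass
class ScenarioParams:
    """Per-cell transcriptional response to lineage splitting.

    scenario
        ``subdivision``: every copy keeps its presplit rate.
        ``complementation``: copies of dosage-depleted families are
        up-regulated by 1/d_f, rescuing presplit population totals.
        ``overcompensation``: genome-wide up-regulation by factor ``k``.
        ``disruption``: multiplicative lognormal noise ``sigma_d`` per copy.
    """

    scenario: str = "subdivision"
    mu_beta: float = DEFAULT_MU_BETA
    sigma_beta: float = DEFAULT_SIGMA_BETA
    k: float = DEFAULT_K_OVER
    sigma_d: float = DEFAULT_SIGMA_D
    antisense: float = DEFAULT_ANTISENSE
    readthrough: float = 0.0
    rrna_multiplier: float = DEFAULT_RRNA_MULTIPLIER
    seed: int = 0

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "overcompensation" and not self.k > 1:
            raise ValidationError("overcompensation requires k > 1")
        if self.scenario == "disruption" and not self.sigma_d > 0:
            raise ValidationError("disruption requires sigma_d > 0")
        if not 0 <= self.antisense < 1:
            raise ValidationError("antisense proportion must be in [0, 1)")
        if not 0 <= self.readthrough < 1:
            raise ValidationError("readthrough probability must be in [0, 1)")
        if self.sigma_beta < 0:
            raise ValidationError("sigma_beta must be >= 0")


# ---------------------------------------------------------------------------
# Statistical results

@dataclass
class TestResult:
    """A correlation test: estimate, approximation statistic and p-value.

    ``statistic`` is a normal-approximation Z for rank methods and a t value
    for Pearson (with ``df`` = n - 2). ``gn`` counts controlled variables
    (1 for the semipartial test, else 0).
    """

    method: str
    estimate: float
    statistic: float
    p: float
    n: int
    df: Optional[int] = None
    gn: int = 0

    def to_dict(self) -> Dict[str, object]:
        return {
            "method": self.method,
            "estimate": self.estimate,
            "statistic": self.statistic,
            "p": self.p,
            "n": self.n,
            "df": self.df,
            "gn": self.gn,
        }


@dataclass
class ClassificationResult:
    """Scenario call with the evidence it was derived from."""

    label: str
    r_ratio: float
    total_test: Optional[TestResult]
    sp_test: Optional[TestResult]
    alpha: float
    theta_over: float
    annotations: List[str] = field(default_factory=list)

    def to_dict(self) -> Dict[str, object]:
        return {
            "label": self.label,
            "r_ratio": self.r_ratio,
            "total_test": self.total_test.to_dict() if self.total_test else None,
            "sp_test": self.sp_test.to_dict() if self.sp_test else None,
            "alpha": self.alpha,
            "theta_over": self.theta_over,
            "annotations": list(self.annotations),
        }
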