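"""Genome abundance and per-gene relative dosage from DNA coverage.

The relative dosage of a gene family is the fraction of the symbiont's
total DNA sequencing coverage contributed by the contigs that carry at
least one copy of it — 1.0 for a family retained by every lineage, down
to the coverage share of the rarest lineage for a family exclusive to it.
"""

from __future__ import annotations

from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from .model import (
    DegenerateInputError,
    InputError,
    SymbiontSystem,
    UndefinedValueError,
    ValidationError,
)


def contig_coverage_proportions(
    dna_fragments: pd.DataFrame,
    contig_lengths: Mapping[str, int],
    grouping: Mapping[str, str],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Mean depth per contig, symbiont coverage fractions, and within-symbiont
    contig proportions.

    Coverage is the plain length-weighted mean depth: summed overlap bp
    (fragments clipped to the contig) divided by contig length. A
    symbiont's fraction of total coverage is its summed coverage mass
    ``depth * length`` over the mass of all contigs including the host;
    within a symbiont, contig proportions are renormalized to sum to 1.

    Returns ``(summary, per_contig)``: ``summary`` indexed by symbiont with
    ``coverage_mass`` and ``fraction``; ``per_contig`` with
    ``contig, symbiont, mean_depth, fraction, proportion``.
    """
    unknown = set(dna_fragments["contig"]) - set(contig_lengths)
    if unknown:
        raise InputError(f"fragments on unmapped contigs {sorted(unknown)}")
    missing_group = set(contig_lengths) - set(grouping)
    if missing_group:
        raise InputError(f"contigs without symbiont grouping {sorted(missing_group)}")

    lens = pd.Series(dict(contig_lengths), name="length")
    clipped = np.minimum(
        dna_fragments["end"], dna_fragments["contig"].map(lens)
    ) - np.maximum(dna_fragments["start"], 0)
    mass = (
        pd.Series(clipped.to_numpy(), index=dna_fragments["contig"])
        .groupby(level=0)
        .sum()
        .reindex(lens.index, fill_value=0)
        .astype(float)
    )
    if mass.sum() <= 0:
        raise UndefinedValueError("zero total DNA coverage")

    per_contig = pd.DataFrame(
        {
            "contig": lens.index,
            "symbiont": [grouping[c] for c in lens.index],
            "mean_depth": (mass / lens).to_numpy(),
            "fraction": (mass / mass.sum()).to_numpy(),
        }
    )
    group_mass = per_contig.groupby("symbiont")["fraction"].transform("sum")
    with np.errstate(invalid="ignore"):
        per_contig["proportion"] = np.where(
            group_mass > 0, per_contig["fraction"] / group_mass, 0.0
        )
    summary = (
        per_contig.groupby("symbiont")
        .agg(coverage_mass=("fraction", "sum"))
        .rename(columns={"coverage_mass": "fraction"})
    )
    return summary, per_contig


def gene_dosage(
    proportions: pd.Series, system: SymbiontSystem
) -> pd.DataFrame:
    """Per-family relative dosage from within-symbiont contig proportions.

    ``proportions`` is indexed by the focal symbiont's contigs and must sum
    to 1. ``d_f`` sums the proportions of contigs carrying at least one
    copy of family f; families on every contig score exactly 1.0.
    """
    if abs(float(proportions.sum()) - 1.0) > 1e-6:
        raise ValidationError("contig proportions must sum to 1")
    gdf = system.genes_frame()
    prot = gdf[gdf["biotype"] == "protein"]
    carriers = prot.groupby("family_id")["contig"].agg(lambda s: sorted(set(s)))
    missing = set(system.retention) - set(carriers.index)
    if missing:
        raise ValidationError(
            f"families with no surviving copy (complementarity violated): "
            f"{sorted(missing)[:5]}"
        )
    unknown = set(np.concatenate(list(carriers))) - set(proportions.index)
    if unknown:
        raise InputError(f"gene on contig without a proportion: {sorted(unknown)}")
    d = carriers.map(lambda cs: float(proportions[cs].sum())).clip(upper=1.0)
    return pd.DataFrame({"dosage": d}).rename_axis("family_id").sort_index()


def zscore_dosage(dosages: pd.DataFrame) -> pd.DataFrame:
    """Standardize dosages to Z scores (sample sd, n-1 denominator)."""
    d = dosages["dosage"].astype(float)
    if len(d) < 2:
        raise DegenerateInputError("need >= 2 families to standardize")
    sd = float(d.std(ddof=1))
    if sd == 0:
        raise DegenerateInputError("zero dosage variance; Z scores undefined")
    out = dosages.copy()
    out["dosage_z"] = (d - d.mean()) / sd
    return out


def abundance_summary(
    summary_dna: pd.DataFrame, summary_rna: pd.DataFrame
) -> pd.DataFrame:
    """Combine DNA and RNA coverage fractions into one per-symbiont table.

    Inputs are the summaries from :func:`contig_coverage_proportions` run
    on DNA fragments and on (rRNA-filtered) RNA fragments. The result has
    ``dna_frac``, ``rna_frac`` and ``rna_dna_ratio`` per symbiont/host
    category.
    """
    out = pd.DataFrame(
        {
            "dna_frac": summary_dna["fraction"],
            "rna_frac": summary_rna["fraction"],
        }
    ).fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["rna_dna_ratio"] = np.where(
            out["dna_frac"] > 0, out["rna_frac"] / out["dna_frac"], np.nan
        )
    return out


def rna_dna_ratio(
    summary: pd.DataFrame, focal: str, reference: str
) -> Dict[str, float]:
    """RNA%/DNA% coverage ratios for two symbionts and their quotient.

    ``summary`` is the table from :func:`abundance_summary`. The quotient
    ``R = focal_ratio / reference_ratio`` exceeds 1 when the focal
    symbiont produces disproportionately much RNA for its genome
    abundance, the signature screened for genome-wide overcompensation.
    """
    out: Dict[str, float] = {}
    for name, key in ((focal, "focal_ratio"), (reference, "reference_ratio")):
        if name not in summary.index:
            raise InputError(f"symbiont {name!r} missing from coverage summary")
        dna = float(summary.loc[name, "dna_frac"])
        rna = float(summary.loc[name, "rna_frac"])
        if dna <= 0:
            raise UndefinedValueError(f"zero DNA fraction for {name!r}")
        out[key] = rna / dna
    out["R"] = (
        out["focal_ratio"] / out["reference_ratio"]
        if out["reference_ratio"] > 0
        else float("inf")
    )
    return out
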