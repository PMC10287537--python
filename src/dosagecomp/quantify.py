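"""Stranded fragment quantification: fractional counts, TPM, coverage.

Counting follows the fractional-assignment convention for gene-dense
bacterial genomes: a fragment's unit weight is split among the genes it
overlaps on the queried strand in proportion to overlap length, so counts
are fractional but conserve fragment mass. No expectation-maximization
reassignment is performed; proportional splitting is deterministic and
independent of input order.
"""

from __future__ import annotations

import math
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from ncls import NCLS

from .model import InputError, UndefinedValueError, genes_to_frame


def _as_gene_frame(genes) -> pd.DataFrame:
    if isinstance(genes, pd.DataFrame):
        return genes
    return genes_to_frame(list(genes))


def _overlap_pairs(
    frag: pd.DataFrame, genes: pd.DataFrame
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (fragment_row, gene_row, overlap_bp) pairs, per contig."""
    f_idx_all, g_idx_all = [], []
    genes_by_contig = {c: sub for c, sub in genes.groupby("contig", sort=False)}
    for contig, fsub in frag.groupby("contig", sort=False):
        gsub = genes_by_contig.get(contig)
        if gsub is None or not len(gsub):
            continue
        tree = NCLS(
            gsub["start"].to_numpy(np.int64),
            gsub["end"].to_numpy(np.int64),
            np.arange(len(gsub), dtype=np.int64),
        )
        fi, gi = tree.all_overlaps_both(
            fsub["start"].to_numpy(np.int64),
            fsub["end"].to_numpy(np.int64),
            np.arange(len(fsub), dtype=np.int64),
        )
        f_idx_all.append(fsub.index.to_numpy()[fi])
        g_idx_all.append(gsub.index.to_numpy()[gi])
    if not f_idx_all:
        e = np.array([], dtype=np.int64)
        return e, e, e
    f_idx = np.concatenate(f_idx_all)
    g_idx = np.concatenate(g_idx_all)
    olap = np.minimum(
        frag["end"].to_numpy()[f_idx], genes["end"].to_numpy()[g_idx]
    ) - np.maximum(
        frag["start"].to_numpy()[f_idx], genes["start"].to_numpy()[g_idx]
    )
    keep = olap > 0
    return f_idx[keep], g_idx[keep], olap[keep]


def count_fragments(
    fragments: pd.DataFrame,
    genes,
    orientation: str = "sense",
    strict: bool = True,
) -> pd.Series:
    """Fractional per-copy counts of RNA fragments in one orientation.

    ``orientation="sense"`` counts a fragment toward genes on its own
    strand, ``"antisense"`` toward genes on the opposite strand; within the
    qualifying genes the fragment's unit weight is divided proportionally
    to overlap length. Fragments overlapping no qualifying gene contribute
    nothing. With ``strict=True`` a fragment on a contig absent from the
    annotation raises :class:`InputError` (pre-filter fragments to one
    genome, as after a per-genome alignment, to quantify mixed libraries).

    Returns a float Series indexed by ``copy_id`` covering every annotated
    gene (zeros included), with ``attrs["library_size"]`` set to the number
    of fragments overlapping at least one gene on either strand.
    """
    if orientation not in ("sense", "antisense"):
        raise InputError(f"unknown orientation {orientation!r}")
    gdf = _as_gene_frame(genes).reset_index(drop=True)
    frag = fragments.reset_index(drop=True)
    if strict and len(frag):
        known = set(gdf["contig"])
        bad = ~frag["contig"].isin(known)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise InputError(
                f"fragment {i} on unknown contig {frag['contig'].iloc[i]!r}"
            )
    counts = pd.Series(0.0, index=gdf["copy_id"], name=orientation)
    if not len(frag) or not len(gdf):
        counts.attrs["library_size"] = 0
        return counts

    f_idx, g_idx, olap = _overlap_pairs(frag, gdf)
    library_size = int(len(np.unique(f_idx)))
    if len(f_idx):
        f_strand = frag["strand"].to_numpy()[f_idx]
        g_strand = gdf["strand"].to_numpy()[g_idx]
        match = (
            f_strand == g_strand if orientation == "sense" else f_strand != g_strand
        )
        f_idx, g_idx, olap = f_idx[match], g_idx[match], olap[match]
    if len(f_idx):
        denom = np.zeros(len(frag))
        np.add.at(denom, f_idx, olap.astype(float))
        weights = olap / denom[f_idx]
        acc = np.zeros(len(gdf))
        np.add.at(acc, g_idx, weights)
        counts = pd.Series(acc, index=gdf["copy_id"].to_numpy(), name=orientation)
    counts.attrs["library_size"] = library_size
    return counts


def count_both(
    fragments: pd.DataFrame, genes, strict: bool = True
) -> pd.DataFrame:
    """Sense and antisense fractional counts side by side."""
    s = count_fragments(fragments, genes, "sense", strict=strict)
    a = count_fragments(fragments, genes, "antisense", strict=strict)
    return pd.DataFrame({"sense": s, "antisense": a})


def antisense_fraction(
    counts_sense: pd.Series, counts_antisense: pd.Series
) -> float:
    """Antisense counts as a percentage of sense + antisense counts."""
    if not counts_sense.index.equals(counts_antisense.index):
        raise InputError("sense and antisense tables cover different genes")
    s = float(counts_sense.sum())
    a = float(counts_antisense.sum())
    if s + a == 0:
        raise UndefinedValueError("no counts in either orientation")
    if a == 0:
        return 0.0
    return 100.0 * a / (s + a)


def tpm(counts: pd.Series, genes) -> pd.DataFrame:
    """Convert sense counts to transcripts per million.

    Only protein-coding copies enter the normalization universe (rRNA and
    tRNA are excluded); the effective length is the annotated gene length.
    Returns ``copy_id``-indexed DataFrame with ``family_id, length, tpm``.
    """
    gdf = _as_gene_frame(genes)
    prot = gdf[gdf["biotype"] == "protein"].set_index("copy_id")
    if not len(prot):
        raise UndefinedValueError("no protein-coding genes to normalize over")
    missing = prot.index.difference(counts.index)
    if len(missing):
        raise InputError(f"counts missing for copies {list(missing[:5])}")
    c = counts.reindex(prot.index).astype(float)
    rate = c / prot["length"]
    total = rate.sum()
    if total <= 0:
        raise UndefinedValueError("all counts are zero; TPM undefined")
    out = pd.DataFrame(
        {
            "family_id": prot["family_id"],
            "length": prot["length"],
            "tpm": 1e6 * rate / total,
        }
    )
    return out


def filter_rrna(fragments: pd.DataFrame, genes) -> pd.DataFrame:
    """Bioinformatic rRNA depletion.

    Removes every fragment overlapping an rRNA-biotype copy by >= 1 bp on
    either strand; all other fragments pass through with order preserved.
    """
    gdf = _as_gene_frame(genes)
    rrna = gdf[gdf["biotype"] == "rRNA"]
    if not len(rrna) or not len(fragments):
        return fragments.copy()
    frag = fragments.reset_index(drop=True)
    f_idx, _, _ = _overlap_pairs(frag, rrna.reset_index(drop=True))
    drop = np.zeros(len(frag), dtype=bool)
    drop[f_idx] = True
    return fragments.loc[~drop].copy()


def per_base_coverage(
    fragments: pd.DataFrame, contig_lengths: Dict[str, int]
) -> Dict[Tuple[str, str], np.ndarray]:
    """Strand-specific per-base depth arrays, genomecov style.

    Returns ``{(contig, strand): depth}`` for every contig in
    ``contig_lengths`` and both strands.
    """
    tracks = {
        (c, s): np.zeros(length, dtype=np.int64)
        for c, length in contig_lengths.items()
        for s in ("+", "-")
    }
    if len(fragments):
        unknown = ~fragments["contig"].isin(contig_lengths)
        if unknown.any():
            raise InputError(
                f"fragment on unknown contig "
                f"{fragments['contig'][unknown].iloc[0]!r}"
            )
    for (contig, strand), sub in fragments.groupby(["contig", "strand"], sort=False):
        length = contig_lengths[contig]
        if (sub["end"] > length).any() or (sub["start"] < 0).any():
            raise InputError(f"fragment beyond the end of contig {contig!r}")
        diff = np.zeros(length + 1, dtype=np.int64)
        np.add.at(diff, sub["start"].to_numpy(), 1)
        np.add.at(diff, sub["end"].to_numpy(), -1)
        tracks[(contig, strand)] = np.cumsum(diff[:-1])
    return tracks


def downsample(
    fragments: pd.DataFrame,
    target_mean_coverage: float,
    contig_lengths: Dict[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Random subset of fragments achieving roughly a target mean coverage.

    Draws a uniform subset without replacement of size
    ``ceil(target * total_genome_length / mean_fragment_length)``, capped at
    the input size; the same seed always yields the same subset. Input
    order is preserved among the survivors.
    """
    if target_mean_coverage <= 0:
        raise InputError("target coverage must be > 0")
    if not len(fragments):
        return fragments.copy()
    mean_len = float((fragments["end"] - fragments["start"]).mean())
    genome = float(sum(contig_lengths.values()))
    n_target = math.ceil(target_mean_coverage * genome / mean_len)
    if n_target >= len(fragments):
        return fragments.copy()
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(fragments), size=n_target, replace=False))
    return fragments.iloc[keep].copy()
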