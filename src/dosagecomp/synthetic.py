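"""Synthetic split-symbiont systems and sequencing fragments.

Emulates the measurable structure of a bacteriome sequencing experiment:
a focal symbiont split into genome lineages at unequal cell abundances
with complementary gene loss, a structurally stable unsplit reference
symbiont, and a host read background. Transcription follows one of four
scenario models (see :class:`dosagecomp.model.ScenarioParams`); DNA and
RNA fragments are drawn multinomially from the implied analytic weights,
so every downstream statistic has a closed-form ground truth recorded in
the returned truth tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .model import (
    ConfigurationError,
    GeneCopy,
    Lineage,
    ScenarioParams,
    SimulationError,
    SymbiontSystem,
    ValidationError,
    fragments_frame,
)

# ---------------------------------------------------------------------------
# Structural defaults (bp unless noted)

GENE_LENGTH_RANGE = (300, 1500)
SPACER_RANGE = (50, 200)
RRNA_PER_LINEAGE = 2
RRNA_LENGTH = 1500
TRNA_PER_LINEAGE = 4
TRNA_LENGTH = 75
DEFAULT_CORE_FRACTION = 0.05
DEFAULT_SINGLE_LINEAGE_PROB = 0.3
DEFAULT_HOST_DNA_FRACTION = 0.5
DEFAULT_HOST_RNA_FRACTION = 0.3
DEFAULT_HOST_CONTIG_LENGTH = 200_000
DEFAULT_FRAGMENT_LENGTH = 150

#: Approximate genome abundance distributions of documented multi-lineage
#: symbiont complexes, keyed by host species. "single" is the unsplit case.
ABUNDANCE_PRESETS: Dict[str, List[float]] = {
    "single": [1.0],
    "D_semicincta": [1.0],
    "T_ulnaria": [1.0],
    "T_undata": [0.60, 0.40],
    "O_oregona": [0.45, 0.35, 0.18, 0.02],
    "T_limbata": [0.75, 0.10, 0.08, 0.05, 0.02],
}


# ---------------------------------------------------------------------------
# Lineage splitting

def _sample_retention(
    families: Sequence[str],
    lineage_ids: Sequence[str],
    core_fraction: float,
    single_lineage_prob: float,
    rng: np.random.Generator,
) -> Dict[str, set]:
    """Assign each family a nonempty retention set.

    Core families stay in every lineage; the rest are lost down to a single
    lineage with probability ``single_lineage_prob`` or to a random subset
    of >= 2 lineages otherwise (a modeling choice: complementarity fixes
    only that the union covers everything).
    """
    n_lin = len(lineage_ids)
    retention: Dict[str, set] = {}
    for fam in families:
        if n_lin == 1:
            retention[fam] = {lineage_ids[0]}
            continue
        u = rng.random()
        if u < core_fraction:
            kept = set(lineage_ids)
        elif u < core_fraction + single_lineage_prob:
            kept = {lineage_ids[rng.integers(n_lin)]}
        else:
            size = int(rng.integers(2, n_lin + 1))
            kept = set(rng.choice(lineage_ids, size=size, replace=False))
        retention[fam] = kept
    # Repair: every lineage must keep at least one family.
    for lid in lineage_ids:
        if not any(lid in kept for kept in retention.values()):
            fam = families[rng.integers(len(families))]
            retention[fam] = retention[fam] | {lid}
    return retention


def _place_genes_on_contig(
    contig_id: str,
    lineage_id: str,
    fams: Sequence[str],
    fam_lengths: Dict[str, int],
    rng: np.random.Generator,
) -> Tuple[List[GeneCopy], int]:
    """Lay out gene copies with intergenic spacers on alternating strands."""
    genes: List[GeneCopy] = []
    pos = int(rng.integers(*SPACER_RANGE))
    entries = [(f, fam_lengths[f], "protein") for f in fams]
    entries += [
        (f"rRNA_{i + 1}", RRNA_LENGTH, "rRNA") for i in range(RRNA_PER_LINEAGE)
    ]
    entries += [
        (f"tRNA_{i + 1}", TRNA_LENGTH, "tRNA") for i in range(TRNA_PER_LINEAGE)
    ]
    for i, (fam, length, biotype) in enumerate(entries):
        strand = "+" if i % 2 == 0 else "-"
        genes.append(
            GeneCopy(
                copy_id=f"{fam}@{lineage_id}",
                family_id=fam,
                contig_id=contig_id,
                start=pos,
                end=pos + length,
                strand=strand,
                biotype=biotype,
            )
        )
        pos += length + int(rng.integers(*SPACER_RANGE))
    return genes, pos


def simulate_splitting(
    n_families: int,
    n_lineages: int,
    core_fraction: float = DEFAULT_CORE_FRACTION,
    single_lineage_prob: float = DEFAULT_SINGLE_LINEAGE_PROB,
    seed: int = 0,
    symbiont_id: str = "focal",
) -> SymbiontSystem:
    """Generate a symbiont split into ``n_lineages`` complementary lineages.

    One contig per lineage; protein-coding gene lengths are drawn uniformly
    from [300, 1500] bp and each family's length is shared by all of its
    copies. Lineage abundances start equal; see
    :func:`set_lineage_abundances` for presets. rRNA/tRNA copies are added
    per lineage but excluded from the retention map (they are quantified
    nowhere downstream).
    """
    if n_families < 1 or n_lineages < 1:
        raise ConfigurationError("need at least one family and one lineage")
    if not (0 <= core_fraction <= 1 and 0 <= single_lineage_prob <= 1):
        raise ConfigurationError("fractions must be in [0, 1]")
    if core_fraction + single_lineage_prob > 1:
        raise ConfigurationError("core_fraction + single_lineage_prob > 1")
    if n_lineages > n_families:
        raise ConfigurationError(
            f"cannot give each of {n_lineages} lineages a gene "
            f"from only {n_families} families"
        )
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_families)))
    families = [f"fam{i + 1:0{width}d}" for i in range(n_families)]
    lineage_ids = [f"L{i + 1}" for i in range(n_lineages)]
    fam_lengths = {
        f: int(rng.integers(GENE_LENGTH_RANGE[0], GENE_LENGTH_RANGE[1] + 1))
        for f in families
    }
    retention = _sample_retention(
        families, lineage_ids, core_fraction, single_lineage_prob, rng
    )

    genes: List[GeneCopy] = []
    contig_lengths: Dict[str, int] = {}
    lineages: List[Lineage] = []
    for lid in lineage_ids:
        contig_id = f"{symbiont_id}_{lid}"
        fams = [f for f in families if lid in retention[f]]
        placed, length = _place_genes_on_contig(
            contig_id, lid, fams, fam_lengths, rng
        )
        genes.extend(placed)
        contig_lengths[contig_id] = length
        lineages.append(
            Lineage(lineage_id=lid, contig_ids=[contig_id], abundance=1.0 / n_lineages)
        )
    system = SymbiontSystem(
        symbiont_id=symbiont_id,
        lineages=lineages,
        genes=genes,
        retention=retention,
        contig_lengths=contig_lengths,
    )
    system.validate()
    return system


def dirichlet_abundances(
    n: int, concentration: float = 1.0, seed: int = 0
) -> List[float]:
    """Random abundance vector from a symmetric Dirichlet."""
    rng = np.random.default_rng(seed)
    draw = rng.dirichlet([concentration] * n)
    return [float(a) for a in draw]


def set_lineage_abundances(
    system: SymbiontSystem, spec: Union[str, Sequence[float]]
) -> SymbiontSystem:
    """Set lineage cell abundances from a preset name or explicit fractions.

    Explicit fractions are normalized to sum to 1; presets reproduce the
    documented genome abundance distributions (e.g. ``"T_undata"`` ->
    60:40).
    """
    if isinstance(spec, str):
        if spec not in ABUNDANCE_PRESETS:
            raise ValidationError(
                f"unknown preset {spec!r}; known: {sorted(ABUNDANCE_PRESETS)}"
            )
        fractions = ABUNDANCE_PRESETS[spec]
    else:
        fractions = [float(a) for a in spec]
    if not fractions:
        raise ValidationError("empty abundance spec")
    if any(a <= 0 for a in fractions):
        raise ValidationError("abundances must be positive")
    total = sum(fractions)
    fractions = [a / total for a in fractions]
    new = system.with_abundances(fractions)
    new.validate()
    return new


# ---------------------------------------------------------------------------
# Expression rates

def assign_expression_rates(
    system: SymbiontSystem, params: ScenarioParams
) -> pd.DataFrame:
    """Per-copy per-cell transcription rates under the scenario model.

    The family baseline beta_f ~ lognormal(mu_beta, sigma_beta) is drawn
    first from the seeded stream and is identical across scenarios for a
    given seed, so scenario tables for the same seed differ only by the
    scenario transform. rRNA copies get a large fixed multiple of the mean
    baseline and tRNA copies the mean baseline itself; neither enters the
    expression universe downstream.

    Returns a DataFrame with one row per gene copy:
    ``copy_id, family_id, lineage_id, contig, biotype, length, baseline, rate``.
    """
    system.validate()
    params.validate()
    rng = np.random.default_rng(params.seed)
    families = sorted(system.retention)
    beta = pd.Series(
        np.exp(rng.normal(params.mu_beta, params.sigma_beta, size=len(families))),
        index=families,
    )
    dosage = system.family_dosage()

    df = system.genes_frame()
    contig_lineage = system.contig_lineage
    df["lineage_id"] = df["contig"].map(contig_lineage)
    mean_baseline = math.exp(params.mu_beta + 0.5 * params.sigma_beta**2)

    is_protein = df["biotype"] == "protein"
    base = np.where(
        is_protein,
        df["family_id"].map(beta).to_numpy(dtype=float, na_value=np.nan),
        np.where(df["biotype"] == "rRNA", params.rrna_multiplier, 1.0)
        * mean_baseline,
    )
    df["baseline"] = base

    if params.scenario == "subdivision":
        rate = base.copy()
    elif params.scenario == "complementation":
        d = df["family_id"].map(dosage).to_numpy(dtype=float, na_value=1.0)
        rate = np.where(is_protein, base / d, base)
    elif params.scenario == "overcompensation":
        rate = np.where(is_protein, base * params.k, base)
    elif params.scenario == "disruption":
        # Mean-one multiplicative noise: E[eps] = 1 keeps the expected
        # total transcriptional output at its presplit level, so decay
        # scrambles per-gene rates without mimicking genome-wide
        # up-regulation.
        eps = np.exp(
            rng.normal(-0.5 * params.sigma_d**2, params.sigma_d, size=len(df))
        )
        rate = np.where(is_protein, base * eps, base)
    else:  # pragma: no cover - guarded by params.validate()
        raise ValidationError(f"unknown scenario {params.scenario!r}")
    df["rate"] = rate
    if not (df["rate"] > 0).all():
        raise SimulationError("non-positive transcription rate")
    return df


# ---------------------------------------------------------------------------
# Fragment simulation

@dataclass
class SystemSet:
    """Focal + reference symbionts and the host background weight."""

    focal: SymbiontSystem
    reference: Optional[SymbiontSystem] = None
    host_contig_length: int = DEFAULT_HOST_CONTIG_LENGTH
    host_dna_fraction: float = DEFAULT_HOST_DNA_FRACTION
    host_rna_fraction: float = DEFAULT_HOST_RNA_FRACTION

    @property
    def systems(self) -> List[SymbiontSystem]:
        out = [self.focal]
        if self.reference is not None:
            out.append(self.reference)
        return out

    def contig_lengths(self) -> Dict[str, int]:
        lengths: Dict[str, int] = {}
        for sys in self.systems:
            lengths.update(sys.contig_lengths)
        lengths["host"] = self.host_contig_length
        return lengths

    def contig_groups(self) -> Dict[str, str]:
        groups = {"host": "host"}
        for sys in self.systems:
            for c in sys.contig_lengths:
                groups[c] = sys.symbiont_id
        return groups


def _uniform_starts(
    lengths: np.ndarray, fragment_length: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform fragment start within [0, length - fragment_length]."""
    span = np.maximum(lengths - fragment_length, 0)
    return np.floor(rng.random(len(lengths)) * (span + 1)).astype(np.int64)


def simulate_fragments(
    systems: SystemSet,
    rates: pd.DataFrame,
    depth_dna: int,
    depth_rna: int,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    params: Optional[ScenarioParams] = None,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, pd.DataFrame]]:
    """Draw stranded DNA and RNA fragments from the system's analytic weights.

    DNA fragments are multinomially allocated to contigs with weight
    ``a_l * contig_length`` (host as its own category sized so its expected
    share equals ``host_dna_fraction``) and placed uniformly with a random
    strand. Sense RNA fragments are allocated to gene copies with weight
    ``a_l * rate * length`` and placed within the gene on its strand; with
    probability ``params.antisense`` a gene fragment is flipped to the
    opposite strand, so the expected antisense share of gene-overlapping
    RNA fragments is exactly the antisense parameter. With probability
    ``params.readthrough`` a fragment's placement window slides past the
    gene's 3' end (run-on transcription).

    ``rates`` may cover one system or the concatenated tables of several
    (see :func:`assign_expression_rates`); copies are matched by contig.

    Returns ``(dna, rna, truth)`` where ``truth`` carries the analytic
    tables: per-lineage abundances, per-family dosage and baseline, per-copy
    rates with expected fragment shares and expected TPM, and per-contig
    DNA weights.
    """
    if params is None:
        params = ScenarioParams()
    params.validate()
    if depth_dna < 0 or depth_rna < 0:
        raise ValidationError("depths must be >= 0")
    rng = np.random.default_rng(seed)

    contig_lengths = systems.contig_lengths()
    if fragment_length >= min(contig_lengths.values()):
        raise ValidationError("fragment_length must be below the shortest contig")

    # --- DNA ---------------------------------------------------------------
    contigs = [c for c in contig_lengths if c != "host"]
    abundance: Dict[str, float] = {}
    for sys in systems.systems:
        lin_ab = sys.lineage_abundance
        for c, lid in sys.contig_lineage.items():
            abundance[c] = lin_ab[lid]
    dna_weights = np.array(
        [abundance[c] * contig_lengths[c] for c in contigs], dtype=float
    )
    if dna_weights.sum() <= 0:
        raise SimulationError("all DNA weights are zero")
    hf = systems.host_dna_fraction
    host_w = hf / (1.0 - hf) * dna_weights.sum() if hf > 0 else 0.0
    all_contigs = contigs + ["host"]
    w = np.append(dna_weights, host_w)
    dna_probs = w / w.sum()

    if depth_dna > 0:
        counts = rng.multinomial(depth_dna, dna_probs)
        rep_contig = np.repeat(np.arange(len(all_contigs)), counts)
        lens = np.array([contig_lengths[c] for c in all_contigs])[rep_contig]
        starts = _uniform_starts(lens, fragment_length, rng)
        strands = np.where(rng.random(len(starts)) < 0.5, "+", "-")
        dna = fragments_frame(
            [all_contigs[i] for i in rep_contig],
            starts,
            starts + fragment_length,
            strands,
            source="dna",
        )
    else:
        dna = fragments_frame([], [], [], [], source="dna")

    # --- RNA ---------------------------------------------------------------
    r = rates.copy()
    missing = set(r["contig"]) - set(contig_lengths)
    if missing:
        raise ValidationError(f"rates reference unknown contigs {sorted(missing)}")
    r["abundance"] = r["contig"].map(abundance)
    r["weight"] = r["abundance"] * r["rate"] * r["length"]
    if not len(r) or r["weight"].sum() <= 0:
        raise SimulationError("all RNA weights are zero")
    hr = systems.host_rna_fraction
    host_rw = hr / (1.0 - hr) * r["weight"].sum() if hr > 0 else 0.0
    rna_w = np.append(r["weight"].to_numpy(), host_rw)
    rna_probs = rna_w / rna_w.sum()

    if depth_rna > 0:
        counts = rng.multinomial(depth_rna, rna_probs)
        gene_counts, host_count = counts[:-1], counts[-1]
        idx = np.repeat(np.arange(len(r)), gene_counts)
        g_start = r["start"].to_numpy()[idx]
        g_end = r["end"].to_numpy()[idx]
        g_strand = np.asarray(r["strand"])[idx]
        g_contig = np.asarray(r["contig"])[idx]
        clens = np.array([contig_lengths[c] for c in g_contig])

        # Fragments from genes shorter than fragment_length are capped at
        # the gene length so they never spill into a neighboring gene.
        frag_lens = np.minimum(fragment_length, g_end - g_start)
        span = g_end - g_start - frag_lens
        offset = np.floor(rng.random(len(idx)) * (span + 1)).astype(np.int64)
        starts = g_start + offset
        if params.readthrough > 0:
            run_on = rng.random(len(idx)) < params.readthrough
            shift = rng.integers(1, fragment_length + 1, size=len(idx))
            plus = g_strand == "+"
            starts = np.where(run_on & plus, g_end - frag_lens + shift, starts)
            starts = np.where(run_on & ~plus, g_start - shift, starts)
        starts = np.clip(starts, 0, clens - frag_lens)

        anti = rng.random(len(idx)) < params.antisense
        flipped = np.where(g_strand == "+", "-", "+")
        strands = np.where(anti, flipped, g_strand)

        host_starts = _uniform_starts(
            np.full(host_count, systems.host_contig_length), fragment_length, rng
        )
        host_strands = np.where(rng.random(host_count) < 0.5, "+", "-")
        rna = fragments_frame(
            list(g_contig) + ["host"] * host_count,
            np.concatenate([starts, host_starts]),
            np.concatenate([starts + frag_lens, host_starts + fragment_length]),
            list(strands) + list(host_strands),
            source="rna",
        )
    else:
        rna = fragments_frame([], [], [], [], source="rna")

    # --- truth tables ------------------------------------------------------
    copies = r.drop(columns=["weight"]).copy()
    copies["expected_share"] = rna_probs[:-1] * (1.0 - params.antisense)
    tpm_truth = []
    for sys in systems.systems:
        sub = copies[
            (copies["contig"].map(systems.contig_groups()) == sys.symbiont_id)
            & (copies["biotype"] == "protein")
        ].copy()
        dens = sub["abundance"] * sub["rate"]
        sub["expected_tpm"] = 1e6 * dens / dens.sum()
        tpm_truth.append(sub)
    truth = {
        "lineages": pd.concat(
            [
                pd.DataFrame(
                    {
                        "symbiont": sys.symbiont_id,
                        "lineage_id": [l.lineage_id for l in sys.lineages],
                        "abundance": [l.abundance for l in sys.lineages],
                    }
                )
                for sys in systems.systems
            ],
            ignore_index=True,
        ),
        "families": pd.concat(
            [
                sys.family_dosage()
                .rename("dosage")
                .rename_axis("family_id")
                .reset_index()
                .assign(symbiont=sys.symbiont_id)
                for sys in systems.systems
            ],
            ignore_index=True,
        ),
        "copies": pd.concat(tpm_truth, ignore_index=True),
        "dna_contigs": pd.DataFrame(
            {"contig": all_contigs, "weight": w, "prob": dna_probs}
        ),
    }
    return dna, rna, truth
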