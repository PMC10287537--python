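"""End-to-end orchestration: simulate, quantify, test, classify.

The pipeline mirrors the analysis order of a bacteriome sequencing study:
DNA coverage -> genome/lineage abundances -> per-gene relative dosage;
RNA fragments -> rRNA depletion -> stranded counts -> TPM -> homolog
totals -> dosage-expression tests -> scenario call.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .model import (
    ClassificationResult,
    DegenerateInputError,
    DosagecompError,
    ScenarioParams,
    TestResult,
    UndefinedValueError,
)
from .synthetic import (
    SystemSet,
    assign_expression_rates,
    set_lineage_abundances,
    simulate_fragments,
    simulate_splitting,
)
from .quantify import antisense_fraction, count_fragments, filter_rrna, tpm
from .dosage import (
    abundance_summary,
    contig_coverage_proportions,
    gene_dosage,
    rna_dna_ratio,
    zscore_dosage,
)
from .inference import (
    classify_scenario,
    dosage_expression_test,
    semipartial_kendall,
    sum_homolog_tpm,
)
from .io import RunConfig, write_bed, write_fasta, write_gff3

logger = logging.getLogger("dosagecomp")


def derive_seeds(seed: int, n: int) -> list:
    """Deterministic named sub-seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def simulate_experiment(config: RunConfig):
    """Build the system set, rates and fragments a config describes.

    Returns ``(systems, rates, dna, rna, truth)``. The reference symbiont
    is always unsplit and transcribes under subdivision (its stability is
    the experimental contrast).
    """
    config.validate()
    s_focal, s_ref, s_rates, s_ref_rates, s_frag = derive_seeds(config.seed, 5)
    n_lineages = (
        len(config.abundances)
        if isinstance(config.abundances, (list, tuple))
        else {
            "single": 1,
            "D_semicincta": 1,
            "T_ulnaria": 1,
            "T_undata": 2,
            "O_oregona": 4,
            "T_limbata": 5,
        }.get(config.abundances, config.n_lineages)
    )
    focal = simulate_splitting(
        config.n_families,
        n_lineages,
        core_fraction=config.core_fraction,
        single_lineage_prob=config.single_lineage_prob,
        seed=s_focal,
        symbiont_id="focal",
    )
    focal = set_lineage_abundances(focal, config.abundances)
    reference = simulate_splitting(
        config.reference_families, 1, seed=s_ref, symbiont_id="reference"
    )
    systems = SystemSet(
        focal=focal,
        reference=reference,
        host_contig_length=config.host_contig_length,
        host_dna_fraction=config.host_dna_fraction,
        host_rna_fraction=config.host_rna_fraction,
    )
    params = ScenarioParams(
        scenario=config.scenario,
        mu_beta=config.mu_beta,
        sigma_beta=config.sigma_beta,
        k=config.k,
        sigma_d=config.sigma_d,
        antisense=config.antisense,
        readthrough=config.readthrough,
        rrna_multiplier=config.rrna_multiplier,
        seed=s_rates,
    )
    ref_params = ScenarioParams(
        scenario="subdivision",
        mu_beta=config.mu_beta,
        sigma_beta=config.sigma_beta,
        antisense=config.antisense,
        rrna_multiplier=config.rrna_multiplier,
        seed=s_ref_rates,
    )
    rates = pd.concat(
        [
            assign_expression_rates(focal, params),
            assign_expression_rates(reference, ref_params),
        ],
        ignore_index=True,
    )
    dna, rna, truth = simulate_fragments(
        systems,
        rates,
        depth_dna=config.depth_dna,
        depth_rna=config.depth_rna,
        fragment_length=config.fragment_length,
        params=params,
        seed=s_frag,
    )
    return systems, rates, dna, rna, truth


def analyze_experiment(
    systems: SystemSet,
    dna: pd.DataFrame,
    rna: pd.DataFrame,
    alpha: float = 0.05,
    theta_over: float = 2.0,
) -> Dict[str, object]:
    """Quantify and test one experiment; returns the full report dict.

    Keys: ``summary`` (per-symbiont DNA/RNA fractions), ``per_contig``,
    ``ratios`` (RNA:DNA ratio pair and R), ``dosage``, ``expression``
    (per-copy TPM), ``family_tpm``, ``antisense_pct``, ``total_test``,
    ``sp_test``, ``classification``. Tests are ``None`` for degenerate
    systems (e.g. a single-lineage focal symbiont has no dosage variance).
    """
    focal = systems.focal
    lengths = systems.contig_lengths()
    groups = systems.contig_groups()

    summary_dna, per_contig = contig_coverage_proportions(dna, lengths, groups)
    all_genes = pd.concat(
        [s.genes_frame() for s in systems.systems], ignore_index=True
    )
    rna_filtered = filter_rrna(rna, all_genes)
    summary_rna, _ = contig_coverage_proportions(rna_filtered, lengths, groups)
    summary = abundance_summary(summary_dna, summary_rna)
    ref_id = systems.reference.symbiont_id if systems.reference else None
    ratios = (
        rna_dna_ratio(summary, focal.symbiont_id, ref_id) if ref_id else None
    )

    focal_prop = (
        per_contig[per_contig["symbiont"] == focal.symbiont_id]
        .set_index("contig")["proportion"]
    )
    dosage_table = gene_dosage(focal_prop, focal)
    try:
        dosage_table = zscore_dosage(dosage_table)
    except DegenerateInputError:
        pass

    fgenes = focal.genes_frame()
    prot = fgenes[fgenes["biotype"] == "protein"].reset_index(drop=True)
    rna_focal = rna_filtered[
        rna_filtered["contig"].isin(focal.contig_lengths)
    ].reset_index(drop=True)
    sense = count_fragments(rna_focal, prot, "sense")
    anti = count_fragments(rna_focal, prot, "antisense")
    try:
        anti_pct = antisense_fraction(sense, anti)
    except UndefinedValueError:
        anti_pct = None
    expr = tpm(sense, prot)
    family_tpm = sum_homolog_tpm(expr, focal)

    total_test: Optional[TestResult] = None
    sp_test: Optional[TestResult] = None
    classification: Optional[ClassificationResult] = None
    try:
        total_test = dosage_expression_test(dosage_table["dosage"], family_tpm)
        x = expr["tpm"].to_numpy()
        y = expr["family_id"].map(dosage_table["dosage"]).to_numpy(dtype=float)
        copy_contig = prot.set_index("copy_id")["contig"]
        z = expr.index.map(copy_contig).map(focal_prop).to_numpy(dtype=float)
        sp_test = semipartial_kendall(x, y, z)
        if ratios is not None:
            classification = classify_scenario(
                ratios, total_test, sp_test, alpha=alpha, theta_over=theta_over
            )
    except DegenerateInputError as err:
        logger.info("tests skipped: %s", err)

    return {
        "summary": summary,
        "per_contig": per_contig,
        "ratios": ratios,
        "dosage": dosage_table,
        "expression": expr,
        "family_tpm": family_tpm,
        "antisense_pct": anti_pct,
        "total_test": total_test,
        "sp_test": sp_test,
        "classification": classification,
    }


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise DosagecompError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig, outdir: Union[str, Path]) -> Dict[str, object]:
    """Simulate, quantify, test and classify; write all outputs to outdir.

    Identical configs produce byte-identical outputs. Returns the in-memory
    report from :func:`analyze_experiment`.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("simulate"):
        systems, rates, dna, rna, truth = simulate_experiment(config)
    with _stage("write-inputs"):
        config.save(outdir / "config.yaml")
        write_fasta(systems.contig_lengths(), outdir / "contigs.fasta", config.seed)
        genes = [g for s in systems.systems for g in s.genes]
        write_gff3(genes, outdir / "genes.gff3")
        write_bed(dna, outdir / "dna.bed")
        write_bed(rna, outdir / "rna.bed")
        for name, frame in truth.items():
            frame.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)
    with _stage("analyze"):
        report = analyze_experiment(
            systems, dna, rna, alpha=config.alpha, theta_over=config.theta_over
        )
    with _stage("write-results"):
        report["summary"].to_csv(outdir / "abundance_summary.tsv", sep="\t")
        report["per_contig"].to_csv(
            outdir / "contig_proportions.tsv", sep="\t", index=False
        )
        report["dosage"].to_csv(outdir / "dosage.tsv", sep="\t")
        report["expression"].to_csv(outdir / "expression.tsv", sep="\t")
        report["family_tpm"].to_csv(outdir / "family_tpm.tsv", sep="\t")
        (outdir / "report.json").write_text(report_json(report, config))
    logger.info("pipeline complete: %s", outdir)
    return report


def report_json(report: Dict[str, object], config: Optional[RunConfig] = None) -> str:
    """Serialize the test/classification portion of a report to JSON."""
    payload: Dict[str, object] = {
        "version": __version__,
        "antisense_pct": report["antisense_pct"],
        "ratios": report["ratios"],
        "total_test": report["total_test"].to_dict()
        if report["total_test"]
        else None,
        "sp_test": report["sp_test"].to_dict() if report["sp_test"] else None,
        "classification": report["classification"].to_dict()
        if report["classification"]
        else None,
    }
    if config is not None:
        payload["config"] = config.to_dict()
    return json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n"
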