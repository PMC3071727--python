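"""End-to-end orchestration and direction-consistency integration.

Stage order: miRNA differential expression -> transcript differential
expression -> iTRAQ protein quantification -> eight cross-layer gene sets ->
degree-preserving target enrichment -> integration with miRNA expression
direction. A family's significant cells are classified against the dogma of
miRNA regulation: a family up-regulated in tissue T whose targets are
enriched in a set down-regulated in T is a consistent target signal
(repression); a family up in T whose targets are depleted among genes up in
T is a consistent anti-target signal (co-expressed genes avoiding the
family's sites). Everything else with a significant cell is inconsistent,
and significant cells of families without differential expression are
reported as mirna_not_de, never suppressed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import integration_sets, itraq_quant, mirna_diffexp, mrna_diffexp
from .data_io import (
    ExpressionMatrix,
    GeneSetCollection,
    PeptideQuantTable,
    TargetPredictionTable,
    TwoColorMirnaArray,
    write_results,
)
from .integration_sets import LayerCorrelation, set_down_tissue, set_layer
from .target_enrichment import test_all

logger = logging.getLogger(__name__)


@dataclass
class StudyTables:
    """The four input tables plus the probe -> family annotation.

    Any object with these attributes (e.g. a generated synthetic study) can
    be passed to :func:`run_study`.
    """

    mirna_arrays: TwoColorMirnaArray
    expression: ExpressionMatrix
    peptides: PeptideQuantTable
    predictions: TargetPredictionTable
    probe_to_family: dict[str, str]


@dataclass(frozen=True)
class RunConfig:
    """Every stage threshold, recorded verbatim in the run manifest."""

    mirna_fold: float = 1.25
    mirna_alpha: float = 0.05
    detection_k_sd: float = 2.0
    detection_min_samples: int = 2
    mrna_fold: float = 1.3
    mrna_fdr: float = 0.1
    protein_fold: float = 1.3
    min_peptides: int = 3
    channel_of_a: int = 114
    n_perm: int = 10_000
    alpha_enrichment: float = 0.05
    seed: int = 0
    layers: tuple[str, ...] = ("mrna", "protein")

    def __post_init__(self) -> None:
        for name in ("mirna_fold", "mrna_fold", "protein_fold"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("mirna_alpha", "mrna_fdr", "alpha_enrichment"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class PipelineResult:
    mirna_probes: pd.DataFrame
    mirna_families: pd.DataFrame
    n_families_without_probes: int
    mrna: pd.DataFrame
    proteins: pd.DataFrame
    sets: GeneSetCollection
    correlation: LayerCorrelation | None
    enrichment: pd.DataFrame
    integrated: pd.DataFrame
    manifest: dict


def direction_consistency(
    family_summary: pd.DataFrame,
    enrichment: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify every (family, set) significant cell against miRNA dogma.

    Output has one row per significant cell plus a per-family verdict:
    consistent_target beats consistent_antitarget beats inconsistent when a
    family has several cells; families with cells but no differential
    expression are mirna_not_de.
    """
    cells = []
    sig = enrichment.loc[
        (enrichment["p_enrich"] < alpha) | (enrichment["p_deplete"] < alpha)
    ]
    for _, row in sig.iterrows():
        fam = row["family_id"]
        set_name = row["set_name"]
        down_tissue = set_down_tissue(set_name)
        if fam in family_summary.index:
            fam_dir = family_summary.loc[fam, "direction"]
            fam_ratio = float(family_summary.loc[fam, "mean_log2_ratio"])
        else:
            fam_dir, fam_ratio = "not_de", np.nan
        for tail, p in (("enriched", row["p_enrich"]), ("depleted", row["p_deplete"])):
            if not (pd.notna(p) and p < alpha):
                continue
            if fam_dir == "not_de":
                verdict = "mirna_not_de"
            else:
                fam_up = fam_dir.removeprefix("up_in_")
                if tail == "enriched":
                    # targets repressed where the family is high
                    verdict = (
                        "consistent_target" if down_tissue == fam_up else "inconsistent"
                    )
                else:
                    # anti-targets: depletion among genes up where the family is high
                    verdict = (
                        "consistent_antitarget"
                        if down_tissue != fam_up
                        else "inconsistent"
                    )
            cells.append(
                {
                    "family_id": fam,
                    "set_name": set_name,
                    "tail": tail,
                    "p": float(p),
                    "family_direction": fam_dir,
                    "family_log2_ratio": fam_ratio,
                    "cell_consistency": verdict,
                }
            )
    cell_df = pd.DataFrame(
        cells,
        columns=[
            "family_id",
            "set_name",
            "tail",
            "p",
            "family_direction",
            "family_log2_ratio",
            "cell_consistency",
        ],
    )
    rank = {
        "consistent_target": 0,
        "consistent_antitarget": 1,
        "inconsistent": 2,
        "mirna_not_de": 3,
    }
    verdicts = (
        cell_df.groupby("family_id")["cell_consistency"]
        .agg(lambda v: min(v, key=rank.__getitem__))
        .rename("consistency")
    )
    return cell_df.merge(verdicts, on="family_id", how="left")


def _filter_sets_for_layers(
    sets: GeneSetCollection, layers: tuple[str, ...]
) -> GeneSetCollection:
    keep = {
        name
        for name in sets.sets
        if (set_layer(name) == "mrna" and "mrna" in layers)
        or (set_layer(name) in ("protein", "joint") and "protein" in layers)
    }
    return GeneSetCollection(
        {n: sets.sets[n] for n in keep}, {n: sets.universes[n] for n in keep}
    )


def run_study(study: StudyTables, config: RunConfig | None = None) -> PipelineResult:
    """Run the full integration pipeline on an in-memory study."""
    config = config or RunConfig()

    # miRNA layer
    probes = mirna_diffexp.mirna_de(
        study.mirna_arrays,
        fold_threshold=config.mirna_fold,
        alpha=config.mirna_alpha,
        k_sd=config.detection_k_sd,
        min_samples=config.detection_min_samples,
    )
    families, n_without = mirna_diffexp.map_to_families(
        probes, study.probe_to_family, families=study.predictions.families
    )

    # transcript layer
    matrix = mrna_diffexp.quantile_normalize(study.expression)
    matrix = mrna_diffexp.presence_filter(matrix)
    mrna = mrna_diffexp.diffexp_mrna(
        matrix, fold=config.mrna_fold, fdr=config.mrna_fdr
    )

    # protein layer
    proteins = itraq_quant.itraq_protein_table(
        study.peptides,
        channel_of_a=config.channel_of_a,
        min_peptides=config.min_peptides,
        fold=config.protein_fold,
    )

    # cross-layer sets and correlation
    sets = integration_sets.build_eight_sets(mrna, proteins)
    sets = _filter_sets_for_layers(sets, config.layers)
    correlation = None
    if "protein" in config.layers:
        protein_log2 = np.log2(proteins.loc[proteins["valid"], "ratio_a_over_b"])
        correlation = integration_sets.layer_correlation(
            mrna["mean_log2_fold"], protein_log2
        )

    # permutation test and integration
    enrichment = test_all(
        study.predictions,
        sets,
        n_perm=config.n_perm,
        seed=config.seed,
        alpha=config.alpha_enrichment,
    )
    integrated = direction_consistency(
        families, enrichment, alpha=config.alpha_enrichment
    )

    manifest = {
        "config": asdict(config),
        "study_seed": getattr(getattr(study, "config", None), "seed", None),
        "counts": {
            "probes": int(len(probes)),
            "probes_detected_any": int(
                (probes["detected_in_A"] | probes["detected_in_B"]).sum()
            ),
            "mirna_de": int((probes["de_call"] != "not_de").sum()),
            "families_testable": int(len(families)),
            "families_without_probes": int(n_without),
            "genes_after_presence_filter": int(len(mrna)),
            "mrna_de": int((mrna["de_call"] != "not_de").sum()),
            "proteins": int(len(proteins)),
            "proteins_valid": int(proteins["valid"].sum()),
            "proteins_de": int((proteins["abundance_call"] != "none").sum()),
            "set_sizes": {n: len(sets.sets[n]) for n in sorted(sets.sets)},
            "significant_cells": int(
                (
                    (enrichment["p_enrich"] < config.alpha_enrichment)
                    | (enrichment["p_deplete"] < config.alpha_enrichment)
                ).sum()
            ),
        },
    }
    return PipelineResult(
        mirna_probes=probes,
        mirna_families=families,
        n_families_without_probes=n_without,
        mrna=mrna,
        proteins=proteins,
        sets=sets,
        correlation=correlation,
        enrichment=enrichment,
        integrated=integrated,
        manifest=manifest,
    )


def write_result_bundle(result: PipelineResult, directory: str | Path) -> None:
    """Write every stage table plus the JSON run manifest to ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_results(
        result.mirna_probes.reset_index(), directory / "mirna_probes.tsv"
    )
    write_results(
        result.mirna_families.reset_index(), directory / "mirna_families.tsv"
    )
    write_results(result.mrna.reset_index(names="gene_id"), directory / "mrna_de.tsv")
    write_results(
        result.proteins.reset_index(names="protein_id"), directory / "proteins.tsv"
    )
    write_results(result.enrichment, directory / "enrichment.tsv")
    write_results(result.integrated, directory / "integrated_calls.tsv")
    from .data_io import write_gmt

    write_gmt(result.sets, directory / "sets.gmt")
    manifest = dict(result.manifest)
    if result.correlation is not None:
        manifest["layer_correlation"] = {
            "spearman_rho": result.correlation.spearman_rho,
            "spearman_p": result.correlation.spearman_p,
            "pearson_r": result.correlation.pearson_r,
            "n": result.correlation.n,
        }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
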