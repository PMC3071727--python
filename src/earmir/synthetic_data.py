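"""Synthetic paired-tissue studies with planted miRNA-driven suppression.

A generated study mirrors the design of the inner-ear comparison that
motivates this package: two tissues (A, the vestibule analog; B, the cochlea
analog), three biological replicates each, a two-color miRNA array with
dye-swapped technical pairs, a log-normal transcript matrix with presence
flags, a peptide-level iTRAQ table, and a TargetScan-style prediction table.

Planted miRNA families are up-regulated in tissue A by a configurable fold
and suppress a fraction of their predicted targets in that tissue at one of
three layers:

* ``mRNA`` — the transcript ratio is shifted by log2(1 - suppression); the
  protein layer is left at its unshifted value (destabilization that the
  proteomics screen fails to resolve).
* ``protein`` — both the transcript and the protein ratios are shifted
  (canonical mRNA-destabilizing regulation, visible at both layers).
* ``protein_only`` — only the protein ratio is shifted (translational
  suppression; the transcript expectation stays at zero).

Every source of randomness derives from the master seed through one
``numpy`` SeedSequence child per data layer, so changing one layer's
parameters never perturbs the draws of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .data_io import (
    ExpressionMatrix,
    PeptideQuantTable,
    TargetPredictionTable,
    TwoColorMirnaArray,
    sha256_of,
    write_expression_tsv,
    write_manifest,
    write_mirna_array_tsv,
    write_peptide_tsv,
    write_targetscan,
)

Layer = Literal["mRNA", "protein", "protein_only"]


class ConfigError(ValueError):
    """Raised when a synthetic-study configuration violates an invariant."""


@dataclass(frozen=True)
class PlantedFamily:
    """One miRNA family with planted target suppression in tissue A."""

    family_id: str
    layer: Layer
    suppression: float  # mean suppression fraction, open interval (0, 1)
    fraction_targets: float  # fraction of the family's targets affected


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters; defaults match the emulated experiment."""

    n_genes: int = 500
    n_families: int = 20
    n_mirnas_per_family: int = 2
    targets_per_family: int = 40
    n_replicates: int = 3  # biological replicates per tissue
    planted_families: tuple[PlantedFamily, ...] = ()
    mirna_fold_for_planted: float = 2.5

    # noise (all on the log2 scale unless stated otherwise)
    mirna_signal_log2_sd: float = 0.15
    mrna_log2_sd: float = 0.1
    peptide_log2_sd: float = 0.1

    # miRNA array background (intensity units, Gaussian truncated at 0)
    background_mean: float = 200.0
    background_sd: float = 30.0
    mirna_signal_mean: float = 3000.0
    dye_bias: float = 1.15  # multiplicative Hy5/Hy3 labeling bias

    # iTRAQ
    itraq_channel_bias: float = 1.2  # global 114/115 loading bias
    min_peptides: int = 3
    max_peptides: int = 8
    fraction_low_peptide_proteins: float = 0.0  # emit 1-2-peptide proteins

    # coverage / filtering structure
    protein_fraction: float = 0.5  # fraction of genes measured at protein level
    fraction_absent_genes: float = 0.05  # all-'A' presence-flag rows
    n_null_probes: int = 140  # expressed probes without family annotation
    n_unexpressed_probes: int = 20  # decoy probes with no true signal
    families_without_probes: int = 0  # families present only in predictions
    conserved_site_prob: float = 0.7

    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_families": self.n_families,
            "n_mirnas_per_family": self.n_mirnas_per_family,
            "targets_per_family": self.targets_per_family,
            "n_replicates": self.n_replicates,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigError(f"{name} must be >= 1, got {value}")
        if self.targets_per_family > self.n_genes:
            raise ConfigError("targets_per_family cannot exceed n_genes")
        if self.mirna_fold_for_planted < 1:
            raise ConfigError("mirna_fold_for_planted must be >= 1")
        if self.families_without_probes >= self.n_families:
            raise ConfigError("families_without_probes must leave probed families")
        family_ids = set(self.family_ids())
        for pf in self.planted_families:
            if pf.family_id not in family_ids:
                raise ConfigError(f"planted family {pf.family_id!r} not generated")
            if not 0.0 < pf.suppression < 1.0:
                raise ConfigError(
                    f"suppression must lie in (0,1), got {pf.suppression}"
                )
            if not 0.0 < pf.fraction_targets <= 1.0:
                raise ConfigError("fraction_targets must lie in (0,1]")
            if pf.layer not in ("mRNA", "protein", "protein_only"):
                raise ConfigError(f"unknown planted layer {pf.layer!r}")

    def family_ids(self) -> list[str]:
        return [f"FAM{i:03d}" for i in range(1, self.n_families + 1)]

    def gene_ids(self) -> list[str]:
        return [f"GENE{i:04d}" for i in range(1, self.n_genes + 1)]


@dataclass(frozen=True)
class FamilyTruth:
    direction: str  # 'up_in_A'
    layer: Layer
    suppressed_genes: frozenset[str]


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: directions, suppressed targets, true layer ratios."""

    families: dict[str, FamilyTruth]
    mirna_probe_log2_ratio: dict[str, float]  # probe -> true log2(A/B)
    mrna_log2_ratio: dict[str, float]  # gene -> true log2(A/B)
    protein_log2_ratio: dict[str, float]  # gene -> true log2(A/B)


@dataclass(frozen=True)
class SyntheticStudy:
    config: SyntheticConfig
    mirna_arrays: TwoColorMirnaArray
    expression: ExpressionMatrix
    peptides: PeptideQuantTable
    predictions: TargetPredictionTable
    truth: GroundTruth
    probe_to_family: dict[str, str]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _layer_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ("predictions", "mirna", "mrna", "protein")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _generate_predictions(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[TargetPredictionTable, dict[str, list[str]], dict[str, list[str]]]:
    """Prediction table plus family -> targets and family -> suppressed maps."""
    genes = np.array(config.gene_ids())
    rows = []
    targets_of: dict[str, list[str]] = {}
    suppressed_of: dict[str, list[str]] = {}
    planted = {pf.family_id: pf for pf in config.planted_families}
    for fam in config.family_ids():
        targets = list(rng.choice(genes, size=config.targets_per_family, replace=False))
        targets_of[fam] = targets
        pf = planted.get(fam)
        n_sup = math.ceil(pf.fraction_targets * len(targets)) if pf else 0
        suppressed = targets[:n_sup]
        suppressed_of[fam] = suppressed
        for gene in targets:
            n_sites = 1 + int(rng.random() < 0.3)
            for s in range(n_sites):
                score = -abs(rng.normal(0.25, 0.1))
                score = min(score, -0.01)
                conserved = bool(rng.random() < config.conserved_site_prob)
                if gene in suppressed and s == 0:
                    conserved = True  # suppressed targets carry a conserved site
                rows.append((fam, gene, round(score, 4), conserved))
    df = pd.DataFrame(
        rows, columns=["family_id", "gene_id", "site_context_score", "conserved"]
    ).drop_duplicates()
    return TargetPredictionTable(df.reset_index(drop=True)), targets_of, suppressed_of


def _true_ratios(
    config: SyntheticConfig, suppressed_of: dict[str, list[str]]
) -> tuple[dict[str, float], dict[str, float], dict[str, FamilyTruth]]:
    mrna = {g: 0.0 for g in config.gene_ids()}
    prot = {g: 0.0 for g in config.gene_ids()}
    fam_truth: dict[str, FamilyTruth] = {}
    for pf in config.planted_families:
        delta = math.log2(1.0 - pf.suppression)  # < 0: down in tissue A
        suppressed = suppressed_of[pf.family_id]
        for gene in suppressed:
            if pf.layer in ("mRNA", "protein"):
                mrna[gene] += delta
            if pf.layer in ("protein", "protein_only"):
                prot[gene] += delta
        fam_truth[pf.family_id] = FamilyTruth(
            direction="up_in_A", layer=pf.layer, suppressed_genes=frozenset(suppressed)
        )
    return mrna, prot, fam_truth


def _generate_mirna_arrays(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[TwoColorMirnaArray, dict[str, str], dict[str, float]]:
    planted = {pf.family_id for pf in config.planted_families}
    fam_ratio = {
        fam: (math.log2(config.mirna_fold_for_planted) if fam in planted else 0.0)
        for fam in config.family_ids()
    }
    probed = config.family_ids()[: config.n_families - config.families_without_probes]
    probe_to_family: dict[str, str] = {}
    probe_ratio: dict[str, float] = {}
    probes: list[str] = []
    for fam in probed:
        for k in range(1, config.n_mirnas_per_family + 1):
            probe = f"mmu-{fam}-m{k}"
            probes.append(probe)
            probe_to_family[probe] = fam
            probe_ratio[probe] = fam_ratio[fam]
    # most array probes interrogate miRNAs without a predicted family; they
    # are expressed at a null ratio and keep the mean-scaling normalization
    # representative of the whole array
    null_probes = [f"mmu-null-{i:03d}" for i in range(1, config.n_null_probes + 1)]
    for probe in null_probes:
        probe_ratio[probe] = 0.0
    decoys = [f"unexpr-{i:03d}" for i in range(1, config.n_unexpressed_probes + 1)]
    all_probes = probes + null_probes + decoys
    base_log2 = {
        p: rng.normal(math.log2(config.mirna_signal_mean), 1.0)
        for p in probes + null_probes
    }

    dye_factor = {"Hy3": 1.0, "Hy5": config.dye_bias}
    records = []
    for rep in range(1, config.n_replicates + 1):
        pair_id = f"pair_r{rep}"
        # tech 1: A in Hy3; tech 2 (the dye swap): A in Hy5
        for tech, a_channel in ((1, "Hy3"), (2, "Hy5")):
            sample_id = f"hyb_r{rep}_t{tech}"
            for channel in ("Hy3", "Hy5"):
                tissue = "A" if channel == a_channel else "B"
                sign = 0.5 if tissue == "A" else -0.5
                for probe in all_probes:
                    if probe in base_log2:
                        signal = (
                            2.0
                            ** (
                                base_log2[probe]
                                + sign * probe_ratio[probe]
                                + rng.normal(0.0, config.mirna_signal_log2_sd)
                            )
                            * dye_factor[channel]
                        )
                    else:
                        signal = 0.0
                    bg = max(
                        0.0, rng.normal(config.background_mean, config.background_sd)
                    )
                    records.append(
                        (
                            probe,
                            sample_id,
                            rep,
                            channel,
                            tissue,
                            signal + bg,
                            bg,
                            pair_id,
                        )
                    )
    df = pd.DataFrame(
        records,
        columns=[
            "probe_id",
            "sample_id",
            "biological_replicate",
            "channel",
            "tissue",
            "fg_intensity",
            "bg_intensity",
            "dye_swap_pair_id",
        ],
    )
    return TwoColorMirnaArray(df), probe_to_family, probe_ratio


def _generate_expression(
    config: SyntheticConfig,
    mrna_ratio: dict[str, float],
    rng: np.random.Generator,
    protected: set[str],
) -> ExpressionMatrix:
    genes = config.gene_ids()
    samples = [f"A{r}" for r in range(1, config.n_replicates + 1)] + [
        f"B{r}" for r in range(1, config.n_replicates + 1)
    ]
    base = rng.normal(8.0, 1.5, size=len(genes))
    values = np.empty((len(genes), len(samples)))
    for j, s in enumerate(samples):
        sign = 0.5 if s.startswith("A") else -0.5
        noise = rng.normal(0.0, config.mrna_log2_sd, size=len(genes))
        values[:, j] = base + sign * np.array([mrna_ratio[g] for g in genes]) + noise
    vdf = pd.DataFrame(values, index=genes, columns=samples)

    # all-absent rows exercise the presence filter; never planted targets
    eligible = [g for g in genes if g not in protected]
    n_absent = int(round(config.fraction_absent_genes * len(genes)))
    n_absent = min(n_absent, len(eligible))
    absent = set(rng.choice(eligible, size=n_absent, replace=False)) if n_absent else set()
    flags = pd.DataFrame("P", index=genes, columns=samples)
    for g in absent:
        flags.loc[g, :] = "A"
    groups = {s: ("A" if s.startswith("A") else "B") for s in samples}
    return ExpressionMatrix(vdf, groups, flags)


def _generate_peptides(
    config: SyntheticConfig,
    protein_ratio: dict[str, float],
    rng: np.random.Generator,
    must_include: set[str],
) -> PeptideQuantTable:
    genes = config.gene_ids()
    n_measured = int(round(config.protein_fraction * len(genes)))
    measured = set(rng.choice(genes, size=n_measured, replace=False))
    measured |= must_include
    n_low = int(round(config.fraction_low_peptide_proteins * len(measured)))
    low_eligible = sorted(measured - must_include)
    low = set(
        rng.choice(low_eligible, size=min(n_low, len(low_eligible)), replace=False)
    ) if n_low else set()

    rows = []
    for protein in sorted(measured):
        if protein in low:
            n_pep = int(rng.integers(1, 3))
        else:
            n_pep = int(rng.integers(config.min_peptides, config.max_peptides + 1))
        base_log2 = rng.normal(13.0, 1.5)
        ratio = protein_ratio[protein]
        for k in range(1, n_pep + 1):
            ia = 2.0 ** (base_log2 + 0.5 * ratio + rng.normal(0, config.peptide_log2_sd))
            ib = 2.0 ** (base_log2 - 0.5 * ratio + rng.normal(0, config.peptide_log2_sd))
            # tissue A labeled with reporter 114; a global loading bias on 114
            rows.append((protein, f"{protein}_pep{k}", config.itraq_channel_bias * ia, ib))
    df = pd.DataFrame(
        rows, columns=["protein_id", "peptide_id", "intensity_114", "intensity_115"]
    )
    return PeptideQuantTable(df)


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate one complete synthetic study; deterministic given the seed."""
    config.validate()
    rngs = _layer_rngs(config.seed)
    predictions, _targets_of, suppressed_of = _generate_predictions(
        config, rngs["predictions"]
    )
    mrna_ratio, protein_ratio, fam_truth = _true_ratios(config, suppressed_of)
    arrays, probe_to_family, probe_ratio = _generate_mirna_arrays(
        config, rngs["mirna"]
    )
    all_suppressed = set().union(*suppressed_of.values()) if suppressed_of else set()
    expression = _generate_expression(
        config, mrna_ratio, rngs["mrna"], protected=all_suppressed
    )
    peptides = _generate_peptides(
        config, protein_ratio, rngs["protein"], must_include=all_suppressed
    )
    truth = GroundTruth(
        families=fam_truth,
        mirna_probe_log2_ratio=probe_ratio,
        mrna_log2_ratio=mrna_ratio,
        protein_log2_ratio=protein_ratio,
    )
    return SyntheticStudy(
        config=config,
        mirna_arrays=arrays,
        expression=expression,
        peptides=peptides,
        predictions=predictions,
        truth=truth,
        probe_to_family=probe_to_family,
    )


def write_fixtures(study: SyntheticStudy, directory: str | Path) -> dict[str, str]:
    """Write all study tables to ``directory``; return a file -> sha256 manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {
        "mirna_arrays.tsv": lambda p: write_mirna_array_tsv(study.mirna_arrays, p),
        "predictions.tsv": lambda p: write_targetscan(study.predictions, p),
        "peptides.tsv": lambda p: write_peptide_tsv(study.peptides, p),
    }
    for name, writer in files.items():
        writer(directory / name)
    write_expression_tsv(
        study.expression,
        directory / "expression.tsv",
        groups_path=directory / "groups.yaml",
        flags_path=directory / "flags.tsv",
    )
    probe_map = pd.DataFrame(
        sorted(study.probe_to_family.items()), columns=["probe_id", "family_id"]
    )
    probe_map.to_csv(directory / "probe_families.tsv", sep="\t", index=False)
    written = sorted(
        [
            "mirna_arrays.tsv",
            "predictions.tsv",
            "peptides.tsv",
            "expression.tsv",
            "groups.yaml",
            "flags.tsv",
            "probe_families.tsv",
        ]
    )
    manifest = {name: sha256_of(directory / name) for name in written}
    write_manifest(
        {"seed": study.config.seed, "files": manifest}, directory / "manifest.json"
    )
    return manifest
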