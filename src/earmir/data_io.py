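"""Readers and writers for every external table the pipeline touches.

All on-disk tables are tab-separated text with a header row; gene identifiers
are joined across platforms (expression array, iTRAQ, target predictions) by
upper-cased gene symbol, the only key the three platforms share. Readers
validate eagerly and raise :class:`DataIOError` on malformed input so the
downstream modules only ever see well-formed in-memory tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CHANNELS = ("Hy3", "Hy5")
TISSUES = ("A", "B")

_FLOAT_FMT = "%.6g"


class DataIOError(ValueError):
    """Raised on malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetPredictionTable:
    """Per-site miRNA-family target predictions.

    ``sites`` has one row per predicted target site with columns
    ``family_id``, ``gene_id`` (upper-cased), ``site_context_score``
    (dimensionless; <= 0 for effective sites) and ``conserved`` (bool).
    Fully identical rows are collapsed.
    """

    sites: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"family_id", "gene_id", "site_context_score", "conserved"} - set(
            self.sites.columns
        )
        if missing:
            raise DataIOError(f"prediction table missing columns: {sorted(missing)}")

    @property
    def families(self) -> list[str]:
        return sorted(self.sites["family_id"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.sites["gene_id"].unique())


@dataclass
class GeneSetCollection:
    """Named gene sets, each with a declared universe."""

    sets: dict[str, frozenset[str]]
    universes: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            uni = self.universes.get(name)
            if uni is None:
                raise DataIOError(f"gene set {name!r} has no declared universe")
            if not members <= uni:
                extra = sorted(members - uni)[:5]
                raise DataIOError(f"gene set {name!r} escapes its universe: {extra}")

    def __iter__(self):
        return iter(self.sets)


@dataclass
class ExpressionMatrix:
    """log2 expression values (rows = probes/genes, columns = samples).

    ``groups`` maps every sample to its tissue group; ``flags`` optionally
    holds MAS5-style presence calls ('P'/'A') of the same shape as ``values``.
    """

    values: pd.DataFrame
    groups: dict[str, str]
    flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise DataIOError(f"samples without group assignment: {missing}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise DataIOError("expression matrix contains non-finite values")
        if self.flags is not None and self.flags.shape != self.values.shape:
            raise DataIOError(
                f"flags shape {self.flags.shape} != values shape {self.values.shape}"
            )


@dataclass(frozen=True)
class PeptideQuantTable:
    """Peptide-level iTRAQ reporter intensities (114 vs 115)."""

    peptides: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"protein_id", "peptide_id", "intensity_114", "intensity_115"}
        missing = required - set(self.peptides.columns)
        if missing:
            raise DataIOError(f"peptide table missing columns: {sorted(missing)}")
        for col in ("intensity_114", "intensity_115"):
            if (self.peptides[col] < 0).any():
                raise DataIOError(f"negative reporter intensity in {col}")


@dataclass(frozen=True)
class TwoColorMirnaArray:
    """Raw two-color miRNA array records.

    One row per (probe, hybridization, channel). Each biological replicate is
    hybridized twice with the dyes exchanged (a dye-swap pair); ``tissue``
    names the tissue whose labeled RNA is in that row's channel.
    """

    records: pd.DataFrame

    REQUIRED = (
        "probe_id",
        "sample_id",
        "biological_replicate",
        "channel",
        "tissue",
        "fg_intensity",
        "bg_intensity",
        "dye_swap_pair_id",
    )

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.records.columns)
        if missing:
            raise DataIOError(f"miRNA array table missing columns: {sorted(missing)}")
        bad = set(self.records["channel"].unique()) - set(CHANNELS)
        if bad:
            raise DataIOError(f"unknown channel label(s): {sorted(bad)}")
        bad_t = set(self.records["tissue"].unique()) - set(TISSUES)
        if bad_t:
            raise DataIOError(f"unknown tissue label(s): {sorted(bad_t)}")
        for col in ("fg_intensity", "bg_intensity"):
            if (self.records[col] < 0).any():
                raise DataIOError(f"negative intensity in {col}")
        # every dye-swap pair must consist of exactly two hybridizations
        pair_sizes = self.records.groupby("dye_swap_pair_id")["sample_id"].nunique()
        bad_pairs = pair_sizes[pair_sizes != 2]
        if len(bad_pairs):
            raise DataIOError(
                f"dye-swap pair(s) without exactly two hybridizations: "
                f"{sorted(bad_pairs.index.tolist())}"
            )
        # every probe appears in every hybridization
        counts = self.records.groupby("sample_id")["probe_id"].nunique()
        if counts.nunique() > 1:
            raise DataIOError("probes are not complete across hybridizations")

    @property
    def hybridizations(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())


# ---------------------------------------------------------------------------
# TargetScan-style predictions
# ---------------------------------------------------------------------------

DEFAULT_TARGETSCAN_COLUMNS = {
    "family": "family_id",
    "gene": "gene_id",
    "context_score": "site_context_score",
    "conserved": "conserved",
}

_TRUE_STRINGS = {"1", "true", "t", "yes", "y"}
_FALSE_STRINGS = {"0", "false", "f", "no", "n"}


def _parse_bool(value) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise DataIOError(f"cannot parse conservation flag {value!r}")


def read_targetscan(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> TargetPredictionTable:
    """Read a per-site TargetScan-style prediction TSV.

    ``columns`` maps the logical names family/gene/context_score/conserved to
    the header names in the file. Sites with a missing or unparseable context
    score are kept with weight-neutral score 0 and a logged warning.
    """
    colmap = dict(DEFAULT_TARGETSCAN_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise DataIOError(f"empty prediction file: {path}")
    for logical, name in colmap.items():
        if name not in df.columns:
            raise DataIOError(f"missing mapped column {name!r} (for {logical!r})")
    out = pd.DataFrame(
        {
            "family_id": df[colmap["family"]].astype(str).str.strip(),
            "gene_id": df[colmap["gene"]].astype(str).str.strip().str.upper(),
        }
    )
    if (out["family_id"] == "").any() or (out["gene_id"] == "").any():
        raise DataIOError("empty family_id or gene_id")
    scores = pd.to_numeric(df[colmap["context_score"]], errors="coerce")
    n_bad = int(scores.isna().sum())
    if n_bad:
        logger.warning(
            "%d site(s) with missing/unparseable context score set to 0", n_bad
        )
    out["site_context_score"] = scores.fillna(0.0).astype(float)
    out["conserved"] = df[colmap["conserved"]].map(_parse_bool).astype(bool)
    out = out.drop_duplicates().reset_index(drop=True)
    return TargetPredictionTable(out)


def write_targetscan(table: TargetPredictionTable, path: str | Path) -> None:
    df = table.sites.copy()
    df["conserved"] = df["conserved"].map({True: "1", False: "0"})
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path, universe_path: str | Path | None = None) -> GeneSetCollection:
    """Read gene sets in GMT dialect (name, description, then gene ids).

    Unless ``universe_path`` (one gene per line) is supplied, the universe of
    every set is the union of all genes in the file.
    """
    sets: dict[str, frozenset[str]] = {}
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise DataIOError(f"{path}:{lineno}: malformed GMT line (<2 fields)")
        name = parts[0].strip()
        if not name:
            raise DataIOError(f"{path}:{lineno}: empty set name")
        if name in sets:
            raise DataIOError(f"{path}:{lineno}: duplicate set name {name!r}")
        genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
        if not genes:
            logger.warning("gene set %r is empty", name)
        sets[name] = genes
    if universe_path is not None:
        universe = frozenset(
            g.strip().upper()
            for g in Path(universe_path).read_text().splitlines()
            if g.strip()
        )
    else:
        universe = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(sets, {name: universe for name in sets})


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name in sorted(collection.sets):
        genes = sorted(collection.sets[name])
        lines.append("\t".join([name, "na"] + genes))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------


def read_expression_tsv(
    path: str | Path,
    groups: Mapping[str, str] | str | Path,
    flags_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a log2 expression matrix; ``groups`` maps sample -> tissue group.

    ``groups`` may be a mapping or the path of a YAML sidecar
    (``{sample: group}``). ``flags_path`` optionally supplies a P/A presence
    flag matrix of identical shape.
    """
    if not isinstance(groups, Mapping):
        with open(groups) as fh:
            groups = yaml.safe_load(fh)
        if not isinstance(groups, Mapping):
            raise DataIOError("groups sidecar must be a mapping of sample -> group")
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    flags = None
    if flags_path is not None:
        flags = pd.read_csv(flags_path, sep="\t", index_col=0)
        flags.index = flags.index.astype(str)
        if not flags.index.equals(values.index) or list(flags.columns) != list(
            values.columns
        ):
            raise DataIOError("flags matrix does not match expression matrix layout")
    return ExpressionMatrix(values, dict(groups), flags)


def write_expression_tsv(
    matrix: ExpressionMatrix,
    path: str | Path,
    groups_path: str | Path | None = None,
    flags_path: str | Path | None = None,
) -> None:
    matrix.values.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    if groups_path is not None:
        Path(groups_path).write_text(
            yaml.safe_dump({s: matrix.groups[s] for s in sorted(matrix.groups)})
        )
    if flags_path is not None and matrix.flags is not None:
        matrix.flags.to_csv(flags_path, sep="\t")


# ---------------------------------------------------------------------------
# peptide and miRNA array tables
# ---------------------------------------------------------------------------


def read_peptide_tsv(path: str | Path) -> PeptideQuantTable:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"protein_id": str, "peptide_id": str},
    )
    missing = {"protein_id", "peptide_id", "intensity_114", "intensity_115"} - set(
        df.columns
    )
    if missing:
        raise DataIOError(f"peptide table missing columns: {sorted(missing)}")
    df["protein_id"] = df["protein_id"].str.upper()
    return PeptideQuantTable(df)


def write_peptide_tsv(table: PeptideQuantTable, path: str | Path) -> None:
    cols = ["protein_id", "peptide_id", "intensity_114", "intensity_115"]
    table.peptides[cols].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_mirna_array_tsv(path: str | Path) -> TwoColorMirnaArray:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "probe_id": str,
            "sample_id": str,
            "channel": str,
            "tissue": str,
            "dye_swap_pair_id": str,
        },
    )
    return TwoColorMirnaArray(df)


def write_mirna_array_tsv(arrays: TwoColorMirnaArray, path: str | Path) -> None:
    cols = list(TwoColorMirnaArray.REQUIRED)
    arrays.records[cols].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# results + manifest
# ---------------------------------------------------------------------------


def write_results(df: pd.DataFrame, path: str | Path, columns: Iterable[str] | None = None) -> None:
    """Write a results table with deterministic column order and formatting."""
    out = df if columns is None else df[list(columns)]
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(manifest: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
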