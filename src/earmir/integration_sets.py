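"""Cross-layer gene sets and transcriptome-proteome integration statistics.

The eight sets: for each tissue T, the genes down-regulated in T at the
transcript level, at the protein level, at both, and at the protein level
only (protein-down with no significant transcript change — the signature of
translational suppression). Universes differ by layer: transcript sets are
tested against all presence-filtered genes, protein sets against all valid
proteins, and the both/protein-only sets against the genes measured at both
layers.

Also here: rank/linear correlation of the two layers' log2 ratios,
hypergeometric overlap and flat term enrichment, and average-linkage
(UPGMA) hierarchical clustering on correlation distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data_io import DataIOError, GeneSetCollection
from .mrna_diffexp import benjamini_hochberg

logger = logging.getLogger(__name__)

SET_NAMES = (
    "down_mrna_A",
    "down_protein_A",
    "down_both_A",
    "down_protein_only_A",
    "down_mrna_B",
    "down_protein_B",
    "down_both_B",
    "down_protein_only_B",
)


def set_down_tissue(name: str) -> str:
    """Tissue in which a set's genes are down-regulated ('A' or 'B')."""
    tissue = name.rsplit("_", 1)[-1]
    if tissue not in ("A", "B"):
        raise DataIOError(f"cannot parse tissue from set name {name!r}")
    return tissue


def set_layer(name: str) -> str:
    """Measurement layer a set is defined on: mrna, protein or joint."""
    if "both" in name or "protein_only" in name:
        return "joint"
    if "protein" in name:
        return "protein"
    return "mrna"


def build_eight_sets(mrna: pd.DataFrame, proteins: pd.DataFrame) -> GeneSetCollection:
    """Assemble the eight cross-layer sets from the two layers' call tables.

    ``mrna`` is the diffexp_mrna output indexed by gene; ``proteins`` the
    itraq call table indexed by protein/gene id. Down in tissue T means
    called up in the other tissue. protein_only additionally requires the
    gene to be measured at the transcript level and to fail the transcript
    DE criterion (either fold or FDR).
    """
    mrna_universe = frozenset(mrna.index)
    valid = proteins.loc[proteins["valid"]]
    protein_universe = frozenset(valid.index)
    joint = mrna_universe & protein_universe
    if not joint:
        raise DataIOError("no genes measured at both layers")

    def mrna_down(tissue: str) -> frozenset[str]:
        other = "B" if tissue == "A" else "A"
        return frozenset(mrna.index[mrna["de_call"] == f"up_in_{other}"])

    def protein_down(tissue: str) -> frozenset[str]:
        other = "B" if tissue == "A" else "A"
        return frozenset(valid.index[valid["abundance_call"] == f"up_in_{other}"])

    mrna_not_de = frozenset(mrna.index[mrna["de_call"] == "not_de"])
    sets: dict[str, frozenset[str]] = {}
    universes: dict[str, frozenset[str]] = {}
    for t in ("A", "B"):
        m_down, p_down = mrna_down(t), protein_down(t)
        sets[f"down_mrna_{t}"] = m_down
        universes[f"down_mrna_{t}"] = mrna_universe
        sets[f"down_protein_{t}"] = p_down
        universes[f"down_protein_{t}"] = protein_universe
        sets[f"down_both_{t}"] = m_down & p_down & joint
        universes[f"down_both_{t}"] = frozenset(joint)
        sets[f"down_protein_only_{t}"] = p_down & mrna_not_de & joint
        universes[f"down_protein_only_{t}"] = frozenset(joint)
    return GeneSetCollection(sets, universes)


@dataclass(frozen=True)
class LayerCorrelation:
    spearman_rho: float
    spearman_p: float
    pearson_r: float
    n: int
    degenerate: bool


def layer_correlation(
    mrna_log2: pd.Series, protein_log2: pd.Series
) -> LayerCorrelation:
    """Spearman and Pearson correlation of the matched layer log2 ratios."""
    joint = mrna_log2.index.intersection(protein_log2.index)
    if len(joint) < 3:
        raise DataIOError("layer correlation needs at least 3 joint genes")
    x = mrna_log2.loc[joint].to_numpy(dtype=float)
    y = protein_log2.loc[joint].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return LayerCorrelation(np.nan, np.nan, np.nan, len(joint), True)
    rho, p_rho = stats.spearmanr(x, y)
    r, _ = stats.pearsonr(x, y)
    return LayerCorrelation(float(rho), float(p_rho), float(r), len(joint), False)


def overlap_test(
    set1: frozenset[str] | set[str],
    set2: frozenset[str] | set[str],
    universe: frozenset[str] | set[str],
) -> tuple[int, float]:
    """Upper-tail hypergeometric p for the observed overlap of two sets."""
    set1, set2, universe = set(set1), set(set2), set(universe)
    if not set1 <= universe or not set2 <= universe:
        raise DataIOError("sets must be subsets of the universe")
    k = len(set1 & set2)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(set1), len(set2)))
    return k, min(p, 1.0)


def term_enrichment(
    gene_set: frozenset[str] | set[str],
    annotations: Mapping[str, set[str] | frozenset[str]],
    universe: frozenset[str] | set[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene set in flat term annotations.

    One test per term with at least one annotated universe gene; BH across
    tested terms; ``significant`` flags q < ``fdr``.
    """
    universe = set(universe)
    gene_set = set(gene_set) & universe
    rows = []
    for term in sorted(annotations):
        term_genes = set(annotations[term]) & universe
        if not term_genes:
            logger.info("term %r has no universe genes; skipped", term)
            continue
        k, p = overlap_test(gene_set, term_genes, universe)
        rows.append((term, k, len(term_genes), p))
    out = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"])
    if len(out):
        out["q"] = benjamini_hochberg(out["p"].to_numpy())
        out["significant"] = out["q"] < fdr
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out.set_index("term")


@dataclass(frozen=True)
class Dendrogram:
    labels: tuple[str, ...]
    linkage: np.ndarray  # scipy linkage matrix over ``labels`` in order
    flagged_constant: tuple[str, ...]

    def first_split(self) -> tuple[frozenset[str], frozenset[str]]:
        """Partition of the labels induced by the root join."""
        n = len(self.labels)
        members: dict[int, frozenset[str]] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        for i, (left, right, _h, _c) in enumerate(self.linkage):
            members[n + i] = members[int(left)] | members[int(right)]
        left, right = int(self.linkage[-1, 0]), int(self.linkage[-1, 1])
        return members[left], members[right]


def average_linkage_cluster(profiles: pd.DataFrame) -> Dendrogram:
    """UPGMA on 1 - Pearson correlation distance between profile rows.

    Rows are samples, columns features. Samples are ordered lexicographically
    before clustering so ties break deterministically; a constant profile has
    undefined correlation — its distance to everything is defined as 1 and it
    is flagged.
    """
    if len(profiles) < 2:
        raise DataIOError("clustering needs at least 2 profiles")
    profiles = profiles.sort_index()
    arr = profiles.to_numpy(dtype=float)
    constant = np.ptp(arr, axis=1) == 0
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(arr)
    dist = 1.0 - corr
    dist[constant, :] = 1.0
    dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(
        labels=tuple(profiles.index),
        linkage=linkage,
        flagged_constant=tuple(profiles.index[constant]),
    )
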