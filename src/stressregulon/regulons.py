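"""Common stress regulons and co-expression cluster summaries.

A *regulon* is the set of genes significantly up- (or down-) regulated in
**all three** stress experiments at a given phase (early or late), computed
from the wild-type genotype's phase-vs-control contrasts.  The module also
provides Ward hierarchical clustering of z-scored expression and boxplot
statistics of per-cluster log2 fold-changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .core_io import CountExperiment, GeneSet, ValidationError
from .diffexp import Contrast, call_degs, nb_wald
from .preprocess import NormalizedMatrix


@dataclass
class RegulonSet:
    """The four common stress regulons plus their per-stress input sets."""

    early_up: GeneSet
    early_down: GeneSet
    late_up: GeneSet
    late_down: GeneSet
    inputs: dict[str, GeneSet] = field(default_factory=dict)
    venn: dict[str, dict[str, int]] = field(default_factory=dict)

    def get(self, name: str) -> GeneSet:
        return getattr(self, name)


def build_deg_sets(experiment: CountExperiment, genotype: str, stress: str,
                   phase: str, dispersions: pd.Series, sf: pd.Series,
                   alpha: float = 0.01, lfc: float = 0.5
                   ) -> tuple[pd.DataFrame, GeneSet, GeneSet]:
    """DEG up/down sets for one genotype x stress phase-vs-control contrast."""
    if phase not in ("early", "late"):
        raise ValidationError(f"phase must be early or late, got {phase!r}")
    contrast = Contrast(
        group_a=(genotype, stress, "control"),
        group_b=(genotype, stress, phase),
        label=f"{genotype}_{stress}_{phase}_vs_control",
    )
    table = nb_wald(experiment, contrast, dispersions, sf)
    table, up, down = call_degs(table, alpha=alpha, lfc=lfc,
                                label=f"{stress}_{phase}")
    return table, up, down


def _venn_regions(sets: dict[str, frozenset[str]]) -> dict[str, int]:
    """All 7 membership-pattern counts for three named sets.

    Keys are '100', '110', ... in the order of the given stress names: a '1'
    marks membership in that stress's set (exclusive regions).
    """
    names = list(sets)
    if len(names) != 3:
        raise ValidationError("Venn regions require exactly 3 sets")
    union = frozenset().union(*sets.values())
    regions = {"".join(bits): 0
               for bits in product("01", repeat=3) if "1" in "".join(bits)}
    for gene in union:
        key = "".join("1" if gene in sets[n] else "0" for n in names)
        regions[key] += 1
    return regions


def intersect_regulons(per_stress: dict[str, GeneSet], phase: str,
                       direction: str) -> tuple[GeneSet, dict[str, int]]:
    """Three-way intersection of per-stress DEG sets plus Venn region counts."""
    if len(per_stress) != 3:
        raise ValidationError(
            f"need exactly 3 stress sets, got {len(per_stress)}")
    sets = {s: gs.genes for s, gs in per_stress.items()}
    common = frozenset.intersection(*sets.values())
    name = f"{phase}_{direction}"
    return GeneSet(name=name, genes=common, direction=direction), _venn_regions(sets)


def build_regulons(experiment: CountExperiment, wild_type: str,
                   stresses: tuple[str, ...], dispersions: pd.Series,
                   sf: pd.Series, alpha: float = 0.01, lfc: float = 0.5
                   ) -> tuple[RegulonSet, dict[str, pd.DataFrame]]:
    """Build all four common regulons from the wild-type contrasts.

    Returns the RegulonSet (inputs and Venn region counts attached) and the
    per-contrast DE tables keyed by ``{stress}_{phase}``.
    """
    if len(stresses) != 3:
        raise ValidationError("regulon construction expects exactly 3 stresses")
    tables: dict[str, pd.DataFrame] = {}
    inputs: dict[str, GeneSet] = {}
    for stress in stresses:
        for phase in ("early", "late"):
            table, up, down = build_deg_sets(
                experiment, wild_type, stress, phase, dispersions, sf,
                alpha=alpha, lfc=lfc)
            tables[f"{stress}_{phase}"] = table
            inputs[f"{stress}_{phase}_up"] = up
            inputs[f"{stress}_{phase}_down"] = down

    regulons = {}
    venns = {}
    for phase in ("early", "late"):
        for direction in ("up", "down"):
            per_stress = {s: inputs[f"{s}_{phase}_{direction}"]
                          for s in stresses}
            regulons[f"{phase}_{direction}"], venns[f"{phase}_{direction}"] = \
                intersect_regulons(per_stress, phase, direction)
    return RegulonSet(
        early_up=regulons["early_up"], early_down=regulons["early_down"],
        late_up=regulons["late_up"], late_down=regulons["late_down"],
        inputs=inputs, venn=venns,
    ), tables


# ---------------------------------------------------------------------------
# co-expression clustering (heatmap-style summaries)
# ---------------------------------------------------------------------------

def hcluster_expression(matrix: NormalizedMatrix, k: int = 5) -> pd.Series:
    """Ward/Euclidean agglomerative clustering of genes cut at *k* clusters.

    Deterministic under permutation of input gene order: genes are sorted
    lexicographically before linkage, and cluster labels are renumbered by
    the lexicographically smallest member.
    """
    if k > len(matrix.genes):
        raise ValidationError(f"k={k} exceeds {len(matrix.genes)} genes")
    order = np.argsort(np.asarray(matrix.genes, dtype=object))
    genes = [matrix.genes[i] for i in order]
    values = matrix.values[order]
    if k == 1:
        return pd.Series(1, index=genes, name="cluster")
    Z = linkage(values, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    # renumber so cluster ids follow first (lexicographic) appearance
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    return pd.Series([remap[l] for l in labels], index=genes, name="cluster")


def box_stats(values: np.ndarray) -> dict[str, float]:
    """Five-number boxplot summary with whiskers at 1.5 x IQR (type-7 quantiles)."""
    values = np.asarray(values, float)
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "q1": float(q1), "median": float(med), "q3": float(q3),
        "whisker_low": float(inside.min()), "whisker_high": float(inside.max()),
        "n_outliers": int(((values < lo_fence) | (values > hi_fence)).sum()),
    }


def cluster_fc_summary(clusters: pd.Series,
                       de_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Boxplot statistics of log2FC per cluster x contrast phase.

    ``de_tables`` maps a phase label (e.g. ``heat_early``) to a DE table with
    ``gene`` and ``log2fc`` columns.  Genes missing from a table are skipped.
    """
    rows = []
    for phase, table in de_tables.items():
        lfc = table.set_index("gene")["log2fc"]
        for cluster_id, members in clusters.groupby(clusters):
            genes = [g for g in members.index if g in lfc.index]
            if not genes:
                continue
            stats_ = box_stats(lfc.loc[genes].to_numpy())
            rows.append({"cluster": cluster_id, "phase": phase,
                         "n_genes": len(genes), **stats_})
    return pd.DataFrame(rows)
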