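"""Mutant non-responsiveness and its mechanism (loss of repression vs activation).

A regulon gene is *non-responsive* in a mutant if it fails the full DEG
criterion (significance AND magnitude AND direction) in that mutant's own
early-vs-control contrast for the same stress.  Non-responsive genes split
into two mechanisms by the mutant-vs-wild-type contrast at the control
time-point:

* **LR (loss of repression)** — the gene is already significantly
  de-repressed in the mutant before stress (significant in the regulon's
  direction at control), so there is nothing left to induce.
* **LA (loss of activation)** — the gene sits at its wild-type pre-stress
  level but fails to be induced.

LR and LA partition the non-responsive set.  All calls are pure functions of
the DE tables and regulon membership.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core_io import GeneSet, ValidationError
from .diffexp import DEFAULT_ALPHA, DEFAULT_LFC


def _deg_mask(table: pd.DataFrame, direction: str, alpha: float,
              lfc: float) -> pd.Series:
    sig = table["padj"] <= alpha
    if direction == "up":
        return sig & (table["log2fc"] >= lfc)
    if direction == "down":
        return sig & (table["log2fc"] <= -lfc)
    raise ValidationError(f"direction must be up or down, got {direction!r}")


def non_responsive(regulon: GeneSet, mutant_table: pd.DataFrame,
                   alpha: float = DEFAULT_ALPHA, lfc: float = DEFAULT_LFC
                   ) -> GeneSet:
    """Regulon genes that are NOT significant DEGs in the regulon's direction.

    ``mutant_table`` is the mutant's early-vs-control DE table (must contain
    ``gene``, ``log2fc``, ``padj``).  A gene responds only if it passes
    padj <= alpha AND |log2fc| >= lfc with the correct sign; anything else —
    including regulon genes absent from the table — is non-responsive.
    """
    if regulon.direction not in ("up", "down"):
        raise ValidationError("regulon must have a direction")
    if "padj" not in mutant_table.columns:
        raise ValidationError("mutant DE table lacks a padj column")
    responsive = set(
        mutant_table.loc[_deg_mask(mutant_table, regulon.direction, alpha, lfc),
                         "gene"])
    genes = frozenset(g for g in regulon.genes if g not in responsive)
    return GeneSet(name=f"{regulon.name}_nonresponsive", genes=genes,
                   direction=regulon.direction)


def classify_mechanism(nonresp: GeneSet, control_table: pd.DataFrame,
                       alpha: float = DEFAULT_ALPHA, lfc: float = DEFAULT_LFC
                       ) -> pd.DataFrame:
    """Split a non-responsive set into LR and LA.

    ``control_table`` is the mutant-vs-wild-type DE table at the control
    time-point of the matching growth system.  For an UP regulon, LR genes
    are those significantly UP at control; for a DOWN regulon the control
    direction is mirrored (significantly DOWN = de-repression of repression).
    Returns one row per non-responsive gene with a ``mechanism`` column.
    """
    if "padj" not in control_table.columns:
        raise ValidationError("control DE table lacks a padj column")
    pre_shifted = set(
        control_table.loc[
            _deg_mask(control_table, nonresp.direction, alpha, lfc), "gene"])
    rows = [{"gene": g,
             "mechanism": "LR" if g in pre_shifted else "LA"}
            for g in sorted(nonresp.genes)]
    return pd.DataFrame(rows, columns=["gene", "mechanism"])


def response_calls(regulon: GeneSet, mutant: str, stress: str, phase: str,
                   mutant_table: pd.DataFrame, control_table: pd.DataFrame,
                   alpha: float = DEFAULT_ALPHA, lfc: float = DEFAULT_LFC
                   ) -> pd.DataFrame:
    """Full per-gene ResponseCall table for one mutant x stress x regulon.

    Columns: gene, mutant, stress, phase, regulon, status
    (responsive/non_responsive), mechanism (LR/LA/not_applicable).
    """
    nonresp = non_responsive(regulon, mutant_table, alpha=alpha, lfc=lfc)
    mech = dict(classify_mechanism(nonresp, control_table, alpha=alpha,
                                   lfc=lfc).itertuples(index=False))
    rows = []
    for gene in sorted(regulon.genes):
        nr = gene in nonresp.genes
        rows.append({
            "gene": gene, "mutant": mutant, "stress": stress, "phase": phase,
            "regulon": regulon.name,
            "status": "non_responsive" if nr else "responsive",
            "mechanism": mech[gene] if nr else "not_applicable",
        })
    return pd.DataFrame(rows)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def antagonism_overlap(reference: GeneSet,
                       comparisons: dict[str, GeneSet]) -> pd.DataFrame:
    """Overlap of a reference DE set with other genotypes' opposite-direction sets.

    Counts and percentages (of the reference size, rounded half-up to
    integers) for each comparison set and for the all-way intersection.  An
    empty reference yields zero overlaps with percentage NA.
    """
    ref = reference.genes
    rows = []
    inter = set(ref)
    for name, gs in comparisons.items():
        overlap = len(ref & gs.genes)
        inter &= gs.genes
        pct = _round_half_up(100.0 * overlap / len(ref)) if ref else None
        rows.append({"comparison": name, "overlap": overlap,
                     "reference_size": len(ref),
                     "percent": pct if pct is not None else np.nan})
    if len(comparisons) > 1:
        pct = _round_half_up(100.0 * len(inter) / len(ref)) if ref else None
        rows.append({"comparison": "all", "overlap": len(inter),
                     "reference_size": len(ref),
                     "percent": pct if pct is not None else np.nan})
    return pd.DataFrame(rows)
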