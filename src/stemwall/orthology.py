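"""Putative-ortholog calling by cross-species expression-class concordance.

Each maize gene's closest reference-species homolog (precomputed, one per
gene) carries a wall class — ``primary``, ``secondary`` or ``none`` — from a
published reference stem study.  A maize gene above the high expression gate
is called a putative ortholog when its own stage class maps to the same side:
Elongation and Transitional map to the primary-wall side, Secondary to the
secondary-wall side.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from . import stage

REF_PRIMARY = "primary"
REF_SECONDARY = "secondary"
REF_NONE = "none"

SIDE_PRIMARY = "primary-side"
SIDE_SECONDARY = "secondary-side"

#: Maize stage class -> orthology side.
CLASS_TO_SIDE = {
    stage.CLASS_ELONGATION: SIDE_PRIMARY,
    stage.CLASS_TRANSITIONAL: SIDE_PRIMARY,
    stage.CLASS_SECONDARY: SIDE_SECONDARY,
}

_SIDE_TO_REF = {SIDE_PRIMARY: REF_PRIMARY, SIDE_SECONDARY: REF_SECONDARY}


def read_homolog_map(path) -> pd.DataFrame:
    """Read a homolog TSV: maize_id, ref_id, score, ref_class (one row/gene)."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index("maize_id")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"multiple homologs for maize genes: {dup[:5]}")
    bad = set(df["ref_class"]) - {REF_PRIMARY, REF_SECONDARY, REF_NONE}
    if bad:
        raise ValueError(f"unknown reference wall classes: {sorted(bad)}")
    return df


def call_orthologs(calls: pd.DataFrame, homolog_map: pd.DataFrame) -> pd.DataFrame:
    """Concordance calls for every high-gate maize gene.

    ``calls`` is the stage-call table (``gate``/``stage_class`` columns,
    indexed by gene); ``homolog_map`` is indexed by maize gene with ``ref_id``
    and ``ref_class``.  Genes with no homolog or reference class ``none`` are
    never orthologous.  Asking about a maize gene absent from the stage calls
    is an error.

    Returns a DataFrame indexed by maize gene with columns ``maize_class``,
    ``ref_id``, ``ref_class``, ``side``, ``is_putative_ortholog``.
    """
    absent = [g for g in homolog_map.index if g not in calls.index]
    if absent:
        raise KeyError(f"homolog-map genes absent from stage calls: {absent[:5]}")
    high = calls[calls["gate"] == stage.GATE_500]
    rows = {}
    for g in high.index:
        cls = high.loc[g, "stage_class"]
        side = CLASS_TO_SIDE.get(cls)
        if g in homolog_map.index:
            ref_id = homolog_map.loc[g, "ref_id"]
            ref_class = homolog_map.loc[g, "ref_class"]
        else:
            ref_id, ref_class = None, REF_NONE
        is_ortho = side is not None and ref_class == _SIDE_TO_REF[side]
        rows[g] = {
            "maize_class": cls,
            "ref_id": ref_id,
            "ref_class": ref_class,
            "side": side,
            "is_putative_ortholog": bool(is_ortho),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def ortholog_fractions(
    n_primary_side: int,
    n_secondary_side: int,
    n_elongation: int,
    n_transitional: int,
    n_secondary: int,
) -> dict:
    """Ortholog totals and per-side fractions from tallied counts.

    The primary-side fraction is primary-side orthologs over the Elongation +
    Transitional gene count; the secondary-side fraction is secondary-side
    orthologs over the Secondary gene count.  Fractions are rounded half-up to
    two decimals and are ``None`` on a zero denominator.
    """
    n_primary_genes = n_elongation + n_transitional
    return {
        "primary_side_orthologs": int(n_primary_side),
        "secondary_side_orthologs": int(n_secondary_side),
        "total_orthologs": int(n_primary_side + n_secondary_side),
        "primary_side_fraction": (
            _round2(n_primary_side / n_primary_genes) if n_primary_genes else None
        ),
        "secondary_side_fraction": (
            _round2(n_secondary_side / n_secondary) if n_secondary else None
        ),
    }


def summarize_orthologs(ocalls: pd.DataFrame, class_counts: dict) -> dict:
    """Ortholog fractions from a concordance-call table and class counts."""
    ortho = ocalls[ocalls["is_putative_ortholog"]]
    return ortholog_fractions(
        n_primary_side=int((ortho["side"] == SIDE_PRIMARY).sum()),
        n_secondary_side=int((ortho["side"] == SIDE_SECONDARY).sum()),
        n_elongation=class_counts[stage.CLASS_ELONGATION],
        n_transitional=class_counts[stage.CLASS_TRANSITIONAL],
        n_secondary=class_counts[stage.CLASS_SECONDARY],
    )


def family_summary(
    ocalls: pd.DataFrame,
    calls: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Per-family gene, expression, and ortholog counts.

    ``annotation`` is indexed by gene with a ``family`` column; unannotated
    genes are tallied under ``unassigned``.  Returns one row per family with
    ``n_genes``, ``n_expressed`` (>= the 95 gate), ``primary_orthologs``,
    ``secondary_orthologs``, plus a ``Total`` row.
    """
    fam = annotation["family"].reindex(calls.index).fillna("unassigned")
    expressed = calls["gate"] != stage.GATE_NOT_EXPRESSED
    ortho = ocalls[ocalls["is_putative_ortholog"]]
    rows = []
    for family in sorted(fam.unique()):
        genes = fam.index[fam == family]
        fam_ortho = ortho[ortho.index.isin(genes)]
        rows.append(
            {
                "family": family,
                "n_genes": int(len(genes)),
                "n_expressed": int(expressed.loc[genes].sum()),
                "primary_orthologs": int((fam_ortho["side"] == SIDE_PRIMARY).sum()),
                "secondary_orthologs": int((fam_ortho["side"] == SIDE_SECONDARY).sum()),
            }
        )
    df = pd.DataFrame(rows).set_index("family")
    df.loc["Total"] = df.sum()
    return df
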