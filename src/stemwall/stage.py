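"""Developmental-stage classification from secondary:elongation ratios.

Each gene's replicate-collapsed reads-per-20M profile is reduced to a single
ratio — mean expression over the secondary-wall-forming internodes divided by
mean expression over the elongating internodes — and genes passing a high
expression gate are classed Elongation, Transitional, or Secondary by fixed
ratio boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .expression import NormalizedMatrix

GATE_NOT_EXPRESSED = "NotExpressed"
GATE_95 = "Expressed95"
GATE_500 = "Expressed500"

CLASS_ELONGATION = "Elongation"
CLASS_TRANSITIONAL = "Transitional"
CLASS_SECONDARY = "Secondary"
CLASS_UNCLASSIFIED = "Unclassified"

STAGE_CLASSES = (CLASS_ELONGATION, CLASS_TRANSITIONAL, CLASS_SECONDARY)


@dataclass(frozen=True)
class StageConfig:
    """Internode groupings, expression gates, and ratio class boundaries.

    Defaults follow the stem time-course convention: internodes 3-5 are
    enriched for secondary wall deposition, internodes 8-9 are elongating;
    genes are "expressed" at >= 95 reads per 20 M and "highly expressed" at
    >= 500; ratio <= 1.04 reads as elongation/primary-wall expression,
    >= 1.95 as secondary-wall expression, in between as transitional.
    """

    secondary_internodes: tuple[int, ...] = (5, 4, 3)
    elongation_internodes: tuple[int, ...] = (9, 8)
    expressed_gate: float = 95.0
    high_gate: float = 500.0
    elongation_max_ratio: float = 1.04
    secondary_min_ratio: float = 1.95

    def __post_init__(self) -> None:
        if self.expressed_gate <= 0 or self.high_gate <= 0:
            raise ValueError("expression gates must be positive")
        if self.elongation_max_ratio >= self.secondary_min_ratio:
            raise ValueError("elongation_max_ratio must be < secondary_min_ratio")
        if set(self.secondary_internodes) & set(self.elongation_internodes):
            raise ValueError("secondary and elongation internode sets overlap")


@dataclass
class StageCall:
    """Per-gene gate and stage class.

    ``ratio`` is ``None`` when the elongation-internode mean is zero (the
    ratio is undefined); such genes are flagged ``secondary_only`` when their
    secondary mean is positive.  A class other than Unclassified is assigned
    only to genes above the high gate.
    """

    gene_id: str
    max_expression: float
    ratio: float | None
    gate: str
    stage_class: str
    secondary_only: bool = False


def stage_ratio(profile: pd.Series, cfg: StageConfig = StageConfig()) -> float | None:
    """Secondary:elongation mean-expression ratio for one gene profile.

    ``profile`` is indexed by internode ordinal.  Returns ``None`` when the
    elongation mean is zero (including the 0/0 case).
    """
    missing = [
        i
        for i in (*cfg.secondary_internodes, *cfg.elongation_internodes)
        if i not in profile.index
    ]
    if missing:
        raise ValueError(f"profile lacks configured internodes: {missing}")
    sec = float(profile.loc[list(cfg.secondary_internodes)].mean())
    elo = float(profile.loc[list(cfg.elongation_internodes)].mean())
    if elo == 0.0:
        return None
    return sec / elo


def classify_gene(
    gene_id: str, profile: pd.Series, cfg: StageConfig = StageConfig()
) -> StageCall:
    """Assign an expression gate and, above the high gate, a stage class.

    The gate uses the maximum replicate-collapsed value across internodes
    (expression "in one or more internodes").  Secondary-only genes — zero
    elongation mean but secondary mean at or above the high gate — are classed
    Secondary: their ratio exceeds any finite boundary.
    """
    max_expr = float(profile.max())
    ratio = stage_ratio(profile, cfg)
    sec_mean = float(profile.loc[list(cfg.secondary_internodes)].mean())
    secondary_only = ratio is None and sec_mean > 0.0

    if max_expr >= cfg.high_gate:
        gate = GATE_500
    elif max_expr >= cfg.expressed_gate:
        gate = GATE_95
    else:
        gate = GATE_NOT_EXPRESSED

    stage_class = CLASS_UNCLASSIFIED
    if gate == GATE_500:
        if ratio is None:
            if sec_mean >= cfg.high_gate:
                stage_class = CLASS_SECONDARY
        elif ratio <= cfg.elongation_max_ratio:
            stage_class = CLASS_ELONGATION
        elif ratio >= cfg.secondary_min_ratio:
            stage_class = CLASS_SECONDARY
        else:
            stage_class = CLASS_TRANSITIONAL

    return StageCall(
        gene_id=gene_id,
        max_expression=max_expr,
        ratio=ratio,
        gate=gate,
        stage_class=stage_class,
        secondary_only=secondary_only,
    )


def classify_matrix(
    m: NormalizedMatrix, cfg: StageConfig = StageConfig()
) -> pd.DataFrame:
    """Classify every gene of a normalized matrix.

    Returns a DataFrame indexed by gene with columns ``max_expression``,
    ``ratio``, ``gate``, ``stage_class``, ``secondary_only``.
    """
    calls = [classify_gene(g, m.values.loc[g], cfg) for g in m.values.index]
    return pd.DataFrame(
        {
            "max_expression": [c.max_expression for c in calls],
            "ratio": [c.ratio for c in calls],
            "gate": [c.gate for c in calls],
            "stage_class": [c.stage_class for c in calls],
            "secondary_only": [c.secondary_only for c in calls],
        },
        index=[c.gene_id for c in calls],
    )


def _round2(x: float) -> float:
    """Half-up rounding to two decimals, the printed-table convention."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_classes(calls: pd.DataFrame) -> dict:
    """Tally gates and stage classes and compute class fractions.

    ``calls`` may be the output of :func:`classify_matrix` or any DataFrame
    with ``gate`` and ``stage_class`` columns.  Fractions are of the
    high-gate (Expressed500) total, rounded half-up to two decimals;
    fractions are ``None`` on empty input.
    """
    n_total = int(calls.shape[0])
    n500 = int((calls["gate"] == GATE_500).sum())
    n95 = int((calls["gate"] != GATE_NOT_EXPRESSED).sum())
    high = calls[calls["gate"] == GATE_500]
    counts = {c: int((high["stage_class"] == c).sum()) for c in STAGE_CLASSES}
    fractions = {
        c: (_round2(counts[c] / n500) if n500 else None) for c in STAGE_CLASSES
    }
    return {
        "total_genes": n_total,
        "expressed_95": n95,
        "expressed_500": n500,
        "class_counts": counts,
        "class_fractions": fractions,
    }


def summarize_counts(
    n_elongation: int, n_transitional: int, n_secondary: int
) -> dict:
    """Class fractions from already-tallied counts (printed-table arithmetic)."""
    rows = []
    for cls, n in (
        (CLASS_ELONGATION, n_elongation),
        (CLASS_TRANSITIONAL, n_transitional),
        (CLASS_SECONDARY, n_secondary),
    ):
        rows.extend({"gate": GATE_500, "stage_class": cls} for _ in range(n))
    return summarize_classes(pd.DataFrame(rows))
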