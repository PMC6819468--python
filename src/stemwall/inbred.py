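"""Two-genotype comparison: stage-pooled fold-changes and PAV block calling.

Expression of two inbred genotypes is pooled over elongation- and
secondary-wall-stage internodes, fold-changes between genotypes are computed
with a pseudocount and binned (< 2, >= 2, >= 5, >= 100), and genes expressed
in only one genotype at extreme fold-change are scanned for contiguous runs —
candidate presence-absence variation (PAV) blocks such as a multi-megabase
deletion removing a run of genes from one genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import NormalizedMatrix, PER20M_PER_CPM

#: Default internode pooling: elongating vs secondary-wall-rich internodes of
#: the two-genotype greenhouse series.
DEFAULT_POOLING: dict[str, tuple[int, ...]] = {
    "Elongation": (7, 6),
    "Secondary": (5, 4),
}

BIN_LABELS = ("<2", ">=2", ">=5", ">=100")
_BIN_EDGES = (2.0, 5.0, 100.0)


@dataclass
class PAVBlock:
    """A maximal run of consecutive same-direction PAV candidate genes."""

    chromosome: str
    start_ordinal: int
    end_ordinal: int
    genes: list[str]
    direction: str  # "absent-in-A" | "absent-in-B"

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def pool_stages(
    m_a: NormalizedMatrix,
    m_b: NormalizedMatrix,
    pooling: Mapping[str, Sequence[int]] = DEFAULT_POOLING,
) -> pd.DataFrame:
    """Mean expression per gene, stage, and genotype over pooled internodes.

    The gene universe is the union of both matrices; a gene absent from one
    genotype contributes zero there.  Returns a long DataFrame with columns
    ``gene_id``, ``stage``, ``value_a``, ``value_b``.
    """
    for name, internodes in pooling.items():
        for label, m in (("A", m_a), ("B", m_b)):
            missing = [i for i in internodes if i not in m.values.columns]
            if missing:
                raise ValueError(
                    f"genotype {label} matrix lacks internodes {missing} "
                    f"for stage {name!r}"
                )
    genes = m_a.values.index.union(m_b.values.index, sort=True)
    va = m_a.values.reindex(genes).fillna(0.0)
    vb = m_b.values.reindex(genes).fillna(0.0)
    frames = []
    for name, internodes in pooling.items():
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "stage": name,
                    "value_a": va[list(internodes)].mean(axis=1).to_numpy(),
                    "value_b": vb[list(internodes)].mean(axis=1).to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _bin_label(fold: float) -> str:
    if fold >= 100.0:
        return ">=100"
    if fold >= 5.0:
        return ">=5"
    if fold >= 2.0:
        return ">=2"
    return "<2"


def fold_change_bins(pooled: pd.DataFrame, pseudocount: float = 10.0) -> pd.DataFrame:
    """Fold-change, direction, and bin per gene and stage.

    ``fold = (max + p) / (min + p)`` with pseudocount ``p`` bounding the
    fold-change of zero-expression genes.  ``direction`` names the higher
    genotype (``A``/``B``/``equal``).  The reported ``bin`` is the highest
    threshold passed; bins are nested, so a >=100 gene also counts toward >=5
    and >=2 in :func:`bin_fractions`.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if (pooled[["value_a", "value_b"]].to_numpy() < 0).any():
        raise ValueError("negative pooled expression values")
    out = pooled.copy()
    hi = np.maximum(out["value_a"], out["value_b"])
    lo = np.minimum(out["value_a"], out["value_b"])
    out["fold"] = (hi + pseudocount) / (lo + pseudocount)
    out["direction"] = np.select(
        [out["value_a"] > out["value_b"], out["value_b"] > out["value_a"]],
        ["A", "B"],
        default="equal",
    )
    out["bin"] = [_bin_label(f) for f in out["fold"]]
    return out


def bin_fractions(
    comparisons: pd.DataFrame,
    per_gene: bool = True,
) -> dict:
    """Fractions of genes at or above each fold-change threshold.

    With ``per_gene=True`` a gene's fold is its maximum over stages (a
    difference "at any stage"); otherwise fractions are per stage.  Fractions
    are cumulative over the nested bins, so ``>=2`` includes ``>=5`` and
    ``>=100``.
    """
    def _fracs(folds: pd.Series) -> dict:
        n = len(folds)
        return {
            f">={int(e)}": (float((folds >= e).sum() / n) if n else None)
            for e in _BIN_EDGES
        } | {"n": int(n)}

    if per_gene:
        return _fracs(comparisons.groupby("gene_id")["fold"].max())
    return {
        stage_name: _fracs(grp["fold"])
        for stage_name, grp in comparisons.groupby("stage")
    }


def flag_pav(
    comparisons: pd.DataFrame,
    gene_order: pd.DataFrame,
    min_fold: float = 26.0,
    min_run: int = 5,
    detection_floor: float = PER20M_PER_CPM,
    m_a: NormalizedMatrix | None = None,
    m_b: NormalizedMatrix | None = None,
) -> tuple[pd.DataFrame, list[PAVBlock]]:
    """Flag one-sided genes and emit contiguous candidate deletion blocks.

    A gene is a PAV candidate when one genotype is below the detection floor
    (all internodes when the full matrices are supplied, otherwise all pooled
    stage values) while the other genotype's fold-change reaches ``min_fold``
    at some stage.  ``gene_order`` is indexed by gene with ``chromosome`` and
    ``ordinal`` columns (ordinal gene index along the chromosome).  Maximal
    runs of at least ``min_run`` consecutive same-direction candidates are
    returned as blocks.

    Returns ``(per-gene candidate table, blocks)``.
    """
    per_gene = comparisons.pivot_table(
        index="gene_id", columns="stage", values="fold", aggfunc="max"
    )
    max_fold = per_gene.max(axis=1)
    a_vals = comparisons.pivot_table(index="gene_id", columns="stage", values="value_a")
    b_vals = comparisons.pivot_table(index="gene_id", columns="stage", values="value_b")

    if m_a is not None and m_b is not None:
        genes = max_fold.index
        low_a = (
            m_a.values.reindex(genes).fillna(0.0).max(axis=1) < detection_floor
        )
        low_b = (
            m_b.values.reindex(genes).fillna(0.0).max(axis=1) < detection_floor
        )
    else:
        low_a = (a_vals < detection_floor).all(axis=1)
        low_b = (b_vals < detection_floor).all(axis=1)

    absent_in_a = low_a & ~low_b & (max_fold >= min_fold)
    absent_in_b = low_b & ~low_a & (max_fold >= min_fold)

    table = pd.DataFrame(
        {
            "max_fold": max_fold,
            "pav_candidate": absent_in_a | absent_in_b,
            "direction": np.select(
                [absent_in_a, absent_in_b], ["absent-in-A", "absent-in-B"], default=""
            ),
        }
    )

    known = table.index.intersection(gene_order.index)
    dropped = table.index.difference(gene_order.index)
    order = gene_order.loc[known].copy()
    order["_dir"] = table.loc[known, "direction"]

    blocks: list[PAVBlock] = []
    for chrom, grp in order.groupby("chromosome", sort=True):
        grp = grp.sort_values("ordinal")
        run_genes: list[str] = []
        run_dir = ""
        prev_ord: int | None = None

        def _close() -> None:
            if len(run_genes) >= min_run:
                ords = gene_order.loc[run_genes, "ordinal"]
                blocks.append(
                    PAVBlock(
                        chromosome=str(chrom),
                        start_ordinal=int(ords.min()),
                        end_ordinal=int(ords.max()),
                        genes=list(run_genes),
                        direction=run_dir,
                    )
                )

        for g, row in grp.iterrows():
            d = row["_dir"]
            contiguous = prev_ord is not None and row["ordinal"] == prev_ord + 1
            if d and d == run_dir and contiguous:
                run_genes.append(g)
            else:
                _close()
                run_genes = [g] if d else []
                run_dir = d
            prev_ord = int(row["ordinal"])
        _close()

    if len(dropped):
        table.attrs["dropped_from_order"] = list(dropped)
    return table, blocks


def size_bias(
    comparisons: pd.DataFrame,
    annotation: pd.DataFrame,
    min_fold: float = 2.0,
) -> dict:
    """Mean transcript length by fold-change direction, a size-bias check.

    Compares the mean ``transcript_length`` of genes whose fold-change (max
    over stages) reaches ``min_fold`` in each direction; near-equal means
    indicate no length bias in the comparison.
    """
    per_gene = comparisons.groupby("gene_id").agg(
        fold=("fold", "max"), direction=("direction", "first")
    )
    lengths = annotation["transcript_length"].reindex(per_gene.index)
    high = per_gene["fold"] >= min_fold
    mean_a = float(lengths[high & (per_gene["direction"] == "A")].mean())
    mean_b = float(lengths[high & (per_gene["direction"] == "B")].mean())
    return {"mean_length_up_in_A": mean_a, "mean_length_up_in_B": mean_b}
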