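"""Expression templates by hierarchical clustering and slope-metric matching.

A curated set of cell-wall genes is clustered (average linkage) on their
gene-scaled profiles; clades are grouped into five named stage templates; and
the whole detected transcriptome is then screened against each template with a
slope metric — the L1 distance between the successive inter-internode slopes
of the bait and the test profile:

    score(A, X) = sum_{i=1}^{n-1} | (A[i+1] - A[i]) - (X[i+1] - X[i]) |

The score is zero exactly when the two profiles differ by a constant offset,
making it insensitive to absolute expression level and sensitive to shape.
Genes scoring below one standard deviation of a template's score distribution
are flagged as matching that template and rank-ordered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .expression import GeneScaledMatrix
from .shapes import PATTERN_NAMES, archetype


@dataclass
class PatternTemplate:
    """A named per-internode bait profile on the gene-scaled scale."""

    name: str
    profile: np.ndarray
    member_genes: list[str] = field(default_factory=list)


def slope_metric(bait: Sequence[float], test: Sequence[float]) -> float:
    """Sum of absolute differences between successive slopes of two profiles."""
    a = np.asarray(bait, dtype=float)
    x = np.asarray(test, dtype=float)
    if a.shape != x.shape:
        raise ValueError(f"profile length mismatch: {a.shape} vs {x.shape}")
    if a.size < 2:
        raise ValueError("slope metric needs profiles of length >= 2")
    return float(np.abs(np.diff(a) - np.diff(x)).sum())


def hcluster(
    m: GeneScaledMatrix,
    gene_set: Sequence[str],
    k: int = 13,
    metric: str = "correlation",
) -> pd.Series:
    """Average-linkage clustering of gene-scaled profiles, cut into k clades.

    ``metric`` is ``"correlation"`` (1 - Pearson, the heat-map clustering
    convention) or ``"euclidean"``.  Returns a Series mapping gene -> clade
    label (1..k); deterministic given the input order.
    """
    genes = list(gene_set)
    missing = [g for g in genes if g not in m.values.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:5]}")
    if not 2 <= k <= len(genes):
        raise ValueError(f"k={k} out of range for {len(genes)} genes")
    x = m.values.loc[genes].to_numpy(dtype=float)
    if metric == "correlation":
        # constant (all-zero) rows have no direction; nudge to avoid 0/0
        x = x.copy()
        const = x.std(axis=1) == 0
        x[const, 0] += 1e-12
    dist = pdist(x, metric=metric)
    tree = linkage(dist, method="average")
    labels = fcluster(tree, t=k, criterion="maxclust")
    return pd.Series(labels, index=genes, name="clade")


def derive_templates(
    m: GeneScaledMatrix,
    clades: pd.Series,
    grouping: Mapping[int, str] | str = "auto",
) -> dict[str, PatternTemplate]:
    """Group clades into named stage templates and average their profiles.

    ``grouping`` maps clade label -> template name, or ``"auto"`` assigns each
    clade to the canonical archetype shape with which its mean profile is most
    correlated.  The template profile is the mean gene-scaled profile of all
    member genes of the clades sharing a name.
    """
    internodes = m.internodes
    clade_ids = sorted(clades.unique())
    if grouping == "auto":
        canon = {
            name: _zscale(archetype(name, len(internodes)))
            for name in PATTERN_NAMES
        }
        mapping: dict[int, str] = {}
        for cid in clade_ids:
            prof = m.values.loc[clades.index[clades == cid]].mean(axis=0).to_numpy()
            best = max(canon, key=lambda n: _corr(canon[n], prof))
            mapping[cid] = best
    else:
        mapping = dict(grouping)
        missing = [c for c in clade_ids if c not in mapping]
        if missing:
            raise ValueError(f"grouping lacks clades: {missing}")

    templates: dict[str, PatternTemplate] = {}
    for name in dict.fromkeys(mapping.values()):
        members: list[str] = []
        for cid, nm in mapping.items():
            if nm == name:
                members.extend(clades.index[clades == cid])
        if not members:
            raise ValueError(f"template {name!r} has no member clades")
        profile = m.values.loc[members].mean(axis=0).to_numpy()
        templates[name] = PatternTemplate(name=name, profile=profile, member_genes=members)
    return templates


def _zscale(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v * 0.0


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def match_genome(
    m: GeneScaledMatrix,
    templates: Mapping[str, PatternTemplate],
    universe: Sequence[str],
    sd_mode: str = "scores",
) -> dict[str, pd.DataFrame]:
    """Score every universe gene against each template with the slope metric.

    Per template, the within-threshold flag marks genes whose score is
    strictly less than one standard deviation of that template's score
    distribution over the universe (``sd_mode="scores"``); with
    ``sd_mode="abundance"`` the threshold is instead the standard deviation of
    the gene-scaled expression values themselves.  Genes are rank-ordered
    ascending by score, ties broken by gene ID.

    Returns ``{template name: DataFrame[score, rank, within_sd]}`` indexed by
    gene, sorted by rank.
    """
    genes = list(universe)
    if not genes:
        raise ValueError("empty universe")
    missing = [g for g in genes if g not in m.values.index]
    if missing:
        raise KeyError(f"universe genes absent from matrix: {missing[:5]}")
    x = m.values.loc[genes].to_numpy(dtype=float)
    dx = np.diff(x, axis=1)
    out: dict[str, pd.DataFrame] = {}
    for name, tpl in templates.items():
        da = np.diff(np.asarray(tpl.profile, dtype=float))
        scores = np.abs(dx - da).sum(axis=1)
        if sd_mode == "scores":
            threshold = float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0
        elif sd_mode == "abundance":
            threshold = float(np.std(m.values.loc[genes].to_numpy(), ddof=1))
        else:
            raise ValueError(f"unknown sd_mode {sd_mode!r}")
        df = pd.DataFrame({"score": scores}, index=genes)
        # stable sort on an ID-sorted frame: ties stay in lexicographic order
        df = df.sort_index(kind="mergesort").sort_values("score", kind="mergesort")
        df["rank"] = np.arange(1, len(df) + 1)
        df["within_sd"] = df["score"] < threshold
        out[name] = df
    return out


def pca_covariance(
    m: GeneScaledMatrix, gene_set: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the internode x internode covariance matrix over a gene set.

    Genes are observations and internodes variables.  Returns ``(loadings,
    variance_fractions)`` with components in descending order of explained
    variance; loadings columns are unit eigenvectors.
    """
    genes = list(gene_set) if gene_set is not None else m.values.index.tolist()
    if len(genes) < 3:
        raise ValueError("PCA needs at least three genes")
    x = m.values.loc[genes].to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("PCA needs at least two internodes")
    cov = np.cov(x, rowvar=False)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    total = eigval.sum()
    fractions = eigval / total if total > 0 else eigval
    return eigvec, fractions


def templates_to_json(templates: Mapping[str, PatternTemplate]) -> list[dict]:
    return [
        {
            "name": t.name,
            "profile": [float(v) for v in t.profile],
            "member_genes": list(t.member_genes),
        }
        for t in templates.values()
    ]


def templates_from_json(data: Iterable[dict]) -> dict[str, PatternTemplate]:
    return {
        d["name"]: PatternTemplate(
            name=d["name"],
            profile=np.asarray(d["profile"], dtype=float),
            member_genes=list(d.get("member_genes", [])),
        )
        for d in data
    }
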