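"""Count-matrix ingestion, reads-per-20M normalization, and expression gating.

Raw RNA-seq counts are scaled per sample to a 20-million-read reference depth
("reads per 20 M"), replicates of the same internode are averaged, and genes
are gated at a counts-per-million detection threshold before any downstream
staging or pattern matching.  A per-gene z-scale transform puts profiles on a
common scale for clustering and slope-metric comparison.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: Reference library depth for normalized expression values.
SCALE = 20_000_000.0

#: Reads-per-20M units corresponding to one count per million.
PER20M_PER_CPM = SCALE / 1_000_000.0


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


@dataclass
class ExpressionMatrix:
    """Gene x sample read counts with per-sample metadata.

    ``counts`` rows are genes, columns are samples.  ``sample_meta`` is indexed
    by sample name with columns ``internode`` (integer ordinal), ``replicate``
    (integer) and ``genotype`` (label).  ``library_sizes`` holds total mapped
    reads per sample; it defaults to the column sum, but an explicit value wins
    because a gene-subset table cannot recover the true sequencing depth.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        dup = self.counts.index[self.counts.index.duplicated()].unique().tolist()
        if dup:
            raise ValidationError(f"duplicate gene IDs: {dup}")
        if (self.counts.values < 0).any():
            raise ValidationError("negative counts")
        missing = [s for s in self.counts.columns if s not in self.sample_meta.index]
        if missing:
            raise ValidationError(f"samples without metadata: {missing}")
        for col in ("internode", "replicate", "genotype"):
            if col not in self.sample_meta.columns:
                raise ValidationError(f"sample metadata lacks a {col!r} column")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = self.library_sizes.reindex(self.counts.columns).astype(float)
            if self.library_sizes.isna().any():
                raise ValidationError("library size missing for some samples")
        if (self.library_sizes <= 0).any():
            bad = self.library_sizes.index[self.library_sizes <= 0].tolist()
            raise ValidationError(f"non-positive library sizes: {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.sample_meta.loc[self.counts.columns, "genotype"].unique())


@dataclass
class NormalizedMatrix:
    """Replicate-collapsed reads-per-20M values, genes x internodes.

    Columns are internode ordinals in developmental order, youngest (highest
    internode number) first.  ``dispersion`` records the spread across
    replicates at each internode: standard deviation for three or more
    replicates, variance for exactly two (the reporting convention used for
    two- vs three-replicate collections), zero for a single replicate.
    """

    values: pd.DataFrame
    dispersion: pd.DataFrame
    genotype: str | None = None

    @property
    def internodes(self) -> list[int]:
        return list(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()


@dataclass
class GeneScaledMatrix:
    """Per-gene centered and scaled profiles (z-scores, population SD).

    Constant raw rows map to all-zero rows; their IDs are kept in
    ``constant_genes``.
    """

    values: pd.DataFrame
    constant_genes: list[str] = field(default_factory=list)

    @property
    def internodes(self) -> list[int]:
        return list(self.values.columns)


def _load_sample_meta(meta) -> pd.DataFrame:
    """Accept a DataFrame, a mapping, or a YAML/TSV path describing samples."""
    if isinstance(meta, pd.DataFrame):
        df = meta.copy()
    elif isinstance(meta, Mapping):
        df = pd.DataFrame.from_dict(meta, orient="index")
        df.index.name = "sample"
    else:
        path = os.fspath(meta)
        if path.endswith((".yaml", ".yml")):
            with open(path) as fh:
                raw = yaml.safe_load(fh)
            samples = raw.get("samples", raw) if isinstance(raw, dict) else raw
            if isinstance(samples, list):
                df = pd.DataFrame(samples).set_index("sample")
            else:
                df = pd.DataFrame.from_dict(samples, orient="index")
                df.index.name = "sample"
        else:
            df = pd.read_csv(path, sep="\t").set_index("sample")
    if "sample" in df.columns:
        df = df.set_index("sample")
    df["internode"] = df["internode"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    return df


def read_counts(path, meta, library_sizes: Mapping[str, float] | None = None) -> ExpressionMatrix:
    """Read a gene x sample count TSV and validate it against sample metadata.

    The first column holds gene IDs; the header holds sample names.  Library
    sizes may come from the metadata (``library_size`` column), from the
    ``library_sizes`` argument, or default to column sums.
    """
    if isinstance(path, (str, os.PathLike)):
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif isinstance(path, io.IOBase):
        df = pd.read_csv(path, sep="\t", index_col=0)
    else:
        df = path
    if df.shape[0] == 0:
        raise ValidationError("no data rows")
    meta_df = _load_sample_meta(meta)
    libs = None
    if library_sizes is not None:
        libs = pd.Series(library_sizes, dtype=float)
    elif "library_size" in meta_df.columns and meta_df["library_size"].notna().all():
        libs = meta_df["library_size"].astype(float)
    return ExpressionMatrix(counts=df, sample_meta=meta_df, library_sizes=libs)


def normalize_per20m(m: ExpressionMatrix, genotype: str | None = None) -> NormalizedMatrix:
    """Scale each sample to 20 M reads, then average replicates per internode.

    Each sample column is multiplied by ``20e6 / library_size`` and replicate
    columns of the same internode (within one genotype) are collapsed by
    arithmetic mean.  Scaling precedes averaging so replicates with unequal
    depth contribute equally.
    """
    meta = m.sample_meta.loc[m.counts.columns]
    genotypes = meta["genotype"].unique().tolist()
    if genotype is None:
        if len(genotypes) > 1:
            raise ValueError(
                f"matrix holds multiple genotypes {genotypes}; pass genotype="
            )
        genotype = genotypes[0]
    cols = meta.index[meta["genotype"] == genotype]
    if len(cols) == 0:
        raise ValueError(f"no samples for genotype {genotype!r}")
    scaled = m.counts[cols] * (SCALE / m.library_sizes[cols])
    internodes = meta.loc[cols, "internode"]
    order = sorted(internodes.unique(), reverse=True)  # youngest (apex) first
    values = {}
    disp = {}
    for ino in order:
        grp = scaled[internodes.index[internodes == ino]]
        values[ino] = grp.mean(axis=1)
        k = grp.shape[1]
        if k >= 3:
            disp[ino] = grp.std(axis=1, ddof=1)
        elif k == 2:
            disp[ino] = grp.var(axis=1, ddof=1)
        else:
            disp[ino] = pd.Series(0.0, index=grp.index)
    return NormalizedMatrix(
        values=pd.DataFrame(values)[order],
        dispersion=pd.DataFrame(disp)[order],
        genotype=genotype,
    )


def detection_filter(
    m: NormalizedMatrix, threshold_cpm: float = 1.0
) -> tuple[list[str], dict]:
    """Keep genes detected at or above a counts-per-million threshold.

    A gene is detected when its maximum replicate-collapsed reads-per-20M value
    across internodes, expressed per million reads, meets the threshold
    (1 CPM == 20 reads per 20 M).
    """
    if threshold_cpm <= 0:
        raise ValueError("threshold_cpm must be positive")
    max_cpm = m.values.max(axis=1) / PER20M_PER_CPM
    kept = m.values.index[max_cpm >= threshold_cpm].tolist()
    report = {
        "n_genes": int(m.values.shape[0]),
        "n_kept": len(kept),
        "n_dropped": int(m.values.shape[0]) - len(kept),
        "threshold_cpm": float(threshold_cpm),
    }
    return kept, report


def scale_genes(m: NormalizedMatrix) -> GeneScaledMatrix:
    """Center and scale each gene profile to mean 0, population SD 1.

    Constant rows (zero variance) become all-zero rows and are reported in
    ``constant_genes`` rather than raising.
    """
    if m.values.shape[1] < 2:
        raise ValueError("gene scaling needs at least two internodes")
    vals = m.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    scaled = (vals - mean) / sd
    scaled[constant] = 0.0
    return GeneScaledMatrix(
        values=pd.DataFrame(scaled, index=m.values.index, columns=m.values.columns),
        constant_genes=m.values.index[constant].tolist(),
    )


def housekeeping_qc(
    m: ExpressionMatrix,
    panel: Sequence[str],
    max_abs_deviation: float = 2.0,
) -> pd.DataFrame:
    """Flag samples whose housekeeping-panel expression departs from the rest.

    For each sample the statistic is the median, over panel genes, of the log2
    deviation of the gene's depth-scaled level from its cross-sample median.
    Samples with ``|deviation| > max_abs_deviation`` are marked ``exclude`` —
    the rule used to drop an internode whose panel expression collapses.

    Returns a DataFrame indexed by sample with ``deviation`` and ``exclude``.
    """
    present = [g for g in panel if g in m.counts.index]
    if len(present) < 5:
        raise ValidationError(
            f"only {len(present)} housekeeping panel genes found; need >= 5"
        )
    scaled = m.counts.loc[present] * (SCALE / m.library_sizes)
    log = np.log2(scaled + 1.0)
    ref = log.median(axis=1)
    dev = log.sub(ref, axis=0).median(axis=0)
    return pd.DataFrame(
        {"deviation": dev, "exclude": dev.abs() > max_abs_deviation}
    )


def write_normalized(m: NormalizedMatrix, path) -> None:
    """Write a normalized matrix as TSV (gene_id + one column per internode)."""
    out = m.values.copy()
    out.index.name = "gene_id"
    out.columns = [f"internode_{c}" for c in out.columns]
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_normalized(path, genotype: str | None = None) -> NormalizedMatrix:
    """Read a normalized matrix TSV written by :func:`write_normalized`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [int(str(c).replace("internode_", "")) for c in df.columns]
    return NormalizedMatrix(values=df, dispersion=df * 0.0, genotype=genotype)
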