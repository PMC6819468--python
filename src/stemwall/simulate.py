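"""Seeded synthetic data with the statistical structure of a stem time course.

One generator emits every input the analysis modules read — two genotypes'
replicate count tables, a gene annotation with chromosome ordinals and
families, a homolog map with controlled concordance, and paired promoter
FASTA sets with planted motifs — together with a ground-truth table so
recovery can be scored exactly.

The model: each gene follows one of five developmental archetypes (or a flat
background shape) scaled by a log-normal abundance; replicate counts are
negative-binomial around the per-internode mean (the standard RNA-seq count
model); genotype B shares every shape but differs by a fold-effect mixture
(none / 2-5x / 5-100x / >100x) plus one contiguous presence-absence (PAV)
block zeroed in the absent genotype; promoters are uniform-random DNA with a
consensus motif planted in secondary-pattern genes and knocked out by a
single substitution in a labelled subset of genotype-B copies.

Fold effects are drawn from mid-class ranges (away from the 2/5/100-fold bin
edges) so that count noise and the fold pseudocount leave a gene's measured
bin unambiguous; the mixture proportions, not the ranges, carry the planted
bin fractions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, SCALE
from .motifs import IUPAC, Motif
from .shapes import PATTERN_NAMES, archetype
from .stage import StageConfig, classify_gene

#: Mixture-class -> planted fold-change bin.
EFFECT_BIN = {
    "none": "<2",
    "two_to_five": ">=2",
    "five_to_hundred": ">=5",
    "over_hundred": ">=100",
}

_FAMILIES = {
    "Elongation": ("Expansin", "XTH", "AGP", "GT8D", "SUS"),
    "TransitionI": ("CesA", "GT43", "GT61", "CslF"),
    "TransitionII": ("CesA", "GT47E", "TBL", "BAHD"),
    "Secondary": ("CesA", "GT43", "PAL", "4CL", "CCR", "CAD", "Laccase", "Peroxidase"),
    "EarlyLate": ("GH17", "BGAL", "PGase"),
    "Flat": ("background",),
}


@dataclass
class SimConfig:
    """All knobs of the synthetic stem time course; the seed fixes every draw."""

    n_genes: int = 2000
    internodes: tuple[int, ...] = (9, 8, 7, 6, 5, 4, 3, 2)
    n_replicates: int = 3
    genotypes: tuple[str, str] = ("B73", "Mo17")
    pattern_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "Elongation": 0.20,
            "TransitionI": 0.10,
            "TransitionII": 0.10,
            "Secondary": 0.15,
            "EarlyLate": 0.10,
            "Flat": 0.35,
        }
    )
    #: natural-log mean/sd of per-gene peak abundance on the reads-per-20M scale
    abundance_log_mean: float = 4.0
    abundance_log_sd: float = 2.0
    #: shaped-pattern genes model curated, expressed cell-wall genes: their
    #: peak abundance is drawn from the same log-normal truncated at this
    #: floor (the expressed gate); background (Flat) genes are unrestricted
    pattern_min_abundance: float = 95.0
    #: negative-binomial overdispersion phi (variance mu + phi*mu^2);
    #: default phi = 0.01, i.e. a replicate biological CV of 0.1, the
    #: standard figure for libraries of a genetically identical inbred line
    dispersion: float = 0.01
    noise: bool = True
    library_size: int = 20_000_000
    #: genotype fold-effect mixture: class -> (proportion, (fold lo, fold hi))
    genotype_effects: Mapping[str, tuple[float, tuple[float, float]]] = field(
        default_factory=lambda: {
            "none": (0.35, (1.0, 1.0)),
            "two_to_five": (0.35, (3.2, 3.8)),
            "five_to_hundred": (0.285, (9.0, 60.0)),
            "over_hundred": (0.015, (250.0, 500.0)),
        }
    )
    n_chromosomes: int = 10
    #: (chromosome, start ordinal, gene count, direction); None disables
    pav_block: tuple[str, int, int, str] | None = ("chr6", 100, 53, "absent-in-B")
    #: abundance range (per-20M) for PAV-block genes; high enough that the
    #: presence genotype clears the 26-fold pseudocounted detection contrast
    pav_abundance_range: tuple[float, float] = (600.0, 5000.0)
    primary_concordance: float = 0.56
    secondary_concordance: float = 0.20
    motif: Motif = field(default_factory=lambda: Motif("PALBOXA", "CCGTCC"))
    motif_plant_rate: float = 0.8
    motif_background_rate: float = 0.05
    motif_knockout_rate: float = 0.2
    promoter_length: int = 1000
    with_promoters: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.pattern_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("pattern proportions must sum to 1")
        if abs(sum(p for p, _ in self.genotype_effects.values()) - 1.0) > 1e-9:
            raise ValueError("genotype effect proportions must sum to 1")
        for r in (
            self.motif_plant_rate,
            self.motif_background_rate,
            self.motif_knockout_rate,
            self.primary_concordance,
            self.secondary_concordance,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class SimResult:
    """Simulated inputs plus the ground-truth labels they were built from."""

    config: SimConfig
    counts: dict[str, ExpressionMatrix]
    annotation: pd.DataFrame
    homologs: pd.DataFrame
    promoters: dict[str, dict[str, str]]
    truth: pd.DataFrame

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        for geno, m in self.counts.items():
            m.counts.rename_axis("gene_id").to_csv(
                os.path.join(outdir, f"counts_{geno}.tsv"), sep="\t"
            )
            m.sample_meta.rename_axis("sample").to_csv(
                os.path.join(outdir, f"meta_{geno}.tsv"), sep="\t"
            )
        self.annotation.rename_axis("gene_id").to_csv(
            os.path.join(outdir, "annotation.tsv"), sep="\t"
        )
        self.homologs.rename_axis("maize_id").to_csv(
            os.path.join(outdir, "homologs.tsv"), sep="\t"
        )
        self.truth.rename_axis("gene_id").to_csv(
            os.path.join(outdir, "ground_truth.tsv"), sep="\t", float_format="%.6g"
        )
        for geno, seqs in self.promoters.items():
            with open(os.path.join(outdir, f"promoters_{geno}.fasta"), "w") as fh:
                for gene_id in sorted(seqs):
                    fh.write(f">{gene_id}\n{seqs[gene_id]}\n")


def largest_remainder(proportions: Mapping[str, float], n: int) -> dict[str, int]:
    """Integer counts summing to n, closest to the requested proportions."""
    quotas = {k: p * n for k, p in proportions.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    short = n - sum(counts.values())
    order = sorted(quotas, key=lambda k: quotas[k] - counts[k], reverse=True)
    for k in order[:short]:
        counts[k] += 1
    return counts


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(["A", "C", "G", "T"])[rng.integers(0, 4, size=length)])


def _motif_instance(rng: np.random.Generator, motif: Motif) -> str:
    """A concrete realization of a degenerate consensus."""
    return "".join(
        IUPAC[c][rng.integers(0, len(IUPAC[c]))] for c in motif.consensus.upper()
    )


def _knockout_base(rng: np.random.Generator, consensus_char: str) -> str:
    allowed = set(IUPAC[consensus_char.upper()])
    choices = sorted(set("ACGT") - allowed)
    return choices[rng.integers(0, len(choices))]


def simulate(cfg: SimConfig = SimConfig()) -> SimResult:
    """Generate the full synthetic dataset from a single seeded RNG."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    internodes = list(cfg.internodes)
    n_ino = len(internodes)
    gene_ids = [f"Zm{i:06d}" for i in range(n)]

    # --- chromosome layout ---------------------------------------------------
    per_chrom = int(np.ceil(n / cfg.n_chromosomes))
    chroms = [f"chr{i // per_chrom + 1}" for i in range(n)]
    ordinals = [i % per_chrom for i in range(n)]

    pav_idx: list[int] = []
    if cfg.pav_block is not None:
        chrom, start, length, direction = cfg.pav_block
        chrom_idx = [i for i, c in enumerate(chroms) if c == chrom]
        if not chrom_idx:
            raise ValueError(f"PAV chromosome {chrom!r} does not exist")
        chrom_len = len(chrom_idx)
        if start < 0 or start + length > chrom_len:
            raise ValueError(
                f"PAV block [{start}, {start + length}) exceeds {chrom} "
                f"({chrom_len} genes)"
            )
        pav_idx = chrom_idx[start : start + length]
        if direction not in ("absent-in-A", "absent-in-B"):
            raise ValueError(f"bad PAV direction {direction!r}")
    pav_mask = np.zeros(n, dtype=bool)
    pav_mask[pav_idx] = True

    # --- pattern assignment (exact counts; PAV genes forced Flat) ------------
    counts_by_pattern = largest_remainder(cfg.pattern_proportions, n)
    labels = np.concatenate(
        [np.repeat(name, c) for name, c in counts_by_pattern.items()]
    )
    labels = labels[rng.permutation(n)]
    if pav_mask.any():
        if counts_by_pattern.get("Flat", 0) < len(pav_idx):
            raise ValueError("PAV block larger than the Flat gene pool")
        flat_pool = [
            i for i in np.nonzero((labels == "Flat") & ~pav_mask)[0]
        ]
        swap_iter = iter(flat_pool)
        for i in pav_idx:
            if labels[i] != "Flat":
                j = next(swap_iter)
                labels[j] = labels[i]
                labels[i] = "Flat"

    # --- abundances ----------------------------------------------------------
    abundance = np.exp(
        rng.normal(cfg.abundance_log_mean, cfg.abundance_log_sd, size=n)
    )
    shaped = (labels != "Flat") & ~pav_mask
    if shaped.any() and cfg.pattern_min_abundance > 0:
        # truncated log-normal via inverse-CDF so the floor preserves the
        # distribution shape above it
        from scipy.special import ndtr, ndtri

        lo_q = ndtr(
            (np.log(cfg.pattern_min_abundance) - cfg.abundance_log_mean)
            / cfg.abundance_log_sd
        )
        u = rng.uniform(lo_q, 1.0, size=int(shaped.sum()))
        abundance[shaped] = np.exp(
            cfg.abundance_log_mean + cfg.abundance_log_sd * ndtri(u)
        )
    if pav_mask.any():
        lo, hi = cfg.pav_abundance_range
        abundance[pav_mask] = np.exp(
            rng.uniform(np.log(lo), np.log(hi), size=pav_mask.sum())
        )

    # --- genotype fold effects (non-PAV genes only) --------------------------
    effect_class = np.full(n, "none", dtype=object)
    fold = np.ones(n)
    favored = np.full(n, "", dtype=object)
    non_pav = np.nonzero(~pav_mask)[0]
    eff_props = {k: p for k, (p, _) in cfg.genotype_effects.items()}
    eff_counts = largest_remainder(eff_props, len(non_pav))
    eff_labels = np.concatenate(
        [np.repeat(name, c) for name, c in eff_counts.items()]
    )
    eff_labels = eff_labels[rng.permutation(len(non_pav))]
    effect_class[non_pav] = eff_labels
    for name, (_, (lo, hi)) in cfg.genotype_effects.items():
        idx = np.nonzero(effect_class == name)[0]
        if name == "none" or len(idx) == 0:
            continue
        fold[idx] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(idx)))
        favored[idx] = np.where(
            rng.random(len(idx)) < 0.5, cfg.genotypes[0], cfg.genotypes[1]
        )
    effect_class[pav_mask] = "pav"

    # --- per-genotype mean profiles ------------------------------------------
    shape_by_pattern = {
        name: archetype(name, internodes) for name in (*PATTERN_NAMES, "Flat")
    }
    shapes = np.vstack([shape_by_pattern[p] for p in labels])
    geno_a, geno_b = cfg.genotypes
    abund = {
        geno_a: np.where(favored == geno_a, abundance * fold, abundance),
        geno_b: np.where(favored == geno_b, abundance * fold, abundance),
    }
    if pav_mask.any():
        absent_geno = geno_a if direction == "absent-in-A" else geno_b
        abund[absent_geno] = abund[absent_geno].copy()
        abund[absent_geno][pav_mask] = 0.0

    # --- counts --------------------------------------------------------------
    lib_factor = cfg.library_size / SCALE
    matrices: dict[str, ExpressionMatrix] = {}
    for geno in cfg.genotypes:
        mean = shapes * abund[geno][:, None] * lib_factor  # genes x internodes
        cols, data, meta_rows = [], [], []
        for ino_pos, ino in enumerate(internodes):
            for rep in range(1, cfg.n_replicates + 1):
                mu = mean[:, ino_pos]
                if not cfg.noise:
                    draws = np.rint(mu).astype(np.int64)
                elif cfg.dispersion <= 0:
                    draws = rng.poisson(mu)
                else:
                    size = 1.0 / cfg.dispersion
                    p = size / (size + mu)
                    draws = rng.negative_binomial(size, p)
                name = f"{geno}_I{ino}_R{rep}"
                cols.append(name)
                data.append(draws)
                meta_rows.append(
                    {"sample": name, "internode": ino, "replicate": rep, "genotype": geno}
                )
        counts_df = pd.DataFrame(
            np.column_stack(data), index=gene_ids, columns=cols
        )
        meta = pd.DataFrame(meta_rows).set_index("sample")
        libs = pd.Series(float(cfg.library_size), index=cols)
        matrices[geno] = ExpressionMatrix(
            counts=counts_df, sample_meta=meta, library_sizes=libs
        )

    # --- expected (noiseless) stage calls ------------------------------------
    stage_cfg = StageConfig()
    expected_class = np.full(n, "", dtype=object)
    expected_gate = np.full(n, "", dtype=object)
    usable = [i for i in internodes if i in
              (*stage_cfg.secondary_internodes, *stage_cfg.elongation_internodes)]
    can_stage = len(usable) == len(
        set(stage_cfg.secondary_internodes) | set(stage_cfg.elongation_internodes)
    )
    if can_stage:
        # the stage class depends only on the shape (the ratio is scale-free)
        # and the gate only on peak abundance, so one call per pattern at a
        # reference abundance above both gates fixes the class.
        for pattern in (*PATTERN_NAMES, "Flat"):
            idx = np.nonzero(labels == pattern)[0]
            if len(idx) == 0:
                continue
            shape_profile = pd.Series(shape_by_pattern[pattern], index=internodes)
            ref_call = classify_gene(
                pattern, shape_profile * (2 * stage_cfg.high_gate), stage_cfg
            )
            # Flat genes sit exactly on a ratio boundary by construction and
            # carry no stage label in the ground truth.
            if pattern != "Flat":
                expected_class[idx] = ref_call.stage_class
        peak = abund[geno_a]
        expected_gate[:] = np.select(
            [peak >= stage_cfg.high_gate, peak >= stage_cfg.expressed_gate],
            ["Expressed500", "Expressed95"],
            default="NotExpressed",
        )
        expected_class[expected_gate != "Expressed500"] = np.where(
            expected_class[expected_gate != "Expressed500"] == "", "", "Unclassified"
        )

    # --- homolog map ----------------------------------------------------------
    ref_ids = np.array([f"AT{i:05d}" for i in range(n)], dtype=object)
    ref_class = np.full(n, "none", dtype=object)
    concordant = np.zeros(n, dtype=bool)
    for i in range(n):
        side = {
            "Elongation": "primary",
            "Transitional": "primary",
            "Secondary": "secondary",
        }.get(expected_class[i])
        u = rng.random()
        if side == "primary":
            if u < cfg.primary_concordance:
                ref_class[i], concordant[i] = "primary", True
            elif u < cfg.primary_concordance + (1 - cfg.primary_concordance) / 2:
                ref_class[i] = "secondary"
        elif side == "secondary":
            if u < cfg.secondary_concordance:
                ref_class[i], concordant[i] = "secondary", True
            elif u < cfg.secondary_concordance + (1 - cfg.secondary_concordance) / 2:
                ref_class[i] = "primary"
    homologs = pd.DataFrame(
        {
            "ref_id": ref_ids,
            "score": np.round(rng.uniform(1e-50, 1e-5, size=n), 60),
            "ref_class": ref_class,
        },
        index=gene_ids,
    )

    # --- annotation -----------------------------------------------------------
    families = np.empty(n, dtype=object)
    for pattern, fams in _FAMILIES.items():
        idx = np.nonzero(labels == pattern)[0]
        families[idx] = [fams[j % len(fams)] for j in range(len(idx))]
    annotation = pd.DataFrame(
        {
            "family": families,
            "chromosome": chroms,
            "ordinal": ordinals,
            "transcript_length": rng.integers(500, 5001, size=n),
        },
        index=gene_ids,
    )

    # --- promoters ------------------------------------------------------------
    promoters: dict[str, dict[str, str]] = {}
    motif_offset = np.full(n, -1, dtype=int)
    motif_ko = np.zeros(n, dtype=bool)
    if cfg.with_promoters:
        L = cfg.promoter_length
        mlen = len(cfg.motif)
        seqs_a: dict[str, str] = {}
        seqs_b: dict[str, str] = {}
        for i, gid in enumerate(gene_ids):
            seq = _random_dna(rng, L)
            rate = (
                cfg.motif_plant_rate
                if labels[i] == "Secondary"
                else cfg.motif_background_rate
            )
            if rng.random() < rate:
                off = int(rng.integers(0, L - mlen + 1))
                inst = _motif_instance(rng, cfg.motif)
                seq = seq[:off] + inst + seq[off + mlen:]
                motif_offset[i] = off
            seq_b = seq
            if (
                motif_offset[i] >= 0
                and labels[i] == "Secondary"
                and rng.random() < cfg.motif_knockout_rate
            ):
                pos = int(rng.integers(0, mlen))
                base = _knockout_base(rng, cfg.motif.consensus[pos])
                j = motif_offset[i] + pos
                seq_b = seq[:j] + base + seq[j + 1:]
                motif_ko[i] = True
            seqs_a[gid] = seq
            seqs_b[gid] = seq_b
        promoters = {geno_a: seqs_a, geno_b: seqs_b}

    truth = pd.DataFrame(
        {
            "pattern": labels,
            "abundance": abundance,
            "effect_class": effect_class,
            "fold": fold,
            "favored_genotype": favored,
            "fold_bin": [EFFECT_BIN.get(c, "") for c in effect_class],
            "pav": pav_mask,
            "expected_gate": expected_gate,
            "expected_class": expected_class,
            "ref_id": ref_ids,
            "ref_concordant": concordant,
            "motif_offset": motif_offset,
            "motif_knockout": motif_ko,
        },
        index=gene_ids,
    )
    return SimResult(
        config=cfg,
        counts=matrices,
        annotation=annotation,
        homologs=homologs,
        promoters=promoters,
        truth=truth,
    )


def read_ground_truth(path) -> pd.DataFrame:
    """Round-trip a ground-truth TSV written by :meth:`SimResult.write`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("pav", "ref_concordant", "motif_knockout"):
        df[col] = df[col].astype(bool)
    df["fold_bin"] = df["fold_bin"].fillna("")
    for col in ("expected_gate", "expected_class", "favored_genotype"):
        df[col] = df[col].fillna("")
    return df
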