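"""Degenerate promoter-motif scanning, enrichment, and genotype comparison.

Motifs are IUPAC consensus strings (e.g. ``CCWACC`` where W = A/T) scanned
over the promoter window immediately upstream of each gene's start.  Matching
allows an optional substitution budget (degeneracy codes match their whole
letter set at zero cost).  Over-representation in a gene set is tested
against randomly sampled background genes with an empirical resampling
p-value, and paired promoters from two genotypes can be compared to detect
motif instances lost to point mutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class Motif:
    """A named IUPAC consensus motif with an optional group label."""

    name: str
    consensus: str
    group: str = ""

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("empty motif consensus")
        bad = [c for c in self.consensus.upper() if c not in IUPAC]
        if bad:
            raise ValueError(
                f"illegal IUPAC letters {bad} in motif {self.name!r}"
            )

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass
class EnrichmentResult:
    """Gene-level motif enrichment of a target set over sampled backgrounds."""

    motif: str
    target_hits: int
    target_size: int
    background_proportion: float
    p_value: float
    n_background: int
    n_resample: int
    background_genes: list[str] = field(default_factory=list)

    @property
    def target_proportion(self) -> float:
        return self.target_hits / self.target_size


def _encode(seq: str) -> np.ndarray:
    """4-bit base encoding; non-ACGT characters encode as 0 (match nothing)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    table = np.zeros(256, dtype=np.uint8)
    for base, bit in _BASE_BIT.items():
        table[ord(base)] = bit
    return table[arr]


def _motif_masks(consensus: str) -> np.ndarray:
    return np.array(
        [sum(_BASE_BIT[b] for b in IUPAC[c]) for c in consensus.upper()],
        dtype=np.uint8,
    )


def load_promoters(source) -> dict[str, str]:
    """Read promoter sequences from FASTA (gene ID = record ID) or pass a dict."""
    if isinstance(source, Mapping):
        return {k: str(v) for k, v in source.items()}
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(source, "fasta")}


def _window(seq: str, window: int | None, gene_id: str) -> str:
    """The window of sequence closest to the gene start (FASTA 3' end)."""
    if window is None or len(seq) <= window:
        if window is not None and len(seq) < window:
            warnings.warn(
                f"promoter of {gene_id} is {len(seq)} bp, shorter than the "
                f"{window} bp window; scanning the full sequence",
                stacklevel=2,
            )
        return seq
    return seq[-window:]


def scan_sequence(
    seq: str, motif: Motif, max_mismatch: int = 0
) -> list[tuple[int, int]]:
    """All (offset, mismatches) where the motif matches with the budget."""
    code = _encode(seq)
    masks = _motif_masks(motif.consensus)
    L = len(masks)
    n = code.size - L + 1
    if n <= 0:
        return []
    mism = np.zeros(n, dtype=np.int32)
    for j in range(L):
        mism += (code[j : j + n] & masks[j]) == 0
    offsets = np.nonzero(mism <= max_mismatch)[0]
    return [(int(o), int(mism[o])) for o in offsets]


def scan(
    promoters,
    motifs: Iterable[Motif],
    max_mismatch: int = 0,
    window: int | None = 1000,
    both_strands: bool = False,
) -> pd.DataFrame:
    """Scan promoter windows for every motif.

    ``promoters`` is a FASTA path/handle or a ``{gene_id: sequence}`` mapping.
    Only the ``window`` bases nearest the gene start are scanned (shorter
    sequences are scanned fully with a warning).  Offsets are 0-based from the
    window start; ``upstream`` is the distance of the motif start upstream of
    the gene start.  Scanning is forward-strand by default.

    Returns a DataFrame with columns ``gene_id``, ``motif``, ``offset``,
    ``upstream``, ``strand``, ``mismatches``.
    """
    seqs = load_promoters(promoters)
    rows = []
    for gene_id in seqs:
        win = _window(seqs[gene_id], window, gene_id)
        strands = [("+", win)]
        if both_strands:
            strands.append(("-", win.upper().translate(_COMPLEMENT)[::-1]))
        for motif in motifs:
            for strand, s in strands:
                for offset, mm in scan_sequence(s, motif, max_mismatch):
                    rows.append(
                        {
                            "gene_id": gene_id,
                            "motif": motif.name,
                            "offset": offset,
                            "upstream": len(win) - offset,
                            "strand": strand,
                            "mismatches": mm,
                        }
                    )
    return pd.DataFrame(
        rows, columns=["gene_id", "motif", "offset", "upstream", "strand", "mismatches"]
    )


def genes_with_hit(
    promoters, motif: Motif, max_mismatch: int = 0, window: int | None = 1000
) -> set[str]:
    """IDs of genes whose promoter window contains at least one motif hit."""
    seqs = load_promoters(promoters)
    out = set()
    for gene_id, seq in seqs.items():
        win = _window(seq, window, gene_id)
        if scan_sequence(win, motif, max_mismatch):
            out.add(gene_id)
    return out


def enrich(
    target_genes: Sequence[str],
    all_genes: Sequence[str],
    promoters,
    motif: Motif,
    n_background: int = 500,
    n_resample: int = 999,
    seed: int | np.random.Generator | None = None,
    max_mismatch: int = 0,
    window: int | None = 1000,
    hit_genes: set[str] | None = None,
) -> EnrichmentResult:
    """Empirical over-representation of a motif in a target gene set.

    The background pool is ``all_genes`` minus the target.  One background
    sample of ``n_background`` genes (without replacement) is drawn and
    recorded as the reported background hit proportion.  The p-value is a
    permutation test: ``n_resample`` gene sets of the *target's* size are
    re-drawn from the pool and the p-value is the fraction whose hit
    proportion reaches the target's, with a +1/(n+1) continuity correction.
    Drawing the resamples at the target's size keeps the compared proportions
    exchangeable under the null, so null p-values are uniform; because hits
    are gene-level presence flags, each re-drawn set's hit count is an exact
    without-replacement (hypergeometric) draw from the pool.

    ``hit_genes`` may carry a precomputed set of promoter-hit gene IDs to
    avoid rescanning when testing many sets against one scan.
    """
    target = list(dict.fromkeys(target_genes))
    if not target:
        raise ValueError("empty target gene set")
    target_set = set(target)
    pool = [g for g in all_genes if g not in target_set]
    if len(pool) < n_background:
        raise ValueError(
            f"background pool of {len(pool)} genes is smaller than "
            f"n_background={n_background}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if hit_genes is None:
        seqs = load_promoters(promoters)
        hit_genes = genes_with_hit(
            seqs, motif, max_mismatch=max_mismatch, window=window
        )
    target_hits = sum(g in hit_genes for g in target)
    target_prop = target_hits / len(target)

    background = list(rng.choice(pool, size=n_background, replace=False))
    bg_hits = sum(g in hit_genes for g in background)

    pool_hits = sum(g in hit_genes for g in pool)
    resampled = rng.hypergeometric(
        pool_hits, len(pool) - pool_hits, len(target), size=n_resample
    )
    p = (1 + int((resampled / len(target) >= target_prop).sum())) / (n_resample + 1)

    return EnrichmentResult(
        motif=motif.name,
        target_hits=int(target_hits),
        target_size=len(target),
        background_proportion=bg_hits / n_background,
        p_value=float(p),
        n_background=n_background,
        n_resample=n_resample,
        background_genes=[str(g) for g in background],
    )


VERDICT_CONSERVED = "conserved"
VERDICT_LOST_A = "lost-in-A"
VERDICT_LOST_B = "lost-in-B"
VERDICT_ABSENT = "absent-in-both"


def compare_genotype_promoters(
    promoters_a,
    promoters_b,
    motifs: Iterable[Motif],
    gene_pairs: Sequence[str] | None = None,
    slack: int = 10,
    max_mismatch: int = 0,
    window: int | None = 1000,
) -> pd.DataFrame:
    """Per-gene motif presence comparison between two genotypes' promoters.

    For each gene present in both promoter sets (or listed in ``gene_pairs``)
    and each motif, hit offsets in the two genotypes are matched within
    ``slack`` bases; unmatched hits on one side yield a lost-in-the-other
    verdict.  Genes missing from either set are skipped with a warning.
    """
    seqs_a = load_promoters(promoters_a)
    seqs_b = load_promoters(promoters_b)
    genes = gene_pairs if gene_pairs is not None else sorted(seqs_a)
    motifs = list(motifs)
    rows = []
    for g in genes:
        if g not in seqs_a or g not in seqs_b:
            warnings.warn(f"gene {g} lacks a paired promoter; skipped", stacklevel=2)
            continue
        win_a = _window(seqs_a[g], window, g)
        win_b = _window(seqs_b[g], window, g)
        for motif in motifs:
            hits_a = [o for o, _ in scan_sequence(win_a, motif, max_mismatch)]
            hits_b = [o for o, _ in scan_sequence(win_b, motif, max_mismatch)]
            if not hits_a and not hits_b:
                verdict = VERDICT_ABSENT
            else:
                unmatched_a = [
                    o for o in hits_a if not any(abs(o - p) <= slack for p in hits_b)
                ]
                unmatched_b = [
                    o for o in hits_b if not any(abs(o - p) <= slack for p in hits_a)
                ]
                if unmatched_a and not hits_b:
                    verdict = VERDICT_LOST_B
                elif unmatched_b and not hits_a:
                    verdict = VERDICT_LOST_A
                elif unmatched_a:
                    verdict = VERDICT_LOST_B
                elif unmatched_b:
                    verdict = VERDICT_LOST_A
                else:
                    verdict = VERDICT_CONSERVED
            rows.append(
                {
                    "gene_id": g,
                    "motif": motif.name,
                    "offsets_a": ",".join(map(str, hits_a)),
                    "offsets_b": ",".join(map(str, hits_b)),
                    "verdict": verdict,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "motif", "offsets_a", "offsets_b", "verdict"]
    )


def read_motifs(path) -> list[Motif]:
    """Read a motif TSV with columns name, consensus, and optional group."""
    df = pd.read_csv(path, sep="\t")
    return [
        Motif(
            name=str(r["name"]),
            consensus=str(r["consensus"]),
            group=str(r.get("group", "") or ""),
        )
        for _, r in df.iterrows()
    ]
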