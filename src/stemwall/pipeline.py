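"""End-to-end orchestration: normalize -> classify -> templates -> match ->
orthology -> genotype comparison -> motif scan, from a single config.

Stages whose inputs are absent are skipped (recorded in the report) so the
core single-genotype classifier pipeline runs without a second genotype or
promoter sequences.  The report JSON mirrors the per-stage output files; no
number is recomputed for the report.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import pandas as pd
import yaml

from . import expression, inbred, motifs, orthology, patterns, stage

log = logging.getLogger("stemwall")


@dataclass
class RunConfig:
    """Paths and parameters for a full pipeline run."""

    counts_a: str
    meta_a: str
    out_dir: str
    counts_b: str | None = None
    meta_b: str | None = None
    annotation: str | None = None
    homologs: str | None = None
    promoters_a: str | None = None
    promoters_b: str | None = None
    motifs_file: str | None = None
    curated_genes: str | None = None
    stage_config: stage.StageConfig = field(default_factory=stage.StageConfig)
    pooling: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(inbred.DEFAULT_POOLING)
    )
    cpm_threshold: float = 1.0
    n_clades: int = 13
    max_mismatch: int = 0
    window: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        stage_cfg = stage.StageConfig(**raw.pop("stage_config", {}))
        pooling = {
            k: tuple(v) for k, v in raw.pop("pooling", inbred.DEFAULT_POOLING).items()
        }
        return cls(stage_config=stage_cfg, pooling=pooling, **raw)


def _exists(path: str | None) -> bool:
    return path is not None and os.path.exists(path)


def run_all(cfg: RunConfig) -> dict[str, Any]:
    """Execute every stage whose inputs are present; write report + artifacts.

    Returns the report dict (also written to ``report.json`` / ``report.md``).
    Any stage error aborts with the stage name attached.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    report: dict[str, Any] = {"stages": {}}

    def out(name: str) -> str:
        return os.path.join(cfg.out_dir, name)

    current = "normalize"
    try:
        m_a = expression.read_counts(cfg.counts_a, cfg.meta_a)
        norm_a = expression.normalize_per20m(m_a)
        expression.write_normalized(norm_a, out("normalized_A.tsv"))
        kept, det_report = expression.detection_filter(norm_a, cfg.cpm_threshold)
        report["stages"]["normalize"] = {
            "genotype": norm_a.genotype,
            "internodes": norm_a.internodes,
            **det_report,
        }

        current = "classify"
        calls = stage.classify_matrix(norm_a, cfg.stage_config)
        calls.rename_axis("gene_id").to_csv(out("stage_calls.tsv"), sep="\t")
        summary = stage.summarize_classes(calls)
        report["stages"]["classify"] = summary

        current = "templates"
        scaled = expression.scale_genes(norm_a)
        if _exists(cfg.curated_genes):
            curated = (
                pd.read_csv(cfg.curated_genes, sep="\t")["gene_id"].astype(str).tolist()
            )
        else:
            high = calls.index[calls["gate"] == stage.GATE_500]
            curated = [g for g in high if g in scaled.values.index]
        if len(curated) >= max(cfg.n_clades, 10):
            clades = patterns.hcluster(scaled, curated, k=cfg.n_clades)
            templates = patterns.derive_templates(scaled, clades, "auto")
            with open(out("templates.json"), "w") as fh:
                json.dump(patterns.templates_to_json(templates), fh, indent=1)

            current = "slope_match"
            matches = patterns.match_genome(scaled, templates, kept)
            frames = []
            for name, df in matches.items():
                d = df.copy()
                d["template"] = name
                frames.append(d.rename_axis("gene_id").reset_index())
            pd.concat(frames, ignore_index=True).to_csv(
                out("slope_matches.tsv"), sep="\t", index=False
            )
            report["stages"]["templates"] = {
                name: {
                    "n_members": len(t.member_genes),
                    "n_within_sd": int(matches[name]["within_sd"].sum()),
                }
                for name, t in templates.items()
            }
        else:
            report["stages"]["templates"] = "skipped"
            report["stages"]["slope_match"] = "skipped"

        current = "orthology"
        if _exists(cfg.homologs):
            hmap = orthology.read_homolog_map(cfg.homologs)
            hmap = hmap[hmap.index.isin(calls.index)]
            ocalls = orthology.call_orthologs(calls, hmap)
            ocalls.rename_axis("gene_id").to_csv(out("ortholog_calls.tsv"), sep="\t")
            ortho_summary = orthology.summarize_orthologs(
                ocalls, summary["class_counts"]
            )
            report["stages"]["orthology"] = ortho_summary
            if _exists(cfg.annotation):
                annot = pd.read_csv(cfg.annotation, sep="\t", index_col=0)
                fam = orthology.family_summary(ocalls, calls, annot)
                fam.to_csv(out("family_summary.tsv"), sep="\t")
        else:
            report["stages"]["orthology"] = "skipped"

        current = "compare"
        if _exists(cfg.counts_b) and _exists(cfg.meta_b):
            m_b = expression.read_counts(cfg.counts_b, cfg.meta_b)
            norm_b = expression.normalize_per20m(m_b)
            pooled = inbred.pool_stages(norm_a, norm_b, cfg.pooling)
            comp = inbred.fold_change_bins(pooled)
            comp.to_csv(out("comparisons.tsv"), sep="\t", index=False)
            fractions = inbred.bin_fractions(comp)
            result: dict[str, Any] = {"bin_fractions": fractions}
            if _exists(cfg.annotation):
                annot = pd.read_csv(cfg.annotation, sep="\t", index_col=0)
                _, blocks = inbred.flag_pav(
                    comp, annot, m_a=norm_a, m_b=norm_b
                )
                pd.DataFrame(
                    [
                        {
                            "chromosome": b.chromosome,
                            "start_ordinal": b.start_ordinal,
                            "end_ordinal": b.end_ordinal,
                            "n_genes": b.n_genes,
                            "direction": b.direction,
                        }
                        for b in blocks
                    ]
                ).to_csv(out("pav_blocks.tsv"), sep="\t", index=False)
                result["pav_blocks"] = [
                    {"chromosome": b.chromosome, "n_genes": b.n_genes,
                     "direction": b.direction}
                    for b in blocks
                ]
            report["stages"]["compare"] = result
        else:
            report["stages"]["compare"] = "skipped"

        current = "motifs"
        if _exists(cfg.promoters_a) and _exists(cfg.motifs_file):
            motif_list = motifs.read_motifs(cfg.motifs_file)
            hits = motifs.scan(
                cfg.promoters_a, motif_list,
                max_mismatch=cfg.max_mismatch, window=cfg.window,
            )
            hits.to_csv(out("motif_hits.tsv"), sep="\t", index=False)
            motif_report: dict[str, Any] = {
                "n_hits": int(hits.shape[0]),
                "genes_with_hits": int(hits["gene_id"].nunique()),
            }
            if _exists(cfg.promoters_b):
                cmp_table = motifs.compare_genotype_promoters(
                    cfg.promoters_a, cfg.promoters_b, motif_list,
                    max_mismatch=cfg.max_mismatch, window=cfg.window,
                )
                cmp_table.to_csv(out("motif_comparison.tsv"), sep="\t", index=False)
                motif_report["verdicts"] = (
                    cmp_table["verdict"].value_counts().to_dict()
                )
            report["stages"]["motifs"] = motif_report
        else:
            report["stages"]["motifs"] = "skipped"
    except Exception as exc:
        raise RuntimeError(f"stage {current!r} failed: {exc}") from exc

    with open(out("report.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    with open(out("report.md"), "w") as fh:
        fh.write("# stemwall pipeline report\n\n")
        for name, body in report["stages"].items():
            fh.write(f"## {name}\n\n```\n{json.dumps(body, indent=1, default=str)}\n```\n\n")
    return report
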