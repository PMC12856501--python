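"""End-to-end synthetic pipeline driver.

Stages run in dependency order: **simulate** (reference leader, edited
alleles, clone sets, quantification tables) → **annotate** → **edit**
(edit-outcome deltas) → **guides** → **genotype** → **stats**.  Every output
file is recorded in a manifest with its SHA-256 checksum plus provenance
(tool version, seed, config hash), so a rerun with the same config and seed
is byte-identical and a stage failure halts before downstream outputs exist.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .annotate import ScanConfig, annotate_leader
from .edits import apply_edits, predict_edit_outcome
from .genotype import classify_zygosity, genotype_clone, summarize_cohort
from .guides import enumerate_protospacers, rank_guides
from .quant import ddct, tanshinone_summary
from .simulate import (
    EditPattern,
    TruthBundle,
    ck_spec,
    plant_leader,
    simulate_clones,
    simulate_edit_pattern,
    simulate_expression_tables,
)

STAGES = ("simulate", "annotate", "edit", "guides", "genotype", "stats")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Pipeline parameters; defaults emulate the study's conditions at
    a small cohort size suitable for smoke runs."""

    outdir: str = "results/pipeline"
    seed: int = 0
    n_explants: int = 24
    cohort: dict = field(
        default_factory=lambda: {
            "HETEROZYGOUS": 3, "HOMOZYGOUS": 2, "CHIMERIC": 2, "WILD_TYPE": 1
        }
    )
    n_clones_per_line: int = 12
    clone_error_rate: float = 0.001
    min_support: int = 2
    guide_max_dist: int = 50
    gc_min: float = 0.30
    gc_max: float = 0.80
    ct_sd: float = 0.1
    analyte_cv: float = 0.05

    def as_dict(self) -> dict:
        # outdir is a location, not a scientific parameter: keep it out of
        # the provenance hash so identical runs in different places match.
        return {k: getattr(self, k) for k in self.__dataclass_fields__ if k != "outdir"}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _edited_allele(truth: TruthBundle, pattern: EditPattern, seed: int):
    edits = simulate_edit_pattern(truth, pattern, seed=seed)
    return apply_edits(truth.context.transcript_seq, edits, f"allele_{seed}")


def run_pipeline(config: PipelineConfig | None = None,
                 stages: tuple[str, ...] = STAGES) -> tuple[int, dict]:
    """Run the requested stages; returns ``(exit_status, manifest)``."""
    cfg = config or PipelineConfig()
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = io.provenance(seed=cfg.seed, config=cfg.as_dict())
    files: list[Path] = []

    def emit_tsv(name: str, df: pd.DataFrame) -> None:
        p = out / name
        io.write_tsv(p, df, meta)
        files.append(p)

    def emit_json(name: str, payload: dict) -> None:
        p = out / name
        io.write_json(p, payload, meta)
        files.append(p)

    try:
        truth = plant_leader(ck_spec(seed=cfg.seed))
    except Exception as exc:  # pragma: no cover - CK planting is robust
        raise PipelineError(f"stage simulate failed: {exc}") from exc
    ctx = truth.context
    reference = ctx.transcript_seq

    if "simulate" in stages:
        io.write_fasta(out / "reference.fa", {
            f"{ctx.transcript_id}_leader": ctx.leader_seq,
            f"{ctx.transcript_id}_cds": ctx.cds_seq,
        })
        files.append(out / "reference.fa")

    annotation = annotate_leader(ctx)
    if "annotate" in stages:
        emit_tsv("uorf_annotation.tsv", io.annotation_frame(annotation))
        emit_json("uorf_summary.json", io.annotation_summary(annotation))

    del_patterns = {
        "Del1": EditPattern("preserve_all_uatg"),
        "Del2": EditPattern("disrupt_k_uatg", k=2),
        "Del4": EditPattern("convert_to_type2"),
    }
    if "edit" in stages:
        frames, alleles = [], {}
        for i, (line, pattern) in enumerate(del_patterns.items()):
            try:
                edits = simulate_edit_pattern(truth, pattern, seed=cfg.seed + i)
            except Exception as exc:
                if pattern.kind == "convert_to_type2":
                    continue  # feasibility depends on the sampled leader
                raise PipelineError(f"stage edit failed for {line}: {exc}") from exc
            edited_ctx, _, delta = predict_edit_outcome(ctx, edits, allele_id=line)
            frames.append(io.edit_frame(line, edits))
            alleles[line] = edited_ctx.transcript_seq
            emit_json(f"delta_{line}.json", io.delta_payload(delta))
        emit_tsv("edits.tsv", pd.concat(frames, ignore_index=True))
        io.write_fasta(out / "edited_alleles.fa", alleles)
        files.append(out / "edited_alleles.fa")

    if "guides" in stages:
        cands = enumerate_protospacers(reference)
        ranked = rank_guides(cands, list(annotation.uatg_positions()),
                             max_dist=cfg.guide_max_dist,
                             gc_bounds=(cfg.gc_min, cfg.gc_max))
        emit_tsv("guides_ranked.tsv", io.guides_frame(ranked))

    if "genotype" in stages:
        line_no = 0
        calls = []
        zpayload = []
        for category, n_lines in sorted(cfg.cohort.items()):
            for _ in range(n_lines):
                line_no += 1
                line_id = f"line_{line_no:02d}"
                seed = cfg.seed * 1000 + line_no
                wt = ("WT", reference)
                if category == "WILD_TYPE":
                    mix, props = [wt], [1.0]
                elif category == "HOMOZYGOUS":
                    a = _edited_allele(truth, EditPattern("disrupt_k_uatg", k=1), seed)
                    mix, props = [(line_id + "_a", a.seq)], [1.0]
                elif category == "HETEROZYGOUS":
                    a = _edited_allele(truth, EditPattern("disrupt_k_uatg", k=1), seed)
                    mix, props = [wt, (line_id + "_a", a.seq)], [0.5, 0.5]
                else:  # CHIMERIC
                    a = _edited_allele(truth, EditPattern("disrupt_k_uatg", k=1), seed)
                    b = _edited_allele(truth, EditPattern("disrupt_k_uatg", k=2), seed + 500)
                    mix = [wt, (line_id + "_a", a.seq), (line_id + "_b", b.seq)]
                    props = [1 / 3, 1 / 3, 1 / 3]
                clones = simulate_clones(mix, props, cfg.n_clones_per_line,
                                         cfg.clone_error_rate, seed=seed)
                sigs = [genotype_clone(reference, c.seq) for c in clones]
                call = classify_zygosity(line_id, sigs, min_support=cfg.min_support)
                calls.append(call)
                zpayload.append(io.zygosity_payload(call))
        summary = summarize_cohort(cfg.n_explants, len(calls), calls)
        emit_json("zygosity_calls.json", {"lines": zpayload})
        emit_tsv("cohort_summary.tsv", io.cohort_frame(summary))

    if "stats" in stages:
        ct_df, met_df = simulate_expression_tables(
            ct_sd=cfg.ct_sd, analyte_cv=cfg.analyte_cv, seed=cfg.seed
        )
        emit_tsv("ct_values.tsv", ct_df)
        emit_tsv("metabolites.tsv", met_df)
        expr = ddct(ct_df)
        emit_tsv("relative_expression.tsv", pd.DataFrame([e.__dict__ for e in expr]))
        tans = tanshinone_summary(met_df, ck_line_id="CK")
        emit_tsv(
            "tanshinone_summary.tsv",
            pd.DataFrame(
                [
                    dict(line_id=t.line_id, tta_mg_per_g_dw=round(t.tta, 4),
                         fold_vs_ck=t.fold_vs_ck_2dp)
                    for t in tans
                ]
            ),
        )

    manifest = {
        "provenance": meta,
        "stages": list(stages),
        "files": {p.name: _sha256(p) for p in sorted(files)},
    }
    io.write_json(out / "manifest.json", manifest)
    return 0, manifest
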