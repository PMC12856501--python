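"""File formats: FASTA in/out, TSV/JSON reports, edit-spec tables.

Tabular outputs are tab-separated UTF-8 with a header row and ``.`` for
missing values; nested reports are JSON.  All user-facing coordinates are
1-based inclusive (stated in report headers); internal coordinates are
0-based half-open.  Every report carries a provenance block (tool version,
seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .annotate import LeaderContext, UOrfAnnotation, UOrfType
from .edits import DeltaReport, Edit, EditKind
from .genotype import CohortSummary, ZygosityCall
from .guides import GuideCandidate

_IUPAC = frozenset("ACGTUNRYSWKMBDHV")


class InputError(ValueError):
    pass


def read_fasta(path) -> dict[str, str]:
    """Order-preserving ``{id: sequence}``; uppercased, U normalized to T."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise InputError(f"duplicate FASTA identifier {rec.id!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - _IUPAC
        if bad:
            raise InputError(f"non-IUPAC characters {sorted(bad)} in record {rec.id!r}")
        records[rec.id] = seq
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records: dict[str, str]) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()],
        str(path),
        "fasta",
    )


def read_leader_context(path, transcript_id: str | None = None) -> LeaderContext:
    """Build a LeaderContext from a two-record FASTA (``<id>_leader`` + ``<id>_cds``)."""
    recs = read_fasta(path)
    leaders = {n[: -len("_leader")]: s for n, s in recs.items() if n.endswith("_leader")}
    cdss = {n[: -len("_cds")]: s for n, s in recs.items() if n.endswith("_cds")}
    ids = sorted(set(leaders) & set(cdss))
    if transcript_id is None:
        if len(ids) != 1:
            raise InputError(f"expected one <id>_leader/<id>_cds pair, found {ids}")
        transcript_id = ids[0]
    if transcript_id not in leaders or transcript_id not in cdss:
        raise InputError(f"missing {transcript_id}_leader / {transcript_id}_cds records")
    return LeaderContext(transcript_id, leaders[transcript_id], cdss[transcript_id])


def provenance(seed=None, config: dict | None = None) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str) if config else ""
    return {
        "tool": "uorfkit",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest() if blob else None,
    }


def _header_lines(meta: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_tsv(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    """TSV with '# key: value' provenance header lines and '.' for missing."""
    with open(path, "w", encoding="utf-8") as fh:
        if meta:
            fh.write(_header_lines(meta))
            fh.write("# coordinates: 1-based inclusive\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=".")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["."])


def write_json(path, payload: dict, meta: dict | None = None) -> None:
    doc = {"provenance": meta or {}, **payload}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, default=str) + "\n")


# ---------------------------------------------------------------------------
# Report builders
# ---------------------------------------------------------------------------


def annotation_frame(ann: UOrfAnnotation) -> pd.DataFrame:
    """Annotation report: 1-based inclusive positions, 5'->3' indexing."""
    rows = []
    for i, u in enumerate(ann.uorfs, start=1):
        rows.append(
            dict(
                transcript_id=ann.context.transcript_id,
                uorf_index=i,
                uatg_pos_1based=u.uatg_pos + 1,
                stop_end_1based=u.stop_end if u.stop_end is not None else None,
                length_nt=u.length_nt,
                type=u.utype.value,
                in_frame_with_morf=u.in_frame_with_morf,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "uorf_index", "uatg_pos_1based", "stop_end_1based",
            "length_nt", "type", "in_frame_with_morf",
        ],
    )


def annotation_summary(ann: UOrfAnnotation) -> dict:
    return {
        "transcript_id": ann.context.transcript_id,
        "counts_by_type": {t.value: n for t, n in ann.counts_by_type.items()},
        "total_complete": ann.total_complete,
    }


def delta_payload(delta: DeltaReport) -> dict:
    return {
        "counts_before": {t.value: n for t, n in delta.counts_before.items()},
        "counts_after": {t.value: n for t, n in delta.counts_after.items()},
        "total_before": delta.total_before,
        "total_after": delta.total_after,
        "percent_change_total": delta.percent_change_total,
        "uatgs_destroyed_1based": [p + 1 for p in delta.uatgs_destroyed],
        "uatgs_created_1based": [p + 1 for p in delta.uatgs_created],
        "type_transitions": [
            {"uatg_pos_1based": p + 1, "before": a.value, "after": b.value}
            for p, a, b in delta.type_transitions
        ],
    }


def guides_frame(candidates: list[GuideCandidate]) -> pd.DataFrame:
    rows = [
        dict(
            protospacer=c.protospacer,
            strand=c.strand,
            pam=c.pam,
            pam_start_1based=c.pam_start + 1,
            cut_pos_1based=c.cut_pos + 1,
            gc_fraction=round(c.gc_fraction, 3),
            dist_to_nearest_uatg=c.dist_to_nearest_uatg,
            external_offtarget_score=None,  # free-text column for web-tool scores
        )
        for c in candidates
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protospacer", "strand", "pam", "pam_start_1based", "cut_pos_1based",
            "gc_fraction", "dist_to_nearest_uatg", "external_offtarget_score",
        ],
    )


def read_edit_table(path) -> dict[str, list[Edit]]:
    """Edit specification TSV: allele_id, kind, pos_1based, del_len, alt_seq."""
    df = read_tsv(path)
    need = {"allele_id", "kind", "pos_1based"}
    if not need <= set(df.columns):
        raise InputError(f"edit table missing columns {sorted(need - set(df.columns))}")
    out: dict[str, list[Edit]] = {}
    for _, row in df.iterrows():
        kind = EditKind(str(row["kind"]).upper())
        del_len = int(float(row["del_len"])) if "del_len" in df.columns and pd.notna(row.get("del_len")) else 0
        alt = str(row["alt_seq"]) if "alt_seq" in df.columns and pd.notna(row.get("alt_seq")) else ""
        out.setdefault(str(row["allele_id"]), []).append(
            Edit(kind, int(row["pos_1based"]) - 1, del_len=del_len, alt_seq=alt)
        )
    return out


def edit_frame(allele_id: str, edits: list[Edit]) -> pd.DataFrame:
    rows = [
        dict(
            allele_id=allele_id,
            kind=e.kind.value,
            pos_1based=e.pos + 1,
            del_len=e.del_len or None,
            alt_seq=e.alt_seq or None,
        )
        for e in edits
    ]
    return pd.DataFrame(rows, columns=["allele_id", "kind", "pos_1based", "del_len", "alt_seq"])


def zygosity_payload(call: ZygosityCall) -> dict:
    return {
        "line_id": call.line_id,
        "category": call.category,
        "n_clones": call.n_clones,
        "n_discarded": call.n_discarded,
        "hemizygous_possible": call.hemizygous_possible,
        "allele_signatures": [
            {
                "support": support,
                "edits": [
                    dict(kind=e.kind.value, pos_1based=e.pos + 1,
                         del_len=e.del_len or None, alt_seq=e.alt_seq or None)
                    for e in sig
                ],
            }
            for sig, support in call.allele_signatures
        ],
    }


def cohort_frame(summary: CohortSummary) -> pd.DataFrame:
    return pd.DataFrame([asdict(summary)])
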