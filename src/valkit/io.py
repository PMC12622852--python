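"""Readers and writers for the package's plain-text dialects.

Internal coordinates are 0-based half-open; the profile and VAF TSV dialects
export 1-based inclusive coordinates (and convert back on read), and a
standard SEG export is provided for interoperability. All writers format
numbers deterministically so write -> read -> write is byte-identical.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import (
    PROFILE_COLUMNS,
    CopyNumberProfile,
    ReplicateRecord,
    SnpVafTable,
)

MANIFEST_COLUMNS = [
    "replicate_id",
    "specimen_id",
    "study",
    "site",
    "reagent_lot",
    "sequencer_or_run",
    "plate",
    "rep_k",
    "dilution_level",
    "interferent",
    "interferent_concentration",
    "qc_valid",
    "qc_fail_stage",
    "effective_purity",
    "score",
    "call",
    "call_reason",
]

SEG_FLOOR = -4.0  # log2-ratio floor for total_cn = 0


class FileFormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if isinstance(value, bool) or isinstance(value, np.bool_):
        return "1" if value else "0"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


# ---------------------------------------------------------------------------
# profiles


def write_profiles(profiles: dict[str, CopyNumberProfile], path: str | Path) -> None:
    """Write profiles as TSV (sample_id, chrom, start, end, total_cn,
    minor_cn), 1-based inclusive coordinates."""
    lines = ["sample_id\tchrom\tstart\tend\ttotal_cn\tminor_cn"]
    for sid in profiles:
        for row in profiles[sid].segments.itertuples(index=False):
            lines.append(
                f"{sid}\t{row.chrom}\t{row.start + 1}\t{row.end}\t{row.total_cn}\t{row.minor_cn}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_profiles(path: str | Path) -> dict[str, CopyNumberProfile]:
    """Parse the profile TSV dialect; validates ordering and overlap."""
    rows_by_sample: dict[str, list] = {}
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != [
        "sample_id", "chrom", "start", "end", "total_cn", "minor_cn",
    ]:
        raise FileFormatError("line 1: bad or missing profile header")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise FileFormatError(f"line {lineno}: expected 6 columns, got {len(parts)}")
        sid, chrom, start, end, t, m = parts
        try:
            row = (chrom, int(start) - 1, int(end), int(t), int(m))
        except ValueError as exc:
            raise FileFormatError(f"line {lineno}: {exc}") from exc
        prev = rows_by_sample.setdefault(sid, [])
        if prev and prev[-1][0] == chrom and row[1] < prev[-1][2]:
            raise FileFormatError(
                f"line {lineno}: segment {chrom}:{row[1]}-{row[2]} overlaps "
                f"previous segment {prev[-1][0]}:{prev[-1][1]}-{prev[-1][2]}"
            )
        prev.append(row)
    return {
        sid: CopyNumberProfile(pd.DataFrame(rows, columns=PROFILE_COLUMNS))
        for sid, rows in rows_by_sample.items()
    }


def write_seg(profiles: dict[str, CopyNumberProfile], path: str | Path) -> None:
    """Standard SEG export: seg.mean = log2(total_cn / 2), floored at -4."""
    lines = ["ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean"]
    for sid in profiles:
        for row in profiles[sid].segments.itertuples(index=False):
            mean = SEG_FLOOR if row.total_cn == 0 else math.log2(row.total_cn / 2.0)
            nmark = max(1, round((row.end - row.start) / 1_000_000))
            lines.append(
                f"{sid}\t{row.chrom}\t{row.start + 1}\t{row.end}\t{nmark}\t{mean:.4f}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# VAF tables


def write_vafs(vafs: dict[str, SnpVafTable], path: str | Path) -> None:
    lines = ["sample_id\tchrom\tpos\tvaf\tdepth\thet_in_normal"]
    for sid in vafs:
        for row in vafs[sid].rows.itertuples(index=False):
            lines.append(
                f"{sid}\t{row.chrom}\t{row.pos + 1}\t{row.vaf:.6f}\t{row.depth}\t"
                f"{1 if row.het_in_normal else 0}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vafs(path: str | Path) -> dict[str, SnpVafTable]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != [
        "sample_id", "chrom", "pos", "vaf", "depth", "het_in_normal",
    ]:
        raise FileFormatError("line 1: bad or missing VAF header")
    rows_by_sample: dict[str, list] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise FileFormatError(f"line {lineno}: expected 6 columns, got {len(parts)}")
        sid, chrom, pos, vaf, depth, het = parts
        try:
            row = (chrom, int(pos) - 1, float(vaf), int(depth), het == "1")
        except ValueError as exc:
            raise FileFormatError(f"line {lineno}: {exc}") from exc
        rows_by_sample.setdefault(sid, []).append(row)
    return {
        sid: SnpVafTable(
            pd.DataFrame(rows, columns=["chrom", "pos", "vaf", "depth", "het_in_normal"])
        )
        for sid, rows in rows_by_sample.items()
    }


# ---------------------------------------------------------------------------
# replicate manifests


def manifest_frame(replicates: list[ReplicateRecord]) -> pd.DataFrame:
    """Flatten replicate records (minus observed data) into a manifest frame."""
    rows = [{k: getattr(r, k) for k in MANIFEST_COLUMNS} for r in replicates]
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def write_manifest(replicates: list[ReplicateRecord] | pd.DataFrame, path: str | Path) -> None:
    df = replicates if isinstance(replicates, pd.DataFrame) else manifest_frame(replicates)
    lines = ["\t".join(MANIFEST_COLUMNS)]
    for row in df.itertuples(index=False):
        lines.append("\t".join(_fmt(getattr(row, c)) for c in MANIFEST_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> pd.DataFrame:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != MANIFEST_COLUMNS:
        raise FileFormatError("line 1: bad or missing manifest header")
    body = [ln for ln in lines[1:] if ln.strip()]
    if not body:
        raise FileFormatError("manifest contains no replicates (empty cohort)")
    rows = []
    for lineno, line in enumerate(body, start=2):
        parts = line.split("\t")
        if len(parts) != len(MANIFEST_COLUMNS):
            raise FileFormatError(
                f"line {lineno}: expected {len(MANIFEST_COLUMNS)} columns, got {len(parts)}"
            )
        rows.append(dict(zip(MANIFEST_COLUMNS, parts)))
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    for col in ("site", "reagent_lot", "sequencer_or_run", "plate", "rep_k"):
        df[col] = df[col].astype(int)
    for col in ("dilution_level", "effective_purity", "score"):
        df[col] = pd.to_numeric(df[col].where(df[col] != "", np.nan))
    df["qc_valid"] = df["qc_valid"] == "1"
    for col in ("interferent", "interferent_concentration", "qc_fail_stage", "call", "call_reason"):
        df[col] = df[col].where(df[col] != "", None)
    return df


def records_from_manifest(df: pd.DataFrame) -> list[ReplicateRecord]:
    """Rehydrate manifest rows into records (observed data not included)."""
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ReplicateRecord(
                replicate_id=row.replicate_id,
                specimen_id=row.specimen_id,
                study=row.study,
                site=int(row.site),
                reagent_lot=int(row.reagent_lot),
                sequencer_or_run=int(row.sequencer_or_run),
                plate=int(row.plate),
                rep_k=int(row.rep_k),
                dilution_level=None if pd.isna(row.dilution_level) else float(row.dilution_level),
                interferent=row.interferent,
                interferent_concentration=row.interferent_concentration,
                qc_valid=bool(row.qc_valid),
                qc_fail_stage=row.qc_fail_stage,
                effective_purity=float(row.effective_purity),
                score=None if pd.isna(row.score) else float(row.score),
                call=row.call,
                call_reason=row.call_reason,
            )
        )
    return records


# ---------------------------------------------------------------------------
# configs


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
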