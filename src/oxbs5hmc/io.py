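"""TSV / BED / sample-sheet readers and writers.

Matrices travel as TSV with probes in rows and a header of sample ids;
interval tracks as plain BED (0-based half-open, no header).  Floats are
written with 6 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .errors import ParseError, ValidationError
from .qc import PairedBetaSet

FLOAT_FMT = "%.6g"

BED_COLUMNS = (
    "chrom", "start", "end", "name", "score", "strand",
    "thick_start", "thick_end", "item_rgb", "block_count",
    "block_sizes", "block_starts",
)

SHEET_REQUIRED = ("sample_id", "age", "group")


def write_beta_tsv(mat: pd.DataFrame, path):
    mat.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="probe_id")


def read_beta_tsv(path) -> pd.DataFrame:
    try:
        mat = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001 - rewrap with path context
        raise ParseError(f"cannot parse matrix TSV {path}: {exc}") from exc
    return mat


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in SHEET_REQUIRED:
        if col not in sheet.columns:
            raise ParseError(f"sample sheet {path} is missing required column {col!r}")
    bad_group = set(sheet["group"].unique()) - {"young", "old"}
    if bad_group:
        raise ParseError(f"sample sheet group values must be young/old, got {sorted(bad_group)}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path):
    sheet.to_csv(path, sep="\t", index=False)


def read_bed(path) -> pd.DataFrame:
    rows = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = rows.shape[1]
    if ncol < 3 or ncol > 12:
        raise ParseError(f"{path}: BED needs 3-12 columns, found {ncol}")
    rows.columns = list(BED_COLUMNS[:ncol])
    for i, (s, e) in enumerate(zip(rows["start"], rows["end"])):
        try:
            s, e = int(s), int(e)
        except (TypeError, ValueError):
            raise ParseError(f"{path}: non-integer coordinates", line=i + 1) from None
        if s < 0 or s >= e:
            raise ParseError(f"{path}: invalid interval [{s}, {e})", line=i + 1)
    rows["start"] = rows["start"].astype(int)
    rows["end"] = rows["end"].astype(int)
    return rows


def write_bed(track: pd.DataFrame, path):
    cols = [c for c in BED_COLUMNS if c in track.columns]
    track[cols].to_csv(path, sep="\t", header=False, index=False)


def read_probe_annotation(path) -> pd.DataFrame:
    probes = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("chrom", "pos"):
        if col not in probes.columns:
            raise ParseError(f"probe annotation {path} is missing column {col!r}")
    if (probes["pos"] < 1).any():
        raise ValidationError("probe positions must be 1-based (>= 1)")
    return probes


def pair_conversions(betas: pd.DataFrame, sheet: pd.DataFrame) -> PairedBetaSet:
    """Split an array-level beta matrix into a PairedBetaSet.

    ``betas`` columns are array sample ids; ``sheet`` maps them to
    biological ids via ``biological_id`` and ``conversion`` (BS / oxBS)
    columns.  Every biological sample must have exactly one column of each
    conversion.
    """
    for col in ("biological_id", "conversion"):
        if col not in sheet.columns:
            raise ParseError(f"sample sheet is missing column {col!r}")
    sheet = sheet.set_index("sample_id")
    missing = [c for c in betas.columns if c not in sheet.index]
    if missing:
        raise ValidationError(f"beta columns absent from sample sheet: {missing[:5]}")
    by_bio: dict[str, dict[str, str]] = {}
    for sid in betas.columns:
        row = sheet.loc[sid]
        by_bio.setdefault(row["biological_id"], {})[row["conversion"]] = sid
    bs_cols, ox_cols, bios = [], [], []
    for bio, convs in by_bio.items():
        if set(convs) != {"BS", "oxBS"}:
            raise ValidationError(f"sample {bio} lacks a BS/oxBS pair")
        bios.append(bio)
        bs_cols.append(convs["BS"])
        ox_cols.append(convs["oxBS"])
    bs = betas[bs_cols].set_axis(bios, axis=1)
    ox = betas[ox_cols].set_axis(bios, axis=1)
    meta = (
        sheet.loc[bs_cols, ["biological_id", "age", "group"]]
        .assign(batch=sheet.loc[bs_cols].get("batch", "b1"))
        .set_index("biological_id")
    )
    return PairedBetaSet(bs=bs, oxbs=ox, samples=meta)


def load_config_file(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)
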