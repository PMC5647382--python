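"""File readers and writers.

All tabular files are tab-separated UTF-8 with a header row; an empty field
denotes a missing value.  β-values are printed with 4 decimals.  Signature
definitions are JSON.  Parse errors name the offending row and column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import BetaMatrix
from .signature import SignatureDefinition, SignatureLocus

__all__ = [
    "read_beta_tsv",
    "write_beta_tsv",
    "read_assay_tsv",
    "write_assay_tsv",
    "read_signature_json",
    "write_signature_json",
    "read_calls_tsv",
    "write_calls_tsv",
    "read_survival_tsv",
    "write_survival_tsv",
    "ParseError",
]


class ParseError(ValueError):
    """Malformed input file; the message names the row and column."""


def _read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: cannot parse TSV: {exc}") from exc


def read_beta_tsv(path: str | Path) -> BetaMatrix:
    """Read a β matrix TSV: first column sample id, remaining columns loci."""
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected a sample-id column plus >=1 locus column")
    sample_col = raw.columns[0]
    ids = raw[sample_col].tolist()
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ParseError(f"{path}: duplicate sample ids {dup[:5]}")
    loci = list(raw.columns[1:])
    if len(set(loci)) != len(loci):
        raise ParseError(f"{path}: duplicate locus columns")
    values = np.full((len(ids), len(loci)), np.nan)
    for j, locus in enumerate(loci):
        col = raw[locus].to_numpy()
        for i, cell in enumerate(col):
            cell = cell.strip()
            if cell == "":
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: row {i + 2} (sample {ids[i]!r}), column {locus!r}: "
                    f"non-numeric value {cell!r}"
                ) from None
            if not 0.0 <= v <= 1.0:
                raise ParseError(
                    f"{path}: row {i + 2} (sample {ids[i]!r}), column {locus!r}: "
                    f"beta {v} outside [0, 1]"
                )
            values[i, j] = v
    return BetaMatrix(pd.DataFrame(values, index=ids, columns=loci))


def write_beta_tsv(beta: BetaMatrix, path: str | Path, sample_col: str = "sample_id") -> None:
    df = beta.values.copy()
    out = df.map(lambda v: "" if pd.isna(v) else f"{v:.4f}")
    out.insert(0, sample_col, df.index)
    out.to_csv(path, sep="\t", index=False)


def read_signature_json(path: str | Path) -> SignatureDefinition:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    loci = [
        SignatureLocus(
            locus_id=entry["locus_id"],
            contrast=entry.get("contrast"),
            plex=int(entry.get("plex", 1)),
            chrom=entry.get("chrom"),
            pos=int(entry["pos"]) if entry.get("pos") is not None else None,
        )
        for entry in payload["loci"]
    ]
    return SignatureDefinition(loci=loci)


def write_signature_json(signature: SignatureDefinition, path: str | Path) -> None:
    payload = {
        "format": "msmimic-signature/1",
        "loci": [
            {
                "locus_id": l.locus_id,
                "contrast": l.contrast,
                "plex": l.plex,
                "chrom": l.chrom,
                "pos": l.pos,
            }
            for l in signature.loci
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_assay_tsv(path: str | Path) -> list:
    """Read assay records: long format, one row per sample × locus.

    Columns: sample_id, locus_id, meth_intensity, unmeth_intensity plus the
    per-sample fields control_beta, material, input_ng (repeated per row;
    empty = absent).
    """
    from .assay import AssayRecord, LocusCall

    raw = _read_table(path)
    required = {"sample_id", "locus_id", "meth_intensity", "unmeth_intensity"}
    missing = required - set(raw.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")

    def _num(cell: str, row: int, col: str, sample: str) -> float | None:
        cell = cell.strip()
        if cell == "":
            return None
        try:
            return float(cell)
        except ValueError:
            raise ParseError(
                f"{path}: row {row} (sample {sample!r}), column {col!r}: "
                f"non-numeric value {cell!r}"
            ) from None

    records: dict[str, AssayRecord] = {}
    for i, row in enumerate(raw.itertuples(index=False), start=2):
        sid = row.sample_id
        if sid not in records:
            control = _num(getattr(row, "control_beta", ""), i, "control_beta", sid)
            if control is not None and not 0.0 <= control <= 1.0:
                raise ParseError(
                    f"{path}: row {i} (sample {sid!r}), column 'control_beta': "
                    f"beta {control} outside [0, 1]"
                )
            ng = _num(getattr(row, "input_ng", ""), i, "input_ng", sid)
            material = getattr(row, "material", "") or None
            records[sid] = AssayRecord(
                sample_id=sid, calls={}, control_beta=control,
                material=material, input_ng=ng,
            )
        m = _num(row.meth_intensity, i, "meth_intensity", sid)
        u = _num(row.unmeth_intensity, i, "unmeth_intensity", sid)
        if row.locus_id in records[sid].calls:
            raise ParseError(f"{path}: row {i}: duplicate locus {row.locus_id!r} for sample {sid!r}")
        records[sid].calls[row.locus_id] = LocusCall(
            meth=m if m is not None else 0.0,
            unmeth=u if u is not None else 0.0,
        )
    return list(records.values())


def write_assay_tsv(records: list, path: str | Path) -> None:
    rows = []
    for rec in records:
        for locus, call in rec.calls.items():
            rows.append(
                {
                    "sample_id": rec.sample_id,
                    "locus_id": locus,
                    "meth_intensity": f"{call.meth:.4f}",
                    "unmeth_intensity": f"{call.unmeth:.4f}",
                    "control_beta": "" if rec.control_beta is None else f"{rec.control_beta:.4f}",
                    "material": rec.material or "",
                    "input_ng": "" if rec.input_ng is None else f"{rec.input_ng:g}",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_calls_tsv(results: pd.DataFrame, path: str | Path) -> None:
    """Write classification calls (sample_id, call, probability, n_missing, qc_code)."""
    out = results.copy()
    if "probability" in out:
        out["probability"] = out["probability"].map(
            lambda v: "" if pd.isna(v) else f"{v:.4f}"
        )
    out.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    if "probability" in df:
        df["probability"] = pd.to_numeric(df["probability"].replace("", np.nan))
    if "n_missing" in df:
        df["n_missing"] = pd.to_numeric(df["n_missing"].replace("", np.nan))
    return df


def read_survival_tsv(path: str | Path) -> pd.DataFrame:
    """Read survival records: sample_id, time_months, event, optional group."""
    df = _read_table(path)
    required = {"sample_id", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    df["time_months"] = pd.to_numeric(df["time_months"])
    df["event"] = pd.to_numeric(df["event"]).astype(int)
    if (df["time_months"] < 0).any():
        bad = df.index[df["time_months"] < 0][0]
        raise ParseError(f"{path}: row {bad + 2}: negative time")
    if not df["event"].isin([0, 1]).all():
        bad = df.index[~df["event"].isin([0, 1])][0]
        raise ParseError(f"{path}: row {bad + 2}: event must be 0 or 1")
    return df


def write_survival_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
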