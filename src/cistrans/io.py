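"""Readers and writers for the pipeline's interchange formats.

TSV tables (with header rows) are the primary interchange format; sequences
go to FASTA, TADs to BED (0-based half-open), position-weight matrices to
minimal MEME format, and reports/truth to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_fasta(sequences: pd.DataFrame, path: str | Path) -> None:
    """Write a (element_id, sequence) table as FASTA."""
    records = [
        SeqRecord(Seq(row.sequence), id=row.element_id, description="")
        for row in sequences.itertuples()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> pd.DataFrame:
    rows = [
        {"element_id": rec.id, "sequence": str(rec.seq)}
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return pd.DataFrame(rows)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write (chrom, start, end[, source]) intervals as BED (half-open)."""
    cols = ["chrom", "start", "end"] + (
        ["source"] if "source" in intervals.columns else []
    )
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, source: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "source"][: df.shape[1]]
    df.columns = names + [f"extra{i}" for i in range(df.shape[1] - len(names))]
    if source is not None:
        df["source"] = source
    return df


def write_meme(pwms: dict[str, np.ndarray], path: str | Path) -> None:
    """Write PWMs in minimal MEME motif format (uniform background)."""
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        "A 0.25 C 0.25 G 0.25 T 0.25",
        "",
    ]
    for motif_id, pwm in pwms.items():
        pwm = np.asarray(pwm, dtype=float)
        lines.append(f"MOTIF {motif_id}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {len(pwm)} "
            f"nsites= 20 E= 0"
        )
        for row in pwm:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_meme(path: str | Path) -> dict[str, np.ndarray]:
    """Read minimal MEME motifs into {motif_id: (width, 4) probability matrix}."""
    with open(path) as handle:
        parsed = bio_motifs.parse(handle, "minimal")
    out = {}
    for m in parsed:
        pwm = np.column_stack([m.pwm[b] for b in "ACGT"])
        out[m.name] = pwm
    return out


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    raise TypeError(f"not JSON serialisable: {type(obj)}")
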