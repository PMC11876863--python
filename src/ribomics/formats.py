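"""Readers and writers for the plain-text formats used across the pipeline.

Dialect: tab-separated, UTF-8, ``#`` comment lines permitted only before the
header, ``.`` for missing values.  Malformed input is reported with the
offending line number.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .normde import AbundanceMatrix
from .ribo import TranscriptModel

__all__ = [
    "FormatError",
    "read_matrix",
    "write_matrix",
    "read_conditions",
    "write_conditions",
    "read_abundance",
    "read_gmt",
    "write_gmt",
    "read_fasta",
    "write_fasta",
    "read_transcript_models",
    "write_transcript_models",
    "read_footprints",
    "write_footprints",
    "write_table",
]

MISSING = "."


class FormatError(ValueError):
    def __init__(self, path, lineno: int | None, message: str):
        self.path, self.lineno = str(path), lineno
        where = f"{path}:{lineno}" if lineno is not None else str(path)
        super().__init__(f"{where}: {message}")


def _data_lines(path):
    """Yield (lineno, fields) skipping leading comments; header is first."""
    with open(path, encoding="utf-8") as fh:
        in_preamble = True
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if in_preamble:
                    continue
                raise FormatError(path, lineno, "comment lines only allowed before the header")
            in_preamble = False
            yield lineno, line.split("\t")


def read_matrix(path, allow_missing: bool = True, nonnegative: bool = True) -> pd.DataFrame:
    """Feature-by-sample TSV matrix: header = sample ids, first column = id."""
    rows, index = [], []
    header: list[str] | None = None
    for lineno, fields in _data_lines(path):
        if header is None:
            header = fields[1:]
            if not header:
                raise FormatError(path, lineno, "header has no sample columns")
            continue
        if len(fields) != len(header) + 1:
            raise FormatError(path, lineno, f"expected {len(header) + 1} columns, got {len(fields)}")
        index.append(fields[0])
        values = []
        for col, tok in zip(header, fields[1:]):
            if tok == MISSING:
                if not allow_missing:
                    raise FormatError(path, lineno, f"missing value in column {col}")
                values.append(np.nan)
                continue
            try:
                v = float(tok)
            except ValueError:
                raise FormatError(path, lineno, f"non-numeric value {tok!r}") from None
            if nonnegative and v < 0:
                raise FormatError(path, lineno, f"negative value {v} in column {col}")
            values.append(v)
        rows.append(values)
    if header is None:
        raise FormatError(path, None, "empty matrix file")
    df = pd.DataFrame(rows, index=pd.Index(index, name="gene_id"), columns=header)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(path, None, f"duplicate feature id {dup!r}")
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(map(str, df.columns)) + "\n")
        for gid, row in df.iterrows():
            toks = [MISSING if not np.isfinite(v) else format(v, "g") for v in row.to_numpy(dtype=float)]
            fh.write(str(gid) + "\t" + "\t".join(toks) + "\n")


def read_conditions(path) -> dict[str, str]:
    """Two-column TSV (sample, condition) with header."""
    out: dict[str, str] = {}
    header_seen = False
    for lineno, fields in _data_lines(path):
        if not header_seen:
            header_seen = True
            continue
        if len(fields) != 2:
            raise FormatError(path, lineno, "expected 2 columns (sample, condition)")
        sample, condition = fields
        if sample in out:
            raise FormatError(path, lineno, f"duplicate sample {sample!r}")
        out[sample] = condition
    if not out:
        raise FormatError(path, None, "no condition assignments found")
    return out


def write_conditions(conditions: Mapping[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\tcondition\n")
        for sample, condition in conditions.items():
            fh.write(f"{sample}\t{condition}\n")


def read_abundance(matrix_path, conditions_path) -> AbundanceMatrix:
    return AbundanceMatrix(read_matrix(matrix_path), read_conditions(conditions_path))


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: name, description, member genes (tab-separated)."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(path, lineno, "GMT line needs name, description and >=1 gene")
            name, genes = fields[0], fields[2:]
            if name in sets:
                raise FormatError(path, lineno, f"duplicate set name {name!r}")
            if len(set(genes)) != len(genes):
                raise FormatError(path, lineno, f"duplicate genes within set {name!r}")
            sets[name] = genes
    if not sets:
        raise FormatError(path, None, "no gene sets found")
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write(name + "\t" + description + "\t" + "\t".join(genes) + "\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_transcript_models(model_path, fasta_path=None) -> dict[str, TranscriptModel]:
    """Model TSV (transcript_id, utr5_len, cds_len, utr3_len [, coding])."""
    seqs = read_fasta(fasta_path) if fasta_path else {}
    models: dict[str, TranscriptModel] = {}
    header_seen = False
    for lineno, fields in _data_lines(model_path):
        if not header_seen:
            header_seen = True
            continue
        if len(fields) not in (4, 5):
            raise FormatError(model_path, lineno, "expected 4 or 5 columns")
        tid = fields[0]
        try:
            utr5, cds, utr3 = (int(x) for x in fields[1:4])
        except ValueError:
            raise FormatError(model_path, lineno, "region lengths must be integers") from None
        coding = fields[4].lower() == "true" if len(fields) == 5 else True
        try:
            models[tid] = TranscriptModel(tid, utr5, cds, utr3, seqs.get(tid), coding)
        except ValueError as exc:
            raise FormatError(model_path, lineno, str(exc)) from None
    if not models:
        raise FormatError(model_path, None, "no transcript models found")
    return models


def write_transcript_models(models: Mapping[str, TranscriptModel], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("transcript_id\tutr5_len\tcds_len\tutr3_len\tcoding\n")
        for m in models.values():
            fh.write(f"{m.transcript_id}\t{m.utr5_len}\t{m.cds_len}\t{m.utr3_len}\t{m.coding}\n")


def read_footprints(path) -> pd.DataFrame:
    """Footprint TSV: transcript_id, pos_0based_5prime, read_length."""
    rows = []
    header_seen = False
    for lineno, fields in _data_lines(path):
        if not header_seen:
            header_seen = True
            continue
        if len(fields) != 3:
            raise FormatError(path, lineno, "expected 3 columns")
        try:
            rows.append((fields[0], int(fields[1]), int(fields[2])))
        except ValueError:
            raise FormatError(path, lineno, "position and length must be integers") from None
        if rows[-1][1] < 0 or rows[-1][2] <= 0:
            raise FormatError(path, lineno, "position must be >=0 and length positive")
    return pd.DataFrame(rows, columns=["transcript_id", "pos5", "length"])


def write_footprints(footprints: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("transcript_id\tpos_0based_5prime\tread_length\n")
        for tid, pos5, length in footprints[["transcript_id", "pos5", "length"]].itertuples(index=False):
            fh.write(f"{tid}\t{pos5}\t{length}\n")


def write_table(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    """Generic result table writer (TSV, '.' for missing)."""
    df.to_csv(path, sep="\t", na_rep=MISSING, index_label=index_label or df.index.name)


def _ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
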