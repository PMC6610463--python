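"""TSV formats: probes-by-samples matrices, phenotype tables, result tables.

Conventions: tab separator, '.' decimal, 'NA' missing token, probe ids in
the first column, floats written with 17 significant digits so a write/read
round trip is bitwise exact.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .meta import to_metal_table

FLOAT_FORMAT = "%.17g"
NA_TOKEN = "NA"


def read_matrix(path) -> pd.DataFrame:
    """Read a probes x samples TSV matrix, validating ids and row shape."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=NA_TOKEN,
                         keep_default_na=False,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV ({exc})") from exc
    if df.index.has_duplicates:
        dup = df.index.duplicated(keep="first")
        first = int(dup.argmax())
        raise ValueError(
            f"{path}: duplicate probe id {df.index[first]!r} on line "
            f"{first + 2}")
    ncols = df.shape[1]
    if ncols == 0:
        raise ValueError(f"{path}: no sample columns (malformed header?)")
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep=NA_TOKEN)


def read_table(path) -> pd.DataFrame:
    """Read a long-format table (phenotypes, annotation, CpG sets)."""
    return pd.read_csv(path, sep="\t", na_values=NA_TOKEN,
                       keep_default_na=False)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep=NA_TOKEN,
              index=index)


def write_results(results: pd.DataFrame, path, format: str = "ewas_tsv"
                  ) -> None:
    """Write an EWAS table (probe_id, beta, se, p, n) or a METAL-style
    meta-analysis table."""
    if format == "ewas_tsv":
        out = results.reset_index(names="probe_id")
    elif format == "metal_tsv":
        out = to_metal_table(results)
    else:
        raise ValueError(f"unknown format {format!r}")
    write_table(out, path)


def read_cpg_set(path):
    """Probe-set file: one probe id per line, optional sign and weight."""
    from .smoking_index import CpGSet
    df = read_table(path)
    if df.shape[1] == 1:
        ids = df.iloc[:, 0].tolist()
        return CpGSet(probe_ids=ids, signs=["+"] * len(ids))
    return CpGSet(
        probe_ids=df["probe_id"].tolist(),
        signs=df["sign"].tolist(),
        weights=df["weight"].tolist() if "weight" in df else None)
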