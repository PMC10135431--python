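"""Tabular input/output: TSV matrices with ``#`` metadata headers, sample
sheets, and GMT gene-set collections."""

from __future__ import annotations

import pandas as pd

SAMPLE_COLUMNS = ["sample_id", "subject_id", "age_months", "fraction", "batch"]


def write_tsv(df: pd.DataFrame, path, params: dict | None = None, index_label=None) -> None:
    """Write a DataFrame as TSV, preceded by ``# key=value`` metadata lines."""
    with open(path, "w") as fh:
        for key, value in (params or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    """Read a TSV matrix (first column = row index), skipping ``#`` lines."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def read_samples(path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SAMPLE_COLUMNS) - set(samples.columns)
    if missing:
        raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")
    samples["age_months"] = samples["age_months"].astype(int)
    samples["fraction"] = samples["fraction"].astype(str)
    return samples.set_index("sample_id", drop=False)


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file: set name, description, then tab-separated gene ids."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict, path, description: str = "ribolens") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")
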