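"""Delimited-text readers and writers for the pipeline's tables.

All tables are comma-delimited with one header line. Missing values are
empty fields. Within a replicate row, the observed allele sizes live in a
single ``alleles`` field as semicolon-joined integers; an empty field is a
failed amplification. Readers validate invariants and fail loudly, naming
the offending row; writers emit a deterministic column order so identical
inputs give byte-identical files.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

REPLICATE_COLUMNS = ["sample", "population", "species", "locus", "replicate", "alleles"]
GENOTYPE_COLUMNS = ["sample", "population", "species", "locus", "allele_a", "allele_b"]
QPCR_COLUMNS = ["well", "sample", "role", "concentration", "cq"]
QPCR_ROLES = {"standard", "unknown", "spiked_sample", "positive_control"}


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing column(s) {missing}")
    unknown = [c for c in df.columns if c not in required and c not in ("lineage", "sex")]
    if unknown:
        raise ValueError(f"{what}: unknown column(s) {unknown}")


def _parse_alleles(field) -> tuple[int, ...]:
    if field is None or pd.isna(field) or str(field) == "":
        return ()
    sizes = tuple(sorted(int(tok) for tok in str(field).split(";")))
    if any(s <= 0 for s in sizes):
        raise ValueError(f"allele sizes must be positive integers, got {field!r}")
    return sizes


def _format_alleles(alleles) -> str:
    return ";".join(str(int(a)) for a in sorted(alleles))


def read_replicate_table(path: str | Path, n_replicates: int | None = None) -> pd.DataFrame:
    """Read a replicate table; alleles become sorted integer tuples.

    Raises on duplicate (sample, locus, replicate) keys, out-of-range
    replicate indices when `n_replicates` is declared, or malformed rows.
    """
    df = pd.read_csv(path, dtype={"alleles": "string"}, keep_default_na=True)
    extra = "lineage" if "lineage" in df.columns else None
    _require_columns(df, REPLICATE_COLUMNS, f"replicate table {path}")
    df["alleles"] = [_parse_alleles(v) for v in df["alleles"]]
    df["replicate"] = df["replicate"].astype(int)
    if (df["replicate"] < 1).any():
        bad = df.index[df["replicate"] < 1][0]
        raise ValueError(f"replicate table {path}: replicate index < 1 at row {bad + 2}")
    if n_replicates is not None and (df["replicate"] > n_replicates).any():
        bad = df.index[df["replicate"] > n_replicates][0]
        raise ValueError(
            f"replicate table {path}: replicate index exceeds R={n_replicates} "
            f"at row {bad + 2}"
        )
    dup = df.duplicated(subset=["sample", "locus", "replicate"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ValueError(
            f"replicate table {path}: duplicate key "
            f"({row['sample']}, {row['locus']}, {row['replicate']})"
        )
    cols = REPLICATE_COLUMNS + ([extra] if extra else [])
    return df[cols]


def write_replicate_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out["alleles"] = [_format_alleles(a) for a in out["alleles"]]
    cols = REPLICATE_COLUMNS + (["lineage"] if "lineage" in out.columns else [])
    out[cols].to_csv(path, index=False)


def read_genotype_table(path: str | Path) -> pd.DataFrame:
    """Read consensus/reference genotypes; allele pairs are normalized so
    allele_a <= allele_b. A row with both alleles empty is a missing genotype."""
    df = pd.read_csv(path)
    _require_columns(df, GENOTYPE_COLUMNS, f"genotype table {path}")
    a = pd.to_numeric(df["allele_a"], errors="raise").astype("Int64")
    b = pd.to_numeric(df["allele_b"], errors="raise").astype("Int64")
    if (a.isna() != b.isna()).any():
        bad = df.index[(a.isna() != b.isna())][0]
        raise ValueError(
            f"genotype table {path}: half-missing genotype at row {bad + 2}"
        )
    present = ~a.isna()
    if ((a[present] <= 0) | (b[present] <= 0)).any():
        raise ValueError(f"genotype table {path}: non-positive allele size")
    lo = pd.concat([a, b], axis=1).min(axis=1)
    hi = pd.concat([a, b], axis=1).max(axis=1)
    df["allele_a"], df["allele_b"] = lo.astype("Int64"), hi.astype("Int64")
    dup = df.duplicated(subset=["sample", "locus"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ValueError(
            f"genotype table {path}: duplicate (sample, locus) "
            f"({row['sample']}, {row['locus']})"
        )
    cols = GENOTYPE_COLUMNS + [c for c in ("lineage", "sex") if c in df.columns]
    return df[cols]


def write_genotype_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = GENOTYPE_COLUMNS + [c for c in ("lineage", "sex") if c in table.columns]
    out = table[cols].copy()
    out["allele_a"] = out["allele_a"].astype("Int64")
    out["allele_b"] = out["allele_b"].astype("Int64")
    out.to_csv(path, index=False)


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR plate. Standards must carry concentrations; an empty Cq
    field marks a failed well."""
    df = pd.read_csv(path)
    _require_columns(df, QPCR_COLUMNS, f"qPCR table {path}")
    bad_role = ~df["role"].isin(QPCR_ROLES)
    if bad_role.any():
        raise ValueError(
            f"qPCR table {path}: unknown role {df.loc[bad_role.idxmax(), 'role']!r}"
        )
    std = df["role"] == "standard"
    if df.loc[std, "concentration"].isna().any():
        bad = df.index[std & df["concentration"].isna()][0]
        raise ValueError(f"qPCR table {path}: standard without concentration at row {bad + 2}")
    has_cq = df["cq"].notna()
    if (df.loc[has_cq, "cq"] <= 0).any():
        raise ValueError(f"qPCR table {path}: Cq must be positive when present")
    return df[QPCR_COLUMNS]


def write_qpcr_table(table: pd.DataFrame, path: str | Path) -> None:
    table[QPCR_COLUMNS].to_csv(path, index=False)


def write_genalex(genotypes: pd.DataFrame, path: str | Path, title: str = "kiwisat export") -> None:
    """Two-columns-per-locus codominant export for GenAlEx-style tools.

    Missing genotypes are written as 0/0, the convention those tools expect.
    """
    loci = list(pd.unique(genotypes["locus"]))
    wide_a = genotypes.pivot(index="sample", columns="locus", values="allele_a")
    wide_b = genotypes.pivot(index="sample", columns="locus", values="allele_b")
    pops = genotypes.groupby("sample")["population"].first()
    samples = list(wide_a.index)
    with open(path, "w") as fh:
        fh.write(f"{len(loci)},{len(samples)},{pops.nunique()}\n")
        fh.write(f"{title}\n")
        header = ["sample", "population"]
        for loc in loci:
            header += [loc, ""]
        fh.write(",".join(header) + "\n")
        for s in samples:
            row = [str(s), str(pops[s])]
            for loc in loci:
                a, b = wide_a.loc[s, loc], wide_b.loc[s, loc]
                row += ["0", "0"] if pd.isna(a) else [str(int(a)), str(int(b))]
            fh.write(",".join(row) + "\n")


def genotypes_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Project a simulated true-genotype table onto the genotype-table schema."""
    cols = GENOTYPE_COLUMNS + [c for c in ("lineage", "sex") if c in truth.columns]
    out = truth[cols].copy()
    out["allele_a"] = out["allele_a"].astype("Int64")
    out["allele_b"] = out["allele_b"].astype("Int64")
    return out
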