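"""Readers and writers: cohort TSV, genotype VCF, result bundles.

The cohort table is a tab-separated file with a fixed documented header
(see ``containers.COHORT_COLUMNS``); boolean flags are serialized 0/1.
Genotypes travel as a small VCF v4.2 dialect: one ALT per record, diploid
unphased GT, functional class in ``INFO/FCLASS``.  Both formats
round-trip exactly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .containers import COHORT_COLUMNS, LIPID_COLUMNS, Genotypes, ResultBundle

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_genotypes",
    "read_genotypes",
    "write_bundle",
]

_BOOL_COLUMNS = ["smoking", "hypertension", "diabetes", "mi_event", "prior_mi"]


class FormatError(ValueError):
    """A file does not conform to the documented format."""


def write_cohort(cohort: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write a cohort table as TSV with a commented metadata header."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise FormatError(f"cohort is missing mandatory columns: {missing}")
    out = cohort[COHORT_COLUMNS].copy()
    for col in _BOOL_COLUMNS:
        out[col] = out[col].astype(bool).astype(int)
    with open(path, "w") as fh:
        fh.write("# popreseq cohort table v1\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort TSV.

    Errors name the offending column (missing mandatory column) or the
    1-based data line (non-numeric lipid value).  Sanity warnings fire
    when apoA-I does not look like mg/dL or HDL does not look like
    mmol/L.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {missing}")
    for col in LIPID_COLUMNS + ["age_at_exam", "entry_age", "exit_age"]:
        raw = df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna()
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 1
            raise FormatError(
                f"{path}: non-numeric value {raw[bad].iloc[0]!r} in column "
                f"{col!r} at data line {line}"
            )
        df[col] = coerced
    bad_sex = ~df["sex"].isin(["F", "M"])
    if bad_sex.any():
        raise FormatError(f"{path}: sex must be F or M (line {int(np.nonzero(bad_sex.to_numpy())[0][0]) + 1})")
    for col in _BOOL_COLUMNS:
        df[col] = df[col].astype(bool)
    neg = [c for c in LIPID_COLUMNS if (df[c].dropna() < 0).any()]
    if neg:
        raise FormatError(f"{path}: negative lipid values in {neg}")
    apoa1_med = df["apoa1"].median()
    if not 30 <= apoa1_med <= 400:
        warnings.warn(
            f"apoA-I median {apoa1_med:.1f} looks implausible for mg/dL",
            stacklevel=2,
        )
    hdl_med = df["hdl"].median()
    if not 0.2 <= hdl_med <= 6:
        warnings.warn(
            f"HDL median {hdl_med:.2f} looks implausible for mmol/L", stacklevel=2
        )
    return df


_CONTIG = "APOA1"


def write_genotypes(genotypes: Genotypes, path: str | Path, seed: int | None = None) -> None:
    """Write genotypes as an uncompressed VCF v4.2 subset.

    One biallelic record per variant at consecutive positions on a
    free-text contig; functional class in INFO/FCLASS; diploid unphased
    GT per sample.
    """
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={_CONTIG},length=1000000>")
    header.add_line(
        '##INFO=<ID=FCLASS,Number=1,Type=String,Description="Functional class">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if seed is not None:
        header.add_line(f"##popreseq_seed={seed}")
    for s in genotypes.sample_ids:
        header.add_sample(str(s))

    gt_by_dosage = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, vid in enumerate(genotypes.variant_ids):
            rec = vcf.new_record(
                contig=_CONTIG, start=j, stop=j + 1, alleles=("A", "C"), id=vid
            )
            rec.info["FCLASS"] = str(genotypes.variants["functional_class"].iloc[j])
            col = genotypes.matrix[:, j]
            for i, s in enumerate(genotypes.sample_ids):
                rec.samples[str(s)]["GT"] = gt_by_dosage[int(col[i])]
            vcf.write(rec)


def read_genotypes(path: str | Path, cohort: pd.DataFrame) -> Genotypes:
    """Read a genotype VCF and align it to a cohort.

    Sample ids must match the cohort's ids exactly (order-insensitive);
    multi-allelic records are rejected; monomorphic records are excluded
    with a warning.  MAC/MAF and genotype counts are recomputed from the
    GT fields.
    """
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        cohort_ids = list(cohort["id"].astype(str))
        extra = sorted(set(samples) - set(cohort_ids))
        absent = sorted(set(cohort_ids) - set(samples))
        if extra or absent:
            raise FormatError(
                f"{path}: sample ids do not match cohort; "
                f"vcf-only={extra[:5]}, cohort-only={absent[:5]}"
            )
        order = [samples.index(i) for i in cohort_ids]

        columns, vids, classes = [], [], []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError(
                    f"{path}: multi-allelic record {rec.id or rec.pos} unsupported"
                )
            dosage = np.array(
                [sum(a or 0 for a in rec.samples[s]["GT"]) for s in samples],
                dtype=np.int8,
            )[order]
            if dosage.sum() == 0:
                warnings.warn(
                    f"excluding monomorphic variant {rec.id}", stacklevel=2
                )
                continue
            columns.append(dosage)
            vids.append(rec.id or f"{rec.contig}:{rec.pos}")
            classes.append(rec.info.get("FCLASS", "NS"))
    if not columns:
        matrix = np.zeros((len(cohort_ids), 0), dtype=np.int8)
    else:
        matrix = np.column_stack(columns)
    return Genotypes.from_matrix(matrix, vids, classes, np.array(cohort_ids))


# serialization precision: percentiles at 4 decimals, p-values as 4
# significant digits in scientific notation, other floats shortest-repr
_PCT_COLUMNS = {"percentile", "mean_percentile", "median_percentile"}


def _format_table(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        name = str(col)
        if name in _PCT_COLUMNS:
            out[col] = out[col].map(lambda x: f"{x:.4f}")
        elif name == "p" or name.endswith("_p"):
            out[col] = out[col].map(lambda x: f"{x:.4e}")
    return out


def write_bundle(bundle: ResultBundle, out_dir: str | Path) -> list[Path]:
    """Write every bundle table as TSV plus a run-metadata JSON file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for key, table in bundle:
        fname = key.replace("/", "_") + ".tsv"
        target = out_dir / fname
        _format_table(table).to_csv(target, sep="\t", index=False)
        written.append(target)
    meta = out_dir / "run_metadata.json"
    with open(meta, "w") as fh:
        json.dump(bundle.metadata, fh, indent=2, sort_keys=True, default=str)
    written.append(meta)
    return written
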