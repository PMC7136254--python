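"""Per-sample mutation loads from MAF-like somatic mutation tables.

A sample's *mutation load* is the count of its somatic mutation events. Three
loads are tracked, mirroring the screen's three mutation classes:

* ``load_all`` — every event regardless of class (base substitutions,
  insertions and deletions alike);
* ``load_missense`` — missense substitutions only;
* ``load_sense`` — synonymous (silent) substitutions, the neutral-selection
  contrast to missense.

Loads count mutation *events*, not mutated genes: two hits in one gene in one
sample contribute two. Unknown variant-class strings never abort a run — they
map to ``"other"`` (with a warning) and count toward ``load_all`` only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical variant classes. Anything else becomes "other".
VARIANT_CLASSES = (
    "missense", "silent", "nonsense", "splice", "insertion", "deletion", "other",
)

#: Variant_Classification values used by standard MAF files.
MAF_CLASS_MAP: dict[str, str] = {
    "Missense_Mutation": "missense",
    "Silent": "silent",
    "Nonsense_Mutation": "nonsense",
    "Nonstop_Mutation": "nonsense",
    "Splice_Site": "splice",
    "Splice_Region": "splice",
    "Frame_Shift_Ins": "insertion",
    "In_Frame_Ins": "insertion",
    "Frame_Shift_Del": "deletion",
    "In_Frame_Del": "deletion",
}


@dataclass(frozen=True)
class MafDialect:
    """Column names and class vocabulary of a MAF-like table."""

    sample_col: str = "sample"
    gene_col: str = "gene"
    class_col: str = "variant_class"
    class_map: Mapping[str, str] = field(
        default_factory=lambda: {c: c for c in VARIANT_CLASSES}
    )


#: Dialect for the simple three-column TSV written by the synthetic generator.
SIMPLE_DIALECT = MafDialect()

#: Dialect for cBioPortal/TCGA-style MAF extracts.
MAF_DIALECT = MafDialect(
    sample_col="Tumor_Sample_Barcode",
    gene_col="Hugo_Symbol",
    class_col="Variant_Classification",
    class_map=MAF_CLASS_MAP,
)


def read_maf_like(path: str | Path, dialect: MafDialect = SIMPLE_DIALECT) -> pd.DataFrame:
    """Read a tab-delimited mutation table into records.

    Returns a DataFrame with canonical columns ``sample``, ``gene``,
    ``variant_class`` (any extra input columns are passed through). Exact
    duplicate rows are dropped once each, with a logged count; variant-class
    strings missing from the dialect's vocabulary map to ``"other"`` with a
    warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in (dialect.sample_col, dialect.gene_col, dialect.class_col)
               if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    n_raw = len(df)
    df = df.drop_duplicates()
    n_dup = n_raw - len(df)
    if n_dup:
        logger.info("%s: deduplicated %d exact duplicate row(s)", path, n_dup)

    df = df.rename(columns={dialect.sample_col: "sample",
                            dialect.gene_col: "gene",
                            dialect.class_col: "variant_class"})
    if df["sample"].isna().any() or (df["sample"].str.strip() == "").any():
        raise ValueError(f"{path}: empty sample ID in mutation table")
    if df["gene"].isna().any() or (df["gene"].str.strip() == "").any():
        raise ValueError(f"{path}: empty gene symbol in mutation table")

    mapped = df["variant_class"].map(dialect.class_map)
    unknown = df.loc[mapped.isna(), "variant_class"]
    if len(unknown):
        logger.warning(
            "%s: %d record(s) with unknown variant class %s mapped to 'other'",
            path, len(unknown), sorted(unknown.unique()),
        )
    df["variant_class"] = mapped.fillna("other")
    return df.reset_index(drop=True)


def compute_loads(records: pd.DataFrame, cancer_type: str,
                  roster: Sequence[str] | None = None) -> pd.DataFrame:
    """Tally per-sample mutation loads.

    Parameters
    ----------
    records
        Mutation records with ``sample``/``gene``/``variant_class`` columns
        (as from :func:`read_maf_like`).
    cancer_type
        Cohort label carried into the output.
    roster
        Optional full sample list; rostered samples with no records get load
        0. Without a roster, ``records`` must be non-empty and only observed
        samples appear.

    Returns a DataFrame indexed by sample with integer columns ``load_all``,
    ``load_missense``, ``load_sense`` and a ``cancer_type`` column.
    """
    if len(records) == 0 and roster is None:
        raise ValueError("no mutation records and no sample roster: loads undefined")

    if len(records):
        load_all = records.groupby("sample").size()
        by_class = (records.groupby(["sample", "variant_class"]).size()
                    .unstack(fill_value=0))
    else:
        load_all = pd.Series(0, index=pd.Index([], name="sample"), dtype=int)
        by_class = pd.DataFrame(index=load_all.index)

    index = load_all.index
    if roster is not None:
        index = index.union(pd.Index(roster, name="sample"))
    if index.has_duplicates:
        raise ValueError("duplicate sample IDs in roster")

    out = pd.DataFrame(index=index)
    out["load_all"] = load_all.reindex(index, fill_value=0).astype(int)
    for col, cls in (("load_missense", "missense"), ("load_sense", "silent")):
        if cls in by_class.columns:
            out[col] = by_class[cls].reindex(index, fill_value=0).astype(int)
        else:
            out[col] = 0
    out["cancer_type"] = cancer_type
    out.index.name = "sample"
    return out


def write_loads(loads: pd.DataFrame, path: str | Path) -> None:
    loads.to_csv(path, sep="\t")


def read_loads(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    for col in ("load_all", "load_missense", "load_sense"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing load column {col!r}")
    return df
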