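"""Expression matrices and z-score transformation.

Expression is held genes x samples. A z-score expresses a sample's expression
of a gene as the number of standard deviations from the mean of a reference
population; by default the reference is the whole cohort, with sample
standard deviation (ddof=1). Genes whose reference values are constant have
no defined z-score and are dropped with a logged list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with z-score provenance.

    Attributes
    ----------
    values
        DataFrame, index = gene symbols, columns = sample IDs.
    is_zscore
        Whether values are z-scores.
    reference
        Human-readable descriptor of the reference population used (or
        ``"none"`` for raw values).
    """

    values: pd.DataFrame
    is_zscore: bool = False
    reference: str = "none"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene symbols: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def zscore_transform(raw: ExpressionMatrix,
                     reference_samples: Sequence[str] | str = "all") -> ExpressionMatrix:
    """Per-gene z-scores against a reference population.

    ``z = (x - mu_ref) / sigma_ref`` with sigma_ref the sample sd (ddof=1)
    over the reference samples (``"all"`` = every sample in the cohort).
    Genes with zero reference variance are dropped and enumerated in the log;
    if none survive the input has no variable genes and that is an error.
    """
    if isinstance(reference_samples, str):
        if reference_samples != "all":
            raise ValueError("reference_samples must be 'all' or a sample list")
        ref = raw.values
        ref_desc = f"all {raw.values.shape[1]} cohort samples"
    else:
        reference_samples = list(reference_samples)
        if not reference_samples:
            raise ValueError("reference sample subset is empty")
        missing = [s for s in reference_samples if s not in raw.values.columns]
        if missing:
            raise ValueError(f"reference samples not in matrix: {missing[:5]}")
        ref = raw.values[reference_samples]
        ref_desc = f"{len(reference_samples)} designated reference samples"

    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()]
    if len(constant) == len(raw.values):
        raise ValueError("no variable genes: every gene is constant in the reference")
    if len(constant):
        logger.warning("dropped %d zero-variance gene(s): %s%s",
                       len(constant), list(constant[:10]),
                       "..." if len(constant) > 10 else "")
    keep = raw.values.index.difference(constant, sort=False)
    z = raw.values.loc[keep].sub(mu.loc[keep], axis=0).div(sd.loc[keep], axis=0)
    return ExpressionMatrix(z, is_zscore=True, reference=ref_desc)


def read_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene symbol)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        width = len(header)
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and len(line.rstrip("\n").split("\t")) != width:
                raise ValueError(f"{path}:{lineno}: ragged row "
                                 f"(expected {width} fields)")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df)  # duplicate genes rejected in __post_init__


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write genes x samples TSV, lossless to 10 significant digits."""
    matrix.values.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")
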