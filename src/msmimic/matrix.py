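"""Sample-by-locus methylation matrices.

The β-value — the fraction of methylated signal at a CpG locus, in
[0, 1] — is the universal currency of the pipeline.  A :class:`BetaMatrix`
wraps a pandas DataFrame (samples as rows, CpG loci as columns) with
explicit missingness (NaN) and validation of the [0, 1] range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BetaMatrix"]


@dataclass
class BetaMatrix:
    """Samples × loci methylation fractions with explicit missingness.

    Parameters
    ----------
    values
        DataFrame of β-values; index holds sample ids, columns locus ids.
        Missing measurements are NaN.
    """

    values: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        vals = self.values
        if not isinstance(vals, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame")
        if vals.index.has_duplicates:
            dups = vals.index[vals.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if vals.columns.has_duplicates:
            dups = vals.columns[vals.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate locus ids: {dups}")
        arr = vals.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (arr < 0.0) | (arr > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value out of [0, 1] at sample {vals.index[i]!r}, "
                f"locus {vals.columns[j]!r}: {arr[i, j]}"
            )

    # -- basic introspection -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    # -- derived matrices ----------------------------------------------------

    def subset_loci(self, loci: list[str]) -> "BetaMatrix":
        missing = [l for l in loci if l not in self.values.columns]
        if missing:
            raise KeyError(f"loci absent from matrix: {missing[:5]}")
        return BetaMatrix(self.values.loc[:, loci].copy())

    def subset_samples(self, samples: list[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[samples].copy())

    def fill_median(self) -> "BetaMatrix":
        """Fill missing entries with per-locus medians (0.5 for all-NaN loci)."""
        med = self.values.median(axis=0).fillna(0.5)
        return BetaMatrix(self.values.fillna(med))

    def top_variable_loci(self, n: int) -> list[str]:
        """Ids of the ``n`` most variably methylated loci.

        Variance is computed over present values; ties broken by locus id so
        the selection is reproducible.
        """
        var = self.values.var(axis=0, ddof=1).fillna(0.0)
        order = sorted(var.index, key=lambda l: (-var[l], l))
        return order[: min(n, len(order))]

    def equals(self, other: "BetaMatrix") -> bool:
        """Equality including the missingness pattern."""
        a, b = self.values, other.values
        if list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
            return False
        return np.array_equal(a.to_numpy(), b.to_numpy(), equal_nan=True)
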