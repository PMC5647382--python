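"""Extension-assay records and sample-level QC.

A methylation-sensitive extension assay reports, per CpG locus, the
intensities of the methylated and unmethylated alleles (bisulfite treatment
turns methylation state into a sequence variant, resolved by single-base
extension and mass spectrometry).  The apparent β is the methylated
proportion m/(m+u).  Plex 1 carries a bisulfite-conversion control
targeting an invariably unmethylated locus: residual methylated-like signal
there indicates failed conversion.

Sample QC follows a fixed precedence: conversion failure dominates, then
the per-locus fail count (more than ``max_failed`` missing loci of the
signature), otherwise the sample is analyzable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "LocusCall",
    "AssayRecord",
    "QCReport",
    "ConcordanceReport",
    "beta_from_extension",
    "conversion_control_check",
    "sample_qc",
    "qc_report",
    "compare_beta",
    "DEFAULT_DNA_BINS",
]

#: Input-DNA mass bins (ng) for assay-performance reports.
DEFAULT_DNA_BINS = (2.0, 10.0, 50.0, 100.0)


@dataclass
class LocusCall:
    """Methylated/unmethylated intensity pair for one locus."""

    meth: float
    unmeth: float

    def __post_init__(self) -> None:
        if self.meth < 0 or self.unmeth < 0:
            raise ValueError("intensities must be >= 0")

    @property
    def status(self) -> str:
        return "NO_CALL" if self.meth + self.unmeth == 0 else "OK"

    @property
    def beta(self) -> float:
        return beta_from_extension(self.meth, self.unmeth)


@dataclass
class AssayRecord:
    """Per-sample extension-assay intensities plus the conversion control."""

    sample_id: str
    calls: dict[str, LocusCall] = field(default_factory=dict)
    control_beta: float | None = None
    material: str | None = None
    input_ng: float | None = None

    def __post_init__(self) -> None:
        if self.control_beta is not None and not 0.0 <= self.control_beta <= 1.0:
            raise ValueError("control beta must be in [0, 1]")

    def beta_vector(self, loci: Sequence[str]) -> np.ndarray:
        """Partial β vector aligned to ``loci`` (NaN for failed/absent calls)."""
        out = np.full(len(loci), np.nan)
        for i, locus in enumerate(loci):
            call = self.calls.get(locus)
            if call is not None and call.status == "OK":
                out[i] = call.beta
        return out

    def n_failed(self, loci: Sequence[str]) -> int:
        return int(np.isnan(self.beta_vector(loci)).sum())


def beta_from_extension(meth: float, unmeth: float) -> float:
    """β = m / (m + u); both-zero intensities mean the locus had no call."""
    if meth < 0 or unmeth < 0:
        raise ValueError("intensities must be >= 0")
    total = meth + unmeth
    if total == 0:
        raise ValueError("no call: both intensities are zero")
    return meth / total


def conversion_control_check(record: AssayRecord, cutoff: float = 0.1) -> bool:
    """Pass iff the conversion-control apparent β is at or below ``cutoff``.

    An absent control is treated, conservatively, as a conversion failure.
    """
    if record.control_beta is None:
        return False
    return record.control_beta <= cutoff


@dataclass
class QCReport:
    """Per-sample QC dispositions and cohort tallies."""

    per_sample: pd.DataFrame  # sample_id, n_failed_loci, conversion_pass, disposition
    tallies: dict[str, int]
    by_dna_bin: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if sum(self.tallies.values()) != len(self.per_sample):
            raise ValueError("QC tallies must sum to the cohort size")


def sample_qc(
    record: AssayRecord,
    loci: Sequence[str],
    max_failed: int = 6,
    conversion_cutoff: float = 0.1,
) -> dict:
    """QC disposition for one sample.

    Conversion failure dominates; otherwise a sample with more than
    ``max_failed`` failed loci is LOCUS_QC_FAIL; otherwise ANALYZABLE.
    """
    n_failed = record.n_failed(loci)
    conv = conversion_control_check(record, cutoff=conversion_cutoff)
    if not conv:
        disposition = "BISULFITE_FAIL"
    elif n_failed > max_failed:
        disposition = "LOCUS_QC_FAIL"
    else:
        disposition = "ANALYZABLE"
    return {
        "sample_id": record.sample_id,
        "n_failed_loci": n_failed,
        "conversion_pass": conv,
        "disposition": disposition,
        "input_ng": record.input_ng,
        "material": record.material,
    }


def qc_report(
    records: Sequence[AssayRecord],
    loci: Sequence[str],
    max_failed: int = 6,
    conversion_cutoff: float = 0.1,
    dna_bins: Sequence[float] = DEFAULT_DNA_BINS,
) -> QCReport:
    """Cohort QC report: per-sample dispositions, tallies and DNA-input bins."""
    rows = [
        sample_qc(r, loci, max_failed=max_failed, conversion_cutoff=conversion_cutoff)
        for r in records
    ]
    per_sample = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "n_failed_loci", "conversion_pass",
            "disposition", "input_ng", "material",
        ],
    )
    tallies = {
        d: int((per_sample["disposition"] == d).sum())
        for d in ("ANALYZABLE", "BISULFITE_FAIL", "LOCUS_QC_FAIL")
    }
    by_bin = None
    if per_sample["input_ng"].notna().any():
        edges = [-np.inf, *dna_bins, np.inf]
        names = (
            [f"<{dna_bins[0]:g}"]
            + [f"{a:g}-{b:g}" for a, b in zip(dna_bins[:-1], dna_bins[1:])]
            + [f">{dna_bins[-1]:g}"]
        )
        binned = pd.cut(per_sample["input_ng"], bins=edges, labels=names)
        by_bin = (
            per_sample.assign(dna_bin=binned)
            .groupby("dna_bin", observed=False)["disposition"]
            .value_counts()
            .unstack(fill_value=0)
        )
    return QCReport(per_sample=per_sample, tallies=tallies, by_dna_bin=by_bin)


@dataclass
class ConcordanceReport:
    """Agreement between two β-measurement platforms on paired samples."""

    r_squared: float
    slope: float
    intercept: float
    n_pairs: int
    per_locus_mad: pd.Series
    call_agreement: float | None = None

    def __post_init__(self) -> None:
        if self.r_squared > 1.0 + 1e-12:
            raise ValueError("R^2 cannot exceed 1")


def compare_beta(
    a: pd.DataFrame,
    b: pd.DataFrame,
    pairing: dict[str, str] | None = None,
    calls_a: pd.Series | None = None,
    calls_b: pd.Series | None = None,
) -> ConcordanceReport:
    """Concordance of paired β estimates from two sources.

    ``a`` and ``b`` are samples × loci frames sharing locus columns; rows are
    paired by shared sample id unless an explicit ``pairing`` (a-id → b-id)
    is given.  Reports the pooled least-squares R², slope and intercept,
    the per-locus mean absolute difference, and — when calls are supplied —
    the call-level agreement fraction.
    """
    if pairing is None:
        shared = [s for s in a.index if s in b.index]
        pairing = {s: s for s in shared}
    if not pairing:
        raise ValueError("no overlapping sample pairs")
    loci = [l for l in a.columns if l in b.columns]
    if not loci:
        raise ValueError("no shared loci between sources")
    A = a.loc[list(pairing.keys()), loci].to_numpy(dtype=float)
    B = b.loc[list(pairing.values()), loci].to_numpy(dtype=float)
    ok = ~(np.isnan(A) | np.isnan(B))
    if not ok.any():
        raise ValueError("no complete paired values")
    x, y_ = A[ok], B[ok]
    if np.ptp(x) == 0:  # degenerate regressor: fall back to agreement-only
        slope, intercept, r = 0.0, float(y_.mean()), 0.0
    else:
        fit = sps.linregress(x, y_)
        slope, intercept, r = fit.slope, fit.intercept, fit.rvalue
    mad = pd.Series(
        np.nanmean(np.abs(A - B), axis=0), index=loci, name="mean_abs_difference"
    )
    agreement = None
    if calls_a is not None and calls_b is not None:
        pa = calls_a.loc[list(pairing.keys())].to_numpy()
        pb = calls_b.loc[list(pairing.values())].to_numpy()
        agreement = float((pa == pb).mean())
    return ConcordanceReport(
        r_squared=float(r**2),
        slope=float(slope),
        intercept=float(intercept),
        n_pairs=len(pairing),
        per_locus_mad=mad,
        call_agreement=agreement,
    )
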