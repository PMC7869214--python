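"""Calibrator-normalized expression arithmetic.

Relative mRNA levels come from qPCR quantification cycles by the classic
double-delta method: with amplification efficiency E (2.0 for perfect
doubling),

    level(s) = E ** -[(Cq_target,s - Cq_ref,s) - (Cq_target,cal - Cq_ref,cal)]

against a housekeeping reference gene (ACT1 in yeast work) and a calibrator
sample whose level is 1 by definition.  Relative protein abundance comes
from GFP fluorescence normalized to culture density (RFU = FI / OD600),
again expressed relative to a calibrator.  Translation efficiency is the
ratio of relative protein to relative mRNA for the same gene, sample and
calibrator; strain comparisons are reported as percent differences.

Cq values are taken as inputs: quantification-cycle calling (e.g. the
second-derivative-maximum method) happens in the instrument software,
upstream of this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CqMeasurement",
    "RelativeLevel",
    "FluorescenceReading",
    "TranslationEfficiency",
    "relative_expression",
    "rfu",
    "relative_abundance",
    "translation_efficiency",
    "percent_difference",
    "stress_te_gain",
    "replicate_summary",
    "two_group_test",
    "significance_stars",
]


@dataclass(frozen=True)
class CqMeasurement:
    """One qPCR quantification cycle for (sample, gene, replicate)."""

    sample: str
    gene: str
    cq: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if not self.cq > 0:
            raise ValueError(f"cq must be > 0, got {self.cq}")


@dataclass(frozen=True)
class RelativeLevel:
    """A calibrator-normalized quantity; level(calibrator) == 1 exactly."""

    sample: str
    gene: str
    level: float
    kind: str  # "mRNA" or "protein"
    calibrator: str

    def __post_init__(self) -> None:
        if not self.level > 0:
            raise ValueError(f"level must be > 0, got {self.level}")
        if self.kind not in ("mRNA", "protein"):
            raise ValueError(f"kind must be 'mRNA' or 'protein', got {self.kind!r}")


@dataclass(frozen=True)
class FluorescenceReading:
    """GFP fluorescence intensity (ex 488 / em 509 nm) with culture OD600."""

    sample: str
    fi: float
    od600: float


@dataclass(frozen=True)
class TranslationEfficiency:
    """Relative protein level / relative mRNA level, same calibrator."""

    sample: str
    gene: str
    te: float

    def __post_init__(self) -> None:
        if not self.te > 0:
            raise ValueError(f"te must be > 0, got {self.te}")


def _cq_frame(cq: Iterable[CqMeasurement] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(cq, pd.DataFrame):
        missing = {"sample", "gene", "cq"} - set(cq.columns)
        if missing:
            raise ValueError(f"Cq table missing columns: {sorted(missing)}")
        return cq
    return pd.DataFrame(
        [{"sample": m.sample, "gene": m.gene, "replicate": m.replicate, "cq": m.cq}
         for m in cq]
    )


def relative_expression(
    cq: Iterable[CqMeasurement] | pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_sample: str,
    efficiency: float = 2.0,
) -> list[RelativeLevel]:
    """Relative transcription of ``target_gene`` by the ΔΔCq method.

    Replicate Cq are averaged per (sample, gene) before the ΔΔ arithmetic.
    The calibrator sample's level is exactly 1.  ``efficiency`` must lie in
    (1, 2]: 2.0 is perfect per-cycle doubling.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError(f"efficiency must be in (1, 2], got {efficiency}")
    df = _cq_frame(cq)
    mean_cq = df.groupby(["sample", "gene"])["cq"].mean()

    def _get(sample: str, gene: str) -> float:
        try:
            return float(mean_cq.loc[(sample, gene)])
        except KeyError:
            raise ValueError(f"missing Cq for gene {gene!r} in sample {sample!r}")

    samples = sorted(df["sample"].unique())
    if calibrator_sample not in samples:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in Cq table")
    dcq_cal = _get(calibrator_sample, target_gene) - _get(
        calibrator_sample, reference_gene
    )
    levels = []
    for s in samples:
        dcq = _get(s, target_gene) - _get(s, reference_gene)
        level = efficiency ** -(dcq - dcq_cal)
        levels.append(
            RelativeLevel(
                sample=s, gene=target_gene, level=level,
                kind="mRNA", calibrator=calibrator_sample,
            )
        )
    return levels


def rfu(reading: FluorescenceReading, blank_fi: float = 0.0) -> float:
    """Relative fluorescence unit: FI / OD600, a per-biomass GFP proxy.

    ``blank_fi`` optionally subtracts an untagged-strain background before
    normalization (off by default).
    """
    if not reading.od600 > 0:
        raise ValueError(f"od600 must be > 0, got {reading.od600}")
    return (reading.fi - blank_fi) / reading.od600


def relative_abundance(
    rfus: Mapping[str, float],
    calibrator_sample: str,
    gene: str = "",
) -> list[RelativeLevel]:
    """Protein levels relative to the calibrator sample's RFU."""
    if calibrator_sample not in rfus:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in RFU map")
    cal = rfus[calibrator_sample]
    if not cal > 0:
        raise ValueError(f"calibrator RFU must be > 0, got {cal}")
    return [
        RelativeLevel(
            sample=s, gene=gene, level=v / cal, kind="protein",
            calibrator=calibrator_sample,
        )
        for s, v in rfus.items()
    ]


def translation_efficiency(
    protein: RelativeLevel, mrna: RelativeLevel
) -> TranslationEfficiency:
    """TE = relative protein / relative mRNA (same sample, gene, calibrator)."""
    if protein.sample != mrna.sample:
        raise ValueError(
            f"sample mismatch: {protein.sample!r} vs {mrna.sample!r}"
        )
    if protein.gene and mrna.gene and protein.gene != mrna.gene:
        raise ValueError(f"gene mismatch: {protein.gene!r} vs {mrna.gene!r}")
    if protein.calibrator != mrna.calibrator:
        raise ValueError(
            f"calibrator mismatch: {protein.calibrator!r} vs {mrna.calibrator!r}"
        )
    if not mrna.level > 0:
        raise ValueError("mRNA level must be > 0")
    return TranslationEfficiency(
        sample=protein.sample,
        gene=protein.gene or mrna.gene,
        te=protein.level / mrna.level,
    )


def percent_difference(a: float, b: float) -> float:
    """100 × (a − b) / b.  Tables round to the nearest integer percent."""
    if not b > 0:
        raise ValueError(f"baseline must be > 0, got {b}")
    return 100.0 * (a - b) / b


def stress_te_gain(
    baseline_te_ratio: float,
    mrna_fold_control: float,
    mrna_fold_treated: float,
    protein_fold_control: float,
    protein_fold_treated: float,
) -> float:
    """Percent TE advantage of a treated strain over a control under stress.

    Each strain's stressed TE is its unstressed TE scaled by its own
    protein/mRNA induction ratio; the control's unstressed TE is the
    calibrator (1), the treated strain starts ``baseline_te_ratio`` higher.
    Returns percent_difference(TE_treated, TE_control) under stress.
    """
    te_control = 1.0 * protein_fold_control / mrna_fold_control
    te_treated = baseline_te_ratio * protein_fold_treated / mrna_fold_treated
    return percent_difference(te_treated, te_control)


def replicate_summary(values: Sequence[float]) -> tuple[float, float, int]:
    """(mean, sample sd with n−1 denominator, n); sd is NaN for n < 2."""
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n == 0:
        raise ValueError("no values")
    sd = float(arr.std(ddof=1)) if n >= 2 else math.nan
    return float(arr.mean()), sd, n


def two_group_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided unequal-variance (Welch) two-sample t-test p-value."""
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need >= 2 values per group for a two-group test, got {len(a)} and {len(b)}"
        )
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else p


def significance_stars(p: float) -> str:
    """'**' for P < 0.01, '*' for P < 0.05, '' otherwise."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
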