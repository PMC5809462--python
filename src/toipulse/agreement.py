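"""Method-agreement statistics: Bland-Altman limits and Pearson correlation.

Differences are taken as method A minus method B — in the validation
setting, contactless (TOI) minus reference (ECG) — so a negative bias
means the contactless branch reads low.  Limits of agreement are
bias +/- 1.96 * SD of the differences (sample SD, large-sample normal
limits, no small-sample t correction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class PairedMeasurements:
    """Per-subject values from two methods, pairwise aligned."""

    a: np.ndarray
    b: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("paired series must be equal-length 1-D arrays")
        if self.a.size < 3:
            raise ValueError("need at least 3 pairs")

    @property
    def n(self) -> int:
        return self.a.size


@dataclass
class AgreementReport:
    bias: float
    loa_lower: float
    loa_upper: float
    pearson_r: float
    n: int
    label: str = ""
    difference: str = "A - B (TOI - ECG)"

    def to_json(self) -> str:
        return json.dumps(
            {
                "label": self.label,
                "difference": self.difference,
                "bias": self.bias,
                "loa_lower": self.loa_lower,
                "loa_upper": self.loa_upper,
                "pearson_r": self.pearson_r,
                "n": self.n,
            },
            sort_keys=True,
        )


def bland_altman(pairs: PairedMeasurements) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement of the paired differences."""
    d = pairs.a - pairs.b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def pearson_r(pairs: PairedMeasurements) -> float:
    """Product-moment correlation between the two methods."""
    if pairs.a.std() == 0 or pairs.b.std() == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(stats.pearsonr(pairs.a, pairs.b).statistic)


def agreement_report(pairs: PairedMeasurements) -> AgreementReport:
    bias, lo, hi = bland_altman(pairs)
    return AgreementReport(
        bias=bias, loa_lower=lo, loa_upper=hi, pearson_r=pearson_r(pairs),
        n=pairs.n, label=pairs.label,
    )
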