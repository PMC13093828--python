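"""Quantitation utilities: ddCt relative expression, survival, petites.

Relative expression follows the standard 2^-ddCt method with an assumed
amplification efficiency of 2 per cycle: dCt = mean Ct(target) - mean
Ct(reference) within a sample, ddCt = dCt(test) - dCt(calibrator), ratio =
2^-ddCt.  The uncertainty is propagated from replicate standard deviations
in quadrature on the Ct scale and reported as the symmetrised half-width of
2^-(ddCt +/- sd).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CtTable",
    "RelativeExpression",
    "PlatingObservation",
    "delta_delta_ct",
    "survival_fraction",
    "petite_fraction",
]


@dataclass
class CtTable:
    """Long-format qPCR Ct measurements: (sample, gene, replicate, ct)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "gene", "replicate", "ct"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        if not np.isfinite(self.frame["ct"]).all():
            raise ValueError("Ct values must be finite")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"))

    def group(self, sample: str, gene: str) -> np.ndarray:
        sel = (self.frame["sample"] == sample) & (self.frame["gene"] == gene)
        return self.frame.loc[sel, "ct"].to_numpy(dtype=float)


@dataclass(frozen=True)
class RelativeExpression:
    test_sample: str
    calibrator_sample: str
    target_gene: str
    reference_gene: str
    ratio: float
    sd: float

    def __post_init__(self) -> None:
        if self.ratio <= 0 or self.sd < 0:
            raise ValueError("ratio must be positive and sd non-negative")


def _rep_stats(cts: np.ndarray, what: str) -> tuple[float, float]:
    if cts.size == 0:
        raise ValueError(f"no Ct replicates for {what}")
    mean = float(np.mean(cts))
    sd = float(np.std(cts, ddof=1)) if cts.size > 1 else 0.0
    return mean, sd


def delta_delta_ct(
    table: CtTable,
    target: str,
    reference: str,
    test_sample: str,
    calibrator_sample: str,
) -> RelativeExpression:
    """Relative expression 2^-ddCt of target vs reference between samples."""
    stats = {}
    for sample in (test_sample, calibrator_sample):
        for gene in (target, reference):
            stats[(sample, gene)] = _rep_stats(
                table.group(sample, gene), f"({sample}, {gene})"
            )
    dct_test = stats[(test_sample, target)][0] - stats[(test_sample, reference)][0]
    dct_cal = (
        stats[(calibrator_sample, target)][0]
        - stats[(calibrator_sample, reference)][0]
    )
    ddct = dct_test - dct_cal
    sd_ddct = math.sqrt(sum(s**2 for _, s in stats.values()))
    ratio = 2.0**-ddct
    hi = 2.0 ** (-(ddct - sd_ddct))
    lo = 2.0 ** (-(ddct + sd_ddct))
    return RelativeExpression(
        test_sample=test_sample,
        calibrator_sample=calibrator_sample,
        target_gene=target,
        reference_gene=reference,
        ratio=ratio,
        sd=(hi - lo) / 2.0,
    )


@dataclass(frozen=True)
class PlatingObservation:
    """Colony count from a plated volume at one starvation time point."""

    time_hr: float
    colonies: int
    volume_ml: float

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise ValueError("colony count must be non-negative")
        if self.volume_ml <= 0:
            raise ValueError("plated volume must be positive")


def survival_fraction(t0: PlatingObservation, t: PlatingObservation) -> float:
    """Volume-corrected colony fraction relative to the first time point."""
    if t0.colonies == 0:
        raise ValueError("no colonies at the reference time point")
    return (t.colonies / t.volume_ml) / (t0.colonies / t0.volume_ml)


def petite_fraction(white: int, total: int) -> float:
    """Percent of colonies scored petite (white in an ade2 background)."""
    if total <= 0:
        raise ValueError("total colony count must be positive")
    if not 0 <= white <= total:
        raise ValueError("white count must lie in [0, total]")
    return 100.0 * white / total
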