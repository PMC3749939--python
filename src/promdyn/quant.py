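"""ChIP-qPCR percent-input, relative expression, and densitometry folds.

Small closed-form quantifications used throughout targeted validation work:

* percent input: % Input = 2^(Cp(WCE) - Cp(IP)) x (% WCE), expressing ChIP
  recovery as a percentage of starting chromatin from qPCR crossing points;
* relative expression: 2^(Cp(control) - Cp(target)) with perfect-doubling
  amplification efficiency;
* densitometry fold change: WT/mutant transgene-to-H3 band-ratio folds per
  replicate, with the headline average fold computed as a ratio of means.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np


def _round2(x: float) -> float:
    """Two-decimal display rounding, round-half-even."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_EVEN))


@dataclass(frozen=True)
class QpcrMeasurement:
    cp_ip: float
    cp_wce: float
    wce_percent: float
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.cp_ip <= 0 or self.cp_wce <= 0:
            raise ValueError("Cp values must be positive")
        if not 0.0 < self.wce_percent <= 100.0:
            raise ValueError("WCE fraction must lie in (0, 100] percent")


def percent_input(m: QpcrMeasurement) -> float:
    """% Input = 2^(Cp(WCE) - Cp(IP)) x (% WCE)."""
    return 2.0 ** (m.cp_wce - m.cp_ip) * m.wce_percent


def relative_expression(cp_target, cp_control, efficiency: float = 2.0) -> float:
    """Expression of target relative to a control gene from Cp values.

    Replicate Cp values (arrays) are aggregated by mean before the
    exponent.  Efficiency defaults to perfect doubling.
    """
    ct = float(np.mean(cp_target))
    cc = float(np.mean(cp_control))
    if ct <= 0 or cc <= 0:
        raise ValueError("Cp values must be positive")
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    return efficiency ** (cc - ct)


@dataclass
class DensitometryFoldChange:
    """Per-replicate and average WT/mutant band-ratio fold changes."""

    per_replicate: list[float]
    average: float  # ratio of means (headline)
    mean_of_folds: float

    @property
    def per_replicate_rounded(self) -> list[float]:
        return [_round2(f) for f in self.per_replicate]

    @property
    def average_rounded(self) -> float:
        return _round2(self.average)


def densitometry_fold_change(
    wt_ratios, mutant_ratios_by_replicate
) -> DensitometryFoldChange:
    """Fold changes from transgene/H3 band ratios.

    ``wt_ratios`` is either one sequence of ratios shared by all replicates
    or one sequence per replicate; ``mutant_ratios_by_replicate`` is one
    sequence per replicate.  The per-replicate fold is mean(WT)/mean(mutant)
    within the replicate; the average fold is the ratio of means,
    mean(all WT)/mean(all mutant) — not the mean of per-replicate folds,
    which is also reported.
    """
    mut = [np.asarray(r, dtype=float) for r in mutant_ratios_by_replicate]
    if len(mut) == 0:
        raise ValueError("need at least one mutant replicate")
    first = np.asarray(wt_ratios[0] if len(wt_ratios) else wt_ratios, dtype=float)
    if first.ndim == 0:  # flat sequence of floats: shared WT ratios
        wt = [np.asarray(wt_ratios, dtype=float)] * len(mut)
        wt_pool = np.asarray(wt_ratios, dtype=float)
    else:  # one WT sequence per replicate
        if len(wt_ratios) != len(mut):
            raise ValueError("per-replicate WT ratios must match replicate count")
        wt = [np.asarray(r, dtype=float) for r in wt_ratios]
        wt_pool = np.concatenate(wt)
    for arr in list(wt) + mut:
        if (arr <= 0).any():
            raise ValueError("band ratios must be positive")
    per_rep = [float(w.mean() / m.mean()) for w, m in zip(wt, mut)]
    mut_pool = np.concatenate(mut)
    average = float(wt_pool.mean() / mut_pool.mean())
    return DensitometryFoldChange(
        per_replicate=per_rep,
        average=average,
        mean_of_folds=float(np.mean(per_rep)),
    )
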