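"""Immunoblot quantification: reference normalization and the composite
fold-change / p-value significance rule.

Densitometry signals are divided lane-by-lane by a loading-control reference
(actin), both groups are scaled so the control-group mean is 1, means are
compared by a two-sample t test on log2-transformed values (log2 stabilizes
the variance of ratio data), and a comparison is called significant only when
p < 0.05 AND the fold change is at least 1.25x up or at most 0.8x down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class QuantGroup:
    """Replicate densitometry measurements for one genotype/condition.

    ``values`` and ``reference_values`` are positionally paired (sample and
    loading-control bands from the same lane) and must be strictly positive.
    """

    label: str
    values: np.ndarray
    reference_values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.reference_values = np.asarray(self.reference_values, dtype=float)
        if self.values.size < 1:
            raise ValueError(f"{self.label}: at least one replicate required")
        if self.values.shape != self.reference_values.shape:
            raise ValueError(f"{self.label}: values and references differ in length")
        if (self.values <= 0).any():
            raise ValueError(f"{self.label}: non-positive signal value")
        if (self.reference_values <= 0).any():
            raise ValueError(f"{self.label}: non-positive reference value")


@dataclass(frozen=True)
class QuantCall:
    fold_change: float
    p: float
    significant: bool
    direction: str  # up | down | none


def normalize_and_scale(
    experimental: QuantGroup, control: QuantGroup
) -> tuple[np.ndarray, np.ndarray]:
    """Reference-normalize both groups and set the control-group mean to 1."""
    exp_norm = experimental.values / experimental.reference_values
    ctl_norm = control.values / control.reference_values
    scale = ctl_norm.mean()
    return exp_norm / scale, ctl_norm / scale


def significance_call(
    experimental,
    control,
    alpha: float = 0.05,
    fold_up: float = 1.25,
    fold_down: float = 0.8,
    equal_var: bool = True,
) -> QuantCall:
    """Composite significance call on normalized replicate values.

    Student t test (pooled variance; ``equal_var=False`` for Welch) on log2
    values, two-sided.  Significant only when the p criterion and the fold
    criterion (>= ``fold_up`` or <= ``fold_down``, on the raw ratio scale)
    both hold.
    """
    exp = np.asarray(experimental, dtype=float)
    ctl = np.asarray(control, dtype=float)
    if exp.size < 2 or ctl.size < 2:
        raise ValueError("significance testing requires >= 2 replicates per group")
    if (exp <= 0).any() or (ctl <= 0).any():
        raise ValueError("normalized values must be strictly positive")

    fold = exp.mean() / ctl.mean()
    _, p = stats.ttest_ind(np.log2(exp), np.log2(ctl), equal_var=equal_var)
    p = float(p)
    significant = bool(p < alpha and (fold >= fold_up or fold <= fold_down))
    direction = "none" if not significant else ("up" if fold > 1 else "down")
    return QuantCall(fold_change=float(fold), p=p, significant=significant, direction=direction)


def compare_groups(experimental: QuantGroup, control: QuantGroup, **kwargs) -> QuantCall:
    """Normalize, scale, and call significance in one step."""
    exp_norm, ctl_norm = normalize_and_scale(experimental, control)
    return significance_call(exp_norm, ctl_norm, **kwargs)
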