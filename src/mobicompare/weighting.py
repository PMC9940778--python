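"""Poststratification raking (iterative proportional fitting).

Unit weights are adjusted variable by variable so that every weighted
marginal distribution matches its population target, cycling until the
worst margin gap falls below tolerance.  This is marginal raking (the
anesrake-style workflow), not full poststratification on joint cells:
only marginal population distributions are required.

Weights are normalised to mean 1; optional trimming clips extreme
weights and renormalises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ValidationError

__all__ = [
    "MarginTargets",
    "RakingWeights",
    "RakingConvergenceError",
    "InfeasibleMarginError",
    "rake_weights",
    "weighted_aggregate",
]

MarginTargets = dict[str, dict[str, float]]


class RakingConvergenceError(RuntimeError):
    """IPF did not reach tolerance within max_iter; carries the worst gap."""

    def __init__(self, max_gap: float, max_iter: int):
        self.max_gap = max_gap
        super().__init__(
            f"raking did not converge in {max_iter} iterations (worst margin gap {max_gap:.3g})"
        )


class InfeasibleMarginError(ValueError):
    """A positive target sits on a level with no sample units."""


@dataclass
class RakingWeights:
    """Per-unit weights with convergence metadata."""

    weights: pd.Series  # index = unit_id, mean 1
    iterations: int
    max_margin_error: float

    def __post_init__(self) -> None:
        if (self.weights <= 0).any():
            raise ValidationError("raking weights must all be positive")


def _validate_targets(units: pd.DataFrame, targets: MarginTargets) -> None:
    for var, target in targets.items():
        if var not in units.columns:
            raise ValidationError(f"weighting variable '{var}' not in sample")
        total = sum(target.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"targets for '{var}' sum to {total}, expected 1")
        present = set(units[var].unique())
        for level, p in target.items():
            if p < 0:
                raise ValidationError(f"negative target for {var}={level}")
            if p > 0 and level not in present:
                raise InfeasibleMarginError(
                    f"positive target {p} for {var}={level} but no sample units at that level"
                )
        extra = present - set(target)
        if extra:
            raise ValidationError(f"sample levels of '{var}' without a target: {sorted(extra)}")


def rake_weights(
    units: pd.DataFrame,
    targets: MarginTargets,
    tol: float = 1e-6,
    max_iter: int = 100,
    trim_bounds: tuple[float, float] | None = None,
    base_weights: pd.Series | None = None,
) -> RakingWeights:
    """Rake unit weights to the target margins.

    ``units`` holds one row per unit with the categorical weighting
    variables as columns (the index is the unit id).  Variables are
    adjusted in the declared order of ``targets``; one pass over all
    variables is one iteration.  Convergence: every weighted margin within
    ``tol`` of its target.
    """
    _validate_targets(units, targets)
    n = len(units)
    if n == 0:
        raise ValidationError("cannot rake an empty sample")
    w = (
        np.ones(n)
        if base_weights is None
        else base_weights.reindex(units.index).to_numpy(dtype=float)
    )
    codes = {var: units[var].to_numpy() for var in targets}

    def max_gap() -> float:
        gap = 0.0
        W = w.sum()
        for var, target in targets.items():
            for level, p in target.items():
                share = w[codes[var] == level].sum() / W
                gap = max(gap, abs(share - p))
        return gap

    it = 0
    gap = max_gap()
    while gap > tol and it < max_iter:
        for var, target in targets.items():
            W = w.sum()
            for level, p in target.items():
                mask = codes[var] == level
                current = w[mask].sum() / W
                if current > 0:
                    w[mask] *= p / current
        it += 1
        gap = max_gap()
    if gap > tol:
        raise RakingConvergenceError(gap, max_iter)
    if trim_bounds is not None:
        lo, hi = trim_bounds
        w = np.clip(w * n / w.sum(), lo, hi)
    w = w * n / w.sum()
    return RakingWeights(
        weights=pd.Series(w, index=units.index, name="weight"),
        iterations=it,
        max_margin_error=gap,
    )


def weighted_aggregate(
    values: pd.Series, weights: pd.Series, statistic: str = "mean"
) -> float:
    """Weighted mean (or proportion) of ``values``.

    Missing values are excluded pairwise together with their weights; if
    every value is missing the result is NaN.  For 'proportion' the values
    must be 0/1 indicators (or booleans).
    """
    if statistic not in ("mean", "proportion"):
        raise ValidationError(f"unknown statistic '{statistic}'")
    v = pd.Series(values).astype(float)
    w = pd.Series(weights).reindex(v.index).astype(float)
    ok = v.notna() & w.notna()
    if not ok.any():
        return float("nan")
    if statistic == "proportion" and not v[ok].isin([0.0, 1.0]).all():
        raise ValidationError("proportion requires 0/1 values")
    return float((v[ok] * w[ok]).sum() / w[ok].sum())
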