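"""Survey calibration by the raking ratio method (iterative proportional
fitting) and weighted descriptive summaries.

Raking rescales unit weights so that the weighted marginal distribution of
each calibration variable matches its population target, cycling over the
margin variables until every weighted margin is within tolerance.  Weights
are normalized to mean 1, so the weighted sample size equals the raw sample
size and model degrees of freedom stay comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .errors import EmptyCellError, NonConvergenceError


@dataclass
class PopulationMargins:
    """Target population proportions per calibration variable.

    ``margins[variable][category] = target proportion``; each variable's
    proportions must sum to 1.
    """

    margins: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        for var, props in self.margins.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"margin {var!r} proportions sum to {total}, expected 1"
                )
            if any(p < 0 for p in props.values()):
                raise ValueError(f"margin {var!r} has negative proportions")

    @property
    def variables(self) -> list[str]:
        return list(self.margins)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"variable": var, "category": cat, "proportion": p}
            for var, props in self.margins.items()
            for cat, p in props.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PopulationMargins":
        margins: dict[str, dict[str, float]] = {}
        for var, sub in df.groupby("variable", sort=False):
            margins[str(var)] = dict(
                zip(sub["category"].astype(str), sub["proportion"].astype(float))
            )
        return cls(margins)


@dataclass
class WeightVector:
    """Calibrated household weights (mean 1) with convergence diagnostics."""

    weights: pd.Series  # indexed by household_id
    iterations_used: int
    max_margin_error: float

    def __post_init__(self):
        if (self.weights <= 0).any():
            raise ValueError("all weights must be > 0")

    def reindex(self, household_ids) -> np.ndarray:
        return self.weights.reindex(household_ids).to_numpy()


def rake(
    sample: pd.DataFrame,
    margins: PopulationMargins,
    tol: float = 1e-6,
    max_iter: int = 200,
    id_column: str = "household_id",
) -> WeightVector:
    """Calibrate weights so weighted sample margins match population targets.

    Parameters
    ----------
    sample
        One row per household; must contain ``id_column`` and one column per
        margin variable holding that household's category.
    margins
        Target proportions.  Every category present in the sample must appear
        in the margins, and every category with a positive target must have
        at least one sample member (otherwise :class:`EmptyCellError`).
    tol
        Maximum absolute difference allowed between any weighted marginal
        proportion and its target.
    """
    n = len(sample)
    w = np.ones(n)
    cat_codes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for var in margins.variables:
        if var not in sample.columns:
            raise KeyError(f"sample lacks margin variable {var!r}")
        cats = list(margins.margins[var])
        observed = set(sample[var].astype(str))
        unknown = observed - set(cats)
        if unknown:
            raise KeyError(
                f"sample categories {sorted(unknown)} of {var!r} missing "
                "from margins"
            )
        codes = sample[var].astype(str).map({c: i for i, c in enumerate(cats)})
        codes = codes.to_numpy(dtype=int)
        targets = np.array([margins.margins[var][c] for c in cats])
        counts = np.bincount(codes, minlength=len(cats))
        empty = (counts == 0) & (targets > 0)
        if empty.any():
            missing = [cats[i] for i in np.flatnonzero(empty)]
            raise EmptyCellError(
                f"margin {var!r} categories {missing} have positive target "
                "but no sample members"
            )
        cat_codes[var] = (codes, targets)

    def max_error(w):
        err = 0.0
        for codes, targets in cat_codes.values():
            props = np.bincount(codes, weights=w, minlength=len(targets))
            props = props / w.sum()
            err = max(err, float(np.abs(props - targets).max()))
        return err

    iterations = 0
    err = max_error(w)
    while err > tol and iterations < max_iter:
        for codes, targets in cat_codes.values():
            props = np.bincount(codes, weights=w, minlength=len(targets))
            props = props / w.sum()
            with np.errstate(divide="ignore", invalid="ignore"):
                factors = np.where(props > 0, targets / props, 1.0)
            w = w * factors[codes]
        iterations += 1
        err = max_error(w)
    w = w / w.mean()
    if err > tol:
        raise NonConvergenceError(
            f"raking did not converge in {max_iter} iterations "
            f"(max margin error {err:.3e})",
            max_margin_error=err,
        )
    return WeightVector(
        weights=pd.Series(w, index=sample[id_column].to_numpy(), name="weight"),
        iterations_used=max(iterations, 1),
        max_margin_error=err,
    )


def weighted_proportions(
    sample: pd.DataFrame,
    weights: WeightVector | pd.Series | np.ndarray | None,
    variable: str,
) -> pd.Series:
    """Weighted category proportions of ``variable``; sums to 1.

    With equal (or absent) weights this reduces to raw frequencies.
    """
    if weights is None:
        w = np.ones(len(sample))
    elif isinstance(weights, WeightVector):
        w = weights.reindex(sample["household_id"])
    else:
        w = np.asarray(weights, dtype=float)
    cats = sample[variable].astype(str)
    totals = pd.Series(w).groupby(cats.to_numpy()).sum()
    return totals / totals.sum()
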