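"""Cohort statistics: skeletal barcodes, the permutation global test, and
allometric normalization.

A *skeletal barcode* is the matrix of standard scores of one fish (or one
group mean) against a control cohort, cell by cell over (measure, vertebra).

The *global test* asks whether group membership is associated with one
measure's profile across the 20-vertebra window as a whole.  The statistic is
the squared norm of the covariate-wise score, ``Q = ||X' (y - ybar)||^2``,
with the covariate block X standardized per vertebra; its null distribution
is obtained by label permutation, which is exact-in-expectation at the small
group sizes typical of fish cohorts (6-10 per group) and assumption-free.

*Allometric normalization* removes body-size dependence: each measure is
modelled on controls as ``m = a * SL^b`` (ordinary least squares on logs) and
every fish is rescaled to the reference standard length,
``m* = m * (SL_ref / SL)^b``, so group contrasts are not driven by
developmental delay alone.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .errors import DegenerateControlError, FishCTError

__all__ = [
    "SkeletalBarcode",
    "GlobalTestResult",
    "AllometricModel",
    "standard_scores",
    "global_test",
    "fit_allometry",
    "allometric_normalize",
    "phenome_wide_table",
]


@dataclasses.dataclass
class SkeletalBarcode:
    """Standard-score matrix against a control cohort.

    ``z`` has one row per target fish (or a single ``"group"`` row in group
    mode) and one column per (measure, vertebra) cell; ``control_mean``,
    ``control_sd`` and ``control_n`` summarize the control cohort per cell.
    """

    z: pd.DataFrame
    control_mean: pd.Series
    control_sd: pd.Series
    control_n: int


@dataclasses.dataclass(frozen=True)
class GlobalTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None

    def __post_init__(self):
        if not 0.0 < self.p_value <= 1.0:
            raise FishCTError(f"permutation p-value out of range: {self.p_value}")


@dataclasses.dataclass(frozen=True)
class AllometricModel:
    """Power law ``m = a * SL^b`` fitted on controls."""

    measure: str
    exponent: float          # b
    coefficient: float       # a
    reference_sl: float      # um

    def __post_init__(self):
        if not self.coefficient > 0:
            raise FishCTError("allometric coefficient must be positive")


def phenome_wide_table(long: pd.DataFrame, measures=None) -> pd.DataFrame:
    """Pivot a long cohort table (fish, group, vertebra, measures...) to wide.

    Returns a DataFrame indexed by fish with MultiIndex columns
    ``(measure, vertebra)`` plus the per-fish ``group`` and
    ``standard_length`` carried in ``.attrs["meta"]``.
    """
    value_cols = [c for c in long.columns
                  if c not in ("fish", "group", "vertebra", "standard_length")]
    if measures is not None:
        value_cols = [c for c in value_cols if c in set(measures)]
    wide = long.pivot(index="fish", columns="vertebra", values=value_cols)
    meta = long.groupby("fish").agg({"group": "first", "standard_length": "first"}) \
        if "standard_length" in long.columns else long.groupby("fish").agg({"group": "first"})
    wide.attrs["meta"] = meta.loc[wide.index]
    return wide


def standard_scores(
    target: pd.DataFrame,
    control: pd.DataFrame,
    mode: str = "fish",
) -> SkeletalBarcode:
    """Standard scores of target fish against a control cohort.

    ``target`` and ``control`` are wide tables (rows fish, columns measure
    cells).  ``mode="fish"`` scores each target row; ``mode="group"`` scores
    the target group mean, yielding a single-row barcode.  A control cell
    with zero spread cannot define a score and raises
    :class:`DegenerateControlError`.
    """
    if len(control) < 2:
        raise DegenerateControlError("control cohort needs n >= 2")
    control = control[target.columns]
    mean = control.mean(axis=0)
    sd = control.std(axis=0, ddof=1)
    dead = sd[sd == 0]
    if len(dead):
        raise DegenerateControlError(
            f"zero control SD in cell(s) {list(dead.index)[:5]}"
        )
    if mode == "group":
        x = target.mean(axis=0).to_frame().T
        x.index = pd.Index(["group"], name=target.index.name)
    elif mode == "fish":
        x = target
    else:
        raise ValueError(f"mode must be 'fish' or 'group', got {mode!r}")
    z = (x - mean) / sd
    return SkeletalBarcode(z=z, control_mean=mean, control_sd=sd, control_n=len(control))


# ---------------------------------------------------------------------------
# global test
# ---------------------------------------------------------------------------

def global_test_statistic(X: np.ndarray, y: np.ndarray) -> float:
    """``Q = ||X' (y - ybar)||^2`` on per-column standardized covariates."""
    y = np.asarray(y, dtype=float)
    resid = y - y.mean()
    return float(np.sum((X.T @ resid) ** 2))


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise DegenerateControlError(
            f"covariate column(s) {bad.tolist()} have zero variance"
        )
    return (X - mu) / sd


def global_test(
    values: pd.DataFrame | np.ndarray,
    groups,
    n_permutations: int = 10000,
    seed: int | None = 0,
) -> GlobalTestResult:
    """Permutation global test of group association with a covariate block.

    ``values``: n_fish x n_covariates (e.g. one measure over vertebrae 1-20),
    standardized per covariate before testing.  ``groups``: two-level labels.
    The p-value is ``(1 + #{Q_perm >= Q_obs}) / (B + 1)`` over ``B`` random
    label permutations of a fixed seed; it can never be smaller than
    ``1 / (B + 1)``.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise FishCTError("values must be a 2-D fish x covariates block")
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise FishCTError(f"global test needs exactly two groups, got {list(levels)}")
    y = (groups == levels[1]).astype(float)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if min(n0, n1) < 2:
        raise FishCTError(f"each group needs n >= 2, got {n0} and {n1}")
    if n_permutations < 99:
        raise FishCTError("use at least 99 permutations")
    X = _standardize_columns(X)
    q_obs = global_test_statistic(X, y)
    rng = np.random.default_rng(seed)
    # vectorized: all permuted centered labels at once -> (B, covariates)
    perm = np.tile(y, (n_permutations, 1))
    idx = np.argsort(rng.random(perm.shape), axis=1)
    perm = np.take_along_axis(perm, idx, axis=1)
    scores = (perm - perm.mean(axis=1, keepdims=True)) @ X
    q_perm = np.sum(scores ** 2, axis=1)
    p = (1.0 + np.count_nonzero(q_perm >= q_obs - 1e-12)) / (n_permutations + 1.0)
    return GlobalTestResult(statistic=q_obs, p_value=float(p),
                            n_permutations=n_permutations, seed=seed)


def global_test_table(
    wide: pd.DataFrame,
    groups,
    measures,
    n_permutations: int = 10000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Global-test p-values for each measure's vertebral profile."""
    rows = []
    for m in measures:
        res = global_test(wide[m].to_numpy(), groups,
                          n_permutations=n_permutations, seed=seed)
        rows.append({"measure": m, "Q": res.statistic, "p": res.p_value})
    return pd.DataFrame(rows).set_index("measure")


# ---------------------------------------------------------------------------
# allometry
# ---------------------------------------------------------------------------

def fit_allometry(
    standard_length: np.ndarray,
    values: np.ndarray,
    measure: str = "measure",
) -> AllometricModel:
    """Fit ``m = a * SL^b`` on control fish by OLS on logs."""
    import statsmodels.api as sm

    sl = np.asarray(standard_length, dtype=float)
    m = np.asarray(values, dtype=float)
    if np.any(m <= 0) or np.any(sl <= 0):
        raise FishCTError("allometric fit requires positive measures and lengths")
    if np.unique(sl).size < 2:
        raise FishCTError("control standard lengths must span more than one value")
    design = sm.add_constant(np.log(sl))
    fit = sm.OLS(np.log(m), design).fit()
    log_a, b = fit.params
    return AllometricModel(
        measure=measure,
        exponent=float(b),
        coefficient=float(np.exp(log_a)),
        reference_sl=float(sl.mean()),
    )


def allometric_normalize(
    values: np.ndarray,
    standard_length: np.ndarray,
    model: AllometricModel,
) -> np.ndarray:
    """Rescale measures to the reference SL: ``m* = m * (SL_ref / SL)^b``."""
    sl = np.asarray(standard_length, dtype=float)
    if np.any(sl <= 0):
        raise FishCTError("standard length must be positive")
    return np.asarray(values, dtype=float) * (model.reference_sl / sl) ** model.exponent
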