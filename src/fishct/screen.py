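"""Reverse-genetic-screen scoring.

Somatic CRISPR mutant pools are compared to their control cohort on a panel
of lean-mass and skeletal measures.  Each gene gets a z-score per measure
(group-mean difference in control-SD units), an effect-size summary (the
mean absolute z over the panel), and a prioritization score that corrects
for incomplete editing: somatic pools are mosaics, so an allele with low
mutation efficiency dilutes its phenotype.  Mutation efficiency is defined
from sequence-trace decomposition output as ``1 - %WT/100``, and the
normalized score is ``mean|z| / efficiency``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateControlError, FishCTError

__all__ = [
    "ScreenScore",
    "mutation_efficiency",
    "screen_zscores",
    "aggregate_score",
    "score_screen",
    "round_sig",
    "DEFAULT_SCREEN_MEASURES",
]

#: default measure panel: skeletal myomere correlates, soft-tissue morphology
#: and body size
DEFAULT_SCREEN_MEASURES = (
    "Cent.Le",
    "Neur.Angle",
    "Neur.Le",
    "trunk_lean_mm3",
    "anterior_trunk_lean_mm3",
    "posterior_trunk_lean_mm3",
    "anterior_chamber_um",
    "posterior_chamber_um",
    "standard_length",
)


@dataclasses.dataclass
class ScreenScore:
    """Per-gene screen summary."""

    gene: str
    z: pd.Series                  # per-measure z-scores
    p: pd.Series                  # per-measure unpaired t-test p-values
    mean_abs_z: float
    efficiency: float
    normalized: float             # mean_abs_z / efficiency
    n_significant: int            # measures with p < 0.05

    def __post_init__(self):
        if not np.isfinite(self.normalized):
            raise FishCTError(f"non-finite screen score for {self.gene}")


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (used for reported scores)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def mutation_efficiency(percent_wt: float) -> float:
    """Mutation efficiency from a TIDE-style %WT: ``1 - %WT/100``.

    %WT is the predicted frequency of zero-indel sequences in the somatic
    pool, in percent.
    """
    if not 0.0 <= percent_wt <= 100.0:
        raise ValueError(f"%WT must be within [0, 100], got {percent_wt}")
    return 1.0 - percent_wt / 100.0


def screen_zscores(
    mutant: pd.DataFrame,
    control: pd.DataFrame,
    measures: Sequence[str] = DEFAULT_SCREEN_MEASURES,
) -> tuple[pd.Series, pd.Series]:
    """Per-measure z-scores of a mutant group against controls.

    ``z_m = (mean_mutant - mean_control) / SD_control`` per measure, plus the
    unpaired two-sided t-test p-value alongside.  Requires control n >= 2 and
    nonzero control SD per measure.
    """
    measures = [m for m in measures if m in mutant.columns and m in control.columns]
    if not measures:
        raise FishCTError("no overlapping measures between mutant and control tables")
    if len(control) < 2:
        raise DegenerateControlError("control cohort needs n >= 2")
    z, p = {}, {}
    for m in measures:
        c = control[m].astype(float).dropna()
        x = mutant[m].astype(float).dropna()
        sd = c.std(ddof=1)
        if sd == 0:
            raise DegenerateControlError(f"zero control SD for measure {m!r}")
        z[m] = (x.mean() - c.mean()) / sd
        p[m] = float(stats.ttest_ind(x, c, equal_var=True).pvalue)
    return pd.Series(z, name="z"), pd.Series(p, name="p")


def aggregate_score(
    zs: pd.Series | Sequence[float],
    efficiency: float,
    gene: str = "gene",
    p: pd.Series | None = None,
    alpha: float = 0.05,
) -> ScreenScore:
    """Mean |z| and the efficiency-normalized screen score of one gene.

    ``normalized = mean|z| / efficiency``; with partial editing
    (efficiency < 1) the normalized score exceeds the raw effect size,
    extrapolating the phenotype of a fully mutant pool.  Reported values are
    conventionally rounded to two significant figures via :func:`round_sig`.
    """
    zs = pd.Series(zs, dtype=float)
    if len(zs) == 0:
        raise FishCTError("need at least one measure z-score")
    if efficiency == 0:
        raise ZeroDivisionError("mutation efficiency of 0 cannot normalize a score")
    if not 0.0 < efficiency <= 1.0:
        raise FishCTError(f"mutation efficiency must be in (0, 1], got {efficiency}")
    mean_abs = float(zs.abs().mean())
    if p is None:
        p = pd.Series(np.nan, index=zs.index if hasattr(zs, "index") else None)
    n_sig = int((p.dropna() < alpha).sum())
    return ScreenScore(
        gene=gene,
        z=zs,
        p=p,
        mean_abs_z=mean_abs,
        efficiency=float(efficiency),
        normalized=mean_abs / float(efficiency),
        n_significant=n_sig,
    )


def score_screen(
    table: pd.DataFrame,
    percent_wt: Mapping[str, float],
    control_group: str = "control",
    group_col: str = "group",
    measures: Sequence[str] = DEFAULT_SCREEN_MEASURES,
) -> pd.DataFrame:
    """Score every mutant group in a per-fish measure table.

    ``table`` holds one row per fish with a group column; ``percent_wt`` maps
    each mutant group (gene) to its TIDE %WT.  Returns genes ranked by the
    efficiency-normalized score, with per-measure z columns, mean |z|,
    efficiency, the normalized score and the significant-measure count.
    """
    control = table[table[group_col] == control_group]
    if control.empty:
        raise FishCTError(f"no fish in control group {control_group!r}")
    rows = []
    for gene in [g for g in pd.unique(table[group_col]) if g != control_group]:
        mutant = table[table[group_col] == gene]
        z, p = screen_zscores(mutant, control, measures=measures)
        eff = mutation_efficiency(float(percent_wt[gene]))
        score = aggregate_score(z, eff, gene=gene, p=p)
        row = {"gene": gene, "mean_abs_z": score.mean_abs_z,
               "efficiency": eff, "normalized": score.normalized,
               "n_significant": score.n_significant}
        row.update({f"z:{m}": v for m, v in z.items()})
        rows.append(row)
    out = pd.DataFrame(rows).set_index("gene")
    return out.sort_values("normalized", ascending=False)
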