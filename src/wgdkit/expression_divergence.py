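"""Expression divergence between paralog pairs.

Three tests, applied to each paralog pair over an ordered sample series
(by design 8 developmental stages x 2 sexes = 16 samples):

* Pearson correlation of the two expression profiles; a pair is called
  divergent when r^2 < 0.3;
* a 2x2 Fisher exact test (rows = paralogs, columns = sexes) on summed read
  counts within a stage pool (developing or mature flowers), two-sided by
  minimum-likelihood summation;
* log10 male/female expression ratios per paralog, with a flag for pairs
  whose ratios differ by more than 5-fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, pearsonr

from .io_formats import ExpressionMatrix

__all__ = [
    "PairExpressionResult",
    "expression_correlation",
    "sex_bias_test",
    "fold_bias",
    "pair_expression_table",
    "summarize",
]

R_SQUARED_CUTOFF = 0.3
FISHER_ALPHA = 0.01
FOLD_CUTOFF = 5.0


@dataclass(frozen=True)
class PairExpressionResult:
    pair_id: str
    pearson_r: float
    r_squared: float
    divergent: bool  # r^2 < cutoff; False when r is undefined
    defined: bool  # correlation defined (both genes had variance)
    fisher_p_developing: float
    fisher_p_mature: float
    significant_developing: bool
    significant_mature: bool
    degenerate_developing: bool
    degenerate_mature: bool
    log10_ratio_a: float
    log10_ratio_b: float
    fold5_flag: bool


def expression_correlation(
    pair: tuple[str, str],
    matrix: ExpressionMatrix,
    cutoff: float = R_SQUARED_CUTOFF,
) -> tuple[float, float, bool]:
    """Pearson r, r^2 and the divergence call for one paralog pair.

    The correlation runs across the matrix's ordered sample series.  A gene
    with zero variance leaves r undefined (NaN, NaN, False); such pairs are
    excluded from reported denominators.
    """
    a, b = pair
    if matrix.values.shape[1] < 3:
        raise ValueError("need at least 3 samples for a correlation")
    xa = matrix.values.loc[a].to_numpy(dtype=float)
    xb = matrix.values.loc[b].to_numpy(dtype=float)
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        return math.nan, math.nan, False
    r = float(pearsonr(xa, xb).statistic)
    return r, r * r, r * r < cutoff


def _stage_counts(
    gene: str, matrix: ExpressionMatrix, stages: Iterable[str]
) -> tuple[int, int]:
    stages = set(stages)
    male = matrix.values.loc[gene, matrix.samples_where("M", stages)].sum()
    female = matrix.values.loc[gene, matrix.samples_where("F", stages)].sum()
    return int(round(male)), int(round(female))


def sex_bias_test(
    pair: tuple[str, str],
    matrix: ExpressionMatrix,
    stages: Iterable[str],
) -> tuple[float, bool]:
    """Two-sided Fisher exact p for male/female bias between the paralogs.

    Read counts are summed over the samples of the given stage pool, per
    sex, into the 2x2 table [[a_M, a_F], [b_M, b_F]].  A zero margin makes
    the test degenerate: p = 1 by convention, flagged.  The two-sided
    p-value is the minimum-likelihood summation of hypergeometric table
    probabilities (verified against exact enumeration).
    """
    if matrix.unit != "counts":
        raise ValueError("Fisher exact test requires raw read counts")
    a, b = pair
    table = np.array([_stage_counts(a, matrix, stages), _stage_counts(b, matrix, stages)])
    row0, row1 = table.sum(axis=1)
    col0, col1 = table.sum(axis=0)
    if 0 in (row0, row1, col0, col1):
        return 1.0, True
    return float(fisher_exact(table, alternative="two-sided")[1]), False


def fold_bias(
    pair: tuple[str, str],
    matrix: ExpressionMatrix,
    stages: Iterable[str],
    pseudocount: float = 1.0,
    fold_cutoff: float = FOLD_CUTOFF,
) -> tuple[float, float, bool]:
    """log10 male/female ratios per paralog and the >fold_cutoff flag.

    Expression is summed over the stage pool per sex; each paralog's ratio
    is log10((male + pseudocount) / (female + pseudocount)); the flag is set
    when the two ratios differ by more than log10(fold_cutoff).
    """
    ratios = []
    for gene in pair:
        male, female = _stage_counts(gene, matrix, stages)
        ratios.append(math.log10((male + pseudocount) / (female + pseudocount)))
    flag = abs(ratios[0] - ratios[1]) > math.log10(fold_cutoff)
    return ratios[0], ratios[1], flag


def pair_expression_table(
    pairs: Sequence[tuple[str, str]],
    matrix: ExpressionMatrix,
    developing_stages: Iterable[str],
    mature_stages: Iterable[str],
    r2_cutoff: float = R_SQUARED_CUTOFF,
    alpha: float = FISHER_ALPHA,
    pseudocount: float = 1.0,
    fold_cutoff: float = FOLD_CUTOFF,
) -> list[PairExpressionResult]:
    """Run all three tests on every pair (ratio stage pool: developing)."""
    developing = list(developing_stages)
    mature = list(mature_stages)
    results = []
    for a, b in pairs:
        r, r2, divergent = expression_correlation((a, b), matrix, cutoff=r2_cutoff)
        p_dev, deg_dev = sex_bias_test((a, b), matrix, developing)
        p_mat, deg_mat = sex_bias_test((a, b), matrix, mature)
        ra, rb, fold5 = fold_bias(
            (a, b), matrix, developing, pseudocount=pseudocount, fold_cutoff=fold_cutoff
        )
        results.append(
            PairExpressionResult(
                pair_id=f"{a}--{b}",
                pearson_r=r,
                r_squared=r2,
                divergent=divergent,
                defined=math.isfinite(r),
                fisher_p_developing=p_dev,
                fisher_p_mature=p_mat,
                significant_developing=p_dev < alpha,
                significant_mature=p_mat < alpha,
                degenerate_developing=deg_dev,
                degenerate_mature=deg_mat,
                log10_ratio_a=ra,
                log10_ratio_b=rb,
                fold5_flag=fold5,
            )
        )
    return results


def summarize(results: Sequence[PairExpressionResult]) -> pd.Series:
    """Headline fractions: divergent share, Fisher calls, >5-fold share.

    Pairs with an undefined correlation are excluded from the divergent
    denominator.
    """
    defined = [r for r in results if r.defined]
    n_def = len(defined)
    n_div = sum(r.divergent for r in defined)
    return pd.Series(
        {
            "n_pairs": len(results),
            "n_defined": n_def,
            "n_divergent": n_div,
            "divergent_fraction": n_div / n_def if n_def else math.nan,
            "n_significant_developing": sum(r.significant_developing for r in results),
            "n_significant_mature": sum(r.significant_mature for r in results),
            "n_fold5": sum(r.fold5_flag for r in results),
            "fold5_fraction": (
                sum(r.fold5_flag for r in results) / len(results) if results else math.nan
            ),
        }
    )


def results_to_frame(results: Sequence[PairExpressionResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
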