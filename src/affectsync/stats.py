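"""Nonparametric comparison of related accuracy samples.

Implements, from their textbook formulas, the four rank tests used to
compare classifier accuracy across related conditions: the classical
Friedman chi-square test, the Iman-Davenport F correction, the
aligned-ranks variant, and the Quade test (the latter two in the forms
popularized for classifier comparison by Garcia et al.).  Blocks are
the classifiers, treatments the participant groups: the question asked
is whether the *groups* are equivalent, not the algorithms.  A
transposed mode compares algorithms instead.

The accuracy matrix is a pandas DataFrame: rows (index) = algorithm
names, columns = group names, entries = accuracy percent in [0, 100].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata

ALGORITHMS = ("SVM", "L", "RF", "RIPPER", "KNN", "NB", "LR", "C4.5",
              "RBF", "MLP")

# Published benchmark: accuracy (%) of the ten classifiers on EEG
# emotion features for the non-self-regulated group (G1), the
# self-regulated group (G2), and all participants pooled.
_BENCHMARK_CSV = """\
algorithm,G1,G2,All
SVM,36.8035,38.7097,39.0098
L,35.1906,37.9416,34.5086
RF,40.0293,39.4777,41.2603
RIPPER,39.8827,39.9386,42.4606
KNN,35.4839,37.3272,35.9340
NB,34.3109,29.8003,32.2581
LR,40.9091,41.1674,42.0855
C4.5,35.1906,33.9478,33.5334
RBF,35.7771,38.4025,39.6099
MLP,40.6158,42.7035,42.1605
"""


def published_benchmark() -> pd.DataFrame:
    """The published 10-classifier x 3-group accuracy benchmark used as
    the printed input of the statistics chain."""
    return pd.read_csv(StringIO(_BENCHMARK_CSV), index_col="algorithm")


@dataclass
class RankTestResult:
    method: str
    statistic: float
    df: tuple[float, ...]
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")
        if any(d <= 0 for d in self.df):
            raise ValueError("degrees of freedom must be positive")


def _validate(m: pd.DataFrame) -> np.ndarray:
    x = m.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("accuracy matrix contains missing entries")
    n, k = x.shape
    if k < 2 or n < 2:
        raise ValueError(f"need >= 2 treatments and >= 2 blocks, got {n}x{k}")
    return x


def column_stats(m: pd.DataFrame) -> pd.DataFrame:
    """Per-column mean, sample SD (n-1), max and argmax (row name)."""
    if m.empty:
        raise ValueError("empty accuracy matrix")
    if len(m) == 1:
        warnings.warn("single row: sample SD undefined, reported as 0")
        sd = pd.Series(0.0, index=m.columns)
    else:
        sd = m.std(ddof=1)
    return pd.DataFrame({"mean": m.mean(), "sd": sd, "max": m.max(),
                         "argmax": m.idxmax()})


def friedman(m: pd.DataFrame) -> RankTestResult:
    """Classical Friedman test; mid-ranks within blocks (rows).

    chi2_F = 12/(n k (k+1)) * sum_j R_j^2 - 3 n (k+1), ~ chi2(k-1).
    """
    x = _validate(m)
    n, k = x.shape
    r = np.apply_along_axis(rankdata, 1, x)
    R = r.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float(np.sum(R ** 2)) - 3.0 * n * (k + 1)
    chi2 = max(chi2, 0.0)
    p = float(sps.chi2.sf(chi2, k - 1))
    return RankTestResult("friedman", chi2, (float(k - 1),), p)


def iman_davenport(m: pd.DataFrame) -> RankTestResult:
    """Iman-Davenport F correction of the Friedman statistic:
    F_F = (n-1) chi2_F / (n (k-1) - chi2_F), ~ F(k-1, (k-1)(n-1))."""
    x = _validate(m)
    n, k = x.shape
    chi2 = friedman(m).statistic
    denom = n * (k - 1) - chi2
    if denom <= 0:
        raise ZeroDivisionError(
            f"degenerate Iman-Davenport denominator n(k-1) - chi2 = {denom}")
    F = (n - 1) * chi2 / denom
    p = float(sps.f.sf(F, k - 1, (k - 1) * (n - 1)))
    return RankTestResult("iman_davenport", F,
                          (float(k - 1), float((k - 1) * (n - 1))), p)


def aligned_friedman(m: pd.DataFrame) -> RankTestResult:
    """Aligned-ranks Friedman test.

    Observations are aligned by subtracting block means, all n*k aligned
    values ranked jointly (mid-ranks), and

        T = (k-1) [sum_j Rc_j^2 - (k n^2 / 4)(k n + 1)^2]
            / { k n (k n + 1)(2 k n + 1)/6 - (1/k) sum_i Rr_i^2 }

    with Rc_j / Rr_i the column / row rank totals, ~ chi2(k-1).
    Alignment makes the statistic invariant to adding a constant to any
    whole block.
    """
    x = _validate(m)
    n, k = x.shape
    aligned = x - x.mean(axis=1, keepdims=True)
    r = rankdata(aligned).reshape(n, k)
    Rc = r.sum(axis=0)
    Rr = r.sum(axis=1)
    num = (k - 1) * (float(np.sum(Rc ** 2)) - (k * n * n / 4.0) * (k * n + 1) ** 2)
    den = (k * n * (k * n + 1) * (2 * k * n + 1)) / 6.0 - float(np.sum(Rr ** 2)) / k
    if den == 0:
        return RankTestResult("aligned_friedman", 0.0, (float(k - 1),), 1.0)
    T = max(num / den, 0.0)
    p = float(sps.chi2.sf(T, k - 1))
    return RankTestResult("aligned_friedman", T, (float(k - 1),), p)


def quade(m: pd.DataFrame) -> RankTestResult:
    """Quade test: blocks weighted by the rank Q_i of their sample range.

    S_ij = Q_i (r_ij - (k+1)/2);  B = sum_j S_j^2 / n;  A = sum S_ij^2;
    F = (n-1) B / (A - B), ~ F(k-1, (k-1)(n-1)).  A == B (zero residual
    variability) yields p = 1 with a warning.
    """
    x = _validate(m)
    n, k = x.shape
    r = np.apply_along_axis(rankdata, 1, x)
    Q = rankdata(x.max(axis=1) - x.min(axis=1))
    S = Q[:, None] * (r - (k + 1) / 2.0)
    A = float(np.sum(S ** 2))
    B = float(np.sum(S.sum(axis=0) ** 2)) / n
    if A <= B:
        warnings.warn("Quade: zero residual variability; p = 1")
        return RankTestResult("quade", 0.0,
                              (float(k - 1), float((k - 1) * (n - 1))), 1.0)
    F = (n - 1) * B / (A - B)
    p = float(sps.f.sf(F, k - 1, (k - 1) * (n - 1)))
    return RankTestResult("quade", F, (float(k - 1), float((k - 1) * (n - 1))), p)


def all_tests(m: pd.DataFrame, transpose: bool = False
              ) -> dict[str, RankTestResult]:
    """Run all four tests. ``transpose=True`` compares algorithms
    (treatments = rows) instead of groups.

    A perfectly column-ordered matrix drives the Friedman statistic to
    its maximum n(k-1), where the Iman-Davenport F is unbounded; that
    limit is reported as statistic inf, p = 0.
    """
    mm = m.T if transpose else m
    out = {}
    for fn in (friedman, iman_davenport, aligned_friedman, quade):
        try:
            r = fn(mm)
        except ZeroDivisionError:
            n, k = mm.shape
            r = RankTestResult(fn.__name__, float("inf"),
                               (float(k - 1), float((k - 1) * (n - 1))), 0.0)
        out[r.method] = r
    return out
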