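"""Cross-tabulation and chance-corrected agreement (Cohen's kappa).

Agreement between experimentally determined and imputed three-state
deletion genotypes is summarised by a 3x3 confusion matrix (rows = truth,
columns = predicted, category order wt/wt, wt/del, del/del) and Cohen's
kappa, optionally weighted.  Weights for k ordered categories are

* ``none``      : identity (classic unweighted kappa),
* ``linear``    : w_ij = 1 - |i - j| / (k - 1)  (Cicchetti-Allison),
* ``quadratic`` : w_ij = 1 - (i - j)**2 / (k - 1)**2  (Fleiss-Cohen).

kappa = (po_w - pe_w) / (1 - pe_w) with pe_w from the marginal products.
The standard error is the large-sample weighted formula of Fleiss, Cohen
and Everitt; the 95% CI is kappa +/- 1.96 * SE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import GENOTYPE_LABELS
from .errors import DataError

WEIGHTINGS = ("none", "linear", "quadratic")


@dataclass
class ConfusionMatrix:
    """k x k cross-tabulation; rows are truth, columns are predicted."""

    counts: np.ndarray
    labels: tuple[str, ...] = GENOTYPE_LABELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected a {k}x{k} matrix")
        if (self.counts < 0).any():
            raise ValueError("negative cell count")
        if self.n < 1:
            raise DataError("empty confusion matrix")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class KappaEstimate:
    kappa: float
    weighting: str
    se: float
    ci95: tuple[float, float]


def cross_tabulate(truth: pd.Series, predicted: pd.Series) -> ConfusionMatrix:
    """Cross-tabulate two dosage call sets over their shared, non-missing
    sample ids (category order fixed as wt/wt, wt/del, del/del)."""
    common = truth.index.intersection(predicted.index)
    t = truth.loc[common]
    p = predicted.loc[common]
    ok = t.notna() & p.notna()
    t, p = t[ok].astype(int), p[ok].astype(int)
    if len(t) == 0:
        raise DataError("no samples with both truth and predicted calls")
    k = len(GENOTYPE_LABELS)
    counts = np.zeros((k, k))
    np.add.at(counts, (t.to_numpy(), p.to_numpy()), 1)
    return ConfusionMatrix(counts=counts)


def overall_accuracy(cm: ConfusionMatrix) -> tuple[float, str]:
    """Trace / n, plus a percent string rendered to 2 decimals."""
    prop = float(np.trace(cm.counts) / cm.n)
    return prop, f"{100 * prop:.2f}%"


def _weight_matrix(k: int, weighting: str) -> np.ndarray:
    i, j = np.indices((k, k))
    if weighting == "none":
        return (i == j).astype(float)
    if weighting == "linear":
        return 1.0 - np.abs(i - j) / (k - 1)
    if weighting == "quadratic":
        return 1.0 - (i - j) ** 2 / (k - 1) ** 2
    raise ValueError(f"unknown weighting {weighting!r}; expected one of {WEIGHTINGS}")


def cohen_kappa(cm: ConfusionMatrix, weighting: str = "none") -> KappaEstimate:
    """Cohen's kappa with asymptotic SE and normal 95% CI."""
    n = cm.n
    if n < 2:
        raise DataError("kappa requires n >= 2")
    p = cm.counts / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    w = _weight_matrix(len(cm.labels), weighting)
    po = float((w * p).sum())
    pe = float((w * np.outer(row, col)).sum())
    if pe >= 1.0:
        raise DataError("degenerate marginals: chance agreement is 1, kappa undefined")
    kappa = (po - pe) / (1 - pe)

    # Fleiss-Cohen-Everitt large-sample variance of weighted kappa-hat
    wbar_i = w @ col          # row-wise expected weight
    wbar_j = row @ w          # column-wise expected weight
    term = (w - (wbar_i[:, None] + wbar_j[None, :]) * (1 - kappa)) ** 2
    var = ((p * term).sum() - (kappa - pe * (1 - kappa)) ** 2) / (n * (1 - pe) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    ci = (kappa - 1.96 * se, kappa + 1.96 * se)
    return KappaEstimate(kappa=float(kappa), weighting=weighting, se=se, ci95=ci)


def agreement_report(cm: ConfusionMatrix) -> pd.DataFrame:
    """One row per weighting scheme: kappa, SE, CI, accuracy, n."""
    acc, _ = overall_accuracy(cm)
    rows = []
    for w in WEIGHTINGS:
        est = cohen_kappa(cm, weighting=w)
        rows.append(
            {
                "weighting": w,
                "kappa": est.kappa,
                "se": est.se,
                "ci_low": est.ci95[0],
                "ci_high": est.ci95[1],
                "accuracy": acc,
                "n": cm.n,
            }
        )
    return pd.DataFrame(rows)
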