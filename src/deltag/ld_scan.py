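"""Pairwise linkage disequilibrium between the deletion and each SNP.

Two r² estimators are provided:

* ``dosage`` (default) — the squared Pearson correlation of the two
  unphased genotype-dosage vectors (composite LD).  The deletion genotype
  is unphased, so this is the natural estimator and is what the candidate
  threshold (r² > 0.2) is applied to.
* ``em`` — the classical haplotype-frequency EM for two unphased biallelic
  loci: double heterozygotes are split between cis and trans configurations
  at each iteration, and r² = D²/(p_A q_A p_B q_B) at the fixed point.

Samples missing either genotype are dropped pairwise; a constant vector on
the complete pairs makes LD undefined (an explicit error, never r² = 0).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import Cohort
from .errors import UndefinedLdError

logger = logging.getLogger(__name__)

METHODS = ("dosage", "em")


@dataclass(frozen=True)
class LdEstimate:
    """r² between one SNP and the deletion variant."""

    snp_id: str
    r2: float
    method: str
    n_used: int


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors must have equal length")
    mask = ~np.isnan(x) & ~np.isnan(y)
    if mask.sum() < 2:
        raise UndefinedLdError("fewer than 2 pairwise-complete samples")
    xs, ys = x[mask], y[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise UndefinedLdError("constant genotype vector: LD undefined")
    return xs, ys


def dosage_r2(x, y) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Symmetric in its arguments and invariant under an allele-label flip
    (dosage -> 2 - dosage) of either vector.
    """
    xs, ys = _complete_pairs(x, y)
    r = np.corrcoef(xs, ys)[0, 1]
    return float(min(r * r, 1.0))


def _em_fixed_point(
    counts: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> tuple[np.ndarray, bool]:
    """Run EM on a 3x3 genotype-count table; return haplotype frequencies
    (f11, f10, f01, f00) and a convergence flag.

    Allele marginals are invariant under the E-step (phase ambiguity never
    changes allele counts), so only the cis/trans split of the (1,1) cell
    is iterated.
    """
    n = counts.sum()
    two_n = 2.0 * n
    # deterministic haplotype contributions from the 8 unambiguous cells
    c11 = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    c10 = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    c01 = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    c00 = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    ndh = counts[1, 1]  # double heterozygotes: cis (11/00) or trans (10/01)

    pa = (c11 + c10 + ndh) / two_n  # allele-1 frequency, locus A
    pb = (c11 + c01 + ndh) / two_n
    f = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    converged = False
    for _ in range(max_iter):
        cis_w = f[0] * f[3]
        trans_w = f[1] * f[2]
        p_cis = 0.5 if cis_w + trans_w == 0 else cis_w / (cis_w + trans_w)
        new = np.array(
            [
                c11 + ndh * p_cis,
                c10 + ndh * (1 - p_cis),
                c01 + ndh * (1 - p_cis),
                c00 + ndh * p_cis,
            ]
        ) / two_n
        if np.max(np.abs(new - f)) < tol:
            f = new
            converged = True
            break
        f = new
    return f, converged


def em_haplotype_r2(x, y, tol: float = 1e-10, max_iter: int = 1000) -> float:
    """Maximum-likelihood haplotype r² for two unphased biallelic loci.

    Maximises the two-locus multinomial likelihood over the four haplotype
    frequencies by EM and returns D²/(p_A q_A p_B q_B) at the fixed point.
    Non-convergence (rare) emits a warning and returns the last iterate.
    """
    xs, ys = _complete_pairs(x, y)
    counts = np.zeros((3, 3), dtype=float)
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((xs == i) & (ys == j))
    f, converged = _em_fixed_point(counts, tol=tol, max_iter=max_iter)
    if not converged:
        warnings.warn("EM for haplotype frequencies did not converge", RuntimeWarning)
    pa = f[0] + f[1]
    pb = f[0] + f[2]
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom <= 0:
        raise UndefinedLdError("monomorphic locus at the EM fixed point")
    d = f[0] - pa * pb
    return float(min(d * d / denom, 1.0))


_ESTIMATORS = {"dosage": dosage_r2, "em": em_haplotype_r2}


def scan_region(
    cohort: Cohort, threshold: float = 0.2, method: str = "dosage"
) -> list[LdEstimate]:
    """Estimate r² between the deletion and every SNP; return candidates.

    Returns the subset with r² > ``threshold``, sorted by descending r²,
    ties broken by ascending genomic position.  SNPs with undefined LD
    (monomorphic on the complete pairs) are skipped with a logged count.
    Use :func:`scan_table` for the full per-SNP table.
    """
    return [
        LdEstimate(row.snp_id, row.r2, method, int(row.n_used))
        for row in scan_table(cohort, method=method).itertuples()
        if not np.isnan(row.r2) and row.r2 > threshold
    ]


def scan_table(cohort: Cohort, method: str = "dosage") -> pd.DataFrame:
    """Full LD scan as a DataFrame (snp_id, chrom, pos, r2, n_used, method),
    sorted by descending r² with position tie-break; undefined LD -> NaN r².
    """
    if method not in _ESTIMATORS:
        raise ValueError(f"unknown LD method {method!r}; expected one of {METHODS}")
    estimator = _ESTIMATORS[method]
    del_dosage = cohort.deletion_calls.to_numpy(dtype=float)
    rows = []
    n_undefined = 0
    for snp_id in cohort.snp_matrix.snp_ids:
        snp = cohort.snp_matrix.dosages[snp_id].to_numpy(dtype=float)
        n_used = int((~np.isnan(snp) & ~np.isnan(del_dosage)).sum())
        meta = cohort.snp_matrix.variants.loc[snp_id]
        try:
            r2 = estimator(snp, del_dosage)
        except UndefinedLdError:
            n_undefined += 1
            r2 = np.nan
        rows.append((snp_id, meta["chrom"], int(meta["pos"]), r2, n_used, method))
    if n_undefined:
        logger.info("scan: LD undefined for %d SNPs (skipped)", n_undefined)
    table = pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "r2", "n_used", "method"]
    )
    return table.sort_values(
        ["r2", "pos"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)


def write_scan_tsv(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
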