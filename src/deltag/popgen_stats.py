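"""Population-genetic statistics: allele frequencies, Hardy-Weinberg
likelihood-ratio testing, cross-population frequency comparison, and
case-control logistic association with covariates.

Conventions
-----------
* The deletion-allele frequency from genotype counts (n_wtwt, n_wtdel,
  n_deldel) is (n_wtdel + 2 n_deldel) / 2n.
* HWE is tested by the likelihood-ratio (G) statistic against expected
  counts (q^2 n, 2pq n, p^2 n), df = 1.
* Cross-population comparisons are allele-level: each individual
  contributes two allele observations, exactly the construction used when
  regressing allele (0 = wild-type, 1 = deletion) on population of origin.
  The within-individual correlation of the two alleles is ignored by this
  construction (a documented caveat of the allele-level model).
* Case-control association is a multivariable logistic regression with the
  genotype entered as two indicators (wt/del and del/del vs wt/wt) and age
  and sex as a priori covariates; sex is coded female = 1.  The joint
  genotype test is an LRT (df = 2) against the covariates-only model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort_io import Cohort
from .errors import DataError

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class GenotypeCounts:
    """Three-state genotype counts for one population/group."""

    n_wtwt: int
    n_wtdel: int
    n_deldel: int
    population: str = ""

    def __post_init__(self) -> None:
        if min(self.n_wtwt, self.n_wtdel, self.n_deldel) < 0:
            raise ValueError("negative genotype count")
        if self.n < 1:
            raise DataError("empty genotype counts")

    @property
    def n(self) -> int:
        return self.n_wtwt + self.n_wtdel + self.n_deldel

    @property
    def del_alleles(self) -> int:
        return self.n_wtdel + 2 * self.n_deldel

    @property
    def wt_alleles(self) -> int:
        return 2 * self.n - self.del_alleles


@dataclass(frozen=True)
class HweResult:
    G: float
    df: int
    p: float
    expected: tuple[float, float, float]


@dataclass(frozen=True)
class FreqComparison:
    """Allele-level 2x2 comparison of two groups (a vs b)."""

    freq_a: float
    freq_b: float
    odds_ratio: float
    ci95: tuple[float, float] | None
    p_wald: float | None
    flagged: str | None = None


@dataclass
class AssociationFit:
    """Per-term ORs/CIs/p-values plus the joint genotype LRT."""

    terms: pd.DataFrame
    lrt_genotype_p: float
    lrt_genotype_stat: float
    n_used: int
    n_dropped: int
    outcome: str = "phenotype"
    covariates: tuple[str, ...] = ()
    converged: bool = True


def allele_frequency(counts: GenotypeCounts) -> float:
    """Deletion-allele frequency: (n_wtdel + 2 n_deldel) / 2n."""
    return counts.del_alleles / (2 * counts.n)


def hwe_lrt(counts: GenotypeCounts) -> HweResult:
    """Likelihood-ratio (G) test of Hardy-Weinberg proportions, df = 1.

    G = 2 sum O ln(O/E) over cells with O > 0; if one allele is absent the
    data fit HWE exactly and G = 0, p = 1.
    """
    n = counts.n
    p_del = allele_frequency(counts)
    q = 1.0 - p_del
    expected = (q * q * n, 2 * p_del * q * n, p_del * p_del * n)
    observed = (counts.n_wtwt, counts.n_wtdel, counts.n_deldel)
    if p_del in (0.0, 1.0):
        return HweResult(G=0.0, df=1, p=1.0, expected=expected)
    g = 2.0 * sum(o * np.log(o / e) for o, e in zip(observed, expected) if o > 0)
    g = max(float(g), 0.0)
    return HweResult(G=g, df=1, p=float(stats.chi2.sf(g, df=1)), expected=expected)


def allelic_odds_ratio(
    a: GenotypeCounts | tuple[float, int | None],
    b: GenotypeCounts | tuple[float, int | None],
) -> FreqComparison:
    """Allele-level odds ratio of group a vs group b.

    Arguments are either :class:`GenotypeCounts` (Wald CI and p from the
    2x2 allele table) or ``(frequency, n_or_None)`` pairs (point estimate
    only).  A frequency of exactly 0 or 1 yields an infinite/zero OR,
    flagged, with no CI.
    """

    def _freq_cells(g):
        if isinstance(g, GenotypeCounts):
            return allele_frequency(g), (g.del_alleles, g.wt_alleles)
        freq, _n = g
        return float(freq), None

    fa, cells_a = _freq_cells(a)
    fb, cells_b = _freq_cells(b)
    if fa in (0.0, 1.0) or fb in (0.0, 1.0):
        if fa == fb:
            or_ = 1.0
        else:
            num = fa / (1 - fa) if fa < 1 else np.inf
            den = fb / (1 - fb) if fb < 1 else np.inf
            or_ = 0.0 if num == 0 else (np.inf if den == 0 or num is np.inf else num / den)
        return FreqComparison(fa, fb, float(or_), None, None, flagged="boundary frequency")
    or_ = (fa / (1 - fa)) / (fb / (1 - fb))
    if cells_a is None or cells_b is None:
        return FreqComparison(fa, fb, float(or_), None, None)
    cells = np.array([*cells_a, *cells_b], dtype=float)
    se = float(np.sqrt((1.0 / cells).sum()))
    log_or = np.log(or_)
    ci = (float(np.exp(log_or - Z95 * se)), float(np.exp(log_or + Z95 * se)))
    p = float(2 * stats.norm.sf(abs(log_or) / se))
    return FreqComparison(fa, fb, float(or_), ci, p)


def population_freq_regression(
    groups: list[GenotypeCounts], reference: str
) -> pd.DataFrame:
    """Regress allele (deletion = 1) on population of origin.

    Each individual contributes two allele observations; the model is a
    binomial GLM with logit link on per-group allele counts, which is the
    same likelihood.  Per-group ORs equal the closed-form 2x2 allelic ORs
    against the reference (saturated-model identity).  Returns one row per
    non-reference group plus an ``overall_lrt`` row (population effect,
    df = #groups - 1).  Monomorphic groups are flagged and excluded from
    Wald reporting.
    """
    names = [g.population for g in groups]
    if len(groups) < 2:
        raise DataError("need at least two groups")
    if reference not in names:
        raise DataError(f"reference population {reference!r} not among groups")
    if len(set(names)) != len(names):
        raise DataError("duplicate population labels")
    ref = next(g for g in groups if g.population == reference)
    others = [g for g in groups if g.population != reference]

    endog = np.array([[g.del_alleles, g.wt_alleles] for g in [ref, *others]], dtype=float)
    exog = np.zeros((len(groups), len(groups)))
    exog[:, 0] = 1.0
    for i in range(len(others)):
        exog[i + 1, i + 1] = 1.0
    monomorphic = [g.population for g in [ref, *others] if g.del_alleles == 0 or g.wt_alleles == 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(tol=1e-12)
        null = sm.GLM(endog, exog[:, :1], family=sm.families.Binomial()).fit(tol=1e-12)
    lrt = max(0.0, 2.0 * (full.llf - null.llf))
    lrt_p = float(stats.chi2.sf(lrt, df=len(others)))

    rows = []
    for i, g in enumerate(others):
        flagged = g.population in monomorphic or reference in monomorphic
        coef = full.params[i + 1]
        se = full.bse[i + 1]
        rows.append(
            {
                "population": g.population,
                "freq": allele_frequency(g),
                "odds_ratio": float(np.exp(coef)),
                "ci_low": float(np.exp(coef - Z95 * se)) if not flagged else np.nan,
                "ci_high": float(np.exp(coef + Z95 * se)) if not flagged else np.nan,
                "p_wald": float(2 * stats.norm.sf(abs(coef) / se)) if not flagged else np.nan,
                "test": "wald",
                "flagged": "separation" if flagged else "",
            }
        )
    rows.append(
        {
            "population": f"overall (vs {reference})",
            "freq": allele_frequency(ref),
            "odds_ratio": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p_wald": lrt_p,
            "test": "lrt",
            "flagged": "",
        }
    )
    return pd.DataFrame(rows)


def _design_from_cohort(
    cohort: Cohort, covariates: tuple[str, ...]
) -> tuple[pd.Series, pd.DataFrame, int]:
    pheno = cohort.phenotypes.table
    df = pd.DataFrame(index=pheno.index)
    df["y"] = pheno["phenotype"].map({"control": 0.0, "case": 1.0})
    dosage = cohort.deletion_calls.reindex(pheno.index)
    df["wt_del"] = (dosage == 1).astype(float).where(dosage.notna())
    df["del_del"] = (dosage == 2).astype(float).where(dosage.notna())
    cols = ["wt_del", "del_del"]
    if "age" in covariates:
        df["age"] = pheno["age"]
        cols.append("age")
    if "sex" in covariates:
        df["female"] = pheno["sex"].map({"male": 0.0, "female": 1.0})
        cols.append("female")
    eth_cols: list[str] = []
    if "ethnicity" in covariates:
        eth = pheno["ethnicity"]
        levels = eth.value_counts()
        if len(levels) > 1:
            ref_level = levels.index[0]  # most frequent group is the reference
            for lev in levels.index[1:]:
                cname = f"ethnicity[{lev}]"
                df[cname] = (eth == lev).astype(float).where(eth.notna())
                eth_cols.append(cname)
        cols.extend(eth_cols)
    before = len(df)
    df = df.dropna(subset=["y", "wt_del", "del_del", *cols])
    n_dropped = before - len(df)
    X = sm.add_constant(df[cols], has_constant="add")
    return df["y"], X, n_dropped


def genotype_association(
    cohort: Cohort,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> AssociationFit:
    """Multivariable logistic regression of case/control status on the
    deletion genotype (two indicators vs wt/wt) plus covariates.

    Fit by Newton-Raphson IRLS (score tolerance 1e-8, max 100 iterations)
    on complete cases; the joint genotype effect is tested by an LRT
    (df = 2) against the covariates-only model.
    """
    y, X, n_dropped = _design_from_cohort(cohort, tuple(covariates))
    if y.nunique() < 2:
        raise DataError("outcome must have both cases and controls")
    n_params = X.shape[1]
    if len(y) < 10 * n_params:
        warnings.warn(
            f"only {len(y)} complete cases for {n_params} parameters "
            "(fewer than 10 per parameter)",
            UserWarning,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.Logit(y, X).fit(method="newton", tol=1e-8, maxiter=100, disp=0)
        reduced_cols = [c for c in X.columns if c not in ("wt_del", "del_del")]
        reduced = sm.Logit(y, X[reduced_cols]).fit(
            method="newton", tol=1e-8, maxiter=100, disp=0
        )
    if not full.mle_retvals.get("converged", True):
        raise DataError(f"logistic fit did not converge: {full.mle_retvals}")
    flagged = bool(np.any(np.abs(full.params) > 15))  # crude separation screen
    if flagged:
        warnings.warn("possible perfect separation (extreme coefficient)", UserWarning)

    conf = full.conf_int()
    terms = []
    rename = {"wt_del": "genotype wt/del", "del_del": "genotype del/del"}
    for name in X.columns:
        if name == "const":
            continue
        terms.append(
            {
                "term": rename.get(name, name),
                "odds_ratio": float(np.exp(full.params[name])),
                "ci_low": float(np.exp(conf.loc[name, 0])),
                "ci_high": float(np.exp(conf.loc[name, 1])),
                "p": float(full.pvalues[name]),
                "test": "wald",
            }
        )
    lrt = max(0.0, 2.0 * (full.llf - reduced.llf))
    lrt_p = float(stats.chi2.sf(lrt, df=2))
    terms.append(
        {
            "term": "genotype (joint)",
            "odds_ratio": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p": lrt_p,
            "test": "lrt",
        }
    )
    # reference level row for report parity
    terms.insert(
        0,
        {
            "term": "genotype wt/wt (ref)",
            "odds_ratio": 1.0,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p": np.nan,
            "test": "",
        },
    )
    return AssociationFit(
        terms=pd.DataFrame(terms),
        lrt_genotype_p=lrt_p,
        lrt_genotype_stat=float(lrt),
        n_used=int(len(y)),
        n_dropped=int(n_dropped),
        covariates=tuple(covariates),
        converged=not flagged,
    )


def power_additive(
    n_cases: int,
    n_controls: int,
    freq: float,
    or_per_allele: float,
    alpha: float = 0.05,
    reps: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Monte-Carlo power of the additive (dosage-trend) Wald test.

    Control genotypes are drawn from HWE at ``freq``; case genotypes from
    HWE proportions tilted by ``or_per_allele ** dosage`` (the logistic
    retrospective-sampling model).  Each replicate fits case/control status
    on dosage by logistic regression and tests the dosage coefficient at
    ``alpha``.  Returns (power, 95% binomial CI).
    """
    if not 0 < freq < 1:
        raise ValueError("freq must be in (0,1)")
    if or_per_allele <= 0 or reps < 100:
        raise ValueError("or_per_allele must be > 0 and reps >= 100")
    rng = np.random.default_rng(seed)
    q = 1 - freq
    hwe = np.array([q * q, 2 * freq * q, freq * freq])
    tilt = hwe * or_per_allele ** np.arange(3)
    case_probs = tilt / tilt.sum()
    dosage = np.array([0.0, 1.0, 2.0])
    rejections = 0
    for _ in range(reps):
        case_counts = rng.multinomial(n_cases, case_probs)
        ctrl_counts = rng.multinomial(n_controls, hwe)
        # aggregated binomial GLM: 3 covariate patterns
        endog = np.column_stack([case_counts, ctrl_counts]).astype(float)
        keep = endog.sum(axis=1) > 0
        exog = sm.add_constant(dosage[keep], has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(endog[keep], exog, family=sm.families.Binomial()).fit()
            p = 2 * stats.norm.sf(abs(fit.params[1] / fit.bse[1]))
        except Exception:
            continue
        if p < alpha:
            rejections += 1
    power = rejections / reps
    half = Z95 * np.sqrt(power * (1 - power) / reps)
    return float(power), (max(0.0, power - half), min(1.0, power + half))


def read_genotype_counts(path: str) -> list[GenotypeCounts]:
    """Read a genotype-counts TSV (population, n_wtwt, n_wtdel, n_deldel),
    enabling published-table comparisons without raw data."""
    df = pd.read_csv(path, sep="\t")
    required = ["population", "n_wtwt", "n_wtdel", "n_deldel"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"genotype-counts TSV missing columns: {missing}")
    return [
        GenotypeCounts(
            int(r["n_wtwt"]), int(r["n_wtdel"]), int(r["n_deldel"]), str(r["population"])
        )
        for _, r in df.iterrows()
    ]


def write_association_report(fit: AssociationFit, path: str) -> None:
    fit.terms.to_csv(path, sep="\t", index=False, float_format="%.6g")
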