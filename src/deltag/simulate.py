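"""Synthetic cohort generator.

Generates a genomic region carrying one deletion variant in specified LD
with a handful of tag SNPs, a background of unlinked noise SNPs in HWE,
and a binary phenotype driven by age, sex and genotype odds ratios — the
test bed for the LD scan, tag-SNP model and association statistics.

Genetic model: each sample receives two haplotypes drawn independently
(random union of gametes, hence HWE at every locus).  On each haplotype
the deletion allele is Bernoulli(p_del) and each tag SNP's alt allele is
drawn conditionally on that haplotype's deletion allele from the two-locus
haplotype table implied by the target correlation r:

    f(del,alt) = p_del * p_alt + D,   D = r * sqrt(p_del q_del p_alt q_alt)

Tags are conditionally independent given the deletion allele, which
reproduces the dominant tag-target LD structure without modelling full
haplotype blocks.  A tag spec whose implied haplotype table has a negative
frequency (Lewontin bound violation) is rejected at validation time.

Defaults emulate the Gambian study setting: deletion frequency 0.362,
three tags at r = 0.968/0.943/0.942 (r^2 ~ 0.937/0.889/0.888), 100 noise
SNPs, age effect OR 1.07 per year over ages 30-95, female OR 1.68.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import cohort_io
from .cohort_io import Cohort, PhenotypeTable, SnpGenotypeMatrix
from .errors import ConfigError
from .ld_scan import dosage_r2, UndefinedLdError

TRUTH_SCHEMA_VERSION = 1

#: Default seed used for packaged fixtures.
DEFAULT_SEED = 20160616

_REGION_CHROM = "chr12"
_DELETION_START = 10_440_000
_DELETION_END = 10_456_000  # 16-kb deletion
_TAG_POSITIONS = (10_431_500, 10_462_300, 10_470_900, 10_425_100, 10_480_700)
_NOISE_SPAN = (9_500_000, 11_500_000)


@dataclass(frozen=True)
class TagSnpSpec:
    """One tag SNP: alt-allele frequency and target correlation with the
    deletion allele (r, signed; r**2 is the familiar LD measure)."""

    snp_id: str
    alt_freq: float
    r: float

    def __post_init__(self) -> None:
        if not 0 < self.alt_freq < 1:
            raise ConfigError(f"tag {self.snp_id}: alt_freq must be in (0,1)")
        if not -1 <= self.r <= 1:
            raise ConfigError(f"tag {self.snp_id}: r must be in [-1,1]")


def _default_tags() -> tuple[TagSnpSpec, ...]:
    return (
        TagSnpSpec("tag_1", 0.37, 0.968),
        TagSnpSpec("tag_2", 0.35, 0.943),
        TagSnpSpec("tag_3", 0.38, 0.942),
    )


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 2000
    p_del: float = 0.362
    tags: tuple[TagSnpSpec, ...] = field(default_factory=_default_tags)
    n_noise_snps: int = 100
    noise_freq_range: tuple[float, float] = (0.05, 0.5)
    intercept_odds: float = 0.01
    or_age_per_year: float = 1.07
    or_female: float = 1.68
    or_wtdel: float = 1.0
    or_deldel: float = 1.0
    age_range: tuple[float, float] = (30.0, 95.0)
    prop_female: float = 0.71
    snp_missing_rate: float = 0.0
    del_missing_rate: float = 0.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if not 0 < self.p_del < 1:
            raise ConfigError("p_del must be in (0,1)")
        lo, hi = self.noise_freq_range
        if not (0 < lo <= hi < 1):
            raise ConfigError("noise_freq_range must satisfy 0 < lo <= hi < 1")
        for name in ("intercept_odds", "or_age_per_year", "or_female", "or_wtdel", "or_deldel"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not 0 <= self.prop_female <= 1:
            raise ConfigError("prop_female must be in [0,1]")
        for name in ("snp_missing_rate", "del_missing_rate"):
            if not 0 <= getattr(self, name) < 1:
                raise ConfigError(f"{name} must be in [0,1)")
        if len({t.snp_id for t in self.tags}) != len(self.tags):
            raise ConfigError("duplicate tag SNP ids")
        for t in self.tags:
            haplotype_table(self.p_del, t)  # raises on Lewontin violation

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        tags = raw.pop("tags", None)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("noise_freq_range", "age_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        try:
            if tags is not None:
                raw["tags"] = tuple(
                    TagSnpSpec(t["snp_id"], float(t["alt_freq"]), float(t["r"]))
                    for t in tags
                )
            return cls(**raw)
        except (TypeError, KeyError, ValueError) as exc:
            raise ConfigError(f"invalid simulation config: {exc}") from exc


@dataclass
class SimulatedCohort:
    """A Cohort plus the generating truth needed to score imputation."""

    cohort: Cohort
    true_del_dosage: pd.Series  # pre-missingness deletion dosages
    realized_tag_r2: dict[str, float]
    config: SimulationConfig


def haplotype_table(p_del: float, spec: TagSnpSpec) -> tuple[float, float, float, float]:
    """Two-locus haplotype frequencies (del-alt, del-ref, wt-alt, wt-ref).

    f(del,alt) = p_del p_alt + D with D = r sqrt(p_del q_del p_alt q_alt);
    a negative implied frequency (Lewontin bound violation) is a config
    error naming the offending tag spec.
    """
    p, a = p_del, spec.alt_freq
    d = spec.r * np.sqrt(p * (1 - p) * a * (1 - a))
    table = (p * a + d, p * (1 - a) - d, (1 - p) * a - d, (1 - p) * (1 - a) + d)
    if min(table) < -1e-12:
        raise ConfigError(
            f"tag {spec.snp_id} (alt_freq={a}, r={spec.r}) violates Lewontin "
            f"bounds at p_del={p}: implied haplotype frequencies {table}"
        )
    return tuple(max(f, 0.0) for f in table)


def _random_alleles(rng: np.random.Generator, n: int) -> tuple[list[str], list[str]]:
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n)
    alt_off = rng.integers(1, 4, size=n)
    return list(bases[ref_idx]), list(bases[(ref_idx + alt_off) % 4])


def simulate_genotypes(config: SimulationConfig) -> SimulatedCohort:
    """Draw deletion + tag + noise genotypes for ``config.n_samples``
    samples (two independent haplotypes per sample, hence HWE), apply
    missingness masks, and record the per-sample truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i + 1:05d}" for i in range(n)]

    # two deletion haplotypes per sample
    del_haps = rng.random((n, 2)) < config.p_del
    true_del = del_haps.sum(axis=1).astype(float)

    snp_ids: list[str] = []
    positions: list[int] = []
    columns: list[np.ndarray] = []
    if len(config.tags) > len(_TAG_POSITIONS):
        raise ConfigError(f"at most {len(_TAG_POSITIONS)} tag SNPs supported")
    for spec, pos in zip(config.tags, _TAG_POSITIONS):
        f_da, f_dr, f_wa, f_wr = haplotype_table(config.p_del, spec)
        p_alt_given_del = f_da / config.p_del
        p_alt_given_wt = f_wa / (1 - config.p_del)
        cond = np.where(del_haps, p_alt_given_del, p_alt_given_wt)
        tag_dosage = (rng.random((n, 2)) < cond).sum(axis=1).astype(float)
        snp_ids.append(spec.snp_id)
        positions.append(pos)
        columns.append(tag_dosage)

    noise_freqs = rng.uniform(*config.noise_freq_range, size=config.n_noise_snps)
    noise_pos = sorted(
        rng.choice(
            np.arange(_NOISE_SPAN[0], _NOISE_SPAN[1], 50), config.n_noise_snps, replace=False
        ).tolist()
    )
    for j in range(config.n_noise_snps):
        columns.append(rng.binomial(2, noise_freqs[j], size=n).astype(float))
        snp_ids.append(f"noise_{j + 1:03d}")
        positions.append(int(noise_pos[j]))

    dosages = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((n, 0)),
        index=pd.Index(samples, name="sample_id"),
        columns=snp_ids,
    )
    if config.snp_missing_rate > 0:
        mask = rng.random(dosages.shape) < config.snp_missing_rate
        dosages = dosages.mask(mask)
    refs, alts = _random_alleles(rng, len(snp_ids))
    variants = pd.DataFrame(
        {"chrom": _REGION_CHROM, "pos": positions, "ref": refs, "alt": alts},
        index=pd.Index(snp_ids, name="snp_id"),
    )
    matrix = SnpGenotypeMatrix(dosages=dosages, variants=variants)

    deletion = pd.Series(true_del, index=dosages.index, name="dosage")
    if config.del_missing_rate > 0:
        deletion = deletion.mask(rng.random(n) < config.del_missing_rate)

    # placeholder phenotype table until simulate_phenotypes fills it in
    pheno = PhenotypeTable(
        table=pd.DataFrame(
            {
                "age": np.nan,
                "sex": pd.Series(np.nan, index=dosages.index, dtype=object),
                "phenotype": pd.Series(np.nan, index=dosages.index, dtype=object),
                "population": "simulated",
                "ethnicity": pd.Series(np.nan, index=dosages.index, dtype=object),
            },
            index=dosages.index,
        )
    )
    cohort = Cohort(snp_matrix=matrix, deletion_calls=deletion, phenotypes=pheno)

    realized = {}
    for spec in config.tags:
        try:
            realized[spec.snp_id] = dosage_r2(
                dosages[spec.snp_id].to_numpy(), deletion.to_numpy()
            )
        except UndefinedLdError:
            realized[spec.snp_id] = float("nan")
    return SimulatedCohort(
        cohort=cohort,
        true_del_dosage=pd.Series(true_del, index=dosages.index, name="dosage"),
        realized_tag_r2=realized,
        config=config,
    )


def simulate_phenotypes(
    sim: SimulatedCohort, config: SimulationConfig | None = None, seed: int | None = None
) -> SimulatedCohort:
    """Draw ages, sexes and the binary phenotype.

    logit P(case) = ln(intercept_odds) + ln(or_age) age + ln(or_female) female
                    + ln(or_wtdel) 1[dosage=1] + ln(or_deldel) 1[dosage=2]
    """
    config = config or sim.config
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = len(sim.cohort.samples)
    age = rng.uniform(*config.age_range, size=n)
    female = rng.random(n) < config.prop_female
    dosage = sim.true_del_dosage.to_numpy()
    logit = (
        np.log(config.intercept_odds)
        + np.log(config.or_age_per_year) * age
        + np.log(config.or_female) * female
        + np.log(config.or_wtdel) * (dosage == 1)
        + np.log(config.or_deldel) * (dosage == 2)
    )
    p_case = 1.0 / (1.0 + np.exp(-logit))
    case = rng.random(n) < p_case
    table = sim.cohort.phenotypes.table
    table["age"] = age
    table["sex"] = np.where(female, "female", "male")
    table["phenotype"] = np.where(case, "case", "control")
    return sim


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Genotypes + phenotypes in one call."""
    return simulate_phenotypes(simulate_genotypes(config))


def write_fixture(sim: SimulatedCohort, out_dir) -> dict[str, str]:
    """Write VCF + deletion-call TSV + phenotype TSV + truth JSON; returns
    the path of each artifact."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": str(out / "genotypes.vcf"),
        "deletion_calls": str(out / "deletion_calls.tsv"),
        "phenotypes": str(out / "phenotypes.tsv"),
        "truth": str(out / "truth.json"),
    }
    cohort_io.write_vcf(sim.cohort.snp_matrix, paths["vcf"])
    cohort_io.write_deletion_calls(sim.cohort.deletion_calls, paths["deletion_calls"])
    cohort_io.write_phenotypes(sim.cohort.phenotypes, paths["phenotypes"])
    cfg = asdict(sim.config)
    cfg["tags"] = [asdict(t) for t in sim.config.tags]
    truth = {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "true_del_dosage": {
            s: (None if pd.isna(d) else int(d))
            for s, d in sim.true_del_dosage.items()
        },
        "realized_tag_r2": sim.realized_tag_r2,
        "config": cfg,
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1)
    return paths
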