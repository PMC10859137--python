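"""Synthetic biobank-style cohort generator.

Produces individual-level data with the statistical structure an MR analysis
assumes: biallelic SNPs in Hardy-Weinberg equilibrium, an exposure that is
linear in a weighted allele score plus a latent confounder, binary outcomes
from a logistic model with a specified causal effect, optional per-SNP
pleiotropic effects on the outcome, rare large-effect carrier variants, and
kinship pairs for relatedness pruning.  Every draw is reproducible from the
seed in the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "Cohort",
    "ConfigError",
    "simulate_genotypes",
    "simulate_exposure",
    "simulate_binary_outcome",
    "simulate_kinship_pairs",
    "emit_health_records",
    "simulate_cohort",
    "default_config",
]

#: Complementary bases, used when building synthetic variant codings.
BASES = np.array(["A", "C", "G", "T"])

#: Record sources recognised downstream.  HES records carry ICD10/OPCS4
#: vocabularies; GP and SELF carry their own vocabulary.
RECORD_SOURCES = ("HES", "GP", "SELF")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic cohort.

    The exposure model is
    ``X_i = sum_j w_j g_ij + gamma_x U_i + carrier_i * shift + eps_i`` with
    ``U ~ N(0,1)`` latent and ``eps ~ N(0, exposure_noise_sd^2)``.  The
    outcome model is
    ``logit P(Y_i=1) = intercept + beta X_i + gamma_y U_i + sum_j alpha_j g_ij
    + age/sex terms`` with ``beta`` the causal effect (log-odds per exposure
    unit) and ``alpha`` per-SNP direct (pleiotropic) effects.
    """

    n_individuals: int
    n_snps: int
    allele_freqs: np.ndarray
    snp_weights: np.ndarray
    confounder_effect_on_exposure: float = 0.0
    confounder_effect_on_outcome: float = 0.0
    causal_effect: float = 0.0
    pleiotropy_effects: np.ndarray | None = None
    exposure_noise_sd: float = 1.0
    outcome_intercept: float = -4.0
    rare_carrier_freq: float = 0.0
    rare_carrier_exposure_shift: float = 0.0
    n_kinship_pairs: int = 0
    seed: int = 0
    # optional extras beyond the core contract
    age_effect_on_outcome: float = 0.0  # log-odds per year (age centred at 57)
    sex_effect_on_outcome: float = 0.0  # log-odds for sex == 1
    missing_rate: float = 0.0  # per-entry genotype missingness
    # negative-testing switch: couples age to the allele score, breaking the
    # MR independence assumption by construction
    independence_break_effect: float = 0.0
    # boundary-relaxed test configs may set allele freqs to exactly 0 or 1
    allow_boundary_freqs: bool = False

    def __post_init__(self) -> None:
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        self.snp_weights = np.asarray(self.snp_weights, dtype=float)
        if self.pleiotropy_effects is None:
            self.pleiotropy_effects = np.zeros(self.n_snps)
        self.pleiotropy_effects = np.asarray(self.pleiotropy_effects, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_individuals < 0 or self.n_snps < 0:
            raise ConfigError("n_individuals and n_snps must be non-negative")
        for name, vec in (
            ("allele_freqs", self.allele_freqs),
            ("snp_weights", self.snp_weights),
            ("pleiotropy_effects", self.pleiotropy_effects),
        ):
            if vec.shape != (self.n_snps,):
                raise ConfigError(
                    f"{name} has length {vec.shape[0] if vec.ndim else 0}, "
                    f"expected n_snps={self.n_snps}"
                )
        lo, hi = (0.0, 1.0)
        ok = (
            (self.allele_freqs >= lo) & (self.allele_freqs <= hi)
            if self.allow_boundary_freqs
            else (self.allele_freqs > lo) & (self.allele_freqs < hi)
        )
        if not ok.all():
            bad = np.where(~ok)[0]
            raise ConfigError(f"allele_freqs outside (0,1) at SNP index {bad.tolist()}")
        if not 0.0 <= self.rare_carrier_freq <= 0.01:
            raise ConfigError("rare_carrier_freq must lie in [0, 0.01]")
        if not self.exposure_noise_sd > 0:
            raise ConfigError("exposure_noise_sd must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.n_kinship_pairs > self.n_individuals // 2:
            raise ConfigError("n_kinship_pairs must be at most n_individuals/2")


@dataclass
class Cohort:
    """Individual-level synthetic cohort.

    ``genotypes`` holds dosages in {0,1,2} as floats (NaN marks a missing
    call when a missing rate is configured).  ``confounder`` is the latent
    U, retained for oracle checks only and never passed to estimators.
    ``coding`` records, per SNP, which allele the dosage counts — the
    harmonization layer aligns published instrument weights against it.
    """

    genotypes: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    pcs: np.ndarray
    confounder: np.ndarray
    exposure: np.ndarray
    carrier_flag: np.ndarray
    kinship_pairs: list[tuple[int, int, float]]
    coding: pd.DataFrame  # columns: id, counted_allele, other_allele, eaf
    records: pd.DataFrame | None = None  # columns: id, vocabulary, code, source
    outcomes: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def ids(self) -> np.ndarray:
        return np.arange(self.n)

    def subset(self, keep: np.ndarray) -> "Cohort":
        """Restrict to the individuals indexed/masked by ``keep``.

        Kinship pairs and coded records are re-indexed to the retained ids;
        pairs with a dropped member disappear.
        """
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.where(keep)[0]
        old_to_new = {int(o): i for i, o in enumerate(keep)}
        pairs = [
            (old_to_new[a], old_to_new[b], k)
            for a, b, k in self.kinship_pairs
            if a in old_to_new and b in old_to_new
        ]
        records = None
        if self.records is not None:
            rec = self.records[self.records["id"].isin(old_to_new)].copy()
            rec["id"] = rec["id"].map(old_to_new)
            records = rec.reset_index(drop=True)
        return Cohort(
            genotypes=self.genotypes[keep],
            age=self.age[keep],
            sex=self.sex[keep],
            pcs=self.pcs[keep],
            confounder=self.confounder[keep],
            exposure=self.exposure[keep],
            carrier_flag=self.carrier_flag[keep],
            kinship_pairs=pairs,
            coding=self.coding,
            records=records,
            outcomes={k: v[keep] for k, v in self.outcomes.items()},
        )


def _stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent, reproducible generator per named simulation stream."""
    import zlib

    return np.random.default_rng([seed, zlib.crc32(stream.encode())])


def simulate_genotypes(config: SimulationConfig) -> np.ndarray:
    """Draw an n x m dosage matrix, entry (i,j) ~ Binomial(2, f_j) (HWE)."""
    rng = _stream_rng(config.seed, "genotypes")
    g = rng.binomial(2, config.allele_freqs, size=(config.n_individuals, config.n_snps))
    g = g.astype(float)
    if config.missing_rate > 0:
        miss = rng.random(g.shape) < config.missing_rate
        g[miss] = np.nan
    return g


def simulate_exposure(
    genotypes: np.ndarray, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exposure from the linear generative model.

    Returns ``(exposure, confounder, carrier_flag)``; the confounder is the
    latent U drawn here and retained on the cohort for oracle use.
    """
    if genotypes.shape[1] != config.snp_weights.shape[0]:
        raise ConfigError(
            f"genotype matrix has {genotypes.shape[1]} SNPs but "
            f"{config.snp_weights.shape[0]} weights were supplied"
        )
    rng = _stream_rng(config.seed, "exposure")
    n = genotypes.shape[0]
    confounder = rng.standard_normal(n)
    carrier = (rng.random(n) < config.rare_carrier_freq).astype(int)
    noise = rng.standard_normal(n) * config.exposure_noise_sd
    g = np.nan_to_num(genotypes, nan=0.0)
    exposure = (
        g @ config.snp_weights
        + config.confounder_effect_on_exposure * confounder
        + carrier * config.rare_carrier_exposure_shift
        + noise
    )
    return exposure, confounder, carrier


def simulate_binary_outcome(
    exposure: np.ndarray,
    config: SimulationConfig,
    *,
    confounder: np.ndarray | None = None,
    genotypes: np.ndarray | None = None,
    age: np.ndarray | None = None,
    sex: np.ndarray | None = None,
    causal_effect: float | None = None,
    outcome_intercept: float | None = None,
    stream: str = "outcome",
) -> np.ndarray:
    """Bernoulli outcome from the logistic generative model.

    ``causal_effect`` / ``outcome_intercept`` default to the config values
    but can be overridden so one cohort can carry several conditions with
    different prevalences and effects.
    """
    beta = config.causal_effect if causal_effect is None else causal_effect
    intercept = (
        config.outcome_intercept if outcome_intercept is None else outcome_intercept
    )
    logit = intercept + beta * exposure
    if confounder is not None:
        logit = logit + config.confounder_effect_on_outcome * confounder
    if genotypes is not None and np.any(config.pleiotropy_effects):
        logit = logit + np.nan_to_num(genotypes, nan=0.0) @ config.pleiotropy_effects
    if age is not None and config.age_effect_on_outcome:
        logit = logit + config.age_effect_on_outcome * (age - 57.0)
    if sex is not None and config.sex_effect_on_outcome:
        logit = logit + config.sex_effect_on_outcome * sex
    p = 1.0 / (1.0 + np.exp(-logit))
    rng = _stream_rng(config.seed, stream)
    return (rng.random(exposure.shape[0]) < p).astype(int)


def simulate_kinship_pairs(config: SimulationConfig) -> list[tuple[int, int, float]]:
    """Random related pairs with kinship coefficients above the 3rd-degree cut.

    Coefficients are drawn uniformly in [0.0625, 0.25] (2nd degree up to
    parent-offspring/full sibling); pairs may share ids, forming chains.
    """
    if config.n_kinship_pairs == 0:
        return []
    rng = _stream_rng(config.seed, "kinship")
    pairs: list[tuple[int, int, float]] = []
    while len(pairs) < config.n_kinship_pairs:
        a, b = rng.integers(0, config.n_individuals, size=2)
        if a == b:
            continue
        coef = float(rng.uniform(0.0625, 0.25))
        pairs.append((int(a), int(b), coef))
    return pairs


def emit_health_records(
    case_status: Mapping[str, np.ndarray],
    code_lists: Mapping[str, "object"],
    source_mix: Mapping[str, float],
    *,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit one coded record per simulated case, per condition.

    Each case receives a code drawn from the condition's code list, from a
    source drawn according to ``source_mix`` (proportions over HES/GP/SELF
    that must sum to 1).  HES records use the list's ICD10/OPCS4 entries, GP
    and SELF their respective vocabularies.  Prefix-mode ICD10/OPCS4 entries
    are emitted with a random extra final digit half of the time, so
    hierarchy matching is exercised.  Non-cases receive no codes from that
    condition's list.
    """
    props = np.array([source_mix.get(s, 0.0) for s in RECORD_SOURCES], dtype=float)
    if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
        raise ConfigError(
            f"source_mix proportions over {RECORD_SOURCES} must be non-negative "
            f"and sum to 1 (got {dict(source_mix)})"
        )
    rng = _stream_rng(seed, "records")
    rows: list[tuple[int, str, str, str]] = []
    for condition, status in case_status.items():
        clist = code_lists[condition]
        by_vocab: dict[str, list] = {}
        for entry in clist.entries:  # (vocabulary, code, match_mode)
            by_vocab.setdefault(entry[0], []).append(entry)
        hes_entries = by_vocab.get("ICD10", []) + by_vocab.get("OPCS4", [])
        case_ids = np.where(np.asarray(status) == 1)[0]
        sources = rng.choice(len(RECORD_SOURCES), size=case_ids.shape[0], p=props)
        for ind, src_idx in zip(case_ids, sources):
            source = RECORD_SOURCES[src_idx]
            pool = hes_entries if source == "HES" else by_vocab.get(source, [])
            if not pool:
                raise ConfigError(
                    f"code list for {condition!r} has no entry usable for "
                    f"source {source!r}"
                )
            vocab, code, mode = pool[int(rng.integers(len(pool)))]
            if mode == "prefix" and rng.random() < 0.5:
                code = f"{code}{rng.integers(10)}"
            rows.append((int(ind), vocab, code, source))
    return pd.DataFrame(rows, columns=["id", "vocabulary", "code", "source"])


def _make_coding(config: SimulationConfig, genotypes: np.ndarray) -> pd.DataFrame:
    """Variant ids and allele coding for the simulated SNPs.

    Allele pairs are assigned deterministically from the seed; the counted
    allele is the one whose frequency is ``allele_freqs[j]``.  Observed EAF
    is computed from the dosage matrix (matching what a real pipeline would
    report alongside its coding).
    """
    rng = _stream_rng(config.seed, "coding")
    counted, other = [], []
    for _ in range(config.n_snps):
        a, b = rng.choice(4, size=2, replace=False)
        counted.append(BASES[a])
        other.append(BASES[b])
    if genotypes.size:
        with np.errstate(invalid="ignore"):
            eaf = np.nanmean(genotypes, axis=0) / 2.0
    else:
        eaf = np.full(config.n_snps, np.nan)
    return pd.DataFrame(
        {
            "id": [f"rs{j + 1}" for j in range(config.n_snps)],
            "counted_allele": counted,
            "other_allele": other,
            "eaf": eaf,
        }
    )


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Full cohort draw: genotypes, covariates, exposure, kinship, coding."""
    rng = _stream_rng(config.seed, "covariates")
    n = config.n_individuals
    genotypes = simulate_genotypes(config)
    exposure, confounder, carrier = simulate_exposure(genotypes, config)
    age = rng.uniform(40.0, 70.0, size=n)
    if config.independence_break_effect:
        score = np.nan_to_num(genotypes, nan=0.0) @ config.snp_weights
        sd = score.std()
        if sd > 0:
            age = age + config.independence_break_effect * (score - score.mean()) / sd
    sex = rng.integers(0, 2, size=n)
    pcs = rng.standard_normal((n, 5))
    return Cohort(
        genotypes=genotypes,
        age=age,
        sex=sex.astype(int),
        pcs=pcs,
        confounder=confounder,
        exposure=exposure,
        carrier_flag=carrier,
        kinship_pairs=simulate_kinship_pairs(config),
        coding=_make_coding(config, genotypes),
    )


def default_config(
    n_individuals: int = 20_000,
    n_snps: int = 50,
    *,
    seed: int = 0,
    grs_r2: float = 0.02,
    confounder_effect_on_exposure: float = 0.4,
    confounder_effect_on_outcome: float = 0.4,
    causal_effect: float = np.log(1.5),
    outcome_intercept: float = -3.5,
    rare_carrier_freq: float = 0.004,
    rare_carrier_exposure_shift: float = 2.0,
    n_kinship_pairs: int | None = None,
    **overrides,
) -> SimulationConfig:
    """Study-condition defaults, scaled to desk size.

    Allele frequencies are spread over (0.1, 0.9); equal per-allele weights
    are sized so the allele score explains ``grs_r2`` of an exposure of
    total variance ~1 — the weak-but-many-variants regime of polygenic
    instruments.  Exposure units are standardized (variance ~= 1), so the
    causal effect is a log-OR per SD of exposure.
    """
    if n_kinship_pairs is None:
        n_kinship_pairs = n_individuals // 40  # ~2.5% of the cohort in related pairs
    rng = _stream_rng(seed, "config")
    freqs = rng.uniform(0.1, 0.9, size=n_snps)
    var_g = float(np.sum(2 * freqs * (1 - freqs)))
    w = np.sqrt(grs_r2 / var_g) if var_g > 0 else 0.0
    noise_var = 1.0 - grs_r2 - confounder_effect_on_exposure**2
    if noise_var <= 0:
        raise ConfigError("confounder and genetic variance exceed total variance 1")
    return SimulationConfig(
        n_individuals=n_individuals,
        n_snps=n_snps,
        allele_freqs=freqs,
        snp_weights=np.full(n_snps, w),
        confounder_effect_on_exposure=confounder_effect_on_exposure,
        confounder_effect_on_outcome=confounder_effect_on_outcome,
        causal_effect=causal_effect,
        exposure_noise_sd=float(np.sqrt(noise_var)),
        outcome_intercept=outcome_intercept,
        rare_carrier_freq=rare_carrier_freq,
        rare_carrier_exposure_shift=rare_carrier_exposure_shift,
        n_kinship_pairs=n_kinship_pairs,
        seed=seed,
        **overrides,
    )
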