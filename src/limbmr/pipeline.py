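"""Configuration-driven orchestration of the full study emulation.

``run_study`` chains the stages in analysis order — simulate cohorts,
prune relatives, ascertain cases under both definition tiers, observational
logistic models, one-sample MR, per-variant scans, two-sample MR per
cohort, cross-cohort meta-analysis and rare-carrier Fisher tests — and
returns (optionally writes) tidy result tables plus a manifest of every
seed, so a run is reproducible stage by stage.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .instruments import InstrumentTable, compute_grs, harmonize
from .one_sample_mr import run_one_sample_mr
from .phenotypes import (
    KINSHIP_THIRD_DEGREE,
    ascertain_cases,
    packaged_code_lists,
    select_unrelated,
)
from .rare_variant import carrier_association
from .regression_core import FitError, logistic_fit, per_variant_association
from .synthetic_cohort import (
    Cohort,
    SimulationConfig,
    default_config,
    emit_health_records,
    simulate_binary_outcome,
    simulate_cohort,
)
from .two_sample_mr import MetaInput, egger, ivw, make_summary_stats, meta_fixed, weighted_median

__all__ = [
    "StudyConfig",
    "StudyResult",
    "run_study",
    "render_forest_table",
    "stage_seed",
    "make_instrument_table",
    "default_study_config",
]

Z95 = 1.959963984540054


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic child seed for a named stage (stable across runs)."""
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class StudyConfig:
    """Everything one full emulation run needs; loadable from YAML."""

    seed: int = 0
    n_individuals: int = 20_000
    n_snps: int = 50
    cohorts: list[str] = field(default_factory=lambda: ["discovery", "replication"])
    conditions: dict[str, dict] = field(
        default_factory=lambda: {
            # per-SD causal log-ORs and baseline intercepts chosen to give
            # case fractions in the 0.5-3% band typical of these conditions
            "frozen_shoulder": {"causal_effect": float(np.log(1.5)), "intercept": -5.3},
            "dupuytren": {"causal_effect": float(np.log(1.17)), "intercept": -4.5},
            "trigger_finger": {"causal_effect": float(np.log(1.3)), "intercept": -5.3},
            "carpal_tunnel": {"causal_effect": float(np.log(1.2)), "intercept": -3.6},
        }
    )
    tiers: list[str] = field(default_factory=lambda: ["broad", "specific"])
    source_mix: dict[str, float] = field(
        default_factory=lambda: {"HES": 0.6, "GP": 0.3, "SELF": 0.1}
    )
    one_sample_modes: list[str] = field(
        default_factory=lambda: ["linear", "logistic-2sri"]
    )
    two_sample_methods: list[str] = field(
        default_factory=lambda: ["IVW", "MR-Egger", "WM", "PWM"]
    )
    mr_tier: str = "specific"
    kinship_threshold: float = KINSHIP_THIRD_DEGREE
    simulation_overrides: dict = field(default_factory=dict)
    instrument_file: str | None = None
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def default_study_config(seed: int = 0, **overrides) -> StudyConfig:
    return StudyConfig(seed=seed, **overrides)


def make_instrument_table(
    sim: SimulationConfig, coding: pd.DataFrame, seed: int, weight_noise_frac: float = 0.05
) -> InstrumentTable:
    """Synthetic published weight table for the simulated variants.

    Emulates an external GWAS: the effect allele is the cohort's counted
    allele for half the variants and the other allele (sign-flipped weight)
    for the rest; 30% of rows are strand-complemented; published weights
    carry a little estimation noise and an SE.
    """
    from .instruments import COMPLEMENT

    rng = np.random.default_rng(seed)
    rows = []
    for j, row in enumerate(coding.itertuples()):
        w_true = float(sim.snp_weights[j])
        se = max(abs(w_true) * 0.1, 1e-4)
        w_pub = w_true + rng.normal(0.0, weight_noise_frac * max(abs(w_true), 1e-3))
        ea, oa = str(row.counted_allele), str(row.other_allele)
        eaf = float(row.eaf)
        if rng.random() < 0.5:  # report the other allele as effect allele
            ea, oa = oa, ea
            w_pub = -w_pub
            eaf = 1.0 - eaf
        if rng.random() < 0.3:  # opposite strand
            ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
        rows.append(
            {
                "id": str(row.id),
                "effect_allele": ea,
                "other_allele": oa,
                "weight": w_pub,
                "se": se,
                "eaf": eaf,
            }
        )
    return InstrumentTable(pd.DataFrame(rows))


@dataclass
class StudyResult:
    tables: dict[str, pd.DataFrame]
    manifest: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _simulate_labelled_cohort(
    config: StudyConfig, label: str, code_lists
) -> tuple[Cohort, SimulationConfig]:
    """One cohort: simulate, attach per-condition outcomes + records, prune kin."""
    sim = default_config(
        config.n_individuals,
        config.n_snps,
        seed=stage_seed(config.seed, "variants"),  # shared variant definition
        **config.simulation_overrides,
    )
    # cohort-specific sampling seed, shared variant seed
    sim.seed = stage_seed(config.seed, f"cohort:{label}")
    cohort = simulate_cohort(sim)
    cohort.coding = _shared_coding(config, sim, cohort)
    for name, spec in config.conditions.items():
        cohort.outcomes[name] = simulate_binary_outcome(
            cohort.exposure,
            sim,
            confounder=cohort.confounder,
            genotypes=cohort.genotypes,
            age=cohort.age,
            sex=cohort.sex,
            causal_effect=float(spec["causal_effect"]),
            outcome_intercept=float(spec["intercept"]),
            stream=f"outcome:{name}",
        )
    cohort.records = emit_health_records(
        cohort.outcomes,
        code_lists,
        config.source_mix,
        seed=stage_seed(config.seed, f"records:{label}"),
    )
    retained = select_unrelated(cohort.kinship_pairs, config.kinship_threshold)
    related_ids = {i for a, b, _ in cohort.kinship_pairs for i in (a, b)}
    keep = np.ones(cohort.n, dtype=bool)
    for i in related_ids - retained:
        keep[i] = False
    return cohort.subset(keep), sim


def _shared_coding(config: StudyConfig, sim: SimulationConfig, cohort: Cohort) -> pd.DataFrame:
    """Allele coding shared across cohorts (EAF observed per cohort)."""
    from .synthetic_cohort import _make_coding

    base = SimulationConfig(
        n_individuals=0,
        n_snps=sim.n_snps,
        allele_freqs=sim.allele_freqs,
        snp_weights=sim.snp_weights,
        seed=stage_seed(config.seed, "variants"),
        allow_boundary_freqs=True,
    )
    coding = _make_coding(base, np.empty((0, sim.n_snps)))
    with np.errstate(invalid="ignore"):
        coding["eaf"] = np.nanmean(cohort.genotypes, axis=0) / 2.0
    return coding


def run_study(config: StudyConfig, write: bool | None = None) -> StudyResult:
    """Run the full emulated study deterministically under one seed."""
    code_lists = packaged_code_lists()
    missing = set(config.conditions) - set(code_lists)
    if missing:
        raise ValueError(f"no packaged code list for condition(s) {sorted(missing)}")

    cohorts: dict[str, Cohort] = {}
    sims: dict[str, SimulationConfig] = {}
    for label in config.cohorts:
        cohorts[label], sims[label] = _simulate_labelled_cohort(config, label, code_lists)
    primary = config.cohorts[0]
    cohort = cohorts[primary]
    sim = sims[primary]

    if config.instrument_file:
        from .instruments import load_instrument_table

        instr = load_instrument_table(config.instrument_file)
    else:
        instr = make_instrument_table(
            sim, cohort.coding, stage_seed(config.seed, "instruments")
        )

    # --- case ascertainment (both tiers), per cohort -----------------------
    status = {
        label: {
            (name, tier): ascertain_cases(c.records, code_lists[name], tier, c.n)
            for name in config.conditions
            for tier in config.tiers
        }
        for label, c in cohorts.items()
    }
    case_rows = [
        {
            "cohort": label,
            "condition": name,
            "tier": tier,
            "n": cohorts[label].n,
            "n_cases": cs.n_cases,
        }
        for label, per in status.items()
        for (name, tier), cs in per.items()
    ]

    # --- observational logistic models (primary cohort) --------------------
    obs_rows = []
    exposure_z = (cohort.exposure - cohort.exposure.mean()) / cohort.exposure.std()
    for name in config.conditions:
        for tier in config.tiers:
            y = status[primary][(name, tier)].status
            if y.sum() == 0:
                continue
            fit = logistic_fit(
                y,
                np.column_stack(
                    [np.ones(cohort.n), exposure_z, cohort.age, cohort.sex]
                ),
                ["intercept", "exposure", "age", "sex"],
            )
            b = fit.coefficients["exposure"]
            s = fit.standard_errors["exposure"]
            obs_rows.append(
                {
                    "condition": name,
                    "tier": tier,
                    "analysis": "observational",
                    "or": float(np.exp(b)),
                    "ci_low": float(np.exp(b - Z95 * s)),
                    "ci_high": float(np.exp(b + Z95 * s)),
                    "p": fit.wald_p("exposure"),
                    "n_cases": int(y.sum()),
                }
            )

    # --- one-sample MR (primary cohort) -------------------------------------
    onesample_rows = []
    for name in config.conditions:
        for mode in config.one_sample_modes:
            cs = status[primary][(name, config.mr_tier)]
            row = {"condition": name, "tier": config.mr_tier, "mode": mode}
            try:
                est = run_one_sample_mr(cohort, instr, cs, mode=mode)
            except FitError as exc:
                # the linear-probability OR conversion is undefined when the
                # risk difference exceeds a rare condition's baseline risk;
                # record the degeneracy instead of aborting the run
                row.update(
                    {"or": float("nan"), "ci_low": float("nan"),
                     "ci_high": float("nan"), "p": float("nan"),
                     "n_instruments": 0, "F": float("nan"),
                     "scale": "", "note": str(exc)}
                )
            else:
                row.update(
                    {
                        "or": est.or_,
                        "ci_low": est.or_ci_low,
                        "ci_high": est.or_ci_high,
                        "p": est.p,
                        "n_instruments": est.n_instruments,
                        "F": est.diagnostics["F"],
                        "scale": est.scale,
                        "note": "",
                    }
                )
            onesample_rows.append(row)

    # --- per-variant scans + two-sample MR per cohort -----------------------
    exposure_side = instr.table.rename(columns={"weight": "beta"})
    gwas_tables: dict[str, pd.DataFrame] = {}
    twosample_rows = []
    per_cohort_ivw: dict[str, dict[str, MetaInput]] = {n: {} for n in config.conditions}
    method_runs = {
        "IVW": lambda s: ivw(s),
        "MR-Egger": lambda s: egger(s),
        "WM": lambda s: weighted_median(s, penalized=False, seed=stage_seed(config.seed, "wm")),
        "PWM": lambda s: weighted_median(s, penalized=True, seed=stage_seed(config.seed, "pwm")),
    }
    for label, c in cohorts.items():
        covs = np.column_stack([c.age, c.sex])
        for name in config.conditions:
            y = status[label][(name, config.mr_tier)].status
            scan = per_variant_association(
                c.genotypes, y, covs, variant_ids=c.coding["id"]
            )
            scan = scan.merge(
                c.coding.rename(
                    columns={"counted_allele": "effect_allele"}
                )[["id", "effect_allele", "other_allele", "eaf"]],
                on="id",
            )
            gwas_tables[f"gwas_{label}_{name}"] = scan[
                ["id", "effect_allele", "other_allele", "beta", "se", "n", "eaf"]
            ]
            stats, excl = make_summary_stats(exposure_side, scan)
            for method in config.two_sample_methods:
                est = method_runs[method](stats)
                row = {
                    "cohort": label,
                    "condition": name,
                    "method": est.method,
                    "beta": est.beta,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "p": est.p,
                    "n_instruments": est.n_instruments,
                    "n_excluded": len(excl),
                }
                if est.method == "MR-Egger":
                    row["egger_intercept"] = est.diagnostics["intercept"]
                    row["egger_intercept_p"] = est.diagnostics["intercept_p"]
                twosample_rows.append(row)
                if method == "IVW":
                    per_cohort_ivw[name][label] = MetaInput(label, est.beta, est.se)

    # --- fixed-effect meta-analysis across cohorts --------------------------
    meta_rows = []
    for name, per in per_cohort_ivw.items():
        inputs = list(per.values())
        pooled, se, diag = meta_fixed(inputs)
        meta_rows.append(
            {
                "condition": name,
                "method": "IVW meta",
                "n_cohorts": len(inputs),
                "beta": pooled,
                "se": se,
                "ci_low": pooled - Z95 * se,
                "ci_high": pooled + Z95 * se,
                "cochran_q": diag.get("cochran_q", float("nan")),
                "i_squared": diag.get("i_squared", float("nan")),
                "warning": diag.get("warning", ""),
            }
        )

    # --- rare-variant carrier tests (primary cohort) -------------------------
    carrier_labels = {
        f"{name}/{tier}": status[primary][(name, tier)].status
        for name in config.conditions
        for tier in config.tiers
    }
    carrier_table = carrier_association(cohort.carrier_flag, carrier_labels)
    carrier_table = carrier_table.assign(
        condition=[lbl.split("/")[0] for lbl in carrier_table["label"]],
        tier=[lbl.split("/")[1] for lbl in carrier_table["label"]],
    )

    tables = {
        "case_counts": pd.DataFrame(case_rows),
        "observational": pd.DataFrame(obs_rows),
        "onesample_mr": pd.DataFrame(onesample_rows),
        "twosample_mr": pd.DataFrame(twosample_rows),
        "meta_analysis": pd.DataFrame(meta_rows),
        "carrier_tests": carrier_table,
        **gwas_tables,
    }
    tables["forest"] = render_forest_table(tables)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            s: stage_seed(config.seed, s)
            for s in ["variants", "instruments", "wm", "pwm"]
            + [f"cohort:{l}" for l in config.cohorts]
            + [f"records:{l}" for l in config.cohorts]
        },
        "config": config.to_dict(),
        "n_after_kinship_pruning": {l: int(c.n) for l, c in cohorts.items()},
        "case_counts": {
            f"{label}:{name}:{tier}": int(cs.n_cases)
            for label, per in status.items()
            for (name, tier), cs in per.items()
        },
    }
    result = StudyResult(tables=tables, manifest=manifest)
    if write is None:
        write = config.output_dir is not None
    if write:
        if not config.output_dir:
            raise ValueError("write requested but config.output_dir is not set")
        result.write(config.output_dir)
    return result


def render_forest_table(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Plot-ready rows (analysis, condition, OR, ci_low, ci_high) in figure order."""
    rows = []
    obs = tables.get("observational", pd.DataFrame())
    for r in obs.to_dict("records"):
        if r["tier"] != "specific":
            continue
        rows.append(("observational", r["condition"], r["or"], r["ci_low"], r["ci_high"]))
    one = tables.get("onesample_mr", pd.DataFrame())
    for r in one.to_dict("records"):
        rows.append((f"one-sample MR ({r['mode']})", r["condition"], r["or"], r["ci_low"], r["ci_high"]))
    meta = tables.get("meta_analysis", pd.DataFrame())
    for r in meta.to_dict("records"):
        rows.append(
            (
                "two-sample IVW meta",
                r["condition"],
                float(np.exp(r["beta"])),
                float(np.exp(r["ci_low"])),
                float(np.exp(r["ci_high"])),
            )
        )
    return pd.DataFrame(rows, columns=["analysis", "condition", "or", "ci_low", "ci_high"])
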