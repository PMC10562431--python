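"""Seeded synthetic-data generators for every stage of the trial pipeline.

The generators emulate the study conditions end to end: raw DTC genotype
exports drawn under Hardy-Weinberg proportions, a screening cohort with the
trial's demographic structure (age 54.4 SD 13.2 y truncated to 18-75; BMI
34.9 SD 5.1 truncated to the 27.0-47.5 eligibility window; 84% women; race
probabilities 0.68/0.295/0.025), a weight-change outcome with individual-level
SD 2.8 kg and ~11% attrition, and per-week macronutrient adherence around the
arm targets.

All generators are pure functions of (config, seed): identical inputs give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import Assignment, DietArm, Participant, Sex, is_concordant
from .genotype_io import Dialect, GenotypeRecord, GenotypeTable, write_dtc_table
from .scoring import ResponderClass, ScoreTable, class_probabilities

__all__ = [
    "DemographicsConfig",
    "OutcomeConfig",
    "AdherenceConfig",
    "SimulationConfig",
    "TrialDataset",
    "generate_genotype_tables",
    "generate_genotype_files",
    "generate_cohort",
    "simulate_outcomes",
    "simulate_adherence",
    "calibrate_allele_frequencies",
    "DEFAULT_ALLELE_FREQS",
]


@dataclass(frozen=True)
class DemographicsConfig:
    """Marginals of the screening cohort (defaults mirror the trial table)."""

    age_mean: float = 54.4
    age_sd: float = 13.2
    age_bounds: tuple[float, float] = (18.0, 75.0)
    bmi_mean: float = 34.9
    bmi_sd: float = 5.1
    bmi_bounds: tuple[float, float] = (27.0, 47.5)
    female_fraction: float = 0.84
    race_labels: tuple[str, ...] = ("white", "black", "other")
    race_probs: tuple[float, ...] = (0.68, 0.295, 0.025)
    height_mean: dict = field(default_factory=lambda: {"female": 162.0, "male": 176.0})
    height_sd: float = 6.5
    # fasting labs: log-normal marginals (median, GSD on the natural scale)
    glucose_median: float = 95.0  # mg/dL
    glucose_gsd: float = 1.10
    insulin_median: float = 12.0  # uU/mL
    insulin_gsd: float = 1.55


@dataclass(frozen=True)
class OutcomeConfig:
    """Linear model for 12-week change scores.

    ``residual_sd`` is the individual-level SD of the weight-change score
    (2.8 kg, the value the trial's power analysis assumed); the published
    group-level dispersion figures are treated as standard errors.  Setting
    ``sd_interpretation="group_se"`` instead rescales so that the group-level
    SE at the realised arm sizes matches ``residual_sd``.
    """

    mu_change: float = -4.8  # kg, mean change on a discordant diet
    concordance_effect: float = -0.6  # kg, added change when diet matches genotype
    residual_sd: float = 2.8  # kg
    attrition_prob: float = 0.11
    sd_interpretation: str = "individual"  # or "group_se"
    informative_attrition_beta: float = 0.0  # logit slope on weight change
    # secondary outcomes: mean change (concordance effect, residual sd)
    bodyfat_mu: float = -1.0
    bodyfat_effect: float = -0.5
    bodyfat_sd: float = 4.0
    sbp_mu: float = -1.0
    sbp_effect: float = 2.0
    sbp_sd: float = 11.0
    dbp_mu: float = 0.5
    dbp_effect: float = 0.0
    dbp_sd: float = 7.0
    craving_mu: float = -0.3
    craving_effect: float = 0.1
    craving_sd: float = 0.8


# Arm/week adherence means and SDs (% energy), as reported at weeks 4/8/12.
_HC_ADHERENCE = {
    4: {"carb": (63.4, 2.3), "fat": (20.9, 2.4), "protein": (16.0, 1.0)},
    8: {"carb": (63.3, 2.8), "fat": (20.5, 1.7), "protein": (15.9, 1.0)},
    12: {"carb": (62.7, 4.0), "fat": (20.5, 2.5), "protein": (15.7, 1.8)},
}
_HF_ADHERENCE = {
    4: {"carb": (45.4, 2.2), "fat": (39.4, 2.0), "protein": (15.8, 1.2)},
    8: {"carb": (44.7, 2.2), "fat": (40.5, 2.1), "protein": (15.7, 2.3)},
    12: {"carb": (44.5, 3.4), "fat": (39.9, 2.5), "protein": (16.1, 3.3)},
}


@dataclass(frozen=True)
class AdherenceConfig:
    """Per-arm, per-week Normal means/SDs for reported macro percentages."""

    high_carb: Mapping[int, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: _HC_ADHERENCE
    )
    high_fat: Mapping[int, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: _HF_ADHERENCE
    )

    def params(self, arm: DietArm, week: int) -> Mapping[str, tuple[float, float]]:
        table = self.high_carb if DietArm(arm) is DietArm.HIGH_CARB else self.high_fat
        return table[week]


#: Effect-allele frequencies for the shipped synthetic 10-SNP score table,
#: calibrated (scipy least-squares on the exact class-probability map) so the
#: four-way classification split is ~0.41 fat / 0.20 carb / 0.39 both+neither.
DEFAULT_ALLELE_FREQS: dict[str, float] = {
    # fat-axis loci
    "rs838147": 0.4043384375,
    "rs662799": 0.4043384375,
    "rs894160": 0.4043384375,
    "rs5082": 0.4043384375,
    # carbohydrate-axis loci
    "rs12255372": 0.3561738398,
    "rs2943641": 0.3561738398,
    "rs10423928": 0.3561738398,
    # antagonistic loci
    "rs9939609": 0.5736499705,
    "rs1801282": 0.5736499705,
    "rs1478290": 0.5736499705,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generators need, in one seedable bundle."""

    n_screened: int = 275
    allele_freqs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ALLELE_FREQS))
    missing_call_rate: float = 0.0
    pre_randomization_dropout: float = 24.0 / 169.0  # lost between screening and baseline
    demographics: DemographicsConfig = field(default_factory=DemographicsConfig)
    outcome_model: OutcomeConfig = field(default_factory=OutcomeConfig)
    adherence_model: AdherenceConfig = field(default_factory=AdherenceConfig)

    def __post_init__(self) -> None:
        if not 0 <= self.missing_call_rate <= 1:
            raise ValueError("missing_call_rate must be in [0,1]")
        for rsid, p in self.allele_freqs.items():
            if not 0 < p <= 1:
                raise ValueError(f"{rsid}: allele frequency must be in (0,1], got {p}")


@dataclass
class TrialDataset:
    """Per-subject baseline data, assignments and week-12 change scores.

    ``data`` has one row per randomized subject with baseline covariates, arm,
    concordance, completion flag and change scores (NaN for non-completers).
    """

    data: pd.DataFrame
    seed: int | None = None

    @property
    def completers(self) -> pd.DataFrame:
        return self.data[self.data["completed"]]


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b), size=n)
    return mean + sd * stats.norm.ppf(u)


def generate_genotype_tables(
    n: int, cfg: SimulationConfig, table: ScoreTable, seed: int
) -> list[GenotypeTable]:
    """Draw per-subject panel genotypes under Hardy-Weinberg proportions.

    Genotypes are generated directly in the locus reference orientation;
    missing calls are injected at ``cfg.missing_call_rate`` per SNP.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        t = GenotypeTable(subject_id=f"S{i:04d}", source_dialect=None)
        for snp in table.panel:
            p = cfg.allele_freqs[snp.rsid]
            if cfg.missing_call_rate and rng.random() < cfg.missing_call_rate:
                t.add(GenotypeRecord(snp.rsid, None))
                continue
            k = rng.binomial(2, p)  # copies of the first-listed allele
            alleles = [snp.alleles[0]] * k + [snp.alleles[1]] * (2 - k)
            t.add(GenotypeRecord(snp.rsid, frozenset(alleles)))
        out.append(t)
    return out


def generate_genotype_files(
    n: int,
    cfg: SimulationConfig,
    table: ScoreTable,
    seed: int,
    dialect: Dialect = Dialect.TWENTYTHREE_AND_ME,
) -> dict[str, str]:
    """Serialise generated genotype tables as raw DTC export text.

    Returns subject_id -> file content; byte-identical for identical
    (cfg, seed, dialect).
    """
    positions = {s.rsid: (s.chromosome, "0") for s in table.panel}
    return {
        t.subject_id: write_dtc_table(t, dialect, positions)
        for t in generate_genotype_tables(n, cfg, table, seed)
    }


def generate_cohort(n: int, cfg: SimulationConfig, seed: int) -> pd.DataFrame:
    """Draw demographics, anthropometrics and fasting labs for n subjects.

    BMI is truncated-normal on the eligibility window; height is drawn per
    sex and weight derived so BMI is internally consistent.
    """
    rng = np.random.default_rng(seed)
    d = cfg.demographics
    if n == 0:
        return pd.DataFrame(
            columns=[
                "subject_id", "sex", "race", "age", "height", "weight", "bmi",
                "fasting_glucose", "fasting_insulin",
            ]
        )
    sex = np.where(rng.random(n) < d.female_fraction, Sex.FEMALE.value, Sex.MALE.value)
    race = rng.choice(d.race_labels, size=n, p=d.race_probs)
    age = _truncated_normal(rng, d.age_mean, d.age_sd, *d.age_bounds, n)
    bmi = _truncated_normal(rng, d.bmi_mean, d.bmi_sd, *d.bmi_bounds, n)
    height = np.array([rng.normal(d.height_mean[s], d.height_sd) for s in sex])
    weight = bmi * (height / 100.0) ** 2
    glucose = d.glucose_median * np.exp(rng.normal(0, np.log(d.glucose_gsd), n))
    insulin = d.insulin_median * np.exp(rng.normal(0, np.log(d.insulin_gsd), n))
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "sex": sex,
            "race": race,
            "age": np.round(age, 1),
            "height": np.round(height, 1),
            "weight": np.round(weight, 1),
            "bmi": np.round(bmi, 2),
            "fasting_glucose": np.round(glucose, 1),
            "fasting_insulin": np.round(insulin, 2),
        }
    )


def cohort_to_participants(
    cohort: pd.DataFrame, classes: Mapping[str, ResponderClass]
) -> list[Participant]:
    """Join demographics with responder classes into Participant objects."""
    out = []
    for row in cohort.itertuples(index=False):
        out.append(
            Participant(
                subject_id=row.subject_id,
                sex=Sex(row.sex),
                race=row.race,
                age=row.age,
                weight=row.weight,
                height=row.height,
                bmi=row.bmi,
                responder_class=ResponderClass(classes[row.subject_id]),
                fasting_glucose=row.fasting_glucose,
                fasting_insulin=row.fasting_insulin,
            )
        )
    return out


def simulate_outcomes(
    cohort: pd.DataFrame,
    assignments: Sequence[Assignment],
    cfg: SimulationConfig,
    seed: int,
    responder_classes: Mapping[str, str] | None = None,
) -> TrialDataset:
    """Generate week-12 change scores and completion flags.

    weight_change = mu + effect * 1[concordant] + eps,  eps ~ N(0, sd^2);
    attrition is Bernoulli and non-informative unless an informative slope is
    configured.  Non-completers have missing (NaN) outcomes.
    """
    rng = np.random.default_rng(seed)
    oc = cfg.outcome_model
    amap = {a.subject_id: a for a in assignments}
    rows = cohort[cohort["subject_id"].isin(amap)].reset_index(drop=True).copy()
    n = len(rows)
    conc = np.array([amap[s].concordant for s in rows["subject_id"]], dtype=float)
    sd = oc.residual_sd
    if oc.sd_interpretation == "group_se":
        sd = oc.residual_sd * np.sqrt(max(n, 2) / 2.0)
    eps = rng.normal(0.0, sd, n)
    weight_change = oc.mu_change + oc.concordance_effect * conc + eps
    bodyfat_change = oc.bodyfat_mu + oc.bodyfat_effect * conc + rng.normal(0, oc.bodyfat_sd, n)
    sbp_change = oc.sbp_mu + oc.sbp_effect * conc + rng.normal(0, oc.sbp_sd, n)
    dbp_change = oc.dbp_mu + oc.dbp_effect * conc + rng.normal(0, oc.dbp_sd, n)
    craving_change = oc.craving_mu + oc.craving_effect * conc + rng.normal(0, oc.craving_sd, n)

    logit = stats.norm.ppf(np.clip(oc.attrition_prob, 1e-9, 1 - 1e-9))
    drop_score = logit + oc.informative_attrition_beta * (weight_change - oc.mu_change)
    completed = rng.random(n) >= stats.norm.cdf(drop_score)

    rows["arm"] = [amap[s].arm.value for s in rows["subject_id"]]
    rows["concordant"] = conc.astype(bool)
    rows["energy_tier"] = [amap[s].energy_tier for s in rows["subject_id"]]
    if responder_classes is not None:
        rows["responder_class"] = [responder_classes[s] for s in rows["subject_id"]]
    rows["completed"] = completed
    for name, values in [
        ("weight_change", weight_change),
        ("bodyfat_change", bodyfat_change),
        ("sbp_change", sbp_change),
        ("dbp_change", dbp_change),
        ("craving_change", craving_change),
    ]:
        col = np.where(completed, values, np.nan)
        rows[name] = col
    rows["pct_weight_change"] = 100.0 * rows["weight_change"] / rows["weight"]
    return TrialDataset(data=rows, seed=seed)


def simulate_adherence(
    assignments: Sequence[Assignment],
    cfg: SimulationConfig,
    seed: int,
    weeks: Sequence[int] = (4, 8, 12),
) -> pd.DataFrame:
    """Per-subject, per-week reported macro percentages.

    Carbohydrate and fat percentages are drawn from the configured arm/week
    Normals; protein is the residual 100 - carb - fat, so every record sums to
    100 exactly and the carb/fat means match the configured values.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for a in assignments:
        for week in weeks:
            params = cfg.adherence_model.params(a.arm, week)
            carb = rng.normal(*params["carb"])
            fat = rng.normal(*params["fat"])
            rows.append(
                {
                    "subject_id": a.subject_id,
                    "arm": a.arm.value,
                    "week": week,
                    "carb_pct": carb,
                    "fat_pct": fat,
                    "protein_pct": 100.0 - carb - fat,
                }
            )
    return pd.DataFrame(rows)


def calibrate_allele_frequencies(
    table: ScoreTable,
    target_fat: float = 112 / 275,
    target_carb: float = 57 / 275,
    groups: Mapping[str, Sequence[str]] | None = None,
    x0: Sequence[float] | None = None,
) -> dict[str, float]:
    """Tune effect-allele frequencies so the exact class probabilities match a
    target (fat, carb) responder split.

    Frequencies are tied within ``groups`` (rsid lists sharing one free
    frequency); by default every SNP is its own group.  Uses bounded
    least-squares on the exact class-probability map (no sampling noise).
    """
    if groups is None:
        groups = {s.rsid: [s.rsid] for s in table.panel}
    names = list(groups)

    def freqs_from(x: np.ndarray) -> dict[str, float]:
        f = {}
        for name, xi in zip(names, x):
            for rsid in groups[name]:
                f[rsid] = float(xi)
        return f

    def residual(x: np.ndarray) -> np.ndarray:
        probs = class_probabilities(freqs_from(x), table)
        return np.array(
            [
                probs[ResponderClass.FAT_RESPONDER] - target_fat,
                probs[ResponderClass.CARB_RESPONDER] - target_carb,
            ]
        )

    if x0 is None:
        # spread the start to break the symmetric saddle of mirrored tables
        x0 = np.linspace(0.35, 0.65, len(names))
    else:
        x0 = np.asarray(x0, dtype=float)
    sol = optimize.least_squares(residual, x0, bounds=(0.02, 0.98), xtol=1e-12, ftol=1e-12)
    if not sol.success or np.linalg.norm(sol.fun) > 5e-3:
        raise RuntimeError(
            f"calibration failed: residual {sol.fun} with frequencies {freqs_from(sol.x)}"
        )
    return freqs_from(sol.x)
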