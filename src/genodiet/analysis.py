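"""Statistical analysis of the trial: baseline-adjusted treatment effects,
insulin/HOMA-IR association models, Holm step-down multiplicity adjustment,
adherence summaries and participant-flow accounting.

The core is :class:`TreatmentEffectModel`, a statsmodels-style model object:
construct it from a tidy DataFrame (or a simulated :class:`TrialDataset`),
call :meth:`~TreatmentEffectModel.fit`, and read estimates, t-based 95%
confidence intervals, p-values and a text summary off the returned
:class:`TreatmentEffectResults`.

The default fit is ANCOVA on the change score — a linear model of the
12-week change on group plus sex, race and the baseline value of the outcome.
For a pre/post design with a single follow-up this is the standard
change-score equivalent of a two-timepoint mixed model; a random-intercept
longitudinal variant is available via ``fit(method="mixed")``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "EffectEstimate",
    "HolmResult",
    "TreatmentEffectModel",
    "TreatmentEffectResults",
    "homa_ir",
    "adjusted_difference",
    "holm_adjust",
    "insulin_association",
    "summarize_adherence",
    "consort_accounting",
]


def homa_ir(glucose, insulin, denominator: float = 405.0):
    """Homeostatic model assessment of insulin resistance.

    ``(glucose [mg/dL] x insulin [uU/mL]) / 405``; pass ``denominator=22.5``
    for molar glucose (mmol/L).  Bilinear and vectorised; negative inputs are
    a domain error.
    """
    g = np.asarray(glucose, dtype=float)
    i = np.asarray(insulin, dtype=float)
    if np.any(g < 0) or np.any(i < 0):
        raise ValueError("glucose and insulin must be non-negative")
    out = g * i / denominator
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EffectEstimate:
    """A fitted contrast: point estimate, 95% CI, p-value and metadata."""

    contrast: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    covariates: tuple[str, ...]
    n_used: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence interval does not bracket the estimate")


@dataclass(frozen=True)
class HolmResult:
    """Raw and Holm-Bonferroni step-down adjusted p-values, in input order."""

    raw_p: tuple[float, ...]
    adjusted_p: tuple[float, ...]
    family_label: str = ""


class TreatmentEffectModel:
    """ANCOVA-style model of a change score on group and covariates.

    Parameters
    ----------
    data
        Tidy DataFrame, one row per subject.  Rows with a missing outcome are
        dropped (complete-case analysis).
    outcome
        Column holding the change score.
    group
        Column holding the two-level contrast (bool or two labels).  The
        reported effect is level-of-interest minus reference.
    covariates
        Categorical/numeric adjustment columns (default sex and race).
        Covariates constant in the analysis set are dropped with a warning.
    baseline
        Column holding the baseline value of the outcome, entered as a
        numeric covariate; ``None`` omits it.
    reference
        Group level to treat as the reference; defaults to the
        lexicographically first level (``False`` for boolean contrasts).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        group: str,
        covariates: Sequence[str] = ("sex", "race"),
        baseline: str | None = None,
        reference=None,
    ) -> None:
        work = data.dropna(subset=[outcome]).copy()
        if work.empty:
            raise ValueError(f"no non-missing values of outcome {outcome!r}")
        levels = sorted(work[group].unique(), key=str)
        if len(levels) != 2:
            raise ValueError(f"group column {group!r} must have exactly 2 levels, got {levels}")
        if any((work[group] == lv).sum() < 2 for lv in levels):
            raise ValueError("each group level needs at least 2 subjects with outcomes")
        self.reference = levels[0] if reference is None else reference
        self.interest = [lv for lv in levels if lv != self.reference][0]
        kept, dropped = [], []
        for cov in covariates:
            if work[cov].nunique(dropna=True) < 2:
                dropped.append(cov)
            else:
                kept.append(cov)
        if dropped:
            warnings.warn(f"dropping constant covariate(s): {', '.join(dropped)}")
        self.data = work
        self.outcome = outcome
        self.group = group
        self.covariates = tuple(kept)
        self.dropped_covariates = tuple(dropped)
        self.baseline = baseline

    @classmethod
    def from_dataset(cls, dataset, outcome: str = "weight_change", **kwargs):
        """Build from a simulated :class:`~genodiet.simulate.TrialDataset`,
        contrasting genotype-concordant vs discordant diet."""
        kwargs.setdefault("group", "concordant")
        kwargs.setdefault("baseline", "weight" if outcome.endswith("weight_change") else None)
        return cls(dataset.data, outcome=outcome, **kwargs)

    def _formula(self, extra: str = "") -> str:
        terms = [f"C({self.group}, Treatment(reference={self.reference!r}))"]
        for cov in self.covariates:
            if pd.api.types.is_numeric_dtype(self.data[cov]) and not pd.api.types.is_bool_dtype(
                self.data[cov]
            ):
                terms.append(cov)
            else:
                terms.append(f"C({cov})")
        if self.baseline:
            terms.append(self.baseline)
        if extra:
            terms.append(extra)
        return f"{self.outcome} ~ " + " + ".join(terms)

    def fit(self, method: str = "ancova") -> "TreatmentEffectResults":
        """Fit by ANCOVA on the change score (default) or a two-timepoint
        random-intercept mixed model (``method="mixed"``)."""
        if method == "ancova":
            return self._fit_ancova()
        if method == "mixed":
            return self._fit_mixed()
        raise ValueError(f"unknown method {method!r}")

    def _group_term(self) -> str:
        return (
            f"C({self.group}, Treatment(reference={self.reference!r}))"
            f"[T.{self.interest}]"
        )

    def _fit_ancova(self) -> "TreatmentEffectResults":
        res = smf.ols(self._formula(), data=self.data).fit()
        term = self._group_term()
        est = float(res.params[term])
        degenerate = res.ssr <= 1e-12 or not np.isfinite(res.bse[term])
        if degenerate:
            return TreatmentEffectResults(
                model=self,
                effect=EffectEstimate(
                    contrast=f"{self.interest} - {self.reference}",
                    estimate=est,
                    ci_low=est,
                    ci_high=est,
                    p_value=1.0,
                    covariates=self._covariate_labels(),
                    n_used=int(res.nobs),
                    degenerate=True,
                ),
                sm_results=res,
            )
        ci = res.conf_int().loc[term]
        return TreatmentEffectResults(
            model=self,
            effect=EffectEstimate(
                contrast=f"{self.interest} - {self.reference}",
                estimate=est,
                ci_low=float(ci[0]),
                ci_high=float(ci[1]),
                p_value=float(res.pvalues[term]),
                covariates=self._covariate_labels(),
                n_used=int(res.nobs),
            ),
            sm_results=res,
        )

    def _fit_mixed(self) -> "TreatmentEffectResults":
        """Two-timepoint random-intercept model; the group x time coefficient
        is the adjusted difference in change."""
        if not self.baseline:
            raise ValueError("mixed fit requires a baseline column")
        d = self.data
        long = pd.concat(
            [
                d.assign(time=0, value=d[self.baseline]),
                d.assign(time=1, value=d[self.baseline] + d[self.outcome]),
            ],
            ignore_index=True,
        )
        terms = [f"C({self.group}, Treatment(reference={self.reference!r}))*time"]
        terms += [f"C({c})" if not pd.api.types.is_numeric_dtype(d[c]) else c for c in self.covariates]
        formula = "value ~ " + " + ".join(terms)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm(formula, data=long, groups=long["subject_id"]).fit(reml=True)
        term = self._group_term() + ":time"
        est = float(res.params[term])
        se = float(res.bse[term])
        z = stats.norm.ppf(0.975)
        return TreatmentEffectResults(
            model=self,
            effect=EffectEstimate(
                contrast=f"{self.interest} - {self.reference}",
                estimate=est,
                ci_low=est - z * se,
                ci_high=est + z * se,
                p_value=float(res.pvalues[term]),
                covariates=self._covariate_labels(),
                n_used=int(len(d)),
            ),
            sm_results=res,
        )

    def _covariate_labels(self) -> tuple[str, ...]:
        labels = list(self.covariates)
        if self.baseline:
            labels.append(f"baseline:{self.baseline}")
        return tuple(labels)


@dataclass
class TreatmentEffectResults:
    """Results container: the contrast estimate plus the underlying fit."""

    model: TreatmentEffectModel
    effect: EffectEstimate
    sm_results: object = field(repr=False, default=None)

    @property
    def estimate(self) -> float:
        return self.effect.estimate

    @property
    def conf_int(self) -> tuple[float, float]:
        return (self.effect.ci_low, self.effect.ci_high)

    @property
    def p_value(self) -> float:
        return self.effect.p_value

    def summary(self) -> str:
        e = self.effect
        lines = [
            "Treatment effect (baseline-adjusted change score)",
            "=" * 56,
            f"outcome:     {self.model.outcome}",
            f"contrast:    {e.contrast}",
            f"estimate:    {e.estimate:.3f}  (95% CI {e.ci_low:.3f}, {e.ci_high:.3f})",
            f"p-value:     {e.p_value:.4f}",
            f"adjusted for: {', '.join(e.covariates) if e.covariates else '(none)'}",
            f"n used:      {e.n_used} (complete case)",
        ]
        if self.model.dropped_covariates:
            lines.append(f"dropped (constant): {', '.join(self.model.dropped_covariates)}")
        if e.degenerate:
            lines.append("note: zero residual variance; degenerate fit")
        return "\n".join(lines)


def adjusted_difference(
    data: pd.DataFrame,
    outcome: str,
    group: str,
    covariates: Sequence[str] = ("sex", "race"),
    baseline: str | None = None,
    method: str = "ancova",
    reference=None,
) -> EffectEstimate:
    """One-call wrapper: fit :class:`TreatmentEffectModel` and return the
    contrast as an :class:`EffectEstimate`."""
    model = TreatmentEffectModel(
        data, outcome=outcome, group=group, covariates=covariates,
        baseline=baseline, reference=reference,
    )
    return model.fit(method=method).effect


def holm_adjust(raw_p: Sequence[float], family_label: str = "") -> HolmResult:
    """Holm-Bonferroni step-down adjusted p-values.

    Sort ascending; the i-th smallest is multiplied by (m - i + 1), a running
    maximum enforces monotonicity, values are capped at 1 and mapped back to
    input order.
    """
    p = np.asarray(list(raw_p), dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return HolmResult(raw_p=tuple(p.tolist()), adjusted_p=tuple(adj.tolist()), family_label=family_label)


def insulin_association(
    data: pd.DataFrame,
    predictor: str,
    outcome: str = "weight_change",
    covariates: Sequence[str] = ("sex", "race"),
    group: str = "arm",
) -> dict:
    """Association of a baseline lab predictor with weight change, adjusted
    for diet group and covariates, plus the diet x predictor interaction.

    Returns ``{"slope": EffectEstimate, "interaction_p": float}``.  The slope
    is the coefficient of the predictor in the main-effects model; the
    interaction p comes from adding a diet-by-predictor term.
    """
    work = data.dropna(subset=[outcome, predictor]).copy()
    if work[predictor].nunique() < 2:
        raise ValueError(f"predictor {predictor!r} has no variance")
    cov_terms = []
    for cov in covariates:
        if work[cov].nunique(dropna=True) < 2:
            warnings.warn(f"dropping constant covariate: {cov}")
            continue
        cov_terms.append(
            cov if pd.api.types.is_numeric_dtype(work[cov]) else f"C({cov})"
        )
    base = f"{outcome} ~ {predictor} + C({group})" + ("".join(" + " + t for t in cov_terms))
    main = smf.ols(base, data=work).fit()
    ci = main.conf_int().loc[predictor]
    slope = EffectEstimate(
        contrast=f"per-unit {predictor}",
        estimate=float(main.params[predictor]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(main.pvalues[predictor]),
        covariates=tuple([group, *covariates]),
        n_used=int(main.nobs),
    )
    inter = smf.ols(base + f" + C({group}):{predictor}", data=work).fit()
    inter_terms = [t for t in inter.params.index if t.endswith(f":{predictor}")]
    f_test = inter.f_test([f"{t} = 0" for t in inter_terms])
    return {"slope": slope, "interaction_p": float(f_test.pvalue)}


def summarize_adherence(records: pd.DataFrame, targets: dict | None = None) -> pd.DataFrame:
    """Arm-by-week table of mean (SD) reported macro percentages and their
    deviation from the diet target.

    ``targets`` maps arm value -> {macro: target %}; defaults to the diet-arm
    macro targets.  SD is NaN for single-record cells.
    """
    from .design import DietArm

    if targets is None:
        targets = {arm.value: arm.macro_targets for arm in DietArm}
    rows = []
    for (arm, week), grp in records.groupby(["arm", "week"]):
        for macro in ("carb", "fat", "protein"):
            vals = grp[f"{macro}_pct"]
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
            target = targets[arm][macro]
            rows.append(
                {
                    "arm": arm,
                    "week": week,
                    "macro": macro,
                    "n": len(vals),
                    "mean": mean,
                    "sd": sd,
                    "target": target,
                    "deviation": mean - target,
                }
            )
    return pd.DataFrame(rows)


def consort_accounting(
    stages: dict[str, Sequence[str]],
    class_by_subject: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Participant-flow table: ordered stages with counts and exclusions.

    ``stages`` maps stage label -> subject ids, in chain order; every stage
    must be a subset of the one before (consistency error otherwise).  If
    ``class_by_subject`` is given, responder-class fractions among the
    genotyped stage (any stage named ``"genotyped"``, else the first) are
    attached as DataFrame ``attrs["class_fractions"]``.
    """
    labels = list(stages)
    sets = {k: set(v) for k, v in stages.items()}
    for prev, cur in zip(labels, labels[1:]):
        if not sets[cur] <= sets[prev]:
            extra = sorted(sets[cur] - sets[prev])[:5]
            raise ValueError(
                f"stage {cur!r} is not nested in {prev!r} (e.g. {extra})"
            )
    rows = []
    for i, label in enumerate(labels):
        n = len(sets[label])
        excluded = len(sets[labels[i - 1]]) - n if i else 0
        rows.append({"stage": label, "n": n, "excluded_from_previous": excluded})
    out = pd.DataFrame(rows)
    if class_by_subject is not None:
        ref = "genotyped" if "genotyped" in sets else labels[0]
        ids = sets[ref]
        classes = pd.Series({s: class_by_subject[s] for s in ids if s in class_by_subject})
        out.attrs["class_fractions"] = classes.value_counts(normalize=True).to_dict()
    return out
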