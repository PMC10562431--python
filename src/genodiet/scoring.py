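"""Config-driven responder scoring: classify subjects as fat- or
carbohydrate-responders from a SNP panel.

Each panel locus assigns points on two axes — predicted responsiveness to a
high-fat hypocaloric diet and to a high-carbohydrate one — for each of its
three diploid genotypes.  A subject's axis totals are compared against
inclusive thresholds:

* ``FAT_RESPONDER``  — fat total >= fat threshold, carb total < carb threshold
* ``CARB_RESPONDER`` — carb total >= carb threshold, fat total < fat threshold
* ``BOTH`` / ``NEITHER`` — both or neither threshold met; ineligible states.

Point values and thresholds live entirely in a versioned YAML config; the
engine is table-agnostic.  The shipped 10-SNP default is a synthetic stand-in
(see ``data/score_table_10snp_synthetic.yaml``).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .genotype_io import (
    GenotypeRecord,
    GenotypeTable,
    SnpDefinition,
    extract_panel,
    normalize_alleles,
)

__all__ = [
    "ResponderClass",
    "MissingPolicy",
    "ScoreTable",
    "ResponderScore",
    "ConfigError",
    "UnscorableError",
    "load_score_table",
    "score_subject",
    "classify",
    "screen_cohort",
    "class_probabilities",
]


class ResponderClass(str, Enum):
    FAT_RESPONDER = "fat_responder"
    CARB_RESPONDER = "carb_responder"
    BOTH = "both"
    NEITHER = "neither"

    @property
    def eligible(self) -> bool:
        """Only single-axis responders are trial-eligible."""
        return self in (ResponderClass.FAT_RESPONDER, ResponderClass.CARB_RESPONDER)


class MissingPolicy(str, Enum):
    #: Missing panel SNPs contribute zero points (sensitivity analyses).
    ZERO_CONTRIBUTION = "zero_contribution"
    #: Any missing panel SNP makes the subject unscorable (screening default).
    REJECT_IF_ANY_MISSING = "reject_if_any_missing"


class ConfigError(ValueError):
    """Invalid or incomplete score-table configuration."""


class UnscorableError(ValueError):
    """Subject cannot be scored under the active missing-call policy."""


_VERSION_TAGS = {"ORIGINAL_6SNP", "UPDATED_10SNP"}


@dataclass(frozen=True)
class ScoreTable:
    """Per-genotype points on the two responsiveness axes, plus thresholds."""

    panel: tuple[SnpDefinition, ...]
    entries: Mapping[tuple[str, str], tuple[float, float]]  # (rsid, genotype) -> (fat, carb)
    fat_threshold: float
    carb_threshold: float
    version_tag: str

    def points(self, rsid: str, genotype: str) -> tuple[float, float]:
        key = (rsid, "".join(sorted(genotype)))
        if key not in self.entries:
            raise ConfigError(f"no score entry for {rsid} genotype {genotype}")
        return self.entries[key]

    def snp(self, rsid: str) -> SnpDefinition:
        for s in self.panel:
            if s.rsid == rsid:
                return s
        raise KeyError(rsid)


@dataclass(frozen=True)
class ResponderScore:
    subject_id: str
    fat_points: float
    carb_points: float
    n_missing: int


def load_score_table(source: str | Path | Mapping) -> ScoreTable:
    """Load and validate a score table from YAML (path or parsed mapping).

    The config must declare ``version_tag``, both thresholds, a ``panel`` of
    loci and per-genotype ``entries`` covering all three diploid genotypes of
    every panel locus.  Placeholder (null/non-numeric) point values are
    rejected.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = dict(source)
    try:
        tag = doc["version_tag"]
        fat_thr = float(doc["fat_threshold"])
        carb_thr = float(doc["carb_threshold"])
        panel_doc = doc["panel"]
        entries_doc = doc["entries"]
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"score-table config missing required field: {exc}") from exc
    if tag not in _VERSION_TAGS:
        raise ConfigError(f"unknown version_tag {tag!r}; expected one of {sorted(_VERSION_TAGS)}")

    panel: list[SnpDefinition] = []
    for item in panel_doc:
        panel.append(
            SnpDefinition(
                rsid=item["rsid"],
                chromosome=str(item.get("chromosome", "0")),
                alleles=tuple(item["alleles"]),
            )
        )
    if len({s.rsid for s in panel}) != len(panel):
        raise ConfigError("duplicate rsid in panel")

    entries: dict[tuple[str, str], tuple[float, float]] = {}
    for snp in panel:
        per_snp = entries_doc.get(snp.rsid)
        if per_snp is None:
            raise ConfigError(f"no score entries for panel SNP {snp.rsid}")
        for genotype in snp.genotypes():
            val = per_snp.get(genotype)
            if val is None:
                raise ConfigError(f"missing genotype entry {genotype} for {snp.rsid}")
            fat, carb = val.get("fat"), val.get("carb")
            if not isinstance(fat, (int, float)) or not isinstance(carb, (int, float)):
                raise ConfigError(
                    f"placeholder or non-numeric points for {snp.rsid} {genotype}: {val!r}"
                )
            entries[(snp.rsid, genotype)] = (float(fat), float(carb))
    return ScoreTable(
        panel=tuple(panel),
        entries=entries,
        fat_threshold=fat_thr,
        carb_threshold=carb_thr,
        version_tag=tag,
    )


def score_subject(
    panel_genotypes: Mapping[str, GenotypeRecord],
    table: ScoreTable,
    missing_policy: MissingPolicy = MissingPolicy.REJECT_IF_ANY_MISSING,
    subject_id: str = "subject",
) -> ResponderScore:
    """Sum per-SNP points over the panel.

    ``panel_genotypes`` maps rsid -> normalised :class:`GenotypeRecord` (see
    :func:`genodiet.genotype_io.normalize_alleles`).  Missing calls contribute
    zero or reject the subject depending on ``missing_policy``.
    """
    missing_policy = MissingPolicy(missing_policy)
    fat = carb = 0.0
    n_missing = 0
    for snp in table.panel:
        rec = panel_genotypes.get(snp.rsid)
        if rec is None or rec.is_missing:
            n_missing += 1
            continue
        f, c = table.points(snp.rsid, rec.genotype_string())
        fat += f
        carb += c
    if missing_policy is MissingPolicy.REJECT_IF_ANY_MISSING and n_missing > 0:
        raise UnscorableError(
            f"subject {subject_id}: {n_missing} panel SNP(s) without a call"
        )
    return ResponderScore(subject_id=subject_id, fat_points=fat, carb_points=carb, n_missing=n_missing)


def classify(score: ResponderScore, table: ScoreTable) -> ResponderClass:
    """Four-way threshold classification (inclusive thresholds).

    The four predicates partition the plane of (fat, carb) totals: exactly one
    class is returned for any finite score.
    """
    fat_hit = score.fat_points >= table.fat_threshold
    carb_hit = score.carb_points >= table.carb_threshold
    if fat_hit and carb_hit:
        return ResponderClass.BOTH
    if fat_hit:
        return ResponderClass.FAT_RESPONDER
    if carb_hit:
        return ResponderClass.CARB_RESPONDER
    return ResponderClass.NEITHER


def screen_cohort(
    tables: list[GenotypeTable],
    score_table: ScoreTable,
    missing_policy: MissingPolicy = MissingPolicy.REJECT_IF_ANY_MISSING,
) -> pd.DataFrame:
    """Score and classify a batch of genotype tables.

    Returns a DataFrame with one row per subject: fat/carb points, class,
    eligibility, missing count and an ``error`` column for subjects that were
    unscorable (the batch never aborts on a per-subject failure).  Aggregate
    fractions are available via :func:`screening_summary`.
    """
    if not tables:
        raise ValueError("empty batch")
    rows = []
    for t in tables:
        row: dict = {"subject_id": t.subject_id}
        try:
            genotypes, _ = extract_panel(t, list(score_table.panel))
            oriented: dict[str, GenotypeRecord] = {}
            for rsid, rec in genotypes.items():
                if rec.is_missing:
                    oriented[rsid] = rec
                else:
                    alleles, _, _ = normalize_alleles(rec.alleles, score_table.snp(rsid))
                    oriented[rsid] = GenotypeRecord(rsid, alleles)
            score = score_subject(oriented, score_table, missing_policy, subject_id=t.subject_id)
            cls = classify(score, score_table)
            row.update(
                fat_points=score.fat_points,
                carb_points=score.carb_points,
                n_missing=score.n_missing,
                responder_class=cls.value,
                eligible=cls.eligible,
                error="",
            )
        except (UnscorableError, ValueError) as exc:
            row.update(
                fat_points=float("nan"),
                carb_points=float("nan"),
                n_missing=pd.NA,
                responder_class="unscorable",
                eligible=False,
                error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def screening_summary(screened: pd.DataFrame) -> dict:
    """Aggregate counts and fractions per responder class from screen output."""
    n = len(screened)
    counts = screened["responder_class"].value_counts().to_dict()
    fractions = {k: v / n for k, v in counts.items()}
    return {
        "n": n,
        "counts": counts,
        "fractions": fractions,
        "n_eligible": int(screened["eligible"].sum()),
        "n_excluded": int(n - screened["eligible"].sum()),
    }


def class_probabilities(
    allele_freqs: Mapping[str, float], table: ScoreTable
) -> dict[ResponderClass, float]:
    """Exact class probabilities under Hardy-Weinberg, independent loci.

    ``allele_freqs`` maps rsid to the frequency of the *first* allele in the
    locus definition.  The joint distribution of the (fat, carb) point totals
    is built by convolving the per-SNP genotype point distributions, then the
    classification rule is applied to every support point.  Used both to
    verify the sampling generator and to calibrate frequencies to an observed
    class split.
    """
    joint: dict[tuple[float, float], float] = {(0.0, 0.0): 1.0}
    for snp in table.panel:
        p = allele_freqs[snp.rsid]
        if not 0.0 < p < 1.0:
            raise ValueError(f"{snp.rsid}: allele frequency must be in (0,1), got {p}")
        a, b = snp.alleles
        hom_a, het, hom_b = "".join(sorted(a + a)), "".join(sorted(a + b)), "".join(sorted(b + b))
        geno_probs = {hom_a: p * p, het: 2 * p * (1 - p), hom_b: (1 - p) * (1 - p)}
        new: dict[tuple[float, float], float] = {}
        for (f0, c0), w0 in joint.items():
            for g, w in geno_probs.items():
                f, c = table.points(snp.rsid, g)
                key = (round(f0 + f, 9), round(c0 + c, 9))
                new[key] = new.get(key, 0.0) + w0 * w
        joint = new
    out = {cls: 0.0 for cls in ResponderClass}
    for (f, c), w in joint.items():
        cls = classify(ResponderScore("_", f, c, 0), table)
        out[cls] += w
    return out
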