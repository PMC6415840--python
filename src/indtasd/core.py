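"""Scoring engine and validation statistics for the AIIMS-Modified-INDT-ASD tool.

The AIIMS-Modified-INDT-ASD instrument is a DSM-5 based, physician-administered
diagnostic questionnaire for autism spectrum disorder (ASD).  Section A holds
28 yes/no/unsure questions organised into seven criterion subdomains: three
social interaction/communication subdomains (A1a social-emotional reciprocity,
8 questions; A1b non-verbal communication, 4; A1c relationships, 3) and four
restricted/repetitive-behaviour subdomains (A2a stereotyped movements or
speech, 7; A2b fixed routines, 1; A2c fixed interests, 1; A2d sensory
symptoms, 4).  Section B adds two mandatory gating items: symptom onset in the
early developmental period and impairment of daily functioning.

Each question is answered by two raters (parent interview and investigator
observation).  Answers are reconciled (unsure only when both raters are
unsure; a yes-versus-no conflict is settled by the rater with per-question
precedence), flagged abnormal by per-question polarity, and aggregated:

* total score  = number of abnormal answers, 0-28;
* diagnosis    = ASD positive iff all three A1 subdomains are abnormal, at
  least 2 of the 4 A2 subdomains are abnormal, and both Section B items hold;
* severity     = total-score bands at cutoffs >=10 (ASD), >=11 (moderate),
  >=14 (severe, corresponding to CARS > 36.5).

This module is organised in the order the pipeline runs:

1. constants and configuration
2. instrument model: structure, reconciliation, scoring, decision rule
3. diagnostic accuracy: 2x2 measures with exact Clopper-Pearson intervals,
   ROC/Youden, CARS severity banding and cross-tabulation, Cohen's kappa,
   Cronbach's alpha, Pearson correlation
4. synthetic cohort simulator: seeded latent-class generative model of a
   validation study
5. tabular I/O and report rendering used by the command-line interface
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import betaincinv, expit, logit

__all__ = [
    # instrument model
    "YES", "NO", "UNSURE", "RESPONSES",
    "SUBDOMAIN_IDS", "SUBDOMAIN_QUESTION_COUNTS", "A1_IDS", "A2_IDS",
    "QuestionSpec", "SubdomainSpec", "InstrumentSpec",
    "RawAnswer", "ReconciledAnswer", "SectionBRecord",
    "SubdomainResult", "DiagnosisResult", "SeverityCutoffs",
    "InstrumentError", "load_instrument", "default_instrument",
    "reconcile_answer", "flag_abnormal", "score_subdomain", "total_score",
    "diagnose", "severity_band", "score_child", "score_cohort",
    # diagnostic accuracy
    "ConfusionTable", "EstimateWithCI", "RocPoint", "RocResult",
    "ReliabilityResult", "StatisticError",
    "confusion_from_records", "clopper_pearson",
    "sensitivity", "specificity", "ppv", "npv", "accuracy_report",
    "roc_curve", "cars_band", "CARS_BANDS", "cross_tab_severity",
    "cohens_kappa", "cronbach_alpha", "pearson_r",
    # synthetic cohort
    "CohortParams", "SimulatedChild", "SimulatedCohort",
    "default_params", "simulate_cohort", "oracle_accuracy",
    "analytic_call_probability",
    # I/O
    "read_responses", "read_section_b", "read_covariates",
    "write_score_report", "render_accuracy_text", "render_crosstab_text",
]

# ---------------------------------------------------------------------------
# 1. Constants and configuration
# ---------------------------------------------------------------------------

logger = logging.getLogger("indtasd")

YES = "yes"
NO = "no"
UNSURE = "unsure"
RESPONSES = (YES, NO, UNSURE)

#: The seven Section A subdomains, in instrument order.
SUBDOMAIN_IDS = ("A1a", "A1b", "A1c", "A2a", "A2b", "A2c", "A2d")
A1_IDS = ("A1a", "A1b", "A1c")
A2_IDS = ("A2a", "A2b", "A2c", "A2d")

#: Fixed question counts per subdomain; the instrument has 28 questions total.
SUBDOMAIN_QUESTION_COUNTS = {
    "A1a": 8, "A1b": 4, "A1c": 3, "A2a": 7, "A2b": 1, "A2c": 1, "A2d": 4,
}
TOTAL_QUESTIONS = 28

B_ITEMS = ("onset_early_development", "functional_impairment")

#: CARS total-score severity bands (band name, inclusive-lower test).
CARS_BANDS = ("non_autistic", "mild_moderate", "severe")
CARS_PLAUSIBLE_RANGE = (15.0, 60.0)

SEVERITY_LABELS = ("below_threshold", "asd_mild", "asd_moderate", "asd_severe")


class InstrumentError(ValueError):
    """Raised for malformed instrument definitions or incomplete answer sets."""


class StatisticError(ValueError):
    """Raised when a requested statistic is undefined for the given input."""


@dataclass(frozen=True)
class SeverityCutoffs:
    """Total-score cutoffs for severity bands (each read as score >= cutoff).

    Defaults: >=10 diagnoses ASD, >=11 moderate ASD, >=14 severe ASD.  The
    band labels are a reporting convention layered on these three cutoffs;
    the published analysis gives the cutoffs but does not name bands.
    """

    asd: int = 10
    moderate: int = 11
    severe: int = 14

    def __post_init__(self) -> None:
        if not (0 < self.asd <= self.moderate <= self.severe):
            raise ValueError("severity cutoffs must be positive and non-decreasing")


# ---------------------------------------------------------------------------
# 2. Instrument model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuestionSpec:
    """One Section A question: identity, polarity and rater precedence.

    ``abnormal_response`` is the yes/no answer that counts as abnormal for
    this question; ``precedence`` names the rater whose definite answer wins
    a yes-versus-no conflict between parent and investigator.
    """

    question_id: str
    subdomain_id: str
    prompt: str = ""
    abnormal_response: str = NO
    precedence: str = "investigator"

    def __post_init__(self) -> None:
        if self.abnormal_response not in (YES, NO):
            raise InstrumentError(
                f"question {self.question_id}: abnormal_response must be "
                f"'yes' or 'no', got {self.abnormal_response!r}"
            )
        if self.precedence not in ("parent", "investigator"):
            raise InstrumentError(
                f"question {self.question_id}: precedence must be 'parent' or "
                f"'investigator', got {self.precedence!r}"
            )


@dataclass(frozen=True)
class SubdomainSpec:
    subdomain_id: str
    questions: tuple[QuestionSpec, ...]
    abnormal_min_count: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        expected = SUBDOMAIN_QUESTION_COUNTS.get(self.subdomain_id)
        if expected is None:
            raise InstrumentError(f"unknown subdomain id {self.subdomain_id!r}")
        if len(self.questions) != expected:
            raise InstrumentError(
                f"subdomain {self.subdomain_id} must have {expected} questions, "
                f"got {len(self.questions)}"
            )
        if not 1 <= self.abnormal_min_count <= len(self.questions):
            raise InstrumentError(
                f"subdomain {self.subdomain_id}: abnormal_min_count "
                f"{self.abnormal_min_count} outside [1, {len(self.questions)}]"
            )

    @property
    def question_ids(self) -> tuple[str, ...]:
        return tuple(q.question_id for q in self.questions)


@dataclass(frozen=True)
class InstrumentSpec:
    """The full instrument: 7 subdomains (28 questions) plus Section B gates."""

    subdomains: tuple[SubdomainSpec, ...]
    mandatory_b_items: tuple[str, ...] = B_ITEMS
    name: str = "AIIMS-Modified-INDT-ASD"
    version: str = "1.0"

    def __post_init__(self) -> None:
        ids = tuple(sd.subdomain_id for sd in self.subdomains)
        if ids != SUBDOMAIN_IDS:
            raise InstrumentError(
                f"instrument must define subdomains {SUBDOMAIN_IDS} in order, got {ids}"
            )
        qids = [q.question_id for sd in self.subdomains for q in sd.questions]
        if len(set(qids)) != len(qids):
            dupes = sorted({q for q in qids if qids.count(q) > 1})
            raise InstrumentError(f"duplicate question ids: {dupes}")
        if len(qids) != TOTAL_QUESTIONS:
            raise InstrumentError(
                f"instrument must have {TOTAL_QUESTIONS} questions, got {len(qids)}"
            )
        if tuple(self.mandatory_b_items) != B_ITEMS:
            raise InstrumentError(f"mandatory Section B items must be {B_ITEMS}")

    @property
    def questions(self) -> tuple[QuestionSpec, ...]:
        return tuple(q for sd in self.subdomains for q in sd.questions)

    @property
    def question_ids(self) -> tuple[str, ...]:
        return tuple(q.question_id for q in self.questions)

    def question(self, question_id: str) -> QuestionSpec:
        try:
            return self._by_id[question_id]
        except KeyError:
            raise InstrumentError(f"unknown question id {question_id!r}") from None

    @property
    def _by_id(self) -> dict[str, QuestionSpec]:
        # cached lazily on the instance; frozen dataclass so go via __dict__
        cache = self.__dict__.get("_qindex")
        if cache is None:
            cache = {q.question_id: q for q in self.questions}
            self.__dict__["_qindex"] = cache
        return cache


def _require(mapping: Mapping, key: str, context: str):
    if key not in mapping:
        raise InstrumentError(f"{context}: missing field {key!r}")
    return mapping[key]


def load_instrument(source: str | Path | io.TextIOBase | Mapping) -> InstrumentSpec:
    """Load and validate an instrument definition.

    ``source`` may be a path to a YAML file, an open text stream, a YAML
    string, or an already-parsed mapping.  The definition must describe all
    seven subdomains with their fixed question counts; violations raise
    :class:`InstrumentError` naming the offending field or subdomain.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        if isinstance(source, Path):
            text = source.read_text()
        elif isinstance(source, io.TextIOBase):
            text = source.read()
        elif isinstance(source, str) and "\n" not in source and Path(source).exists():
            text = Path(source).read_text()
        else:
            text = str(source)
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise InstrumentError(f"instrument definition does not parse: {exc}") from exc
        if not isinstance(doc, Mapping):
            raise InstrumentError("instrument definition must be a mapping at top level")

    subdomains = []
    for block in _require(doc, "subdomains", "instrument"):
        sd_id = str(_require(block, "id", "subdomain block"))
        questions = []
        for q in _require(block, "questions", f"subdomain {sd_id}"):
            questions.append(
                QuestionSpec(
                    question_id=str(_require(q, "id", f"question in {sd_id}")),
                    subdomain_id=sd_id,
                    prompt=str(q.get("prompt", "")),
                    abnormal_response=str(q.get("abnormal_response", NO)).lower(),
                    precedence=str(q.get("precedence", "investigator")).lower(),
                )
            )
        subdomains.append(
            SubdomainSpec(
                subdomain_id=sd_id,
                questions=tuple(questions),
                abnormal_min_count=int(block.get("abnormal_min_count", 1)),
                label=str(block.get("label", "")),
            )
        )
    b_items = tuple(doc.get("mandatory_b_items", B_ITEMS))
    return InstrumentSpec(
        subdomains=tuple(subdomains),
        mandatory_b_items=b_items,
        name=str(doc.get("name", "AIIMS-Modified-INDT-ASD")),
        version=str(doc.get("version", "1.0")),
    )


@lru_cache(maxsize=1)
def default_instrument() -> InstrumentSpec:
    """The shipped default definition (placeholder prompts, uniform polarity)."""
    with resources.files("indtasd.data").joinpath("default_instrument.yaml").open() as fh:
        return load_instrument(fh)


@dataclass(frozen=True)
class RawAnswer:
    """Dual-rater response to one question for one child."""

    child_id: str
    question_id: str
    parent_response: str
    investigator_response: str

    def __post_init__(self) -> None:
        for r in (self.parent_response, self.investigator_response):
            if r not in RESPONSES:
                raise InstrumentError(
                    f"child {self.child_id}, question {self.question_id}: "
                    f"response must be one of {RESPONSES}, got {r!r}"
                )


@dataclass(frozen=True)
class ReconciledAnswer:
    question_id: str
    final_response: str
    is_abnormal: bool


@dataclass(frozen=True)
class SectionBRecord:
    child_id: str
    onset_early_development: bool
    functional_impairment: bool


@dataclass(frozen=True)
class SubdomainResult:
    subdomain_id: str
    abnormal_question_count: int
    is_abnormal: bool


@dataclass(frozen=True)
class DiagnosisResult:
    child_id: str
    subdomain_abnormal: dict[str, bool]
    a2_abnormal_count: int
    criteria_met_count: int
    asd_positive: bool
    total_score: int
    severity_band: str


def reconcile_answer(raw: RawAnswer, q: QuestionSpec) -> ReconciledAnswer:
    """Resolve the parent and investigator responses to one final response.

    Agreement keeps the shared value; ``unsure`` is recorded only when both
    raters are unsure; when exactly one rater is unsure the definite answer
    stands (precedence is not invoked); a definite yes-versus-no conflict is
    settled by the rater named in ``q.precedence``.
    """
    if raw.question_id != q.question_id:
        raise InstrumentError(
            f"answer for {raw.question_id!r} reconciled against question "
            f"{q.question_id!r}"
        )
    p, i = raw.parent_response, raw.investigator_response
    if p == i:
        final = p
    elif p == UNSURE:
        final = i
    elif i == UNSURE:
        final = p
    else:  # definite yes-vs-no conflict
        final = p if q.precedence == "parent" else i
    return ReconciledAnswer(q.question_id, final, flag_abnormal(final, q))


def flag_abnormal(final_response: str, q: QuestionSpec) -> bool:
    """True iff the final response equals the question's abnormal polarity.

    ``unsure`` is never abnormal and contributes nothing to the total score.
    """
    return final_response == q.abnormal_response


def _check_complete(
    answer_ids: Sequence[str], expected_ids: Sequence[str], context: str
) -> None:
    got, want = set(answer_ids), set(expected_ids)
    if len(answer_ids) != len(got):
        dupes = sorted({a for a in answer_ids if list(answer_ids).count(a) > 1})
        raise InstrumentError(f"{context}: duplicate answers for {dupes}")
    if got != want:
        missing, extra = sorted(want - got), sorted(got - want)
        parts = []
        if missing:
            parts.append(f"missing {missing}")
        if extra:
            parts.append(f"unexpected {extra}")
        raise InstrumentError(f"{context}: {'; '.join(parts)}")


def score_subdomain(
    answers: Iterable[ReconciledAnswer], sd: SubdomainSpec
) -> SubdomainResult:
    """Count abnormal answers in one subdomain and flag it abnormal.

    The subdomain is abnormal when at least ``sd.abnormal_min_count`` of its
    questions are abnormal (default 1: any abnormal question flags it).
    """
    answers = list(answers)
    _check_complete(
        [a.question_id for a in answers], sd.question_ids, f"subdomain {sd.subdomain_id}"
    )
    count = sum(a.is_abnormal for a in answers)
    return SubdomainResult(sd.subdomain_id, count, count >= sd.abnormal_min_count)


def total_score(
    answers: Iterable[ReconciledAnswer], instrument: InstrumentSpec | None = None
) -> int:
    """The child's total score: number of abnormal answers over all 28 questions."""
    instrument = instrument or default_instrument()
    answers = list(answers)
    _check_complete(
        [a.question_id for a in answers], instrument.question_ids, "total score"
    )
    return sum(a.is_abnormal for a in answers)


def diagnose(
    subdomain_results: Iterable[SubdomainResult],
    b: SectionBRecord,
    *,
    total: int = 0,
    cutoffs: SeverityCutoffs = SeverityCutoffs(),
) -> DiagnosisResult:
    """Apply the structural decision rule to seven subdomain results.

    ASD positive iff all three A1 subdomains are abnormal AND at least 2 of
    the 4 A2 subdomains are abnormal AND both mandatory Section B items hold.
    ``criteria_met_count`` counts abnormal subdomains plus satisfied B items
    (0-9); a positive call always meets at least 7 of the 9.
    """
    results = {r.subdomain_id: r for r in subdomain_results}
    _check_complete(list(results), SUBDOMAIN_IDS, "diagnosis")
    a1_count = sum(results[sd].is_abnormal for sd in A1_IDS)
    a2_count = sum(results[sd].is_abnormal for sd in A2_IDS)
    b_count = int(b.onset_early_development) + int(b.functional_impairment)
    positive = a1_count == 3 and a2_count >= 2 and b_count == 2
    return DiagnosisResult(
        child_id=b.child_id,
        subdomain_abnormal={sd: results[sd].is_abnormal for sd in SUBDOMAIN_IDS},
        a2_abnormal_count=a2_count,
        criteria_met_count=a1_count + a2_count + b_count,
        asd_positive=positive,
        total_score=total,
        severity_band=severity_band(total, cutoffs=cutoffs),
    )


def severity_band(
    score: int, *, cutoffs: SeverityCutoffs = SeverityCutoffs()
) -> str:
    """Map a total score to a severity band via the >=10 / >=11 / >=14 cutoffs.

    Scores below the ASD cutoff are ``below_threshold``; the three cutoffs
    partition the rest into mild / moderate / severe bands.
    """
    if not 0 <= score <= TOTAL_QUESTIONS:
        raise InstrumentError(f"total score {score} outside [0, {TOTAL_QUESTIONS}]")
    if score >= cutoffs.severe:
        return "asd_severe"
    if score >= cutoffs.moderate:
        return "asd_moderate"
    if score >= cutoffs.asd:
        return "asd_mild"
    return "below_threshold"


def score_child(
    raw_answers: Iterable[RawAnswer],
    b: SectionBRecord,
    instrument: InstrumentSpec | None = None,
    cutoffs: SeverityCutoffs = SeverityCutoffs(),
) -> DiagnosisResult:
    """Run the full per-child pipeline: reconcile, flag, score, diagnose."""
    instrument = instrument or default_instrument()
    raw_answers = list(raw_answers)
    _check_complete(
        [a.question_id for a in raw_answers],
        instrument.question_ids,
        f"child {b.child_id}",
    )
    reconciled = {
        a.question_id: reconcile_answer(a, instrument.question(a.question_id))
        for a in raw_answers
    }
    sd_results = [
        score_subdomain((reconciled[qid] for qid in sd.question_ids), sd)
        for sd in instrument.subdomains
    ]
    total = sum(r.is_abnormal for r in reconciled.values())
    return diagnose(sd_results, b, total=total, cutoffs=cutoffs)


def score_cohort(
    responses: pd.DataFrame,
    section_b: pd.DataFrame,
    instrument: InstrumentSpec | None = None,
    cutoffs: SeverityCutoffs = SeverityCutoffs(),
) -> pd.DataFrame:
    """Score every child in a long-format response table.

    ``responses`` columns: child_id, question_id, parent_response,
    investigator_response.  ``section_b`` columns: child_id,
    onset_early_development, functional_impairment.  Returns one row per
    child: total_score, per-subdomain flags, criteria_met_count,
    asd_positive, severity_band.  Incomplete children are a hard error.
    """
    instrument = instrument or default_instrument()
    b_by_child = {
        str(row.child_id): SectionBRecord(
            str(row.child_id),
            bool(row.onset_early_development),
            bool(row.functional_impairment),
        )
        for row in section_b.itertuples()
    }
    rows = []
    for child_id, grp in responses.groupby("child_id", sort=True):
        child_id = str(child_id)
        if child_id not in b_by_child:
            raise InstrumentError(f"child {child_id}: missing Section B record")
        raw = [
            RawAnswer(child_id, str(r.question_id),
                      str(r.parent_response).lower(), str(r.investigator_response).lower())
            for r in grp.itertuples()
        ]
        res = score_child(raw, b_by_child[child_id], instrument, cutoffs)
        row = {
            "child_id": child_id,
            "total_score": res.total_score,
            **{f"{sd}_abnormal": res.subdomain_abnormal[sd] for sd in SUBDOMAIN_IDS},
            "criteria_met_count": res.criteria_met_count,
            "asd_positive": res.asd_positive,
            "severity_band": res.severity_band,
        }
        rows.append(row)
    missing_answers = set(b_by_child) - {str(c) for c in responses["child_id"].unique()}
    if missing_answers:
        raise InstrumentError(
            f"children with Section B but no answers: {sorted(missing_answers)}"
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 3. Diagnostic accuracy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionTable:
    """2x2 table of tool call against reference diagnosis."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise StatisticError("confusion cells must be non-negative")
        if self.total == 0:
            raise StatisticError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EstimateWithCI:
    """A proportion with an exact confidence interval."""

    point: float
    lower: float
    upper: float
    level: float = 0.95
    successes: int = 0
    trials: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.lower <= self.point <= self.upper <= 1:
            raise StatisticError(
                f"interval ordering violated: {self.lower}, {self.point}, {self.upper}"
            )

    def as_percent(self, decimals: int = 2) -> tuple[float, float, float]:
        """Point and bounds on the percentage scale, half-up rounding."""
        return tuple(_round_half_up(100 * v, decimals)
                     for v in (self.point, self.lower, self.upper))


def _round_half_up(x: float, decimals: int) -> float:
    factor = 10 ** decimals
    return math.floor(x * factor + 0.5) / factor


def confusion_from_records(
    tool_calls: Mapping[str, bool] | pd.Series,
    reference: Mapping[str, bool] | pd.Series,
) -> ConfusionTable:
    """Cross-tabulate per-child tool calls against the reference diagnosis."""
    tool = pd.Series(dict(tool_calls)) if not isinstance(tool_calls, pd.Series) else tool_calls
    ref = pd.Series(dict(reference)) if not isinstance(reference, pd.Series) else reference
    if len(tool) == 0 or len(ref) == 0:
        raise StatisticError("empty input")
    if set(tool.index) != set(ref.index):
        raise StatisticError("tool calls and reference cover different children")
    ref = ref.reindex(tool.index)
    t = tool.astype(bool).to_numpy()
    r = ref.astype(bool).to_numpy()
    return ConfusionTable(
        tp=int((t & r).sum()),
        fp=int((t & ~r).sum()),
        fn=int((~t & r).sum()),
        tn=int((~t & ~r).sum()),
    )


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> EstimateWithCI:
    """Exact (Clopper-Pearson) binomial confidence interval for a proportion.

    The bounds are beta-distribution quantiles: lower = Beta(x, n-x+1)
    quantile at alpha/2 (0 when x = 0), upper = Beta(x+1, n-x) quantile at
    1-alpha/2 (1 when x = n).
    """
    if not 0 < level < 1:
        raise StatisticError(f"confidence level must be in (0,1), got {level}")
    if trials < 1 or not 0 <= successes <= trials:
        raise StatisticError(f"invalid counts: {successes}/{trials}")
    alpha = 1.0 - level
    x, n = successes, trials
    lower = 0.0 if x == 0 else float(betaincinv(x, n - x + 1, alpha / 2))
    upper = 1.0 if x == n else float(betaincinv(x + 1, n - x, 1 - alpha / 2))
    return EstimateWithCI(x / n, lower, upper, level, successes=x, trials=n)


def _proportion_measure(
    name: str, num: int, den: int, level: float
) -> EstimateWithCI:
    if den == 0:
        raise StatisticError(f"{name} undefined: zero denominator")
    return clopper_pearson(num, den, level)


def sensitivity(ct: ConfusionTable, level: float = 0.95) -> EstimateWithCI:
    """TP / (TP + FN) with exact CI."""
    return _proportion_measure("sensitivity", ct.tp, ct.tp + ct.fn, level)


def specificity(ct: ConfusionTable, level: float = 0.95) -> EstimateWithCI:
    """TN / (TN + FP) with exact CI."""
    return _proportion_measure("specificity", ct.tn, ct.tn + ct.fp, level)


def ppv(ct: ConfusionTable, level: float = 0.95) -> EstimateWithCI:
    """Positive predictive value TP / (TP + FP) with exact CI."""
    return _proportion_measure("ppv", ct.tp, ct.tp + ct.fp, level)


def npv(ct: ConfusionTable, level: float = 0.95) -> EstimateWithCI:
    """Negative predictive value TN / (TN + FN) with exact CI."""
    return _proportion_measure("npv", ct.tn, ct.tn + ct.fn, level)


def accuracy_report(ct: ConfusionTable, level: float = 0.95) -> pd.DataFrame:
    """All four accuracy measures as a tidy table (measure, point, lower, upper)."""
    rows = []
    for name, fn_ in (("sensitivity", sensitivity), ("specificity", specificity),
                      ("ppv", ppv), ("npv", npv)):
        est = fn_(ct, level)
        rows.append({
            "measure": name, "point": est.point, "lower": est.lower,
            "upper": est.upper, "level": level,
            "n_num": est.successes, "n_den": est.trials,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RocPoint:
    cutoff: float
    tpr: float
    fpr: float


@dataclass(frozen=True)
class RocResult:
    """ROC over the rule positive <=> score >= cutoff, with Youden-optimal cutoff."""

    points: tuple[RocPoint, ...]
    auc: float
    youden_cutoff: float
    youden_j: float


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """ROC curve, trapezoidal AUC and Youden-index cutoff for score >= cutoff.

    One operating point per distinct observed score plus a sentinel above the
    maximum (no positives called).  The AUC equals the tie-corrected
    concordance probability; Youden ties break toward the smallest cutoff,
    which favours sensitivity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise StatisticError("scores and labels must be equal-length 1-D sequences")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise StatisticError("AUC undefined: both classes must be represented")
    cutoffs = np.concatenate([np.unique(s), [s.max() + 1.0]])
    tpr = np.array([(s[y] >= c).mean() for c in cutoffs])
    fpr = np.array([(s[~y] >= c).mean() for c in cutoffs])
    # integrate TPR over FPR; points run from (1,1) at the lowest cutoff
    # down to (0,0) at the sentinel
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    j = tpr - fpr
    best = int(np.argmax(j))  # argmax takes the first (smallest) cutoff on ties
    points = tuple(RocPoint(float(c), float(t), float(f))
                   for c, t, f in zip(cutoffs, tpr, fpr))
    return RocResult(points, auc, float(cutoffs[best]), float(j[best]))


def cars_band(cars_score: float) -> str:
    """Band a CARS total score: <30 non-autistic, 30-36.5 mild-moderate, >36.5 severe.

    Scores outside the plausible instrument range (15-60) are banded anyway
    with a warning.
    """
    lo, hi = CARS_PLAUSIBLE_RANGE
    if not lo <= cars_score <= hi:
        logger.warning("CARS score %.1f outside plausible range [%g, %g]",
                       cars_score, lo, hi)
    if cars_score < 30:
        return "non_autistic"
    if cars_score <= 36.5:
        return "mild_moderate"
    return "severe"


def cross_tab_severity(
    tool_calls: Mapping[str, bool] | pd.Series,
    cars_scores: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """Tool-positive/negative counts and row percentages per CARS band.

    Children without a CARS score are excluded (logged with a count).  Row
    percentages use half-up rounding to one decimal; empty bands render as NA.
    """
    tool = pd.Series(dict(tool_calls)) if not isinstance(tool_calls, pd.Series) else tool_calls
    cars = pd.Series(dict(cars_scores)) if not isinstance(cars_scores, pd.Series) else cars_scores
    cars = cars.reindex(tool.index)
    missing = int(cars.isna().sum())
    if missing:
        logger.warning("cross_tab_severity: excluded %d children without CARS", missing)
    keep = cars.notna()
    tool, cars = tool[keep].astype(bool), cars[keep].astype(float)
    bands = cars.map(cars_band)
    rows = []
    for band in CARS_BANDS:
        in_band = bands == band
        n = int(in_band.sum())
        pos = int((tool & in_band).sum())
        neg = n - pos
        rows.append({
            "cars_band": band, "n": n,
            "tool_positive": pos, "tool_negative": neg,
            "pct_positive": _round_half_up(100 * pos / n, 1) if n else float("nan"),
            "pct_negative": _round_half_up(100 * neg / n, 1) if n else float("nan"),
        })
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = missing
    return out


@dataclass(frozen=True)
class ReliabilityResult:
    statistic: str  # kappa | alpha | pearson_r
    value: float
    n: int
    detail: dict = field(default_factory=dict)


def cohens_kappa(
    rater_a: Sequence, rater_b: Sequence
) -> ReliabilityResult:
    """Unweighted Cohen's kappa between two raters over the same subjects.

    kappa = (p_o - p_e) / (1 - p_e) with expected agreement p_e from the
    product of the two raters' marginal label distributions.  Undefined when
    both raters are constant (p_e = 1).
    """
    a = pd.Series(list(rater_a))
    b = pd.Series(list(rater_b))
    if len(a) != len(b) or len(a) == 0:
        raise StatisticError("raters must label the same non-empty subject set")
    cats = sorted(set(a) | set(b), key=str)
    pa = a.value_counts(normalize=True).reindex(cats, fill_value=0.0)
    pb = b.value_counts(normalize=True).reindex(cats, fill_value=0.0)
    p_o = float((a.to_numpy() == b.to_numpy()).mean())
    p_e = float((pa * pb).sum())
    if p_e >= 1.0 - 1e-12:
        raise StatisticError("kappa undefined: both raters are constant")
    kappa = (p_o - p_e) / (1 - p_e)
    return ReliabilityResult("kappa", kappa, len(a),
                             {"p_observed": p_o, "p_expected": p_e})


def cronbach_alpha(item_matrix: np.ndarray | pd.DataFrame) -> ReliabilityResult:
    """Cronbach's alpha over a children x items score matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of row totals),
    with sample (ddof=1) variances.  ``detail['alpha_if_deleted']`` gives the
    per-item leave-one-out alphas used to report item-level consistency.
    """
    m = np.asarray(item_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise StatisticError("need at least 2 children and 2 items")
    if np.isnan(m).any():
        raise StatisticError("item matrix contains missing values")

    def _alpha(mat: np.ndarray) -> float:
        k = mat.shape[1]
        total_var = mat.sum(axis=1).var(ddof=1)
        if total_var <= 0:
            raise StatisticError("alpha undefined: zero total-score variance")
        return k / (k - 1) * (1 - mat.var(axis=0, ddof=1).sum() / total_var)

    k = m.shape[1]
    detail = {}
    if k > 2:
        detail["alpha_if_deleted"] = {
            j: _alpha(np.delete(m, j, axis=1)) for j in range(k)
        }
    return ReliabilityResult("alpha", float(_alpha(m)), m.shape[0], detail)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> ReliabilityResult:
    """Pearson product-moment correlation between two paired real sequences."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or len(xa) < 3:
        raise StatisticError("need paired 1-D sequences of length >= 3")
    if xa.std(ddof=1) == 0 or ya.std(ddof=1) == 0:
        raise StatisticError("correlation undefined: zero variance")
    from scipy import stats

    res = stats.pearsonr(xa, ya)
    return ReliabilityResult("pearson_r", float(res.statistic), len(xa),
                             {"p_value": float(res.pvalue)})


# ---------------------------------------------------------------------------
# 4. Synthetic cohort simulator
# ---------------------------------------------------------------------------
#
# The generative model mirrors the structure of a validation study: each
# child has a latent ASD class, a class-conditional CARS severity band with a
# score drawn uniformly within the band, per-question latent abnormality
# drawn per subdomain (optionally modulated by CARS severity within the ASD
# class), and two raters who each report the true response corrupted by
# independent unsure-replacement and flip noise.  Defaults reproduce the
# validation cohort's marginals: n = 225, ASD prevalence 56.9% (128/225),
# CARS band mixture 8.6/28.9/62.5% within ASD and 97.9/2.1/0% outside it,
# and the full-cohort developmental-quotient distribution.

DQ_BANDS = ("<=50", "51-60", "61-70", "71-80", "81-90", ">90")


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the synthetic validation-cohort generative model.

    Probabilities ``p_abnormal_pos`` / ``p_abnormal_neg`` are per-question
    latent-abnormality rates, one shared value per subdomain (override any
    subset).  ``severity_slope`` couples item probability to CARS within the
    ASD class on the logit scale, centred at CARS 36.5 (0 = off).
    ``rater_disagreement`` is the per-rater flip probability and
    ``unsure_rate`` the per-rater unsure-replacement probability.
    """

    n: int = 225
    prevalence: float = 0.569
    band_mix_pos: tuple[float, float, float] = (0.086, 0.289, 0.625)
    band_mix_neg: tuple[float, float, float] = (0.979, 0.021, 0.0)
    p_abnormal_pos: Mapping[str, float] = field(
        default_factory=lambda: {sd: 0.55 for sd in SUBDOMAIN_IDS})
    p_abnormal_neg: Mapping[str, float] = field(
        default_factory=lambda: {sd: 0.12 for sd in SUBDOMAIN_IDS})
    severity_slope: float = 0.0
    rater_disagreement: float = 0.05
    unsure_rate: float = 0.03
    b_item_rates_pos: tuple[float, float] = (0.98, 0.98)
    b_item_rates_neg: tuple[float, float] = (0.60, 0.50)
    dq_mix: tuple[float, ...] = (0.511, 0.284, 0.147, 0.036, 0.009, 0.013)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        props = [self.prevalence, self.rater_disagreement, self.unsure_rate,
                 *self.band_mix_pos, *self.band_mix_neg,
                 *self.b_item_rates_pos, *self.b_item_rates_neg, *self.dq_mix,
                 *self.p_abnormal_pos.values(), *self.p_abnormal_neg.values()]
        if any(not 0 <= p <= 1 for p in props):
            raise ValueError("all probabilities must lie in [0, 1]")
        for name, dist in (("band_mix_pos", self.band_mix_pos),
                           ("band_mix_neg", self.band_mix_neg),
                           ("dq_mix", self.dq_mix)):
            if abs(sum(dist) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {sum(dist)}")
        for name, p in (("p_abnormal_pos", self.p_abnormal_pos),
                        ("p_abnormal_neg", self.p_abnormal_neg)):
            if set(p) != set(SUBDOMAIN_IDS):
                raise ValueError(f"{name} must give one probability per subdomain")


def default_params(seed: int = 0, **overrides) -> CohortParams:
    """Cohort parameters matching the validation study's reported marginals."""
    return replace(CohortParams(seed=seed), **overrides) if overrides else CohortParams(seed=seed)


@dataclass(frozen=True)
class SimulatedChild:
    child_id: str
    latent_class: bool
    cars_score: float
    dq_band: str
    raw_answers: tuple[RawAnswer, ...]
    section_b: SectionBRecord


@dataclass(frozen=True)
class SimulatedCohort:
    params: CohortParams
    children: tuple[SimulatedChild, ...]

    def responses_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"child_id": a.child_id, "question_id": a.question_id,
             "parent_response": a.parent_response,
             "investigator_response": a.investigator_response}
            for c in self.children for a in c.raw_answers
        ])

    def section_b_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"child_id": c.child_id,
             "onset_early_development": c.section_b.onset_early_development,
             "functional_impairment": c.section_b.functional_impairment}
            for c in self.children
        ])

    def covariates_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"child_id": c.child_id, "cars_score": round(c.cars_score, 2),
             "expert_dsm5": "positive" if c.latent_class else "negative",
             "dq_band": c.dq_band}
            for c in self.children
        ])

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"child_id": c.child_id, "latent_class": c.latent_class,
             "cars_score": round(c.cars_score, 2)}
            for c in self.children
        ])


# CARS score support per band: uniform within the band's range
_BAND_RANGES = {
    "non_autistic": (15.0, 30.0),
    "mild_moderate": (30.0, 36.5),
    "severe": (36.5, 60.0),
}


def _flip(response: str) -> str:
    return YES if response == NO else NO


def simulate_cohort(params: CohortParams) -> SimulatedCohort:
    """Draw a seeded synthetic cohort from the latent-class generative model.

    Per child: latent class ~ Bernoulli(prevalence); CARS band
    class-conditional categorical with a uniform score inside the band; each
    question's latent abnormality ~ Bernoulli with per-subdomain probability,
    logit-shifted by ``severity_slope * (CARS - 36.5)`` inside the ASD class;
    abnormality maps through the question's polarity to a true response; each
    rater independently replaces the true response with ``unsure`` (rate
    ``unsure_rate``) or flips it (rate ``rater_disagreement``); Section B
    items are class-conditional Bernoulli draws.

    Each child uses its own deterministic substream of the root seed, so the
    content of a child is independent of cohort size or iteration order.
    """
    instrument = default_instrument()
    root = np.random.SeedSequence(params.seed)
    streams = root.spawn(params.n)
    width = len(str(params.n))
    children = []
    for idx, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        child_id = f"C{idx + 1:0{width}d}"
        is_pos = bool(rng.random() < params.prevalence)
        mix = params.band_mix_pos if is_pos else params.band_mix_neg
        band = CARS_BANDS[rng.choice(3, p=np.asarray(mix) / sum(mix))]
        lo, hi = _BAND_RANGES[band]
        cars = float(rng.uniform(lo, hi))
        dq = DQ_BANDS[rng.choice(len(DQ_BANDS),
                                 p=np.asarray(params.dq_mix) / sum(params.dq_mix))]
        p_map = params.p_abnormal_pos if is_pos else params.p_abnormal_neg

        answers = []
        for q in instrument.questions:
            p = p_map[q.subdomain_id]
            if is_pos and params.severity_slope != 0.0 and 0.0 < p < 1.0:
                p = float(expit(logit(p) + params.severity_slope * (cars - 36.5)))
            abnormal = rng.random() < p
            true_resp = q.abnormal_response if abnormal else _flip(q.abnormal_response)
            reported = []
            for _ in range(2):  # parent, investigator
                u = rng.random()
                if u < params.unsure_rate:
                    reported.append(UNSURE)
                elif rng.random() < params.rater_disagreement:
                    reported.append(_flip(true_resp))
                else:
                    reported.append(true_resp)
            answers.append(RawAnswer(child_id, q.question_id, reported[0], reported[1]))

        b_rates = params.b_item_rates_pos if is_pos else params.b_item_rates_neg
        section_b = SectionBRecord(
            child_id,
            bool(rng.random() < b_rates[0]),
            bool(rng.random() < b_rates[1]),
        )
        children.append(SimulatedChild(child_id, is_pos, cars, dq,
                                       tuple(answers), section_b))
    return SimulatedCohort(params, tuple(children))


def oracle_accuracy(
    cohort: SimulatedCohort, tool_calls: Mapping[str, bool] | pd.Series
) -> ConfusionTable:
    """Confusion of tool calls against the cohort's latent ground truth."""
    truth = {c.child_id: c.latent_class for c in cohort.children}
    tool = dict(tool_calls) if not isinstance(tool_calls, pd.Series) else tool_calls.to_dict()
    if not tool:
        raise StatisticError("empty tool calls")
    if set(tool) != set(truth):
        raise StatisticError("tool calls do not cover the simulated children")
    return confusion_from_records(tool, truth)


def analytic_call_probability(
    params: CohortParams,
    positive_class: bool,
    instrument: InstrumentSpec | None = None,
) -> float:
    """Exact probability that a noise-free child of one class is called ASD positive.

    Valid when ``rater_disagreement``, ``unsure_rate`` and ``severity_slope``
    are all zero, so each question's reconciled abnormality is an independent
    Bernoulli draw with its subdomain's probability.  The call probability
    factorises over subdomains: P(A1a)*P(A1b)*P(A1c) * P(>=2 abnormal among
    A2a-A2d, by enumeration over the 16 outcomes) * P(both B items).
    """
    if params.rater_disagreement or params.unsure_rate or params.severity_slope:
        raise ValueError("analytic call probability requires noise-free parameters")
    instrument = instrument or default_instrument()
    p_map = params.p_abnormal_pos if positive_class else params.p_abnormal_neg
    p_sd = {}
    for sd in instrument.subdomains:
        from scipy import stats

        k, p = len(sd.questions), p_map[sd.subdomain_id]
        p_sd[sd.subdomain_id] = float(
            stats.binom.sf(sd.abnormal_min_count - 1, k, p))
    p_a1 = p_sd["A1a"] * p_sd["A1b"] * p_sd["A1c"]
    p_a2 = 0.0
    for mask in range(16):
        flags = [(mask >> i) & 1 for i in range(4)]
        if sum(flags) >= 2:
            prob = 1.0
            for f, sd in zip(flags, A2_IDS):
                prob *= p_sd[sd] if f else 1 - p_sd[sd]
            p_a2 += prob
    b = params.b_item_rates_pos if positive_class else params.b_item_rates_neg
    return p_a1 * p_a2 * b[0] * b[1]


# ---------------------------------------------------------------------------
# 5. Tabular I/O and report rendering
# ---------------------------------------------------------------------------

_RESPONSE_COLS = ("child_id", "question_id", "parent_response", "investigator_response")
_SECTION_B_COLS = ("child_id", "onset_early_development", "functional_impairment")

_BOOL_STRINGS = {"true": True, "false": False, "1": True, "0": False,
                 "yes": True, "no": False}


def _read_csv(path: str | Path, required: Sequence[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InstrumentError(f"{what} file {path}: missing columns {missing}")
    return df


def _parse_bool(series: pd.Series, what: str) -> pd.Series:
    parsed = series.astype(str).str.strip().str.lower().map(_BOOL_STRINGS)
    if parsed.isna().any():
        bad = series[parsed.isna()].iloc[0]
        raise InstrumentError(f"{what}: unparseable boolean {bad!r}")
    return parsed.astype(bool)


def read_responses(path: str | Path) -> pd.DataFrame:
    """Read the long-format dual-rater response CSV (values case-insensitive)."""
    df = _read_csv(path, _RESPONSE_COLS, "responses")
    for col in ("parent_response", "investigator_response"):
        df[col] = df[col].astype(str).str.strip().str.lower()
        bad = ~df[col].isin(RESPONSES)
        if bad.any():
            row = df.index[bad][0] + 2  # header + 1-based
            raise InstrumentError(
                f"responses file line {row}: {col} must be yes|no|unsure, "
                f"got {df.loc[df.index[bad][0], col]!r}"
            )
    return df


def read_section_b(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, _SECTION_B_COLS, "Section B")
    for col in _SECTION_B_COLS[1:]:
        df[col] = _parse_bool(df[col], f"Section B column {col}")
    return df


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the optional per-child covariates CSV (cars_score, expert_dsm5, ...)."""
    df = _read_csv(path, ("child_id",), "covariates")
    if "cars_score" in df.columns:
        df["cars_score"] = pd.to_numeric(df["cars_score"], errors="coerce")
    if "expert_dsm5" in df.columns:
        lab = df["expert_dsm5"].astype(str).str.strip().str.lower()
        ok = lab.isin(["positive", "negative"])
        if not ok.all():
            raise InstrumentError(
                f"covariates: expert_dsm5 must be positive|negative, got "
                f"{df.loc[~ok, 'expert_dsm5'].iloc[0]!r}"
            )
        df["expert_dsm5"] = lab
    return df


def write_score_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, index=False)


def render_accuracy_text(report: pd.DataFrame, ct: ConfusionTable) -> str:
    """Aligned console rendering of the four accuracy measures with CIs."""
    lines = [
        "Validation against reference diagnosis",
        f"  2x2 table: TP={ct.tp}  FP={ct.fp}  FN={ct.fn}  TN={ct.tn}  (n={ct.total})",
        "",
        f"  {'measure':<12} {'point':>8} {'95% CI':>20} {'n':>9}",
    ]
    for row in report.itertuples():
        pct = _round_half_up(100 * row.point, 2)
        lo = _round_half_up(100 * row.lower, 2)
        hi = _round_half_up(100 * row.upper, 2)
        lines.append(
            f"  {row.measure:<12} {pct:>7.2f}% {f'[{lo:.2f}%, {hi:.2f}%]':>20}"
            f" {f'{row.n_num}/{row.n_den}':>9}"
        )
    return "\n".join(lines)


def render_crosstab_text(tab: pd.DataFrame) -> str:
    """Aligned console rendering of the CARS-band cross-tabulation."""
    lines = [
        "Tool performance across CARS severity bands",
        f"  {'CARS band':<14} {'n':>5} {'tool +':>12} {'tool -':>12}",
    ]
    for row in tab.itertuples():
        pos = f"{row.tool_positive} ({row.pct_positive:.1f}%)" if row.n else "-"
        neg = f"{row.tool_negative} ({row.pct_negative:.1f}%)" if row.n else "-"
        lines.append(f"  {row.cars_band:<14} {row.n:>5} {pos:>12} {neg:>12}")
    if tab.attrs.get("n_excluded"):
        lines.append(f"  (excluded without CARS: {tab.attrs['n_excluded']})")
    return "\n".join(lines)
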