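"""Diagnostic confusion matrix, covert-responder identification, outcome
dichotomization and exact 2x2 inference.

The behavioral diagnosis is the reference standard: MCS+ is
reference-positive (overt command following), VS/UWS and MCS- are
reference-negative. The instrumental response flag is the test standard.
Reference-negative subjects with an instrumental response are the covert
(CMD) cases; the remaining reference-negative subjects are "true DOC".

The two-sided Fisher exact test uses the point-probability definition: the
p-value sums hypergeometric probabilities of all tables with the observed
margins whose point probability does not exceed the observed one (relative
tolerance 1e-7 for ties). It is computed by full enumeration in exact
integer arithmetic.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import comb

from .errors import EmptyCohortError, InvalidParameterError

DIAGNOSES_NEGATIVE = ("VS/UWS", "MCS-")
DIAGNOSIS_POSITIVE = "MCS+"

CMD = "CMD"
TRUE_DOC = "true_DOC"
MCSP_RESPONDER = "MCS+_responder"
MCSP_NONRESPONDER = "MCS+_nonresponder"


@dataclass
class SubjectRecord:
    subject_id: str
    diagnosis: str
    fnirs_response: bool
    gose_6mo: int | None = None

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES_NEGATIVE + (DIAGNOSIS_POSITIVE,):
            raise InvalidParameterError(f"unknown diagnosis {self.diagnosis!r}")
        if self.gose_6mo is not None and not 1 <= self.gose_6mo <= 8:
            raise InvalidParameterError("gose_6mo must be in 1..8")

    @property
    def cmd_status(self) -> str:
        if self.diagnosis == DIAGNOSIS_POSITIVE:
            return MCSP_RESPONDER if self.fnirs_response else MCSP_NONRESPONDER
        return CMD if self.fnirs_response else TRUE_DOC


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fn: int
    tn: int
    fp: int

    @staticmethod
    def _rate(num: int, denom: int) -> float:
        # empty reference group -> undefined rate, reported as NaN
        return 100.0 * num / denom if denom else float("nan")

    @property
    def tpr(self) -> float:
        return self._rate(self.tp, self.tp + self.fn)

    @property
    def fnr(self) -> float:
        return self._rate(self.fn, self.tp + self.fn)

    @property
    def tnr(self) -> float:
        return self._rate(self.tn, self.tn + self.fp)

    @property
    def fpr(self) -> float:
        return self._rate(self.fp, self.tn + self.fp)

    def rates_rounded(self) -> dict[str, float]:
        return {
            "TPR": round(self.tpr, 1),
            "FNR": round(self.fnr, 1),
            "TNR": round(self.tnr, 1),
            "FPR": round(self.fpr, 1),
        }

    def as_dict(self) -> dict:
        return {
            "counts": {"TP": self.tp, "FN": self.fn, "TN": self.tn, "FP": self.fp},
            "rates_percent": {
                "TPR": self.tpr,
                "FNR": self.fnr,
                "TNR": self.tnr,
                "FPR": self.fpr,
            },
            "rates_percent_rounded": self.rates_rounded(),
        }


def confusion_summary(records: list[SubjectRecord]) -> ConfusionSummary:
    """Count TP/FN/TN/FP against the behavioral reference."""
    if not records:
        raise EmptyCohortError("no subject records")
    tp = fn = tn = fp = 0
    for r in records:
        if r.diagnosis == DIAGNOSIS_POSITIVE:
            if r.fnirs_response:
                tp += 1
            else:
                fn += 1
        else:
            if r.fnirs_response:
                fp += 1
            else:
                tn += 1
    return ConfusionSummary(tp=tp, fn=fn, tn=tn, fp=fp)


def identify_cmd(records: list[SubjectRecord]) -> list[str]:
    """Subject ids of reference-negative subjects with an instrumental
    response, in a stable (sorted) order."""
    return sorted(r.subject_id for r in records if r.cmd_status == CMD)


def dichotomize_gose(score: int) -> str:
    """'favorable' for 4..8, 'unfavorable' for 1..3."""
    if not isinstance(score, int) or not 1 <= score <= 8:
        raise InvalidParameterError(f"GOS-E score must be an integer in 1..8, got {score!r}")
    return "favorable" if score >= 4 else "unfavorable"


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InvalidParameterError("cells must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise InvalidParameterError("table total must be >= 1")

    @property
    def rows(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def fisher_exact_2x2(table) -> float:
    """Two-sided exact p-value by integer enumeration.

    Accepts a ContingencyTable2x2 or a [[a, b], [c, d]] nested sequence.
    A zero margin makes the table degenerate; by convention p = 1.0.
    """
    if isinstance(table, ContingencyTable2x2):
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise InvalidParameterError("cells must be non-negative")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if n < 1:
        raise InvalidParameterError("table total must be >= 1")
    if 0 in (r1, r2, c1, c2):
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    obs = weights[a]
    cutoff = obs + int(obs * 1e-7)  # relative tolerance for ties
    num = sum(w for w in weights.values() if w <= cutoff)
    return num / comb(n, c1)


def bonferroni_alpha(family_alpha: float = 0.05, n_comparisons: int = 1) -> float:
    """family_alpha / n_comparisons, rounded to 4 decimals."""
    if n_comparisons < 1:
        raise InvalidParameterError("n_comparisons must be >= 1")
    return round(family_alpha / n_comparisons, 4)


def _outcome_counts(records: list[SubjectRecord]) -> tuple[int, int, int]:
    """(favorable, unfavorable, lost_to_follow_up)."""
    fav = unfav = lost = 0
    for r in records:
        if r.gose_6mo is None:
            lost += 1
        elif dichotomize_gose(r.gose_6mo) == "favorable":
            fav += 1
        else:
            unfav += 1
    return fav, unfav, lost


def prognosis_analysis(records: list[SubjectRecord], family_alpha: float = 0.05) -> dict:
    """Outcome comparisons between the covert-responder and true-DOC strata.

    Builds favorable/unfavorable 2x2 tables for CMD vs true DOC and for the
    three pairwise comparisons among true VS/UWS, true MCS- and CMD, applies
    the exact test to each, and annotates the pairwise family with its
    Bonferroni threshold. Subjects lost to follow-up are excluded from these
    tables only.
    """
    groups = {
        CMD: [r for r in records if r.cmd_status == CMD],
        TRUE_DOC: [r for r in records if r.cmd_status == TRUE_DOC],
        "true_VS/UWS": [
            r for r in records if r.cmd_status == TRUE_DOC and r.diagnosis == "VS/UWS"
        ],
        "true_MCS-": [
            r for r in records if r.cmd_status == TRUE_DOC and r.diagnosis == "MCS-"
        ],
    }
    counts = {}
    for name, members in groups.items():
        fav, unfav, lost = _outcome_counts(members)
        counts[name] = {
            "n": len(members),
            "favorable": fav,
            "unfavorable": unfav,
            "lost_to_follow_up": lost,
        }

    def compare(g1: str, g2: str):
        c1, c2 = counts[g1], counts[g2]
        if c1["favorable"] + c1["unfavorable"] == 0 or c2["favorable"] + c2["unfavorable"] == 0:
            return None
        table = ContingencyTable2x2(
            c1["favorable"], c1["unfavorable"], c2["favorable"], c2["unfavorable"]
        )
        p = fisher_exact_2x2(table)
        return {
            "groups": [g1, g2],
            "table": table.rows,
            "p_value": p,
            "p_value_rounded": round(p, 3),
        }

    primary = compare(CMD, TRUE_DOC)
    pairwise_specs = [
        ("true_VS/UWS", CMD),
        ("true_VS/UWS", "true_MCS-"),
        ("true_MCS-", CMD),
    ]
    pairwise = []
    skipped = []
    for g1, g2 in pairwise_specs:
        res = compare(g1, g2)
        if res is None:
            skipped.append([g1, g2])
        else:
            pairwise.append(res)
    threshold = bonferroni_alpha(family_alpha, len(pairwise_specs))
    for res in pairwise:
        res["bonferroni_threshold"] = threshold
        res["significant"] = res["p_value"] < threshold
    return {
        "group_outcomes": counts,
        "cmd_vs_true_doc": primary,
        "pairwise": pairwise,
        "pairwise_skipped": skipped,
        "bonferroni_threshold": threshold,
    }


def study_report(records: list[SubjectRecord], family_alpha: float = 0.05) -> dict:
    """Machine-readable report: confusion matrix, CMD list, prognosis tables."""
    summary = confusion_summary(records)
    return {
        "n_patients": len(records),
        "confusion": summary.as_dict(),
        "cmd_subjects": identify_cmd(records),
        "prognosis": prognosis_analysis(records, family_alpha=family_alpha),
    }


def format_report(report: dict) -> str:
    """Human-readable text rendering of a study report."""
    lines = []
    c = report["confusion"]["counts"]
    r = report["confusion"]["rates_percent_rounded"]
    lines.append(f"Patients scored: {report['n_patients']}")
    lines.append(
        f"Confusion: TP={c['TP']} FN={c['FN']} TN={c['TN']} FP={c['FP']}"
    )
    lines.append(
        f"Rates: TPR={r['TPR']}% FNR={r['FNR']}% TNR={r['TNR']}% FPR={r['FPR']}%"
    )
    cmd = report["cmd_subjects"]
    lines.append(f"Covert responders (CMD): {len(cmd)} -> {', '.join(cmd) if cmd else 'none'}")
    prog = report["prognosis"]
    if prog["cmd_vs_true_doc"] is not None:
        res = prog["cmd_vs_true_doc"]
        lines.append(
            f"CMD vs true DOC outcome: table={res['table']} p={res['p_value_rounded']}"
        )
    for res in prog["pairwise"]:
        g1, g2 = res["groups"]
        star = "*" if res["significant"] else ""
        lines.append(
            f"{g1} vs {g2}: table={res['table']} p={res['p_value_rounded']}{star}"
            f" (threshold {res['bonferroni_threshold']})"
        )
    return "\n".join(lines) + "\n"
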