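"""Individual scoring reports against the published EAR norms.

Applies the published demographic adjustment and Equivalent Score bands to
one participant's raw ER/EA indices and produces an interpretive report:
adjusted scores, ES levels 0-4 and their qualitative labels ("abnormal",
"borderline", "low-end normal", "normal").

Adjusted scores are classified at full precision; the two-decimal values
shown in the report are display rounding only.  Elderly respondents
(age > 65) were sparsely represented in the normative sample, so reports
for them carry a standing caution; outside the normative age range 17-88
the ES is withheld entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .adjustment import AgeOutOfRangeError, adjust_score, round_half_away
from .limits import ES_LABELS, assign_es
from .norms import PublishedNorms, load_published_norms

__all__ = ["IndividualReport", "score_individual", "batch_score"]

_EDU_RANGE = (5, 24)
_ELDERLY_CAUTION = (
    "age > 65: elderly respondents were sparsely represented in the "
    "normative sample; interpret the adjustment with caution"
)


@dataclass
class IndividualReport:
    age: float
    sex: str
    er_raw: int
    ea_raw: int
    er_adjusted: float | None = None
    ea_adjusted: float | None = None
    er_es: int | None = None
    ea_es: int | None = None
    er_label: str | None = None
    ea_label: str | None = None
    norms_version: str = ""
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "age": self.age,
            "sex": self.sex,
            "er_raw": self.er_raw,
            "ea_raw": self.ea_raw,
            "er_adjusted": None if self.er_adjusted is None
            else round_half_away(self.er_adjusted, 2),
            "ea_adjusted": None if self.ea_adjusted is None
            else round_half_away(self.ea_adjusted, 2),
            "er_es": self.er_es,
            "ea_es": self.ea_es,
            "er_label": self.er_label,
            "ea_label": self.ea_label,
            "norms_version": self.norms_version,
            "warnings": list(self.warnings),
        }
        return d

    def to_text(self) -> str:
        lines = [
            f"EAR test report (norms {self.norms_version})",
            f"  age {self.age:g}, sex {self.sex}",
        ]
        for index, raw, adj, es, label in (
            ("ER", self.er_raw, self.er_adjusted, self.er_es, self.er_label),
            ("EA", self.ea_raw, self.ea_adjusted, self.ea_es, self.ea_label),
        ):
            if adj is None:
                lines.append(f"  {index}: raw {raw} - ES withheld")
            else:
                lines.append(
                    f"  {index}: raw {raw}, adjusted "
                    f"{round_half_away(adj, 2):.2f}, ES {es} ({label})"
                )
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)


def score_individual(
    er_raw: int,
    ea_raw: int,
    age: float,
    sex: str,
    norms: PublishedNorms | None = None,
    education: float | None = None,
) -> IndividualReport:
    """Score one participant against the published norms.

    Raw scores must be integers in [0, 60].  If the age lies outside the
    norms' validity range the report is still produced, with a prominent
    warning and the ES withheld.
    """
    for name, raw in (("er_raw", er_raw), ("ea_raw", ea_raw)):
        if not float(raw).is_integer() or not 0 <= raw <= 60:
            raise ValueError(f"{name} = {raw!r} is not an integer in [0, 60]")
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    if norms is None:
        norms = load_published_norms()

    report = IndividualReport(
        age=age, sex=sex, er_raw=int(er_raw), ea_raw=int(ea_raw),
        norms_version=norms.version,
    )
    if education is not None and not (
        _EDU_RANGE[0] <= education <= _EDU_RANGE[1]
    ):
        report.warnings.append(
            f"education {education:g} outside the normative range "
            f"{_EDU_RANGE[0]}-{_EDU_RANGE[1]} years"
        )
    if age > 65:
        report.warnings.append(_ELDERLY_CAUTION)

    for index, raw in (("ER", er_raw), ("EA", ea_raw)):
        model = norms.model(index)
        try:
            adjusted = adjust_score(raw, age, sex, model)
        except AgeOutOfRangeError as err:
            report.warnings.append(f"{index}: {err}; ES withheld")
            continue
        es = assign_es(adjusted, norms.bands(index))
        label = ES_LABELS[es]
        if index == "ER":
            report.er_adjusted, report.er_es, report.er_label = adjusted, es, label
        else:
            report.ea_adjusted, report.ea_es, report.ea_label = adjusted, es, label
    return report


def batch_score(
    cohort: pd.DataFrame, norms: PublishedNorms | None = None
) -> pd.DataFrame:
    """Append adjusted scores and ES levels to a cohort table.

    Expects columns age, sex, er_raw, ea_raw; rows whose age falls outside
    the norms' validity range get missing adjusted/ES values.
    """
    if norms is None:
        norms = load_published_norms()
    out = cohort.copy()
    adj = {"er": [], "ea": []}
    es = {"er": [], "ea": []}
    for row in cohort.itertuples():
        rep = score_individual(
            int(row.er_raw), int(row.ea_raw), float(row.age), row.sex, norms
        )
        adj["er"].append(rep.er_adjusted)
        adj["ea"].append(rep.ea_adjusted)
        es["er"].append(rep.er_es)
        es["ea"].append(rep.ea_es)
    out["er_adjusted"] = adj["er"]
    out["ea_adjusted"] = adj["ea"]
    out["er_es"] = pd.array(es["er"], dtype="Int64")
    out["ea_es"] = pd.array(es["ea"], dtype="Int64")
    return out
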