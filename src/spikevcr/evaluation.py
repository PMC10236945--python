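"""Outcome evaluation: in/out adjudication, cohort metrics, Fisher test.

The model is scored against surgery outcome: a candidate cluster inside
the resection cavity in a seizure-free (favourable, Engel 1) patient is
a true positive; inside with an unfavourable outcome, a false positive;
outside with unfavourable, a true negative; outside with favourable, a
false negative.  TP and TN count as model successes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .bundle import ResectionMask
from .clusters import ClusterCandidate

__all__ = [
    "OutcomeRecord",
    "ContingencyTable",
    "MetricsReport",
    "locate_cluster",
    "classify",
    "metrics",
    "fisher_exact",
    "evaluate_cohort",
    "load_example_cohort",
]

_CLASSIFICATION = {
    ("in", "favourable"): ("TP", "Success"),
    ("in", "unfavourable"): ("FP", "Failure"),
    ("out", "unfavourable"): ("TN", "Success"),
    ("out", "favourable"): ("FN", "Failure"),
}


@dataclass
class OutcomeRecord:
    patient_id: str
    outcome: str                 # 'favourable' | 'unfavourable'
    location: str                # 'in' | 'out'
    overlap: float | None = None
    classification: str = ""     # TP | FP | TN | FN
    model_performance: str = ""  # Success | Failure


@dataclass
class ContingencyTable:
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    def __post_init__(self) -> None:
        for v in (self.tp, self.fn, self.tn, self.fp):
            if v < 0 or int(v) != v:
                raise ValueError("contingency counts must be nonnegative integers")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def as_2x2(self) -> list[list[int]]:
        # rows: cluster in/out; columns: favourable/unfavourable
        return [[self.tp, self.fp], [self.fn, self.tn]]


@dataclass
class MetricsReport:
    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    fisher_p: Optional[float] = None


def locate_cluster(
    candidate: ClusterCandidate,
    resection: ResectionMask,
    inside_fraction: float = 0.5,
) -> tuple[str, float]:
    """Majority-overlap in/out verdict plus the raw overlap fraction.

    ``overlap = |cluster ∩ resection| / |cluster|``; the verdict is
    'in' iff overlap >= ``inside_fraction``.  The fraction is always
    reported so that alternative thresholds can be audited.
    """
    members = (
        candidate.source_ids
        if candidate.source_ids is not None
        else candidate.sources
    )
    members = np.asarray(members, dtype=int)
    if len(members) == 0:
        raise ValueError("cannot locate an empty cluster")
    overlap = float(
        np.isin(members, resection.member_indices).sum() / len(members)
    )
    return ("in" if overlap >= inside_fraction else "out", overlap)


def classify(outcome: str, location: str) -> tuple[str, str]:
    """Map (outcome, in/out location) to TP/FP/TN/FN and Success/Failure."""
    key = (location, outcome)
    if key not in _CLASSIFICATION:
        raise ValueError(
            f"cannot classify outcome={outcome!r}, location={location!r}"
        )
    return _CLASSIFICATION[key]


def metrics(table: ContingencyTable) -> MetricsReport:
    """Accuracy, sensitivity and specificity; zero denominators -> None."""
    if table.n < 1:
        raise ValueError("empty contingency table")

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    return MetricsReport(
        accuracy=ratio(table.tp + table.tn, table.n),
        sensitivity=ratio(table.tp, table.tp + table.fn),
        specificity=ratio(table.tn, table.tn + table.fp),
    )


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p for the in/out x favourable/unfavourable table.

    Uses the probability-mass two-sided convention: the sum of
    hypergeometric probabilities of all same-margin tables no more
    likely than the observed one.
    """
    if table.n < 1:
        raise ValueError("empty contingency table")
    return float(stats.fisher_exact(table.as_2x2(), alternative="two-sided")[1])


def evaluate_cohort(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a cohort of (outcome, in/out) records.

    ``records`` needs columns ``id``, ``outcome`` ('favourable' /
    'unfavourable') and ``in_out`` ('in' / 'out'); an optional
    ``sample`` column defines subgroups.  Records with unknown outcome
    are excluded with a warning.  Returns (per-patient table with
    classification and model_performance, per-subgroup metrics table
    including an 'all' row).
    """
    import warnings

    df = records.copy()
    known = df["outcome"].isin(["favourable", "unfavourable"])
    if not known.all():
        warnings.warn(
            f"excluding {(~known).sum()} records with unknown outcome",
            stacklevel=2,
        )
        df = df[known].copy()
    cls = [classify(o, l) for o, l in zip(df["outcome"], df["in_out"])]
    df["classification"] = [c[0] for c in cls]
    df["model_performance"] = [c[1] for c in cls]

    def summarise(sub: pd.DataFrame, name: str) -> dict:
        counts = sub["classification"].value_counts()
        table = ContingencyTable(
            tp=int(counts.get("TP", 0)),
            fn=int(counts.get("FN", 0)),
            tn=int(counts.get("TN", 0)),
            fp=int(counts.get("FP", 0)),
        )
        rep = metrics(table)
        return {
            "sample": name,
            "n": table.n,
            "tp": table.tp,
            "fn": table.fn,
            "tn": table.tn,
            "fp": table.fp,
            "accuracy": rep.accuracy,
            "sensitivity": rep.sensitivity,
            "specificity": rep.specificity,
            "fisher_p": fisher_exact(table),
            "successes": int((sub["model_performance"] == "Success").sum()),
        }

    rows = []
    if "sample" in df.columns:
        for name, sub in df.groupby("sample", sort=True):
            rows.append(summarise(sub, str(name)))
    rows.append(summarise(df, "all"))
    return df, pd.DataFrame(rows)


def load_example_cohort() -> pd.DataFrame:
    """Bundled example cohort: 24 paediatric resective-surgery cases.

    Per patient: study arm (step1 used the post-surgical cavity in the
    network definition, step2 was blinded), spike count, the candidate
    cluster's transition profile, size, band run and emergence
    threshold, the surgical outcome and the in/out verdict.
    """
    with resources.files("spikevcr.data").joinpath("example_cohort.csv").open() as fh:
        return pd.read_csv(fh)
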