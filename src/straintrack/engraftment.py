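"""Engraftment and persistence accounting for defined microbiota transplants.

After gavaging a donor consortium into a mouse already colonized with a
recipient consortium, three per-mouse quantities summarize the outcome:

* engraftment fraction — share of donor-consortium strains detected post
  transplant;
* persistence fraction — share of recipient-consortium strains still detected;
* strain counts — total strains present before and after, and the change.

Strains declared in both consortia are attributionally ambiguous and are by
default excluded from both fractions (configurable to attribute them to the
recipient). "Detected" is whatever presence-calling produced the input matrix;
thresholds travel with the table's metadata, not here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InputError
from .stats import group_summary, one_way_anova

__all__ = [
    "TransplantExperiment",
    "engraftment_fraction",
    "persistence_fraction",
    "strain_counts",
    "cohort_metrics",
    "summarize_engraftment",
]


@dataclass
class TransplantExperiment:
    """One recipient+donor combination with per-mouse presence at pre/post.

    ``presence`` is indexed by (mouse_id, timepoint) with one boolean column
    per strain of the union universe.
    """

    recipient_consortium: set[str]
    donor_consortium: set[str]
    presence: pd.DataFrame
    shared_policy: str = "exclude"  # or "recipient"

    def __post_init__(self) -> None:
        if self.shared_policy not in ("exclude", "recipient"):
            raise InputError(f"unknown shared_policy {self.shared_policy!r}")
        universe = set(self.presence.columns)
        missing = (self.recipient_consortium | self.donor_consortium) - universe
        if missing:
            raise InputError(f"presence matrix lacks strains {sorted(missing)!r}")

    def _effective_sets(self) -> tuple[set[str], set[str]]:
        shared = self.recipient_consortium & self.donor_consortium
        if self.shared_policy == "exclude":
            return self.recipient_consortium - shared, self.donor_consortium - shared
        return set(self.recipient_consortium), self.donor_consortium - shared

    def mice(self) -> list[str]:
        return sorted(self.presence.index.get_level_values("mouse_id").unique())

    def _present(self, mouse: str, timepoint: str) -> set[str]:
        try:
            row = self.presence.loc[(mouse, timepoint)]
        except KeyError:
            raise InputError(f"no {timepoint!r} sample for mouse {mouse!r}") from None
        return set(row.index[row.astype(bool)])


def engraftment_fraction(experiment: TransplantExperiment) -> pd.Series:
    """Per-mouse fraction of donor strains detected after transplant."""
    _, donor = experiment._effective_sets()
    if not donor:
        raise InputError("donor consortium empty after overlap exclusion")
    out = {}
    for mouse in experiment.mice():
        post = experiment._present(mouse, "post")
        out[mouse] = len(post & donor) / len(donor)
    return pd.Series(out, name="engraftment_fraction")


def persistence_fraction(experiment: TransplantExperiment) -> pd.Series:
    """Per-mouse fraction of recipient strains still detected after transplant."""
    recipient, _ = experiment._effective_sets()
    if not recipient:
        raise InputError("recipient consortium empty after overlap exclusion")
    out = {}
    for mouse in experiment.mice():
        post = experiment._present(mouse, "post")
        out[mouse] = len(post & recipient) / len(recipient)
    return pd.Series(out, name="persistence_fraction")


def strain_counts(experiment: TransplantExperiment) -> pd.DataFrame:
    """Per-mouse strains present pre, post, the change, and turnover.

    turnover = strains lost + strains gained; always >= |delta|. An empty post
    sample is flagged.
    """
    rows = []
    for mouse in experiment.mice():
        pre = experiment._present(mouse, "pre")
        post = experiment._present(mouse, "post")
        rows.append({
            "mouse_id": mouse,
            "n_pre": len(pre),
            "n_post": len(post),
            "delta": len(post) - len(pre),
            "turnover": len(pre - post) + len(post - pre),
            "empty_post": len(post) == 0,
        })
    return pd.DataFrame(rows).set_index("mouse_id")


def cohort_metrics(presence: pd.DataFrame, metadata: pd.DataFrame,
                   consortia: dict[str, set[str]], shared_policy: str = "exclude") -> pd.DataFrame:
    """Per-mouse engraftment/persistence/count metrics over a whole cohort.

    ``metadata`` maps mouse_id -> (recipient, donor) consortium names;
    ``consortia`` maps names to strain sets.
    """
    rows = []
    for (rec, don), sub in metadata.groupby(["recipient", "donor"]):
        mice = sub.index
        exp = TransplantExperiment(consortia[rec], consortia[don],
                                   presence.loc[presence.index.get_level_values("mouse_id").isin(mice)],
                                   shared_policy)
        ef = engraftment_fraction(exp)
        pf = persistence_fraction(exp)
        sc = strain_counts(exp)
        for mouse in exp.mice():
            rows.append({"mouse_id": mouse, "recipient": rec, "donor": don,
                         "engraftment_fraction": ef[mouse], "persistence_fraction": pf[mouse],
                         **sc.loc[mouse].to_dict()})
    return pd.DataFrame(rows).set_index("mouse_id")


def summarize_engraftment(per_mouse: pd.DataFrame, metric: str, grouping: str):
    """Group mean +/- SE plus one-way ANOVA across groups for a per-mouse metric.

    Returns ``(summary table, TestResult or None)``; the ANOVA is skipped
    (None) when fewer than two groups have >= 2 mice.
    """
    if metric not in per_mouse.columns:
        raise InputError(f"unknown metric {metric!r}")
    if grouping not in per_mouse.columns:
        raise InputError(f"unknown grouping column {grouping!r}")
    groups = {name: sub[metric].to_numpy() for name, sub in per_mouse.groupby(grouping)}
    summary = group_summary(groups)
    testable = [v for v in groups.values() if len(v) >= 2]
    test = one_way_anova(testable, label=f"ANOVA of {metric} across {grouping}") if len(testable) >= 2 else None
    return summary, test
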