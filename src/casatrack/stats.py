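"""Sub-population composition, redistribution percentages and rank tests.

The motile population at each time-step is split into the slow / medium /
rapid classes, and the change in a class's share between time-steps t1 and
t2 is the signed relative variation

    %variation(t2 vs t1) = (%T_t2 - %T_t1) / %T_t1 * 100

(positive = the class grew, negative = it shrank).  Distribution shifts of a
kinematic parameter within one class between two time-steps are assessed by
the Kruskal-Wallis rank test (tie-corrected H, chi-square reference with
k - 1 degrees of freedom), applied pairwise per parameter per class within
one experimental condition.  Conditions originating from different source
samples are deliberately never tested against each other.
"""

from __future__ import annotations

import itertools
import logging
import re
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (KinematicsRecord, MOTILITY_CLASSES, PopulationSummary,
                   ValidationError)

log = logging.getLogger(__name__)

KINEMATIC_PARAMETERS = ("vsl", "vcl", "lin")


@dataclass
class VariationResult:
    """Signed relative change of one class's share between two time-steps."""
    class_label: str
    from_step: str
    to_step: str
    percent_variation: float


@dataclass
class KWResult:
    """One Kruskal-Wallis comparison."""
    parameter: str
    class_label: str
    step_pair: tuple
    h_statistic: float
    p_value: float
    group_sizes: tuple

    def __post_init__(self) -> None:
        if self.h_statistic < -1e-12:
            raise ValidationError("H must be >= 0")


def significance_stars(p: float) -> str:
    """*** p<0.001, ** p<0.01, * p<0.05, empty otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def class_percentages(records: Sequence[KinematicsRecord], condition: str,
                      time_step: str) -> PopulationSummary:
    """Per-class counts and percentages of the motile population.

    Unclassified (VCL < 25 um/s) tracks are excluded from the denominator.
    Zero motile tracks yield an empty summary with a warning.
    """
    counts = {cls: sum(1 for r in records if r.motility_class == cls)
              for cls in MOTILITY_CLASSES}
    total = sum(counts.values())
    if total == 0:
        warnings.warn(f"no motile tracks for {condition}/{time_step}",
                      stacklevel=2)
        return PopulationSummary(condition=condition, time_step=time_step,
                                 counts=counts, percentages={}, total_motile=0)
    pct = {cls: 100.0 * n / total for cls, n in counts.items()}
    return PopulationSummary(condition=condition, time_step=time_step,
                             counts=counts, percentages=pct, total_motile=total)


def percent_variation(p_from: float, p_to: float) -> float:
    """Signed relative change (p_to - p_from) / p_from * 100."""
    if p_from <= 0:
        raise ValidationError(
            "percent variation undefined for a zero starting percentage")
    return (p_to - p_from) / p_from * 100.0


def kruskal_wallis(groups: Sequence[Sequence[float]], parameter: str = "",
                   class_label: str = "", step_pair: tuple = ()) -> KWResult:
    """Tie-corrected Kruskal-Wallis H over k >= 2 groups.

    All values identical across groups is a well-defined no-effect case
    (H = 0, p = 1) rather than an error; an empty group is an error.
    """
    if len(groups) < 2:
        raise ValidationError("Kruskal-Wallis needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValidationError("Kruskal-Wallis groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrays)
    return KWResult(parameter=parameter, class_label=class_label,
                    step_pair=tuple(step_pair), h_statistic=float(h),
                    p_value=float(p), group_sizes=tuple(len(a) for a in arrays))


def _step_sort_key(label: str):
    m = re.search(r"\d+\.?\d*", str(label))
    return (float(m.group()) if m else float("inf"), str(label))


@dataclass
class ConditionReport:
    """All analyses for one experimental condition across its time-steps."""
    condition: str
    time_steps: List[str]
    summaries: Dict[str, PopulationSummary]
    class_kinematics: pd.DataFrame      # mean/std per step x class x parameter
    variations: List[VariationResult]   # consecutive step pairs only
    kw_tests: List[KWResult]            # all step pairs


@dataclass
class Report:
    conditions: Dict[str, ConditionReport]
    note: str = ("Conditions are never compared against each other: they "
                 "originate from different source samples, so only "
                 "within-condition time-step comparisons are meaningful.")


def compare_conditions_report(records: Sequence[KinematicsRecord],
                              time_step_order: Optional[Sequence[str]] = None,
                              bonferroni: bool = False) -> Report:
    """Per-condition composition, redistribution and pairwise KW report.

    Each record must carry ``condition`` and ``time_step`` labels.  For every
    condition: class percentages per time-step, percent variations between
    consecutive time-steps, and pairwise Kruskal-Wallis tests of VSL, VCL and
    LIN per class over every time-step pair.  Cross-condition tests are never
    computed.  ``bonferroni`` multiplies p-values by the number of step pairs
    (default off).
    """
    recs = list(records)
    for r in recs:
        if r.condition is None or r.time_step is None:
            raise ValidationError(
                f"record {r.track_id} lacks condition/time_step labels")

    conditions = sorted({r.condition for r in recs})
    out: Dict[str, ConditionReport] = {}
    for cond in conditions:
        cond_recs = [r for r in recs if r.condition == cond]
        steps = sorted({r.time_step for r in cond_recs}, key=_step_sort_key)
        if time_step_order is not None:
            known = [s for s in time_step_order if s in steps]
            if set(known) != set(steps):
                raise ValidationError(
                    f"time_step_order does not cover steps {steps} of {cond}")
            steps = known

        summaries = {}
        kin_rows = []
        for step in steps:
            step_recs = [r for r in cond_recs if r.time_step == step]
            summaries[step] = class_percentages(step_recs, cond, step)
            for cls in MOTILITY_CLASSES:
                vals = {p: np.array([getattr(r, p) for r in step_recs
                                     if r.motility_class == cls])
                        for p in KINEMATIC_PARAMETERS}
                row = {"condition": cond, "time_step": step, "class": cls,
                       "n": len(vals["vsl"])}
                for p in KINEMATIC_PARAMETERS:
                    row[f"{p}_mean"] = float(vals[p].mean()) if len(vals[p]) else np.nan
                    row[f"{p}_std"] = (float(vals[p].std(ddof=1))
                                       if len(vals[p]) > 1 else np.nan)
                kin_rows.append(row)

        variations = []
        for s_from, s_to in zip(steps[:-1], steps[1:]):
            for cls in MOTILITY_CLASSES:
                p_from = summaries[s_from].percentages.get(cls, 0.0)
                p_to = summaries[s_to].percentages.get(cls, 0.0)
                if p_from > 0:
                    variations.append(VariationResult(
                        class_label=cls, from_step=s_from, to_step=s_to,
                        percent_variation=percent_variation(p_from, p_to)))

        pairs = list(itertools.combinations(steps, 2))
        kw_tests = []
        for cls in MOTILITY_CLASSES:
            for param in KINEMATIC_PARAMETERS:
                for s1, s2 in pairs:
                    g1 = [getattr(r, param) for r in cond_recs
                          if r.time_step == s1 and r.motility_class == cls]
                    g2 = [getattr(r, param) for r in cond_recs
                          if r.time_step == s2 and r.motility_class == cls]
                    if not g1 or not g2:
                        continue
                    res = kruskal_wallis([g1, g2], parameter=param,
                                         class_label=cls, step_pair=(s2, s1))
                    if bonferroni and len(pairs) > 1:
                        res.p_value = min(1.0, res.p_value * len(pairs))
                    kw_tests.append(res)

        out[cond] = ConditionReport(condition=cond, time_steps=steps,
                                    summaries=summaries,
                                    class_kinematics=pd.DataFrame(kin_rows),
                                    variations=variations, kw_tests=kw_tests)
        log.info("condition %s: %d steps, %d variations, %d KW tests",
                 cond, len(steps), len(variations), len(kw_tests))
    return Report(conditions=out)


def report_tables(report: Report) -> Dict[str, pd.DataFrame]:
    """Flatten a report into CSV-ready tables."""
    comp_rows, var_rows, kw_rows, kin = [], [], [], []
    for cond, cr in report.conditions.items():
        kin.append(cr.class_kinematics)
        for step, summ in cr.summaries.items():
            for cls in MOTILITY_CLASSES:
                comp_rows.append({"condition": cond, "time_step": step,
                                  "class": cls, "n": summ.counts.get(cls, 0),
                                  "pct_of_motile": summ.percentages.get(cls, np.nan),
                                  "total_motile": summ.total_motile})
        for v in cr.variations:
            var_rows.append({"condition": cond, "class": v.class_label,
                             "from_step": v.from_step, "to_step": v.to_step,
                             "percent_variation": v.percent_variation})
        for t in cr.kw_tests:
            kw_rows.append({"condition": cond, "parameter": t.parameter,
                            "class": t.class_label,
                            "step_pair": f"{t.step_pair[0]}vs{t.step_pair[1]}",
                            "h_statistic": t.h_statistic, "p_value": t.p_value,
                            "n1": t.group_sizes[0], "n2": t.group_sizes[1],
                            "stars": significance_stars(t.p_value)})
    return {
        "composition": pd.DataFrame(comp_rows),
        "class_kinematics": (pd.concat(kin, ignore_index=True)
                             if kin else pd.DataFrame()),
        "variations": pd.DataFrame(var_rows),
        "kruskal_wallis": pd.DataFrame(kw_rows),
    }
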