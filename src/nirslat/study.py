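"""End-to-end study driver: cohort -> laterality table -> group contrasts.

Ties the pipeline together the way the analysis is actually run: per
subject, preprocess both runs, build the three connectivity matrices (rest,
auditory, visual), detect modules with repeated Louvain, average the two
laterality measures over runs, and finally compare groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import subject_connectivity
from .groupstats import GroupTestResult, RegressionResult, laterality_regression, omnibus_group_test
from .laterality import subject_laterality
from .modularity import DEFAULT_N_RUNS, repeated_louvain
from .montage import Montage
from .preprocess import PreprocessParams, run_preprocessing
from .simulate import SimulatedSubject


def analyze_subject(
    subject: SimulatedSubject,
    montage: Montage,
    n_runs: int = DEFAULT_N_RUNS,
    seed: int = 0,
    params: PreprocessParams | None = None,
) -> list[dict]:
    """Laterality rows (one per condition) for one subject's raw runs."""
    rest, _ = run_preprocessing(subject.runs["rest"], montage, params)
    evoked, _ = run_preprocessing(subject.runs["evoked"], montage, params)
    matrices = subject_connectivity(rest, evoked)
    meta = subject.meta
    rows = []
    for cond, mat in matrices.items():
        parts = repeated_louvain(mat, n_runs=n_runs, master_seed=seed)
        res = subject_laterality(parts, montage, meta.subject_id, cond)
        rows.append(
            {
                "subject": meta.subject_id,
                "group": meta.group,
                "side": meta.tinnitus_side,
                "condition": cond,
                "ml": res.module_laterality,
                "mml": res.modified_module_laterality,
                "n_runs": res.n_runs,
                "mean_module_count": res.mean_module_count,
                "min_module_count": int(np.min(res.module_counts)),
                "max_module_count": int(np.max(res.module_counts)),
                "thi": meta.thi,
                "loudness": meta.loudness,
                "annoyance": meta.annoyance,
                "duration_years": meta.duration_years,
                "device": meta.device,
                "hearing_asymmetry": meta.hearing_asymmetry_db,
            }
        )
    return rows


def analyze_cohort(
    subjects: list[SimulatedSubject],
    montage: Montage,
    n_runs: int = DEFAULT_N_RUNS,
    seed: int = 0,
    params: PreprocessParams | None = None,
) -> pd.DataFrame:
    """Tidy per-subject, per-condition laterality table for a cohort."""
    rows = []
    for i, subject in enumerate(subjects):
        rows.extend(analyze_subject(subject, montage, n_runs, seed + i, params))
    return pd.DataFrame(rows)


@dataclass
class GroupContrasts:
    """The study's headline comparisons for one condition."""

    condition: str
    ml_omnibus: GroupTestResult  # control vs unilateral vs bilateral on ML
    mml_omnibus: GroupTestResult | None  # left vs right vs bilateral on MML
    ml_group_means: pd.Series
    mml_side_means: pd.Series | None


def group_contrasts(table: pd.DataFrame, condition: str = "auditory") -> GroupContrasts:
    """Omnibus tests for one condition.

    Module Laterality is compared across control / unilateral / bilateral;
    Modified Module Laterality across left-sided / right-sided / bilateral
    (the sided contrast the polarity measure exists for).
    """
    sub = table[table.condition == condition]
    ml_omni = omnibus_group_test(sub.ml.to_numpy(), sub.group.to_numpy())
    ml_means = sub.groupby("group").ml.mean()

    sided = sub[(sub.group == "bilateral") | (sub.group == "unilateral")].copy()
    sided["side_group"] = np.where(
        sided.group == "bilateral", "bilateral", sided.side.astype(str) + "-sided"
    )
    mml_omni = None
    mml_means = None
    if sided.side_group.nunique() >= 2 and (sided.groupby("side_group").size() >= 2).all():
        mml_omni = omnibus_group_test(sided.mml.to_numpy(), sided.side_group.to_numpy())
        mml_means = sided.groupby("side_group").mml.mean()
    return GroupContrasts(condition, ml_omni, mml_omni, ml_means, mml_means)


def tinnitus_regression(
    table: pd.DataFrame, condition: str = "auditory", outcome: str = "ml"
) -> RegressionResult:
    """Multiple regression of a laterality outcome on clinical covariates
    within the two tinnitus groups (group dummy + THI, loudness, annoyance,
    duration, device, hearing asymmetry), with a VIF collinearity screen."""
    sub = table[(table.condition == condition) & (table.group != "control")]
    covs = pd.DataFrame(
        {
            "group_unilateral": (sub.group == "unilateral").astype(float),
            "thi": sub.thi,
            "loudness": sub.loudness,
            "annoyance": sub.annoyance,
            "duration_years": sub.duration_years,
            "device": sub.device,
            "hearing_asymmetry": sub.hearing_asymmetry,
        }
    )
    # covariates constant within this subset carry no information; drop them
    constant = [c for c in covs.columns if covs[c].nunique() == 1]
    return laterality_regression(sub[outcome].to_numpy(), covs.drop(columns=constant))
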