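"""Module Laterality statistics.

For a detected module with ``Nr`` channels in the right hemisphere, ``Nl``
in the left and ``Nt`` channels in total:

* Module Laterality (ML)            = |Nr - Nl| / Nt   in [0, 1]
* Modified Module Laterality (MML)  = (Nr - Nl) / Nt   in [-1, 1]

ML is 0 when a module is evenly split between hemispheres and 1 when it is
confined to one; MML adds polarity (positive = right-dominant, negative =
left-dominant).  Midline channels count in Nt but in neither Nr nor Nl.
Per-run values are the unweighted mean over modules; per-subject values are
the mean over repeated Louvain runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .modularity import ModulePartition
from .montage import Montage

log = logging.getLogger(__name__)


def _module_counts(module_channels, montage: Montage) -> tuple[int, int, int]:
    hemis = [montage.hemisphere(c) for c in module_channels]
    return hemis.count("right"), hemis.count("left"), len(hemis)


def module_laterality(
    partition: ModulePartition, montage: Montage, weighted: bool = False
) -> tuple[np.ndarray, float]:
    """Per-module |Nr - Nl| / Nt values and their (run-level) mean."""
    vals = []
    sizes = []
    for chans in partition.modules():
        nr, nl, nt = _module_counts(chans, montage)
        vals.append(abs(nr - nl) / nt)
        sizes.append(nt)
    vals = np.array(vals)
    mean = float(np.average(vals, weights=sizes if weighted else None))
    return vals, mean


def modified_module_laterality(
    partition: ModulePartition, montage: Montage, weighted: bool = False
) -> tuple[np.ndarray, float]:
    """Per-module (Nr - Nl) / Nt values and their (run-level) mean."""
    vals = []
    sizes = []
    for chans in partition.modules():
        nr, nl, nt = _module_counts(chans, montage)
        vals.append((nr - nl) / nt)
        sizes.append(nt)
    vals = np.array(vals)
    mean = float(np.average(vals, weights=sizes if weighted else None))
    return vals, mean


@dataclass
class LateralityResult:
    """Per-subject, per-condition laterality averaged over Louvain runs."""

    subject_id: str
    condition: str
    module_laterality: float
    modified_module_laterality: float
    n_runs: int
    module_counts: list[int]

    def __post_init__(self):
        if not 0.0 <= self.module_laterality <= 1.0 + 1e-12:
            raise ValueError("Module Laterality must lie in [0, 1]")
        if abs(self.modified_module_laterality) > 1.0 + 1e-12:
            raise ValueError("Modified Module Laterality must lie in [-1, 1]")

    @property
    def mean_module_count(self) -> float:
        return float(np.mean(self.module_counts))


def subject_laterality(
    partitions: list[ModulePartition],
    montage: Montage,
    subject_id: str = "",
    condition: str = "",
    weighted: bool = False,
) -> LateralityResult:
    """Average the two laterality measures over repeated Louvain runs.

    The subject value is the mean over runs of the per-run module means.
    Singleton modules (ML = 1 by definition) are included; their frequency
    is logged so their influence on the average is auditable.
    """
    if not partitions:
        raise ValueError("at least one partition is required")
    ml_runs, mml_runs, counts = [], [], []
    n_singletons = 0
    for p in partitions:
        _, ml = module_laterality(p, montage, weighted=weighted)
        _, mml = modified_module_laterality(p, montage, weighted=weighted)
        ml_runs.append(ml)
        mml_runs.append(mml)
        counts.append(p.n_modules)
        n_singletons += sum(1 for m in p.modules() if len(m) == 1)
    if n_singletons:
        log.info(
            "subject %s %s: %d singleton modules across %d runs",
            subject_id,
            condition,
            n_singletons,
            len(partitions),
        )
    return LateralityResult(
        subject_id=subject_id,
        condition=condition,
        module_laterality=float(np.mean(ml_runs)),
        modified_module_laterality=float(np.mean(mml_runs)),
        n_runs=len(partitions),
        module_counts=counts,
    )
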