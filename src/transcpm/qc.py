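"""Motion quality control.

Subjects are excluded when head motion exceeds a priori limits: grand mean
frame-to-frame displacement above ``grand_mean_limit`` across all tasks, or
mean displacement above ``per_task_limit`` on any single task.  Comparisons
are strict (``>``): a subject exactly at a limit is retained.  Subjects with
missing motion values are excluded rather than imputed (conservative QC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PhenotypeTable


@dataclass
class QCReport:
    retained_ids: list[str]
    exclusions: pd.DataFrame  # columns: subject_id, reason

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)


def motion_qc(
    table: PhenotypeTable,
    grand_mean_limit: float = 0.15,
    per_task_limit: float = 0.20,
) -> QCReport:
    """Apply motion exclusion thresholds; returns retained IDs and a report.

    Reasons reported per excluded subject: ``missing-motion``,
    ``grand-mean>{limit}``, ``task:{name}>{limit}`` (first offending task).
    """
    rows = []
    retained = []
    grand = table.motion_grand_mean
    per_task = table.motion_per_task
    for sid in table.subject_ids:
        g = grand.loc[sid]
        task_vals = per_task.loc[sid]
        if pd.isna(g) or task_vals.isna().any():
            rows.append((sid, "missing-motion"))
            continue
        if g > grand_mean_limit:
            rows.append((sid, f"grand-mean>{grand_mean_limit:g}"))
            continue
        over = task_vals[task_vals > per_task_limit]
        if len(over) > 0:
            rows.append((sid, f"task:{over.index[0]}>{per_task_limit:g}"))
            continue
        retained.append(sid)
    report = pd.DataFrame(rows, columns=["subject_id", "reason"])
    return QCReport(retained_ids=retained, exclusions=report)
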