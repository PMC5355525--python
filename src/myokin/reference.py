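"""Published benchmark results of the five-volunteer validation experiment.

The method was originally validated on five healthy volunteers performing
19 lip instructions five times each.  The raw recordings were never
deposited, but the per-volunteer cross-validated RMS errors (mm) of the
best static, first-order and second-order configurations were published
and serve here as reference inputs for arithmetic and statistical checks
(average improvements of the dynamic systems, and the exact one-sided
paired Wilcoxon comparison, reported as p = 0.03 in the source study).
"""

from __future__ import annotations

import numpy as np

from .evaluation import compare_models

#: Per-volunteer best cross-validated RMS error (mm), volunteers 1-5.
PER_VOLUNTEER_RMS_MM = {
    "static": np.array([2.34, 2.55, 3.02, 2.32, 2.92]),
    "first_order": np.array([2.10, 2.29, 2.64, 2.10, 2.66]),
    "second_order": np.array([2.02, 2.42, 2.58, 2.13, 2.66]),
}

#: Published "Average" column (a single shared configuration, not the mean
#: of the per-volunteer bests).
AVERAGE_RMS_MM = {"static": 2.70, "first_order": 2.43, "second_order": 2.46}


def average_improvement(order: str) -> float:
    """Static-minus-dynamic difference of the published average RMS (mm)."""
    return round(AVERAGE_RMS_MM["static"] - AVERAGE_RMS_MM[order], 10)


def static_vs_dynamic_pvalue(order: str = "first_order") -> float:
    """Exact one-sided Wilcoxon p for the published per-volunteer values."""
    return compare_models(
        PER_VOLUNTEER_RMS_MM["static"], PER_VOLUNTEER_RMS_MM[order]
    )
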