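"""Reference cohort: published per-sample lesion volumes.

Three iodine-stained tMCAO (45-min occlusion) mouse brains quantified
both by the automatic deep-learning pipeline and by manual
delineation.  These printed per-sample volumes are the input for the
cohort-summary reconciliation (their population-SD mean +/- SD pairs
are the published summary statistics: automatic total 20.33 +/- 4.48,
automatic core 2.36 +/- 1.56, manual total 21.63 +/- 4.75, manual core
3.10 +/- 1.39 mm^3).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_cohort"]

_ROWS = [
    # sample, method, total lesion (mm^3), core (mm^3)
    ("sample1", "automatic", 16.8906, 3.7642),
    ("sample2", "automatic", 17.4301, 3.1330),
    ("sample3", "automatic", 26.6595, 0.1852),
    ("sample1", "manual", 20.2020, 5.0047),
    ("sample2", "manual", 16.6580, 2.5465),
    ("sample3", "manual", 28.0330, 1.7491),
]


def reference_cohort() -> pd.DataFrame:
    """The reference tMCAO cohort as a long-format table."""
    from .reporting import make_cohort_table

    return make_cohort_table(
        [
            {
                "sample_id": s,
                "method": m,
                "total_lesion_mm3": total,
                "core_mm3": core,
            }
            for s, m, total, core in _ROWS
        ]
    )
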