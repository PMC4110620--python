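"""Variable-gene filtering ahead of the per-gene scans.

A gene enters the scan only if it varies enough across the whole cohort
(interquartile difference on the log scale) and is adequately expressed (a
minimum fraction of its log values above an intensity floor). Both cut-offs
operate on the data's own log base; quartiles use linear interpolation
(the "type 7" convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import RAW_LOG, ExpressionMatrix


@dataclass
class FilterSpec:
    iqr_min: float = 1.0
    floor_value: float = 6.6
    floor_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.iqr_min < 0:
            raise ValueError("iqr_min must be >= 0")
        if not 0 < self.floor_fraction <= 1:
            raise ValueError("floor_fraction must be in (0, 1]")


def filter_variable_genes(
    m: ExpressionMatrix, spec: FilterSpec
) -> tuple[list[str], pd.DataFrame]:
    """Keep genes with IQR >= iqr_min and > floor_fraction of values > floor.

    Returns the passing gene ids plus a per-gene diagnostics frame with the
    two statistics and per-criterion pass flags. On standard-score data the
    intensity floor is meaningless and only the IQR criterion applies.
    """
    if m.n_samples < 4:
        raise ValueError("need at least 4 samples to compute quartiles")
    arr = m.values.to_numpy()
    q1, q3 = np.percentile(arr, [25, 75], axis=1)  # linear interpolation
    iqr = q3 - q1
    frac_above = (arr > spec.floor_value).mean(axis=1)

    pass_iqr = iqr >= spec.iqr_min
    if m.scale_tag == RAW_LOG:
        pass_floor = frac_above > spec.floor_fraction
    else:
        pass_floor = np.ones(m.n_genes, dtype=bool)

    diagnostics = pd.DataFrame(
        {
            "iqr": iqr,
            "frac_above_floor": frac_above,
            "pass_iqr": pass_iqr,
            "pass_floor": pass_floor,
            "pass": pass_iqr & pass_floor,
        },
        index=m.values.index,
    )
    kept = list(diagnostics.index[diagnostics["pass"]])
    return kept, diagnostics
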