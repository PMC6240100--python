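"""Replicate collapsing and total-intensity normalization.

The quantification matrix arrives at run level. Technical replicates of
each sample are averaged arithmetically — zero-filled (undetected)
values count as true zeros — and each sample column is then normalized
to its total intensity so that per-sample loading differences cancel.
The stage order (average, then normalize) is fixed.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

from .xic import QuantMatrix


def average_technical_replicates(
    m: QuantMatrix, rep_map: Mapping[str, str] | pd.DataFrame
) -> QuantMatrix:
    """Collapse run columns to sample columns by arithmetic mean.

    ``rep_map`` maps every run id to its sample id (a dict, or a
    DataFrame with ``run_id`` and ``sample_id`` columns). Output columns
    are sorted by sample label.
    """
    if m.level != "run":
        raise ValueError(f"expected a run-level matrix, got level='{m.level}'")
    if isinstance(rep_map, pd.DataFrame):
        for col in ("run_id", "sample_id"):
            if col not in rep_map.columns:
                raise ValueError(f"replicate map missing column '{col}'")
        rep_map = dict(zip(rep_map["run_id"], rep_map["sample_id"]))
    unmapped = [r for r in m.values.columns if r not in rep_map]
    if unmapped:
        raise ValueError(f"run(s) missing from replicate map: {unmapped}")
    grouped = m.values.T.groupby([rep_map[r] for r in m.values.columns]).mean().T
    grouped = grouped[sorted(grouped.columns)]
    grouped.columns.name = None
    return QuantMatrix(grouped, level="sample")


def normalize_total_intensity(m: QuantMatrix) -> QuantMatrix:
    """Normalize each sample column to total sample intensity.

    Each column is divided by its own total and rescaled by the mean of
    all column totals, so column sums become equal while intensities stay
    on the input's scale. Zeros map to zeros; the result is invariant to
    rescaling any single input column.
    """
    if m.level != "sample":
        raise ValueError(f"expected a sample-level matrix, got level='{m.level}'")
    totals = m.values.sum(axis=0)
    zero_cols = totals.index[totals == 0].tolist()
    if zero_cols:
        raise ValueError(
            f"cannot normalize all-zero sample column(s): {zero_cols}"
        )
    scaled = m.values / totals * float(np.mean(totals.to_numpy()))
    return QuantMatrix(scaled, level="normalized")
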