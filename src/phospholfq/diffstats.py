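"""Differential phosphopeptide regulation between condition groups.

For each phosphopeptide and each comparison (mutant vs. control samples
within a treatment arm), the normalized intensities yield a log2 fold
change and a two-sided pooled-variance Student's t probability. A
peptide is called regulated when its raw P value clears a tier (0.01 or
0.05) and its |log2 fold change| exceeds 0.8 — the volcano-plot gating —
with up/down direction from the sign of the fold change. No
multiple-testing correction is applied to the differential P values: the
classification intentionally uses the raw-P + fold-change gate (the 1%
FDR of the input tables concerns identification, not this test).

Overlap of the significant sets across comparisons is summarised as a
Venn partition, with up- and down-regulated peptides partitioned
separately as well as together.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .xic import QuantMatrix

logger = logging.getLogger(__name__)

SIG_NS = "ns"
SIG_P05 = "sig_p05"
SIG_P01 = "sig_p01"

#: Smallest probability the test reports; used for zero-variance groups
#: with unequal means, where the pooled t statistic is unbounded.
MIN_P = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class Comparison:
    """One two-group contrast: ``group_b`` (mutant) over ``group_a`` (control)."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_a", tuple(self.group_a))
        object.__setattr__(self, "group_b", tuple(self.group_b))
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError(
                f"comparison '{self.name}': each group needs at least 2 samples"
            )
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"comparison '{self.name}': groups overlap")


def students_t(a, b) -> tuple[float, float]:
    """Two-sample pooled-variance Student's t test (two-sided).

    Returns ``(t, p)`` with ``t = (mean(a) - mean(b)) / se`` on
    ``len(a) + len(b) - 2`` degrees of freedom. Degenerate inputs:
    identical constant groups give ``(0, 1)``; zero-variance groups with
    unequal means give an infinite t and the smallest representable
    positive probability, with a logged warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values for a t test")
    n1, n2 = a.size, b.size
    d = float(a.mean() - b.mean())
    sp2 = (
        (n1 - 1) * float(a.var(ddof=1)) + (n2 - 1) * float(b.var(ddof=1))
    ) / (n1 + n2 - 2)
    if sp2 == 0.0:
        if d == 0.0:
            return 0.0, 1.0
        logger.warning("zero within-group variance with unequal means")
        return math.copysign(math.inf, d), MIN_P
    t = d / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(stats.t.sf(abs(t), df=n1 + n2 - 2))
    return t, max(min(p, 1.0), MIN_P)


def epsilon_from_matrix(values: pd.DataFrame | np.ndarray) -> float:
    """Fold-change pseudocount: half the smallest positive matrix value.

    Keeps log2 fold changes finite in the presence of zero-filled
    intensities while scaling with the data.
    """
    arr = np.asarray(values, dtype=float)
    pos = arr[arr > 0]
    if pos.size == 0:
        raise ValueError("matrix has no positive values; epsilon undefined")
    return float(pos.min()) / 2.0


def log2_fold_change(a, b, epsilon: float = 0.0) -> float:
    """log2 of mean(b) over mean(a), with pseudocount ``epsilon``.

    Both means zero is a degenerate case: the fold change is reported as
    0 with a logged warning.
    """
    ma = float(np.mean(np.asarray(a, dtype=float)))
    mb = float(np.mean(np.asarray(b, dtype=float)))
    if ma < 0 or mb < 0:
        raise ValueError("intensities must be non-negative")
    if ma == 0.0 and mb == 0.0:
        logger.warning("both group means are zero; log2 fold change set to 0")
        return 0.0
    return float(np.log2(mb + epsilon) - np.log2(ma + epsilon))


def classify_regulation(
    log2fc: float,
    p: float,
    fc_threshold: float = 0.8,
    p05: float = 0.05,
    p01: float = 0.01,
) -> tuple[str, str]:
    """Volcano significance class and direction.

    ``sig_p01`` for p < ``p01`` and |log2fc| > ``fc_threshold``;
    ``sig_p05`` for ``p01`` <= p < ``p05`` at the same fold-change gate;
    ``ns`` otherwise. The fold-change threshold is taken on the log2
    axis. Direction is ``up``/``down`` by the sign of log2fc for
    significant peptides, ``none`` otherwise.
    """
    if min(fc_threshold, p05, p01) <= 0:
        raise ValueError("thresholds must be positive")
    if abs(log2fc) > fc_threshold and p < p05:
        sig = SIG_P01 if p < p01 else SIG_P05
        return sig, ("up" if log2fc > 0 else "down")
    return SIG_NS, "none"


def volcano_coords(log2fc: float, p: float) -> tuple[float, float]:
    """Volcano-plot coordinates: ``(log2fc, -log10(p))``."""
    if p <= 0:
        raise ValueError(f"invalid parameter 'p': must be in (0, 1], got {p}")
    return float(log2fc), float(-np.log10(p))


def venn_partition(sets: Mapping) -> pd.DataFrame:
    """Exclusive region counts of 2–3 named sets.

    Returns one row per non-empty region combination (``2**n - 1`` rows)
    with the member names, the count of elements belonging to exactly
    those sets, and the percentage relative to the union. Region counts
    always sum to the union cardinality.
    """
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("venn partition supports 2 or 3 sets")
    sets = {k: set(v) for k, v in sets.items()}
    union = set().union(*sets.values())
    rows = []
    for r in range(1, len(names) + 1):
        for members in combinations(names, r):
            inside = set.intersection(*(sets[m] for m in members))
            outside = set().union(*(sets[m] for m in names if m not in members)) \
                if len(members) < len(names) else set()
            exclusive = inside - outside
            rows.append(
                {
                    "region": "&".join(members),
                    "n_sets": r,
                    "count": len(exclusive),
                    "percent": 100.0 * len(exclusive) / len(union) if union else 0.0,
                }
            )
    return pd.DataFrame(rows)


def run_comparison(
    m: QuantMatrix,
    comparison: Comparison,
    fc_threshold: float = 0.8,
    p05: float = 0.05,
    p01: float = 0.01,
    epsilon: float | None = None,
) -> pd.DataFrame:
    """Differential results of one comparison over a normalized matrix.

    Returns a DataFrame with one row per peptide: ``peptide_key,
    log2fc, t, p_value, sig_class, direction``.
    """
    if m.level != "normalized":
        raise ValueError(f"expected a normalized matrix, got level='{m.level}'")
    missing = [s for s in comparison.group_a + comparison.group_b
               if s not in m.values.columns]
    if missing:
        raise ValueError(
            f"comparison '{comparison.name}': sample(s) not in matrix: {missing}"
        )
    if epsilon is None:
        epsilon = epsilon_from_matrix(m.values)
    a = m.values[list(comparison.group_a)].to_numpy()
    b = m.values[list(comparison.group_b)].to_numpy()
    rows = []
    for i, key in enumerate(m.values.index):
        t, p = students_t(a[i], b[i])
        lfc = log2_fold_change(a[i], b[i], epsilon)
        sig, direction = classify_regulation(lfc, p, fc_threshold, p05, p01)
        rows.append(
            {
                "peptide_key": key,
                "log2fc": lfc,
                "t": t,
                "p_value": p,
                "sig_class": sig,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)


def comparisons_from_design(
    samples: pd.DataFrame,
    control_genotype: str | None = None,
) -> list[Comparison]:
    """One mutant-vs-control comparison per treatment arm.

    ``samples`` needs ``sample_id``, ``genotype`` and ``treatment``
    columns; the control genotype defaults to the lexicographically
    first if not given (the default design's labels sort control first).
    """
    for col in ("sample_id", "genotype", "treatment"):
        if col not in samples.columns:
            raise ValueError(f"sample table missing column '{col}'")
    genotypes = sorted(samples["genotype"].unique())
    if len(genotypes) != 2:
        raise ValueError(f"expected exactly 2 genotypes, found {genotypes}")
    control = control_genotype or genotypes[0]
    if control not in genotypes:
        raise ValueError(f"control genotype '{control}' not in {genotypes}")
    mutant = next(g for g in genotypes if g != control)
    comparisons = []
    for treatment in samples["treatment"].unique():
        sub = samples[samples["treatment"] == treatment]
        comparisons.append(
            Comparison(
                name=str(treatment),
                group_a=tuple(sub.loc[sub["genotype"] == control, "sample_id"]),
                group_b=tuple(sub.loc[sub["genotype"] == mutant, "sample_id"]),
            )
        )
    return comparisons


def heatmap_foldchanges(
    m: QuantMatrix,
    comparisons: list[Comparison],
    peptide_subset: list[str],
    epsilon: float | None = None,
    linear: bool = False,
) -> pd.DataFrame:
    """Peptide × comparison fold-change matrix for heatmap display.

    Cell (i, j) is the log2 fold change of peptide i between comparison
    j's mutant and control groups (``linear=True`` returns the plain
    mean fold-change ratio instead). Rows follow ``peptide_subset``
    order; columns follow the comparison order.
    """
    if m.level != "normalized":
        raise ValueError(f"expected a normalized matrix, got level='{m.level}'")
    unknown = [k for k in peptide_subset if k not in m.values.index]
    if unknown:
        raise ValueError(f"unknown peptide key(s): {unknown}")
    if epsilon is None and len(peptide_subset) > 0:
        epsilon = epsilon_from_matrix(m.values)
    data = np.zeros((len(peptide_subset), len(comparisons)))
    for j, comp in enumerate(comparisons):
        a = m.values.loc[peptide_subset, list(comp.group_a)].to_numpy()
        b = m.values.loc[peptide_subset, list(comp.group_b)].to_numpy()
        for i in range(len(peptide_subset)):
            data[i, j] = log2_fold_change(a[i], b[i], epsilon)
    if linear:
        data = np.power(2.0, data)
    return pd.DataFrame(
        data,
        index=pd.Index(peptide_subset, name="peptide_key"),
        columns=[c.name for c in comparisons],
    )

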