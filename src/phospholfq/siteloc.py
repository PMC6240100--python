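"""Phosphosite-assignment confidence via delta scores.

A phosphopeptide with m candidate residues (Ser/Thr/Tyr) and k phosphate
groups has C(m, k) positional isoforms. The search engine scores each
isoform; the delta score — best minus second-best score — quantifies how
confidently the sites are localized. Scores are consumed from the
identification table (database searching itself is upstream of this
package); this module enumerates the isoforms and computes the deltas.

Peptides with a single possible isoform are unambiguous; by default
their delta equals their own score (maximal confidence), configurable to
a sentinel instead. No delta-score filter is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import pandas as pd

PHOSPHO_RESIDUES = "STY"


@dataclass(frozen=True)
class SiteAssignment:
    """One positional isoform of a phosphopeptide.

    Positions are 1-based residue indices into ``sequence``.
    """

    sequence: str
    candidate_positions: tuple[int, ...]
    assigned_positions: tuple[int, ...]
    score: float | None = None

    def __post_init__(self) -> None:
        if not set(self.assigned_positions) <= set(self.candidate_positions):
            raise ValueError("assigned positions must be candidate S/T/Y residues")


def candidate_sites(sequence: str) -> tuple[int, ...]:
    """1-based positions of phosphorylatable residues (S, T, Y)."""
    return tuple(i + 1 for i, aa in enumerate(sequence) if aa in PHOSPHO_RESIDUES)


def enumerate_site_isoforms(sequence: str, n_phospho: int) -> list[SiteAssignment]:
    """All C(m, n_phospho) site assignments, in deterministic order.

    Assignments are ordered lexicographically by position tuple. With
    ``n_phospho=0`` the single empty assignment is returned.
    """
    if n_phospho < 0:
        raise ValueError(f"invalid parameter 'n_phospho': must be >= 0, got {n_phospho}")
    sites = candidate_sites(sequence)
    if n_phospho > len(sites):
        raise ValueError(
            f"n_phospho={n_phospho} exceeds the {len(sites)} candidate "
            f"S/T/Y residues of '{sequence}'"
        )
    return [
        SiteAssignment(sequence, sites, chosen)
        for chosen in combinations(sites, n_phospho)
    ]


def n_site_isoforms(sequence: str, n_phospho: int) -> int:
    """Isoform count C(m, n_phospho) without materialising assignments."""
    sites = candidate_sites(sequence)
    if n_phospho > len(sites):
        raise ValueError(
            f"n_phospho={n_phospho} exceeds the {len(sites)} candidate "
            f"S/T/Y residues of '{sequence}'"
        )
    return comb(len(sites), n_phospho)


def delta_score(
    scores, single_isoform_sentinel: float | None = None
) -> float:
    """Best minus second-best isoform score.

    ``scores`` must be sorted in descending order. For a single-isoform
    peptide the site is unambiguous and the delta defaults to the score
    itself; pass ``single_isoform_sentinel`` to emit a fixed value
    instead.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("delta score needs at least one isoform score")
    if any(scores[i] < scores[i + 1] for i in range(len(scores) - 1)):
        raise ValueError("isoform scores must be sorted in descending order")
    if len(scores) == 1:
        return float(scores[0]) if single_isoform_sentinel is None \
            else float(single_isoform_sentinel)
    return float(scores[0] - scores[1])


def annotate_delta_scores(
    ids: pd.DataFrame,
    scores_column: str = "isoform_scores",
    single_isoform_sentinel: float | None = None,
) -> pd.DataFrame:
    """Add a ``delta_score`` column from semicolon-separated isoform scores.

    Rows without isoform scores (missing column entry) get a missing
    delta. Returns a copy; the input is unchanged.
    """
    if scores_column not in ids.columns:
        raise ValueError(f"identification table missing column '{scores_column}'")
    out = ids.copy()

    def _delta(cell) -> float:
        if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
            return float("nan")
        scores = [float(tok) for tok in str(cell).split(";") if tok != ""]
        return delta_score(scores, single_isoform_sentinel)

    out["delta_score"] = out[scores_column].map(_delta)
    return out
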