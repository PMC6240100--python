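"""Extracted-ion-chromatogram quantification.

Label-free quantification of identified phosphopeptides: for every
peptide and every run, an XIC is built by summing, in each MS1 scan
within ±``rt_tol`` minutes of the peptide's reference retention time, the
centroid intensities inside a ±``ppm_tol`` ppm window around the target
m/z. The trapezoidal area of the trace is the peptide's intensity in that
run. Every (peptide, run) cell is filled — a peptide undetectable in a
run gets intensity 0 — so the resulting matrix is complete
(match-between-runs with zero-fill).

Default tolerances are ±7 ppm and ±2 min.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns an identification table must carry.
ID_COLUMNS = (
    "peptide_key",
    "sequence",
    "phospho_positions",
    "charge",
    "mz",
    "rt",
    "score",
    "fdr",
)


@dataclass
class RunSpectra:
    """One LC-MS run: ordered centroided MS1 scans.

    ``scan_rts`` are retention times in minutes, strictly increasing.
    ``scans[i]`` is a ``(mz, intensity)`` pair of 1-D arrays for scan
    ``i``, with m/z strictly increasing and intensities non-negative.
    """

    run_id: str
    sample_id: str
    tech_rep: int
    scan_rts: np.ndarray
    scans: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scan_rts = np.asarray(self.scan_rts, dtype=float)
        if self.scan_rts.size != len(self.scans):
            raise ValueError(
                f"run '{self.run_id}': {self.scan_rts.size} scan times for "
                f"{len(self.scans)} scans"
            )
        if self.scan_rts.size > 1 and not np.all(np.diff(self.scan_rts) > 0):
            raise ValueError(f"run '{self.run_id}': scan times not strictly increasing")

    @property
    def n_scans(self) -> int:
        return int(self.scan_rts.size)

    def validate_peaks(self) -> None:
        """Check per-scan invariants (sorted m/z, non-negative intensity)."""
        for i, (mz, inten) in enumerate(self.scans):
            if mz.size > 1 and not np.all(np.diff(mz) > 0):
                raise ValueError(
                    f"run '{self.run_id}' scan {i}: m/z not strictly increasing"
                )
            if np.any(inten < 0):
                raise ValueError(
                    f"run '{self.run_id}' scan {i}: negative intensity"
                )


@dataclass
class XICTrace:
    """Extracted ion chromatogram of one peptide in one run."""

    peptide_key: str
    run_id: str
    rts: np.ndarray
    intensities: np.ndarray
    area: float

    @property
    def n_points(self) -> int:
        return int(self.rts.size)


@dataclass
class QuantMatrix:
    """Complete peptide × column intensity matrix.

    ``values`` is a DataFrame indexed by ``peptide_key``; columns are run
    ids (``level='run'``) or sample ids (``level='sample'`` /
    ``'normalized'``). Every cell is present and non-negative; zeros mean
    the peptide gave no detectable signal.
    """

    values: pd.DataFrame
    level: str

    LEVELS = ("run", "sample", "normalized")

    def __post_init__(self) -> None:
        if self.level not in self.LEVELS:
            raise ValueError(f"unknown matrix level '{self.level}'")
        if self.values.isna().any().any():
            raise ValueError("quantification matrix must be complete (no NaN)")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("quantification matrix must be non-negative")

    @property
    def n_cells(self) -> int:
        return int(self.values.size)


def matrix_cell_count(n_peptides: int, n_samples: int, n_technical: int) -> int:
    """Number of data points in a run-level quantification matrix.

    Cross-run quantification fills every cell, so the count is exactly
    ``n_peptides * n_samples * n_technical``.
    """
    if min(n_peptides, n_samples, n_technical) < 0:
        raise ValueError("counts must be non-negative")
    return n_peptides * n_samples * n_technical


def ppm_window(mz: float, ppm_tol: float) -> tuple[float, float]:
    """Symmetric relative mass window ``mz * (1 ± ppm_tol * 1e-6)``."""
    if mz <= 0:
        raise ValueError(f"invalid parameter 'mz': must be positive, got {mz}")
    if ppm_tol < 0:
        raise ValueError(f"invalid parameter 'ppm_tol': must be >= 0, got {ppm_tol}")
    delta = mz * ppm_tol * 1e-6
    return mz - delta, mz + delta


def integrate_area(rts: np.ndarray, intensities: np.ndarray) -> float:
    """Trapezoidal XIC area over retention time (intensity · minutes).

    Empty traces and single points integrate to 0 (a width-less peak has
    no defined area).
    """
    rts = np.asarray(rts, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if rts.size != intensities.size:
        raise ValueError("rt and intensity arrays differ in length")
    if rts.size < 2:
        return 0.0
    if not np.all(np.diff(rts) > 0):
        raise ValueError("XIC points must be strictly ordered by retention time")
    return float(np.trapezoid(intensities, rts))


def _scan_window_sum(mz: np.ndarray, inten: np.ndarray, lo: float, hi: float) -> float:
    """Sum of centroid intensities with lo <= m/z <= hi (binary search)."""
    i = np.searchsorted(mz, lo, side="left")
    j = np.searchsorted(mz, hi, side="right")
    if j <= i:
        return 0.0
    return float(inten[i:j].sum())


def extract_xic(
    run: RunSpectra,
    peptide_key: str,
    mz: float,
    rt_ref: float,
    ppm_tol: float = 7.0,
    rt_tol: float = 2.0,
) -> XICTrace:
    """Build the XIC of one peptide in one run.

    One point per MS1 scan within ±``rt_tol`` min of ``rt_ref``; the
    point's intensity is the summed centroid signal inside the ppm
    window. Scans with no matching centroid contribute 0 — absence of
    signal is a valid all-zero trace, never an error.
    """
    lo_mz, hi_mz = ppm_window(mz, ppm_tol)
    if rt_tol < 0:
        raise ValueError(f"invalid parameter 'rt_tol': must be >= 0, got {rt_tol}")
    i0 = int(np.searchsorted(run.scan_rts, rt_ref - rt_tol, side="left"))
    i1 = int(np.searchsorted(run.scan_rts, rt_ref + rt_tol, side="right"))
    rts = run.scan_rts[i0:i1]
    intensities = np.array(
        [
            _scan_window_sum(run.scans[i][0], run.scans[i][1], lo_mz, hi_mz)
            for i in range(i0, i1)
        ],
        dtype=float,
    )
    area = integrate_area(rts, intensities)
    return XICTrace(peptide_key, run.run_id, rts, intensities, area)


def collapse_identifications(ids: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-run identification rows to one row per peptide key.

    A peptide identified in several runs carries one retention time per
    identification; the cross-run extraction anchor ``rt_ref`` is the
    median of those observed times. Sequence, modification positions,
    charge and theoretical m/z must agree across rows of a key; the best
    (maximal) search score and the smallest FDR are retained.
    """
    missing = [c for c in ID_COLUMNS if c not in ids.columns]
    if missing:
        raise ValueError(f"identification table missing column(s): {missing}")
    rows = []
    for key, grp in ids.groupby("peptide_key", sort=True):
        for col in ("sequence", "charge", "mz", "phospho_positions"):
            if grp[col].nunique() > 1:
                raise ValueError(
                    f"peptide_key '{key}': conflicting values in column '{col}'"
                )
        row = {
            "peptide_key": key,
            "sequence": grp["sequence"].iloc[0],
            "phospho_positions": grp["phospho_positions"].iloc[0],
            "charge": grp["charge"].iloc[0],
            "mz": grp["mz"].iloc[0],
            "rt_ref": float(grp["rt"].median()),
            "score": float(grp["score"].max()),
            "fdr": float(grp["fdr"].min()),
        }
        for extra in ("isoform_scores", "delta_score"):
            if extra in grp.columns:
                row[extra] = grp[extra].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def quantify_all(
    runs: list[RunSpectra],
    ids: pd.DataFrame,
    ppm_tol: float = 7.0,
    rt_tol: float = 2.0,
) -> QuantMatrix:
    """Quantify every identified peptide in every run (zero-filled).

    ``ids`` must carry one row per unique ``peptide_key`` with an
    ``rt_ref`` column (see :func:`collapse_identifications`). The result
    is a complete |peptides| × |runs| matrix of XIC areas; cells with no
    signal inside the extraction windows are exactly 0. Rows are sorted
    by peptide key and columns by run id.
    """
    if "rt_ref" not in ids.columns:
        raise ValueError(
            "identification table lacks 'rt_ref'; collapse per-run "
            "identifications with collapse_identifications() first"
        )
    if ids["peptide_key"].duplicated().any():
        dupes = ids.loc[ids["peptide_key"].duplicated(), "peptide_key"].tolist()
        raise ValueError(f"duplicate peptide_key value(s): {sorted(set(dupes))}")
    if rt_tol < 0:
        raise ValueError(f"invalid parameter 'rt_tol': must be >= 0, got {rt_tol}")

    ids = ids.sort_values("peptide_key").reset_index(drop=True)
    keys = ids["peptide_key"].to_numpy()
    mzs = ids["mz"].to_numpy(dtype=float)
    rt_refs = ids["rt_ref"].to_numpy(dtype=float)
    lo_mzs = np.array([ppm_window(m, ppm_tol)[0] for m in mzs])
    hi_mzs = np.array([ppm_window(m, ppm_tol)[1] for m in mzs])

    run_ids = [r.run_id for r in runs]
    if len(set(run_ids)) != len(run_ids):
        raise ValueError("duplicate run_id among runs")

    areas = np.zeros((len(keys), len(runs)))
    for j, run in enumerate(runs):
        if run.n_scans == 0:
            logger.warning(
                "run '%s' contains no scans; its column is all zeros", run.run_id
            )
            continue
        areas[:, j] = _quantify_run(run, lo_mzs, hi_mzs, rt_refs, rt_tol)

    frame = pd.DataFrame(areas, index=pd.Index(keys, name="peptide_key"), columns=run_ids)
    frame = frame[sorted(run_ids)]
    return QuantMatrix(frame, level="run")


def _quantify_run(
    run: RunSpectra,
    lo_mzs: np.ndarray,
    hi_mzs: np.ndarray,
    rt_refs: np.ndarray,
    rt_tol: float,
) -> np.ndarray:
    """XIC areas of all peptides in one run.

    Scans are visited once; for each scan the per-peptide window sums are
    computed with a vectorised binary search over the scan's centroids.
    Equivalent to calling :func:`extract_xic` per peptide.
    """
    n_pep = lo_mzs.size
    rts = run.scan_rts
    start = np.searchsorted(rts, rt_refs - rt_tol, side="left")
    stop = np.searchsorted(rts, rt_refs + rt_tol, side="right")
    traces = np.zeros((n_pep, run.n_scans))
    for s in range(run.n_scans):
        active = np.nonzero((start <= s) & (s < stop))[0]
        if active.size == 0:
            continue
        mz, inten = run.scans[s]
        if mz.size == 0:
            continue
        cum = np.concatenate(([0.0], np.cumsum(inten)))
        i = np.searchsorted(mz, lo_mzs[active], side="left")
        j = np.searchsorted(mz, hi_mzs[active], side="right")
        traces[active, s] = cum[j] - cum[i]
    areas = np.zeros(n_pep)
    for p in range(n_pep):
        if stop[p] - start[p] >= 2:
            seg = slice(start[p], stop[p])
            areas[p] = np.trapezoid(traces[p, seg], rts[seg])
    return areas
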