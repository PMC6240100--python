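"""Synthetic LC-MS phosphoproteomics study generator.

Produces a complete study — centroided MS1 runs, an identification
table, and the ground truth behind them — with the structure the
quantification pipeline assumes: a factorial genotype × treatment ×
replicate design, Gaussian elution peaks of ~30 s base width sampled at
the instrument duty cycle, log-normal biological and technical
variability, per-run mass and retention-time errors, Bernoulli dropout
of whole peptide-run observations, and a truly regulated peptide subset
carrying a known log2 fold change between genotypes.

Each peptide is simulated as a single monoisotopic centroid (no isotope
envelope): XIC extraction targets one m/z, so one peak per species keeps
the truth exactly recoverable. The Gaussian base width is interpreted as
4σ, giving the closed-form elution area ``amplitude * σ * sqrt(2π)``
used by the oracle checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import StudyDesign, TruthParams
from .xic import RunSpectra

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PHOSPHO_RESIDUES = "STY"

# Gaussian support kept out to 5σ; beyond that the density is < 4e-6 of
# the apex and contributes nothing at float64 XIC precision.
_PEAK_SUPPORT_SIGMAS = 5.0


@dataclass
class GroundTruth:
    """Truth tables of one synthetic study.

    peptides
        One row per peptide: ``peptide_key, sequence, phospho_positions,
        charge, mz, rt_true, base_abundance, regulated, true_log2fc``.
    abundances
        Peptide × sample true abundance (biological variability and the
        genotype effect applied; technical factors excluded).
    presence
        Boolean peptide × run table: False where the peptide dropped out
        of that acquisition entirely.
    runs
        The design's run table (run → sample → condition mapping).
    """

    peptides: pd.DataFrame
    abundances: pd.DataFrame
    presence: pd.DataFrame
    runs: pd.DataFrame

    def regulated_keys(self) -> list[str]:
        return self.peptides.loc[self.peptides["regulated"], "peptide_key"].tolist()


def simulate_peak(
    amplitude: float,
    rt_center: float,
    base_width_s: float,
    scan_times: np.ndarray,
) -> np.ndarray:
    """Gaussian elution profile evaluated at the given scan times.

    The base width (seconds) is 4σ, so a 30 s base gives σ = 7.5 s. At
    the peak centre the value equals ``amplitude``; at half a base width
    from the centre it has fallen to ``amplitude * exp(-2)``.
    """
    if amplitude < 0:
        raise ValueError(f"invalid parameter 'amplitude': must be >= 0, got {amplitude}")
    if base_width_s <= 0:
        raise ValueError(
            f"invalid parameter 'base_width_s': must be > 0, got {base_width_s}"
        )
    scan_times = np.asarray(scan_times, dtype=float)
    if scan_times.size == 0:
        return np.empty(0)
    sigma_min = base_width_s / 4.0 / 60.0
    z = (scan_times - rt_center) / sigma_min
    return amplitude * np.exp(-0.5 * z * z)


def peak_area_closed_form(amplitude: float, base_width_s: float) -> float:
    """Exact area (intensity · minutes) of a simulated Gaussian peak."""
    sigma_min = base_width_s / 4.0 / 60.0
    return amplitude * sigma_min * np.sqrt(2.0 * np.pi)


def _random_sequence(rng: np.random.Generator, n_phospho: int) -> tuple[str, tuple[int, ...]]:
    """Tryptic-like peptide with >= n_phospho S/T/Y residues.

    Returns the sequence and the 1-based positions of the phosphorylated
    residues.
    """
    length = int(rng.integers(8, 25))
    body = rng.choice(list(AMINO_ACIDS), size=length - 1)
    seq = "".join(body) + ("K" if rng.random() < 0.5 else "R")
    sites = [i for i, aa in enumerate(seq) if aa in PHOSPHO_RESIDUES]
    while len(sites) < n_phospho:
        pos = int(rng.integers(0, length - 1))
        seq = seq[:pos] + str(rng.choice(list(PHOSPHO_RESIDUES))) + seq[pos + 1:]
        sites = [i for i, aa in enumerate(seq) if aa in PHOSPHO_RESIDUES]
    chosen = rng.choice(len(sites), size=n_phospho, replace=False)
    positions = tuple(sorted(sites[int(c)] + 1 for c in chosen))
    return seq, positions


def _make_peptides(
    design: StudyDesign, truth: TruthParams, rng: np.random.Generator
) -> pd.DataFrame:
    n = truth.n_peptides
    lo_mz, hi_mz = design.mz_range
    # keep targets clear of the scan-window edges so the ±ppm extraction
    # window always lies inside the instrument range
    margin = hi_mz * 1e-5
    mz = rng.uniform(lo_mz + margin, hi_mz - margin, size=n)
    # peaks elute wholly inside the gradient, jitter included
    edge = truth.peak_base_width_s / 60.0 + 4.0 * truth.rt_jitter_min_sd
    edge = min(edge, 0.45 * design.gradient_minutes)
    rt_true = rng.uniform(edge, design.gradient_minutes - edge, size=n)
    lo_ab, hi_ab = truth.abundance_log10_range
    base_abundance = 10.0 ** rng.uniform(lo_ab, hi_ab, size=n)

    n_reg = int(round(truth.frac_regulated * n))
    regulated = np.zeros(n, dtype=bool)
    reg_idx = rng.choice(n, size=n_reg, replace=False)
    regulated[reg_idx] = True
    true_lfc = np.zeros(n)
    # alternate sign so both up- and down-regulation are represented
    signs = np.where(np.arange(n_reg) % 2 == 0, 1.0, -1.0)
    true_lfc[np.sort(reg_idx)] = signs * truth.effect_log2fc

    rows = []
    for i in range(n):
        n_phospho = 1 if rng.random() < 0.8 else 2
        seq, positions = _random_sequence(rng, n_phospho)
        charge = int(rng.choice([2, 3], p=[0.7, 0.3]))
        key = f"{seq}/p{'.'.join(map(str, positions))}/{charge}+"
        rows.append(
            {
                "peptide_key": key,
                "sequence": seq,
                "phospho_positions": ";".join(map(str, positions)),
                "charge": charge,
                "mz": mz[i],
                "rt_true": rt_true[i],
                "base_abundance": base_abundance[i],
                "regulated": bool(regulated[i]),
                "true_log2fc": true_lfc[i],
            }
        )
    frame = pd.DataFrame(rows)
    if frame["peptide_key"].duplicated().any():
        # vanishing probability at realistic n; disambiguate deterministically
        dup = frame["peptide_key"].duplicated(keep=False)
        frame.loc[dup, "peptide_key"] = [
            f"{k}#{i}" for i, k in frame.loc[dup, "peptide_key"].items()
        ]
    return frame


def simulate_abundances(
    design: StudyDesign, truth: TruthParams, seed: int
) -> GroundTruth:
    """Generate the statistical layer of a study without raw spectra.

    Everything downstream of XIC integration — per-sample abundances,
    presence/dropout, regulation truth — with identical structure to the
    full simulation. Suited to statistical experiments (null calibration,
    power) where the chromatographic layer adds nothing.
    """
    ss = np.random.SeedSequence(seed)
    rng_pep, rng_bio, rng_tech = [np.random.default_rng(s) for s in ss.spawn(3)]
    peptides = _make_peptides(design, truth, rng_pep)
    samples = design.samples()
    runs = design.runs()

    sigma_bio = float(np.sqrt(np.log1p(truth.biological_cv**2)))
    mutant_label = design.genotypes[-1]
    effect = np.where(
        samples["genotype"].to_numpy() == mutant_label, 1.0, 0.0
    )  # (n_samples,)
    base = peptides["base_abundance"].to_numpy()[:, None]
    lfc = peptides["true_log2fc"].to_numpy()[:, None]
    noise = rng_bio.normal(0.0, sigma_bio, size=(len(peptides), len(samples)))
    abund = base * np.power(2.0, lfc * effect[None, :]) * np.exp(noise)
    abundances = pd.DataFrame(
        abund,
        index=pd.Index(peptides["peptide_key"], name="peptide_key"),
        columns=samples["sample_id"].tolist(),
    )

    present = rng_tech.random(size=(len(peptides), len(runs))) >= truth.dropout_prob
    # every peptide must be identifiable somewhere: rescue all-absent rows
    # into their first run, deterministically
    lost = ~present.any(axis=1)
    present[lost, 0] = True
    presence = pd.DataFrame(
        present,
        index=abundances.index.copy(),
        columns=runs["run_id"].tolist(),
    )
    return GroundTruth(peptides, abundances, presence, runs)


def generate_study(
    design: StudyDesign | None = None,
    truth: TruthParams | None = None,
    seed: int = 0,
) -> tuple[list[RunSpectra], pd.DataFrame, GroundTruth]:
    """Simulate a full study: raw MS1 runs, identifications, truth.

    Returns one :class:`~phospholfq.xic.RunSpectra` per (sample,
    technical replicate), an identification table with one row per
    (peptide, run) observation, and the :class:`GroundTruth`. The same
    seed reproduces all three bit-identically.
    """
    design = design or StudyDesign()
    truth = truth or TruthParams()
    gt = simulate_abundances(design, truth, seed)

    run_seeds = np.random.SeedSequence((seed, 1)).spawn(len(gt.runs))
    id_rng = np.random.default_rng((seed, 2))

    scan_rts = np.arange(0.0, design.gradient_minutes, design.scan_interval_s / 60.0)
    sigma_tech = float(np.sqrt(np.log1p(truth.technical_cv**2)))
    pep = gt.peptides
    mz_theory = pep["mz"].to_numpy()
    rt_true = pep["rt_true"].to_numpy()
    keys = pep["peptide_key"].to_numpy()

    runs_out: list[RunSpectra] = []
    id_rows: list[dict] = []
    for k, run in enumerate(gt.runs.itertuples(index=False)):
        rng = np.random.default_rng(run_seeds[k])
        present = gt.presence[run.run_id].to_numpy()
        sample_abund = gt.abundances[run.sample_id].to_numpy()
        tech = np.exp(rng.normal(0.0, sigma_tech, size=len(pep)))
        ppm_err = rng.normal(0.0, truth.mz_error_ppm_sd, size=len(pep))
        rt_err = rng.normal(0.0, truth.rt_jitter_min_sd, size=len(pep))
        mz_obs = mz_theory * (1.0 + ppm_err * 1e-6)
        rt_obs = rt_true + rt_err
        amplitude = sample_abund * tech

        spectra = _assemble_run_spectra(
            scan_rts,
            mz_obs[present],
            rt_obs[present],
            amplitude[present],
            truth,
            design,
            rng,
        )
        runs_out.append(
            RunSpectra(
                run_id=run.run_id,
                sample_id=run.sample_id,
                tech_rep=int(run.tech_rep),
                scan_rts=scan_rts,
                scans=spectra,
            )
        )

        for p in np.nonzero(present)[0]:
            score = float(id_rng.uniform(25.0, 100.0))
            n_iso = _n_site_isoforms(pep["sequence"].iloc[p],
                                     pep["phospho_positions"].iloc[p])
            iso_scores = _isoform_scores(score, n_iso, id_rng)
            id_rows.append(
                {
                    "peptide_key": keys[p],
                    "sequence": pep["sequence"].iloc[p],
                    "phospho_positions": pep["phospho_positions"].iloc[p],
                    "charge": int(pep["charge"].iloc[p]),
                    "mz": mz_theory[p],
                    "rt": rt_obs[p],
                    "score": score,
                    "fdr": float(id_rng.uniform(0.0, 0.01)),
                    "run_id": run.run_id,
                    "isoform_scores": ";".join(f"{s:.2f}" for s in iso_scores),
                }
            )

    ids = pd.DataFrame(id_rows)
    return runs_out, ids, gt


def _n_site_isoforms(sequence: str, phospho_positions: str) -> int:
    from math import comb

    k = len(phospho_positions.split(";")) if phospho_positions else 0
    m = sum(1 for aa in sequence if aa in PHOSPHO_RESIDUES)
    return comb(m, k)


def _isoform_scores(best: float, n_iso: int, rng: np.random.Generator) -> list[float]:
    """Descending per-isoform search scores, best first."""
    if n_iso <= 1:
        return [best]
    others = best - rng.uniform(2.0, 40.0, size=n_iso - 1)
    others = np.clip(others, 0.0, None)
    return [best] + sorted(others, reverse=True)


def _assemble_run_spectra(
    scan_rts: np.ndarray,
    mz_obs: np.ndarray,
    rt_obs: np.ndarray,
    amplitude: np.ndarray,
    truth: TruthParams,
    design: StudyDesign,
    rng: np.random.Generator,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Build per-scan centroid lists from peptide peaks plus background."""
    n_scans = scan_rts.size
    sigma_min = truth.peak_base_width_s / 4.0 / 60.0
    half_support = _PEAK_SUPPORT_SIGMAS * sigma_min

    scan_idx_parts: list[np.ndarray] = []
    mz_parts: list[np.ndarray] = []
    int_parts: list[np.ndarray] = []
    for p in range(mz_obs.size):
        i0 = int(np.searchsorted(scan_rts, rt_obs[p] - half_support, side="left"))
        i1 = int(np.searchsorted(scan_rts, rt_obs[p] + half_support, side="right"))
        if i1 <= i0:
            continue
        profile = simulate_peak(
            amplitude[p], rt_obs[p], truth.peak_base_width_s, scan_rts[i0:i1]
        )
        scan_idx_parts.append(np.arange(i0, i1))
        mz_parts.append(np.full(i1 - i0, mz_obs[p]))
        int_parts.append(profile)

    n_bg = rng.poisson(truth.background_peaks_per_scan * n_scans)
    if n_bg > 0:
        scan_idx_parts.append(rng.integers(0, n_scans, size=n_bg))
        mz_parts.append(rng.uniform(*design.mz_range, size=n_bg))
        int_parts.append(rng.uniform(0.0, truth.background_intensity_max, size=n_bg))

    if not scan_idx_parts:
        return [(np.empty(0), np.empty(0)) for _ in range(n_scans)]

    scan_idx = np.concatenate(scan_idx_parts)
    mz = np.concatenate(mz_parts)
    inten = np.concatenate(int_parts)
    order = np.lexsort((mz, scan_idx))
    scan_idx, mz, inten = scan_idx[order], mz[order], inten[order]
    bounds = np.searchsorted(scan_idx, np.arange(n_scans + 1))

    scans: list[tuple[np.ndarray, np.ndarray]] = []
    for s in range(n_scans):
        a, b = bounds[s], bounds[s + 1]
        smz, sint = mz[a:b], inten[a:b]
        if smz.size > 1 and np.any(np.diff(smz) <= 0):
            smz, inverse = np.unique(smz, return_inverse=True)
            merged = np.zeros(smz.size)
            np.add.at(merged, inverse, sint)
            sint = merged
        scans.append((smz, sint))
    return scans
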