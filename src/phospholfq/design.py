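"""Study design and synthetic-truth parameters.

The default :class:`StudyDesign` mirrors a two-genotype endothelial-cell
phosphoproteomics screen: control vs. PI3Kα-inactivated cells, each under
three treatment arms (vehicle 24 h, 4-OHT 24 h, 4-OHT 96 h), four
biological replicates per condition and two technical LC-MS runs per
sample — 24 samples acquired as 48 runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DEFAULT_GENOTYPES = ("control", "mutant")
DEFAULT_TREATMENTS = ("vehicle_24h", "oht_24h", "oht_96h")


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid parameter '{field_name}': {msg}")


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout of the simulated LC-MS study.

    Parameters
    ----------
    genotypes, treatments
        Condition labels; a sample exists for every genotype × treatment ×
        biological-replicate combination.
    n_biological
        Biological replicates (mice / independent cultures) per condition.
    n_technical
        Repeated LC-MS acquisitions of each sample.
    gradient_minutes
        Simulated LC gradient length. The default is desk-scale (20 min);
        a 120 min gradient matching a typical nano-LC phosphoproteomics
        acquisition is available by configuration.
    scan_interval_s
        MS1 duty cycle in seconds (time between survey scans).
    mz_range
        Instrument survey-scan window in Th.
    """

    genotypes: tuple[str, ...] = DEFAULT_GENOTYPES
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    n_biological: int = 4
    n_technical: int = 2
    gradient_minutes: float = 20.0
    scan_interval_s: float = 2.1
    mz_range: tuple[float, float] = (375.0, 1500.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotypes", tuple(self.genotypes))
        object.__setattr__(self, "treatments", tuple(self.treatments))
        object.__setattr__(self, "mz_range", tuple(self.mz_range))
        _require(len(self.genotypes) >= 1, "genotypes", "at least one label")
        _require(len(self.treatments) >= 1, "treatments", "at least one label")
        _require(self.n_biological >= 2, "n_biological", "must be >= 2")
        _require(self.n_technical >= 1, "n_technical", "must be >= 1")
        _require(self.gradient_minutes > 0, "gradient_minutes", "must be > 0")
        _require(self.scan_interval_s > 0, "scan_interval_s", "must be > 0")
        _require(
            self.mz_range[0] < self.mz_range[1],
            "mz_range",
            "low bound must be below high bound",
        )

    @property
    def n_samples(self) -> int:
        return len(self.genotypes) * len(self.treatments) * self.n_biological

    @property
    def n_runs(self) -> int:
        return self.n_samples * self.n_technical

    def samples(self) -> pd.DataFrame:
        """Sample table: one row per biological sample.

        Columns: ``sample_id, genotype, treatment, bio_rep``. Order is
        deterministic (genotype, then treatment, then replicate).
        """
        rows = [
            {
                "sample_id": f"{g}_{t}_b{b}",
                "genotype": g,
                "treatment": t,
                "bio_rep": b,
            }
            for g in self.genotypes
            for t in self.treatments
            for b in range(1, self.n_biological + 1)
        ]
        return pd.DataFrame(rows)

    def runs(self) -> pd.DataFrame:
        """Run table: one row per LC-MS acquisition.

        Columns: ``run_id, sample_id, genotype, treatment, bio_rep,
        tech_rep``.
        """
        samples = self.samples()
        rows = []
        for sample in samples.itertuples(index=False):
            for k in range(1, self.n_technical + 1):
                rows.append(
                    {
                        "run_id": f"{sample.sample_id}_t{k}",
                        "sample_id": sample.sample_id,
                        "genotype": sample.genotype,
                        "treatment": sample.treatment,
                        "bio_rep": sample.bio_rep,
                        "tech_rep": k,
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TruthParams:
    """Parameters of the synthetic ground truth.

    ``effect_log2fc`` is the true log2 fold change applied to regulated
    peptides in the mutant genotype (sign alternates across regulated
    peptides). Biological and technical variability are multiplicative
    log-normal with the given coefficients of variation. ``dropout_prob``
    is the per-(peptide, run) probability that the peptide is entirely
    absent from that acquisition — the situation the quantification stage
    zero-fills. Chromatographic peaks are Gaussian with
    ``peak_base_width_s`` interpreted as 4σ; per-run mass and retention
    time errors are normal with the given spreads and must stay well
    inside the extraction windows (±7 ppm, ±2 min by default).
    """

    n_peptides: int = 500
    frac_regulated: float = 0.1
    effect_log2fc: float = 2.0
    biological_cv: float = 0.2
    technical_cv: float = 0.05
    dropout_prob: float = 0.05
    peak_base_width_s: float = 30.0
    mz_error_ppm_sd: float = 2.0
    rt_jitter_min_sd: float = 0.3
    background_peaks_per_scan: float = 5.0
    background_intensity_max: float = 200.0
    abundance_log10_range: tuple[float, float] = (5.0, 7.0)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "abundance_log10_range", tuple(self.abundance_log10_range)
        )
        _require(self.n_peptides >= 1, "n_peptides", "must be >= 1")
        _require(
            0.0 <= self.frac_regulated <= 1.0, "frac_regulated", "must be in [0, 1]"
        )
        _require(
            0.0 <= self.dropout_prob < 1.0, "dropout_prob", "must be in [0, 1)"
        )
        _require(self.biological_cv >= 0, "biological_cv", "must be >= 0")
        _require(self.technical_cv >= 0, "technical_cv", "must be >= 0")
        _require(self.peak_base_width_s > 0, "peak_base_width_s", "must be > 0")
        _require(self.mz_error_ppm_sd >= 0, "mz_error_ppm_sd", "must be >= 0")
        _require(self.rt_jitter_min_sd >= 0, "rt_jitter_min_sd", "must be >= 0")
        _require(
            self.background_peaks_per_scan >= 0,
            "background_peaks_per_scan",
            "must be >= 0",
        )
        _require(
            self.background_intensity_max >= 0,
            "background_intensity_max",
            "must be >= 0",
        )
        _require(
            self.abundance_log10_range[0] <= self.abundance_log10_range[1],
            "abundance_log10_range",
            "low bound must not exceed high bound",
        )
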