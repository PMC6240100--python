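"""End-to-end pipeline: simulate → quantify → normalize → diffstats.

The pipeline is configured by a :class:`PipelineConfig` (typically read
from YAML). Default tolerances and thresholds are the analysis defaults
(±7 ppm, ±2 min, fold-change gate 0.8 on the log2 axis, P tiers 0.05 and
0.01). Every run writes a provenance record with the config hash and
input hashes; on failure, partially written outputs are removed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .abundance import average_technical_replicates, normalize_total_intensity
from .design import StudyDesign, TruthParams
from .diffstats import comparisons_from_design, run_comparison, venn_partition
from .plots import heatmap_figure, save_figure, volcano_figure
from .simulate import generate_study
from .siteloc import annotate_delta_scores
from .xic import QuantMatrix, collapse_identifications, quantify_all

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    outdir: Path = Path("phospholfq_out")
    mzml_dir: Path | None = None
    id_table: Path | None = None
    run_table: Path | None = None
    simulate: bool = True
    design: StudyDesign = field(default_factory=StudyDesign)
    truth: TruthParams = field(default_factory=TruthParams)
    seed: int = 0
    ppm_tol: float = 7.0
    rt_tol: float = 2.0
    fc_threshold: float = 0.8
    p05: float = 0.05
    p01: float = 0.01
    write_mzml: bool = False
    write_figures: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(raw)
        if "design" in kwargs and isinstance(kwargs["design"], dict):
            kwargs["design"] = StudyDesign(**kwargs["design"])
        if "truth" in kwargs and isinstance(kwargs["truth"], dict):
            kwargs["truth"] = TruthParams(**kwargs["truth"])
        for key in ("outdir", "mzml_dir", "id_table", "run_table"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key, value in out.items():
            if isinstance(value, Path):
                out[key] = str(value)
        return out


def _echo_overrides(config: PipelineConfig) -> None:
    defaults = PipelineConfig()
    for f in dataclasses.fields(PipelineConfig):
        if f.name in ("outdir", "mzml_dir", "id_table", "run_table"):
            continue
        current, default = getattr(config, f.name), getattr(defaults, f.name)
        if current != default:
            logger.info("config override: %s = %r (default %r)", f.name, current, default)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured pipeline and write the result bundle.

    Returns a dict of the in-memory results (matrices, per-comparison
    result frames, Venn partitions, output paths). Raises on invalid
    inputs; partial outputs are removed before re-raising.
    """
    logging.basicConfig(level=config.log_level)
    _echo_overrides(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run_pipeline_inner(config, outdir, written)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _run_pipeline_inner(
    config: PipelineConfig, outdir: Path, written: list[Path]
) -> dict:
    inputs: dict[str, Path] = {}
    if config.simulate:
        runs, ids, gt = generate_study(config.design, config.truth, config.seed)
        run_table = gt.runs
        samples = config.design.samples()
        written.append(pio.write_id_table(ids, outdir / "identifications.csv"))
        written.append(pio.write_run_table(run_table, outdir / "runs.csv"))
        gt.peptides.to_csv(outdir / "ground_truth_peptides.csv", index=False)
        gt.abundances.to_csv(outdir / "ground_truth_abundances.csv")
        gt.presence.to_csv(outdir / "ground_truth_presence.csv")
        written += [
            outdir / "ground_truth_peptides.csv",
            outdir / "ground_truth_abundances.csv",
            outdir / "ground_truth_presence.csv",
        ]
        if config.write_mzml:
            mzml_dir = outdir / "mzml"
            mzml_dir.mkdir(exist_ok=True)
            for run in runs:
                written.append(pio.write_mzml(run, mzml_dir / f"{run.run_id}.mzML"))
    else:
        if config.id_table is None or not Path(config.id_table).exists():
            raise FileNotFoundError(
                f"identification table not found: {config.id_table}"
            )
        if config.mzml_dir is None or not Path(config.mzml_dir).is_dir():
            raise FileNotFoundError(f"mzML directory not found: {config.mzml_dir}")
        if config.run_table is None or not Path(config.run_table).exists():
            raise FileNotFoundError(f"run table not found: {config.run_table}")
        inputs["id_table"] = Path(config.id_table)
        inputs["run_table"] = Path(config.run_table)
        ids = pio.read_id_table(config.id_table)
        run_table = pio.read_run_table(config.run_table)
        runs = []
        for row in run_table.itertuples(index=False):
            mzml_path = Path(config.mzml_dir) / f"{row.run_id}.mzML"
            if not mzml_path.exists():
                raise FileNotFoundError(f"missing mzML file: {mzml_path}")
            runs.append(
                pio.read_mzml(
                    mzml_path,
                    run_id=row.run_id,
                    sample_id=row.sample_id,
                    tech_rep=int(getattr(row, "tech_rep", 0)),
                )
            )
        gt = None
        samples = (
            run_table[["sample_id", "genotype", "treatment"]].drop_duplicates()
            if {"genotype", "treatment"} <= set(run_table.columns)
            else None
        )

    if "isoform_scores" in ids.columns:
        ids = annotate_delta_scores(ids)
        written.append(
            pio.write_id_table(ids, outdir / "identifications_with_delta.csv")
        )

    unique_ids = collapse_identifications(ids)
    matrix = quantify_all(runs, unique_ids, config.ppm_tol, config.rt_tol)
    written.append(pio.write_matrix(matrix, outdir / "quant_run_level.csv"))

    rep_map = dict(zip(run_table["run_id"], run_table["sample_id"]))
    by_sample = average_technical_replicates(matrix, rep_map)
    normalized = normalize_total_intensity(by_sample)
    written.append(pio.write_matrix(normalized, outdir / "quant_normalized.csv"))

    results: dict[str, pd.DataFrame] = {}
    venns = {}
    if samples is not None and samples["genotype"].nunique() == 2:
        comparisons = comparisons_from_design(samples)
        sig_up: dict[str, set] = {}
        sig_down: dict[str, set] = {}
        for comp in comparisons:
            res = run_comparison(
                normalized, comp, config.fc_threshold, config.p05, config.p01
            )
            results[comp.name] = res
            path = outdir / f"diff_{comp.name}.csv"
            res.to_csv(path, index=False)
            written.append(path)
            sig = res[res["sig_class"] != "ns"]
            sig_up[comp.name] = set(sig.loc[sig["direction"] == "up", "peptide_key"])
            sig_down[comp.name] = set(
                sig.loc[sig["direction"] == "down", "peptide_key"]
            )
            if config.write_figures:
                written.append(
                    save_figure(
                        volcano_figure(res, title=comp.name),
                        outdir / f"volcano_{comp.name}.png",
                    )
                )
        if len(comparisons) >= 2:
            for label, sets in (
                ("up", sig_up),
                ("down", sig_down),
                (
                    "combined",
                    {k: sig_up[k] | sig_down[k] for k in sig_up},
                ),
            ):
                venn = venn_partition(sets)
                venns[label] = venn
                path = outdir / f"venn_{label}.csv"
                venn.to_csv(path, index=False)
                written.append(path)
        if config.write_figures and results:
            from .diffstats import heatmap_foldchanges

            sig_any = sorted(
                set().union(*(sig_up[k] | sig_down[k] for k in sig_up))
            )[:60]
            if sig_any:
                fc = heatmap_foldchanges(normalized, comparisons, sig_any)
                fc.to_csv(outdir / "heatmap_foldchanges.csv")
                written.append(outdir / "heatmap_foldchanges.csv")
                written.append(
                    save_figure(heatmap_figure(fc), outdir / "heatmap.png")
                )

    prov = pio.write_provenance(
        outdir / "provenance.json",
        config.to_dict(),
        inputs,
        [str(p) for p in written],
    )
    written.append(prov)
    return {
        "matrix_run": matrix,
        "matrix_normalized": normalized,
        "results": results,
        "venns": venns,
        "ground_truth": gt,
        "outputs": [str(p) for p in written],
    }
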