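"""End-to-end orchestration: simulate or ingest, surrogates, fit, report.

Every stage reads and writes plain CSV/JSON so any stage can be re-run or
swapped in isolation; identical config + seed reproduces identical outputs.
Each output carries the config hash and seed that produced it (a ``#`` comment
line in CSVs, a provenance block in JSONs, and the run log lists everything).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConfigError, PETTCPError
from .model import GridSpec, TumorRecurrenceModel
from .simulate import GeneratorConfig, generate_cohort
from .stats import DEFAULT_BIN_EDGES, binned_calibration, compare_all_surrogates, correlate
from .surrogates import DEFAULT_THRESHOLD, build_cohort_table, cohort_table_from_files

__all__ = ["PipelineConfig", "run_pipeline", "read_cohort_csv"]


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    mode: str = "simulate"  # or "ingest"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    outcomes_csv: str | None = None  # ingest mode: CSV referencing NIfTI pairs
    threshold: float = DEFAULT_THRESHOLD
    surrogate: str = "mean_ratio"
    grid: GridSpec = field(default_factory=GridSpec)
    ci_level: float = 0.90
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    out_dir: str = "pettcp_run"
    seed: int | None = None  # overrides generator.seed when given
    refine: bool = False
    write_volumes: bool = False
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ConfigError(f"mode must be 'simulate' or 'ingest', got {self.mode!r}")
        if self.mode == "ingest" and not self.outcomes_csv:
            raise ConfigError("ingest mode requires outcomes_csv")
        if not (0 < self.ci_level < 1):
            raise ConfigError("ci_level must lie in (0, 1)")
        if self.seed is not None:
            gen = self.generator.to_dict()
            gen["seed"] = int(self.seed)
            self.generator = GeneratorConfig(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in gen.items()
                }
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen_raw = raw.pop("generator", {})
        gen = GeneratorConfig(
            **{k: tuple(v) if isinstance(v, list) else v for k, v in gen_raw.items()}
        )
        grid_raw = raw.pop("grid", None)
        grid = GridSpec.from_string(grid_raw) if isinstance(grid_raw, str) else (
            GridSpec(**grid_raw) if grid_raw else GridSpec()
        )
        if "bin_edges" in raw:
            raw["bin_edges"] = tuple(raw["bin_edges"])
        raw.update(overrides)
        return cls(generator=gen, grid=grid, **raw)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "generator": self.generator.to_dict(),
            "outcomes_csv": self.outcomes_csv,
            "threshold": self.threshold,
            "surrogate": self.surrogate,
            "grid": {
                "suvr50_min": self.grid.suvr50_min,
                "suvr50_max": self.grid.suvr50_max,
                "n_suvr50": self.grid.n_suvr50,
                "gamma50_min": self.grid.gamma50_min,
                "gamma50_max": self.grid.gamma50_max,
                "n_gamma50": self.grid.n_gamma50,
            },
            "ci_level": self.ci_level,
            "bin_edges": list(self.bin_edges),
            "refine": self.refine,
        }

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, prov: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {prov}\n")
        df.to_csv(fh, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort/stage CSV, ignoring the provenance comment line."""
    return pd.read_csv(path, comment="#")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a dict of output paths plus key results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.generator.seed
    prov = f"config_hash={config.config_hash()} seed={seed}"
    paths: dict[str, str] = {}

    # --- cohort stage -----------------------------------------------------
    if config.mode == "simulate":
        try:
            patients, manifest = generate_cohort(
                config.generator, out_dir=out / "cohort", write_volumes=config.write_volumes
            )
        except PETTCPError as exc:
            raise PETTCPError(f"[simulate] {exc}") from exc
        try:
            table = build_cohort_table(patients, threshold=config.threshold)
        except PETTCPError as exc:
            raise PETTCPError(f"[surrogates] {exc}") from exc
    else:
        try:
            table = cohort_table_from_files(config.outcomes_csv, threshold=config.threshold)
        except PETTCPError as exc:
            raise PETTCPError(f"[surrogates] {exc}") from exc
    cohort_csv = out / "cohort.csv"
    _write_csv(table, cohort_csv, prov)
    paths["cohort_csv"] = str(cohort_csv)

    # --- fit stage --------------------------------------------------------
    try:
        model = TumorRecurrenceModel.from_cohort_table(table, surrogate=config.surrogate)
        results = model.fit(grid=config.grid, refine=config.refine, ci_level=config.ci_level)
    except PETTCPError as exc:
        raise PETTCPError(f"[fit] {exc}") from exc
    fit_json = out / "fit.json"
    results.save_json(fit_json, extra={"provenance": prov})
    paths["fit_json"] = str(fit_json)
    surface_csv = out / "surface.csv"
    _write_csv(results.surface.to_frame(), surface_csv, prov)
    paths["surface_csv"] = str(surface_csv)

    # --- report stage -----------------------------------------------------
    comparisons = compare_all_surrogates(table)
    comp_csv = out / "group_comparisons.csv"
    _write_csv(comparisons, comp_csv, prov)
    paths["group_comparisons_csv"] = str(comp_csv)

    bins = binned_calibration(table, results, edges=config.bin_edges, surrogate=config.surrogate)
    calib_csv = out / "calibration.csv"
    _write_csv(bins, calib_csv, prov)
    paths["calibration_csv"] = str(calib_csv)

    r, p = correlate(table, "mean_pre", "mean_diff")
    corr_payload = {"x": "mean_pre", "y": "mean_diff", "pearson_r": r, "p_value": p}
    try:
        r_resp, p_resp = correlate(table, "mean_pre", "mean_diff", subset="responders")
        corr_payload["responders_only"] = {"pearson_r": r_resp, "p_value": p_resp}
    except PETTCPError:
        pass  # too few responders for a subgroup correlation
    corr_json = out / "correlation.json"
    corr_json.write_text(
        json.dumps({**corr_payload, "provenance": prov}, indent=2, sort_keys=True) + "\n"
    )
    paths["correlation_json"] = str(corr_json)

    if config.make_plots:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        from .plotting import plot_calibration, plot_ll_surface, plot_pre_vs_diff

        for name, plot in (
            ("surface.png", lambda ax: plot_ll_surface(results.surface, results, ax=ax)),
            ("calibration.png", lambda ax: plot_calibration(bins, results, ax=ax)),
            ("pre_vs_diff.png", lambda ax: plot_pre_vs_diff(table, ax=ax)),
        ):
            fig, ax = plt.subplots(figsize=(6, 4.5))
            plot(ax)
            fig.tight_layout()
            fig.savefig(out / name, dpi=120)
            plt.close(fig)
            paths[name.replace(".png", "_png")] = str(out / name)

    log = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": seed,
        "outputs": paths,
        "fit": results.to_dict(),
        "correlation": corr_payload,
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    paths["run_log_json"] = str(log_path)
    return {"paths": paths, "results": results, "table": table, "bins": bins}
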