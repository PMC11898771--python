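"""End-to-end profiling runs with manifests.

Wires the stages of the profiling flow — measure/load → QC → pooled z-score
→ per-feature EMD → Euclidean aggregation → 2-D embedding → feature screen —
into one reproducible run: every parameter and seed is echoed into a run
manifest, outputs are plain CSV, and two runs from the same manifest produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import yaml

from . import __version__
from . import profiling, qc as qc_mod
from .io_tables import FeatureTable, read_feature_table, write_feature_table
from .synthetic import EffectSpec, generate_feature_table

__all__ = ["RunConfig", "run_pipeline", "synthetic_effects_from_config"]


class ConfigurationError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Parameters of one profiling run (all stage defaults surfaced)."""

    output_dir: str
    input_table: "str | None" = None  # CSV path; None -> synthetic input
    dialect: str = "plain"
    synthetic_base_features: int = 50
    synthetic_effects: "list | None" = None  # list of EffectSpec
    seed: int = 0
    count_z_max: float = 3.5
    feature_z_max: float = 3.5
    min_images_kept: int = 2
    min_cells: int = 50
    embed_method: str = "classical_mds"
    alpha: float = 0.05
    overwrite: bool = False

    def validate(self) -> None:
        if self.input_table is None and not self.synthetic_effects:
            raise ConfigurationError(
                "config needs either input_table or synthetic_effects"
            )
        if self.embed_method not in ("classical_mds", "smacof"):
            raise ConfigurationError(f"unknown embed_method {self.embed_method!r}")


def synthetic_effects_from_config(entries) -> list:
    """Build EffectSpecs from plain dicts (as parsed from a YAML config)."""
    specs = []
    for e in entries:
        specs.append(
            EffectSpec(
                condition=e["condition"],
                location_shift=e.get("location_shift", 0.0),
                scale_factor=e.get("scale_factor", 1.0),
                affected_features=tuple(e.get("affected_features", ())),
                n_cells_per_image=int(e.get("n_cells_per_image", 100)),
                n_images=int(e.get("n_images", 4)),
            )
        )
    return specs


def _manifest(config: RunConfig, extra: dict) -> dict:
    cfg = dataclasses.asdict(config)
    cfg["synthetic_effects"] = [
        dataclasses.asdict(e) if dataclasses.is_dataclass(e) else e
        for e in (config.synthetic_effects or [])
    ]
    return {"morphoscreen_version": __version__, "config": cfg, **extra}


def run_pipeline(config: RunConfig) -> dict:
    """Run the profiling flow; return the manifest dict.

    Writes into ``config.output_dir``: the (possibly synthetic) input table,
    QC report, EMD long table, dissimilarity matrix, 2-D embedding, feature
    screen and ``manifest.yaml``.  Refuses to reuse a non-empty output
    directory unless ``overwrite`` is set.  Deterministic given the seed.
    """
    config.validate()
    out = Path(config.output_dir)
    if out.exists() and any(out.iterdir()) and not config.overwrite:
        raise FileExistsError(
            f"output directory {out} is not empty (pass overwrite=True to replace)"
        )
    out.mkdir(parents=True, exist_ok=True)

    notes: dict = {}
    if config.input_table is not None:
        table = read_feature_table(config.input_table, dialect=config.dialect)
        notes["input"] = str(config.input_table)
    else:
        table, _truth = generate_feature_table(
            config.synthetic_base_features, config.synthetic_effects, seed=config.seed
        )
        write_feature_table(table, out / "input_table.csv")
        notes["input"] = "synthetic"
    notes["n_cells"] = table.n_cells
    notes["dropped_nonfinite_rows"] = table.load_report.drop_count

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered, reports = qc_mod.qc_images(
            table,
            count_z_max=config.count_z_max,
            feature_z_max=config.feature_z_max,
            min_images_kept=config.min_images_kept,
        )
    qc_mod.reports_frame(reports).to_csv(out / "qc_report.csv", index=False)
    notes["qc_dropped_images"] = int(sum(not r.passed for r in reports))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ztable, dropped_features = profiling.zscore_features(filtered)
        vectors, D = profiling.condition_dissimilarity(ztable, min_cells=config.min_cells)
    notes["zero_variance_features"] = dropped_features
    profiling.emd_long_frame(vectors).to_csv(out / "emd_long.csv", index=False)
    D.to_frame().to_csv(out / "dissimilarity.csv")

    emb = profiling.embed_2d(D, method=config.embed_method, seed=config.seed)
    emb.to_frame().to_csv(out / "embedding.csv", index=False)
    notes["embedding_stress"] = emb.stress

    screen = profiling.screen_features(ztable, alpha=config.alpha)
    screen.to_csv(out / "feature_screen.csv", index=False)
    notes["n_significant_features"] = int(screen["significant"].sum())

    manifest = _manifest(config, {"results": notes})
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
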