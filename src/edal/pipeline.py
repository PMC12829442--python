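"""End-to-end experiment orchestration: configuration, outputs, reporting.

``run_pipeline`` binds the generator, the active-learning loop, the shift
metrics and the comparison statistics into one reproducible run directory:
a config snapshot, per-iteration metrics, the acquisition log, the
EDL-vs-random comparison table, the FCD trajectory and a calibration table.
Rerunning with the same config reproduces the CSVs byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import datasets as ds
from .active_learning import ALConfig, run_experiment
from .evidential import EvidentialRegressor, desk_scale_model_params
from .shift import ence
from .stats import significance_table

__all__ = ["ExperimentConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


@dataclass
class ExperimentConfig:
    """Serializable snapshot of one experiment."""

    preset: str = "somas_to_pubchem"
    shift: ds.ShiftConfig = field(default_factory=ds.ShiftConfig)
    al: ALConfig = field(default_factory=ALConfig)
    out_dir: str = "edal_run"
    calibration_bins: int = 10

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            blob = yaml.safe_load(fh)
        shift = ds.ShiftConfig(**blob.pop("shift", {}))
        al_blob = blob.pop("al", {})
        al = ALConfig(**al_blob)
        return cls(shift=shift, al=al, **blob)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def _calibration_table(cfg: ExperimentConfig) -> pd.DataFrame:
    """ENCE calibration-curve data for a model trained on the in-distribution
    seed data and evaluated on the OOD test set."""
    in_dist, _, ood_test = ds.generate_bundle(cfg.shift)
    model = EvidentialRegressor(**cfg.al.model_params, seed=cfg.al.base_seed)
    model.fit(ds.feature_matrix(in_dist), in_dist["target"].to_numpy())
    p = model.predict_evidential(ds.feature_matrix(ood_test))
    sq_err = (ood_test["target"].to_numpy() - p.gamma) ** 2
    score, bins = ence(zip(p.aleatoric_var, sq_err), n_bins=cfg.calibration_bins)
    table = pd.DataFrame([{"bin": k, "rmv": b.rmv, "rmse": b.rmse, "count": b.count}
                          for k, b in enumerate(bins)])
    table.attrs["ence"] = score
    return table


def run_pipeline(cfg: ExperimentConfig) -> Path:
    """Run one full experiment and write its artifact directory.

    On failure, whatever partial outputs exist are moved under ``failed/``
    inside the output directory so a clean rerun cannot mix with them.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        cfg.to_yaml(out / "config.yaml")

        iterations, selections = run_experiment(cfg.preset, cfg.al, cfg.shift)
        _write_csv(iterations, out / "iterations.csv")
        _write_csv(selections, out / "selections.csv")

        comparison = significance_table(iterations, paired=True)
        _write_csv(comparison, out / "comparison.csv")

        fcd = iterations[["run", "iteration", "strategy", "fcd_train_pool"]]
        _write_csv(fcd, out / "fcd_trajectory.csv")

        calib = _calibration_table(cfg)
        _write_csv(calib, out / "calibration.csv")

        final_it = int(iterations["iteration"].max())
        final = comparison[(comparison["iteration"] == final_it)
                           & (comparison["metric"] == "rmse")]
        lines = [f"preset: {cfg.preset}",
                 f"runs: {cfg.al.n_runs}, iterations: {cfg.al.n_iterations}, "
                 f"batch: {cfg.al.batch_size}",
                 f"ENCE (seed-trained model on OOD test): {calib.attrs['ence']:.4f}"]
        if not final.empty:
            row = final.iloc[0]
            lines += [
                f"final RMSE  edl: {row['mean_edl']:.4f} +- {row['sd_edl']:.4f}",
                f"final RMSE rand: {row['mean_rand']:.4f} +- {row['sd_rand']:.4f}",
                f"one-tailed p: {row['p_one_tailed']:.4g}  "
                f"Cohen's d: {row['cohens_d']:.3f} ({row['effect_class']})",
            ]
        (out / "summary.txt").write_text("\n".join(lines) + "\n")
        return out
    except Exception:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for f in out.iterdir():
            if f.name != "failed":
                shutil.move(str(f), str(failed / f.name))
        raise
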