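"""End-to-end orchestration: simulate -> phenotype -> neighborhoods ->
metrics -> features -> select -> survive, driven by one YAML config with
fixed seeds, cached stage outputs, and a JSON run manifest.

Every stage reads and writes the CSV interchange formats of
:mod:`metatme.core`, so a run is resumable from any cached intermediate and
bit-identical under a fixed config + seed.
"""

from __future__ import annotations

import argparse
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core, features, neighborhoods, phenotyping, selection, survival, synthetic
from .core import configure_logging, logger

STAGES = ("simulate", "phenotype", "neighborhoods", "metrics", "features",
          "select", "survive")

DEFAULT_FAMILIES = ("prop.cn2", "prop.cn3", "prop.mbn", "ratio.cn3",
                    "gcross.cn3", "jsd.cn2")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("seed", 0)
    cfg.setdefault("out_dir", "metatme_run")
    cfg.setdefault("metrics", {})
    cfg.setdefault("features", {})
    cfg.setdefault("selection", {})
    cfg.setdefault("survival", {})
    cfg.setdefault("neighborhoods", {})
    return cfg


class PipelineRun:
    """Stage runner with file-level caching under ``out_dir``."""

    def __init__(self, config: dict, resume: bool = True):
        self.cfg = load_config(config)
        self.out = Path(self.cfg["out_dir"])
        self.out.mkdir(parents=True, exist_ok=True)
        self.resume = resume
        self.panel = core.default_panel()
        self.manifest: dict = {
            "config_hash": _config_hash(self.cfg),
            "seed": self.cfg["seed"],
            "stages": {},
            "outputs": {},
            "warnings": [],
        }

    # -- helpers -----------------------------------------------------------

    def _path(self, name: str) -> Path:
        return self.out / name

    def _cached(self, *names: str) -> bool:
        return self.resume and all(self._path(n).exists() for n in names)

    def _finish(self, stage: str, t0: float, outputs: list[str]) -> None:
        self.manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        for name in outputs:
            self.manifest["outputs"][name] = _sha256(self._path(name))

    # -- stages ------------------------------------------------------------

    def simulate(self) -> None:
        t0 = time.time()
        if not self._cached("cells.csv", "clinical.csv"):
            if "synthetic" in self.cfg:
                params = dict(self.cfg["synthetic"])
                params.setdefault("seed", self.cfg["seed"])
                if "planted_effects" in params:
                    params["planted_effects"] = [
                        tuple(e) for e in params["planted_effects"]
                    ]
                sc = synthetic.SyntheticConfig(**params)
                cells, clinical = synthetic.generate_cohort(sc, panel=self.panel)
            elif "inputs" in self.cfg:
                cells = core.read_cell_table(self.cfg["inputs"]["cells"], self.panel)
                clinical = core.read_clinical_table(self.cfg["inputs"]["clinical"])
            else:
                raise core.ValidationError(
                    "config needs a 'synthetic' or 'inputs' section"
                )
            clinical = core.derive_cb6(clinical)
            core.write_cell_table(cells, self._path("cells.csv"))
            core.write_clinical_table(clinical, self._path("clinical.csv"))
        self._finish("simulate", t0, ["cells.csv", "clinical.csv"])

    def phenotype(self) -> None:
        t0 = time.time()
        if not self._cached("cells_typed.csv"):
            cells = core.read_cell_table(self._path("cells.csv"), self.panel)
            thresholds = phenotyping.fit_thresholds(
                _subsample_for_thresholds(cells, self.cfg["seed"]), self.panel
            )
            thresholds.to_yaml(self._path("thresholds.yaml"))
            cells = phenotyping.call_markers(cells, thresholds)
            cells = phenotyping.assign_cell_types(cells, self.panel)
            cells = phenotyping.functionalize(cells, self.panel)
            core.write_cell_table(cells, self._path("cells_typed.csv"))
        self._finish("phenotype", t0, ["cells_typed.csv", "thresholds.yaml"])

    def neighborhoods(self) -> None:
        t0 = time.time()
        if not self._cached("cells_nbhd.csv"):
            cells = core.read_cell_table(self._path("cells_typed.csv"), self.panel)
            ncfg = self.cfg["neighborhoods"]
            cells, models = neighborhoods.annotate_neighborhoods(
                cells, self.panel, seed=self.cfg["seed"],
                cn2_window=ncfg.get("cn2_window", neighborhoods.CN_WINDOW_K2),
                cn3_window=ncfg.get("cn3_window", neighborhoods.CN_WINDOW_K3),
                mbn_window=ncfg.get("mbn_window", neighborhoods.MBN_WINDOW),
            )
            for name, model in models.items():
                model.to_files(
                    self._path(f"model_{name}.yaml"),
                    self._path(f"model_{name}_centroids.csv"),
                )
            core.write_cell_table(cells, self._path("cells_nbhd.csv"))
        self._finish("neighborhoods", t0, ["cells_nbhd.csv"])

    def metrics(self) -> None:
        t0 = time.time()
        if not self._cached("spatial_records.csv"):
            cells = core.read_cell_table(self._path("cells_nbhd.csv"), self.panel)
            mcfg = self.cfg["metrics"]
            fams = mcfg.get("families", list(DEFAULT_FAMILIES))
            level = mcfg.get("level", "base")
            grid = int(mcfg.get("jsd_grid", 64))
            frames = []
            for fam in fams:
                parts = fam.split(".")
                view = {v: k for k, v in features.VIEW_TAGS.items()}.get(parts[-1])
                if parts[0] == "gcross" and parts[1] == "edge":
                    frames.append(features.edge_gcross_records(
                        cells, view, self.panel, level=level
                    ))
                elif parts[0] == "gcross":
                    frames.append(features.gcross_records(
                        cells, view, self.panel, level=level
                    ))
                elif parts[0] == "jsd":
                    frames.append(features.jsd_records(
                        cells, view, self.panel, level=level, grid_size=grid
                    ))
                elif parts[0] == "ixn":
                    frames.append(features.interaction_records(
                        cells, view, self.panel,
                        n_perm=int(mcfg.get("n_perm", 100)),
                        seed=self.cfg["seed"],
                    ))
            frames = [f for f in frames if len(f)]
            records = (
                pd.concat(frames, ignore_index=True) if frames
                else pd.DataFrame(columns=["patient_id", "feature", "family", "value"])
            )
            records.to_csv(self._path("spatial_records.csv"), index=False)
        self._finish("metrics", t0, ["spatial_records.csv"])

    def features(self) -> None:
        t0 = time.time()
        if not self._cached("feature_matrix.csv", "feature_records.csv"):
            cells = core.read_cell_table(self._path("cells_nbhd.csv"), self.panel)
            clinical = core.read_clinical_table(self._path("clinical.csv"))
            fams = self.cfg["metrics"].get("families", list(DEFAULT_FAMILIES))
            prop_levels = self.cfg["features"].get(
                "prop_levels", ["base", "functional"]
            )
            frames = [pd.read_csv(self._path("spatial_records.csv"))]
            for fam in fams:
                parts = fam.split(".")
                view = {v: k for k, v in features.VIEW_TAGS.items()}.get(parts[-1])
                if parts[0] == "prop":
                    for lv in prop_levels:
                        frames.append(features.compartment_proportions(
                            cells, view, lv, self.panel
                        ))
                elif parts[0] == "ratio":
                    frames.append(features.count_ratios(
                        cells, view, panel=self.panel
                    ))
            frames = [f for f in frames if len(f)]
            records = pd.concat(frames, ignore_index=True)
            records.to_csv(self._path("feature_records.csv"), index=False)
            fm = features.assemble_features(
                records, clinical["patient_id"],
                min_unique=int(self.cfg["features"].get("min_unique",
                                                        features.MIN_UNIQUE)),
            )
            fm.scaled.to_csv(self._path("feature_matrix.csv"))
            fm.raw.to_csv(self._path("feature_matrix_raw.csv"))
            fm.families.rename("family").to_csv(self._path("feature_families.csv"))
        self._finish("features", t0, ["feature_matrix.csv", "feature_records.csv"])

    def select(self) -> None:
        t0 = time.time()
        if not self._cached("selection.csv"):
            scaled = pd.read_csv(self._path("feature_matrix.csv"),
                                 index_col="patient_id")
            fams = pd.read_csv(self._path("feature_families.csv"),
                               index_col=0)["family"]
            clinical = core.read_clinical_table(self._path("clinical.csv"))
            scfg = dict(self.cfg["selection"])
            endpoint = scfg.pop("endpoint", "binary")
            cfg = selection.SelectionConfig(
                endpoint=endpoint, seed=self.cfg["seed"], **scfg
            )
            clinical = clinical.set_index("patient_id").loc[scaled.index]
            outcome = (
                clinical["cb6"].to_numpy() if endpoint == "binary"
                else (clinical["pfs_time"].to_numpy(),
                      clinical["pfs_event"].to_numpy())
            )
            groups = clinical["cohort_id"].to_numpy() if cfg.grouped else None
            results = selection.select_per_family(scaled, fams, outcome, cfg, groups)
            rows = []
            for fam, res in results.items():
                for feat, freq in res.frequencies.items():
                    rows.append((fam, feat, freq, False, feat in res.selected))
                for feat, freq in res.decoy_frequencies.items():
                    rows.append((fam, feat, freq, True, False))
            pd.DataFrame(
                rows, columns=["family", "feature", "frequency", "is_decoy",
                               "selected"],
            ).to_csv(self._path("selection.csv"), index=False)
        self._finish("select", t0, ["selection.csv"])

    def survive(self) -> None:
        t0 = time.time()
        if not self._cached("survival_loghr.csv"):
            sel = pd.read_csv(self._path("selection.csv"))
            chosen = sel.loc[sel["selected"], "feature"].tolist()
            scaled = pd.read_csv(self._path("feature_matrix.csv"),
                                 index_col="patient_id")
            clinical = core.read_clinical_table(self._path("clinical.csv"))
            clinical = clinical.set_index("patient_id").loc[scaled.index]
            if not chosen:
                logger.warning("no features selected; survival stage skipped")
                pd.DataFrame(
                    columns=["feature", "loghr", "ci_low", "ci_high", "p"]
                ).to_csv(self._path("survival_loghr.csv"), index=False)
                self._finish("survive", t0, ["survival_loghr.csv"])
                return
            vcfg = self.cfg["survival"]
            fit = survival.kfold_cox_auc(
                scaled[chosen],
                clinical["pfs_time"], clinical["pfs_event"],
                k=int(vcfg.get("k", 10)),
                test_size=float(vcfg.get("test_size", 0.25)),
                seed=self.cfg["seed"],
                horizon=float(vcfg.get("horizon", 24.0)),
            )
            fit.loghr.to_csv(self._path("survival_loghr.csv"), index=False)
            pd.DataFrame({
                "time": fit.auc_times, "mean": fit.auc_mean,
                "lo": fit.auc_lo, "hi": fit.auc_hi,
            }).to_csv(self._path("survival_auc.csv"), index=False)
            scores = survival.prognosis_score(fit, scaled)
            scores.rename("prognosis_score").to_csv(
                self._path("prognosis_scores.csv")
            )
            km = survival.km_logrank(
                scores.to_numpy(), clinical["pfs_time"], clinical["pfs_event"]
            )
            km.curves.to_csv(self._path("km_curves.csv"), index=False)
            with open(self._path("km_test.json"), "w") as fh:
                json.dump({"chi2": km.chi2, "p": km.p}, fh)
        self._finish("survive", t0, ["survival_loghr.csv"])

    def run_all(self) -> dict:
        for stage in STAGES:
            getattr(self, stage)()
        with open(self._path("manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2)
        return self.manifest


def _subsample_for_thresholds(
    cells: pd.DataFrame, seed: int, max_cells: int = 10000
) -> pd.DataFrame:
    """Cohort-level thresholds are stable on a bounded random subsample."""
    if len(cells) <= max_cells:
        return cells
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cells), size=max_cells, replace=False)
    return cells.iloc[np.sort(idx)]


def run_pipeline(config, resume: bool = True) -> dict:
    """Execute all stages; returns the run manifest."""
    run = PipelineRun(config, resume=resume)
    try:
        return run.run_all()
    except Exception:
        with open(run._path("manifest.partial.json"), "w") as fh:
            json.dump(run.manifest, fh, indent=2)
        raise


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(
        prog="metatme",
        description="Spatial-metabolic TME feature pipeline",
    )
    parser.add_argument("command", choices=list(STAGES) + ["run-all"])
    parser.add_argument("--config", required=True, help="YAML run config")
    parser.add_argument("--seed", type=int, default=None, help="override seed")
    parser.add_argument("--out", default=None, help="override output directory")
    parser.add_argument("--no-resume", action="store_true",
                        help="ignore cached stage outputs")
    parser.add_argument("--log-level", default="INFO")
    args = parser.parse_args(argv)
    configure_logging(args.log_level)
    cfg = load_config(args.config)
    if args.seed is not None:
        cfg["seed"] = args.seed
    if args.out is not None:
        cfg["out_dir"] = args.out
    run = PipelineRun(cfg, resume=not args.no_resume)
    if args.command == "run-all":
        run.run_all()
    else:
        # run every stage up to and including the requested one so that
        # required inputs exist (cached stages are skipped)
        for stage in STAGES[: STAGES.index(args.command) + 1]:
            getattr(run, stage)()
    with open(run._path("manifest.json"), "w") as fh:
        json.dump(run.manifest, fh, indent=2)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
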