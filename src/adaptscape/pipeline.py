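"""Config-driven end-to-end orchestration of the landscape-genomics flow.

Runs QC -> climate prep -> structure/GEA -> offset engines -> per-scenario
adaptedness surfaces -> seed-transfer analyses -> cross-method comparison,
writing every intermediate artifact under versioned stage directories plus a
JSON manifest of parameters, seeds and artifact checksums.  The manifest is
deterministic for a fixed config and seed, which is the pipeline's
reproducibility contract.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import climate as climate_mod
from . import compare as compare_mod
from . import genotype as genotype_mod
from . import landscape as landscape_mod
from . import offsets as offsets_mod
from . import structure as structure_mod
from . import transfer as transfer_mod

logger = logging.getLogger(__name__)

KNOWN_ENGINES = set(offsets_mod.ENGINE_NAMES)


@dataclass
class RunConfig:
    """One pipeline run: inputs (or a synthetic config), parameters, outputs."""

    out_dir: Path
    seed: int = 0
    synthetic: landscape_mod.LandscapeConfig | None = None
    vcf: Path | None = None
    grids: dict[str, Path] = field(default_factory=dict)   # scenario label -> CSV
    coords: Path | None = None
    qc: dict[str, Any] = field(default_factory=dict)
    keep_priority: list[str] = field(default_factory=list)
    collinearity_r2: float | None = None   # None skips variable pruning
    engines: list[str] = field(default_factory=lambda: ["gf", "rda", "gdm"])
    engine_params: dict[str, dict] = field(default_factory=dict)
    n_retained_axes_rda: int | None = None  # default: axes retained by pRDA
    focal_site: str | None = None           # site id whose cells become recipients
    donor_scope: str = "radius"
    radius_km: float = 50.0
    mantel_permutations: int = 199
    gf_trees: int = 300
    protection: str = "synthetic-west-half"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "RunConfig":
        synth = raw.get("synthetic")
        cfg = cls(
            out_dir=base / raw.get("out_dir", "adaptscape_run"),
            seed=int(raw.get("seed", 0)),
            synthetic=landscape_mod.LandscapeConfig(**synth) if synth is not None else None,
            vcf=(base / raw["vcf"]) if "vcf" in raw else None,
            grids={k: base / v for k, v in raw.get("grids", {}).items()},
            coords=(base / raw["coords"]) if "coords" in raw else None,
            qc=dict(raw.get("qc", {})),
            keep_priority=list(raw.get("keep_priority", [])),
            collinearity_r2=raw.get("collinearity_r2"),
            engines=list(raw.get("engines", ["gf", "rda", "gdm"])),
            engine_params=dict(raw.get("engine_params", {})),
            focal_site=raw.get("focal_site"),
            donor_scope=raw.get("donor_scope", "radius"),
            radius_km=float(raw.get("radius_km", 50.0)),
            mantel_permutations=int(raw.get("mantel_permutations", 199)),
            gf_trees=int(raw.get("gf_trees", 300)),
        )
        return cfg


def validate_config(config: RunConfig | str | Path) -> list[str]:
    """Schema validation with actionable messages; returns a list of errors."""
    errors: list[str] = []
    if not isinstance(config, RunConfig):
        try:
            config = RunConfig.from_yaml(config)
        except Exception as exc:
            return [f"cannot parse config: {exc}"]
    unknown = [e for e in config.engines if e not in KNOWN_ENGINES]
    if unknown:
        errors.append(
            f"unknown engine tag(s) {unknown}; expected one of {sorted(KNOWN_ENGINES)}"
        )
    if config.synthetic is None:
        for name, p in [("vcf", config.vcf), ("coords", config.coords)]:
            if p is None:
                errors.append(f"missing required input path: {name}")
            elif not Path(p).exists():
                errors.append(f"{name} path does not exist: {p}")
        if "recent" not in config.grids:
            errors.append("grids must include the 'recent' scenario")
        for label, p in config.grids.items():
            if not Path(p).exists():
                errors.append(f"grid path for {label!r} does not exist: {p}")
    else:
        try:
            config.synthetic.validate()
        except ValueError as exc:
            errors.append(f"synthetic config invalid: {exc}")
    if config.donor_scope not in {"site", "radius", "range"}:
        errors.append(f"donor_scope must be site|radius|range, got {config.donor_scope!r}")
    return errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stage:
    def __init__(self, manifest: dict, out_dir: Path, name: str):
        self.name = name
        self.out_dir = out_dir
        self.dir = out_dir / name
        self.dir.mkdir(parents=True, exist_ok=True)
        self.manifest = manifest

    def register(self, key: str, path: Path) -> Path:
        # paths are stored relative to the run directory so that two runs of
        # the same config+seed produce byte-identical manifests
        self.manifest["artifacts"][f"{self.name}/{key}"] = {
            "path": str(Path(path).relative_to(self.out_dir)),
            "sha256": _sha256(path),
        }
        return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full flow; returns (and writes) the run manifest.

    Stage failures are re-raised with the stage name; artifacts written by
    completed stages persist.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "qc": config.qc, "engines": config.engines,
            "donor_scope": config.donor_scope, "radius_km": config.radius_km,
            "synthetic": config.synthetic.to_dict() if config.synthetic else None,
        },
        "artifacts": {},
        "stages": [],
    }
    stage_name = "setup"
    try:
        # ------------------------------------------------------------------
        stage_name = "simulate"
        st = _Stage(manifest, out_dir, stage_name)
        if config.synthetic is not None:
            synth = config.synthetic
            grids_raw = landscape_mod.make_climate_grids(synth)
            gm_raw, truth, coords = landscape_mod.simulate_genotypes(synth, grids_raw)
            paths = landscape_mod.write_fixture(gm_raw, grids_raw, coords, st.dir, truth)
            for k, p in paths.items():
                st.register(k, p)
            vcf_path = paths["vcf"]
            grid_paths = {
                label: st.dir / f"climate_{label}.csv" for label in grids_raw
            }
            coords_path = st.dir / "coords.csv"
        else:
            vcf_path, grid_paths, coords_path = config.vcf, dict(config.grids), config.coords
        manifest["stages"].append(stage_name)

        # ------------------------------------------------------------------
        stage_name = "qc"
        st = _Stage(manifest, out_dir, stage_name)
        gm, load_report = genotype_mod.load_genotypes(
            vcf_path, min_gt_depth=config.qc.get("min_gt_depth", 5)
        )
        gm, filter_report = genotype_mod.filter_variants(
            gm,
            min_maf=config.qc.get("min_maf", 0.01),
            max_missing=config.qc.get("max_missing", 0.10),
            min_mean_depth=config.qc.get("min_mean_depth", 5),
        )
        gm, ld_report = genotype_mod.ld_prune(
            gm,
            window=config.qc.get("ld_window", 50),
            step=config.qc.get("ld_step", 10),
            r2_max=config.qc.get("ld_r2_max", 0.1),
        )
        gm = genotype_mod.impute_major(gm)
        coords = pd.read_csv(coords_path)
        gm.samples = pd.DataFrame({
            "id": coords["sample_id"], "lon": coords["lon"],
            "lat": coords["lat"], "site": coords["site_id"],
        })
        st.register("dosages", genotype_mod.write_dosage_csv(gm, st.dir / "dosages.csv"))
        st.register("qc_report", filter_report.to_json(st.dir / "qc_report.json"))
        st.register("ld_report", ld_report.to_json(st.dir / "ld_report.json"))
        manifest["stages"].append(stage_name)

        # ------------------------------------------------------------------
        stage_name = "climate"
        st = _Stage(manifest, out_dir, stage_name)
        grids = {
            label: climate_mod.load_grid(p, climate_mod.ScenarioKey.from_label(label))
            for label, p in grid_paths.items()
        }
        variables = list(grids["recent"].variables)
        if config.collinearity_r2 is not None:
            retained, prune_log = climate_mod.prune_collinear(
                grids["recent"].values(), r2_max=config.collinearity_r2,
                keep_priority=config.keep_priority,
            )
            variables = retained
            (st.dir / "collinearity.json").write_text(json.dumps(prune_log, indent=2))
            st.register("collinearity", st.dir / "collinearity.json")
        grids_std, standardizer = climate_mod.standardize(grids)
        env = climate_mod.extract_at_points(grids_std["recent"], coords)
        env_table = env[variables]
        env.to_csv(st.dir / "climate_at_samples.csv", float_format="%.10g")
        st.register("climate_at_samples", st.dir / "climate_at_samples.csv")
        manifest["stages"].append(stage_name)

        # ------------------------------------------------------------------
        stage_name = "structure"
        st = _Stage(manifest, out_dir, stage_name)
        pca = structure_mod.pca_genotypes(gm.dosages)
        geo_d = structure_mod.haversine_matrix(coords.rename(columns={"lon": "lon", "lat": "lat"}))
        gen_d = offsets_mod.cdist(gm.dosages, gm.dosages, metric="euclidean")
        env_std = (env_table - env_table.mean()) / env_table.std()
        env_d = offsets_mod.cdist(env_std, env_std, metric="euclidean")
        ibd = structure_mod.mantel(
            gen_d, geo_d, n_perm=config.mantel_permutations, seed=config.seed
        )
        ibe = structure_mod.partial_mantel(
            gen_d, env_d, geo_d, n_perm=config.mantel_permutations, seed=config.seed + 1
        )
        geo_X = structure_mod.geography_matrix(coords)
        partition = structure_mod.variance_partition(
            gm.dosages, env_table.to_numpy(), geo_X, pca.scores[:, :1],
            n_perm=49, seed=config.seed + 2,
        )
        summary = {
            "pca_explained": pca.explained_fraction[:5].tolist(),
            "ibd": {"r": ibd.statistic, "r2": ibd.statistic ** 2, "p": ibd.p_value},
            "ibe_partial": {"r": ibe.statistic, "r2": ibe.statistic ** 2, "p": ibe.p_value},
            "variance_partition": partition.fractions,
        }
        (st.dir / "structure.json").write_text(json.dumps(summary, indent=2))
        st.register("structure", st.dir / "structure.json")
        manifest["stages"].append(stage_name)

        # ------------------------------------------------------------------
        stage_name = "outliers"
        st = _Stage(manifest, out_dir, stage_name)
        condition = np.column_stack([geo_X, pca.scores[:, :1]])
        outliers = structure_mod.prda_outliers(
            gm.dosages, env_table.to_numpy(), condition,
            locus_ids=gm.variants["id"].tolist(), seed=config.seed + 3,
        )
        outliers.to_frame(gm.variants).to_csv(
            st.dir / "outliers.tsv", sep="\t", index=False, float_format="%.6g"
        )
        st.register("outliers", st.dir / "outliers.tsv")
        if not outliers.outlier_ids:
            raise RuntimeError("no candidate adaptive loci detected; engines need candidates")
        manifest["parameters"]["n_outliers"] = len(outliers.outlier_ids)
        manifest["parameters"]["retained_axes"] = outliers.retained_axes
        manifest["stages"].append(stage_name)

        # ------------------------------------------------------------------
        stage_name = "engines"
        st = _Stage(manifest, out_dir, stage_name)
        cand_idx = [
            int(np.flatnonzero(gm.variants["id"] == l)[0]) for l in outliers.outlier_ids
        ]
        cand = pd.DataFrame(
            gm.dosages[:, cand_idx], columns=outliers.outlier_ids,
            index=env_table.index,
        )
        sites = gm.samples["site"].tolist()
        models: dict[str, Any] = {}
        for name in config.engines:
            params = dict(config.engine_params.get(name, {}))
            if name == "gf":
                params.setdefault("n_trees", config.gf_trees)
            if name == "rda":
                params.setdefault(
                    "n_axes",
                    config.n_retained_axes_rda or max(outliers.retained_axes, 1),
                )
            models[name] = offsets_mod.fit_engine(
                name, cand, env_table, sites=sites, seed=config.seed + 4, **params
            )
            imp = offsets_mod.variable_importance(models[name])
            imp.rename("importance").to_csv(st.dir / f"importance_{name}.csv")
            st.register(f"importance_{name}", st.dir / f"importance_{name}.csv")
        manifest["stages"].append(stage_name)

        # ------------------------------------------------------------------
        stage_name = "offsets"
        st = _Stage(manifest, out_dir, stage_name)
        future_labels = [l for l in grids_std if l != "recent"]
        surfaces: dict[tuple[str, str], offsets_mod.AdaptednessSurface] = {}
        for name, model in models.items():
            for label in future_labels:
                surf = model.offset(grids_std["recent"], grids_std[label])
                surfaces[(name, label)] = surf
                p = surf.to_csv(st.dir / f"offset_{name}_{label}.csv")
                st.register(f"offset_{name}_{label}", p)
        manifest["stages"].append(stage_name)

        # ------------------------------------------------------------------
        stage_name = "transfer"
        st = _Stage(manifest, out_dir, stage_name)
        focal_site = config.focal_site or sorted(set(sites))[0]
        focal_samples = coords[coords["site_id"] == focal_site]
        focal_cells = np.unique(
            climate_mod.extract_at_points(grids_std["recent"], focal_samples)["cell_id"]
        )
        transfer_label = future_labels[0]
        for name, model in models.items():
            donors = transfer_mod.radius_donors(
                grids_std["recent"], focal_cells,
                radius_km=config.radius_km, scope=config.donor_scope,
            )
            tm = transfer_mod.pairwise_transfer(
                model, grids_std["recent"], grids_std[transfer_label],
                donors, focal_cells,
            )
            baseline = transfer_mod.baseline_adaptedness(
                model, grids_std["recent"], grids_std[transfer_label], focal_cells
            )
            prio = transfer_mod.seed_source_priority(tm, baseline)
            st.register(f"priority_{name}", prio.to_csv(st.dir / f"priority_{name}.csv"))
            fwd = transfer_mod.forward_adaptedness(tm)
            fwd.rename_axis("cell_id").to_csv(st.dir / f"forward_{name}.csv")
            st.register(f"forward_{name}", st.dir / f"forward_{name}.csv")
        manifest["parameters"]["focal_site"] = focal_site
        manifest["parameters"]["transfer_scenario"] = transfer_label
        manifest["stages"].append(stage_name)

        # ------------------------------------------------------------------
        stage_name = "compare"
        st = _Stage(manifest, out_dir, stage_name)
        if len(models) >= 2:
            per_scenario = {}
            for label in future_labels:
                off_maps = {
                    name: surfaces[(name, label)].table["offset"] for name in models
                }
                per_scenario[label] = compare_mod.spearman_table(off_maps)
            spearman_df = pd.concat(per_scenario, names=["scenario", "method"])
            spearman_df.to_csv(st.dir / "spearman.tsv", sep="\t", float_format="%.6g")
            st.register("spearman", st.dir / "spearman.tsv")

            names = list(models)
            recent_vals = grids_std["recent"].values()
            configs = {
                n: compare_mod.reduce_for_procrustes(
                    pd.DataFrame(models[n].embed(recent_vals), index=recent_vals.index)
                )
                for n in names
            }
            proc_rows = []
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    pr = compare_mod.procrustes_residuals(configs[a], configs[b])
                    proc_rows.append({
                        "pair": f"{a}-{b}", "correlation": pr.correlation,
                        "ss_residual": pr.ss_residual,
                    })
            pd.DataFrame(proc_rows).to_csv(st.dir / "procrustes.tsv", sep="\t", index=False)
            st.register("procrustes", st.dir / "procrustes.tsv")

        # protection ANOVA over scenario surfaces of the first engine
        first = config.engines[0]
        cells = grids_std["recent"].data
        protected = cells["x"] < cells["x"].median()  # synthetic western mask
        rows = []
        for label in future_labels:
            key = climate_mod.ScenarioKey.from_label(label)
            surf = surfaces[(first, label)]
            rows.append(pd.DataFrame({
                "adaptedness": surf.table["adaptedness"].to_numpy(),
                "protection": np.where(protected.loc[surf.table.index], "protected", "unprotected"),
                "model": key.model, "rcp": key.rcp, "year": key.period,
            }))
        anova_input = pd.concat(rows, ignore_index=True)
        if anova_input["model"].nunique() >= 2 and anova_input["rcp"].nunique() >= 2:
            table = compare_mod.protection_anova(anova_input)
            table.anova.to_csv(st.dir / "anova.tsv", sep="\t")
            st.register("anova", st.dir / "anova.tsv")
            table.tukey.to_csv(st.dir / "tukey.tsv", sep="\t", index=False)
            st.register("tukey", st.dir / "tukey.tsv")
        manifest["stages"].append(stage_name)

    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
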