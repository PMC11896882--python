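"""Pipeline orchestration: simulate -> metrics -> models -> ordination ->
trait-environment -> host specificity, with per-run config mirroring,
logging and a consolidated JSON report."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hosts, io, metrics, models, ordination, traitenv
from .config import SimulationConfig
from .synth import SyntheticDataset, simulate

__all__ = ["RunConfig", "run"]

log = logging.getLogger("lianascape")

ALL_STAGES = ["simulate", "metrics", "structure", "ordination", "traitenv", "hosts"]


@dataclass
class RunConfig:
    output_dir: str | Path = "lianascape_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    n_perm: int = 999
    n_perm_variogram: int = 9999
    simulation: SimulationConfig | None = None
    liana_min: int = 60
    tree_min: int = 100

    def __post_init__(self) -> None:
        if self.n_perm < 99 or self.n_perm_variogram < 99:
            raise ValueError("n_perm must be >= 99")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "simulation"}
        d["output_dir"] = str(d["output_dir"])
        d["simulation"] = self.simulation.to_dict()
        return d


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def run(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the report."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stamp = {"seed": cfg.seed, "config_hash": _config_hash(cfg)}
    report: dict = {"stamp": stamp}
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    try:
        data: SyntheticDataset | None = None
        t0 = time.time()

        if "simulate" in cfg.stages:
            log.info("stage=simulate seed=%d", cfg.seed)
            data = simulate(cfg.simulation)
            io.write_stem_table(data.trees, out / "trees.csv")
            io.write_liana_table(data.lianas, out / "lianas.csv")
            io.write_herb_grid(data.herbs, out / "herbs.csv")
            io.write_trait_table(data.traits.reset_index(), out / "traits.csv")
            io.write_quadrat_frame(data.quadrats, out / "quadrats.csv")
            for plot_id, (dem, dsm) in data.rasters.items():
                io.write_ascii_grid(dem, out / f"dem_{plot_id}.asc")
                io.write_ascii_grid(dsm, out / f"dsm_{plot_id}.asc")
            report["simulate"] = {"n_trees": len(data.trees),
                                  "n_lianas": len(data.lianas)}
        else:
            data = _load(out)

        env = data.env
        if "metrics" in cfg.stages:
            log.info("stage=metrics")
            struct = metrics.quadrat_liana_structure(data.lianas, data.quadrats)
            env.to_csv(out / "env.csv")
            struct.to_csv(out / "liana_structure.csv")
            report["metrics"] = {
                "mean_N_L": float(struct["N_L"].mean()),
                "flagged_pairs": int(metrics.correlation_screen(
                    env[[c for c in metrics.ENV_COLUMNS if c in env]])["flag"].sum()),
            }
        else:
            struct = None

        zcols = [f"z_{c}" for c in metrics.ENV_COLUMNS if f"z_{c}" in env.columns]
        Z = env[zcols].rename(columns=lambda c: c[2:])

        if "structure" in cfg.stages:
            _require(struct is not None, "structure", "metrics")
            log.info("stage=structure")
            tab = []
            for resp in ("N_L", "BA_L", "QMD_L"):
                y = struct[resp]
                ok = y.notna()
                fit = models.stepwise_select(y[ok], Z[ok.values], response=resp)
                # pseudo-replication check at the 1-ha subplot level (the 9-ha
                # plot level needs several plots and is added when available)
                re_test = models.lr_test_random_effect(
                    y[ok], Z[ok.values], data.quadrats.loc[ok.values, "subplot_id"],
                    predictors=fit.predictors, grouping="1-ha subplot")
                re_p_plot = float("nan")
                if data.quadrats["plot_id"].nunique() >= 2:
                    re_p_plot = models.lr_test_random_effect(
                        y[ok], Z[ok.values], data.quadrats.loc[ok.values, "plot_id"],
                        predictors=fit.predictors, grouping="9-ha plot").p_value
                coefs = fit.coefficients
                for term in coefs.index:
                    tab.append({
                        "response": resp, "term": term,
                        "estimate": coefs.loc[term, "estimate"],
                        "ci_lo": coefs.loc[term, "ci_lo"],
                        "ci_hi": coefs.loc[term, "ci_hi"],
                        "r_squared": fit.r_squared, "f_statistic": fit.f_statistic,
                        "re_p_subplot": re_test.p_value, "re_p_plot": re_p_plot,
                    })
            pd.DataFrame(tab).to_csv(out / "models.csv", index=False)
            report["structure"] = {"n_models": 3}

        A = io.build_abundance_matrix(data.lianas, data.quadrats, level="quadrat")
        A = A.loc[A.sum(axis=1) > 0]
        coords = io.quadrat_centers(data.quadrats).loc[A.index]
        Zr = Z.loc[A.index]

        ord_res = None
        if "ordination" in cfg.stages:
            log.info("stage=ordination")
            rng = np.random.default_rng(cfg.seed + 1)
            ns = ordination.nsca(A, n_axes=2)
            ord_res = ordination.nscaiv(A, Zr, n_axes=2, n_perm=cfg.n_perm, rng=rng)
            pc = ordination.pcca(A, Zr, coords, n_axes=2, n_perm=cfg.n_perm, rng=rng)
            ns.site_scores.to_csv(out / "ordination_scores.csv")
            pd.DataFrame({"eigenvalue": ns.eigenvalues}).to_csv(out / "eigenvalues.csv",
                                                                index=False)
            vario = ordination.variogram_permutation_test(
                ns.site_scores["axis1"], coords, n_perm=cfg.n_perm_variogram, rng=rng)
            pd.DataFrame({
                "bound": vario.bounds, "gamma": vario.semivariance,
                "lo": vario.envelope_lo, "hi": vario.envelope_hi,
                "exceeds": vario.exceeds,
            }).to_csv(out / "variogram.csv", index=False)
            report["ordination"] = {
                "nsca_axis12_fraction": float(ns.eigenvalues[:2].sum() / ns.total_inertia),
                "nscaiv_fraction": ord_res.constrained_fraction,
                "nscaiv_p": ord_res.p_value,
                "pcca_fraction": pc.constrained_fraction,
                "pcca_p": pc.p_value,
                "variogram_exceedances": int(vario.exceeds.sum()),
            }
            report["_nsca_scores"] = ns.site_scores

        if "traitenv" in cfg.stages:
            log.info("stage=traitenv")
            rng = np.random.default_rng(cfg.seed + 2)
            res = traitenv.maxtest(A, data.traits, Zr, n_perm=cfg.n_perm, rng=rng)
            res.table.to_csv(out / "trait_env.csv", index=False)
            report["traitenv"] = {"n_significant": int((res.table["p_max"] < 0.05).sum())}
            if "_nsca_scores" in report:
                axis = report["_nsca_scores"]["axis1"]
                null = traitenv.cwm_axis_null(A, data.traits, axis,
                                              n_perm=cfg.n_perm, rng=rng)
                null.to_csv(out / "cwm_axis_null.csv", index=False)
                report["traitenv"]["axis_null_significant"] = int((null["p"] < 0.05).sum())
            elif "ordination" not in cfg.stages:
                raise RuntimeError(
                    "traitenv axis-null stage requires ordination scores: "
                    "enable the 'ordination' stage")

        if "hosts" in cfg.stages:
            log.info("stage=hosts")
            rng = np.random.default_rng(cfg.seed + 3)
            T = io.build_abundance_matrix(data.trees, data.quadrats,
                                          level="buffered").loc[A.index]
            rv = hosts.rv_test(A, T, n_perm=cfg.n_perm, rng=rng)
            report["hosts"] = {"rv": rv.rv, "rv_p": rv.p_value}
            if ord_res is not None:
                ord_t = ordination.nscaiv(T, Zr, n_perm=0)
                rv_res = hosts.rv_test(ord_res.residual_q, ord_t.residual_q,
                                       n_perm=cfg.n_perm, rng=rng)
                report["hosts"]["rv_residual"] = rv_res.rv
                report["hosts"]["rv_residual_p"] = rv_res.p_value
            links, excluded = hosts.build_links(data.lianas, data.trees, data.quadrats)
            assoc = hosts.host_randomization_test(
                links, data.trees, data.quadrats, liana_min=cfg.liana_min,
                tree_min=cfg.tree_min, n_rep=cfg.n_perm, rng=rng)
            assoc.to_csv(out / "associations.csv", index=False)
            summary = hosts.summarize_associations(assoc)
            summary.pop("mechanism_crosstab").to_csv(out / "mechanism_crosstab.csv")
            summary["n_excluded_lianas"] = excluded
            report["hosts"].update(summary)

        report.pop("_nsca_scores", None)
        report["runtime_s"] = round(time.time() - t0, 2)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        log.info("done runtime=%.1fs", report["runtime_s"])
        return report
    finally:
        log.removeHandler(handler)
        handler.close()


def _require(ok: bool, stage: str, needs: str) -> None:
    if not ok:
        raise RuntimeError(f"stage {stage!r} requires stage {needs!r} to be enabled")


def _load(out: Path) -> SyntheticDataset:
    """Reload a previously simulated dataset from an output directory."""
    quadrats = io.read_quadrat_frame(out / "quadrats.csv")
    trees = io.read_stem_table(out / "trees.csv")
    lianas = io.read_liana_table(out / "lianas.csv", stems=trees)
    herbs = io.read_herb_grid(out / "herbs.csv")
    traits = io.read_trait_table(out / "traits.csv").set_index("taxon")
    rasters = {}
    for plot_id in quadrats["plot_id"].unique():
        dem_p = out / f"dem_{plot_id}.asc"
        dsm_p = out / f"dsm_{plot_id}.asc"
        if not dem_p.exists():
            raise RuntimeError(f"missing upstream artifact {dem_p}; run the simulate stage")
        rasters[plot_id] = (io.read_ascii_grid(dem_p), io.read_ascii_grid(dsm_p))
    env = metrics.env_table(trees, quadrats, rasters=rasters, herbs=herbs)
    return SyntheticDataset(config=SimulationConfig(), quadrats=quadrats,
                            rasters=rasters, trees=trees, herbs=herbs, env=env,
                            lianas=lianas, traits=traits, truth=None)
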