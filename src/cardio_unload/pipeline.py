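"""End-to-end pipeline: (synthetic) case -> fit -> validation -> report.

The pipeline runs the fixed-point fit, then re-inflates the identified
unloaded configuration with a fully converging Newton and computes every
goodness-of-fit measure on that validation loading curve; artifacts
(meshes, iteration history, PV-curves, plots, JSON report) are written to
an output directory.  Configuration is a flat key=value text file.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .klotz import build_klotz, sample_klotz
from .materials import MODEL_IDS, default_params
from .mesh import EllipsoidSpec, Mesh, cavity_volume, read_mesh, write_mesh
from .metrics import goodness_report
from .mff import run_mff
from .solver import SolverConfig, inflate
from .synth import generate_synthetic_case
from .units import MM3_PER_ML

__all__ = ["RunConfig", "pipeline", "load_config"]


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run."""

    mesh_path: str = ""               # empty -> generate a synthetic case
    mesh_format: str = "vtk"
    out_dir: str = "out"
    model_id: str = "reduced_HO"
    p_ed: float = 1.07                # kPa
    V_ed: float = 0.0                 # mL; 0 -> use mesh cavity volume
    n_ls: int = 100
    eps_vol_pct: float = 0.5
    eps_nodal_mm: float = 0.1
    eps_param: float = 0.001
    newton_max_iter: int = 2
    newton_rel_tol: float = 1e-6
    linear_rel_tol: float = 1e-8
    spring_stiffness_base: float = 1.0
    spring_stiffness_apex: float = 0.1
    kappa: float = 650.0
    variant: str = "armijo"
    max_iter: int = 50
    seed: int = 0
    resolution: float = 8.0           # synthetic-mesh edge length, mm
    true_a_scale: float = 1.0         # synthetic truth scalings
    true_b_scale: float = 1.0
    make_plots: bool = True

    def solver_config(self) -> SolverConfig:
        return SolverConfig(
            n_ls=self.n_ls, newton_max_iter=self.newton_max_iter,
            newton_rel_tol=self.newton_rel_tol,
            linear_rel_tol=self.linear_rel_tol,
            spring_stiffness_base=self.spring_stiffness_base,
            spring_stiffness_apex=self.spring_stiffness_apex)


def load_config(path) -> RunConfig:
    """Parse a flat ``key = value`` text file into a RunConfig."""
    cfg = RunConfig()
    defaults = asdict(cfg)
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in defaults:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        cur = defaults[key]
        if isinstance(cur, bool):
            parsed = val.lower() in ("1", "true", "yes")
        elif isinstance(cur, int):
            parsed = int(val)
        elif isinstance(cur, float):
            parsed = float(val)
        else:
            parsed = val
        setattr(cfg, key, parsed)
    return cfg


def pipeline(config: RunConfig) -> dict:
    """Run fit + validation; write the report bundle; return the report."""
    if config.model_id not in MODEL_IDS:
        raise ValueError(f"unknown constitutive law {config.model_id!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.solver_config()

    if config.mesh_path:
        path = Path(config.mesh_path)
        if not path.exists() and config.mesh_format == "vtk":
            raise FileNotFoundError(f"mesh file not found: {path}")
        x_dat = read_mesh(path, config.mesh_format)
        truth = None
    else:
        case = generate_synthetic_case(
            EllipsoidSpec(resolution=config.resolution, seed=config.seed),
            config.model_id,
            true_scalings=(config.true_a_scale, config.true_b_scale),
            p_ed=config.p_ed, seed=config.seed, solver_config=cfg)
        x_dat = case.x_dat
        truth = case

    V_ed = config.V_ed if config.V_ed > 0 else cavity_volume(x_dat)
    params0 = default_params(config.model_id, kappa=config.kappa)

    mff = run_mff(x_dat, config.p_ed, V_ed, params0, solver_config=cfg,
                  max_iter=config.max_iter, unload_variant=config.variant,
                  eps_nodal=config.eps_nodal_mm)

    # validation: full-Newton re-inflation from X* with the fitted set;
    # all reported goodness-of-fit measures come from this loading curve
    val = inflate(mff.unloaded_mesh, mff.fitted_params,
                  cfg.for_validation(), config.p_ed)
    klotz = build_klotz(V_ed, config.p_ed)
    report = goodness_report(klotz, val, x_dat, (1.0, 1.0), V_ed, config.p_ed)

    # -- artifacts --------------------------------------------------------
    write_mesh(mff.unloaded_mesh, out / "unloaded.vtk", "vtk")
    val.pv_curve.to_csv(out / "validation_pv.csv")
    hist_rows = []
    for h in mff.history:
        r = h["report"]
        hist_rows.append(
            f"{h['k']},{h['ell']},{h['beta']},{h['scalings'].a_scale},"
            f"{h['scalings'].b_scale},{r.r_V0_rel},{r.r_An_rel},"
            f"{h['r_inf']},{h['status']}")
    (out / "history.csv").write_text(
        "k,ell,beta,a_scale,b_scale,r_V0_rel_pct,r_An_rel_pct,"
        "r_inf_mm,status\n" + "\n".join(hist_rows) + "\n")

    a_tot, b_tot = mff.cumulative_scalings
    bundle = {
        "inputs": {"p_ed_kPa": config.p_ed, "V_ed_mL": V_ed,
                   "model_id": config.model_id, "n_ls": config.n_ls,
                   "variant": config.variant, "seed": config.seed},
        "klotz": {"V0_klotz_mL": klotz.V0_klotz, "V30_mL": klotz.V30,
                  "alpha": klotz.alpha, "beta": klotz.beta},
        "fit": {"a_scale": a_tot, "b_scale": b_tot,
                "params": mff.fitted_params.to_dict(),
                "iterations": mff.iterations,
                "n_forward_solves": mff.n_forward_solves,
                "converged": mff.converged, "stagnated": mff.stagnated},
        "validation": {**report.to_dict(),
                       "V0_sim_mL": float(val.pv_curve.volumes[0]),
                       "V_ed_sim_mL": float(val.pv_curve.volumes[-1])},
    }
    if truth is not None:
        d = float(np.max(np.linalg.norm(
            mff.unloaded_mesh.nodes - truth.truth_mesh.nodes, axis=1)))
        bundle["synthetic_truth"] = {
            "true_scalings": list(truth.provenance["true_scalings"]),
            "V0_truth_mL": truth.V0_truth,
            "max_nodal_error_X_star_mm": d,
        }
    (out / "report.json").write_text(json.dumps(bundle, indent=2))

    if config.make_plots:
        _plot_fit(out / "fit.png", klotz, val.pv_curve, V_ed, config.p_ed)
    return bundle


def _plot_fit(path, klotz, pv, V_ed, p_ed):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ks = sample_klotz(klotz, 100, p_ed)
    ax.plot(ks.volumes, ks.pressures, "--", color="gray",
            label="empirical EDPVR")
    ax.plot(pv.volumes, pv.pressures, "-", color="crimson",
            label="fitted model")
    ax.axvline(klotz.V0_klotz, color="gray", lw=1)
    ax.plot([V_ed], [p_ed], "o", color="navy", label="measured PV-point")
    ax.set_xlabel("volume [mL]")
    ax.set_ylabel("pressure [kPa]")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
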