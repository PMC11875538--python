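"""One-command orchestration: ensembles in, fingerprint report out.

``run_fingerprint`` reads a YAML config naming one or two replicate
ensembles (multi-model PDB + optional weight/bias table), computes the
collective variables, classifies states, estimates populations with block
errors, combines replicates, builds the free-energy surfaces, and — when an
experimental SAXS curve is configured — back-calculates the ensemble SAXS
curve, fits scale/background and reports chi-square and the Guinier R_g.
The JSON report echoes every threshold so it is self-describing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ensemble_io import (DomainArchitecture, WeightedEnsemble, load_architecture,
                          read_ensemble, read_saxs_curve, write_table)
from .fes import (fes_2d, grid_to_rows, isoline_spacing_printed,
                  state_conditioned_fes)
from .geometry import compute_cv_table, cv_table_to_frame
from .reweighting import block_error, effective_sample_size
from .saxs import ensemble_intensity, fit_scale_and_chi2, guinier_rg
from .states import (STATES, StatePartition, combine_replicates,
                     fingerprint_call, state_populations)

logger = logging.getLogger("lcfingerprint")

__all__ = ["ensemble_average_rg", "run_fingerprint"]


def ensemble_average_rg(ensemble: WeightedEnsemble,
                        n_blocks: int = 5) -> tuple[float, float]:
    """Weighted mean of the per-frame mass-weighted R_g (nm), with block stderr.

    Per frame R_g = sqrt(sum_i m_i |x_i - COM|^2 / sum_i m_i) over all atoms.
    """
    m = ensemble.masses
    M = m.sum()
    com = np.einsum("fij,i->fj", ensemble.coords, m) / M
    dev = ensemble.coords - com[:, None, :]
    rg = np.sqrt(np.einsum("fij,fij,i->f", dev, dev, m) / M)
    if ensemble.n_frames < max(2, n_blocks):
        return float(np.dot(ensemble.weights, rg)), 0.0
    return block_error(rg, ensemble.weights, n_blocks=n_blocks)


def _partition_from_cfg(cfg: dict) -> StatePartition:
    p = cfg.get("partition", {}) or {}
    return StatePartition(
        theta_straight=float(p.get("theta_straight", 2.5)),
        d_low=float(p.get("d_low", 3.4)),
        d_high=float(p.get("d_high", 4.1)),
    )


def _architecture_from_cfg(cfg: dict) -> DomainArchitecture:
    a = cfg.get("architecture")
    if a is None:
        return DomainArchitecture.default()
    chains = tuple(a["chains"])
    return DomainArchitecture(chains, tuple(a["vl"]), tuple(a["linker"]),
                              tuple(a["cl"]))


def run_fingerprint(config_path: str | Path,
                    output_dir: str | Path | None = None) -> dict:
    """Execute the full analysis battery described by a YAML config.

    Returns the report dict; writes ``report.json`` plus per-replicate CV,
    population and FES tables into the output directory.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    out = Path(output_dir or cfg.get("output_dir", config_path.parent / "fingerprint_out"))
    out.mkdir(parents=True, exist_ok=True)

    temperature = float(cfg.get("temperature_K", 310.0))
    n_blocks = int(cfg.get("n_blocks", 5))
    partition = _partition_from_cfg(cfg)
    arch = _architecture_from_cfg(cfg)

    replicates = cfg.get("replicates")
    if not replicates or len(replicates) > 2:
        raise ValueError("config must name 1-2 replicate ensembles")

    report: dict = {
        "schema_version": 1,
        "software": {"name": "lcfingerprint", "version": __version__},
        "config": {
            "file": str(config_path),
            "temperature_K": temperature,
            "n_blocks": n_blocks,
            "partition": asdict(partition),
            "isoline_spacing_kJmol": isoline_spacing_printed(temperature),
        },
        "replicates": [],
    }

    pop_tables = []
    for i, rep in enumerate(replicates):
        stage = f"replicate {i}"
        try:
            ens = read_ensemble(rep["coords"], arch,
                                weight_path=rep.get("weights"),
                                temperature_K=temperature,
                                replicate_id=rep.get("id", f"rep{i}"))
        except Exception as exc:
            raise RuntimeError(f"{stage}: reading ensemble failed: {exc}") from exc
        logger.info("%s: %d frames, ESS %.1f", stage, ens.n_frames,
                    effective_sample_size(ens.weights))

        cvs = compute_cv_table(ens, arch)
        cv_path = out / f"cvs_rep{i}.tsv"
        write_table(cv_table_to_frame(cvs), cv_path)

        pops = state_populations(cvs, partition, n_blocks=n_blocks)
        pop_tables.append(pops)
        write_table(pops.as_rows(), out / f"populations_rep{i}.tsv")

        grid = fes_2d([r.theta for r in cvs], [r.d_vc for r in cvs],
                      [r.weight for r in cvs], temperature_K=temperature,
                      x_name="theta", y_name="d_VC",
                      x_unit="rad", y_unit="nm")
        write_table(grid_to_rows(grid), out / f"fes_theta_dvc_rep{i}.tsv")

        rg, rg_err = ensemble_average_rg(ens, n_blocks=n_blocks)
        rep_report = {
            "id": ens.replicate_id,
            "n_frames": ens.n_frames,
            "effective_sample_size": effective_sample_size(ens.weights),
            "populations": {s: {"percent": pops.percent[s],
                                "stderr": pops.stderr[s]} for s in STATES},
            "rg_nm": {"mean": rg, "stderr": rg_err},
            "files": {"cvs": cv_path.name,
                      "populations": f"populations_rep{i}.tsv",
                      "fes": f"fes_theta_dvc_rep{i}.tsv"},
        }

        if cfg.get("rmsf"):
            from .flexibility import average_rmsf, rmsf
            rmsf_files = {}
            for dom in ("VL", "CL"):
                profs = [rmsf(ens, arch, c, dom) for c in arch.chain_ids]
                avg = average_rmsf(profs)
                fname = f"rmsf_{dom.lower()}_rep{i}.tsv"
                write_table(pd.DataFrame({"res_id": avg.res_ids,
                                          "rmsf_nm": avg.values}), out / fname)
                rmsf_files[dom] = fname
            rep_report["rmsf"] = {"files": rmsf_files,
                                  "averaged_chains": list(arch.chain_ids)}

        saxs_cfg = cfg.get("saxs")
        if saxs_cfg:
            try:
                exp = read_saxs_curve(saxs_cfg["experimental"],
                                      q_unit=saxs_cfg.get("q_unit", "A^-1"))
                calc = ensemble_intensity(ens, exp.q)
                fit = fit_scale_and_chi2(
                    calc, exp, q_max=saxs_cfg.get("q_max"),
                    fit_background=bool(saxs_cfg.get("fit_background", False)))
                gu = guinier_rg(exp)
                rep_report["saxs"] = {
                    "chi2": fit.chi2, "scale": fit.scale,
                    "background": fit.background,
                    "guinier_rg_nm": gu.rg, "guinier_rg_stderr_nm": gu.rg_stderr,
                    "guinier_n_points": gu.n_points,
                }
                write_table(
                    [{"q": q, "residual": r} for q, r in zip(fit.q, fit.residuals)],
                    out / f"saxs_residuals_rep{i}.tsv")
            except Exception as exc:
                raise RuntimeError(f"{stage}: SAXS stage failed: {exc}") from exc
        report["replicates"].append(rep_report)

    combined = pop_tables[0] if len(pop_tables) == 1 else combine_replicates(*pop_tables)
    call = fingerprint_call(combined)
    report["combined_populations"] = {
        s: {"percent": combined.percent[s], "stderr": combined.stderr[s]}
        for s in STATES}
    report["fingerprint_call"] = call
    report["timestamp"] = datetime.now(timezone.utc).isoformat()

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
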