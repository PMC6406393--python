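"""End-to-end analysis pipeline: circuit, cohort, therapy, ensembles.

Runs the whole study at configurable problem sizes and writes
diff-friendly text artifacts (CSV time series, TSV matrices, JSON
summaries). Every text artifact starts with a comment header recording
the package version, seed and configuration hash; JSON artifacts carry
the same metadata under a ``_meta`` key.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import __version__
from .calibrate import default_params
from .circuit import CircuitState, simulate
from .cohort import (limit_cycle, phenotype_fractions, population_cv,
                     sample_initial_conditions, simulate_cohort,
                     sync_order_parameter)
from .ensemble_metrics import (REGIONS, contact_map, contact_pca,
                               ensemble_rg, free_energy_profile)
from .oscillation import detect_period, quench_time
from .protocols import bat, constant_adt, intermittent_adt, no_treatment
from .synthetic_ensembles import default_presets, generate_ensemble

__all__ = ["RunConfig", "run_full_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    output_dir: str = "page4_run"
    seed: int = 42
    params_file: str | None = None      # None -> shipped calibrated default
    n_cells: int = 1000
    n_conformers: int = 150
    snapshot_days: tuple[int, ...] = (0, 7, 14)
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _header(cfg: RunConfig) -> str:
    return (f"# page4-dynamics {__version__} seed={cfg.seed} "
            f"config={cfg.config_hash()}\n")


def _write_csv(cfg: RunConfig, path: Path, df) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, index=False)


def _write_tsv_matrix(cfg: RunConfig, path: Path, matrix: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        np.savetxt(fh, matrix, fmt="%.6f", delimiter="\t")


def _write_json(cfg: RunConfig, path: Path, payload: dict) -> None:
    doc = {"_meta": {"package": "page4-dynamics", "version": __version__,
                     "seed": cfg.seed, "config": cfg.config_hash()}}
    doc.update(payload)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute every analysis stage and return the summary dictionary.

    Stages: load calibrated parameters -> single-cell dynamics (period,
    ADT quench) -> cohort snapshots under constant ADT -> intermittent
    ADT synchronization and BAT phenotype switching -> synthetic-ensemble
    structural signatures. Partial outputs are kept on failure.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    stage = "load-params"
    try:
        if config.params_file:
            import yaml

            from .circuit import CircuitParams
            with open(config.params_file) as fh:
                params = CircuitParams.from_dict(
                    {k: float(v) for k, v in yaml.safe_load(fh).items()})
        else:
            params = default_params()

        # -- single cell ------------------------------------------------
        stage = "single-cell"
        cyc = limit_cycle(params)
        ic = CircuitState.from_array(cyc.states[0])
        free = simulate(params, None, ic, (0.0, 2000.0))
        period = detect_period(free, "H").period
        summary["period_h"] = round(float(period), 2)
        _write_csv(config, out / "trajectory_free.csv", free.to_frame())

        # >3 full periods before onset so the reference amplitude is defined
        t_on = 600.0
        adt = constant_adt(t_on=t_on)
        treated = simulate(params, adt, ic, (0.0, 1600.0))
        q = quench_time(treated, "H", t_on=t_on)
        summary["quench_h"] = round(float(q - t_on), 2)
        _write_csv(config, out / "trajectory_adt.csv", treated.to_frame())

        # -- cohort under constant ADT ---------------------------------
        stage = "cohort"
        t_end = max(config.snapshot_days) * 24.0 or 24.0
        cohort = simulate_cohort(params, constant_adt(t_on=0.0),
                                 config.n_cells, config.seed, (0.0, t_end))
        rows = []
        h_mid, c_mid = cyc.midrange["H"], cyc.midrange["C"]
        for day in config.snapshot_days:
            t = day * 24.0
            cv = population_cv(cohort, "K", t)
            summary[f"cv_day{day}"] = round(float(cv), 4)
            for j in range(cohort.n_cells):
                W, H, C, K, A = cohort.per_cell_states[
                    j, int(np.argmin(np.abs(cohort.times - t)))]
                rows.append((j, day, W, H, C, K, A))
        import pandas as pd

        _write_csv(config, out / "cohort_snapshots.csv",
                   pd.DataFrame(rows, columns=["cell_id", "day", "W", "H",
                                               "C", "K", "A"]))

        # -- alternative protocols -------------------------------------
        stage = "protocols"
        n_sync = min(config.n_cells, 200)
        iadt = intermittent_adt(168.0, 168.0, 0.0, 2)
        co_i = simulate_cohort(params, iadt, n_sync, config.seed, (0.0, 672.0))
        summary["sync_R_iadt"] = round(sync_order_parameter(co_i, 672.0), 4)
        co_b = simulate_cohort(params, bat(), n_sync, config.seed, (0.0, 1344.0))
        # late in the second cycle: end of its OE block / end of its ADT block
        fr_oe = phenotype_fractions(co_b, 1007.0, h_mid, c_mid)
        fr_adt = phenotype_fractions(co_b, 1344.0, h_mid, c_mid)
        summary["bat_ad_fraction_oe"] = round(fr_oe["AD"], 4)
        summary["bat_ai_fraction_adt"] = round(fr_adt["AI"], 4)

        # -- ensembles --------------------------------------------------
        stage = "ensembles"
        presets = default_presets()
        seeds = {"WT": config.seed + 1, "HIPK1": config.seed + 2,
                 "CLK2": config.seed + 3}
        ens = {k: generate_ensemble(p, config.n_conformers, seed=seeds[k])
               for k, p in presets.items()}
        rg = {k: float(ensemble_rg(e).mean()) for k, e in ens.items()}
        for k, e in ens.items():
            if config.n_conformers >= 100:   # profile needs enough samples
                centers, F = free_energy_profile(ensemble_rg(e), n_bins=20)
                _write_csv(config, out / f"rg_profile_{k.lower()}.csv",
                           pd.DataFrame({"rg_A": centers, "F_kT": F}))
            _write_tsv_matrix(config, out / f"contact_map_{k.lower()}.tsv",
                              contact_map(e).matrix)
        summary["rg_ordering_ok"] = bool(
            rg["CLK2"] > rg["WT"]
            and abs(rg["WT"] - rg["HIPK1"]) / rg["WT"] < 0.10)
        pca = contact_pca(ens["HIPK1"])
        pi = pca.pair_index
        in_block = lambda rows, cols: ((pi[:, 0] >= rows[0]) & (pi[:, 0] <= rows[1])
                                       & (pi[:, 1] >= cols[0]) & (pi[:, 1] <= cols[1]))
        n_load = pca.modes[0, in_block(REGIONS["n_motif"],
                                       REGIONS["central_acidic"])].mean()
        c_load = pca.modes[0, in_block(REGIONS["central_acidic"],
                                       REGIONS["c_motif"])].mean()
        summary["pca_anticorrelation_ok"] = bool(n_load * c_load < 0)
        modes_doc = [
            {"pair": [int(a), int(b)], "pc1": float(pca.modes[0, idx]),
             "pc2": float(pca.modes[1, idx])}
            for idx, (a, b) in enumerate(pi)
            if abs(pca.modes[0, idx]) > 0.02 or abs(pca.modes[1, idx]) > 0.02
        ]
        _write_json(config, out / "pca_modes_hipk1.json", {"modes": modes_doc})

        _write_json(config, out / "summary.json", summary)
    except Exception as exc:  # noqa: BLE001 - re-tag with the failing stage
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    return summary
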