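"""End-to-end analysis pipeline: estimate, report, sensitivity, simulate.

``run_pipeline`` ties the stages together in order — pooled estimation,
lineage estimation, flux/probability/stringency reports, sensitivity sweeps,
variability propagation, and a zero-start trajectory ensemble — writing JSON
and CSV artifacts to an output directory.  All sweeps are deterministic
grids, so a given configuration always reproduces byte-identical numbers;
the seed is consumed only by synthetic-cohort generation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import model, rates as rates_mod, sensitivity as sens_mod
from .cohort import cohort_stats, load_cohort_csv, reference_cohort
from .estimation import EstimationConfig, LineageSPEstimator
from .params import CompartmentState

log = logging.getLogger("thymoselect")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings.

    ``cohort_csv`` of None uses the bundled wild-type reference cohort.
    ``sim_t_end`` (days) and ``sim_max_sets`` bound the trajectory ensemble;
    ``round_digits`` applies only to the human-readable report.
    """

    cohort_csv: str | None = None
    outdir: str = "thymoselect_out"
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    sensitivity_fraction: float = 0.1
    sim_t_end: float = 42.0
    sim_dt: float = model.DEFAULT_DT
    sim_max_sets: int = 548
    round_digits: int = 1
    seed: int = 0


def _half_widths(summary: pd.DataFrame) -> dict[str, float]:
    return {name: (row["max"] - row["min"]) / 2.0 for name, row in summary.iterrows()}


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Run every stage and write the report bundle; returns it as a dict."""
    cfg = config or RunConfig()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = (load_cohort_csv(cfg.cohort_csv) if cfg.cohort_csv
              else reference_cohort())
    stats = cohort_stats(cohort)
    log.info("cohort: %d mice from %s", stats.n_mice,
             cfg.cohort_csv or "bundled reference table")

    est = LineageSPEstimator.from_config(cfg.estimation).fit(cohort)
    pooled = est.pooled_
    log.info("pooled fit: %d/%d lam3 candidates accepted; lineage fit: %d/%d "
             "phi4 candidates accepted (rejections %s)",
             pooled.n_accepted_, pooled.fit_.n_candidates,
             est.n_accepted_, est.fit_.n_candidates, est.rejection_counts_)

    pooled_rates = pooled.to_rates()
    lineage_rates = est.to_rates()
    fates_pooled = rates_mod.fate_probabilities(pooled_rates)
    fates_lineage = rates_mod.fate_probabilities(lineage_rates)
    flux_p = rates_mod.flux_report(pooled_rates, stats)
    flux_l = rates_mod.flux_report(lineage_rates, stats)
    str_p = rates_mod.stringency(pooled_rates, stats)
    str_l = rates_mod.stringency(lineage_rates, stats)

    log.info("running pooled sensitivity sweep (+/-%.0f%%, 2^8 corners)",
             100 * cfg.sensitivity_fraction)
    sens_p = sens_mod.sensitivity_pooled(cohort, cfg.estimation,
                                         fraction=cfg.sensitivity_fraction)
    log.info("running lineage sensitivity sweep (2^7 x n_phi4 candidates)")
    sens_l = sens_mod.sensitivity_lineage(cohort, pooled.means_(),
                                          cfg.estimation,
                                          fraction=cfg.sensitivity_fraction)

    hw = {**_half_widths(sens_p), **_half_widths(sens_l)}
    f = cfg.sensitivity_fraction
    deltas = rates_mod.RateDeltas(
        dmu1=hw["mu1"], dphi1=hw["phi1"], dmu2=hw["mu2"], dphi2=hw["phi2"],
        dmu3=hw["mu3"], dphi3=hw["phi3"], dlam3=hw["lam3"],
        dphi4=hw["phi4"], dphi8=hw["phi8"], dmu4=hw["mu4"], dxi4=hw["xi4"],
        dlam4=hw["lam4"], dmu8=hw["mu8"], dxi8=hw["xi8"], dlam8=hw["lam8"],
        dn4bar=f * stats.mean_of("n4"), dn8bar=f * stats.mean_of("n8"),
        dphi=hw["phi"])
    var = rates_mod.variability(pooled_rates, lineage_rates, deltas, stats)

    log.info("simulating zero-start trajectory ensemble (%g d, <=%d sets)",
             cfg.sim_t_end, cfg.sim_max_sets)
    envelope = _trajectory_ensemble(est, cfg)

    bundle = {
        "pooled": {
            "estimates": pooled.means_(),
            "intervals": pooled.intervals_,
            "n_accepted": pooled.n_accepted_,
            "fates_percent": fates_pooled.percent(),
            "survival_product_percent": 100 * fates_pooled.survival_product(),
            "stringency_percent": 100 * str_p.sigma,
        },
        "lineage": {
            "estimates": {**est.fit_.means(),
                          "a3": est.a3_, "a4": est.a4_, "a5": est.a5_},
            "intervals": est.intervals_,
            "n_accepted": est.n_accepted_,
            "rejections": est.rejection_counts_,
            "fates_percent": fates_lineage.percent(),
            "stringency_percent": 100 * str_l.sigma,
        },
        "variability_percent": var.percent(),
    }
    (outdir / "report.json").write_text(json.dumps(bundle, indent=2))
    flux_p.to_csv(outdir / "fluxes_pooled.csv", index=False)
    flux_l.to_csv(outdir / "fluxes_lineage.csv", index=False)
    sens_p.to_csv(outdir / "sensitivity_pooled.csv")
    sens_l.to_csv(outdir / "sensitivity_lineage.csv")
    envelope.to_csv(outdir / "trajectory_envelope.csv", index=False)
    (outdir / "params_pooled.json").write_text(pooled_rates.to_json())
    (outdir / "params_lineage.json").write_text(lineage_rates.to_json())
    _write_report_txt(outdir / "report.txt", bundle, flux_p, flux_l,
                      cfg.round_digits)
    log.info("wrote report bundle to %s", outdir)
    bundle["fluxes_pooled"] = flux_p
    bundle["fluxes_lineage"] = flux_l
    bundle["sensitivity_pooled"] = sens_p
    bundle["sensitivity_lineage"] = sens_l
    bundle["trajectory_envelope"] = envelope
    return bundle


def _trajectory_ensemble(est: LineageSPEstimator, cfg: RunConfig) -> pd.DataFrame:
    """Min/mean/max trajectory envelope over the accepted lineage sweep.

    Every accepted (phi4, phi8, lam4, lam8) candidate — shared-stage rates at
    their pooled means — is integrated with RK4 from an empty thymus; the
    accepted table is thinned to at most ``sim_max_sets`` rows.
    """
    acc = est.accepted_
    if len(acc) > cfg.sim_max_sets:
        idx = np.linspace(0, len(acc) - 1, cfg.sim_max_sets).round().astype(int)
        acc = acc.iloc[np.unique(idx)]
    init = CompartmentState.split(0.0, 0.0, 0.0, 0.0, 0.0)
    base = est.to_rates()
    trajs = []
    for _, row in acc.iterrows():
        r = dataclasses.replace(base, phi4=row["phi4"], phi8=row["phi8"],
                                lam4=row["lam4"], lam8=row["lam8"])
        trajs.append(model.rk4_simulate(r, init, t_end=cfg.sim_t_end,
                                        dt=cfg.sim_dt))
    stack = np.stack([t[["n1", "n2", "n3", "n4", "n8"]].to_numpy()
                      for t in trajs])
    t = trajs[0]["t"].to_numpy()
    out = {"t": t}
    for i, c in enumerate(("n1", "n2", "n3", "n4", "n8")):
        out[f"{c}_min"] = stack[:, :, i].min(axis=0)
        out[f"{c}_mean"] = stack[:, :, i].mean(axis=0)
        out[f"{c}_max"] = stack[:, :, i].max(axis=0)
    return pd.DataFrame(out)


def _write_report_txt(path: Path, bundle: dict, flux_p: pd.DataFrame,
                      flux_l: pd.DataFrame, digits: int) -> None:
    lines = ["thymoselect report", "==================", ""]
    lines.append("Pooled-model estimates (1/day; phi cells/day):")
    for k, v in bundle["pooled"]["estimates"].items():
        lines.append(f"  {k:>6} = {v:.4g}")
    lines.append("Fate probabilities (%):")
    for k, v in bundle["pooled"]["fates_percent"].items():
        lines.append(f"  {k:>6} = {round(v, digits)}")
    lines.append(f"  survival product = "
                 f"{round(bundle['pooled']['survival_product_percent'], digits + 1)}")
    lines.append(f"  stringency sigma = "
                 f"{round(bundle['pooled']['stringency_percent'], digits + 1)}")
    lines.append("")
    lines.append("Lineage-model estimates (1/day):")
    for k, v in bundle["lineage"]["estimates"].items():
        lines.append(f"  {k:>6} = {v:.4g}")
    lines.append("Fate probabilities (%):")
    for k, v in bundle["lineage"]["fates_percent"].items():
        lines.append(f"  {k:>6} = {round(v, digits)}")
    lines.append(f"  stringency sigma = "
                 f"{round(bundle['lineage']['stringency_percent'], digits + 1)}")
    lines.append("")
    for title, fl in (("Pooled fluxes", flux_p), ("Lineage fluxes", flux_l)):
        lines.append(f"{title} (cells/h, at cohort mean counts):")
        for _, row in fl.iterrows():
            lines.append(f"  {row['process']:<26} {row['compartment']:<3} "
                         f"{row['cells_per_hour']:.3g}")
        lines.append("")
    path.write_text("\n".join(lines))
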