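"""End-to-end pipeline: simulate -> estimate -> FRIA -> decompose.

Given a preset library and a list of (construct, condition) selections, the
pipeline simulates every assay, applies the corresponding estimators, and
produces a tidy per-construct metrics table, the QC-loss decomposition, and a
machine-readable JSON report with full provenance (package version, master
seed, preset-file hash). Identical configurations produce identical outputs.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, estimators, fria
from .decomposition import decompose, qc_response, rank_and_tabulate, relative_metrics
from .params import NoiseModel
from .presets import PresetLibrary, load_presets
from .simulate import simulate_chx, simulate_pulse_chase, simulate_surface_pools, simulate_vesicle_ph

__all__ = ["RunConfig", "SummaryReport", "run_pipeline", "derive_seed"]

logger = logging.getLogger(__name__)

#: Default assay schedules (minutes / hours), matching the wet protocols.
INTERNALIZATION_MIN = tuple(float(m) for m in range(8))
TURNOVER_H = (1.5, 3.0, 4.5, 6.0)
RECYCLING_MIN = (2.0, 5.0, 10.0, 15.0, 20.0)
CHX_H = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
FRIA_CHASE_H = 3.0
FRIA_N_VESICLES = 500
PULSE_CHASE_REPS = 3


@dataclass(frozen=True)
class RunConfig:
    preset_path: Path | None = None
    seed: int = 0
    output_dir: Path = Path("hergqc_out")
    selections: tuple = ()  # ((construct, condition), ...); empty = all presets
    noise: NoiseModel = field(default_factory=NoiseModel)
    wt_name: str = "WT"
    permissive: bool = False
    log_level: str = "INFO"


@dataclass
class SummaryReport:
    metrics: pd.DataFrame  # construct, condition, metric, value, sem, n
    decomposition: pd.DataFrame
    provenance: dict
    flagged: list[str]


def derive_seed(master: int, *stream) -> int:
    """Stable per-assay child seed (< 2**31) from the master seed."""
    digest = np.random.SeedSequence(
        [int(master)] + [zlib.crc32(str(s).encode()) for s in stream]
    ).generate_state(1)[0]
    return int(digest) & 0x7FFFFFFF


def _construct_metrics(
    lib: PresetLibrary, construct: str, condition: str, noise: NoiseModel, seed: int
) -> tuple[list[dict], dict, list[str]]:
    """Simulate and estimate every assay for one preset."""
    preset = lib.get(construct, condition)
    params = lib.params(construct, condition)
    flagged: list[str] = []
    rows: list[dict] = []
    raw: dict = {}

    def add(metric: str, value: float, sem: float = 0.0, n: int = 1) -> None:
        rows.append(
            {
                "construct": construct,
                "condition": condition,
                "metric": metric,
                "value": value,
                "sem": sem,
                "n": n,
            }
        )

    pc = simulate_pulse_chase(
        params, noise, n_reps=PULSE_CHASE_REPS, seed=derive_seed(seed, construct, condition, "pc")
    )
    mat = estimators.maturation_from_table(pc)
    add("maturation_pct", mat.mean_pct, mat.sem_pct, len(mat.per_replicate_pct))
    rem = estimators.fraction_remaining(pc)
    add("pct_label_remaining_3h", rem.mean_pct, rem.sem_pct, len(rem.per_replicate_pct))
    raw["maturation_pct"] = mat.mean_pct

    tc = simulate_surface_pools(
        params, TURNOVER_H, "turnover", noise, seed=derive_seed(seed, construct, condition, "to")
    )
    fit = estimators.surface_decay_fit(tc)
    if not fit.converged:
        flagged.append(f"{construct}/{condition}: turnover fit did not converge")
    add("surface_half_life_h", fit.half_life)
    raw["turnover_rate_per_h"] = fit.rate

    itc = simulate_surface_pools(
        params,
        INTERNALIZATION_MIN,
        "internalization",
        noise,
        seed=derive_seed(seed, construct, condition, "int"),
    )
    add("pct_internalized_5min", estimators.percent_internalized(itc, 5.0))

    rt = simulate_surface_pools(
        params, RECYCLING_MIN, "recycling", noise, seed=derive_seed(seed, construct, condition, "rec")
    )
    add("recycling_pct_10min", estimators.recycling_percent(rt, 10.0))

    # paired design: both temperatures share one seed, i.e. the same blotting
    # noise realization, as for dishes processed on the same gel
    chx_seed = derive_seed(seed, construct, condition, "chx")
    chx = [simulate_chx(params, temp, CHX_H, noise, seed=chx_seed) for temp in (37, 41)]
    fits = [
        estimators.fit_single_exponential(c.data["time_h"], c.data["mature"]) for c in chx
    ]
    add("chx_fold_41_vs_37", estimators.temperature_fold(fits[1], fits[0]))

    if FRIA_CHASE_H in preset.ph_mixtures:
        vs = simulate_vesicle_ph(
            preset.ph_mixtures[FRIA_CHASE_H],
            FRIA_N_VESICLES,
            seed=derive_seed(seed, construct, condition, "fria"),
            chase_time_h=FRIA_CHASE_H,
        )
        res = fria.fit_multi_gaussian(fria.build_histogram(vs), k="auto")
        if not res.converged:
            flagged.append(f"{construct}/{condition}: vesicular pH mixture fit not converged")
        add("mean_vesicular_ph_3h", res.mean_ph, n=res.n_vesicles)

    # Steady-state PM expression signal (arbitrary gain), to be mRNA/WT-normalized.
    rng = np.random.default_rng(derive_seed(seed, construct, condition, "pm"))
    gain = 1000.0
    pm_noise = rng.lognormal(
        -np.log1p(noise.cv_well**2) / 2.0, np.sqrt(np.log1p(noise.cv_well**2)), noise.n_wells
    ).mean() if noise.cv_well > 0 else 1.0
    raw["pm_signal"] = gain * (preset.pm_pct_of_wt / 100.0) * preset.mrna_level * pm_noise
    raw["mrna_level"] = preset.mrna_level
    add("pm_signal_raw", raw["pm_signal"])
    return rows, raw, flagged


def run_pipeline(cfg: RunConfig) -> SummaryReport:
    """Run the full simulate -> estimate -> decompose pipeline and write outputs."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    lib = load_presets(cfg.preset_path)
    selections = tuple(cfg.selections) or tuple(lib.keys())
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    all_rows: list[dict] = []
    raw_by_key: dict[tuple[str, str], dict] = {}
    flagged: list[str] = []
    for construct, condition in selections:
        rows, raw, flags = _construct_metrics(lib, construct, condition, cfg.noise, cfg.seed)
        all_rows.extend(rows)
        raw_by_key[(construct, condition)] = raw
        flagged.extend(flags)

    metrics = pd.DataFrame(all_rows)

    # Decomposition over untreated constructs (requires untreated WT).
    untreated = {c: r for (c, cond), r in raw_by_key.items() if cond == "untreated"}
    decomposition = pd.DataFrame()
    if cfg.wt_name in untreated:
        raw_me = {c: r["maturation_pct"] for c, r in untreated.items()}
        norm = estimators.normalize_to_mrna_and_wt(
            {c: r["pm_signal"] for c, r in untreated.items()},
            {c: r["mrna_level"] for c, r in untreated.items()},
            cfg.wt_name,
        )
        rates = {c: r["turnover_rate_per_h"] for c, r in untreated.items()}
        summaries = relative_metrics(raw_me, norm, rates, cfg.wt_name)
        dec_rows = []
        for s in summaries:
            row = decompose(s)
            resp = qc_response(s)
            dec_rows.append(
                {
                    "construct": row.construct,
                    "er_loss_pct": row.er_loss_pct,
                    "peripheral_loss_pct": row.peripheral_loss_pct,
                    "total_loss_pct": row.total_loss_pct,
                    "stability_flag": row.stability_flag,
                    "er_response_fold": resp.er_response_fold,
                    "peripheral_response_fold": resp.peripheral_response_fold,
                }
            )
        order = {
            r.construct: i
            for i, r in enumerate(
                rank_and_tabulate(
                    [decompose(s) for s in summaries]
                )
            )
        }
        dec_rows.sort(key=lambda r: order[r["construct"]])
        decomposition = pd.DataFrame(dec_rows)

    provenance = {
        "package_version": __version__,
        "seed": cfg.seed,
        "preset_sha256": lib.sha256,
    }

    prov_header = {"hergqc_version": __version__, "seed": cfg.seed, "preset_sha256": lib.sha256}
    metrics_path = outdir / "summary.csv"
    with metrics_path.open("w") as fh:
        for key, value in prov_header.items():
            fh.write(f"# {key}: {value}\n")
        metrics.to_csv(fh, index=False)
    if not decomposition.empty:
        dec_path = outdir / "decomposition.csv"
        with dec_path.open("w") as fh:
            for key, value in prov_header.items():
                fh.write(f"# {key}: {value}\n")
            decomposition.to_csv(fh, index=False)

    report = {
        "provenance": provenance,
        "flagged": flagged,
        "metrics": metrics.to_dict(orient="records"),
        "decomposition": decomposition.to_dict(orient="records"),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    if flagged:
        logger.warning("flagged non-convergence: %s", flagged)
    return SummaryReport(metrics, decomposition, provenance, flagged)
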