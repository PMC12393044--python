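"""End-to-end orchestration: simulate -> growth -> lineages -> landscape -> b6.

Stages communicate through plain text files (TSV/CSV/JSON) so that any stage
can be re-run in isolation on real inputs with the same file dialects.  Every
run writes a manifest recording the resolved parameters, the per-stage seeds
(derived from the master seed by stable hashing) and the SHA-256 of every
output, so a run is reproducible byte for byte from its config.
"""

from __future__ import annotations

import hashlib
import json
import warnings
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import growth as gr
from . import landscape as ls
from . import lineage as ln
from . import simulate as sim
from . import vitamer as vq

__all__ = ["stage_seed", "run_pipeline", "make_fixtures", "DEFAULT_CONFIG"]

STAGES = ("simulate", "growth", "lineages", "landscape", "b6")

#: fold predilution of processed samples before the 4-PLA assay, so that
#: readings fall inside the 0-40 nM standard range
PREDILUTION = 6.0

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(STAGES),
    "simulate": {
        "n_reps": 10,
        "cv": 0.1,
        "trace_mus": [0.0375, 0.0097, 0.3],
        "noise_sd": 0.01,
        "measurement_noise_sd": 0.02,
    },
    "growth": {"drop_fraction": 0.05, "max_interval": 2.0, "min_r2": 0.9},
    "lineages": {
        "min_consecutive": 2,
        "min_freq": 0.10,
        "epsilon": 0.05,
        "linkage_threshold": 0.15,
        "max_gap": 0.15,
    },
    "landscape": {"alpha": 0.05, "family": "all-pairs", "accessible_mode": "not-decrease"},
    "b6": {"lysate_volume_ml": 1.0, "medium_volume_ml": 1.0},
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the master seed (below 2^31)."""
    return (master_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(cfg: dict, seed: int, out: Path) -> dict[str, Path]:
    params = cfg["simulate"]
    outputs: dict[str, Path] = {}

    lineage_cfg = sim.default_lineage_config(
        seed=seed, measurement_noise_sd=params["measurement_noise_sd"]
    )
    table, truth = sim.simulate_serial_passage(lineage_cfg)
    outputs["freq_table"] = out / "freq_table.tsv"
    _write_tsv(table, outputs["freq_table"])
    outputs["truth_forest"] = out / "truth_forest.json"
    outputs["truth_forest"].write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))

    frames = []
    for i, mu in enumerate(params["trace_mus"]):
        trace = sim.simulate_turbidostat_trace(
            sim.TraceConfig(
                true_mu=mu,
                duration=48.0,
                noise_sd=params["noise_sd"],
                vial_id=f"vial{i + 1}",
                seed=seed + i + 1,
            )
        )
        frames.append(
            pd.DataFrame(
                {
                    "time_h": trace.times,
                    "od600": trace.od,
                    "vial_id": trace.vial_id,
                    "medium": trace.medium,
                }
            )
        )
    outputs["traces"] = out / "traces.csv"
    _write_tsv(pd.concat(frames, ignore_index=True), outputs["traces"], sep=",")

    meas = sim.simulate_landscape_replicates(
        sim.reference_fitness_map(),
        n_reps=params["n_reps"],
        cv=params["cv"],
        seed=seed + 101,
    )
    rows = [
        {"genotype": "".join(map(str, g)), "replicate": r + 1, "mu_h": v}
        for g, reps in meas.replicates.items()
        for r, v in enumerate(reps)
    ]
    outputs["landscape_reps"] = out / "landscape_reps.csv"
    _write_tsv(pd.DataFrame(rows), outputs["landscape_reps"], sep=",")

    standards = np.linspace(0.0, 40.0, 9)
    truth_b6 = sim.reference_accumulation_truth()
    sample_concs = []
    sample_meta = []
    for strain, rec in truth_b6.items():
        content = rec["rate"] * (np.log(2) / rec["mu"])  # pmol per 1e9 cfu
        cfu = gr.cfu_from_od(0.15) * 25.0  # vial at mid-setpoint, 25 mL culture
        # split content 70/30 between lysate and spent medium, as diluted
        # concentrations in the final assay mixtures (1 mL processed volume,
        # prediluted so readings fall inside the 0-40 nM standard range)
        for frac, ledger in ((0.7, "lysate"), (0.3, "spent_medium")):
            pmol = content * frac * (cfu / 1e9)
            full_ledger = [("predilution", PREDILUTION), *vq.PROTOCOL_LEDGERS[ledger]]
            conc = vq.apply_ledger(pmol / 1.0, full_ledger)  # nM in assay mix
            sample_concs.append(conc)
            sample_meta.append({"strain": strain, "fraction": ledger})
    plate = sim.simulate_assay_plate(
        sample_concs,
        curve_shape="linear",
        coefficients=(100.0, 50.0),
        noise_sd=2.0,
        seed=seed + 202,
        standard_concs=standards,
    )
    is_sample = plate["role"] == "sample"
    plate.loc[is_sample, "strain"] = [m["strain"] for m in sample_meta]
    plate.loc[is_sample, "fraction"] = [m["fraction"] for m in sample_meta]
    outputs["assay_plate"] = out / "assay_plate.csv"
    _write_tsv(plate.fillna(""), outputs["assay_plate"], sep=",")
    outputs["b6_context"] = out / "b6_context.json"
    outputs["b6_context"].write_text(
        json.dumps(
            {
                "od600": 0.15,
                "culture_volume_ml": 25.0,
                "processed_volume_ml": 1.0,
                "sample_predilution": PREDILUTION,
                "strains": {k: {"mu": v["mu"]} for k, v in truth_b6.items()},
            },
            indent=1,
            sort_keys=True,
        )
    )
    return outputs


def _stage_growth(cfg: dict, seed: int, out: Path, traces_path: Path) -> dict[str, Path]:
    params = cfg["growth"]
    df = pd.read_csv(traces_path)
    records = []
    per_vial = {}
    for vial, sub in df.groupby("vial_id"):
        trace = gr.ODTrace(
            times=sub["time_h"].to_numpy(),
            od=sub["od600"].to_numpy(),
            vial_id=str(vial),
            medium=str(sub["medium"].iloc[0]) if "medium" in sub else "",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = gr.estimate_mu(
                trace,
                drop_fraction=params["drop_fraction"],
                max_interval=params["max_interval"],
                min_r2=params["min_r2"],
                random_state=seed,
            )
        per_vial[str(vial)] = {
            "mu": est.mu,
            "ci95": list(est.ci95),
            "n_cycles": est.n_cycles,
            "per_cycle_mu": est.per_cycle_mu.tolist(),
        }
        records.append(
            {"vial_id": vial, "mu": est.mu, "ci95_lo": est.ci95[0], "ci95_hi": est.ci95[1], "n_cycles": est.n_cycles}
        )
    outputs = {
        "growth_json": out / "growth.json",
        "growth_summary": out / "growth_summary.tsv",
    }
    outputs["growth_json"].write_text(json.dumps(per_vial, indent=1, sort_keys=True))
    _write_tsv(pd.DataFrame(records), outputs["growth_summary"])
    return outputs


def _stage_lineages(cfg: dict, seed: int, out: Path, freq_path: Path) -> dict[str, Path]:
    params = cfg["lineages"]
    table = pd.read_csv(freq_path, sep="\t")
    model = ln.CloneLineageInference(
        min_consecutive=params["min_consecutive"],
        min_freq=params["min_freq"],
        epsilon=params["epsilon"],
        linkage_threshold=params["linkage_threshold"],
        max_gap=params["max_gap"],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(table)
    outputs = {
        "forest": out / "forest.json",
        "muller": out / "muller_matrix.csv",
        "audit": out / "filter_audit.tsv",
    }
    outputs["forest"].write_text(json.dumps(model.forest_.to_dict(), indent=1, sort_keys=True))
    muller = model.muller_.copy()
    muller.insert(0, "band", muller.index)
    _write_tsv(muller, outputs["muller"], sep=",")
    _write_tsv(model.audit_, outputs["audit"])
    return outputs


def _stage_landscape(cfg: dict, seed: int, out: Path, reps_path: Path) -> dict[str, Path]:
    params = cfg["landscape"]
    df = pd.read_csv(reps_path, dtype={"genotype": str})
    model = ls.FitnessLandscapeAnalysis(
        alpha=params["alpha"],
        family=params["family"],
        accessible_mode=params["accessible_mode"],
        random_state=seed,
    )
    model.fit(df)
    n_acc, n_tot, reachable = model.accessibility_
    outputs = {
        "edges": out / "edges.tsv",
        "groups": out / "groups.tsv",
        "trajectories": out / "trajectories.tsv",
        "epistasis": out / "epistasis.json",
    }
    _write_tsv(model.edges_frame(), outputs["edges"])
    _write_tsv(model.groups_, outputs["groups"])
    _write_tsv(model.trajectories_, outputs["trajectories"])
    epi = model.epistasis_
    outputs["epistasis"].write_text(
        json.dumps(
            {
                "expected_fold": epi.expected_fold,
                "observed_fold": epi.observed_fold,
                "ratio": epi.ratio,
                "single_mutant_folds": epi.single_mutant_folds,
                "max_single_fold": epi.max_single_fold,
                "n_accessible_steps": n_acc,
                "n_steps": n_tot,
                "n_accessible_genotypes": len(reachable),
                "greedy_path": [model.measurement_.loci[i] for i in model.greedy_path_],
            },
            indent=1,
            sort_keys=True,
        )
    )
    return outputs


def _stage_b6(
    cfg: dict, seed: int, out: Path, plate_path: Path, context_path: Path
) -> dict[str, Path]:
    params = cfg["b6"]
    plate = pd.read_csv(plate_path)
    context = json.loads(Path(context_path).read_text())
    std = plate[plate["role"] == "standard"]
    curve = vq.fit_standard_curve(std["nominal_conc"], std["response"], model="linear")
    cfu = gr.cfu_from_od(context["od600"]) * context["culture_volume_ml"]
    vol = context["processed_volume_ml"]
    predil = float(context.get("sample_predilution", 1.0))
    rows = []
    samples = plate[plate["role"] == "sample"]
    for strain, sub in samples.groupby("strain"):
        conc = {
            frac: float(curve.inverse_predict(s["response"].to_numpy()).mean())
            for frac, s in sub.groupby("fraction")
        }
        content = vq.total_b6_per_cfu(
            lysate_conc=conc.get("lysate", 0.0),
            medium_conc=conc.get("spent_medium", 0.0),
            lysate_volume_ml=params.get("lysate_volume_ml", vol),
            medium_volume_ml=params.get("medium_volume_ml", vol),
            cfu=cfu,
            lysate_ledger=[
                ("predilution", predil),
                *vq.PROTOCOL_LEDGERS["lysate"],
            ],
            medium_ledger=[
                ("predilution", predil),
                *vq.PROTOCOL_LEDGERS["spent_medium"],
            ],
        )
        mu = context["strains"][strain]["mu"]
        rate = vq.accumulation_rate(content, mu)
        rows.append(
            {
                "strain": strain,
                "content_pmol_per_1e9cfu": content.content,
                "mu_h": mu,
                "doubling_time_h": rate.doubling_time,
                "rate_pmol_per_1e9cfu_h": rate.rate,
            }
        )
    outputs = {"b6_rates": out / "b6_rates.tsv"}
    _write_tsv(pd.DataFrame(rows).sort_values("strain"), outputs["b6_rates"])
    return outputs


# ---------------------------------------------------------------------------


def run_pipeline(config: dict | None = None, out_dir: str | Path = "evoland_out") -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    cfg = _merge(DEFAULT_CONFIG, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])
    stages = [s for s in STAGES if s in cfg["stages"]]
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    # resolve inputs up front so a missing path fails before any stage runs
    inputs = {
        "traces": cfg.get("growth", {}).get("traces"),
        "freq_table": cfg.get("lineages", {}).get("freq_table"),
        "landscape_reps": cfg.get("landscape", {}).get("reps"),
        "assay_plate": cfg.get("b6", {}).get("plate"),
        "b6_context": cfg.get("b6", {}).get("context"),
    }
    for name, path in inputs.items():
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"input for {name!r} not found: {path}")

    produced: dict[str, Path] = {}
    for stage in stages:
        seed = stage_seed(master, stage)
        try:
            if stage == "simulate":
                produced.update(_stage_simulate(cfg, seed, out))
            elif stage == "growth":
                path = inputs["traces"] or produced.get("traces")
                if path is None:
                    raise FileNotFoundError("growth stage needs a traces CSV")
                produced.update(_stage_growth(cfg, seed, out, Path(path)))
            elif stage == "lineages":
                path = inputs["freq_table"] or produced.get("freq_table")
                if path is None:
                    raise FileNotFoundError("lineages stage needs a frequency table")
                produced.update(_stage_lineages(cfg, seed, out, Path(path)))
            elif stage == "landscape":
                path = inputs["landscape_reps"] or produced.get("landscape_reps")
                if path is None:
                    raise FileNotFoundError("landscape stage needs a replicate CSV")
                produced.update(_stage_landscape(cfg, seed, out, Path(path)))
            elif stage == "b6":
                plate = inputs["assay_plate"] or produced.get("assay_plate")
                ctx = inputs["b6_context"] or produced.get("b6_context")
                if plate is None or ctx is None:
                    raise FileNotFoundError("b6 stage needs a plate CSV and context JSON")
                produced.update(_stage_b6(cfg, seed, out, Path(plate), Path(ctx)))
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": cfg,
        "stage_seeds": {s: stage_seed(master, s) for s in stages},
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in produced.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the miniature demo datasets (all derived from the generators)."""
    cfg = _merge(DEFAULT_CONFIG, {"seed": seed, "stages": ["simulate"]})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = _stage_simulate(cfg, stage_seed(seed, "simulate"), out)
    return paths
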