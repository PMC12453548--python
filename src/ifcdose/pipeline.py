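"""End-to-end orchestration: simulate -> calibrate -> estimate -> evaluate.

A run is a pure function of (config, seed): every stochastic stage draws
from a named substream derived from the global seed, outputs are written as
delimited text/JSON under the configured output directory, and a manifest
records the config hash and a sha256 checksum per artifact so reruns can be
verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from . import calibration as cal_mod
from . import evaluate as ev
from . import knn as knn_mod
from .io import PipelineConfig, _as_dict, read_feature_table, write_estimates_table, write_feature_table
from .synthdata import default_calibration_design, simulate_feature_table, substream, validation_design

__all__ = ["run_pipeline", "run_study"]

log = logging.getLogger("ifcdose")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_study(config: PipelineConfig, seed: int | None = None) -> dict:
    """Run the full study in memory and return all stage results.

    Stages: simulate the 10-donor calibration and the blinded validation set
    (or load them from configured tables), fit the linear MFI and saturating
    spot-feature curves, estimate every validation dose by CC inversion and
    by K-NN, and evaluate both estimators.
    """
    seed = config.seed if seed is None else seed
    sim = config.sim

    if config.calibration_table:
        cal_df = read_feature_table(config.calibration_table, kind="per_sample")
    else:
        design = default_calibration_design(config.n_donors)
        cal_df = simulate_feature_table(design, sim, substream(seed, "calibration"))

    if config.query_table:
        qry_df = read_feature_table(config.query_table, kind="per_sample")
    else:
        vstream = substream(seed, "validation")
        vdesign = validation_design(config.n_validation, config.n_validation_donors, stream=vstream)
        qry_df = simulate_feature_table(vdesign, sim, vstream)

    lin = cal_mod.fit_linear(cal_df["dose_gy"], cal_df["mfi"])
    sat_count = cal_mod.fit_saturating(cal_df["dose_gy"], cal_df["spot_count"])
    sat_area = cal_mod.fit_saturating(cal_df["dose_gy"], cal_df["spot_area"])
    log.info("calibration fits: alpha=%.3f beta=%.3f; spot v=%.2f xi=%.3f", lin.alpha, lin.beta, sat_count.v, sat_count.xi)

    max_dose = float(cal_df["dose_gy"].max())
    cc_estimates = [cal_mod.invert_linear(m, lin, max_dose=max_dose) for m in qry_df["mfi"]]

    cal_ds = knn_mod.CalibrationDataset.from_frame(cal_df)
    knn_stream = substream(seed, "knn-bootstrap")
    knn_estimates = knn_mod.estimate_batch(qry_df, cal_ds, config.knn, knn_stream, with_ci=config.bootstrap_ci)

    truths = qry_df["dose_gy"].to_numpy(dtype=float)
    report_cc = ev.evaluate_estimates(
        [e.dose_hat for e in cc_estimates], truths, threshold_gy=config.triage_threshold_gy, method="CC"
    )
    report_knn = ev.evaluate_estimates(
        [e.dose_hat for e in knn_estimates], truths, threshold_gy=config.triage_threshold_gy, method="KNN"
    )
    return {
        "calibration_table": cal_df,
        "query_table": qry_df,
        "linear_fit": lin,
        "saturating_fits": {"spot_count": sat_count, "spot_area": sat_area},
        "cc_estimates": cc_estimates,
        "knn_estimates": knn_estimates,
        "report_cc": report_cc,
        "report_knn": report_knn,
    }


def run_pipeline(config: PipelineConfig, seed: int | None = None) -> dict:
    """Run the study and persist every stage output; returns the manifest.

    The manifest holds the canonical-config hash, the seed, and a sha256
    checksum per written artifact — identical (config, seed) pairs reproduce
    identical manifests.
    """
    seed = config.seed if seed is None else seed
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    results = run_study(config, seed)

    files: dict[str, Path] = {}
    files["calibration_table"] = out / "calibration_samples.tsv"
    write_feature_table(results["calibration_table"], files["calibration_table"])
    files["query_table"] = out / "validation_samples.tsv"
    write_feature_table(results["query_table"], files["query_table"])

    files["linear_fit"] = out / "fit_mfi_linear.json"
    cal_mod.save_fit(results["linear_fit"], files["linear_fit"])
    for name, fit in results["saturating_fits"].items():
        files[f"fit_{name}"] = out / f"fit_{name}_saturating.json"
        cal_mod.save_fit(fit, files[f"fit_{name}"])

    qdf = results["query_table"]
    files["estimates_cc"] = out / "estimates_cc.tsv"
    write_estimates_table(results["cc_estimates"], qdf["sample_id"], qdf["dose_gy"], files["estimates_cc"])
    files["estimates_knn"] = out / "estimates_knn.tsv"
    write_estimates_table(results["knn_estimates"], qdf["sample_id"], qdf["dose_gy"], files["estimates_knn"])

    files["evaluation"] = out / "evaluation.json"
    with open(files["evaluation"], "w", encoding="utf-8") as fh:
        json.dump(
            {"CC": results["report_cc"].as_dict(), "KNN": results["report_knn"].as_dict()},
            fh,
            indent=2,
            sort_keys=True,
            allow_nan=True,
        )

    cfg_dict = _as_dict(config)
    cfg_dict["seed"] = seed
    config_hash = hashlib.sha256(json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()
    manifest = {
        "config_hash": config_hash,
        "seed": seed,
        "checksums": {name: _sha256(p) for name, p in sorted(files.items())},
        "outputs": {name: str(p) for name, p in sorted(files.items())},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %d artifacts under %s", len(files), out)
    return manifest
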