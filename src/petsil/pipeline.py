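"""End-to-end pipeline stages: simulate → extract → similarity → stats →
cluster.  Each stage reads/writes plain-text artifacts in the run directory,
so any stage can also be run standalone on externally produced files."""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import SITE_CLASSES
from .clustering import characterize, cluster_lesions
from .config import RunConfig
from .errors import (SilhouetteUndefinedError, SplitError,
                     TestUndefinedError)
from .features import extract_table
from .group_stats import (classify_burden, make_split, patient_site_split,
                          psa_test, silhouette_group_test, univariate_screen)
from .io import (read_cohort, read_features, read_volume, silhouette_report,
                 write_features, write_report)
from .similarity import (anatomy_silhouette, metabolism_silhouette,
                         paired_slicing_test, patient_based, suv_tertiles)
from .synthetic import (generate_feature_cohort, generate_volume_cohort,
                        write_cohort)


def log(run_dir: Path, message: str, verbosity: int = 1) -> None:
    line = f"{datetime.datetime.now().isoformat(timespec='seconds')} {message}"
    with open(run_dir / "run.log", "a") as fh:
        fh.write(line + "\n")
    if verbosity > 1:
        print(line)


def _init_run(config: RunConfig, out: str | Path) -> Path:
    run_dir = Path(out)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.validate()
    log(run_dir, f"petsil {__version__} seed={config.seed} "
                 f"config_hash={config.digest()}", config.verbosity)
    config.to_yaml(run_dir / "config.yaml")
    return run_dir


def stage_simulate(config: RunConfig, out: str | Path) -> Path:
    """Generate the synthetic cohort (tables, features and — in volume mode
    — NIfTI pairs) under ``out/cohort``."""
    run_dir = _init_run(config, out)
    config.synthetic.seed = config.seed
    if config.mode == "volumes":
        cohort = generate_volume_cohort(config.synthetic)
    else:
        cohort = generate_feature_cohort(config.synthetic)
    write_cohort(cohort, run_dir / "cohort")
    log(run_dir, f"simulate: {cohort.cohort_table.n_patients} patients, "
                 f"{cohort.cohort_table.n_lesions} lesions, mode={config.mode}",
        config.verbosity)
    return run_dir / "cohort"


def stage_extract(config: RunConfig, out: str | Path) -> Path:
    """Extract the radiomic feature table from the NIfTI pairs listed in the
    cohort manifest; writes ``features_extracted.csv`` plus a provenance
    sidecar with the extraction settings."""
    run_dir = _init_run(config, out)
    cohort_dir = run_dir / "cohort"
    manifest = yaml.safe_load((cohort_dir / "manifest.yaml").read_text())
    if not manifest.get("lesions"):
        raise FileNotFoundError(f"no volumes listed in {cohort_dir}/manifest.yaml")
    cohort = read_cohort(cohort_dir)
    volumes = {}
    for entry in manifest["lesions"]:
        vol, spacing = read_volume(cohort_dir / entry["volume"])
        mask, _ = read_volume(cohort_dir / entry["mask"])
        volumes[entry["lesion_id"]] = (vol, mask.astype(np.uint8), spacing)
    table = extract_table(volumes, cohort.lesions, config.extraction)
    write_features(table, run_dir / "features_extracted.csv")
    sidecar = {"target_spacing_mm": config.extraction.target_spacing_mm,
               "n_bins": config.extraction.n_bins,
               "discretization_mode": config.extraction.discretization_mode,
               "n_features": len(config.extraction.roster),
               "config_hash": config.digest()}
    write_report(sidecar, run_dir / "features_extracted.settings.yaml")
    log(run_dir, f"extract: {len(table)} lesions x "
                 f"{len(config.extraction.roster)} features", config.verbosity)
    return run_dir / "features_extracted.csv"


def _load_feature_table(run_dir: Path) -> pd.DataFrame:
    extracted = run_dir / "features_extracted.csv"
    if extracted.exists():
        return read_features(extracted)
    return read_features(run_dir / "cohort" / "features.csv")


def stage_similarity(config: RunConfig, out: str | Path) -> dict:
    """Patient-, anatomy- and metabolism-based silhouette analyses with the
    paired slicing comparisons; writes ``similarity.yaml`` and the
    patient-indexed scatter."""
    run_dir = _init_run(config, out)
    features = _load_feature_table(run_dir)
    method, nc = config.embedding_method, config.n_components
    all_result = patient_based(features, method, nc)
    report = {"patient_based": silhouette_report(all_result),
              "anatomy_based": {}, "metabolism_based": {},
              "paired_tests": {}}
    patient_of = dict(zip(features["lesion_id"], features["patient_id"]))
    for site in SITE_CLASSES:
        try:
            res = anatomy_silhouette(features, site, method, nc)
            report["anatomy_based"][site] = silhouette_report(res)
            pt = paired_slicing_test(all_result, res)
            report["paired_tests"][f"ALL_vs_SITE({site})"] = {
                "t": float(pt.t), "p": float(pt.p), "n": pt.n}
        except (SilhouetteUndefinedError, TestUndefinedError) as exc:
            report["anatomy_based"].setdefault(site, {"error": str(exc)})
            report["paired_tests"][f"ALL_vs_SITE({site})"] = {
                "error": str(exc)}
    for tertile in (1, 2, 3):
        try:
            res = metabolism_silhouette(features, tertile, method, nc)
            report["metabolism_based"][f"T{tertile}"] = silhouette_report(res)
            pt = paired_slicing_test(all_result, res)
            report["paired_tests"][f"ALL_vs_TERTILE({tertile})"] = {
                "t": float(pt.t), "p": float(pt.p), "n": pt.n}
        except (SilhouetteUndefinedError, TestUndefinedError) as exc:
            report["metabolism_based"].setdefault(f"T{tertile}",
                                                  {"error": str(exc)})
            report["paired_tests"][f"ALL_vs_TERTILE({tertile})"] = {
                "error": str(exc)}
    write_report(report, run_dir / "similarity.yaml")
    try:
        from .plotting import plot_patient_silhouettes
        plot_patient_silhouettes(all_result, patient_of,
                                 run_dir / "silhouette_patients.png",
                                 seed=config.seed)
    except Exception as exc:  # plotting must never sink the pipeline
        log(run_dir, f"similarity: plot skipped ({exc})", config.verbosity)
    log(run_dir, f"similarity: cohort mean_index="
                 f"{all_result.mean_index:.4f}", config.verbosity)
    return report


def stage_stats(config: RunConfig, out: str | Path) -> dict:
    """Burden classification, univariate screens, PSA tests and
    Kruskal–Wallis silhouette comparisons; writes ``stats.yaml`` and the
    per-feature screen tables."""
    run_dir = _init_run(config, out)
    features = _load_feature_table(run_dir)
    cohort = read_cohort(run_dir / "cohort")
    burden = classify_burden(cohort.lesion_counts(),
                             config.inclusive_thresholds)
    burden.to_csv(run_dir / "burden.csv")
    all_result = patient_based(features, config.embedding_method,
                               config.n_components)
    report: dict = {"burden_counts": {
        "class3": burden["class3"].value_counts().to_dict(),
        "class5": burden["class5"].value_counts().to_dict(),
        "class3way": burden["class3way"].value_counts().to_dict()},
        "screens": {}, "psa": {}, "silhouette_kruskal": {}}
    psa = cohort.patients.set_index("patient_id")["psa_ng_ml"]
    for name in ("BURDEN3", "BURDEN5", "GLEASON", "PSA_MEDIAN", "ADT"):
        try:
            split = make_split(name, cohort, burden)
        except SplitError as exc:
            report["screens"][name] = {"error": str(exc)}
            continue
        try:
            screen = univariate_screen(features, split)
            screen.to_csv(run_dir / f"screen_{name}.csv", index=False)
            report["screens"][name] = {
                "n_significant": int(screen["significant"].sum()),
                "alpha": 0.01 if name == "GLEASON" else 0.001}
        except SplitError as exc:
            report["screens"][name] = {"error": str(exc)}
        if name in ("BURDEN3", "BURDEN5", "GLEASON", "ADT"):
            try:
                res = psa_test(psa, split)
                report["psa"][name] = {"U": res.statistic, "p": res.p,
                                       "significant": res.significant}
            except SplitError as exc:
                report["psa"][name] = {"error": str(exc)}
        try:
            kw = silhouette_group_test(all_result, split)
            report["silhouette_kruskal"][name] = {
                "H": kw.statistic, "p": kw.p, "groups": kw.group_sizes}
        except SplitError as exc:
            report["silhouette_kruskal"][name] = {"error": str(exc)}
    try:
        split3 = make_split("BURDEN3WAY", cohort, burden)
        kw = silhouette_group_test(all_result, split3)
        report["silhouette_kruskal"]["BURDEN3WAY"] = {
            "H": kw.statistic, "p": kw.p, "groups": kw.group_sizes}
    except SplitError as exc:
        report["silhouette_kruskal"]["BURDEN3WAY"] = {"error": str(exc)}
    try:
        site_split = patient_site_split(cohort)
        res = psa_test(psa, site_split)
        if isinstance(res, pd.DataFrame):
            report["psa"]["SITE_DOMINANT"] = res.to_dict(orient="records")
        else:
            report["psa"]["SITE_DOMINANT"] = {"U": res.statistic, "p": res.p}
    except SplitError as exc:
        report["psa"]["SITE_DOMINANT"] = {"error": str(exc)}
    write_report(report, run_dir / "stats.yaml")
    log(run_dir, f"stats: burden3={report['burden_counts']['class3']}",
        config.verbosity)
    return report


def stage_cluster(config: RunConfig, out: str | Path) -> dict:
    """Cluster lesions in the embedded space, select k by mean silhouette,
    and characterize clusters by tertile, burden and site; writes
    ``clusters.csv`` and ``cluster_profile.yaml``."""
    from .similarity import embed

    run_dir = _init_run(config, out)
    features = _load_feature_table(run_dir)
    cohort = read_cohort(run_dir / "cohort")
    space = embed(features, config.embedding_method,
                  config.n_components)
    k_range = [k for k in config.k_range if 2 <= k <= len(features) - 1]
    solution = cluster_lesions(space, k_range, seed=config.seed)
    solution.labels.rename("cluster").to_csv(run_dir / "clusters.csv")
    burden = classify_burden(cohort.lesion_counts(),
                             config.inclusive_thresholds)
    meta = features.set_index("lesion_id")[["site_class", "patient_id"]].copy()
    meta["tertile"] = suv_tertiles(
        features.set_index("lesion_id")["suv_max"]).map("T{}".format)
    meta["burden5"] = meta["patient_id"].map(burden["class5"])
    profile = characterize(solution, meta[["site_class", "tertile", "burden5"]])
    report = {"chosen_k": solution.chosen_k,
              "selection_scores": {int(k): float(v)
                                   for k, v in solution.selection_scores.items()},
              "degenerate": solution.degenerate,
              "profiles": {cat: df.round(6).to_dict()
                           for cat, df in profile.proportions.items()},
              "chi2_p": {k: (None if np.isnan(v) else float(v))
                         for k, v in profile.chi2_p.items()}}
    write_report(report, run_dir / "cluster_profile.yaml")
    log(run_dir, f"cluster: chosen_k={solution.chosen_k} "
                 f"scores={report['selection_scores']}", config.verbosity)
    return report


def run_all(config: RunConfig, out: str | Path) -> dict:
    """Chain every stage; returns the stats, similarity and cluster
    reports."""
    stage_simulate(config, out)
    if config.mode == "volumes":
        stage_extract(config, out)
    similarity = stage_similarity(config, out)
    statistics = stage_stats(config, out)
    clusters = stage_cluster(config, out)
    return {"similarity": similarity, "stats": statistics,
            "clusters": clusters}
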