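"""End-to-end pipeline orchestration with a run manifest.

A single structured YAML config drives the fixed stage order
``simulate → build-matrix → unmix → markers → trophic → ordination``
(any suffix optional).  Every run writes its outputs as CSV plus one
``manifest.json`` capturing the config snapshot, input digests, package
version, seed, per-stage timings and warnings, so a rerun with identical
inputs reproduces identical tables.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datasets import load_ratio_matrix_input
from .profiles import TaxonRatioMatrix, build_ratio_matrix, read_profiles, write_profiles
from .stats import pca, pca_screen
from .synthetic import ConsumerSpec, gen_consumer_profiles, gen_isolate_library, gen_pond_samples, make_scenario
from .trophic import default_scheme, marker_proportions, trophic_comparison
from .unmixing import SampleMatrix, UnmixingConfig, fit, randomized_starts, run_by_location, successive_runs

__all__ = ["PipelineError", "run_pipeline"]

STAGE_ORDER = ("simulate", "build-matrix", "unmix", "markers", "trophic", "ordination")

PROTOCOLS = {"plain": fit, "latasa": successive_runs, "wright": randomized_starts}


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        payload = yaml.safe_load(Path(config).read_text())
    else:
        payload = dict(config)
    if not isinstance(payload, dict):
        raise PipelineError("config", "config must be a mapping")
    return payload


def _validate_stages(stages: list[str]) -> None:
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise PipelineError("config", f"unknown stages {unknown}; valid: {list(STAGE_ORDER)}")
    order = [STAGE_ORDER.index(s) for s in stages]
    if order != sorted(order):
        raise PipelineError("config", f"stages must follow the order {list(STAGE_ORDER)}")


def run_pipeline(config, output_dir: str | Path | None = None) -> Path:
    """Run the configured stages; returns the output directory.

    See the packaged example configs for the schema.  Failures stop the
    run with an error naming the offending stage.
    """
    cfg = _load_config(config)
    out = Path(output_dir or cfg.get("output_dir", "plfatax_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = list(cfg.get("stages", []))
    if not stages:
        raise PipelineError("config", "no stages configured")
    _validate_stages(stages)

    manifest: dict = {
        "config": cfg,
        "version": __version__,
        "seed": seed,
        "input_digests": {},
        "timings_s": {},
        "warnings": [],
        "outputs": [],
    }

    state: dict = {}

    def emit(name: str, df: pd.DataFrame, index: bool = True, index_label=None) -> None:
        path = out / name
        df.to_csv(path, index=index, index_label=index_label)
        manifest["outputs"].append(name)

    for key in ("ratio_matrix", "samples", "isolates", "consumers", "seston"):
        p = cfg.get("inputs", {}).get(key)
        if p:
            manifest["input_digests"][key] = _digest(Path(p))

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for stage in stages:
            t0 = time.perf_counter()
            try:
                _run_stage(stage, cfg, state, seed, emit, out)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(stage, str(exc)) from exc
            manifest["timings_s"][stage] = round(time.perf_counter() - t0, 4)
        manifest["warnings"] = [str(w.message) for w in caught]

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _get_ratio_matrix(cfg: dict, state: dict) -> TaxonRatioMatrix:
    if "ratio_matrix" in state:
        return state["ratio_matrix"]
    p = cfg.get("inputs", {}).get("ratio_matrix")
    if p:
        return TaxonRatioMatrix.from_csv(p)
    return load_ratio_matrix_input()


def _get_samples(cfg: dict, state: dict, stage: str) -> SampleMatrix:
    if "samples" in state:
        return state["samples"]
    p = cfg.get("inputs", {}).get("samples")
    if not p:
        raise PipelineError(stage, "no sample table: configure inputs.samples or a simulate stage")
    profiles = read_profiles(p)
    location = {pr.entity_id: pr.meta.get("location", "all") for pr in profiles}
    return SampleMatrix.from_profiles(profiles, location)


def _run_stage(stage: str, cfg: dict, state: dict, seed: int, emit, out: Path) -> None:
    opts = cfg.get(stage.replace("-", "_"), {}) or {}

    if stage == "simulate":
        R = _get_ratio_matrix(cfg, state)
        sc = make_scenario(
            R,
            n_samples=int(opts.get("n_samples", 20)),
            seed=seed,
            preset=opts.get("preset"),
            cv=float(opts.get("cv", 0.10)),
            noise_model=opts.get("noise_model", "lognormal"),
        )
        samples, truth = gen_pond_samples(sc)
        state["samples"] = samples
        state["truth"] = truth
        emit("true_abundances.csv", truth)
        emit("samples.csv", samples.to_frame(), index_label="entity_id")
        isolates = gen_isolate_library(
            R,
            cv=float(opts.get("isolate_cv", 0.2)),
            n_per_taxon=int(opts.get("n_per_taxon", 5)),
            seed=seed + 1,
        )
        state["isolates"] = isolates
        write_profiles([p for _, p in isolates], out / "isolates.csv")
        # mean seston feeds the consumer generator
        mean = samples.to_frame().mean(axis=0)
        from .profiles import FAProfile

        seston = FAProfile(entity_id="seston_mean", values=mean.to_dict(), lipid_fraction="PLFA")
        state["seston"] = seston
        spec = ConsumerSpec(
            retention=dict(opts.get("retention", {"20:5ω3": 3.0, "22:6ω3": 3.0})),
            de_novo_safa=float(opts.get("de_novo_safa", 0.0)),
            cv=float(opts.get("consumer_cv", opts.get("cv", 0.10))),
        )
        consumers = gen_consumer_profiles(seston, spec, seed=seed + 2)
        state["consumers"] = consumers
        write_profiles(consumers, out / "consumers.csv")
        manifest_note = {"scenario_seed": seed}
        (out / "scenario.json").write_text(json.dumps(manifest_note))

    elif stage == "build-matrix":
        isolates = state.get("isolates")
        if isolates is None:
            p = cfg.get("inputs", {}).get("isolates")
            if not p:
                raise PipelineError(stage, "no isolates: configure inputs.isolates or a simulate stage")
            profs = read_profiles(p)
            isolates = [(pr.meta.get("taxon", pr.entity_id), pr) for pr in profs]
        R = build_ratio_matrix(
            isolates,
            min_mean_pct=float(opts.get("min_mean_pct", 1.0)),
            drop_single_species=bool(opts.get("drop_single_species", True)),
        )
        if bool(opts.get("use_as_ratio_matrix", False)):
            state["ratio_matrix"] = R
        R.to_csv(out / "ratio_matrix_built.csv")

    elif stage == "unmix":
        R = _get_ratio_matrix(cfg, state)
        S = _get_samples(cfg, state, stage)
        ucfg = UnmixingConfig(
            bound_factor=float(opts.get("bound_factor", 1.5)),
            seed=seed,
            max_iter=int(opts.get("max_iter", 500)),
            n_successive_runs=int(opts.get("n_successive_runs", 8)),
            n_random_starts=int(opts.get("n_random_starts", 60)),
        )
        protocol = opts.get("protocol", "plain")
        if protocol not in PROTOCOLS:
            raise PipelineError(stage, f"unknown protocol {protocol!r}; valid: {list(PROTOCOLS)}")
        membership = opts.get("membership")
        if membership:
            for loc, taxa in membership.items():
                missing = [t for t in taxa if t not in R.taxa]
                if missing:
                    raise PipelineError(stage, f"membership for {loc!r} names unknown taxa {missing}")
            abundances, results = run_by_location(S, R, membership, ucfg)
            res = max(results.values(), key=lambda r: r.rmse)
            ratio_out = None
        else:
            res = PROTOCOLS[protocol](S, R, ucfg)
            abundances = res.abundances
            ratio_out = res.ratio_out
        state["abundances"] = abundances
        emit("abundances.csv", abundances)
        if ratio_out is not None:
            ratio_out.to_csv(out / "ratio_matrix_optimized.csv")
        log = pd.DataFrame({"iteration": range(1, len(res.rmse_trajectory) + 1), "rmse": res.rmse_trajectory})
        emit("unmix_log.csv", log, index=False)

    elif stage == "markers":
        S = _get_samples(cfg, state, stage)
        scheme = default_scheme()
        rows = {}
        for sid, row in S.to_frame().iterrows():
            from .profiles import FAProfile

            prof = FAProfile(entity_id=str(sid), values=row[row > 0].to_dict())
            rows[sid] = marker_proportions(prof, scheme, relative=bool(opts.get("relative", True)))
        emit("marker_proportions.csv", pd.DataFrame(rows).T)

    elif stage == "trophic":
        seston = state.get("seston")
        consumers = state.get("consumers")
        if seston is None or consumers is None:
            sp = cfg.get("inputs", {}).get("seston")
            cp = cfg.get("inputs", {}).get("consumers")
            if not (sp and cp):
                raise PipelineError(stage, "no seston/consumer tables: configure inputs or a simulate stage")
            seston = read_profiles(sp)[0]
            consumers = read_profiles(cp)
        comp = trophic_comparison(seston, consumers)
        rows = {"seston": comp.seston_proportions}
        rows.update(comp.consumer_proportions)
        emit("trophic_comparison.csv", pd.DataFrame(rows).T)
        emit("retention_ratios.csv", pd.DataFrame([comp.retention]), index=False)

    elif stage == "ordination":
        S = _get_samples(cfg, state, stage)
        df = S.to_frame()
        df = df.loc[:, (df > 0).any(axis=0)]
        report = pca_screen(df)
        res = pca(df[report.retained])
        screen_rows = pd.DataFrame(
            {
                "fa": report.retained,
                "kmo": [report.kmo_values[f] for f in report.retained],
                "communality": [report.communalities[f] for f in report.retained],
            }
        )
        emit("screening_retained.csv", screen_rows, index=False)
        removed = pd.DataFrame(
            [(f, "short_chain") for f in report.removed_short_chain]
            + [(f, "kmo") for f in report.removed_kmo]
            + [(f, "communality") for f in report.removed_communality],
            columns=["fa", "reason"],
        )
        emit("screening_removed.csv", removed, index=False)
        emit("pca_loadings.csv", res.loadings)
        emit("pca_scores.csv", res.scores)
        emit(
            "pca_eigenvalues.csv",
            pd.DataFrame({"eigenvalue": res.eigenvalues, "explained_pct": res.explained_pct}),
            index=False,
        )

    else:  # pragma: no cover
        raise PipelineError(stage, "unhandled stage")
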