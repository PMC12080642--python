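"""End-to-end orchestration: simulate → preprocess → vigilance → spectrum → fda.

Every stage writes delimited text so any stage can be rerun standalone; a
JSON manifest records the config snapshot, seed, package version, per-stage
row counts, exclusions, and a checksum for every artifact. The same config
and seed always reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import warnings
from pathlib import Path

import pandas as pd

from cptspect import __version__, io
from cptspect.config import RunConfig, validate_config
from cptspect.fda import (
    common_grid,
    primary_band,
    pairwise_pointwise_ttest,
    pointwise_group_ftest,
    smooth_spectrum,
    summarize_band,
)
from cptspect.preprocess import apply_accuracy_filter, classify_cohort, summary_table
from cptspect.simulate import generate_cohort
from cptspect.spectral import lomb_scargle, series_from_session
from cptspect.vigilance import build_cov_table, fit_vigilance_model


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the run manifest.

    Raises :class:`PipelineError` naming the failing stage; partial outputs
    written before the failure are retained and the manifest (also written
    on failure) marks the run incomplete.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid configuration:\n- " + "\n- ".join(violations))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.task_spec()
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "files": {},
        "complete": False,
    }

    def _write(name: str, df: pd.DataFrame):
        path = out / name
        io.write_table(df, path)
        manifest["files"][name] = {"sha256": _sha256(path), "rows": len(df)}

    current_stage = "setup"
    try:
        # ---- simulate / ingest ------------------------------------------
        current_stage = "simulate"
        if config.input_trials is not None:
            trials = io.read_trials(config.input_trials)
            manifest["stages"]["simulate"] = {
                "skipped": True,
                "input": str(config.input_trials),
                "rows": len(trials),
            }
        else:
            trials, covariates = generate_cohort(
                config.group_specs(),
                seed=config.seed,
                spec=spec,
                response_window=config.response_window,
            )
            path = out / "trials.tsv"
            io.write_trials(trials, path)
            manifest["files"]["trials.tsv"] = {
                "sha256": _sha256(path),
                "rows": len(trials),
            }
            _write("covariates.tsv", covariates)
            manifest["stages"]["simulate"] = {
                "participants": trials["participant_id"].nunique(),
                "rows": len(trials),
            }

        # ---- preprocess -------------------------------------------------
        current_stage = "preprocess"
        sessions = classify_cohort(
            trials, response_window=config.response_window, soa=spec.soa
        )
        retained, report = apply_accuracy_filter(sessions, config.min_accuracy)
        _write("session_summary.tsv", summary_table(sessions))
        _write("exclusions.tsv", report.excluded)
        manifest["stages"]["preprocess"] = {
            "n_sessions": len(sessions),
            "n_retained": len(retained),
            "n_excluded": len(sessions) - len(retained),
            "hit_threshold": report.threshold,
        }
        if not retained:
            raise RuntimeError("no session passed the accuracy filter")

        # ---- vigilance --------------------------------------------------
        if config.stages.get("vigilance", True):
            current_stage = "vigilance"
            cov_table = build_cov_table(
                retained, n_blocks=config.n_blocks, block_size=config.block_size
            )
            _write("cov_blocks.tsv", cov_table)
            fit = fit_vigilance_model(cov_table, config.reference_group)
            _write("vigilance_fixed_effects.tsv", fit.fixed_effects)
            _write("vigilance_omnibus.tsv", fit.omnibus)
            _write("vigilance_simple_slopes.tsv", fit.simple_slopes)
            _write("vigilance_level_contrasts.tsv", fit.intercept_contrasts)
            _write("vigilance_slope_contrasts.tsv", fit.slope_contrasts)
            manifest["stages"]["vigilance"] = {
                "rows": len(cov_table),
                "r2_marginal": fit.r2_marginal,
                "r2_conditional": fit.r2_conditional,
                "singular": fit.singular,
            }

        # ---- spectrum ---------------------------------------------------
        periodograms = []
        if config.stages.get("spectrum", True):
            current_stage = "spectrum"
            rows = []
            for s in retained:
                series = series_from_session(s.rt_series, s.participant_id)
                pg = lomb_scargle(
                    series,
                    oversampling=config.oversampling,
                    detrend_first=config.detrend,
                )
                periodograms.append(pg)
                rows.append(
                    pd.DataFrame(
                        {
                            "participant_id": pg.participant_id,
                            "frequency_hz": pg.frequencies,
                            "power": pg.power,
                        }
                    )
                )
            _write("periodograms.tsv", pd.concat(rows, ignore_index=True))
            manifest["stages"]["spectrum"] = {"n_participants": len(periodograms)}

        # ---- fda --------------------------------------------------------
        if config.stages.get("fda", True) and periodograms:
            current_stage = "fda"
            cov_df = pd.DataFrame(
                {
                    "participant_id": [s.participant_id for s in retained],
                    "group": [s.group for s in retained],
                    "age": [s.age for s in retained],
                    "sex": [s.sex for s in retained],
                }
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                spectra = [
                    smooth_spectrum(pg, config.n_interior_knots)
                    for pg in periodograms
                ]
            grid = common_grid(spectra, config.n_eval)
            smooth_rows = pd.concat(
                [
                    pd.DataFrame(
                        {
                            "participant_id": s.participant_id,
                            "frequency_hz": grid,
                            "power": s.evaluate(grid),
                        }
                    )
                    for s in spectra
                ],
                ignore_index=True,
            )
            _write("smoothed_spectra.tsv", smooth_rows)

            result = pointwise_group_ftest(
                spectra, cov_df, grid=grid, alpha=config.alpha
            )
            _write(
                "fcurve.tsv",
                pd.DataFrame(
                    {
                        "frequency_hz": result.frequencies,
                        "F": result.f_stat,
                        "F_crit": result.f_crit,
                        "significant": result.significant,
                    }
                ),
            )
            band = primary_band(result)
            tcurves = []
            group_names = sorted(cov_df["group"].unique())
            for ga, gb in itertools.combinations(group_names, 2):
                tt = pairwise_pointwise_ttest(
                    spectra,
                    cov_df,
                    (ga, gb),
                    band=band,
                    grid=grid,
                    alpha=config.alpha,
                    n_comparisons=config.bonferroni_m,
                )
                tcurves.append(
                    pd.DataFrame(
                        {
                            "pair": f"{ga} vs {gb}",
                            "frequency_hz": tt["frequencies"],
                            "t": tt["t"],
                            "crit_uncorrected": tt["crit_uncorrected"],
                            "crit_bonferroni": tt["crit_bonferroni"],
                        }
                    )
                )
            _write("tcurves.tsv", pd.concat(tcurves, ignore_index=True))
            _write("band_summary.tsv", summarize_band(result, spectra, cov_df))
            manifest["stages"]["fda"] = {
                "bands": result.bands,
                "f_crit": result.f_crit,
            }

        manifest["complete"] = True
    except Exception as exc:
        manifest["error"] = {"stage": current_stage, "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise PipelineError(current_stage, str(exc)) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
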