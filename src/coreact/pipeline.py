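"""End-to-end pipeline driver reproducing the analysis flow on one animal.

Order per animal: ensemble assignment -> burst detection -> ensemble
participation -> co-participation (burst / non-burst, and per sleep state
when EEG/EMG is present) -> time-lagged cross-correlations -> offline
reactivation time courses -> recall reactivation index -> population-vector
correlations -> SVM context decoding -> chemotagging. Stages that lack their
required sessions are skipped with a recorded reason.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from coreact import bursts as bursts_mod
from coreact import chemotag as chemotag_mod
from coreact import coactivity as coact_mod
from coreact import decoding as decoding_mod
from coreact import reactivation as react_mod
from coreact import sleep as sleep_mod
from coreact.core import ExperimentSet, MatchTable, assign_ensembles

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters, serialized verbatim into every output bundle."""

    burst_z: float = 2.0
    cell_z: float = 2.0
    ensemble_z: float = 2.0
    epoch_s: float = 6.0
    theta_band: tuple = (5.0, 9.0)
    delta_band: tuple = (0.5, 4.0)
    crosscorr_bin_s: float = 120.0
    max_lag_frames: int = 5
    recall_bin_s: float = 30.0
    offline_bin_s: float = 60.0
    encoding_pv_bin_s: float = 30.0
    svm_repeats: int = 50
    train_frac: float = 0.5
    chemotag_top_frac: float = 0.10
    chemotag_window_min: tuple = (10.0, 40.0)
    chemotag_prominence: float = 0.3
    peri_burst_window_s: float = 5.0
    shuffle_n: int = 500
    nonburst_framewise: bool = False
    seed: int = 0

    def param_hash(self) -> str:
        blob = json.dumps(
            {k: list(v) if isinstance(v, tuple) else v
             for k, v in dataclasses.asdict(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _empty_table(session: str, other: str) -> MatchTable:
    return MatchTable(session, other, [])


def run_pipeline(
    exp: ExperimentSet, config: PipelineConfig | None = None
) -> dict:
    """Run every applicable analysis stage on one animal's experiment.

    Returns a result bundle: per-stage result objects plus a ``report`` dict
    holding the config, parameter hash, seed, warnings and skip reasons.
    Idempotent under a fixed seed; inputs are never mutated.
    """
    config = config or PipelineConfig()
    report = {
        "group_label": exp.group_label,
        "config": dataclasses.asdict(config),
        "param_hash": config.param_hash(),
        "seed": config.seed,
        "warnings": [],
        "skipped": {},
    }
    results: dict = {"report": report}

    def warn(msg: str) -> None:
        logger.warning(msg)
        report["warnings"].append(msg)

    def have(*names: str) -> bool:
        return all(n in exp.sessions for n in names)

    def table(a: str, b: str) -> MatchTable | None:
        try:
            return exp.match_table(a, b)
        except KeyError:
            return None

    # ---- ensemble assignment --------------------------------------------
    assignments: dict = {}
    for offline in ("offline1", "offline2"):
        if not have(offline):
            report["skipped"][f"assignment:{offline}"] = "session missing"
            continue
        mt_n = table(offline, "neutral_encoding")
        mt_a = table(offline, "aversive_encoding")
        if mt_n is None:
            report["skipped"][f"assignment:{offline}"] = "no neutral match table"
            continue
        if mt_a is None:
            mt_a = _empty_table(offline, "aversive_encoding")
        assignments[offline] = assign_ensembles(
            offline, exp.sessions[offline].matrix.cell_ids.tolist(),
            mt_n, mt_a,
        )
    results["assignments"] = assignments

    # ---- bursts and participation ---------------------------------------
    burst_results: dict = {}
    for offline, assignment in assignments.items():
        rec = exp.sessions[offline]
        trace = bursts_mod.population_trace(rec.matrix)
        catalog = bursts_mod.detect_bursts(trace, config.burst_z)
        part = bursts_mod.cell_participation(rec.matrix, catalog, config.cell_z)
        summary = bursts_mod.ensemble_participation(
            part, rec.matrix.cell_ids, assignment
        )
        if summary.empty:
            warn(f"{offline}: no burst events detected")
        peri = bursts_mod.peri_burst_locomotion(
            rec.locomotion, rec.locomotion_timestamps, catalog,
            rec.matrix.timestamps, config.peri_burst_window_s,
        )
        burst_results[offline] = {
            "catalog": catalog,
            "participation": part,
            "summary": summary,
            "peri_locomotion": peri,
        }
    results["bursts"] = burst_results

    # ---- co-participation and cross-correlations (offline2) -------------
    if "offline2" in assignments:
        rec = exp.sessions["offline2"]
        assignment = assignments["offline2"]
        catalog = burst_results["offline2"]["catalog"]
        traces = coact_mod.ensemble_mean_traces(rec.matrix, assignment)
        participation = coact_mod.ensemble_event_participation(
            traces, catalog, config.ensemble_z
        )
        results["coparticipation_burst"] = coact_mod.coparticipation_fractions(
            participation
        )
        if config.nonburst_framewise:
            results["coparticipation_nonburst"] = (
                coact_mod.frame_exceedance_fractions(
                    traces, catalog, config.ensemble_z
                )
            )
        else:
            results["coparticipation_nonburst"] = (
                coact_mod.nonburst_coparticipation(
                    traces, catalog, config.ensemble_z
                )
            )
        xcorr = {}
        for other in ("neutral", "aversive"):
            if "overlap" in traces and other in traces:
                xcorr[("overlap", other)] = coact_mod.lagged_crosscorr(
                    traces["overlap"], traces[other],
                    rec.matrix.frame_rate, config.crosscorr_bin_s,
                    config.max_lag_frames,
                )
        results["crosscorr"] = xcorr

        # sleep-state-resolved co-participation
        if rec.eeg_emg is not None:
            hyp = sleep_mod.score_sleep(
                rec.eeg_emg, config.epoch_s,
                seed=config.stage_seed("sleep"),
            )
            states = sleep_mod.assign_states_to_frames(
                hyp, rec.matrix.timestamps
            )
            results["hypnogram"] = hyp
            results["sleep_features"] = sleep_mod.sleep_features(hyp)
            results["coparticipation_by_state"] = (
                sleep_mod.coparticipation_by_state(
                    traces, catalog, states, config.ensemble_z
                )
            )
        else:
            report["skipped"]["sleep"] = "no EEG/EMG record"

        results["shuffle_null"] = bursts_mod.shuffle_null(
            rec.matrix, config.shuffle_n,
            seed=config.stage_seed("shuffle"), threshold_z=config.burst_z,
        )

        # offline reactivation time course
        results["offline_activity"] = react_mod.offline_ensemble_activity(
            rec.matrix, assignment, config.offline_bin_s
        )

    # ---- recall reactivation index --------------------------------------
    frac = {}
    for sess in ("recall_neutral", "recall_novel"):
        mt_n = table(sess, "neutral_encoding")
        mt_a = table(sess, "aversive_encoding")
        if have(sess) and mt_n is not None and mt_a is not None:
            frac[sess] = react_mod.recall_reactivation_fractions(
                exp.sessions[sess].matrix, sess, mt_n, mt_a
            )
        else:
            report["skipped"][f"reactivation:{sess}"] = (
                "session or match table missing"
            )
    if len(frac) == 2:
        results["reactivation_index"] = react_mod.reactivation_index(
            frac["recall_neutral"], frac["recall_novel"]
        )

    # ---- population-vector correlations ----------------------------------
    pv = {}
    for enc, rec_name in (
        ("neutral_encoding", "recall_neutral"),
        ("aversive_encoding", "recall_aversive"),
    ):
        mt = table(enc, rec_name)
        if have(enc, rec_name) and mt is not None:
            pv[(enc, rec_name)] = react_mod.encoding_recall_pv_corr(
                exp.sessions[enc].matrix, exp.sessions[rec_name].matrix,
                mt, enc, rec_name, config.recall_bin_s,
            )
    results["encoding_recall_pv"] = pv
    mt_enc = table("neutral_encoding", "aversive_encoding")
    if have("neutral_encoding", "aversive_encoding") and mt_enc is not None:
        results["encoding_pv"] = react_mod.encoding_pv_matrix(
            exp.sessions["neutral_encoding"].matrix,
            exp.sessions["aversive_encoding"].matrix,
            mt_enc, "neutral_encoding", "aversive_encoding",
            config.encoding_pv_bin_s,
        )
        dataset = decoding_mod.build_context_dataset(
            exp.sessions["neutral_encoding"].matrix,
            exp.sessions["aversive_encoding"].matrix,
            mt_enc, "neutral_encoding", "aversive_encoding",
        )
        results["decoding"] = decoding_mod.svm_decode(
            dataset, config.train_frac, config.svm_repeats,
            seed=config.stage_seed("svm"),
        )
        results["decoding_shuffled"] = decoding_mod.shuffled_control(
            dataset, config.train_frac, config.svm_repeats,
            seed=config.stage_seed("svm_shuffle"),
        )
    else:
        report["skipped"]["decoding"] = "encoding sessions or table missing"
        dataset = None

    # ---- chemotagging -----------------------------------------------------
    if have("chemotag"):
        ranking = chemotag_mod.rank_chemotag(
            exp.sessions["chemotag"].matrix,
            config.chemotag_window_min, config.chemotag_prominence,
            top_frac=config.chemotag_top_frac,
        )
        results["chemotag_ranking"] = ranking
        mt_off = table("chemotag", "offline2")
        if mt_off is not None and "offline2" in assignments:
            propagated = chemotag_mod.propagate_labels(
                ranking, mt_off, "chemotag", "offline2",
                exp.sessions["offline2"].matrix.cell_ids.tolist(),
            )
            results["chemotag_offline2"] = propagated
            results["ensemble_composition"] = chemotag_mod.ensemble_composition(
                assignments["offline2"], propagated.flags
            )
        if dataset is not None:
            mt_chem_n = table("chemotag", "neutral_encoding")
            if mt_chem_n is not None:
                enc_ranking = chemotag_mod.propagate_labels(
                    ranking, mt_chem_n, "chemotag", "neutral_encoding",
                    dataset.cell_ids.tolist(),
                )
                results["decoding_by_chemotag"] = (
                    decoding_mod.decode_by_chemotag_fraction(
                        dataset, enc_ranking.ranks, config.train_frac,
                        config.svm_repeats,
                        seed=config.stage_seed("svm_chemotag"),
                    )
                )
    else:
        report["skipped"]["chemotag"] = "session missing"

    return results


# ---------------------------------------------------------------------------
# tidy serialization
# ---------------------------------------------------------------------------


def results_to_tables(results: dict, mouse: str = "mouse") -> dict:
    """Flatten a result bundle into tidy DataFrames keyed by stage."""
    ph = results["report"]["param_hash"]
    tables: dict = {}
    rows = []
    for offline, res in results.get("bursts", {}).items():
        cat = res["catalog"]
        for (s, p, e) in cat.events:
            rows.append({
                "mouse": mouse, "session": offline, "stage": "bursts",
                "start": int(s), "peak": int(p), "end": int(e),
                "peak_z": float(cat.population_trace[p]), "param_hash": ph,
            })
    tables["burst_events"] = pd.DataFrame(rows)

    rows = []
    for offline, res in results.get("bursts", {}).items():
        for name, fracv in res["summary"].ensemble_fractions.items():
            rows.append({
                "mouse": mouse, "session": offline,
                "stage": "ensemble_participation", "ensemble": name,
                "fraction": fracv, "param_hash": ph,
            })
    tables["ensemble_participation"] = pd.DataFrame(rows)

    rows = []
    for period in ("burst", "nonburst"):
        summ = results.get(f"coparticipation_{period}")
        if summ is None or summ.empty:
            continue
        for name, v in summ.independent.items():
            rows.append({
                "mouse": mouse, "session": "offline2", "stage": "coparticipation",
                "period": period, "kind": "independent", "who": name,
                "fraction": v, "param_hash": ph,
            })
        for (a, b), v in summ.pairwise.items():
            rows.append({
                "mouse": mouse, "session": "offline2", "stage": "coparticipation",
                "period": period, "kind": "pairwise", "who": f"{a}x{b}",
                "fraction": v, "param_hash": ph,
            })
    by_state = results.get("coparticipation_by_state", {})
    for state in ("wake", "NREM", "REM"):
        summ = by_state.get(state)
        if summ is None or summ.empty:
            continue
        for (a, b), v in summ.pairwise.items():
            rows.append({
                "mouse": mouse, "session": "offline2", "stage": "coparticipation",
                "period": f"burst_{state}", "kind": "pairwise",
                "who": f"{a}x{b}", "fraction": v, "param_hash": ph,
            })
    tables["coparticipation"] = pd.DataFrame(rows)

    rows = []
    for (a, b), r in results.get("crosscorr", {}).items():
        rows.append({
            "mouse": mouse, "session": "offline2", "stage": "crosscorr",
            "pair": f"{a}x{b}", "mean_max_corr": r["mean_max_corr"],
            "skipped_bins": r["skipped_bins"], "param_hash": ph,
        })
    tables["crosscorr"] = pd.DataFrame(rows)

    rows = []
    ri = results.get("reactivation_index")
    if ri is not None:
        for name in ri.index:
            rows.append({
                "mouse": mouse, "stage": "reactivation_index",
                "ensemble": name,
                "neutral_recall": ri.neutral_recall[name],
                "novel_recall": ri.novel_recall[name],
                "index": ri.index[name], "param_hash": ph,
            })
    tables["reactivation_index"] = pd.DataFrame(rows)

    rows = []
    for key, label in (
        ("decoding", "real"), ("decoding_shuffled", "shuffled"),
    ):
        r = results.get(key)
        if r is not None:
            rows.append({
                "mouse": mouse, "stage": "decoding", "labels": label,
                "mean_accuracy": r.mean_accuracy,
                "n_repeats": len(r.accuracies), "param_hash": ph,
            })
    tables["decoding"] = pd.DataFrame(rows)
    return tables


def write_results(results: dict, outdir: Path, mouse: str = "mouse") -> None:
    """Write tidy CSVs plus the JSON run report under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in results_to_tables(results, mouse).items():
        df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.10g")
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(results["report"], fh, indent=2, sort_keys=True, default=str)
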